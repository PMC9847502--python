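"""Statistics for the orthogonal siRNA validation screen.

Each candidate gene is knocked down with three independent siRNAs; the
per-gene effect under a growth factor is the mean of the three siRNA-level
mean proliferation rates, normalized to the no-siRNA control (1 = no
effect). Significance is assessed per growth factor by one-way ANOVA across
gene groups plus control, followed by many-to-one comparison of each gene
against the control (Dunnett's procedure by default; Holm-adjusted Welch
t-tests as a fallback). Receptor-targeting siRNAs additionally get a
specificity call: the knockdown should depress proliferation under the
cognate growth factor only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

__all__ = [
    "SirnaMeasurement",
    "RECEPTOR_COGNATE_MAP",
    "normalize_and_average",
    "test_effects",
    "receptor_specificity",
]

#: Expressed receptor for each growth factor used in the assay.
RECEPTOR_COGNATE_MAP = {"FGFR1": "FGF2", "VEGFR2": "VEGFA", "MET": "HGF"}


@dataclass(frozen=True)
class SirnaMeasurement:
    """Replicate proliferation rates for one (gene, siRNA, growth factor)."""

    gene: str
    sirna_index: int
    growth_factor: str
    k_p: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.sirna_index not in (1, 2, 3):
            raise ValidationError("sirna_index must be 1, 2 or 3")
        if len(self.k_p) < 1:
            raise ValidationError("need at least one replicate")

    @property
    def mean_kp(self) -> float:
        return float(np.mean(self.k_p))


def normalize_and_average(
    measurements: Sequence[SirnaMeasurement],
    control_kp: Mapping[str, float],
    n_sirnas_expected: int = 3,
) -> pd.DataFrame:
    """Per-gene normalized knockdown effects.

    effect(gene, gf) = mean over siRNAs of (siRNA mean k_p / control k_p);
    the s.e.m. is taken across the siRNA-level means (the siRNA, not the
    well, is the unit of analysis). A gene with fewer than the expected
    number of siRNAs is averaged over those available and flagged.

    Returns columns: gene, growth_factor, effect, sem, n_sirnas, complete.
    """
    rows = []
    keys = sorted({(m.gene, m.growth_factor) for m in measurements})
    for gene, gf in keys:
        if gf not in control_kp:
            raise ValidationError(f"no control k_p for growth factor {gf!r}")
        ctrl = control_kp[gf]
        if ctrl <= 0:
            raise ValidationError(
                f"control k_p for {gf!r} must be positive to normalize"
            )
        means = [
            m.mean_kp / ctrl
            for m in measurements
            if m.gene == gene and m.growth_factor == gf
        ]
        if len(means) < n_sirnas_expected:
            warnings.warn(
                f"{gene}/{gf}: only {len(means)} of {n_sirnas_expected} siRNAs "
                "present; averaging available ones",
                stacklevel=2,
            )
        sem = (
            float(np.std(means, ddof=1) / np.sqrt(len(means)))
            if len(means) > 1
            else 0.0
        )
        rows.append(
            {
                "gene": gene,
                "growth_factor": gf,
                "effect": float(np.mean(means)),
                "sem": sem,
                "n_sirnas": len(means),
                "complete": len(means) >= n_sirnas_expected,
            }
        )
    return pd.DataFrame(rows)


def test_effects(
    samples: Mapping[str, Sequence[float]],
    control: Sequence[float],
    method: str = "dunnett",
    alpha: float = 0.05,
    seed: int | None = 0,
) -> pd.DataFrame:
    """One-way ANOVA plus many-to-one comparisons against the control.

    ``samples`` maps each gene to its k_p observations (the chosen unit of
    analysis — siRNA-level means by convention); ``control`` holds the
    no-siRNA observations. Every group needs >= 2 values. The family-wise
    adjustment is Dunnett's many-to-one procedure (default) or Holm-adjusted
    Welch t-tests (``method="holm-welch"``). The ANOVA p-value is attached
    to every row.

    Returns columns: gene, p_adj, significant, method, anova_p.
    """
    genes = list(samples)
    if not genes:
        raise ValidationError("need at least one gene group")
    groups = [np.asarray(samples[g], float) for g in genes]
    ctrl = np.asarray(control, float)
    if any(len(g) < 2 for g in groups) or len(ctrl) < 2:
        raise ValidationError("every group needs at least two replicates")
    anova_p = float(stats.f_oneway(*groups, ctrl).pvalue)

    if method == "dunnett":
        rng = np.random.default_rng(seed)
        res = stats.dunnett(*groups, control=ctrl, random_state=rng)
        p_adj = np.asarray(res.pvalue, float)
    elif method == "holm-welch":
        from statsmodels.stats.multitest import multipletests

        raw = np.array(
            [stats.ttest_ind(g, ctrl, equal_var=False).pvalue for g in groups]
        )
        p_adj = multipletests(raw, method="holm")[1]
    else:
        raise ValidationError(f"unknown method {method!r}")

    return pd.DataFrame(
        {
            "gene": genes,
            "p_adj": p_adj,
            "significant": p_adj < alpha,
            "method": method,
            "anova_p": anova_p,
        }
    )


def receptor_specificity(
    effects: pd.DataFrame,
    receptor_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """On-target vs off-target contrast for receptor knockdowns.

    ``effects`` needs columns gene, growth_factor, effect, significant (the
    normalized effect table joined with the significance calls). A receptor
    is called specific when its knockdown is significantly reduced under the
    cognate growth factor and not significant under any other.

    Returns columns: receptor, cognate_gf, cognate_effect,
    noncognate_mean_effect, specific.
    """
    rmap = dict(receptor_map or RECEPTOR_COGNATE_MAP)
    receptors = [g for g in effects["gene"].unique() if g in rmap]
    unmapped = [
        g
        for g in effects["gene"].unique()
        if g not in rmap and g.upper().endswith(("R1", "R2", "MET"))
    ]
    rows = []
    for rec in receptors:
        gf = rmap[rec]
        sub = effects[effects["gene"] == rec]
        cog = sub[sub["growth_factor"] == gf]
        non = sub[sub["growth_factor"] != gf]
        if cog.empty:
            raise ValidationError(f"receptor {rec!r}: no cognate ({gf}) measurement")
        cognate_effect = float(cog["effect"].iloc[0])
        cognate_sig = bool(cog["significant"].iloc[0]) and cognate_effect < 1.0
        noncognate_sig = bool(non["significant"].any()) if not non.empty else False
        rows.append(
            {
                "receptor": rec,
                "cognate_gf": gf,
                "cognate_effect": cognate_effect,
                "noncognate_mean_effect": (
                    float(non["effect"].mean()) if not non.empty else np.nan
                ),
                "specific": cognate_sig and not noncognate_sig,
            }
        )
    if not rows:
        raise ValidationError(
            f"no mapped receptors among genes (unmapped candidates: {unmapped})"
        )
    return pd.DataFrame(rows)
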