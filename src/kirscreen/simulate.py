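"""Seeded synthetic proliferation screens with known ground truth.

Emulates a 384-well time-lapse proliferation screen of primary endothelial
cells: ~255 cells plated per well in a basal low-serum medium, growth factor
added after an attachment period, wells imaged every 2 h for 48 h. Cells are
quiescent at stimulation; a dose-dependent fraction commits to the cycle,
exits G0 after a random delay and divides once, producing a semi-synchronous
birth wave whose population birth rate rises around 20 h and peaks near
30 h after stimulation. Apoptotic death runs at a low basal rate, is
suppressed by growth factor, and is abolished by a caspase-inhibitor flag.

Kinase-inhibitor biochemistry is a panel of fractional residual activities
profiled at one reference concentration; screen doses are mapped by
single-site binding with the dissociation constant back-inferred from the
reference point. Inhibitors act on the phenotype through a ground-truth
weight vector over kinases: the commitment probability is multiplied by
``max(0, 1 - sum_k w_k * inhibition_k(dose))``, keeping the phenotype linear
in the weighted fractional inhibition that the downstream regression
assumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import MissingControlError, ValidationError
from .kinetics import WellTrajectory

__all__ = [
    "KinasePanel",
    "InhibitionMatrix",
    "GroundTruth",
    "SimConfig",
    "WellCondition",
    "ScreenDesign",
    "EXPRESSION_CUTOFF",
    "DEFAULT_DOSE_LADDER_UM",
    "DEFAULT_GF_DOSES_NG_ML",
    "generate_panel",
    "generate_inhibition_matrix",
    "generate_ground_truth",
    "inhibition_at_dose",
    "simulate_well",
    "simulate_screen",
    "simulate_sirna_screen",
    "screen_phenotypes_from_truth",
    "default_screen_design",
    "titration_design",
]

#: Expression threshold (arbitrary units) separating "expressed" kinases.
EXPRESSION_CUTOFF = 1.5

#: Six-point inhibitor dose ladder: 5 uM top, serial 3-fold dilution.
DEFAULT_DOSE_LADDER_UM = tuple(5.0 / 3.0**k for k in range(6))

#: Working growth-factor doses (ng/ml) used in the screen.
DEFAULT_GF_DOSES_NG_ML = {"FGF2": 1.25, "VEGFA": 20.0, "HGF": 20.0}


# ---------------------------------------------------------------------------
# Panels, inhibition biochemistry, ground truth
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KinasePanel:
    """Kinase identifiers with expression levels (arbitrary units, >= 0)."""

    kinase_ids: tuple[str, ...]
    expression: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "expression", np.asarray(self.expression, float))
        if len(set(self.kinase_ids)) != len(self.kinase_ids):
            raise ValidationError("kinase ids must be unique")
        if len(self.kinase_ids) != len(self.expression):
            raise ValidationError("ids and expression lengths differ")
        if np.any(self.expression < 0):
            raise ValidationError("expression must be nonnegative")

    def expressed_ids(self, cutoff: float = EXPRESSION_CUTOFF) -> tuple[str, ...]:
        return tuple(
            k for k, e in zip(self.kinase_ids, self.expression) if e >= cutoff
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"kinase_id": self.kinase_ids, "expression_au": self.expression}
        )


@dataclass(frozen=True)
class InhibitionMatrix:
    """Inhibitor x kinase fractional residual activities in [0, 1].

    ``assay_conc_uM`` is the single concentration at which the biochemical
    profiling was performed (default 1 uM).
    """

    inhibitor_ids: tuple[str, ...]
    kinase_ids: tuple[str, ...]
    residual: np.ndarray
    assay_conc_uM: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "residual", np.asarray(self.residual, float))
        if self.residual.shape != (len(self.inhibitor_ids), len(self.kinase_ids)):
            raise ValidationError("residual matrix shape mismatch")
        if np.any(self.residual < 0) or np.any(self.residual > 1):
            raise ValidationError("residual activities must lie in [0, 1]")
        if self.assay_conc_uM <= 0:
            raise ValidationError("assay concentration must be positive")

    def row(self, inhibitor_id: str) -> np.ndarray:
        try:
            i = self.inhibitor_ids.index(inhibitor_id)
        except ValueError:
            raise ValidationError(f"unknown inhibitor {inhibitor_id!r}") from None
        return self.residual[i]

    def subset_kinases(self, kinase_ids: Sequence[str]) -> "InhibitionMatrix":
        index = {k: j for j, k in enumerate(self.kinase_ids)}
        missing = [k for k in kinase_ids if k not in index]
        if missing:
            raise ValidationError(f"kinases not in matrix: {missing[:5]}")
        cols = [index[k] for k in kinase_ids]
        return InhibitionMatrix(
            self.inhibitor_ids,
            tuple(kinase_ids),
            self.residual[:, cols],
            self.assay_conc_uM,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.residual, index=list(self.inhibitor_ids), columns=list(self.kinase_ids)
        )


@dataclass(frozen=True)
class GroundTruth:
    """Per-growth-factor kinase effect weights plus the shared subset.

    ``weights[gf][kinase]`` >= 0 quantifies how strongly inhibiting that
    kinase reduces cycle commitment under that growth factor.
    """

    weights: Mapping[str, Mapping[str, float]]
    shared_kinases: tuple[str, ...]

    def __post_init__(self) -> None:
        for gf, w in self.weights.items():
            if any(v < 0 for v in w.values()):
                raise ValidationError(f"negative weight under {gf}")
            if not set(self.shared_kinases) <= set(w):
                raise ValidationError("shared kinases must appear in every map")

    @property
    def growth_factors(self) -> tuple[str, ...]:
        return tuple(self.weights)


def generate_panel(n_kinases: int, n_expressed: int, seed: int) -> KinasePanel:
    """Kinase panel with exactly ``n_expressed`` kinases at/above the cutoff.

    Expressed kinases get ``cutoff + lognormal`` levels, the rest uniform
    below the cutoff. Deterministic given the seed.
    """
    if not 0 <= n_expressed <= n_kinases:
        raise ValidationError("need 0 <= n_expressed <= n_kinases")
    rng = np.random.default_rng(seed)
    ids = tuple(f"K{i:04d}" for i in range(1, n_kinases + 1))
    expr = rng.uniform(0.0, EXPRESSION_CUTOFF, n_kinases)
    hot = rng.choice(n_kinases, size=n_expressed, replace=False)
    expr[hot] = EXPRESSION_CUTOFF + rng.lognormal(0.5, 1.0, n_expressed)
    return KinasePanel(ids, expr)


def generate_inhibition_matrix(
    panel: KinasePanel,
    n_inhibitors: int,
    hits_per_inhibitor: int,
    seed: int,
    hit_range: tuple[float, float] = (0.02, 0.2),
    weak_range: tuple[float, float] = (0.85, 1.0),
    assay_conc_uM: float = 1.0,
) -> InhibitionMatrix:
    """Inhibitor panel with designated strong hits and weak background.

    Each inhibitor strongly inhibits ``hits_per_inhibitor`` assigned kinases
    (residual drawn in ``hit_range``) and everything else weakly (residual in
    ``weak_range``). Hit sets are dealt from shuffled decks of the kinase
    list, so they collectively cover the panel whenever
    ``n_inhibitors * hits_per_inhibitor >= n_kinases``.
    """
    n_k = len(panel.kinase_ids)
    if n_k == 0:
        raise ValidationError("empty kinase panel")
    if n_inhibitors <= 0 or hits_per_inhibitor < 0:
        raise ValidationError("n_inhibitors must be positive, hits nonnegative")
    rng = np.random.default_rng(seed)
    inhibitor_ids = tuple(f"I{i:03d}" for i in range(1, n_inhibitors + 1))
    residual = rng.uniform(weak_range[0], weak_range[1], (n_inhibitors, n_k))
    if hits_per_inhibitor > 0:
        total = n_inhibitors * hits_per_inhibitor
        decks = [rng.permutation(n_k) for _ in range(math.ceil(total / n_k))]
        pool = np.concatenate(decks)[:total]
        for i in range(n_inhibitors):
            hits = np.unique(pool[i * hits_per_inhibitor : (i + 1) * hits_per_inhibitor])
            residual[i, hits] = rng.uniform(hit_range[0], hit_range[1], len(hits))
    residual = np.clip(residual, 0.0, 1.0)
    return InhibitionMatrix(inhibitor_ids, panel.kinase_ids, residual, assay_conc_uM)


def generate_ground_truth(
    panel: KinasePanel,
    growth_factors: Sequence[str],
    n_true_per_gf: int = 5,
    n_shared: int = 3,
    seed: int = 0,
    weight_range: tuple[float, float] = (0.5, 1.0),
    expression_cutoff: float = EXPRESSION_CUTOFF,
) -> GroundTruth:
    """Plant effect kinases: ``n_shared`` common to all growth factors plus
    distinct private kinases per growth factor, all drawn from the expressed
    subset so the regression can in principle recover them."""
    if n_shared > n_true_per_gf:
        raise ValidationError("n_shared cannot exceed n_true_per_gf")
    pool = list(panel.expressed_ids(expression_cutoff))
    need = n_shared + len(growth_factors) * (n_true_per_gf - n_shared)
    if need > len(pool):
        raise ValidationError("not enough expressed kinases for the ground truth")
    rng = np.random.default_rng(seed)
    picks = [str(k) for k in rng.choice(pool, size=need, replace=False)]
    shared = tuple(sorted(picks[:n_shared]))
    cursor = n_shared
    weights: dict[str, dict[str, float]] = {}
    for gf in growth_factors:
        private = picks[cursor : cursor + (n_true_per_gf - n_shared)]
        cursor += n_true_per_gf - n_shared
        ks = list(shared) + list(private)
        weights[gf] = {
            k: float(rng.uniform(*weight_range)) for k in ks
        }
    return GroundTruth(weights=weights, shared_kinases=shared)


def inhibition_at_dose(residual_at_ref, ref_conc, dose, eps: float = 1e-9):
    """Fractional inhibition at an arbitrary dose from one reference point.

    Single-site binding: the dissociation constant is back-inferred from the
    profiled residual activity ``r`` at the reference concentration,
    ``Kd = ref * r / (1 - r)`` (infinite when ``r`` is within ``eps`` of 1),
    and the inhibition at ``dose`` is ``dose / (dose + Kd)``. Non-decreasing
    in dose, 0 at dose 0, and equal to ``1 - r`` at the reference
    concentration. Accepts scalars or arrays (broadcast).
    """
    r = np.asarray(residual_at_ref, dtype=float)
    d = np.asarray(dose, dtype=float)
    if np.any(r < 0) or np.any(r > 1):
        raise ValidationError("residual activity must lie in [0, 1]")
    if not np.all(np.asarray(ref_conc) > 0):
        raise ValidationError("reference concentration must be positive")
    if np.any(d < 0):
        raise ValidationError("dose must be nonnegative")
    with np.errstate(divide="ignore", invalid="ignore"):
        kd = np.where(r < 1.0 - eps, ref_conc * r / (1.0 - r), np.inf)
        inh = np.where(
            np.isinf(kd),
            0.0,
            np.where((d == 0) & (kd == 0), 0.0, d / (d + kd)),
        )
    out = np.clip(inh, 0.0, 1.0)
    if np.isscalar(residual_at_ref) and np.isscalar(dose):
        return float(out)
    return out


# ---------------------------------------------------------------------------
# Well-level stochastic simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimConfig:
    """Assay geometry, kinetic parameters and noise toggles.

    Times are hours, rates per cell per hour, growth-factor doses in ng/ml
    and inhibitor doses in uM. Defaults reproduce the calibration targets:
    21 h mean cycle, ~8 h G0-exit delay, so first divisions land ~29 h after
    stimulation and the population birth rate peaks near 30 h.
    """

    n_cells_plated: int = 255
    imaging_interval: float = 2.0
    horizon: float = 48.0
    gf_addition_time: float = 24.0
    mean_cycle_length: float = 21.0
    cycle_length_sd: float = 2.5
    basal_death_rate: float = 0.002
    death_suppression: float = 0.9
    residual_death_rate: float = 0.0
    commitment_emax: float = 0.45
    commitment_ec50: float = 0.5
    g0_exit_delay_mean: float = 8.0
    g0_exit_delay_sd: float = 3.0
    toxicity_threshold: float = 0.8
    toxicity_rate: float = 0.05
    sirna_knockdown: float = 0.65
    detection_prob: float = 0.97
    count_error_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "imaging_interval",
            "horizon",
            "gf_addition_time",
            "mean_cycle_length",
            "commitment_ec50",
            "g0_exit_delay_mean",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        for name in (
            "death_suppression",
            "commitment_emax",
            "detection_prob",
            "sirna_knockdown",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1]")
        if self.basal_death_rate < 0 or self.residual_death_rate < 0:
            raise ValidationError("death rates must be nonnegative")


@dataclass(frozen=True)
class WellCondition:
    """Treatment descriptor for one well."""

    growth_factor: str | None = None
    gf_dose: float = 0.0
    inhibitor_id: str | None = None
    inhibitor_dose_uM: float = 0.0
    sirna_target: str | None = None
    sirna_index: int | None = None
    caspase_inhibitor: bool = False
    is_control: bool = False


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


def weighted_inhibition(
    condition: WellCondition,
    truth: GroundTruth | None,
    inhibition: InhibitionMatrix | None,
) -> float:
    """Ground-truth-weighted fractional inhibition for a treated well."""
    if (
        condition.inhibitor_id is None
        or condition.inhibitor_dose_uM <= 0
        or truth is None
        or inhibition is None
        or condition.growth_factor is None
    ):
        return 0.0
    if condition.growth_factor not in truth.weights:
        raise ValidationError(f"unknown growth factor {condition.growth_factor!r}")
    w_map = truth.weights[condition.growth_factor]
    row = inhibition.row(condition.inhibitor_id)
    inh = inhibition_at_dose(
        row, inhibition.assay_conc_uM, condition.inhibitor_dose_uM
    )
    idx = {k: j for j, k in enumerate(inhibition.kinase_ids)}
    eff = 0.0
    for k, w in w_map.items():
        j = idx.get(k)
        if j is not None:
            eff += w * float(inh[j])
    return eff


def simulate_well(
    config: SimConfig,
    condition: WellCondition,
    truth: GroundTruth | None = None,
    inhibition: InhibitionMatrix | None = None,
    seed=0,
    well_id: str = "W000",
    receptor_map: Mapping[str, str] | None = None,
) -> WellTrajectory:
    """Simulate one well and return counts on the imaging grid.

    Per-cell stochastic model, time measured from growth-factor addition:

    * a pre-imaging attachment period of ``gf_addition_time`` hours in basal
      medium thins the plated cells at the basal apoptotic rate;
    * at t=0 each survivor commits to the cycle with probability
      ``Emax * c / (c + EC50)``, multiplied by
      ``max(0, 1 - sum_k w_k inhibition_k(dose))`` for inhibitor wells and by
      ``(1 - knockdown * w)`` for siRNA wells (receptor siRNAs block the
      cognate growth factor entirely);
    * committed cells divide once at ``G0-exit delay (lognormal) + cycle
      length (normal)``; daughters are quiescent;
    * every live cell dies at ``basal * (1 - suppression * c/(c+EC50))``
      (zeroed by the caspase-inhibitor flag, leaving the residual
      non-apoptotic rate) plus a toxicity term when the weighted inhibition
      exceeds ``toxicity_threshold``.

    Detection noise thins cells persistently (each cell carries one
    detection flag), so observed M stays non-decreasing and observed
    ``N(t) + M(t) - N(0)`` still equals the observed cumulative births. The
    optional multiplicative count error (``count_error_cv``) perturbs N only
    and is off by default.

    The event log (exact birth/death times and noise-free counts) is
    attached as ``trajectory.events``.
    """
    rng = np.random.default_rng(seed)
    cfg = config

    c = condition.gf_dose if condition.growth_factor is not None else 0.0
    if truth is not None and condition.growth_factor is not None:
        if condition.growth_factor not in truth.weights:
            raise ValidationError(
                f"unknown growth factor {condition.growth_factor!r}"
            )
    frac = c / (c + cfg.commitment_ec50) if c > 0 else 0.0
    p_commit = cfg.commitment_emax * frac

    eff = weighted_inhibition(condition, truth, inhibition)
    if condition.inhibitor_id is not None and inhibition is not None:
        inhibition.row(condition.inhibitor_id)  # validates the id
    p_commit *= max(0.0, 1.0 - eff)

    if condition.sirna_target is not None:
        target = condition.sirna_target
        cognate = (receptor_map or {}).get(target)
        if cognate is not None:
            if cognate == condition.growth_factor:
                p_commit *= 1.0 - cfg.sirna_knockdown
        elif truth is not None and condition.growth_factor is not None:
            w = truth.weights[condition.growth_factor].get(target, 0.0)
            p_commit *= max(0.0, 1.0 - cfg.sirna_knockdown * min(w, 1.0))
    p_commit = min(max(p_commit, 0.0), 1.0)

    d_apoptotic = cfg.basal_death_rate * (1.0 - cfg.death_suppression * frac)
    d_pre = cfg.basal_death_rate
    if condition.caspase_inhibitor:
        d_apoptotic = 0.0
        d_pre = 0.0
    d_post = d_apoptotic + cfg.residual_death_rate
    d_pre += cfg.residual_death_rate
    if eff > cfg.toxicity_threshold:
        d_post += cfg.toxicity_rate * (eff - cfg.toxicity_threshold)

    n0 = cfg.n_cells_plated
    surv = rng.random(n0) < math.exp(-d_pre * cfg.gf_addition_time)
    n_start = int(surv.sum())

    death_f = (
        rng.exponential(1.0 / d_post, n_start)
        if d_post > 0
        else np.full(n_start, np.inf)
    )
    committed = rng.random(n_start) < p_commit
    n_com = int(committed.sum())
    mu, sigma = _lognormal_params(cfg.g0_exit_delay_mean, cfg.g0_exit_delay_sd)
    t_div = rng.lognormal(mu, sigma, n_com) + np.maximum(
        rng.normal(cfg.mean_cycle_length, cfg.cycle_length_sd, n_com), 1.0
    )
    divides = t_div < death_f[committed]
    birth_times = t_div[divides]
    death_d = (
        birth_times + rng.exponential(1.0 / d_post, len(birth_times))
        if d_post > 0
        else np.full(len(birth_times), np.inf)
    )

    grid = np.arange(0.0, cfg.horizon + 1e-9, cfg.imaging_interval)

    def _counts(n_base, births, deaths):
        b = np.sort(births[np.isfinite(births)])
        d = np.sort(deaths[np.isfinite(deaths)])
        births_cum = np.searchsorted(b, grid, side="right")
        deaths_cum = np.searchsorted(d, grid, side="right")
        return n_base + births_cum - deaths_cum, deaths_cum

    all_deaths = np.concatenate([death_f, death_d])
    true_n, true_m = _counts(n_start, birth_times, all_deaths)

    if cfg.detection_prob < 1.0:
        det_f = rng.random(n_start) < cfg.detection_prob
        det_d = rng.random(len(birth_times)) < cfg.detection_prob
        obs_deaths = np.concatenate([death_f[det_f], death_d[det_d]])
        obs_n, obs_m = _counts(int(det_f.sum()), birth_times[det_d], obs_deaths)
    else:
        obs_n, obs_m = true_n.copy(), true_m.copy()

    if cfg.count_error_cv > 0:
        obs_n = np.maximum(
            np.rint(obs_n * rng.normal(1.0, cfg.count_error_cv, len(obs_n))), 0
        )

    events = {
        "n_start": n_start,
        "birth_times": np.sort(birth_times),
        "death_times": np.sort(all_deaths[np.isfinite(all_deaths)]),
        "true_nuclei": true_n,
        "true_dead": true_m,
        "weighted_inhibition": eff,
        "p_commit": p_commit,
    }
    cond_meta = {
        "growth_factor": condition.growth_factor,
        "gf_dose_ng_ml": condition.gf_dose,
        "inhibitor_id": condition.inhibitor_id,
        "inhibitor_dose_uM": condition.inhibitor_dose_uM,
        "sirna_id": (
            f"{condition.sirna_target}_si{condition.sirna_index}"
            if condition.sirna_target
            else None
        ),
        "is_control": condition.is_control,
    }
    return WellTrajectory(
        well_id=well_id,
        times=grid,
        nuclei=obs_n.astype(float),
        dead=obs_m.astype(float),
        condition=cond_meta,
        events=events,
    )


# ---------------------------------------------------------------------------
# Screen-level simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScreenDesign:
    """Layout of an inhibitor (or titration) screen.

    One plate per (growth factor, replicate): treated wells for every
    inhibitor x dose (or every titration dose), plus vehicle-control wells
    sharing the plate's growth factor at its working dose. The default
    inhibitor design — 58 inhibitors x 6 doses + 36 controls — fills a
    384-well plate exactly.
    """

    growth_factors: Mapping[str, float]
    inhibitors: tuple[str, ...] = ()
    dose_ladder_uM: tuple[float, ...] = DEFAULT_DOSE_LADDER_UM
    n_replicates: int = 4
    controls_per_plate: int = 36
    gf_titration: Mapping[str, tuple[float, ...]] | None = None

    def conditions(self):
        """Yield (well_id, plate_id, replicate, WellCondition) rows."""
        for gf, working in self.growth_factors.items():
            for rep in range(1, self.n_replicates + 1):
                plate = f"P-{gf}-R{rep}"
                w = 0
                if self.gf_titration and gf in self.gf_titration:
                    for dose in self.gf_titration[gf]:
                        w += 1
                        yield (
                            f"{plate}-W{w:03d}",
                            plate,
                            rep,
                            WellCondition(growth_factor=gf, gf_dose=dose),
                        )
                for inh in self.inhibitors:
                    for dose in self.dose_ladder_uM:
                        w += 1
                        yield (
                            f"{plate}-W{w:03d}",
                            plate,
                            rep,
                            WellCondition(
                                growth_factor=gf,
                                gf_dose=working,
                                inhibitor_id=inh,
                                inhibitor_dose_uM=dose,
                            ),
                        )
                for _ in range(self.controls_per_plate):
                    w += 1
                    yield (
                        f"{plate}-W{w:03d}",
                        plate,
                        rep,
                        WellCondition(
                            growth_factor=gf, gf_dose=working, is_control=True
                        ),
                    )


def default_screen_design(
    inhibition: InhibitionMatrix,
    growth_factors: Mapping[str, float] | None = None,
    n_replicates: int = 4,
) -> ScreenDesign:
    """The standard inhibitor screen: every profiled inhibitor at the
    six-point ladder, four replicates, per-plate vehicle controls."""
    return ScreenDesign(
        growth_factors=dict(growth_factors or DEFAULT_GF_DOSES_NG_ML),
        inhibitors=tuple(inhibition.inhibitor_ids),
        n_replicates=n_replicates,
    )


def titration_design(
    growth_factors: Mapping[str, Sequence[float]],
    n_replicates: int = 8,
    working_doses: Mapping[str, float] | None = None,
) -> ScreenDesign:
    """Growth-factor dose-response design (no inhibitors)."""
    working = dict(working_doses or DEFAULT_GF_DOSES_NG_ML)
    return ScreenDesign(
        growth_factors={gf: working.get(gf, max(d)) for gf, d in growth_factors.items()},
        inhibitors=(),
        n_replicates=n_replicates,
        gf_titration={gf: tuple(d) for gf, d in growth_factors.items()},
    )


def simulate_screen(
    config: SimConfig,
    design: ScreenDesign,
    truth: GroundTruth | None,
    inhibition: InhibitionMatrix | None,
    seed: int,
    receptor_map: Mapping[str, str] | None = None,
) -> tuple[list[WellTrajectory], pd.DataFrame]:
    """Simulate every well of a screen design.

    Returns the trajectories plus a platemap table (well_id, plate_id,
    growth_factor, gf_dose_ng_ml, inhibitor_id, inhibitor_dose_uM, sirna_id,
    replicate, is_control). Deterministic given the seed: per-well generators
    are spawned from one seed sequence.

    Raises :class:`MissingControlError` if any plate with treated wells has
    no vehicle-control well.
    """
    rows = list(design.conditions())
    if not rows:
        raise ValidationError("empty screen design")
    plates_with_treated = {p for _, p, _, c in rows if c.inhibitor_id is not None}
    plates_with_control = {p for _, p, _, c in rows if c.is_control}
    orphans = sorted(plates_with_treated - plates_with_control)
    if orphans:
        raise MissingControlError(f"plates without vehicle controls: {orphans}")

    children = np.random.SeedSequence(seed).spawn(len(rows))
    trajectories: list[WellTrajectory] = []
    platemap_rows = []
    for (well_id, plate, rep, cond), child in zip(rows, children):
        traj = simulate_well(
            config,
            cond,
            truth=truth,
            inhibition=inhibition,
            seed=child,
            well_id=well_id,
            receptor_map=receptor_map,
        )
        trajectories.append(traj)
        platemap_rows.append(
            {
                "well_id": well_id,
                "plate_id": plate,
                "growth_factor": cond.growth_factor,
                "gf_dose_ng_ml": cond.gf_dose,
                "inhibitor_id": cond.inhibitor_id,
                "inhibitor_dose_uM": cond.inhibitor_dose_uM,
                "sirna_id": traj.condition["sirna_id"],
                "replicate": rep,
                "is_control": cond.is_control,
            }
        )
    return trajectories, pd.DataFrame(platemap_rows)


def simulate_sirna_screen(
    config: SimConfig,
    genes: Sequence[str],
    truth: GroundTruth,
    seed: int,
    growth_factors: Mapping[str, float] | None = None,
    receptor_map: Mapping[str, str] | None = None,
    n_sirnas: int = 3,
    n_replicates: int = 4,
    controls_per_gf: int = 8,
) -> tuple[list[WellTrajectory], pd.DataFrame]:
    """Simulate the orthogonal siRNA validation screen.

    Each gene is targeted by ``n_sirnas`` independent siRNAs with
    ``n_replicates`` wells per growth factor; no-siRNA control wells share
    each plate. One plate per growth factor.
    """
    gfs = dict(growth_factors or DEFAULT_GF_DOSES_NG_ML)
    rows = []
    for gf, dose in gfs.items():
        plate = f"P-siRNA-{gf}"
        w = 0
        for gene in genes:
            for si in range(1, n_sirnas + 1):
                for rep in range(1, n_replicates + 1):
                    w += 1
                    rows.append(
                        (
                            f"{plate}-W{w:03d}",
                            plate,
                            rep,
                            WellCondition(
                                growth_factor=gf,
                                gf_dose=dose,
                                sirna_target=gene,
                                sirna_index=si,
                            ),
                        )
                    )
        for rep in range(1, controls_per_gf + 1):
            w += 1
            rows.append(
                (
                    f"{plate}-W{w:03d}",
                    plate,
                    rep,
                    WellCondition(growth_factor=gf, gf_dose=dose, is_control=True),
                )
            )
    children = np.random.SeedSequence(seed).spawn(len(rows))
    trajectories = []
    platemap_rows = []
    for (well_id, plate, rep, cond), child in zip(rows, children):
        traj = simulate_well(
            config,
            cond,
            truth=truth,
            inhibition=None,
            seed=child,
            well_id=well_id,
            receptor_map=receptor_map,
        )
        trajectories.append(traj)
        platemap_rows.append(
            {
                "well_id": well_id,
                "plate_id": plate,
                "growth_factor": cond.growth_factor,
                "gf_dose_ng_ml": cond.gf_dose,
                "inhibitor_id": None,
                "inhibitor_dose_uM": 0.0,
                "sirna_id": traj.condition["sirna_id"],
                "replicate": rep,
                "is_control": cond.is_control,
            }
        )
    return trajectories, pd.DataFrame(platemap_rows)


def screen_phenotypes_from_truth(
    truth: GroundTruth,
    inhibition: InhibitionMatrix,
    dose_ladder_uM: Sequence[float] = DEFAULT_DOSE_LADDER_UM,
    effect_scale: float = 0.02,
    noise_sd_frac: float = 0.2,
    seed: int = 0,
) -> pd.DataFrame:
    """Linear-model screen phenotypes with known generating coefficients.

    For each growth factor and (inhibitor, dose) the expected proliferation
    deficit is ``-effect_scale * sum_k w_k * inhibition_k(dose)`` — exactly
    the linear structure the kinome regression assumes — with additive
    Gaussian noise of standard deviation ``noise_sd_frac`` times the largest
    absolute expected effect for that growth factor. ``effect_scale`` is the
    per-hour rate loss at unit weighted inhibition (default 0.02/h, the
    scale of a strong screen hit).

    Returns the phenotype table (growth_factor, inhibitor_id, dose_uM,
    delta_kp, n_replicates).
    """
    rng = np.random.default_rng(seed)
    idx = {k: j for j, k in enumerate(inhibition.kinase_ids)}
    frames = []
    for gf, w_map in truth.weights.items():
        cols = [idx[k] for k in w_map if k in idx]
        w = np.array([w_map[k] for k in w_map if k in idx])
        signal_rows = []
        keys = []
        for i, inh_id in enumerate(inhibition.inhibitor_ids):
            inh = inhibition_at_dose(
                inhibition.residual[i, cols],
                inhibition.assay_conc_uM,
                np.asarray(dose_ladder_uM)[:, None],
            )
            signal_rows.append(-effect_scale * (inh * w).sum(axis=1))
            keys.extend((inh_id, d) for d in dose_ladder_uM)
        signal = np.concatenate(signal_rows)
        sd = noise_sd_frac * np.max(np.abs(signal)) if len(signal) else 0.0
        delta = signal + rng.normal(0.0, sd, len(signal))
        frames.append(
            pd.DataFrame(
                {
                    "growth_factor": gf,
                    "inhibitor_id": [k[0] for k in keys],
                    "dose_uM": [k[1] for k in keys],
                    "delta_kp": delta,
                    "n_replicates": 4,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
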