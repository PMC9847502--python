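"""End-to-end orchestration of the screen analysis.

Stages: simulate (synthetic screen with ground truth) -> rates (per-well
kinetics, plate-referenced phenotypes) -> kir (per-growth-factor rankings
and rank-sum intersection) -> sirna (orthogonal validation statistics) ->
dose-response (growth-factor titration summaries). Every stage writes CSV /
JSON artifacts into an output directory and records the seed and a
configuration hash in ``manifest.json``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io, kir, kinetics, simulate, sirna
from .errors import ConfigError, MissingDataError, ValidationError

log = logging.getLogger("kirscreen")

__all__ = [
    "PipelineConfig",
    "run_simulate",
    "run_rates",
    "run_kir",
    "run_sirna",
    "run_dose_response",
    "run_all",
    "summarize_dose_response",
]


@dataclass
class PipelineConfig:
    """Flat configuration with per-stage blocks.

    ``screen`` controls the synthetic generator (panel size, inhibitor
    count, planted truth); ``sim`` is the well-level kinetic model;
    ``kir`` the regression; ``estimator`` the rate-window conventions.
    """

    seed: int = 0
    sim: simulate.SimConfig = field(default_factory=simulate.SimConfig)
    kir: kir.KirConfig = field(default_factory=kir.KirConfig)
    n_kinases: int = 369
    n_expressed: int = 200
    n_inhibitors: int = 58
    hits_per_inhibitor: int = 7
    n_true_per_gf: int = 5
    n_shared: int = 3
    growth_factors: dict = field(
        default_factory=lambda: dict(simulate.DEFAULT_GF_DOSES_NG_ML)
    )
    n_replicates: int = 4
    gf_titration: dict | None = None
    sirna_genes: list | None = None
    sirna_n_replicates: int = 4
    window: tuple | None = None
    nbar_convention: str = "endpoint_mean"

    @classmethod
    def from_yaml(cls, path, seed_override: int | None = None) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw, seed_override)

    @classmethod
    def from_dict(cls, raw: dict, seed_override: int | None = None) -> "PipelineConfig":
        try:
            sim_cfg = simulate.SimConfig(**raw.pop("sim", {}))
            kir_cfg = kir.KirConfig(**raw.pop("kir", {}))
            cfg = cls(sim=sim_cfg, kir=kir_cfg, **raw)
        except (TypeError, ValidationError) as exc:
            raise ConfigError(str(exc)) from exc
        if cfg.window is not None:
            cfg.window = tuple(cfg.window)
        if seed_override is not None:
            cfg.seed = seed_override
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _outdir(outdir) -> Path:
    p = Path(outdir)
    p.mkdir(parents=True, exist_ok=True)
    return p


def _update_manifest(outdir: Path, cfg: PipelineConfig, stage: str, extra: dict) -> None:
    path = outdir / "manifest.json"
    manifest = json.loads(path.read_text()) if path.exists() else {}
    manifest["seed"] = cfg.seed
    manifest["config_hash"] = cfg.config_hash
    manifest.setdefault("stages", {})[stage] = extra
    io.write_json(manifest, path)


def _timed(stage):
    def deco(fn):
        def wrapper(cfg, outdir, *a, **kw):
            t0 = time.perf_counter()
            log.info("stage %s: start", stage)
            out = fn(cfg, outdir, *a, **kw)
            log.info("stage %s: done in %.1fs", stage, time.perf_counter() - t0)
            return out

        wrapper.__name__ = fn.__name__
        return wrapper

    return deco


@_timed("simulate")
def run_simulate(cfg: PipelineConfig, outdir) -> dict:
    """Generate panel, inhibition biochemistry, truth and all well counts."""
    out = _outdir(outdir)
    ss = np.random.SeedSequence(cfg.seed)
    s_panel, s_inh, s_truth, s_screen = [
        int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(4)
    ]
    panel = simulate.generate_panel(cfg.n_kinases, cfg.n_expressed, s_panel)
    inhibition = simulate.generate_inhibition_matrix(
        panel, cfg.n_inhibitors, cfg.hits_per_inhibitor, s_inh
    )
    truth = simulate.generate_ground_truth(
        panel,
        list(cfg.growth_factors),
        n_true_per_gf=cfg.n_true_per_gf,
        n_shared=cfg.n_shared,
        seed=s_truth,
        expression_cutoff=cfg.kir.expression_cutoff,
    )
    if cfg.n_inhibitors > 0:
        design = simulate.default_screen_design(
            inhibition, cfg.growth_factors, cfg.n_replicates
        )
    else:
        design = simulate.titration_design(
            cfg.gf_titration
            or {gf: (d,) for gf, d in cfg.growth_factors.items()},
            n_replicates=cfg.n_replicates,
            working_doses=cfg.growth_factors,
        )
    if cfg.gf_titration and cfg.n_inhibitors > 0:
        design = dataclasses.replace(
            design, gf_titration={g: tuple(v) for g, v in cfg.gf_titration.items()}
        )
    trajectories, platemap = simulate.simulate_screen(
        cfg.sim, design, truth, inhibition, s_screen
    )
    io.write_counts(trajectories, out / "counts.csv")
    io.write_platemap(platemap, out / "platemap.csv")
    io.write_inhibition(inhibition, out / "inhibition.csv")
    io.write_expression(panel, out / "expression.csv")
    io.write_truth(truth, out / "truth.json")
    summary = {
        "n_wells": len(trajectories),
        "n_plates": int(platemap["plate_id"].nunique()),
        "growth_factors": list(cfg.growth_factors),
        "n_inhibitors": cfg.n_inhibitors,
    }
    _update_manifest(out, cfg, "simulate", summary)
    return summary


@_timed("rates")
def run_rates(cfg: PipelineConfig, outdir) -> dict:
    """Per-well rate estimates and plate-referenced phenotypes."""
    out = _outdir(outdir)
    platemap = io.read_platemap(out / "platemap.csv")
    trajectories = io.read_counts(out / "counts.csv", platemap)
    known = set(platemap["well_id"])
    orphan = [t.well_id for t in trajectories if t.well_id not in known]
    if orphan:
        raise ValidationError(f"wells in counts missing from platemap: {orphan[:5]}")
    rates = kinetics.rates_table(
        trajectories, window=cfg.window, nbar_convention=cfg.nbar_convention
    )
    rates.to_csv(out / "rates.csv", index=False)
    has_inhibitors = platemap["inhibitor_id"].notna().any()
    summary = {"n_wells": len(rates)}
    if has_inhibitors:
        phen = kinetics.phenotype_table(rates, platemap)
        phen.to_csv(out / "phenotypes.csv", index=False)
        summary["n_phenotype_rows"] = len(phen)
    _update_manifest(out, cfg, "rates", summary)
    return summary


@_timed("kir")
def run_kir(cfg: PipelineConfig, outdir) -> dict:
    """Expression filter, per-growth-factor elastic net, intersection."""
    out = _outdir(outdir)
    phen_path = out / "phenotypes.csv"
    if not phen_path.exists():
        raise MissingDataError("phenotypes.csv not found; run the rates stage first")
    phenotypes = pd.read_csv(phen_path)
    inhibition = io.read_inhibition(out / "inhibition.csv")
    panel = io.read_expression(out / "expression.csv")
    filtered = kir.filter_by_expression(inhibition, panel, cfg.kir.expression_cutoff)
    rankings = []
    diagnostics = {}
    for gf in cfg.growth_factors:
        if not (phenotypes["growth_factor"] == gf).any():
            raise MissingDataError(f"no phenotype rows for growth factor {gf!r}")
        design = kir.build_design(
            filtered, sorted(phenotypes["dose_uM"].unique()), phenotypes, gf
        )
        ranking = kir.fit_kir(design, cfg.kir, seed=cfg.seed)
        ranking.to_frame().to_csv(out / f"ranking_{gf}.csv", index=False)
        rankings.append(ranking)
        diagnostics[gf] = ranking.diagnostics
    intersection = kir.intersect_rank_sum(rankings)
    intersection.to_frame().to_csv(out / "intersection.csv", index=False)
    io.write_json(diagnostics, out / "kir_diagnostics.json")
    summary = {
        "n_selected": {r.growth_factor: len(r.entries) for r in rankings},
        "n_intersection": len(intersection.kinases),
    }
    if (out / "truth.json").exists():
        truth = io.read_truth(out / "truth.json")
        report = kir.recovery_metrics(rankings, intersection, truth)
        io.write_json(report, out / "recovery.json")
        summary["all_shared_recovered"] = report["all_shared_recovered"]
    _update_manifest(out, cfg, "kir", summary)
    return summary


@_timed("sirna")
def run_sirna(cfg: PipelineConfig, outdir) -> dict:
    """Simulate and analyse the siRNA validation screen.

    Genes default to the intersection kinases (if the kir stage ran) plus
    the three growth-factor receptors.
    """
    out = _outdir(outdir)
    truth = io.read_truth(out / "truth.json")
    genes = list(cfg.sirna_genes or [])
    if not genes and (out / "intersection.csv").exists():
        inter = pd.read_csv(out / "intersection.csv")
        genes = list(inter["kinase_id"].head(8))
    if not genes:
        genes = sorted(truth.shared_kinases)
    genes = genes + list(sirna.RECEPTOR_COGNATE_MAP)
    trajs, platemap = simulate.simulate_sirna_screen(
        cfg.sim,
        genes,
        truth,
        seed=int(np.random.SeedSequence((cfg.seed, 17)).generate_state(1)[0] % 2**31),
        growth_factors=cfg.growth_factors,
        receptor_map=sirna.RECEPTOR_COGNATE_MAP,
        n_replicates=cfg.sirna_n_replicates,
    )
    rates = kinetics.rates_table(
        trajs, window=cfg.window, nbar_convention=cfg.nbar_convention
    )
    merged = rates.merge(platemap, on="well_id")
    results = analyze_sirna_screen(merged)
    results.to_csv(out / "sirna_results.csv", index=False)
    spec = sirna.receptor_specificity(results)
    spec.to_csv(out / "sirna_receptor_specificity.csv", index=False)
    summary = {
        "n_genes": len(genes),
        "n_significant": int(results["significant"].sum()),
        "receptors_specific": int(spec["specific"].sum()),
    }
    _update_manifest(out, cfg, "sirna", summary)
    return summary


def analyze_sirna_screen(merged: pd.DataFrame, method: str = "dunnett") -> pd.DataFrame:
    """Normalized effects + many-to-one significance from a rates/platemap join.

    ``merged`` needs columns k_p, growth_factor, sirna_id (``gene_siN``),
    is_control. The siRNA-level mean is the unit of analysis.
    """
    results = []
    for gf, sub in merged.groupby("growth_factor"):
        ctrl = sub[sub["is_control"]]["k_p"].to_numpy()
        if len(ctrl) < 2:
            raise ValidationError(f"{gf}: need >= 2 control wells")
        targeted = sub[sub["sirna_id"].notna()].copy()
        if targeted.empty:
            continue
        split = targeted["sirna_id"].str.rsplit("_si", n=1)
        targeted["gene"] = split.str[0]
        targeted["sirna_index"] = split.str[1].astype(int)
        si_means = (
            targeted.groupby(["gene", "sirna_index"])["k_p"].mean().reset_index()
        )
        measurements = [
            sirna.SirnaMeasurement(
                gene=r.gene,
                sirna_index=int(r.sirna_index),
                growth_factor=gf,
                k_p=(float(r.k_p),),
            )
            for r in si_means.itertuples()
        ]
        effects = sirna.normalize_and_average(
            measurements, {gf: float(ctrl.mean())}
        )
        samples = {
            g: grp["k_p"].to_numpy() for g, grp in si_means.groupby("gene")
        }
        tests = sirna.test_effects(samples, ctrl, method=method)
        results.append(effects.merge(tests, on="gene"))
    if not results:
        raise ValidationError("no siRNA wells found")
    return pd.concat(results, ignore_index=True)


def summarize_dose_response(rates: pd.DataFrame, platemap: pd.DataFrame) -> pd.DataFrame:
    """Per-(growth factor, dose) means and dispersions of k_p, k_b, k_d.

    Uses untreated wells (no inhibitor, no siRNA), including vehicle
    controls; rows keyed uniquely by (growth_factor, gf_dose_ng_ml). The row
    means satisfy k_b = k_p + k_d exactly (the relation is linear).
    """
    merged = rates.merge(platemap, on="well_id")
    mask = merged["inhibitor_id"].isna()
    if "sirna_id" in merged:
        mask &= merged["sirna_id"].isna()
    tit = merged[mask]
    if tit.empty:
        import warnings

        warnings.warn("no titration wells found; empty dose-response table")
        return pd.DataFrame(
            columns=[
                "growth_factor",
                "gf_dose_ng_ml",
                "k_p",
                "k_b",
                "k_d",
                "k_p_sd",
                "n_wells",
            ]
        )
    out = (
        tit.groupby(["growth_factor", "gf_dose_ng_ml"])
        .agg(
            k_p=("k_p", "mean"),
            k_b=("k_b", "mean"),
            k_d=("k_d", "mean"),
            k_p_sd=("k_p", "std"),
            n_wells=("k_p", "size"),
        )
        .reset_index()
    )
    return out


@_timed("dose-response")
def run_dose_response(cfg: PipelineConfig, outdir) -> dict:
    out = _outdir(outdir)
    platemap = io.read_platemap(out / "platemap.csv")
    rates = pd.read_csv(out / "rates.csv")
    table = summarize_dose_response(rates, platemap)
    table.to_csv(out / "dose_response.csv", index=False)
    summary = {"n_rows": len(table)}
    _update_manifest(out, cfg, "dose-response", summary)
    return summary


def run_all(cfg: PipelineConfig, outdir) -> dict:
    """Full pipeline: simulate -> rates -> kir -> sirna -> dose-response."""
    out: dict = {}
    out["simulate"] = run_simulate(cfg, outdir)
    out["rates"] = run_rates(cfg, outdir)
    if cfg.n_inhibitors > 0:
        out["kir"] = run_kir(cfg, outdir)
    out["sirna"] = run_sirna(cfg, outdir)
    out["dose_response"] = run_dose_response(cfg, outdir)
    return out
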