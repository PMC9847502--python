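"""Plain-text serialization of the pipeline's tables.

Formats (CSV, UTF-8, comma-separated, '.' decimal; times in hours, rates
per hour, inhibitor doses in uM, growth-factor doses in ng/ml):

* counts: well_id, time_h, n_nuclei, n_dead (long format)
* platemap: well_id, plate_id, growth_factor, gf_dose_ng_ml, inhibitor_id,
  inhibitor_dose_uM, sirna_id, replicate, is_control
* inhibition matrix: inhibitors as rows, kinases as columns, residual
  activity; assay concentration carried in a leading comment line
* expression: kinase_id, expression_au
* ground truth: JSON
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .kinetics import WellTrajectory
from .simulate import GroundTruth, InhibitionMatrix, KinasePanel


def write_counts(trajectories: Sequence[WellTrajectory], path) -> None:
    frames = [
        pd.DataFrame(
            {
                "well_id": t.well_id,
                "time_h": t.times,
                "n_nuclei": t.nuclei,
                "n_dead": t.dead,
            }
        )
        for t in trajectories
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_counts(path, platemap: pd.DataFrame | None = None) -> list[WellTrajectory]:
    df = pd.read_csv(path)
    meta = None
    if platemap is not None:
        meta = platemap.set_index("well_id")
    out = []
    for well_id, sub in df.groupby("well_id", sort=False):
        cond = meta.loc[well_id].to_dict() if meta is not None else None
        out.append(
            WellTrajectory(
                well_id=str(well_id),
                times=sub["time_h"].to_numpy(),
                nuclei=sub["n_nuclei"].to_numpy(),
                dead=sub["n_dead"].to_numpy(),
                condition=cond,
            )
        )
    return out


def write_platemap(platemap: pd.DataFrame, path) -> None:
    platemap.to_csv(path, index=False)


def read_platemap(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"well_id", "plate_id", "growth_factor", "is_control"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"platemap missing columns: {sorted(missing)}")
    return df


def write_inhibition(matrix: InhibitionMatrix, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# assay_concentration_uM: {matrix.assay_conc_uM}\n")
        matrix.to_frame().rename_axis("inhibitor_id").to_csv(fh)


def read_inhibition(path) -> InhibitionMatrix:
    path = Path(path)
    assay = 1.0
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            assay = float(first.split(":")[1])
        else:
            fh.seek(0)
        df = pd.read_csv(fh, index_col=0)
    return InhibitionMatrix(
        inhibitor_ids=tuple(df.index.astype(str)),
        kinase_ids=tuple(df.columns.astype(str)),
        residual=df.to_numpy(dtype=float),
        assay_conc_uM=assay,
    )


def write_expression(panel: KinasePanel, path) -> None:
    panel.to_frame().to_csv(path, index=False)


def read_expression(path) -> KinasePanel:
    df = pd.read_csv(path)
    return KinasePanel(
        kinase_ids=tuple(df["kinase_id"].astype(str)),
        expression=df["expression_au"].to_numpy(dtype=float),
    )


def write_truth(truth: GroundTruth, path) -> None:
    payload = {
        "weights": {gf: dict(w) for gf, w in truth.weights.items()},
        "shared_kinases": list(truth.shared_kinases),
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_truth(path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        weights=payload["weights"],
        shared_kinases=tuple(payload["shared_kinases"]),
    )


def write_json(obj, path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_default))
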