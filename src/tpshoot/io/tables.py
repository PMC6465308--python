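"""Delimited-text tables, the shooting ledger and RC-model serialization.

All pipeline tables are tab-separated text with a header row and
locale-independent decimal parsing (C locale floats via pandas).
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ..errors import SchemaError
from ..rcopt import RCModel
from ..rigidbody import DomainMotion
from ..tps import ShootingRecord

DOMAIN_MOTION_COLUMNS = [
    "time", "dphi_in", "dphi_out", "dz_in", "dz_out", "dphi", "dz",
]
HYDRATION_COLUMNS = ["time", "n_access", "access_state", "n_clusters"]
LEDGER_COLUMNS = ["point_id", "seed", "outcome", "steps"]


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path, required: Sequence[str] | None = None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"table not found: {path}")
    df = pd.read_csv(path, sep="\t")
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise SchemaError(f"table {path} is missing column(s): {missing}")
    return df


def domain_motion_frame(motions: Sequence[DomainMotion]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "time": [m.time for m in motions],
            "dphi_in": [m.dphi_in for m in motions],
            "dphi_out": [m.dphi_out for m in motions],
            "dz_in": [m.dz_in for m in motions],
            "dz_out": [m.dz_out for m in motions],
            "dphi": [m.dphi for m in motions],
            "dz": [m.dz for m in motions],
        }
    )


def write_ledger(records: Sequence[dict], path) -> None:
    """Append-only shooting ledger; rows must be unique on (point_id, seed)."""
    df = pd.DataFrame(list(records))
    missing = [c for c in LEDGER_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"ledger rows missing field(s): {missing}")
    if df.duplicated(subset=["point_id", "seed"]).any():
        raise SchemaError("ledger has duplicate (point_id, seed) rows")
    write_table(df, path)


def read_ledger(path) -> pd.DataFrame:
    df = read_table(path, required=LEDGER_COLUMNS)
    if df.duplicated(subset=["point_id", "seed"]).any():
        raise SchemaError(f"ledger {path} has duplicate (point_id, seed) rows")
    return df


def write_records(records: Sequence[ShootingRecord], path) -> None:
    """Shooting-point descriptor/tally table (one row per point)."""
    if not records:
        raise SchemaError("no records to write")
    k = records[0].q.size
    data = {"point_id": [r.point_id for r in records]}
    for i in range(k):
        data[f"q{i + 1}"] = [float(r.q[i]) for r in records]
    data["n_to_A"] = [r.n_to_A for r in records]
    data["n_to_B"] = [r.n_to_B for r in records]
    data["n_uncommitted"] = [r.n_uncommitted for r in records]
    write_table(pd.DataFrame(data), path)


def read_records(path) -> list[ShootingRecord]:
    df = read_table(path, required=["point_id", "n_to_A", "n_to_B", "n_uncommitted"])
    qcols = sorted(
        (c for c in df.columns if c.startswith("q") and c[1:].isdigit()),
        key=lambda c: int(c[1:]),
    )
    if not qcols:
        raise SchemaError(f"records table {path} has no descriptor columns q1..qK")
    return [
        ShootingRecord(
            point_id=row["point_id"],
            q=np.array([row[c] for c in qcols], dtype=float),
            n_to_A=int(row["n_to_A"]),
            n_to_B=int(row["n_to_B"]),
            n_uncommitted=int(row["n_uncommitted"]),
        )
        for _, row in df.iterrows()
    ]


def write_rc_model(model: RCModel, path) -> None:
    """Human-readable key-value serialization of an RC model."""
    lines = ["# tpshoot reaction-coordinate model", f"n_descriptors\t{model.n_descriptors}"]
    u = model.uncertainties
    lines.append(
        "intercept\t{:.17g}\t{}".format(
            model.coefficients[0], "nan" if u is None else f"{u[0]:.17g}"
        )
    )
    for i, name in enumerate(model.descriptor_names):
        lines.append(
            "descriptor\t{}\t{:.17g}\t{:.17g}\t{:.17g}\t{}".format(
                name,
                model.means[i],
                model.scales[i],
                model.coefficients[i + 1],
                "nan" if u is None else f"{u[i + 1]:.17g}",
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_rc_model(path) -> RCModel:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"model file not found: {path}")
    names, means, scales, coefs, sds = [], [], [], [None], [None]
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if parts[0] == "intercept":
            coefs[0] = float(parts[1])
            sds[0] = float(parts[2])
        elif parts[0] == "descriptor":
            names.append(parts[1])
            means.append(float(parts[2]))
            scales.append(float(parts[3]))
            coefs.append(float(parts[4]))
            sds.append(float(parts[5]))
    if coefs[0] is None:
        raise SchemaError(f"model file {path} has no intercept line")
    sd_arr = np.array(sds, dtype=float)
    return RCModel(
        descriptor_names=names,
        coefficients=np.array(coefs, dtype=float),
        means=np.array(means, dtype=float),
        scales=np.array(scales, dtype=float),
        uncertainties=None if np.all(np.isnan(sd_arr)) else sd_arr,
    )
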