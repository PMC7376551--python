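"""CSV/JSON readers and writers with provenance headers.

There is no standard bioinformatics container for bioreactor physiology, so
artifacts are plain CSV with unit-suffixed column names and a short comment
header recording the package version, configuration hash and seed — enough
to re-run and reproduce the file.  Floats are written with 17 significant
digits so every writer/reader pair round-trips values exactly.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from . import __version__
from .chemostat import ChemostatRecord, GasMeasurement, RatesRecord
from .inference import BiomassSample, MsEstimate
from .pirt import PirtFit, RatePair
from .retentostat import Trajectory

__all__ = [
    "provenance_header",
    "write_csv",
    "read_csv",
    "write_chemostat_csv",
    "read_chemostat_csv",
    "write_samples_csv",
    "read_samples_csv",
    "write_rate_pairs_csv",
    "read_rate_pairs_csv",
    "write_rates_csv",
    "write_ms_csv",
    "read_ms_csv",
    "write_trajectory_csv",
    "read_trajectory_csv",
    "write_pirt_json",
    "read_pirt_json",
    "write_json",
]

FLOAT_FORMAT = "%.17g"

PathLike = Union[str, Path]


def provenance_header(
    config_hash: Optional[str] = None, seed: Optional[int] = None, **extra: object
) -> list[str]:
    fields = {"retenphys_version": __version__}
    if config_hash is not None:
        fields["config_hash"] = config_hash
    if seed is not None:
        fields["seed"] = seed
    fields.update(extra)
    return [f"# {key}: {value}" for key, value in fields.items()]


def write_csv(
    df: pd.DataFrame,
    path: PathLike,
    config_hash: Optional[str] = None,
    seed: Optional[int] = None,
    **extra: object,
) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = "\n".join(provenance_header(config_hash, seed, **extra))
    body = df.to_csv(index=False, float_format=FLOAT_FORMAT)
    path.write_text(header + "\n" + body)
    return path


def read_csv(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


# --- chemostat records -------------------------------------------------------

CHEMOSTAT_COLUMNS = [
    "strain", "replicate", "D_h-1", "feed_glucose_g_L", "residual_glucose_g_L",
    "cx_g_L", "gasflow_L_h", "yO2_in", "yO2_out", "yCO2_in", "yCO2_out",
    "broth_volume_L",
]


def write_chemostat_csv(
    records: Sequence[ChemostatRecord], path: PathLike, **prov: object
) -> Path:
    rows = []
    for r in records:
        row = {
            "strain": r.strain,
            "replicate": r.replicate,
            "D_h-1": r.dilution_rate,
            "feed_glucose_g_L": r.feed_glucose_g_L,
            "residual_glucose_g_L": (
                "BDL" if r.residual_below_detection else r.residual_glucose_g_L
            ),
            "cx_g_L": r.biomass_g_L,
        }
        if r.gas is not None:
            row.update(
                {
                    "gasflow_L_h": r.gas.flow_in_L_h,
                    "yO2_in": r.gas.y_o2_in,
                    "yO2_out": r.gas.y_o2_out,
                    "yCO2_in": r.gas.y_co2_in,
                    "yCO2_out": r.gas.y_co2_out,
                    "broth_volume_L": r.gas.broth_volume_L,
                }
            )
        rows.append(row)
    return write_csv(pd.DataFrame(rows, columns=CHEMOSTAT_COLUMNS), path, **prov)


def read_chemostat_csv(path: PathLike) -> list[ChemostatRecord]:
    df = pd.read_csv(path, comment="#", dtype={"residual_glucose_g_L": str})
    records = []
    for _, row in df.iterrows():
        residual = row["residual_glucose_g_L"]
        bdl = isinstance(residual, str) and residual.strip().upper() == "BDL"
        gas = None
        if not pd.isna(row.get("gasflow_L_h")):
            gas = GasMeasurement(
                flow_in_L_h=float(row["gasflow_L_h"]),
                y_o2_in=float(row["yO2_in"]),
                y_o2_out=float(row["yO2_out"]),
                y_co2_in=float(row["yCO2_in"]),
                y_co2_out=float(row["yCO2_out"]),
                broth_volume_L=float(row["broth_volume_L"]),
            )
        records.append(
            ChemostatRecord(
                dilution_rate=float(row["D_h-1"]),
                feed_glucose_g_L=float(row["feed_glucose_g_L"]),
                biomass_g_L=float(row["cx_g_L"]),
                residual_glucose_g_L=None if bdl else float(residual),
                gas=gas,
                strain=str(row["strain"]),
                replicate=int(row["replicate"]),
            )
        )
    return records


# --- biomass samples ---------------------------------------------------------


def write_samples_csv(
    samples: Sequence[BiomassSample], path: PathLike, **prov: object
) -> Path:
    df = pd.DataFrame(
        {
            "time_h": [s.time_h for s in samples],
            "cx_g_L": [s.c_x_g_L for s in samples],
            "viability_frac": [s.viability for s in samples],
            "strain": [s.strain for s in samples],
            "replicate": [s.replicate for s in samples],
        }
    )
    return write_csv(df, path, **prov)


def read_samples_csv(path: PathLike) -> list[BiomassSample]:
    df = read_csv(path)
    return [
        BiomassSample(
            time_h=float(row["time_h"]),
            c_x_g_L=float(row["cx_g_L"]),
            viability=(
                None if pd.isna(row["viability_frac"]) else float(row["viability_frac"])
            ),
            strain=str(row["strain"]),
            replicate=int(row["replicate"]),
        )
        for _, row in df.iterrows()
    ]


# --- rate pairs and windowed estimates --------------------------------------


def write_rate_pairs_csv(
    pairs: Sequence[RatePair], path: PathLike, **prov: object
) -> Path:
    df = pd.DataFrame(
        {
            "time_h": [p.time_h for p in pairs],
            "mu_h-1": [p.mu_h for p in pairs],
            "qs_g_g_h": [p.q_s_g_g_h for p in pairs],
            "source": [p.source for p in pairs],
            "strain": [p.strain for p in pairs],
            "replicate": [p.replicate for p in pairs],
        }
    )
    return write_csv(df, path, **prov)


def read_rate_pairs_csv(path: PathLike) -> list[RatePair]:
    df = read_csv(path)
    return [
        RatePair(
            mu_h=float(row["mu_h-1"]),
            q_s_g_g_h=float(row["qs_g_g_h"]),
            source=str(row["source"]),
            time_h=None if pd.isna(row["time_h"]) else float(row["time_h"]),
            strain=str(row["strain"]),
            replicate=int(row["replicate"]),
        )
        for _, row in df.iterrows()
    ]


def write_rates_csv(
    rates: Sequence[RatesRecord], path: PathLike, **prov: object
) -> Path:
    df = pd.DataFrame([
        {
            "strain": r.strain,
            "replicate": r.replicate,
            "mu_h-1": r.mu_h,
            "qs_g_g_h": r.q_s_g_g_h,
            "qs_mmol_g_h": r.q_s_mmol_g_h,
            "yxs_g_g": r.y_xs_g_g,
            "qo2_mmol_g_h": r.q_o2_mmol_g_h,
            "qco2_mmol_g_h": r.q_co2_mmol_g_h,
            "yxo2_g_g": r.y_xo2_g_g,
            "rq": r.rq,
            "carbon_recovery_pct": r.carbon_recovery_pct,
            "residual_bdl": r.residual_below_detection,
        }
        for r in rates
    ])
    return write_csv(df, path, **prov)


def write_ms_csv(
    estimates: Sequence[MsEstimate], path: PathLike, **prov: object
) -> Path:
    df = pd.DataFrame(
        {
            "time_h": [e.time_h for e in estimates],
            "ms_g_g_h": [e.m_s for e in estimates],
            "se_ms_g_g_h": [e.se_m_s for e in estimates],
            "window": [e.window for e in estimates],
            "strain": [e.strain for e in estimates],
            "replicate": [e.replicate for e in estimates],
        }
    )
    return write_csv(df, path, **prov)


def read_ms_csv(path: PathLike) -> list[MsEstimate]:
    df = read_csv(path)
    return [
        MsEstimate(
            time_h=float(row["time_h"]),
            m_s=float(row["ms_g_g_h"]),
            se_m_s=float(row["se_ms_g_g_h"]),
            window=int(row["window"]),
            pair_indices=(),
            strain=str(row["strain"]),
            replicate=int(row["replicate"]),
        )
        for _, row in df.iterrows()
    ]


# --- trajectories and fits ---------------------------------------------------


def write_trajectory_csv(traj: Trajectory, path: PathLike, **prov: object) -> Path:
    return write_csv(traj.to_dataframe(), path, **prov)


def read_trajectory_csv(path: PathLike) -> pd.DataFrame:
    return read_csv(path)


def write_json(data: dict, path: PathLike) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
    return path


def write_pirt_json(
    fit: PirtFit,
    path: PathLike,
    config_hash: Optional[str] = None,
    seed: Optional[int] = None,
) -> Path:
    data = dataclasses.asdict(fit)
    data["_provenance"] = {
        "retenphys_version": __version__,
        "config_hash": config_hash,
        "seed": seed,
    }
    return write_json(data, path)


def read_pirt_json(path: PathLike) -> PirtFit:
    data = json.loads(Path(path).read_text())
    data.pop("_provenance", None)
    return PirtFit(**data)
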