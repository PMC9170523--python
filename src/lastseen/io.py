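"""CSV / JSON input-output for cohorts, sweep tables and curve tables."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .models import AgingModel, model_from_dict
from .simulate import Cohort

__all__ = [
    "write_cohort_csv",
    "read_cohort_csv",
    "write_curve_csv",
    "cohort_sidecar_path",
]

CURVE_COLUMNS = [
    "age",
    "real_pdf",
    "real_survival",
    "real_hazard",
    "reported_pdf",
    "reported_survival",
    "reported_hazard",
]


def cohort_sidecar_path(path) -> Path:
    """Path of the JSON metadata file accompanying a cohort CSV."""
    return Path(path).with_suffix(".json")


def write_cohort_csv(cohort: Cohort, path) -> None:
    """Write a cohort as CSV plus a JSON sidecar with its provenance.

    Lifespans are written with shortest round-trip float formatting, so a
    write/read cycle reproduces the cohort exactly.
    """
    from . import __version__

    path = Path(path)
    data: dict[str, np.ndarray] = {"individual_id": np.arange(1, cohort.n + 1)}
    if cohort.real is not None:
        data["real_lifespan"] = cohort.real
    data["reported_lifespan"] = cohort.reported
    pd.DataFrame(data).to_csv(path, index=False)
    meta = {
        "model": cohort.model.to_dict() if cohort.model is not None else None,
        "n": cohort.n,
        "seed": cohort.seed,
        "software_version": __version__,
    }
    cohort_sidecar_path(path).write_text(json.dumps(meta, indent=1) + "\n")


def _bad_rows_message(path, mask: np.ndarray, what: str) -> str:
    # +2: one for the header, one for 1-based line numbering
    lines = (np.flatnonzero(mask) + 2).tolist()
    shown = ", ".join(map(str, lines[:10])) + (" ..." if len(lines) > 10 else "")
    return f"{path}: {what} on line(s) {shown}"


def read_cohort_csv(path) -> Cohort:
    """Read a cohort CSV, validating every row.

    The ``real_lifespan`` column may be absent (field data where only
    last-seen ages exist); ``reported_lifespan`` is required.  Malformed or
    negative values and rows with reported > real are rejected with the
    offending CSV line numbers.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if "reported_lifespan" not in df.columns:
        raise ValueError(f"{path}: missing required column 'reported_lifespan'")
    reported = pd.to_numeric(df["reported_lifespan"], errors="coerce").to_numpy(float)
    bad = ~np.isfinite(reported) | (reported < 0)
    if bad.any():
        raise ValueError(_bad_rows_message(path, bad, "malformed or negative reported lifespan"))
    real = None
    if "real_lifespan" in df.columns:
        real = pd.to_numeric(df["real_lifespan"], errors="coerce").to_numpy(float)
        bad = ~np.isfinite(real) | (real < 0)
        if bad.any():
            raise ValueError(_bad_rows_message(path, bad, "malformed or negative real lifespan"))
        over = reported > real
        if over.any():
            raise ValueError(_bad_rows_message(path, over, "reported lifespan exceeds real lifespan"))

    model: AgingModel | None = None
    seed = None
    sidecar = cohort_sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        if meta.get("model"):
            model = model_from_dict(meta["model"])
        seed = meta.get("seed")
    return Cohort(reported=reported, real=real, model=model, seed=seed)


def write_curve_csv(table: pd.DataFrame, path) -> None:
    """Write a real-vs-reported curve table with the canonical column order."""
    missing = [c for c in CURVE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"curve table missing columns: {missing}")
    table[CURVE_COLUMNS].to_csv(path, index=False)
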