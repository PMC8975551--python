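"""Trace-table and configuration I/O with validation and QC reporting.

Conventions printed in every file header: AP position in %EL with 0 at the
anterior pole, increasing posterior; times in seconds; intensities in
arbitrary units with 0 meaning "no spot detected".
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .promoter_model import (
    BcdGradient,
    KineticRates,
    PromoterArchitecture,
    PromoterModel,
    SignalKernel,
)
from .trace_analysis import TRACE_COLUMNS

__all__ = [
    "read_traces",
    "write_traces",
    "qc_summary",
    "model_from_dict",
    "model_to_dict",
    "load_model_config",
    "save_model_config",
    "write_json",
]

logger = logging.getLogger("bicoidms2")

_HEADER = ("# bicoidms2 trace table | ap_percent_el: 0=anterior, increasing "
           "posterior | time_s: seconds relative to nucleus birth | "
           "intensity_au: 0 = no spot\n")


class TraceValidationError(ValueError):
    """Raised when a trace table violates the schema or its invariants."""


def read_traces(path: str | Path) -> pd.DataFrame:
    """Read and validate a long-format trace table (CSV or TSV).

    Checks the schema, AP range, nonnegative intensities and per-nucleus
    strictly increasing times; errors name the offending rows.  Logs a
    per-embryo QC summary (nuclei, frame cadence, AP coverage).
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    table = pd.read_csv(path, sep=sep, comment="#")
    missing = [c for c in TRACE_COLUMNS if c not in table.columns]
    if missing:
        raise TraceValidationError(f"{path}: missing columns {missing}")
    bad_ap = ~table["ap_percent_el"].between(0, 100)
    if bad_ap.any():
        rows = table.index[bad_ap][:5].tolist()
        raise TraceValidationError(
            f"{path}: ap_percent_el outside [0, 100] at rows {rows}"
        )
    if (table["intensity_au"] < 0).any():
        rows = table.index[table["intensity_au"] < 0][:5].tolist()
        raise TraceValidationError(f"{path}: negative intensity at rows {rows}")
    for (emb, nuc), g in table.groupby(["embryo_id", "nucleus_id"]):
        dt = np.diff(g["time_s"].to_numpy())
        if np.any(dt <= 0):
            raise TraceValidationError(
                f"{path}: non-increasing time_s for nucleus {emb}/{nuc}"
            )
    for line in qc_summary(table).splitlines():
        logger.info(line)
    return table


def write_traces(table: pd.DataFrame, path: str | Path) -> None:
    """Write a trace table as CSV with the coordinate-convention header."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_HEADER)
        table.to_csv(fh, index=False)


def qc_summary(table: pd.DataFrame) -> str:
    lines = []
    for emb, g in table.groupby("embryo_id"):
        n_nuc = g["nucleus_id"].nunique()
        cadence = g.groupby("nucleus_id")["time_s"].apply(
            lambda t: np.median(np.diff(t)) if len(t) > 1 else np.nan).median()
        lines.append(
            f"embryo {emb}: {n_nuc} nuclei, AP "
            f"{g['ap_percent_el'].min():.1f}-{g['ap_percent_el'].max():.1f} %EL, "
            f"median cadence {cadence:.0f} s"
        )
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# Model configuration
# ---------------------------------------------------------------------------

def model_from_dict(cfg: dict) -> tuple[PromoterModel, BcdGradient, SignalKernel]:
    """Build model, gradient and signal kernel from a configuration mapping.

    Expected keys: n_sites, k_threshold, activation_scaling, kb,
    k_off_site (list), k_on_base, k_off_promoter, rnap_rate, optional
    kernel{elongation_time, loop_ramp_time, intensity_per_rnap,
    detection_threshold} and gradient{c0, lambda_decay, dosage_factor}.
    """
    arch = PromoterArchitecture(
        n_sites=int(cfg["n_sites"]),
        k_threshold=int(cfg.get("k_threshold", 3)),
        activation_scaling=cfg.get("activation_scaling", "binomial"),
        weight_table=tuple(cfg["weight_table"]) if "weight_table" in cfg else None,
    )
    rates = KineticRates(
        kb=float(cfg["kb"]),
        k_off_site=tuple(float(v) for v in cfg["k_off_site"]),
        k_on_base=float(cfg["k_on_base"]),
        k_off_promoter=float(cfg["k_off_promoter"]),
        rnap_rate=float(cfg["rnap_rate"]),
    )
    grad = BcdGradient(**cfg.get("gradient", {}))
    kernel = SignalKernel(**cfg.get("kernel", {}))
    return PromoterModel(arch, rates), grad, kernel


def model_to_dict(model: PromoterModel, gradient: BcdGradient,
                  kernel: SignalKernel) -> dict:
    return {
        "n_sites": model.architecture.n_sites,
        "k_threshold": model.architecture.k_threshold,
        "activation_scaling": model.architecture.activation_scaling,
        "kb": model.rates.kb,
        "k_off_site": list(model.rates.k_off_site),
        "k_on_base": model.rates.k_on_base,
        "k_off_promoter": model.rates.k_off_promoter,
        "rnap_rate": model.rates.rnap_rate,
        "gradient": {"c0": gradient.c0, "lambda_decay": gradient.lambda_decay,
                     "dosage_factor": gradient.dosage_factor},
        "kernel": {"elongation_time": kernel.elongation_time,
                   "loop_ramp_time": kernel.loop_ramp_time,
                   "intensity_per_rnap": kernel.intensity_per_rnap,
                   "detection_threshold": kernel.detection_threshold},
    }


def load_model_config(path: str | Path):
    with open(path) as fh:
        return model_from_dict(yaml.safe_load(fh))


def save_model_config(path: str | Path, model: PromoterModel,
                      gradient: BcdGradient, kernel: SignalKernel) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(model_to_dict(model, gradient, kernel), fh, sort_keys=False)


def write_json(path: str | Path, payload: dict) -> None:
    """Write a result JSON, converting numpy scalars/arrays along the way."""

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serialisable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=default)
        fh.write("\n")
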