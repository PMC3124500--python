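"""Serological and endocrine trait computation.

Traits computed from raw assay values:

* TBI — percent inhibition of labeled TSH binding,
  ``[1 - (test - nsb)/(normal - nsb)] * 100``.
* TSAb — cAMP induction as a percent of control serum, ``100 * test/control``.
* TSAb ratio — human over mouse receptor stimulation.
* delta T4 — post-immunization minus baseline thyroxine.

Per-strain summaries report mean and SEM (sample SD / sqrt(n)); the
control-based elevation cut-off is control mean + 2 SD.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd

from .panel import TraitTable

ArrayLike = Union[float, np.ndarray]

__all__ = [
    "tbi_percent",
    "tsab_percent",
    "tsab_ratio",
    "delta_t4",
    "strain_summary",
    "elevation_cutoff",
    "classify",
    "ControlStats",
    "compute_trait",
]


def tbi_percent(
    test_binding: ArrayLike,
    normal_binding: ArrayLike,
    nonspecific_binding: ArrayLike,
) -> ArrayLike:
    """TSH binding inhibition as a percentage.

    Not clipped: noisy inputs may yield slightly negative values or values
    above 100; clipping is left to report layers.
    """
    test = np.asarray(test_binding, dtype=float)
    normal = np.asarray(normal_binding, dtype=float)
    nsb = np.asarray(nonspecific_binding, dtype=float)
    if np.any(normal <= nsb):
        raise ValueError(
            "normal-serum binding must exceed non-specific binding"
        )
    out = (1.0 - (test - nsb) / (normal - nsb)) * 100.0
    return out if out.ndim else float(out)


def tsab_percent(test_cAMP: ArrayLike, control_cAMP: ArrayLike) -> ArrayLike:
    """Thyroid-stimulating antibody activity as percent of control serum."""
    test = np.asarray(test_cAMP, dtype=float)
    control = np.asarray(control_cAMP, dtype=float)
    if np.any(control <= 0):
        raise ValueError("control cAMP must be positive")
    out = 100.0 * test / control
    return out if out.ndim else float(out)


def tsab_ratio(h_tsab: ArrayLike, m_tsab: ArrayLike) -> ArrayLike:
    """Human:mouse receptor stimulation ratio; > 1 means the serum
    preferentially recognises the human receptor."""
    h = np.asarray(h_tsab, dtype=float)
    m = np.asarray(m_tsab, dtype=float)
    if np.any(m <= 0):
        raise ValueError(
            "mouse-receptor TSAb must be positive to form the ratio"
        )
    out = h / m
    return out if out.ndim else float(out)


def delta_t4(post_t4: ArrayLike, baseline_t4: ArrayLike) -> ArrayLike:
    """Change in serum thyroxine (µg/dL); may be negative."""
    post = np.asarray(post_t4, dtype=float)
    base = np.asarray(baseline_t4, dtype=float)
    if np.any(np.isnan(base)):
        raise ValueError("missing baseline T4; delta undefined")
    out = post - base
    return out if out.ndim else float(out)


def strain_summary(records: pd.DataFrame) -> TraitTable:
    """Summarise per-mouse trait values per (strain, trait).

    ``records`` needs columns ``strain_id, trait, value`` (a ``mouse_id``
    column is preserved if present).  SEM uses the n-1 sample SD; a
    single-mouse strain gets SEM 0 with ``sem_flagged`` set.
    """
    required = {"strain_id", "trait", "value"}
    if records is None or len(records) == 0:
        raise ValueError("no assay records to summarise")
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records lack columns: {sorted(missing)}")

    rows = []
    for (strain, trait), sub in records.groupby(
        ["strain_id", "trait"], sort=True
    ):
        vals = sub["value"].to_numpy(dtype=float)
        vals = vals[~np.isnan(vals)]
        if len(vals) == 0:
            continue
        n = len(vals)
        mean = float(np.mean(vals))
        sem = float(np.std(vals, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        rows.append((strain, trait, mean, sem, n, n == 1))
    if not rows:
        raise ValueError("no non-missing values to summarise")
    summary = pd.DataFrame(
        rows,
        columns=["strain_id", "trait", "mean", "sem", "n_mice", "sem_flagged"],
    )
    mouse_values = records if "mouse_id" in records.columns else None
    return TraitTable(summary=summary, mouse_values=mouse_values)


@dataclass(frozen=True)
class ControlStats:
    """Elevation cut-off from control-immunized mice of one strain."""

    mean: float
    sd: float

    @property
    def cutoff(self) -> float:
        return self.mean + 2.0 * self.sd


def elevation_cutoff(control_values: Iterable[float]) -> ControlStats:
    """mean + 2 SD cut-off from >= 2 control measurements (sample SD)."""
    vals = np.asarray(list(control_values), dtype=float)
    vals = vals[~np.isnan(vals)]
    if len(vals) < 2:
        raise ValueError("need >= 2 control records for an SD")
    return ControlStats(mean=float(np.mean(vals)), sd=float(np.std(vals, ddof=1)))


def classify(value: float, stats: ControlStats) -> bool:
    """True when the value lies strictly above the control cut-off."""
    return bool(value > stats.cutoff)


# -- assay record -> trait value dispatch --------------------------------

def compute_trait(records: pd.DataFrame) -> pd.DataFrame:
    """Apply the per-assay formula to a raw assay table.

    Input columns: ``mouse_id, strain_id, assay`` plus the kind-specific
    raw columns (see the writer in :mod:`riqtl.tables`).  Returns the long
    trait table ``mouse_id, strain_id, trait, value``.
    """
    if "assay" not in records.columns:
        raise ValueError("assay table lacks an 'assay' column")
    frames = []
    for kind, sub in records.groupby("assay", sort=False):
        base = sub[["mouse_id", "strain_id"]].copy()
        if kind == "TBI":
            base["value"] = tbi_percent(
                sub["test_binding"].to_numpy(float),
                sub["normal_binding"].to_numpy(float),
                sub["nonspecific_binding"].to_numpy(float),
            )
            base["trait"] = "TBI"
        elif kind == "TSAb":
            base["value"] = tsab_percent(
                sub["test_cAMP"].to_numpy(float),
                sub["control_cAMP"].to_numpy(float),
            )
            base["trait"] = "TSAb"
        elif kind == "ELISA":
            base["value"] = sub["od_490"].to_numpy(float)
            base["trait"] = "ELISA"
        elif kind == "T4":
            base["value"] = sub["value"].to_numpy(float)
            tp = sub["timepoint"] if "timepoint" in sub.columns else "3x"
            base["trait"] = [f"T4_{t}" for t in tp] if not isinstance(tp, str) else "T4_3x"
        else:
            raise ValueError(f"unknown assay kind {kind!r}")
        frames.append(base[["mouse_id", "strain_id", "trait", "value"]])
    return pd.concat(frames, ignore_index=True)
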