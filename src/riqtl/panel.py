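"""Core data containers shared across the pipeline.

The mapping substrate is an :class:`RIPanel` — a genotype matrix for a
recombinant-inbred strain set together with its genetic (cM) and physical
(Mb) marker map.  Traits are carried as per-strain summaries
(:class:`TraitTable`) or as a single aligned vector (:class:`TraitVector`)
ready for a genome scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

#: Valid genotype codes: parental A allele, parental B (B6) allele,
#: heterozygous, unknown.
GENO_CODES = ("A", "B", "H", "U")

MARKER_COLUMNS = ["marker", "chromosome", "position_cM", "position_Mb"]


class PanelError(ValueError):
    """Raised when a panel violates its structural invariants."""


@dataclass
class RIPanel:
    """Genotypes of a recombinant-inbred strain panel plus its marker map.

    Parameters
    ----------
    strain_ids
        Ordered strain names; one column of ``genotypes`` per strain.
    markers
        DataFrame with columns ``marker, chromosome, position_cM,
        position_Mb``; one row per marker, sorted by chromosome then
        position.
    genotypes
        ``(n_markers, n_strains)`` array of single-character codes drawn
        from :data:`GENO_CODES`.
    """

    strain_ids: list[str]
    markers: pd.DataFrame
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        self.strain_ids = list(self.strain_ids)
        self.genotypes = np.asarray(self.genotypes, dtype="<U1")
        self.validate()

    # -- invariants -----------------------------------------------------
    def validate(self) -> None:
        missing = [c for c in MARKER_COLUMNS if c not in self.markers.columns]
        if missing:
            raise PanelError(f"marker table lacks columns: {missing}")
        if self.genotypes.shape != (len(self.markers), len(self.strain_ids)):
            raise PanelError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{len(self.markers)} markers x {len(self.strain_ids)} strains"
            )
        if self.markers["marker"].duplicated().any():
            dup = self.markers["marker"][self.markers["marker"].duplicated()]
            raise PanelError(f"duplicated marker ids: {sorted(set(dup))}")
        for chrom, sub in self.markers.groupby("chromosome", sort=False):
            pos = sub["position_cM"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise PanelError(
                    f"positions not strictly increasing on chromosome {chrom}"
                )
        bad = ~np.isin(self.genotypes, GENO_CODES)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise PanelError(
                f"invalid genotype code {self.genotypes[i, j]!r} at marker "
                f"{self.markers['marker'].iat[i]!r}, strain {self.strain_ids[j]!r}"
            )

    # -- convenience ----------------------------------------------------
    @property
    def n_strains(self) -> int:
        return len(self.strain_ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def chromosome_names(self) -> list[str]:
        return list(dict.fromkeys(self.markers["chromosome"]))

    def marker_index(self, marker: str) -> int:
        idx = self.markers.index[self.markers["marker"] == marker]
        if len(idx) == 0:
            raise KeyError(f"unknown marker {marker!r}")
        return int(idx[0])

    def genotype_numeric(self) -> np.ndarray:
        """Codes as floats: A -> 1, B -> 0, H/U -> NaN.

        This is the encoding the scan engine works with; heterozygous and
        unknown calls drop the strain at that marker only.
        """
        out = np.full(self.genotypes.shape, np.nan)
        out[self.genotypes == "A"] = 1.0
        out[self.genotypes == "B"] = 0.0
        return out

    def flip_alleles(self) -> "RIPanel":
        """Return a panel with every A swapped for B and vice versa."""
        flipped = self.genotypes.copy()
        a = flipped == "A"
        flipped[flipped == "B"] = "A"
        flipped[a] = "B"
        return RIPanel(self.strain_ids, self.markers.copy(), flipped)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RIPanel):
            return NotImplemented
        return (
            self.strain_ids == other.strain_ids
            and self.markers.reset_index(drop=True).equals(
                other.markers.reset_index(drop=True)
            )
            and np.array_equal(self.genotypes, other.genotypes)
        )


@dataclass
class TraitTable:
    """Per-(strain, trait) summaries: mean, SEM and mouse count.

    ``summary`` columns: ``strain_id, trait, mean, sem, n_mice`` plus a
    boolean ``sem_flagged`` column marking strains where n = 1 (SEM is
    reported as 0 but is not estimable).  ``mouse_values``, when present,
    holds the per-mouse long table (``mouse_id, strain_id, trait, value``)
    the summary was computed from.
    """

    summary: pd.DataFrame
    mouse_values: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        required = {"strain_id", "trait", "mean", "sem", "n_mice"}
        missing = required - set(self.summary.columns)
        if missing:
            raise PanelError(f"trait summary lacks columns: {sorted(missing)}")
        if "sem_flagged" not in self.summary.columns:
            self.summary = self.summary.assign(
                sem_flagged=self.summary["n_mice"] == 1
            )
        if (self.summary["sem"] < 0).any():
            raise PanelError("negative SEM in trait summary")
        if (self.summary["n_mice"] < 1).any():
            raise PanelError("n_mice < 1 in trait summary")

    def traits(self) -> list[str]:
        return list(dict.fromkeys(self.summary["trait"]))

    def vector(self, trait: str) -> "TraitVector":
        sub = self.summary[self.summary["trait"] == trait]
        if sub.empty:
            raise KeyError(f"trait {trait!r} not in table")
        return TraitVector(
            strain_ids=list(sub["strain_id"]),
            values=sub["mean"].to_numpy(dtype=float),
            sem=sub["sem"].to_numpy(dtype=float),
            trait=trait,
        )


@dataclass
class TraitVector:
    """One number per strain — the mapping unit of every genome scan."""

    strain_ids: list[str]
    values: np.ndarray
    sem: Optional[np.ndarray] = None
    trait: str = "trait"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.strain_ids) != len(self.values):
            raise PanelError("strain_ids and values length mismatch")
        if self.sem is not None:
            self.sem = np.asarray(self.sem, dtype=float)
            if len(self.sem) != len(self.values):
                raise PanelError("sem length mismatch")

    def align_to(self, panel: RIPanel) -> "TraitVector":
        """Reorder/subset to the panel's strain list (inner join).

        Raises if fewer than 3 shared strains carry non-missing values.
        """
        lookup = {s: i for i, s in enumerate(self.strain_ids)}
        shared = [s for s in panel.strain_ids if s in lookup]
        vals = np.array([self.values[lookup[s]] for s in shared], dtype=float)
        keep = ~np.isnan(vals)
        if keep.sum() < 3:
            raise PanelError(
                f"only {int(keep.sum())} strains shared between panel and "
                f"trait {self.trait!r}; need >= 3"
            )
        sem = None
        if self.sem is not None:
            sem = np.array([self.sem[lookup[s]] for s in shared], dtype=float)
            sem = sem[keep]
        return TraitVector(
            strain_ids=[s for s, k in zip(shared, keep) if k],
            values=vals[keep],
            sem=sem,
            trait=self.trait,
        )
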