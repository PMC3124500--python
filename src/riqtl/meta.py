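"""Cross-family combined linkage.

Evidence from RI families sharing a chromosomal interval is combined with
Fisher's method: chi2 = -2 * sum(ln p_i) on 2k degrees of freedom for k
families, the combined p is the chi-square upper tail, and the combined
LOD is -log10 of that p.  Point-wise per-family p-values may be supplied
directly, derived from an LRS via the chi-square(1 df) tail, or from a
marker-level permutation sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "FamilyEvidence",
    "CombinedResult",
    "fisher_chi2",
    "chi2_pvalue",
    "chi2_sf_even_df",
    "combined_lod",
    "pointwise_p_from_lrs",
    "combine_families",
]


def _check_p(p: float) -> float:
    p = float(p)
    if not 0.0 < p <= 1.0:
        raise ValueError(f"p-value {p} outside (0, 1]")
    return p


def fisher_chi2(pvalues: Sequence[float]) -> tuple[float, int]:
    """Fisher combination: chi2 = -2 * sum(ln p), df = 2k."""
    ps = [_check_p(p) for p in pvalues]
    if not ps:
        raise ValueError("need at least one p-value")
    chi2 = -2.0 * sum(math.log(p) for p in ps)
    return chi2, 2 * len(ps)


def chi2_pvalue(chi2: float, df: int) -> float:
    """Upper-tail chi-square probability."""
    if chi2 < 0:
        raise ValueError("chi-square statistic must be non-negative")
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(stats.chi2.sf(chi2, df))


def chi2_sf_even_df(chi2: float, df: int) -> float:
    """Closed-form upper tail for even df:
    exp(-x/2) * sum_{j<df/2} (x/2)^j / j!  — an independent check on the
    numeric tail."""
    if chi2 < 0:
        raise ValueError("chi-square statistic must be non-negative")
    if df < 2 or df % 2:
        raise ValueError("closed form requires positive even df")
    half = chi2 / 2.0
    term = 1.0
    acc = 1.0
    for j in range(1, df // 2):
        term *= half / j
        acc += term
    return math.exp(-half) * acc


def combined_lod(p: float) -> float:
    """Combined LOD score: -log10(p)."""
    _check_p(p)
    return -math.log10(p)


def pointwise_p_from_lrs(
    lrs: float,
    mode: str = "chi2_df1",
    permutation_sample: Optional[np.ndarray] = None,
) -> float:
    """Point-wise (single-locus) p-value for an LRS.

    ``chi2_df1``: upper tail of chi-square with 1 df at the LRS.
    ``permutation``: (b + 1)/(N + 1) against a marker-level permutation
    sample of the statistic.
    """
    if lrs < 0:
        raise ValueError("LRS must be non-negative")
    if mode == "chi2_df1":
        return float(stats.chi2.sf(lrs, 1))
    if mode == "permutation":
        if permutation_sample is None:
            raise ValueError("permutation mode needs a permutation sample")
        sample = np.asarray(permutation_sample, dtype=float)
        b = int(np.sum(sample >= lrs))
        return (b + 1) / (len(sample) + 1)
    raise ValueError(f"unknown mode {mode!r}")


@dataclass(frozen=True)
class FamilyEvidence:
    """Point-wise linkage evidence from one RI family in one interval."""

    family_id: str
    chromosome: str
    start_Mb: float
    end_Mb: float
    p: float
    lrs: Optional[float] = None

    def __post_init__(self) -> None:
        _check_p(self.p)
        if not self.start_Mb < self.end_Mb:
            raise ValueError(
                f"family {self.family_id}: interval start must precede end"
            )

    @classmethod
    def from_lrs(
        cls,
        family_id: str,
        chromosome: str,
        start_Mb: float,
        end_Mb: float,
        lrs: float,
        mode: str = "chi2_df1",
        permutation_sample: Optional[np.ndarray] = None,
    ) -> "FamilyEvidence":
        p = pointwise_p_from_lrs(lrs, mode=mode, permutation_sample=permutation_sample)
        return cls(family_id, chromosome, start_Mb, end_Mb, p, lrs=lrs)


@dataclass(frozen=True)
class CombinedResult:
    families: tuple[str, ...]
    chromosome: str
    interval_Mb: tuple[float, float]
    chi2: float
    df: int
    p: float
    lod: float

    def report_line(self) -> str:
        """Human-readable line: families, interval, chi2, p, combined LOD."""
        fams = "+".join(self.families)
        lo, hi = self.interval_Mb
        return (
            f"{fams}\tChr{self.chromosome}:{lo:.3f}-{hi:.3f}Mb\t"
            f"X2={self.chi2:.2f} (df={self.df})\tp={self.p:.5E}\t"
            f"comb LOD={self.lod:.2f}"
        )


def combine_families(evidence: Sequence[FamilyEvidence]) -> CombinedResult:
    """Fisher-combine per-family point-wise p-values over a shared interval.

    All families must sit on one chromosome with pairwise-overlapping
    intervals; the intersected interval is reported.  A single family
    passes through (its own p and LOD).
    """
    ev = list(evidence)
    if not ev:
        raise ValueError("no family evidence supplied")
    chroms = {e.chromosome for e in ev}
    if len(chroms) > 1:
        raise ValueError(f"families span multiple chromosomes: {sorted(chroms)}")
    for i, a in enumerate(ev):
        for b in ev[i + 1 :]:
            if a.start_Mb > b.end_Mb or b.start_Mb > a.end_Mb:
                raise ValueError(
                    f"intervals of {a.family_id} and {b.family_id} do not overlap"
                )
    lo = max(e.start_Mb for e in ev)
    hi = min(e.end_Mb for e in ev)
    chi2, df = fisher_chi2([e.p for e in ev])
    p = chi2_pvalue(chi2, df)
    return CombinedResult(
        families=tuple(e.family_id for e in ev),
        chromosome=ev[0].chromosome,
        interval_Mb=(lo, hi),
        chi2=chi2,
        df=df,
        p=p,
        lod=combined_lod(p),
    )
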