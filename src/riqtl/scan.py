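"""Single-marker genome scans on strain means.

The per-marker statistic is the Gaussian two-group likelihood ratio on
strain means,

    LRS = n * ln(RSS0 / RSS1),

where RSS0 is the total sum of squares about the grand mean and RSS1 the
residual sum of squares about the two genotype-class means, over the
``n`` strains informative at that marker (H/U calls and missing trait
values drop the strain at that marker only).  The additive effect is half
the difference of class means, signed so that a positive value means the
A allele raises the trait.  LOD = LRS / 4.61 — the constant is kept at
exactly 4.61, which reproduces every published LRS/LOD pair this code is
validated against (2*ln(10) does not).

Genome-wide thresholds come from permuting trait values across strains
(genotypes fixed) and taking order statistics of the per-permutation
maximum LRS: 95th percentile for significant (genome-wide p 0.05), 37th
for suggestive (p 0.63, the Lander-Kruglyak convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .panel import RIPanel, TraitVector, PanelError

__all__ = [
    "LOD_PER_LRS",
    "lod_from_lrs",
    "lrs_from_lod",
    "marker_lrs",
    "genome_scan",
    "permutation_thresholds",
    "LinkageResult",
    "PermutationNull",
]

#: Published conversion constant: LOD = LRS / 4.61.
LOD_PER_LRS = 4.61

#: Relative floor applied to RSS1: below RSS0 * SEPARATION_EPS the marker is
#: flagged "separated" and its LRS capped at n * ln(1/SEPARATION_EPS).
SEPARATION_EPS = 1e-12

#: Co-peak tie tolerance (LRS units).
DEFAULT_TIE_TOL = 0.01


def lod_from_lrs(lrs):
    """LOD = LRS / 4.61 (vectorised)."""
    arr = np.asarray(lrs, dtype=float)
    if np.any(arr < 0):
        raise ValueError("LRS must be non-negative")
    out = arr / LOD_PER_LRS
    return out if out.ndim else float(out)


def lrs_from_lod(lod):
    """Inverse of :func:`lod_from_lrs`; round-trips to machine precision."""
    arr = np.asarray(lod, dtype=float)
    if np.any(arr < 0):
        raise ValueError("LOD must be non-negative")
    out = arr * LOD_PER_LRS
    return out if out.ndim else float(out)


@dataclass
class MarkerStat:
    lrs: Optional[float]
    additive: Optional[float]
    n_used: int
    separated: bool = False
    skip_reason: Optional[str] = None


def marker_lrs(
    values: np.ndarray,
    genotypes: np.ndarray,
    weights: Optional[np.ndarray] = None,
) -> MarkerStat:
    """Two-group likelihood ratio at one marker.

    ``values`` are strain means; ``genotypes`` the matching codes
    ('A'/'B'/'H'/'U') or numeric 1/0/NaN.  ``weights``, when given,
    switches to inverse-variance weighted class means and sums of squares
    (an option mirroring SEM-weighted mapping; unweighted is the default
    and the validated path).
    """
    y = np.asarray(values, dtype=float)
    g = np.asarray(genotypes)
    if g.dtype.kind in ("U", "S", "O"):
        num = np.full(g.shape, np.nan)
        num[g == "A"] = 1.0
        num[g == "B"] = 0.0
    else:
        num = np.asarray(g, dtype=float)
    keep = ~np.isnan(y) & ~np.isnan(num)
    y = y[keep]
    num = num[keep]
    w = None
    if weights is not None:
        w = np.asarray(weights, dtype=float)[keep]
        if np.any(w <= 0):
            raise ValueError("weights must be positive")
    n = len(y)
    is_a = num == 1.0
    n_a = int(is_a.sum())
    n_b = n - n_a
    if n_a < 2 or n_b < 2:
        return MarkerStat(
            lrs=None,
            additive=None,
            n_used=n,
            skip_reason=f"class sizes {n_a}/{n_b}; need >= 2 each",
        )
    if w is None:
        w = np.ones(n)
    grand = np.average(y, weights=w)
    mean_a = np.average(y[is_a], weights=w[is_a])
    mean_b = np.average(y[~is_a], weights=w[~is_a])
    rss0 = float(np.sum(w * (y - grand) ** 2))
    fitted = np.where(is_a, mean_a, mean_b)
    rss1 = float(np.sum(w * (y - fitted) ** 2))
    additive = (mean_a - mean_b) / 2.0
    if rss0 == 0.0:
        return MarkerStat(lrs=0.0, additive=0.0, n_used=n)
    separated = rss1 < rss0 * SEPARATION_EPS
    rss1 = max(rss1, rss0 * SEPARATION_EPS)
    lrs = n * float(np.log(rss0 / rss1))
    return MarkerStat(lrs=lrs, additive=float(additive), n_used=n, separated=separated)


@dataclass
class LinkageResult:
    """Per-marker scan results plus the peak report for one trait."""

    trait: str
    table: pd.DataFrame  # marker, chromosome, position_cM, position_Mb, lrs, lod, additive, n_used, separated
    peak_lrs: float
    peak_markers: pd.DataFrame  # co-peaks within the tie tolerance
    interval_Mb: tuple[float, float]  # flanking-marker interval around the peaks
    tie_tol: float = DEFAULT_TIE_TOL
    genomewide_p: Optional[float] = None

    @property
    def peak_lod(self) -> float:
        return self.peak_lrs / LOD_PER_LRS


def _numeric_genotypes(panel: RIPanel, strain_subset: list[str]) -> np.ndarray:
    cols = [panel.strain_ids.index(s) for s in strain_subset]
    return panel.genotype_numeric()[:, cols]


def _scan_table(
    panel: RIPanel,
    aligned: TraitVector,
    weights: Optional[np.ndarray],
) -> pd.DataFrame:
    num = _numeric_genotypes(panel, aligned.strain_ids)
    records = []
    for i in range(panel.n_markers):
        stat = marker_lrs(aligned.values, num[i], weights=weights)
        records.append(
            (
                stat.lrs,
                None if stat.lrs is None else stat.lrs / LOD_PER_LRS,
                stat.additive,
                stat.n_used,
                stat.separated,
            )
        )
    out = panel.markers.copy().reset_index(drop=True)
    stats = pd.DataFrame(
        records, columns=["lrs", "lod", "additive", "n_used", "separated"]
    )
    return pd.concat([out, stats], axis=1)


def genome_scan(
    panel: RIPanel,
    trait: TraitVector,
    weights: Optional[np.ndarray] = None,
    tie_tol: float = DEFAULT_TIE_TOL,
) -> LinkageResult:
    """Scan every marker; report the peak and all co-peaks within
    ``tie_tol`` LRS of the maximum, with their flanking-marker interval."""
    aligned = trait.align_to(panel)
    if weights is None and trait.sem is not None:
        pass  # SEM is carried but weighting stays opt-in
    w = None
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        if len(w) != len(aligned.values):
            raise PanelError("weights must align with the joined strain set")
    table = _scan_table(panel, aligned, w)
    valid = table.dropna(subset=["lrs"])
    if valid.empty:
        raise PanelError("no marker had two informative genotype classes")
    peak_lrs = float(valid["lrs"].max())
    peaks = valid[valid["lrs"] >= peak_lrs - tie_tol]
    lo_idx = int(peaks.index.min())
    hi_idx = int(peaks.index.max())
    chrom = table.loc[lo_idx, "chromosome"]
    same = table["chromosome"] == chrom
    lo_flank = lo_idx - 1 if lo_idx - 1 in table.index and same[lo_idx - 1] else lo_idx
    hi_flank = hi_idx + 1 if hi_idx + 1 in table.index and same.get(hi_idx + 1, False) else hi_idx
    interval = (
        float(table.loc[lo_flank, "position_Mb"]),
        float(table.loc[hi_flank, "position_Mb"]),
    )
    return LinkageResult(
        trait=aligned.trait,
        table=table,
        peak_lrs=peak_lrs,
        peak_markers=peaks.copy(),
        interval_Mb=interval,
        tie_tol=tie_tol,
    )


# -- vectorised max-LRS over many trait vectors -------------------------

def _batch_max_lrs(num_geno: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Genome-wide maximum LRS for each row of ``Y``.

    ``num_geno`` is (markers x strains) 1/0/NaN; ``Y`` (batch x strains),
    NaN-free.  Markers are grouped by their informative-strain mask so each
    group reduces to dense matrix algebra; uninformative markers
    (a class smaller than 2) are skipped, matching :func:`marker_lrs`.
    """
    n_batch = Y.shape[0]
    maxima = np.zeros(n_batch)
    masks = ~np.isnan(num_geno)
    # group markers sharing a missingness pattern
    keys: dict[bytes, list[int]] = {}
    for i, m in enumerate(masks):
        keys.setdefault(m.tobytes(), []).append(i)
    any_valid = np.zeros(n_batch, dtype=bool)
    for key, idx in keys.items():
        mask = masks[idx[0]]
        n = int(mask.sum())
        if n < 4:
            continue
        G = num_geno[np.ix_(idx, np.where(mask)[0])]
        n_a = G.sum(axis=1)
        n_b = n - n_a
        ok = (n_a >= 2) & (n_b >= 2)
        if not ok.any():
            continue
        G = G[ok]
        n_a = n_a[ok]
        n_b = n_b[ok]
        Yv = Y[:, mask]
        tot = Yv.sum(axis=1, keepdims=True)
        ss = (Yv**2).sum(axis=1, keepdims=True)
        rss0 = ss - tot**2 / n
        s_a = Yv @ G.T
        rss1 = ss - s_a**2 / n_a - (tot - s_a) ** 2 / n_b
        with np.errstate(invalid="ignore", divide="ignore"):
            floor = np.maximum(rss0, 1e-300) * SEPARATION_EPS
            rss1 = np.maximum(rss1, floor)
            lrs = n * np.log(np.maximum(rss0, 1e-300) / rss1)
        lrs[np.broadcast_to(rss0 == 0.0, lrs.shape)] = 0.0
        maxima = np.maximum(maxima, lrs.max(axis=1))
        any_valid[:] = True
    if not any_valid.any():
        raise PanelError("no marker had two informative genotype classes")
    return maxima


@dataclass
class PermutationNull:
    """Permutation null distribution of the genome-wide maximum LRS."""

    n_permutations: int
    max_lrs: np.ndarray
    seed: int

    @property
    def significant(self) -> float:
        """Genome-wide p = 0.05 threshold (95th-percentile order statistic)."""
        return float(np.quantile(self.max_lrs, 0.95, method="higher"))

    @property
    def suggestive(self) -> float:
        """Genome-wide p = 0.63 threshold (37th-percentile order statistic)."""
        return float(np.quantile(self.max_lrs, 0.37, method="higher"))

    def genomewide_p(self, observed_peak_lrs: float) -> float:
        """(b + 1)/(N + 1) with b = permutation maxima >= observed."""
        b = int(np.sum(self.max_lrs >= observed_peak_lrs))
        return (b + 1) / (self.n_permutations + 1)


def permutation_thresholds(
    panel: RIPanel,
    trait: TraitVector,
    n_permutations: int = 1000,
    seed: int = 0,
) -> PermutationNull:
    """Shuffle trait values across strains (genotypes fixed) and collect
    the genome-wide maximum LRS of each permutation."""
    if n_permutations < 10:
        raise ValueError("need at least 10 permutations")
    if n_permutations < 100:
        warnings.warn(
            f"{n_permutations} permutations give coarse thresholds; "
            "1000 is the standard",
            stacklevel=2,
        )
    aligned = trait.align_to(panel)
    num = _numeric_genotypes(panel, aligned.strain_ids)
    rng = np.random.default_rng(seed)
    Y = np.empty((n_permutations, len(aligned.values)))
    for i in range(n_permutations):
        Y[i] = rng.permutation(aligned.values)
    maxima = _batch_max_lrs(num, Y)
    return PermutationNull(
        n_permutations=n_permutations, max_lrs=maxima, seed=seed
    )
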