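"""Synthetic recombinant-inbred panels with planted-QTL traits.

Genotypes are generated chromosome by chromosome as a two-state Markov
chain over the ordered markers.  The switch probability between adjacent
markers is the RI map expansion of the meiotic recombination fraction:
``R = 4r / (1 + 6r)`` for sib-mated lines (the default) or
``R = 2r / (1 + 2r)`` for selfed lines, with ``r`` obtained from the cM
spacing through the Haldane map function.  Traits are strain means with an
optional planted additive QTL, plus per-mouse replicates, and raw assay
values can be emitted that round-trip exactly through the phenotype
formulas.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .panel import RIPanel, TraitTable
from . import phenotypes

__all__ = [
    "Chromosome",
    "QTLSpec",
    "SimConfig",
    "SimTruth",
    "haldane_r",
    "ri_expansion",
    "simulate_ri_genotypes",
    "simulate_trait",
    "simulate_assay_raw",
]


def haldane_r(d_cM: float) -> float:
    """Recombination fraction from map distance (Haldane, no interference)."""
    if d_cM < 0:
        raise ValueError("map distance must be non-negative")
    return 0.5 * (1.0 - math.exp(-2.0 * d_cM / 100.0))


def ri_expansion(r: float, cross: str = "sib") -> float:
    """Expected discordance between adjacent RI markers at meiotic fraction r.

    ``cross='sib'`` gives 4r/(1+6r) (brother-sister mated lines);
    ``cross='selfing'`` gives 2r/(1+2r).
    """
    if not 0.0 <= r <= 0.5:
        raise ValueError(f"recombination fraction {r} outside [0, 0.5]")
    if cross == "sib":
        return 4.0 * r / (1.0 + 6.0 * r)
    if cross == "selfing":
        return 2.0 * r / (1.0 + 2.0 * r)
    raise ValueError(f"unknown cross type {cross!r}")


@dataclass(frozen=True)
class Chromosome:
    name: str
    length_cM: float
    length_Mb: float


@dataclass(frozen=True)
class QTLSpec:
    """A planted additive QTL: ``high_allele`` carriers gain ``+effect``."""

    chromosome: str
    position_cM: float
    additive_effect: float
    high_allele: str = "A"

    def __post_init__(self) -> None:
        if self.high_allele not in ("A", "B"):
            raise ValueError("high_allele must be 'A' or 'B'")


@dataclass(frozen=True)
class SimConfig:
    n_strains: int = 26
    chromosomes: tuple[Chromosome, ...] = ()
    marker_spacing_cM: float = 1.0
    qtl: Optional[QTLSpec] = None
    trait_baseline: float = 0.0
    strain_sd: float = 1.0
    mouse_sd: float = 0.0
    mice_per_strain: int = 6
    cross: str = "sib"
    corruption_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_strains < 2:
            raise ValueError("n_strains must be >= 2")
        if self.mice_per_strain < 1:
            raise ValueError("mice_per_strain must be >= 1")
        if self.strain_sd < 0 or self.mouse_sd < 0:
            raise ValueError("SDs must be >= 0")
        if self.marker_spacing_cM <= 0:
            raise ValueError("marker spacing must be positive")
        if not self.chromosomes:
            raise ValueError("at least one chromosome required")
        if not 0.0 <= self.corruption_rate < 1.0:
            raise ValueError("corruption_rate must be in [0, 1)")
        if self.cross not in ("sib", "selfing"):
            raise ValueError("cross must be 'sib' or 'selfing'")
        if self.qtl is not None:
            names = {c.name for c in self.chromosomes}
            if self.qtl.chromosome not in names:
                raise ValueError(
                    f"QTL chromosome {self.qtl.chromosome!r} not declared"
                )
            length = {c.name: c.length_cM for c in self.chromosomes}[
                self.qtl.chromosome
            ]
            if not 0.0 <= self.qtl.position_cM <= length:
                raise ValueError("QTL position outside chromosome length")


def axbxa_like_config(**overrides) -> SimConfig:
    """A 26-strain, ~2000-marker panel on 19 autosomes + X at 1 cM spacing."""
    chroms = tuple(
        Chromosome(name, length_cM=99.0, length_Mb=99.0 * 2.0)
        for name in [str(i) for i in range(1, 20)] + ["X"]
    )
    defaults = dict(n_strains=26, chromosomes=chroms, marker_spacing_cM=1.0)
    defaults.update(overrides)
    return SimConfig(**defaults)


@dataclass
class SimTruth:
    """Ground truth emitted alongside every simulated trait."""

    qtl_marker: Optional[str]
    qtl_marker_index: Optional[int]
    additive_effect: float  # signed: positive = A allele raises the trait
    strain_genetic_values: pd.Series  # indexed by strain_id

    @property
    def has_qtl(self) -> bool:
        return self.qtl_marker is not None


def simulate_ri_genotypes(config: SimConfig) -> RIPanel:
    """Draw an RI panel: independent strains, independent chromosomes,
    two-state Markov chain along each chromosome with switch probability
    ``ri_expansion(haldane_r(spacing))``."""
    rng = np.random.default_rng(config.seed)
    strain_ids = [f"RIS{i:03d}" for i in range(1, config.n_strains + 1)]

    rows = []
    blocks = []
    for chrom in config.chromosomes:
        n_mark = int(math.floor(chrom.length_cM / config.marker_spacing_cM)) + 1
        if n_mark < 1:
            raise ValueError(f"chromosome {chrom.name} shorter than spacing")
        pos_cM = np.arange(n_mark) * config.marker_spacing_cM
        pos_Mb = pos_cM / chrom.length_cM * chrom.length_Mb if chrom.length_cM else pos_cM
        r = haldane_r(config.marker_spacing_cM)
        R = ri_expansion(r, config.cross)
        geno = np.empty((n_mark, config.n_strains), dtype=np.int8)
        geno[0] = rng.random(config.n_strains) < 0.5
        if n_mark > 1:
            switches = rng.random((n_mark - 1, config.n_strains)) < R
            for i in range(1, n_mark):
                geno[i] = geno[i - 1] ^ switches[i - 1]
        blocks.append(geno)
        for i in range(n_mark):
            rows.append(
                (f"m{chrom.name}_{i:04d}", chrom.name, float(pos_cM[i]), float(pos_Mb[i]))
            )
    markers = pd.DataFrame(
        rows, columns=["marker", "chromosome", "position_cM", "position_Mb"]
    )
    numeric = np.vstack(blocks)
    codes = np.where(numeric == 1, "A", "B").astype("<U1")
    if config.corruption_rate > 0:
        hit = rng.random(codes.shape) < config.corruption_rate
        which = rng.random(codes.shape) < 0.5
        codes[hit & which] = "H"
        codes[hit & ~which] = "U"
    return RIPanel(strain_ids, markers, codes)


def _qtl_marker_index(panel: RIPanel, qtl: QTLSpec) -> int:
    sub = panel.markers[panel.markers["chromosome"] == qtl.chromosome]
    if sub.empty:
        raise ValueError(f"QTL chromosome {qtl.chromosome!r} not in panel")
    offset = (sub["position_cM"] - qtl.position_cM).abs()
    return int(offset.idxmin())


def simulate_trait(
    panel: RIPanel, config: SimConfig, trait: str = "trait"
) -> tuple[TraitTable, SimTruth]:
    """Simulate one trait on the panel.

    Strain mean = baseline + a*x_s + eps_s with x_s = +1 for high-allele
    carriers at the QTL marker, -1 otherwise; per-mouse values add
    independent Normal(0, mouse_sd^2) noise.  Without a QTL the trait is
    pure noise and the truth records "no QTL".
    """
    # trait noise stream is decoupled from the genotype stream
    rng = np.random.default_rng([config.seed, 1])
    n = panel.n_strains
    if config.qtl is not None:
        idx = _qtl_marker_index(panel, config.qtl)
        codes = panel.genotypes[idx]
        x = np.where(codes == config.qtl.high_allele, 1.0, -1.0)
        x[(codes == "H") | (codes == "U")] = 0.0
        a = config.qtl.additive_effect
        # sign convention: positive additive = A allele raises the trait
        signed_a = a if config.qtl.high_allele == "A" else -a
        marker_id = panel.markers["marker"].iat[idx]
    else:
        idx = None
        x = np.zeros(n)
        a = 0.0
        signed_a = 0.0
        marker_id = None

    genetic = config.trait_baseline + a * x
    strain_means = genetic + rng.normal(0.0, config.strain_sd, size=n)
    m = config.mice_per_strain
    mouse_vals = strain_means[:, None] + rng.normal(
        0.0, config.mouse_sd, size=(n, m)
    )

    long = pd.DataFrame(
        {
            "mouse_id": [
                f"{s}_m{j + 1}" for s in panel.strain_ids for j in range(m)
            ],
            "strain_id": np.repeat(panel.strain_ids, m),
            "trait": trait,
            "value": mouse_vals.ravel(),
        }
    )
    table = phenotypes.strain_summary(long)
    table.mouse_values = long
    truth = SimTruth(
        qtl_marker=marker_id,
        qtl_marker_index=idx,
        additive_effect=signed_a,
        strain_genetic_values=pd.Series(genetic, index=panel.strain_ids),
    )
    return table, truth


# -- raw assay synthesis ------------------------------------------------

#: Fixed instrument constants used when inverting the phenotype formulas.
TBI_NORMAL_BINDING = 10000.0
TBI_NONSPECIFIC_BINDING = 2000.0
TSAB_CONTROL_CAMP = 1.5


def simulate_assay_raw(trait_table: TraitTable, assay: str) -> pd.DataFrame:
    """Invert a phenotype formula: emit per-mouse raw assay values whose
    computed trait equals the per-mouse value in ``trait_table`` exactly.

    ``assay`` is one of ``TBI, TSAb, ELISA, T4``.  Requires the table to
    carry per-mouse values.  Values outside the assay's representable
    range are rejected.
    """
    if trait_table.mouse_values is None:
        raise ValueError("trait table carries no per-mouse values to invert")
    mv = trait_table.mouse_values
    base = mv[["mouse_id", "strain_id"]].copy()
    vals = mv["value"].to_numpy(dtype=float)
    if assay == "TBI":
        if (vals > 100.0).any():
            bad = vals[vals > 100.0][0]
            raise ValueError(
                f"TBI of {bad:g}% is not representable (test binding would be "
                "below non-specific binding floor of 0 counts)"
            )
        span = TBI_NORMAL_BINDING - TBI_NONSPECIFIC_BINDING
        test = TBI_NONSPECIFIC_BINDING + (1.0 - vals / 100.0) * span
        out = base.assign(
            assay="TBI",
            test_binding=test,
            normal_binding=TBI_NORMAL_BINDING,
            nonspecific_binding=TBI_NONSPECIFIC_BINDING,
        )
    elif assay == "TSAb":
        if (vals < 0.0).any():
            raise ValueError("negative percent-of-control TSAb is not representable")
        out = base.assign(
            assay="TSAb",
            test_cAMP=vals / 100.0 * TSAB_CONTROL_CAMP,
            control_cAMP=TSAB_CONTROL_CAMP,
        )
    elif assay == "ELISA":
        if (vals < 0.0).any():
            raise ValueError("negative optical density is not representable")
        out = base.assign(assay="ELISA", od_490=vals)
    elif assay == "T4":
        if (vals < 0.0).any():
            raise ValueError("negative T4 is not representable")
        out = base.assign(assay="T4", value=vals, timepoint="3x")
    else:
        raise ValueError(f"unknown assay kind {assay!r}")
    return out
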