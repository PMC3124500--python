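"""Run configuration and the end-to-end pipeline.

A run is described by a JSON-serializable :class:`RunConfig`.  Stages:
simulate (optional) -> phenotypes -> scan (+ permutations) -> combine
(optional).  Every artifact is tab-separated or JSON text carrying a
header comment with the tool version and the config digest; identical
config + seed reproduces byte-identical result files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd

from . import __version__
from . import geno, meta, phenotypes, scan as scanmod, simulate as simmod
from .panel import RIPanel, TraitTable, TraitVector


@dataclass
class RunConfig:
    out_dir: str = "riqtl_run"
    seed: int = 0
    # simulation block (used when geno_path is not given)
    simulate: bool = True
    n_strains: int = 26
    n_chromosomes: int = 20
    chromosome_length_cM: float = 99.0
    chromosome_length_Mb: float = 198.0
    marker_spacing_cM: float = 1.0
    qtl_chromosome: Optional[str] = None
    qtl_position_cM: float = 0.0
    qtl_additive_effect: float = 0.0
    qtl_high_allele: str = "A"
    trait_baseline: float = 0.0
    strain_sd: float = 1.0
    mouse_sd: float = 0.0
    mice_per_strain: int = 6
    cross: str = "sib"
    # external inputs (alternative to simulation)
    geno_path: Optional[str] = None
    trait_path: Optional[str] = None
    assay_path: Optional[str] = None
    evidence_path: Optional[str] = None
    # scan options
    n_permutations: int = 1000
    weighting: bool = False
    tie_tol: float = 0.01

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    def digest(self) -> str:
        """Hash of the result-determining fields (output location excluded)."""
        doc = asdict(self)
        doc.pop("out_dir")
        payload = json.dumps(doc, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    def sim_config(self) -> simmod.SimConfig:
        chrom_names = [str(i) for i in range(1, self.n_chromosomes)] + ["X"]
        chroms = tuple(
            simmod.Chromosome(
                name, self.chromosome_length_cM, self.chromosome_length_Mb
            )
            for name in chrom_names
        )
        qtl = None
        if self.qtl_chromosome is not None:
            qtl = simmod.QTLSpec(
                chromosome=self.qtl_chromosome,
                position_cM=self.qtl_position_cM,
                additive_effect=self.qtl_additive_effect,
                high_allele=self.qtl_high_allele,
            )
        return simmod.SimConfig(
            n_strains=self.n_strains,
            chromosomes=chroms,
            marker_spacing_cM=self.marker_spacing_cM,
            qtl=qtl,
            trait_baseline=self.trait_baseline,
            strain_sd=self.strain_sd,
            mouse_sd=self.mouse_sd,
            mice_per_strain=self.mice_per_strain,
            cross=self.cross,
            seed=self.seed,
        )


class RunLog:
    """Timestamped stage records; every stochastic stage logs its seed."""

    def __init__(self) -> None:
        self.records: list[dict[str, Any]] = []

    def add(self, stage: str, **info: Any) -> None:
        self.records.append(
            {"stage": stage, "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"), **info}
        )

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(self.records, indent=2) + "\n")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _header(config: RunConfig) -> str:
    return f" riqtl {__version__} config={config.digest()}"


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the configured stages, writing artifacts under ``out_dir``.

    Returns a results bundle: panel, trait table, per-trait scan results,
    permutation nulls, and the combined-linkage result when evidence is
    supplied.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = RunLog()
    (out / "config.json").write_text(config.to_json() + "\n")
    hdr = _header(config)
    bundle: dict[str, Any] = {"config": config}

    # --- acquire a panel ----------------------------------------------
    stage = "simulate" if config.geno_path is None else "read_geno"
    try:
        if config.geno_path is None:
            if not config.simulate:
                raise ValueError("no geno_path and simulation disabled")
            sim_cfg = config.sim_config()
            panel = simmod.simulate_ri_genotypes(sim_cfg)
            geno.write_geno(panel, out / "panel.geno", header_comment=hdr)
            log.add(stage, seed=config.seed, n_markers=panel.n_markers,
                    n_strains=panel.n_strains)
        else:
            panel = geno.read_geno(config.geno_path)
            log.add(stage, path=config.geno_path, n_markers=panel.n_markers,
                    n_strains=panel.n_strains)
    except Exception as exc:
        raise StageError(stage, exc) from exc
    bundle["panel"] = panel

    # --- phenotypes ----------------------------------------------------
    stage = "phenotypes"
    try:
        if config.assay_path is not None:
            records = geno.read_assay_table(config.assay_path)
            long = phenotypes.compute_trait(records)
            table = phenotypes.strain_summary(long)
        elif config.trait_path is not None:
            table = geno.read_trait_table(config.trait_path)
        else:
            table, truth = simmod.simulate_trait(panel, config.sim_config())
            bundle["truth"] = truth
        geno.write_trait_table(table, out / "traits.tsv", header_comment=hdr)
        log.add(stage, traits=table.traits())
    except Exception as exc:
        raise StageError(stage, exc) from exc
    bundle["trait_table"] = table

    # --- scan + permutations ------------------------------------------
    stage = "scan"
    scans: dict[str, scanmod.LinkageResult] = {}
    nulls: dict[str, scanmod.PermutationNull] = {}
    try:
        for trait_name in table.traits():
            vec = table.vector(trait_name)
            weights = None
            if config.weighting and vec.sem is not None:
                sem = np.asarray(vec.sem, dtype=float)
                if np.all(sem > 0):
                    weights = 1.0 / sem**2
            result = scanmod.genome_scan(
                panel, vec, weights=weights, tie_tol=config.tie_tol
            )
            null = scanmod.permutation_thresholds(
                panel, vec, n_permutations=config.n_permutations,
                seed=config.seed,
            )
            result.genomewide_p = null.genomewide_p(result.peak_lrs)
            scans[trait_name] = result
            nulls[trait_name] = null
            safe = trait_name.replace("/", "_")
            tab = result.table.rename(
                columns={
                    "marker": "Locus", "chromosome": "Chr",
                    "position_cM": "cM", "position_Mb": "Mb",
                    "lrs": "LRS", "lod": "LOD",
                }
            )
            geno._write_tsv(
                tab[["Chr", "Locus", "cM", "Mb", "LRS", "LOD", "additive",
                     "n_used"]],
                out / f"scan_{safe}.tsv", header_comment=hdr,
            )
            peak = {
                "trait": trait_name,
                "peak_lrs": round(result.peak_lrs, 4),
                "peak_lod": round(result.peak_lod, 4),
                "peak_markers": list(result.peak_markers["marker"]),
                "interval_Mb": [round(m, 3) for m in result.interval_Mb],
                "genomewide_p": result.genomewide_p,
                "significant_threshold": round(null.significant, 4),
                "suggestive_threshold": round(null.suggestive, 4),
                "n_permutations": null.n_permutations,
                "permutation_seed": null.seed,
            }
            (out / f"peaks_{safe}.json").write_text(
                json.dumps({"_header": hdr.strip(), **peak}, indent=2) + "\n"
            )
            log.add(stage, trait=trait_name, peak_lrs=result.peak_lrs,
                    permutation_seed=config.seed)
    except Exception as exc:
        raise StageError(stage, exc) from exc
    bundle["scans"] = scans
    bundle["nulls"] = nulls

    # --- combine -------------------------------------------------------
    if config.evidence_path is not None:
        stage = "combine"
        try:
            combined = combine_from_file(config.evidence_path)
            (out / "combined.json").write_text(
                json.dumps(
                    {
                        "_header": hdr.strip(),
                        "families": list(combined.families),
                        "chromosome": combined.chromosome,
                        "interval_Mb": list(combined.interval_Mb),
                        "chi2": round(combined.chi2, 4),
                        "df": combined.df,
                        "p": combined.p,
                        "combined_lod": round(combined.lod, 4),
                    },
                    indent=2,
                )
                + "\n"
            )
            log.add(stage, families=list(combined.families))
            bundle["combined"] = combined
        except Exception as exc:
            raise StageError(stage, exc) from exc

    log.write(out / "runlog.json")
    return bundle


def combine_from_file(path: str | Path) -> meta.CombinedResult:
    """Build family evidence from a TSV or JSON file and combine it.

    Columns/keys: family, chromosome, start_Mb, end_Mb and either p or
    lrs (+ optional mode, default chi2_df1).
    """
    path = Path(path)
    if path.suffix == ".json":
        raw = json.loads(path.read_text())
        rows = raw if isinstance(raw, list) else raw["families"]
        df = pd.DataFrame(rows)
    else:
        df = pd.read_csv(path, sep="\t", comment="#")
    ev = []
    for _, row in df.iterrows():
        if "p" in row and not pd.isna(row.get("p")):
            ev.append(
                meta.FamilyEvidence(
                    family_id=str(row["family"]),
                    chromosome=str(row["chromosome"]),
                    start_Mb=float(row["start_Mb"]),
                    end_Mb=float(row["end_Mb"]),
                    p=float(row["p"]),
                )
            )
        elif "lrs" in row and not pd.isna(row.get("lrs")):
            ev.append(
                meta.FamilyEvidence.from_lrs(
                    family_id=str(row["family"]),
                    chromosome=str(row["chromosome"]),
                    start_Mb=float(row["start_Mb"]),
                    end_Mb=float(row["end_Mb"]),
                    lrs=float(row["lrs"]),
                    mode=str(row.get("mode", "chi2_df1")),
                )
            )
        else:
            raise ValueError(
                f"evidence row for {row.get('family')!r} has neither p nor lrs"
            )
    return meta.combine_families(ev)
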