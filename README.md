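# riqtl

QTL mapping toolkit for recombinant-inbred (RI) mouse strain panels.
It covers the analysis chain used for induced autoimmune-thyroid serology
studies on RI sets:

* **Phenotypes** — serological and endocrine traits from raw assay values:
  TSH binding inhibition (`[1 - (test - nsb)/(normal - nsb)] × 100`),
  thyroid-stimulating antibody activity as percent of control cAMP, the
  human:mouse stimulation ratio, delta-T4, per-strain mean ± SEM
  summaries, and control-based elevation cut-offs (mean + 2 SD).
* **Genome scans** — single-marker Gaussian likelihood-ratio statistics
  on strain means (`LRS = n·ln(RSS₀/RSS₁)`), additive effects (half the
  difference of parental-class means, positive = A allele raises the
  trait), LOD = LRS/4.61, permutation genome-wide thresholds
  (significant p 0.05, suggestive p 0.63) and peak/interval reports.
* **Combined linkage** — Fisher's method across RI families sharing an
  interval: χ² = −2·Σln pᵢ on 2k df, combined p from the χ² upper tail,
  combined LOD = −log₁₀(p).
* **Simulation** — RI panels as two-state Markov chains along each
  chromosome with the sib-mating map expansion R = 4r/(1+6r) (Haldane
  cM→r; selfing variant available), planted-QTL traits with
  between-strain and within-strain noise, and raw assay values that
  round-trip exactly through the phenotype formulas.
* **I/O** — GeneNetwork-style `.geno` genotype files, tab-separated trait
  and assay tables, JSON run configs, and a reproducible pipeline runner
  (byte-identical outputs under identical config + seed).

## Test

```sh
python -m pytest -q tests/
```

The suite includes unit tests per module, hypothesis property tests, and
an acceptance suite (`tests/test_acceptance.py`) checking published-value
fidelity, permutation-threshold calibration, oracle equivalence of the
LRS engine, and planted-QTL parameter recovery. The full run takes a few
minutes; most of it is the 500-replicate null-calibration check.

## CLI

```sh
riqtl simulate --seed 3 --qtl 2:20:3.0 --out scratch/sim
riqtl scan --geno scratch/sim/panel.geno --traits scratch/sim/traits.tsv --out scratch/scan.tsv
riqtl permute --geno scratch/sim/panel.geno --traits scratch/sim/traits.tsv \
      --n-permutations 1000 --seed 1 --out scratch/perm.json
riqtl combine --evidence examples/evidence_chr12.tsv
riqtl run --config examples/demo_config.json
```

`riqtl run` executes the full pipeline (simulate → phenotypes → scan +
permutations → combine) from a JSON config; see
`examples/demo_config.json`. Every artifact carries the tool version and
a config digest in its header; stochastic stages log their seeds in
`runlog.json`.

## Layout

```
src/riqtl/
  panel.py       core containers: RIPanel, TraitTable, TraitVector
  simulate.py    RI genotype/trait/assay simulation
  phenotypes.py  assay formulas and strain summaries
  scan.py        LRS genome scan, LOD conversion, permutation thresholds
  meta.py        Fisher combined linkage
  geno.py        .geno and TSV readers/writers
  pipeline.py    RunConfig, RunLog, run_pipeline
  cli.py         click command-line interface
```
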