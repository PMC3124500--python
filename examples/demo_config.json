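{
  "out_dir": "scratch/demo_run",
  "seed": 42,
  "simulate": true,
  "n_strains": 26,
  "n_chromosomes": 8,
  "chromosome_length_cM": 60.0,
  "chromosome_length_Mb": 120.0,
  "marker_spacing_cM": 1.0,
  "qtl_chromosome": "3",
  "qtl_position_cM": 30.0,
  "qtl_additive_effect": 2.5,
  "qtl_high_allele": "A",
  "trait_baseline": 100.0,
  "strain_sd": 1.0,
  "mouse_sd": 0.5,
  "mice_per_strain": 6,
  "cross": "sib",
  "n_permutations": 500,
  "evidence_path": "examples/evidence_chr12.tsv"
}
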