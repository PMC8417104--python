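# Example pipeline configuration for `repfeat run --config ...`.
# Paths are relative to the working directory; depths shown are desk-scale
# values matching the synthetic fixture studies.  For full-scale UMI studies
# the defaults (diversity 1000; RTE 1524 / mnCD4 1063 / nTreg 953; publicity
# top 13000 at 23000-31000 UMIs) apply when the keys are omitted.
manifest: study/manifest.tsv
out_dir: study/results
diversity_depth: 100
segment_depths:
  nTreg: 100
publicity_top_n: 300
publicity_equal_umi:
  nTreg: 1500
master_seed: 4
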