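# Bundled two-condition demo: villustat run --config examples/demo_config.yaml
outdir: scratch/demo_out
seed: 1
n_perm: 1000
conditions:
  WT:
    tissue: {preset: wt_like, n_genes: 1000}
    repertoire: {preset: wt_like}
  cKO:
    tissue: {preset: cko_like, n_genes: 1000}
    repertoire: {preset: cko_like}
composition:
  n_per_sample: {WT_1: 5000, WT_2: 5000, cKO_1: 5000, cKO_2: 5000}
  sample_groups: {WT_1: WT, WT_2: WT, cKO_1: cKO, cKO_2: cKO}
  subset_probs:
    WT:  {CD4_Tn: 0.30, CD4_Tem: 0.15, CD8_Tn: 0.25, CD8_Tem: 0.12, CD8_Teff: 0.08, Treg: 0.10}
    cKO: {CD4_Tn: 0.24, CD4_Tem: 0.15, CD8_Tn: 0.20, CD8_Tem: 0.12, CD8_Teff: 0.19, Treg: 0.10}
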