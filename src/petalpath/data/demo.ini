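# Demo pipeline configuration: synthetic study, all stages.
# Run with:  petalpath run-all --config demo.ini

[output]
dir = petalpath_demo_out
seed = 42
stages = simulate,expression,snps,paralogs,report

[simulate]
# study design: 8 samples per phenotype group, NB dispersion 0.1,
# 10% of genes planted at |log2FC| = 3, one near-silent paralog copy
n_genes = 200
library_size_range = 100000,200000
dispersion = 0.1
de_fraction = 0.1
de_log2fc = 3.0

[expression]
fdr = 1e-5
lfc = 1.0

[snps]
min_diff = 0.25
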