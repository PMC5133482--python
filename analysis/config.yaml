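# Shared configuration for the numbered analysis scripts.
# Full-scale synthetic cohort: 20 extended families of 27-107 members,
# 3 visits, covariate effects and antihypertensive treatment switched on,
# 5000 SNPs of which SNP 42 is causal on the first-visit latent BP.
outdir: results/run
seed: 2026
models: [ar, lg]
visits_used: 3
threshold: 1.0e-5
n_starts: 3
make_plots: true
simulate:
  n_families: 20
  n_children_range: [4, 10]
  n_grandchildren_range: [2, 8]
  family_size_range: [27, 107]
  n_snps: 5000
  causal_snps: {42: 6.0}
ped_file: results/run/data/pedigree.ped
pheno_file: results/run/data/phenotypes.csv
geno_file: results/run/data/genotypes.tsv
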