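# brainprot

Region-resolved analysis of brain proteome maps. The package implements the
statistical pipeline used to chart protein expression across 13 gross
neuroanatomical divisions (FL, TL, PL, OL, CB, BS, THA/HT, OC, CC, VT, HIP,
AN, OB/OT) sampled from multiple donors: normalization and QC of a
label-free intensity matrix, donor-blocked region ANOVA, region-specific
protein calling, cumulative-abundance structure, region-correlation
modules, and proteome–transcriptome specificity concordance. A
synthetic-data generator with planted ground truth makes every stage
testable, so the pipeline's operating characteristics (sensitivity, FDR,
calibration) are measured rather than assumed.

It is written for computational proteomics practitioners who start from a
quantified protein × sample matrix (e.g. a DIA search output) plus a sample
annotation table, and want auditable region-specificity calls.

## The model

Intensities are normalized per sample to parts-per-million of the observed
total, then log2 transformed. For protein *g* in sample *i* of donor *j*
and region *r* the working model is

    y_gij = mu_g + beta_gr + d_gj + eps_gij,
    d_gj ~ N(0, sigma_d^2),   eps ~ N(0, sigma_e^2),

so samples of one donor share a compound-symmetry correlation
rho = sigma_d² / (sigma_d² + sigma_e²). A single consensus rho is pooled
across proteins (method-of-moments residual cross-products with an exact
design-based attenuation correction, Fisher-z trimmed mean, delete-one-donor
jackknife), each donor block is whitened with the closed-form inverse
square root of the compound-symmetry matrix,

    y* = (y − c·ȳ_block)/√(1−rho),  c = 1 − √((1−rho)/(1+(m−1)rho)),

and an ordinary one-way region ANOVA runs on y*. A protein is called
**region-specific** when its highest-mean region exceeds the pooled
remaining regions by ≥ 1.5-fold and the Benjamini–Hochberg adjusted ANOVA
p-value is < 0.01. The RNA side applies the consensus-transcriptomics rule:
nTPM < 1 is floored to missing, and a gene is region-specific when its
maximum log2 nTPM is at least twice the mean log2 nTPM of the remaining
regions.

## Worked example

```sh
python examples/02_region_specific_calling.py
```

plants 10 markers per region (log2 effect 2) among 2,000 proteins across
13 regions × 8 donors and runs the full calling pipeline:

```
consensus intra-donor correlation: 0.254 (planted 0.265)
called 122 proteins region-specific (130 markers planted)
sensitivity 0.94  empirical FDR 0.000  region accuracy 1.00

top 3 called proteins per region (fold change vs remaining regions):
region  rank protein_id  fc_vs_rest
    FL     1     P00705    5.225193
    FL     2     P01235    4.585327
    FL     3     P00784    4.343785
    ...
```

The consensus correlation recovers the planted donor effect, 94% of the
planted markers are called with no false calls, and every true positive is
assigned to its planted region. The other scripts under `examples/` walk
through QC (`01`), abundance quartiles (`03`), region modules (`04`),
cross-omics concordance (`05`) and the benchmark operating characteristics
(`06`).

The same stages are available from a shell:

```sh
brainprot simulate --out sim --seed 1 --n-proteins 500 --markers-per-region 5
brainprot run-all --matrix sim/matrix.tsv --samples sim/samples.tsv \
    --rna sim/rna.tsv --idmap sim/idmap.tsv --out results --seed 1
```

`run-all` chains normalize → qc → specificity → quartiles → modules →
crossomics and writes TSVs plus a run manifest; identical inputs and seed
yield byte-identical tables.

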