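"""Compare protein-level region specificity with an RNA nTPM table.

Generates a matched transcriptome in the coarser RNA vocabulary (the four
lobes and OB/OT collapse onto cortex), calls RNA region specificity with
the log2-ratio rule (nTPM < 1 floored to missing), and classifies every
protein as detected by both omics, one of them, background, or unmapped.
"""

from brainprot import (
    GeneratorParams,
    call_region_specific,
    generate_proteome_dataset,
    generate_rna_table,
)
from brainprot.crossomics import concordance_classify, map_protein_regions_to_rna, rna_specificity
from brainprot.preprocess import normalize

params = GeneratorParams(
    n_proteins=1500, markers_per_region=10, rna_concordance=0.6,
    unmapped_fraction=0.1, seed=5,
)
matrix, annotations, truth = generate_proteome_dataset(params)
rna, id_map = generate_rna_table(truth, params)

result = call_region_specific(normalize(matrix), annotations)
mapped = map_protein_regions_to_rna(result.table)
classes = concordance_classify(mapped, rna_specificity(rna), id_map)

print(classes["class"].value_counts().to_string())
both = classes[classes["class"] == "both"]
agree = both["region_agreement"].mean() if len(both) else float("nan")
print(f"\nregion agreement within 'both': {agree:.2f}")
print(
    "\n'both' proteins are region-specific in proteome and transcriptome"
    "\n(60% of markers were planted RNA-concordant); 'protein_only' calls"
    "\nreflect specificity visible only at the protein level, the dominant"
    "\npattern in cross-omics brain surveys."
)
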