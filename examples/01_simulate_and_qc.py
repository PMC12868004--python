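"""Simulate a region-resolved proteome and inspect its quality control.

Generates the default synthetic study (13 brain regions x 8 donors, 99
samples, 4,660 proteins with intensity-dependent missingness), normalizes
to ppm and prints the QC summaries a mass-spectrometry survey would report.
"""

from brainprot import GeneratorParams, generate_proteome_dataset, qc_report, to_ppm

params = GeneratorParams(seed=1)
matrix, annotations, truth = generate_proteome_dataset(params)
report = qc_report(matrix, to_ppm(matrix), annotations)

print(f"samples: {len(annotations)}  proteins: {len(matrix.protein_ids)}")
print(f"median protein missing rate: {100 * report.median_missing_fraction:.1f}%")
print(f"overall missing cells: {100 * matrix.missing_fraction():.1f}%")
print("\nper-region identification and dynamic range:")
print(report.regions.to_string(index=False))
print(
    "\nThe median missing rate is the completeness statistic label-free DIA"
    "\nstudies report (~16% here); the dynamic range shows the ppm"
    "\nintensities span several orders of magnitude within each region."
)
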