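"""Call region-specific proteins with the donor-blocked ANOVA pipeline.

Plants 10 markers per region (log2 effect 2) in a 2,000-protein survey,
runs ppm + log2 normalization, estimates the consensus intra-donor
correlation, whitens donor blocks and applies the calling rule
(BH-adjusted p < 0.01 and fold change >= 1.5 vs the remaining regions).
"""

from brainprot import GeneratorParams, call_region_specific, generate_proteome_dataset
from brainprot.evaluate import recovery_metrics
from brainprot.preprocess import normalize
from brainprot.specificity import top_k_per_region

params = GeneratorParams(n_proteins=2000, markers_per_region=10, seed=2)
matrix, annotations, truth = generate_proteome_dataset(params)
result = call_region_specific(normalize(matrix), annotations)

report = recovery_metrics(result.table, truth)
print(f"consensus intra-donor correlation: {result.rho:.3f} "
      f"(planted {truth.rho_true:.3f})")
print(f"called {report.n_calls} proteins region-specific "
      f"({report.n_markers} markers planted)")
print(f"sensitivity {report.sensitivity:.2f}  "
      f"empirical FDR {report.empirical_fdr:.3f}  "
      f"region accuracy {report.region_accuracy:.2f}")

top = top_k_per_region(result.table, k=3)
print("\ntop 3 called proteins per region (fold change vs remaining regions):")
print(top.head(12).to_string(index=False))
print(
    "\nSamples from one donor co-vary, so the F-test whitens each donor"
    "\nblock with the consensus correlation before testing region effects;"
    "\nthe fold change compares the top region with the pooled rest."
)
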