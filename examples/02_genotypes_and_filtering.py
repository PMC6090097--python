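"""From VCF allele depths to a filtered allele-frequency genotype matrix.

Genotypes are never called: each cell is the alternative-read fraction, a
continuous dosage proxy in [0, 1] that captures tetraploid allele dosage
from shallow sequencing.  Markers are then filtered on coverage, minor
allele frequency and missingness, and a stringent high-completeness subset
is derived.
"""

import os

import tetrags as tg

OUT = os.path.join(os.path.dirname(__file__), "output")
vcf_path = os.path.join(OUT, "study.vcf")
if not os.path.exists(vcf_path):
    raise SystemExit("run 01_simulate_study.py first")

depths = tg.read_vcf_allele_depths(vcf_path)
af = tg.compute_allele_frequencies(depths)
print(f"allele-frequency matrix: {af.n_samples} samples x {af.n_loci} loci, "
      f"{100 * af.missing.mean():.1f}% missing (zero-depth) cells")

filtered, report = tg.filter_markers(af)   # coverage 5-60x, MAF 1%, missingness
print("\nfilter cascade (rule: removed):")
for step in report.steps:
    print(f"  {step['rule']:20s} {step['removed']:5d} {step['axis']}")
print(f"surviving: {report.n_output_samples} samples x {report.n_output_loci} loci")

strict, sreport = tg.stringent_marker_set(filtered)
print(f"\nstringent set (<=1% missing per marker, samples <=10% missing): "
      f"{strict.n_samples} samples x {strict.n_loci} loci")
print("fewer but near-complete markers: this is the set that removes "
      "library-batch artifacts (see example 03)")

filtered.write_tsv(os.path.join(OUT, "af_filtered.tsv"))
print("\nwrote af_filtered.tsv")
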