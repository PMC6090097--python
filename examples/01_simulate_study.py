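"""Simulate a three-panel tetraploid breeding study and write its files.

Builds a scaled version of a typical design: a large unselected diallel
population, a small selected panel from the same founders, and a selected
panel from a mostly distinct founder pool; then records multi-environment
phenotypes and GBS read depths (one sequencing library per panel, with
batch-specific marker dropout) and writes VCF + TSV outputs.
"""

import os

import tetrags as tg

OUT = os.path.join(os.path.dirname(__file__), "output")
os.makedirs(OUT, exist_ok=True)

study = tg.simulate_study(
    n_loci=1000, n_founders=12, maspot_size=120, dk_size=40, uk_size=60,
    n_uk_founders=10, uk_founder_overlap=2, n_qtl=100, heritability=0.6,
    seed=11)

for label, pop in study["populations"].items():
    print(f"{label:8s} n={pop.n:4d}  mean dosage="
          f"{pop.dosages.mean():.3f} (2.0 expected at allele frequency 0.5)")
print(f"shared varieties genotyped in two batches: {len(study['duplicate_pairs'])}")

records = study["records"]
print(f"\nphenotype records: {len(records)} rows over years "
      f"{sorted(records['year'].unique())} and locations "
      f"{sorted(records['location'].unique())}")

depths = study["depths"]
frac_missing = (depths.total_depth == 0).mean()
print(f"GBS depth matrix: {len(depths.sample_ids)} samples x "
      f"{len(depths.locus_ids)} loci, {100 * frac_missing:.1f}% zero-depth cells "
      "(library dropout + sampling)")

vcf_path = os.path.join(OUT, "study.vcf")
tg.write_vcf_allele_depths(depths, vcf_path)
records.to_csv(os.path.join(OUT, "phenotypes.tsv"), sep="\t", index=False)
print(f"\nwrote {vcf_path} and phenotypes.tsv")
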