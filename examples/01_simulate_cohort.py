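"""Simulate a three-group whole-blood methylation cohort.

Builds the default study design (controls, obese, CRC patients with the
cohort's age structure), plants differentially methylated regions of
every concordance class, and prints what the generator produced.
"""

from methcrossover import SimulationConfig, make_planted_regions, simulate_methylation

regions = make_planted_regions(
    {"concordant_hyper": 5, "concordant_hypo": 5, "obesity_only": 3, "crc_only": 3},
    n_chrom=2,
    n_cpgs=5,
    effect=0.3,
)
config = SimulationConfig(n_chrom=2, cpg_per_chrom=500, planted_regions=regions, seed=1)
callsets, sheet, truth = simulate_methylation(config)

print(f"samples: {len(callsets)}  (groups: {sheet['group'].value_counts().to_dict()})")
print(f"CpG sites per sample: {len(callsets[0])}")
print(f"mean coverage: {callsets[0].data['coverage'].mean():.1f}x")
print("\nplanted regions by class:")
print(truth["class"].value_counts().to_string())
print("\nfirst calls of the first control sample:")
print(callsets[0].data.head(3).to_string(index=False))

# Each sample shares the same CpG coordinates; methylated counts are
# beta-binomial draws around a bimodal background, shifted inside the
# planted regions for the affected group(s).  The truth table is what
# recovery benchmarks score against.
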