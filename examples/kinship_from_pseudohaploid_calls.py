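"""Classify relationship degrees from pseudo-haploid calls.

Simulates the six-member jar-coffin family at 50,000 unlinked SNPs with 30%
site dropout, normalizes each pair's mismatch rate (PMR) by the median PMR
of a simulated unrelated panel, and assigns degrees at the midpoints between
the expected values 0.5/0.75/0.875/0.9375/1.0 x baseline.  Expect six
first-degree, two second-degree and one third-degree pair; the two pairs at
kinship 1/32 sit exactly on the third/unrelated boundary and can print
either label.
"""

from paleokin import pipeline

scen = pipeline.simulate_jar_coffin_scenario(seed=11, n_snps=50_000,
                                             missingness=0.3, panel_size=40)
cfg = pipeline.RunConfig(seed=11)
report = pipeline.run_kinship_pipeline(
    scen["sample"], scen["meta"], scen["panel"], scen["snp_panel"], cfg,
    enumerate_pedigrees=False)

cols = ["individual_a", "individual_b", "n_overlap", "pmr",
        "normalized_pmr", "degree"]
print(report.kinship_table[cols].round(4).to_string(index=False))
print("\nbaseline (panel median PMR):", round(report.baseline.baseline, 4))
print("degree counts:", {k: v for k, v in report.degree_counts.items() if v})
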