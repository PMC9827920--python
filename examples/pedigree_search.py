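"""Enumerate pedigrees consistent with a degree matrix.

Given pairwise degrees, parent-offspring/full-sibling calls, sexes, age
classes and uniparental haplogroups, the search tries every pedigree within
bounds on latent connectors and generations, keeps those whose expected
kinship reproduces the degrees, and ranks them by how much of the observed
mt/Y haplogroup sharing they explain.  For the jar-coffin degree pattern the
top pedigree is the couple + two children, the mother's son by another
father (mother-son preferred over father-daughter because he shares the
children's mtDNA), and a paternal-line third-degree relative of the father.
"""

import itertools

from paleokin import pipeline, simulate
from paleokin.pedigree import co_maximal, enumerate_pedigrees

scen = pipeline.simulate_jar_coffin_scenario(seed=5, n_snps=1_000,
                                             missingness=0.0, panel_size=2)
truth = scen["truth"]
ids = scen["sample"].individual_ids
degrees = {frozenset({a, b}): truth.degree(a, b)
           for a, b in itertools.combinations(ids, 2)}
types = {}
for pair, (k0, k1, k2) in truth.k_coefficients.items():
    if (k0, k1, k2) == (0.0, 1.0, 0.0):
        types[pair] = "parent_offspring"
    elif (k0, k1, k2) == (0.25, 0.5, 0.25):
        types[pair] = "full_sibling"
types = {p: t for p, t in types.items() if p <= set(ids)}

reports = enumerate_pedigrees(scen["meta"], degrees, types, max_latent=2)
print(f"{len(reports)} consistent pedigrees, "
      f"{len(co_maximal(reports))} co-maximal\n")
best = reports[0]
print(f"top-ranked (score {best.score}, explains "
      f"{len(best.satisfied)} haplogroup/age observations):\n")
print(best.pedigree.render())
print("\n(~ prefixes mark latent, unsampled connector individuals)")
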