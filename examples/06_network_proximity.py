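"""Score drug modules against a disease module by network proximity.

p(T, S) averages, over drug targets, the hop distance to the nearest
disease gene; f(p) squashes the normalized closeness through a sigmoid,
so drugs whose targets sit next to the disease module score near 1.  The
permutation p-value compares the observed proximity against degree-
matched random target sets.
"""

from convergene import netprox, synthdata

fixture = synthdata.simulate_interactome(drug_distance=(1, 2, 3), seed=5)
results = netprox.score_drug_modules(
    fixture.graph, fixture.drug_modules, fixture.disease_module
)
print("drug   p(T,S)   f(p)")
for r in sorted(results, key=lambda r: r.p):
    print(f"{r.drug}  {r.p:6.2f}  {r.f:.3f}")

nearest = min(results, key=lambda r: r.p)
obs, pval = netprox.proximity_significance(
    fixture.graph,
    fixture.drug_modules[nearest.drug],
    fixture.disease_module,
    n_permutations=999,
    seed=0,
)
print(f"\n{nearest.drug}: observed p = {obs:.2f}, "
      f"permutation p-value = {pval:.3f} "
      "(closer than degree-matched random target sets)")
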