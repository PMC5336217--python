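"""Per-population diversity and its geographic gradient.

Builds the study-shaped synthetic dataset (91 populations, 2,008 diploid
trees, 14 SSR loci, west-to-east founder gradient), computes the
per-population diversity table (A, Ae, Ho, HE, UHE, rarefied Rs and PAR,
FIS) and regresses diversity on geography with Holm correction.
"""

from walnutpg.diversity import geo_regression, locus_summary, population_diversity
from walnutpg.synthetic import study_shape_fixture

ds, meta = study_shape_fixture(seed=1)
per_locus = locus_summary(ds)
print(f"{ds.n_populations} populations, {ds.n_individuals} individuals, "
      f"{ds.n_loci} loci, {int(per_locus['A'].sum())} alleles "
      f"({per_locus['A'].mean():.2f} per locus)")

summary = population_diversity(ds, g=16)   # rarefied to 8 diploids
print("\nFirst five populations (west -> east):")
print(summary.head()[["n", "A", "Ho", "UHE", "Rs", "PAR", "FIS"]].round(3))

reg = geo_regression(summary, meta)
print("\nDiversity ~ geography (Holm-adjusted):")
print(reg.round(4).to_string(index=False))
print("\nA positive, significant Rs~longitude slope is the built-in "
      "west-to-east richness gradient: eastern populations kept more of "
      "the ancestral allele pool.")
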