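"""Circular-permutation clustering test for annotated site pairs.

Three annotated sites on a 5-kb transcript; contacts between the first
two are planted at 10x background. The null shifts each window pair
jointly around the transcript in 50-nt steps (preserving separation);
one-sided t-tests with Bonferroni correction flag the planted pair.
"""

import chimeramap as cm

transcript = cm.random_transcript(5000, gc=0.4, seed=41)
bg_frac = 2 * (100 / 5000) ** 2
stem_frac = 9 * bg_frac / (1 + 9 * bg_frac)
model = cm.StructureModel(
    transcript,
    [cm.StemSpec((970, 1030), (2970, 3030))],
    background_rate=1 - stem_frac,
)
replicates = [cm.simulate_chimeras(model, 20_000, seed=50 + r) for r in range(3)]

sites = [
    cm.SiteCluster("site1", 1000, radius=50),
    cm.SiteCluster("site2", 3000, radius=50),
    cm.SiteCluster("site3", 4200, radius=50),
]
results = cm.circular_permutation_test(replicates, sites, 5000, step=50)
for res in results:
    print(
        f"{res.pair[0]}-{res.pair[1]}: observed {res.mean_observed:6.1f}  "
        f"permuted {res.mean_permuted:5.1f}  t = {res.t_statistic:6.2f}  "
        f"p = {res.p_value:.2e}  Bonferroni p = {res.p_adjusted:.2e}"
    )

per_site, random_mean = cm.site_vs_random_interaction_counts(
    replicates[0], sites, 5000, total_mapped=20_000, seed=60
)
print(f"\nper-site CPM vs mean of 116 random 110-nt fragments ({random_mean:.0f} CPM):")
for name, v in per_site.items():
    print(f"  {name}: {v:.0f} CPM")
# Only the planted pair clears Bonferroni-adjusted p <= 0.05; the other
# pairs sit at their circular-permutation background.
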