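"""DMS mutational profiling: rates, paired/unpaired separation,
replicate correlation.

Simulates two sequencing replicates of a DMS-probed transcript whose
first half is base-paired, builds reactivity profiles (A/C positions
with coverage >= 1,000) and tests the structural signal.
"""

import chimeramap as cm

transcript = cm.random_transcript(300, gc=0.5, seed=81)
paired = frozenset(range(0, 150))
dms = cm.DmsModel(
    transcript, paired=paired,
    rate_paired=0.005, rate_unpaired=0.05, coverage=8000, profile_seed=82,
)

profiles = [
    cm.mutation_rates(cm.simulate_dms(dms, seed=s), min_cov=1000) for s in (83, 84)
]
prof = profiles[0]
print(f"masked-in A/C positions: {int(prof.mask.sum())} of {len(prof.table)}")

res = cm.paired_unpaired_test(prof, paired)
print(
    f"median rate paired {res.median_paired:.4f} vs unpaired "
    f"{res.median_unpaired:.4f}  (n = {res.n_paired}/{res.n_unpaired})"
)
print(f"rank-sum p (two-sided) = {res.p_two_sided:.2e}, "
      f"one-sided unpaired>paired = {res.p_one_sided:.2e}")

rho, n_shared = cm.profile_correlation(profiles[0], profiles[1])
print(f"replicate Spearman rho = {rho:.3f} over {n_shared} shared positions")
# Unpaired A/C bases mutate ~10x more often than paired ones, and two
# replicates of the same accessibility profile correlate near 1.
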