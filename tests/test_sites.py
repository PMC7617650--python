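"""Circular-permutation site-pair clustering tests."""

import numpy as np
import pytest
from scipy import stats

import chimeramap as cm
from chimeramap.io import ChimeraRecord


def _rec(i, s1, s2, L=5000):
    return ChimeraRecord(f"r{i}", ("tx", s1, s1 + 20), ("tx", s2, s2 + 20))


@pytest.fixture(scope="module")
def background_model():
    t = cm.random_transcript(5000, gc=0.4, seed=61)
    return cm.StructureModel(t, [], background_rate=1.0)


class TestPairContactCounts:
    def test_no_chimeras_in_windows(self):
        a, b = cm.SiteCluster("A", 1000), cm.SiteCluster("B", 3000)
        recs = [_rec(0, 100, 200), _rec(1, 4000, 4500)]
        assert cm.pair_contact_counts(recs, a, b, 5000) == 0

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(5)
        recs = [
            _rec(i, int(rng.integers(0, 2400)), int(rng.integers(2400, 4900)))
            for i in range(2000)
        ]
        a, b = cm.SiteCluster("A", 1000), cm.SiteCluster("B", 3000)
        got = cm.pair_contact_counts(recs, a, b, 5000)
        wa, wb = (950, 1050), (2950, 3050)
        expected = 0
        for r in recs:
            m1, m2 = r.midpoints()
            in_a = wa[0] <= m1 < wa[1] or wa[0] <= m2 < wa[1]
            in_b = wb[0] <= m1 < wb[1] or wb[0] <= m2 < wb[1]
            hit_a1 = wa[0] <= m1 < wa[1]
            hit_a2 = wa[0] <= m2 < wa[1]
            hit_b1 = wb[0] <= m1 < wb[1]
            hit_b2 = wb[0] <= m2 < wb[1]
            expected += int((hit_a1 and hit_b2) or (hit_a2 and hit_b1))
        assert got == expected

    def test_default_radius_is_50(self):
        assert cm.SiteCluster("A", 1000).radius == 50

    def test_overlapping_windows_error(self):
        a, b = cm.SiteCluster("A", 1000), cm.SiteCluster("B", 1050)
        with pytest.raises(ValueError):
            cm.pair_contact_counts([], a, b, 5000)


class TestCircularPermutationTest:
    def test_identity_shift_reproduces_observed(self, background_model):
        reps = [cm.simulate_chimeras(background_model, 5000, seed=s) for s in (1, 2)]
        a, b = cm.SiteCluster("A", 1000), cm.SiteCluster("B", 3000)
        res = cm.circular_permutation_test(reps, [a, b], 5000, step=50)[0]
        for r, chimeras in enumerate(reps):
            assert res.observed[r] == cm.pair_contact_counts(chimeras, a, b, 5000)

    def test_planted_tenfold_pair_significant_after_bonferroni(self):
        """A site pair with 10x contact enrichment over uniform background
        (3 replicates of 20,000 chimeras) reaches adjusted p <= 0.05."""
        t = cm.random_transcript(5000, gc=0.4, seed=62)
        # stem arms sit inside the two site windows; stem fraction chosen
        # so in-window contacts total 10x the background expectation
        bg_frac = 2 * (100 / 5000) ** 2
        stem_frac = 9 * bg_frac / (1 + 9 * bg_frac)
        model = cm.StructureModel(
            t, [cm.StemSpec((970, 1030), (2970, 3030))],
            background_rate=1 - stem_frac,
        )
        reps = [cm.simulate_chimeras(model, 20_000, seed=100 + r) for r in range(3)]
        sites = [
            cm.SiteCluster("planted_a", 1000),
            cm.SiteCluster("planted_b", 3000),
            cm.SiteCluster("decoy", 4200),
        ]
        results = cm.circular_permutation_test(reps, sites, 5000, step=50)
        planted = next(r for r in results if r.pair == ("planted_a", "planted_b"))
        assert planted.p_adjusted <= 0.05
        assert planted.mean_observed > planted.mean_permuted

    def test_doubling_counts_consistent_with_direct_recomputation(self, background_model):
        """Duplicating every chimera doubles observed and permuted means;
        the t statistic matches a direct recomputation on the doubled
        counts (variance scales, so t is recomputed, not assumed)."""
        reps = [cm.simulate_chimeras(background_model, 3000, seed=s) for s in (3, 4)]
        doubled = [r + r for r in reps]
        a, b = cm.SiteCluster("A", 1000), cm.SiteCluster("B", 3000)
        r1 = cm.circular_permutation_test(reps, [a, b], 5000, step=50)[0]
        r2 = cm.circular_permutation_test(doubled, [a, b], 5000, step=50)[0]
        assert np.allclose(r2.observed, 2 * r1.observed)
        assert np.allclose(r2.permuted, 2 * r1.permuted)
        t_direct, p_direct = stats.ttest_ind(
            2 * r1.observed, 2 * r1.permuted.ravel(), equal_var=False, alternative="greater"
        )
        assert r2.t_statistic == pytest.approx(float(t_direct))
        assert r2.p_value == pytest.approx(float(p_direct))

    def test_joint_shift_preserves_separation(self, background_model):
        """Every permuted placement keeps the pair's linear separation:
        with sites 2,000 nt apart a chimera bridging exactly that
        separation scores in every shift where it lands in-window."""
        # direct structural check on the shift grid itself
        L, step = 5000, 50
        a, b = cm.SiteCluster("A", 1000), cm.SiteCluster("B", 3000)
        for k in range(1, L // step - 1):
            sa = (a.center - k * step) % L
            sb = (b.center - k * step) % L
            assert (sb - sa) % L == 2000

    def test_bonferroni_equals_raw_p_for_single_pair(self, background_model):
        reps = [cm.simulate_chimeras(background_model, 2000, seed=s) for s in (5, 6)]
        a, b = cm.SiteCluster("A", 1000), cm.SiteCluster("B", 3000)
        res = cm.circular_permutation_test(reps, [a, b], 5000, step=50)
        assert len(res) == 1
        assert res[0].p_adjusted == pytest.approx(min(1.0, res[0].p_value))

    def test_fewer_than_two_replicates_error(self, background_model):
        reps = [cm.simulate_chimeras(background_model, 100, seed=1)]
        with pytest.raises(ValueError):
            cm.circular_permutation_test(
                reps, [cm.SiteCluster("A", 1000), cm.SiteCluster("B", 3000)], 5000
            )

    def test_transcript_too_short_errors(self, background_model):
        a, b = cm.SiteCluster("A", 60, radius=50), cm.SiteCluster("B", 170, radius=50)
        recs = [[_rec(0, 10, 100)], [_rec(1, 20, 110)]]
        with pytest.raises(ValueError):
            # 190 nt < 2 * (radius 50 + step 50)
            cm.circular_permutation_test(recs, [a, b], 190, step=50)


class TestSiteVsRandom:
    def test_uniform_background_ratio_near_one(self, background_model):
        recs = cm.simulate_chimeras(background_model, 20_000, seed=7)
        sites = [cm.SiteCluster("A", 1000), cm.SiteCluster("B", 3000)]
        per_site, rand_mean = cm.site_vs_random_interaction_counts(
            recs, sites, 5000, total_mapped=20_000, n_random=116, frag_len=110, seed=8
        )
        for v in per_site.values():
            # site windows are 100 nt vs 110-nt fragments: scale accordingly
            assert v / (rand_mean * 100 / 110) == pytest.approx(1.0, rel=0.2)

    def test_zero_chimeras_all_zero(self):
        sites = [cm.SiteCluster("A", 1000)]
        per_site, rand_mean = cm.site_vs_random_interaction_counts(
            [], sites, 5000, total_mapped=1000, seed=1
        )
        assert per_site["A"] == 0.0
        assert rand_mean == 0.0

    def test_defaults_116_fragments_of_110nt(self):
        import inspect

        sig = inspect.signature(cm.site_vs_random_interaction_counts)
        assert sig.parameters["n_random"].default == 116
        assert sig.parameters["frag_len"].default == 110
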