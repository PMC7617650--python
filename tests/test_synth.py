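"""Synthetic chimera/DMS generator: mixture behaviour and determinism."""

import numpy as np
import pytest
from scipy import stats

import chimeramap as cm


class TestRandomTranscript:
    def test_gc_one_gives_only_gc(self):
        t = cm.random_transcript(4, gc=1.0, seed=0)
        assert set(t.sequence) <= {"G", "C"}

    def test_gc_fraction_matches_target(self):
        t = cm.random_transcript(10_000, gc=0.4, seed=1)
        obs = (t.sequence.count("G") + t.sequence.count("C")) / 10_000
        assert obs == pytest.approx(0.4, abs=0.02)  # ~4 sigma binomial bound

    def test_deterministic_under_seed(self):
        a = cm.random_transcript(500, gc=0.5, seed=7)
        b = cm.random_transcript(500, gc=0.5, seed=7)
        assert a.sequence == b.sequence

    @pytest.mark.parametrize("length,gc", [(0, 0.5), (10, -0.1), (10, 1.5)])
    def test_invalid_arguments(self, length, gc):
        with pytest.raises(ValueError):
            cm.random_transcript(length, gc=gc)


class TestSimulateChimeras:
    def test_pure_background_is_uniform(self, small_transcript):
        model = cm.StructureModel(small_transcript, [], background_rate=1.0)
        recs = cm.simulate_chimeras(model, 100, seed=1)
        assert len(recs) == 100
        # chi-square goodness of fit of arm midpoints against uniform bins
        mids = np.concatenate([[r.midpoints()[0] for r in recs],
                               [r.midpoints()[1] for r in recs]])
        counts, _ = np.histogram(mids, bins=5, range=(0, len(small_transcript)))
        p = stats.chisquare(counts).pvalue
        assert p > 0.01

    def test_stem_chimeras_land_on_stem(self):
        """With one stem at 90% weight, 90% +- 1% of chimeras put both arm
        midpoints within +-20 nt of the two stem strands."""
        t = cm.random_transcript(1000, gc=0.4, seed=2)
        model = cm.StructureModel(
            t, [cm.StemSpec((100, 130), (400, 430))], background_rate=0.1
        )
        recs = cm.simulate_chimeras(model, 10_000, seed=1)
        near = [
            (80 <= r.midpoints()[0] <= 150) and (380 <= r.midpoints()[1] <= 450)
            for r in recs
        ]
        assert np.mean(near) == pytest.approx(0.9, abs=0.01)

    def test_zero_chimeras_is_empty_and_writable(self, two_stem_model, tmp_path):
        recs = cm.simulate_chimeras(two_stem_model, 0, seed=1)
        assert recs == []
        path = tmp_path / "zero.hyb.tsv"
        cm.write_hyb(recs, path)
        assert cm.read_hyb(path) == []

    def test_no_signal_at_all_errors(self, small_transcript):
        model = cm.StructureModel(
            small_transcript,
            [cm.StemSpec((10, 40), (100, 130), weight=0.0)],
            background_rate=0.0,
        )
        with pytest.raises(ValueError):
            cm.simulate_chimeras(model, 10, seed=0)

    def test_mixture_conservation(self):
        """The realized background fraction matches background_rate within
        a binomial confidence bound at n=10,000."""
        t = cm.random_transcript(2000, gc=0.5, seed=3)
        model = cm.StructureModel(
            t, [cm.StemSpec((200, 240), (1500, 1540))], background_rate=0.3
        )
        recs = cm.simulate_chimeras(model, 10_000, seed=2)
        on_stem = [
            (189 <= r.midpoints()[0] <= 250) and (1489 <= r.midpoints()[1] <= 1551)
            for r in recs
        ]
        # stem fraction = 1 - background (up to background landing on stem, ~1e-3)
        assert 1 - np.mean(on_stem) == pytest.approx(0.3, abs=0.02)

    def test_condition_multiplier_zero_silences_stem(self, small_transcript):
        stems = [
            cm.StemSpec((100, 130), (400, 430)),
            cm.StemSpec((600, 630), (800, 830)),
        ]
        model = cm.StructureModel(
            small_transcript, stems, background_rate=0.1,
            condition_multipliers={"stress": [0.0, 1.0]},
        )
        recs = cm.simulate_chimeras(model, 5000, condition="stress", seed=4)
        hits = sum(
            (90 <= r.midpoints()[0] <= 140) and (390 <= r.midpoints()[1] <= 440)
            for r in recs
        )
        # background expectation for those windows is ~5000 * (50/1000)^2 * 2 = 25
        assert hits < 40

    def test_deterministic_under_seed(self, two_stem_model):
        a = cm.simulate_chimeras(two_stem_model, 200, seed=9)
        b = cm.simulate_chimeras(two_stem_model, 200, seed=9)
        assert a == b


class TestSimulateControl:
    def test_control_is_uniform_despite_stems(self, two_stem_model):
        recs = cm.simulate_control(two_stem_model, 1000, seed=1)
        # pool both arms: canonical ordering makes arm1 the smaller of the
        # two positions, but the unordered pair is two iid uniforms
        mids = np.array([m for r in recs for m in r.midpoints()])
        p = stats.kstest(mids / len(two_stem_model.transcript), "uniform").pvalue
        assert p > 0.01

    def test_deterministic(self, two_stem_model):
        assert cm.simulate_control(two_stem_model, 100, seed=3) == cm.simulate_control(
            two_stem_model, 100, seed=3
        )

    def test_interaction_map_beats_control_in_stem_cells(self, two_stem_model):
        t = two_stem_model.transcript
        inter = cm.simulate_chimeras(two_stem_model, 10_000, seed=5)
        ctrl = cm.simulate_control(two_stem_model, 10_000, seed=5)
        m_int = cm.build_contact_map(inter, t, 10)
        m_ctl = cm.build_contact_map(ctrl, t, 10)
        ind = two_stem_model.contact_indicator(10)
        stem_cells = ind > 0
        assert m_int.counts[stem_cells].sum() > m_ctl.counts[stem_cells].sum()


class TestSimulateDms:
    def _model(self, seed=0, **kw):
        t = cm.random_transcript(400, gc=0.5, seed=seed)
        return cm.DmsModel(t, **kw)

    def test_zero_rates_give_zero_counts(self):
        dms = self._model(rate_paired=0.0, rate_unpaired=0.0, coverage=100)
        table = cm.simulate_dms(dms, seed=1)
        assert (table["mutations"] == 0).all()

    def test_unpaired_rate_recovered(self):
        dms = self._model(rate_paired=0.0, rate_unpaired=0.05, coverage=10_000)
        table = cm.simulate_dms(dms, seed=1)
        ac = table["ref"].isin(["A", "C"])
        rate = table.loc[ac, "mutations"].sum() / table.loc[ac, "coverage"].sum()
        assert rate == pytest.approx(0.05, abs=0.005)

    def test_gu_positions_never_mutate(self):
        dms = self._model(rate_paired=0.2, rate_unpaired=0.5, coverage=1000)
        table = cm.simulate_dms(dms, seed=2)
        gu = table["ref"].isin(["G", "U"])
        assert (table.loc[gu, "mutations"] == 0).all()

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            self._model(rate_paired=0.5, rate_unpaired=0.1)
        with pytest.raises(ValueError):
            self._model(rate_unpaired=1.5)


class TestPipelineClosure:
    def test_planted_stems_recovered_through_call_and_map(self):
        """simulate -> render reads -> call chimeras -> contact map
        correlates >= 0.8 with the planted-contact indicator."""
        t = cm.random_transcript(2000, gc=0.5, seed=3)
        stems = [
            cm.StemSpec((100, 130), (400, 430)),
            cm.StemSpec((600, 640), (1500, 1540)),
            cm.StemSpec((900, 930), (1100, 1130)),
        ]
        model = cm.StructureModel(t, stems, background_rate=0.2)
        recs = cm.simulate_chimeras(model, 50_000, seed=4)
        reads = cm.chimeras_to_reads(recs, t, seed=5)
        called = cm.call_chimeras(reads, {t.id: t.dna()}, k=12, min_arm=15)
        cmap = cm.build_contact_map(called.chimeras, t, 10)
        ind = model.contact_indicator(10)
        iu = np.triu_indices(cmap.n_bins)
        r = np.corrcoef(cmap.counts[iu], ind[iu])[0, 1]
        assert r >= 0.8
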