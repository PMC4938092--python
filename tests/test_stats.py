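import shutil
import subprocess
import textwrap

import numpy as np
import pytest

from glmpp import (
    ChainScenarioConfig,
    EventDataset,
    NetworkModel,
    chain_scenario,
    crosscorr_histogram,
    latin_matchings,
    markov_transitions,
    matched_correlation,
    mrpp,
    psth_index,
    sample,
    segment_predictability,
)


class TestMRPP:
    def test_perfectly_separated_duplicates(self):
        pts = np.array([[0, 0], [0, 0], [1, 1], [1, 1]], dtype=float)
        labels = np.array(["g1", "g1", "g2", "g2"])
        res = mrpp(pts, labels, n_perm=999, seed=0)
        assert res.observed_delta == 0.0
        assert res.agreement_A == pytest.approx(1.0)
        assert res.p_value <= 0.5
        assert res.p_value >= 1.0 / 1000.0

    def test_group_of_one_rejected(self):
        pts = np.zeros((3, 2))
        with pytest.raises(ValueError, match="at least 2 items"):
            mrpp(pts, np.array(["a", "a", "b"]))

    def test_degenerate_identical_points_warns_A_zero(self):
        pts = np.zeros((6, 2))
        labels = np.array(["a"] * 3 + ["b"] * 3)
        with pytest.warns(UserWarning, match="agreement undefined"):
            res = mrpp(pts, labels, n_perm=99, seed=0)
        assert res.agreement_A == 0.0

    def test_sampled_p_converges_to_exact(self, rng):
        pts = rng.normal(size=(6, 2))
        labels = np.array(["a", "a", "a", "b", "b", "b"])
        exact = mrpp(pts, labels, method="exact")
        sampled = mrpp(pts, labels, n_perm=4000, seed=1)
        se = np.sqrt(exact.p_value * (1 - exact.p_value) / 4000)
        assert abs(sampled.p_value - exact.p_value) < 3 * se + 1e-3
        assert abs(sampled.agreement_A - exact.agreement_A) < 0.05

    def test_stratified_sampled_matches_stratified_exact(self, rng):
        pts = rng.normal(size=(8, 2))
        labels = np.array(["a", "b", "a", "b", "a", "b", "a", "b"])
        strata = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        exact = mrpp(pts, labels, strata=strata, method="exact")
        sampled = mrpp(pts, labels, strata=strata, n_perm=4000, seed=2)
        se = np.sqrt(exact.p_value * (1 - exact.p_value) / 4000)
        assert abs(sampled.p_value - exact.p_value) < 3 * se + 1e-3
        assert abs(sampled.expected_delta - exact.expected_delta) < 0.05

    def test_determinism_under_seed(self, rng):
        pts = rng.normal(size=(10, 2))
        labels = np.array(["a"] * 5 + ["b"] * 5)
        r1 = mrpp(pts, labels, n_perm=200, seed=7)
        r2 = mrpp(pts, labels, n_perm=200, seed=7)
        assert r1.p_value == r2.p_value and r1.expected_delta == r2.expected_delta

    def test_matches_vegan_reference(self, rng):
        """Cross-check observed delta and agreement against vegan::mrpp."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript unavailable")
        pts = rng.normal(size=(8, 2)).round(4)
        labels = ["a"] * 4 + ["b"] * 4
        ours = mrpp(pts, np.array(labels), n_perm=4999, seed=3)
        flat = ",".join(f"{x},{y}" for x, y in pts)
        script = textwrap.dedent(f"""
            suppressMessages(library(vegan))
            set.seed(1)
            pts <- matrix(c({flat}), ncol=2, byrow=TRUE)
            grp <- factor(c({','.join(repr(l) for l in labels)}))
            out <- mrpp(pts, grp, permutations=4999, distance="euclidean", weight.type=1)
            cat(out$delta, out$A, out$Pvalue, sep=",")
        """)
        proc = subprocess.run(["Rscript", "-e", script], capture_output=True,
                              text=True, timeout=120)
        assert proc.returncode == 0, proc.stderr
        delta, A, p = map(float, proc.stdout.strip().split(","))
        assert ours.observed_delta == pytest.approx(delta, rel=1e-6)
        assert ours.agreement_A == pytest.approx(A, abs=0.02)
        assert ours.p_value == pytest.approx(p, abs=0.05)


class TestLatinMatchings:
    locations1 = {"w": "north", "x": "east", "y": "south", "z": "west"}
    locations2 = {"w": "east", "x": "north", "y": "west", "z": "south"}

    def test_identity_and_location(self):
        out = latin_matchings("wxyz", "wxyz", self.locations1, self.locations2)
        assert out["individual"] == {c: c for c in "wxyz"}
        assert out["location"]["w"] == "x" and out["location"]["y"] == "z"

    def test_four_distinct_bijections(self):
        out = latin_matchings("wxyz", "wxyz", self.locations1, self.locations2)
        assert set(out) == {"individual", "location", "null1", "null2"}
        keys = [tuple(m[c] for c in "wxyz") for m in out.values()]
        assert len(set(keys)) == 4
        for m in out.values():
            assert sorted(m.values()) == sorted("wxyz")

    def test_missing_locations_warns(self):
        with pytest.warns(UserWarning, match="location"):
            out = latin_matchings("wxyz", "wxyz")
        assert "location" not in out


class TestMatchedCorrelation:
    @staticmethod
    def _pairs(values, ids="wxyz"):
        out = {}
        k = 0
        for i in ids:
            for j in ids:
                if i != j:
                    out[(i, j)] = values[k]
                    k += 1
        return out

    def test_identity_matching_perfect_correlation(self, rng):
        v = rng.normal(size=12)
        mags = self._pairs(v)
        res = matched_correlation(mags, mags, {c: c for c in "wxyz"})
        assert res.r == pytest.approx(1.0)
        assert res.n == 12

    def test_negation_gives_minus_one(self, rng):
        v = rng.normal(size=12)
        res = matched_correlation(self._pairs(v), self._pairs(-v),
                                  {c: c for c in "wxyz"})
        assert res.r == pytest.approx(-1.0)

    def test_matches_textbook_formula(self, rng):
        x, y = rng.normal(size=12), rng.normal(size=12)
        res = matched_correlation(self._pairs(x), self._pairs(y),
                                  {c: c for c in "wxyz"})
        expected = (np.mean(x * y) - x.mean() * y.mean()) / (x.std() * y.std())
        assert res.r == pytest.approx(expected, rel=1e-9)
        assert res.p is not None and 0 <= res.p <= 1

    def test_small_n_has_no_p(self):
        m1 = {("a", "b"): 1.0, ("b", "a"): 2.0}
        res = matched_correlation(m1, m1, {"a": "a", "b": "b"})
        assert res.p is None and res.flagged


class TestSegmentPredictability:
    def test_hour_in_quarters_pools_three_pairs(self, rng):
        mags = rng.normal(size=(4, 12))  # 4 segments x 12 directed pairs
        res = segment_predictability(mags)
        assert res.n == 3 * 12

    def test_constant_segments_flagged(self):
        res = segment_predictability(np.ones((4, 12)))
        assert res.flagged and res.p is None

    def test_recovers_injected_ar1_structure(self):
        rng = np.random.default_rng(77)
        rho, n_pairs, n_seg = 0.5, 12, 4
        x = rng.normal(size=(n_seg, n_pairs))
        for k in range(1, n_seg):
            x[k] = rho * x[k - 1] + np.sqrt(1 - rho ** 2) * rng.normal(size=n_pairs)
        res = segment_predictability(x)
        assert res.n == 36
        assert abs(res.r - rho) < 2.0 / np.sqrt(res.n - 3)


class TestPSTHIndex:
    def test_hand_computed_strong_follower(self):
        ds = EventDataset(
            ["A", "B"],
            {"A": np.array([10.0, 20.0, 30.0]),
             "B": np.array([10.1, 20.1, 30.1])},
            100.0)
        mat = psth_index(ds)
        # windows: 3 x 0.45 s = 1.35 s containing all 3 B calls
        windowed = 3 / 1.35
        base = 3 / 100.0
        assert mat.loc["A", "B"] == pytest.approx(windowed / base - 1.0)

    def test_empty_window_gives_minus_one(self):
        ds = EventDataset(
            ["A", "B"],
            {"A": np.array([10.0]), "B": np.array([50.0])}, 100.0)
        assert psth_index(ds).loc["A", "B"] == pytest.approx(-1.0)

    def test_independent_channels_near_zero(self, default_basis):
        m = NetworkModel.homogeneous(["A", "B"], 0.3, default_basis)
        vals = []
        for seed in range(25):
            ds = sample(m, 600.0, seed=seed)
            vals.append(psth_index(ds).loc["A", "B"])
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(np.mean(vals)) < 3.5 * se + 0.02

    def test_time_translation_invariance(self):
        t = np.array([5.0, 12.0, 33.0])
        s = np.array([5.2, 12.3, 40.0])
        d1 = EventDataset(["A", "B"], {"A": t, "B": s}, 60.0)
        d2 = EventDataset(["A", "B"], {"A": t + 7, "B": s + 7}, 60.0)
        assert psth_index(d1).loc["A", "B"] == pytest.approx(
            psth_index(d2).loc["A", "B"], rel=1e-9)

    def test_receiver_without_calls_undefined(self):
        ds = EventDataset(["A", "B"], {"A": np.array([1.0]), "B": np.array([])}, 10.0)
        assert np.isnan(psth_index(ds).loc["A", "B"])


class TestCrossCorrelation:
    def test_deterministic_chain_spikes_at_delay(self):
        cfg = ChainScenarioConfig(response_prob=1.0, delay_jitter_sd=0.0,
                                  duration=600.0, seed=5)
        ds = chain_scenario(cfg)
        hists = crosscorr_histogram(ds, max_lag=1.0, bin_width=0.01)
        edges, v = hists[("A", "B")]
        peak_bin = int(np.argmax(v))
        lag = 0.5 * (edges[peak_bin] + edges[peak_bin + 1])
        assert lag == pytest.approx(cfg.response_delay, abs=0.01)
        assert v[peak_bin] > 0.9  # nearly every A is followed by one B

    def test_independent_channels_flat(self, default_basis):
        m = NetworkModel.homogeneous(["A", "B"], 0.5, default_basis)
        ds = sample(m, 1200.0, seed=8)
        _, v = crosscorr_histogram(ds, max_lag=1.0, bin_width=0.05)[("A", "B")]
        # each bin estimates rate*width = 0.025 events per sender call
        expected = 0.5 * 0.05
        assert np.all(np.abs(v - expected) < 5 * np.sqrt(expected / len(ds.events["A"])))


class TestMarkov:
    def test_alternating_sequence(self):
        ds = EventDataset(["A", "B"],
                          {"A": np.array([0.0, 2.0, 4.0]), "B": np.array([1.0, 3.0, 5.0])},
                          6.0)
        mat = markov_transitions(ds)
        assert mat.loc["A", "B"] == 1.0
        assert mat.loc["B", "A"] == 1.0

    def test_rows_sum_to_one(self, rng):
        from tests.conftest import random_dataset

        ds = random_dataset(rng, n_channels=3, duration=120.0, rate=0.5)
        mat = markov_transitions(ds)
        sums = mat.sum(axis=1, skipna=True)
        for ch in ds.channels:
            if len(ds.events[ch]):
                assert sums[ch] == pytest.approx(1.0)

    def test_minimum_events(self):
        ds = EventDataset(["A", "B"], {"A": np.array([1.0]), "B": np.array([])}, 5.0)
        with pytest.raises(ValueError):
            markov_transitions(ds)
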