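"""Differential methylation: Fisher/BH oracles, direction, context, chi-squared."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import hypergeom

import methclock as mc
from methclock.dms import DMSRecord, beta_map, bh_qvalues
from methclock.io import FeatureInterval, SiteKey, SiteMethylation
from tests.conftest import build_channel_matrix


def fisher_oracle(table) -> float:
    """Two-sided Fisher p by full enumeration of tables with fixed margins."""
    (a, b), (c, d) = table
    row1, col1, n = a + b, a + c, a + b + c + d
    k_min, k_max = max(0, row1 + col1 - n), min(row1, col1)
    probs = hypergeom.pmf(np.arange(k_min, k_max + 1), n, row1, col1)
    p_obs = hypergeom.pmf(a, n, row1, col1)
    return float(probs[probs <= p_obs * (1 + 1e-7)].sum())


def bh_oracle(p: np.ndarray) -> np.ndarray:
    """q_i = min over k with p(k) >= p(i) of p(k) * m / rank(k), capped at 1."""
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = min(running, 1.0)
    return q


class TestPoolCounts:
    def make(self, pairs):
        per_sample = {}
        key = SiteKey("c", 0, "+", "a")
        for i, (nm, nv) in enumerate(pairs):
            per_sample[f"s{i}"] = {key: SiteMethylation(key, nv, nm)}
        return per_sample, key

    def test_examples(self):
        per_sample, key = self.make([(3, 30)])
        assert mc.pool_counts(per_sample, ["s0"], key) == (3, 30)
        per_sample, key = self.make([(3, 30), (1, 10)])
        assert mc.pool_counts(per_sample, ["s0", "s1"], key) == (4, 40)
        per_sample, key = self.make([(0, 12)] * 5)
        assert mc.pool_counts(per_sample, [f"s{i}" for i in range(5)], key) == (0, 60)

    def test_missing_site_error(self):
        per_sample, key = self.make([(3, 30)])
        with pytest.raises(KeyError):
            mc.pool_counts(per_sample, ["s0"], SiteKey("c", 99, "+", "a"))


class TestSiteTest:
    def test_no_signal(self):
        p, effect, score = mc.site_test((10, 100), (10, 100))
        assert p == pytest.approx(1.0)
        assert effect == 0.0 and score == 0.0

    def test_matches_hypergeometric_enumeration(self):
        p, _, _ = mc.site_test((10, 100), (30, 100))
        assert p == pytest.approx(fisher_oracle([[10, 90], [30, 70]]), rel=1e-9)

    def test_map_score_extremes(self):
        # MAP of Beta(1, 51) is 0; MAP of Beta(51, 1) is 1
        assert beta_map(0, 50) == 0.0
        assert beta_map(50, 0) == 1.0
        _, _, score = mc.site_test((0, 50), (50, 50))
        assert score == pytest.approx(1.0)

    def test_zero_coverage_error(self):
        with pytest.raises(ValueError):
            mc.site_test((0, 0), (5, 10))

    @given(st.integers(0, 60), st.integers(1, 60), st.integers(0, 60),
           st.integers(1, 60))
    @settings(deadline=None, max_examples=60)
    def test_symmetry_under_condition_swap(self, ma, va_extra, mb, vb_extra):
        va, vb = ma + va_extra, mb + vb_extra
        p1, e1, s1 = mc.site_test((ma, va), (mb, vb))
        p2, e2, s2 = mc.site_test((mb, vb), (ma, va))
        assert p1 == pytest.approx(p2, rel=1e-9)
        assert e1 == pytest.approx(-e2)
        assert s1 == pytest.approx(s2)


class TestBH:
    def test_known_vector_matches_oracle(self):
        p = np.array([0.001, 0.01, 0.02, 0.8])
        assert bh_qvalues(p) == pytest.approx(bh_oracle(p))

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=400))
    @settings(deadline=None, max_examples=60)
    def test_random_vectors_match_oracle(self, p):
        p = np.asarray(p)
        assert bh_qvalues(p) == pytest.approx(bh_oracle(p), abs=1e-12)

    def test_long_vector_and_permutation_invariance(self, rng):
        p = rng.random(10_000)
        q = bh_qvalues(p)
        assert q == pytest.approx(bh_oracle(p), abs=1e-12)
        perm = rng.permutation(len(p))
        assert bh_qvalues(p[perm]) == pytest.approx(q[perm], abs=1e-12)


class TestCallDMS:
    def test_no_signal_yields_no_dms(self):
        key = lambda i: SiteKey("c", i, "+", "a")
        sites = [key(i) for i in range(10)]
        mkmat = mc.MethylationMatrix(
            sites=sites,
            samples=[mc.Sample("y", 7, "W1"), mc.Sample("o", 35, "W5")],
            fractions=np.full((10, 2), 0.1),
            coverages=np.full((10, 2), 30),
        )
        assert mc.call_dms(mkmat, ["y"], ["o"], 0.05) == []

    def test_qvalues_follow_brute_force_bh(self, small_matrix):
        young = small_matrix.group_samples("W1")
        old = small_matrix.group_samples("W5")
        table = mc.dms_table(small_matrix, young, old)
        assert table["q"].to_numpy() == pytest.approx(
            bh_oracle(table["p"].to_numpy()), abs=1e-12
        )

    def test_recall_and_fdr_on_known_truth(self):
        """~100 drifted of 2000 sites: recall >= 0.5, empirical FDR <= 0.10."""
        recalls, fdrs = [], []
        for seed in range(20):
            cfg = mc.SimulationConfig(seed=seed, frac_clock_sites=0.05,
                                      mod_codes=("a",))
            co = mc.simulate_cohort(cfg)
            mat = build_channel_matrix(co)
            young = [s.sample_id for s in co.manifest if s.group == "W1"]
            old = [s.sample_id for s in co.manifest if s.group == "W5"]
            called = {d.key for d in mc.call_dms(mat, young, old, 0.05)}
            truth = {k for k in co.truth.clock_sites if k in mat.site_index()}
            benign = truth | co.truth.entropy_sites
            recalls.append(len(called & truth) / len(truth))
            fdrs.append(len(called - benign) / max(len(called), 1))
        assert np.median(recalls) >= 0.5
        assert np.median(fdrs) <= 0.10

    def test_invalid_inputs(self, small_matrix):
        young = small_matrix.group_samples("W1")
        old = small_matrix.group_samples("W5")
        with pytest.raises(ValueError):
            mc.call_dms(small_matrix, young, old, fdr=1.5)
        with pytest.raises(ValueError):
            mc.call_dms(small_matrix, [], old, fdr=0.05)

    def test_null_p_values_conservative(self, null_matrix):
        """On no-drift data the Fisher p<0.05 rate stays at or below 5%."""
        young = null_matrix.group_samples("W1")
        old = null_matrix.group_samples("W5")
        table = mc.dms_table(null_matrix, young, old)
        frac = (table["p"] < 0.05).mean()
        n = len(table)
        upper = 0.05 + 2.576 * np.sqrt(0.05 * 0.95 / n)
        assert frac <= upper


class TestContext:
    FEATS = [
        FeatureInterval("ctg1", 0, 500, "ncRNA"),
        FeatureInterval("ctg1", 100, 200, "rDNA"),
        FeatureInterval("ctg1", 150, 900, "coding"),
    ]

    def rec(self, pos):
        return DMSRecord(SiteKey("ctg1", pos, "+", "a"), 0.1, 0.01, 0.02, "hyper")

    def test_priority_and_fallback(self):
        out = mc.annotate_context(
            [self.rec(1000), self.rec(300), self.rec(160)], self.FEATS
        )
        assert [r.context for r in out] == ["intergenic", "ncRNA", "rDNA"]

    def test_interval_overlap_oracle(self, rng):
        feats = []
        for i in range(30):
            start = int(rng.integers(0, 900))
            feats.append(FeatureInterval(
                "ctg1", start, start + int(rng.integers(1, 120)),
                ["coding", "ncRNA", "rDNA"][int(rng.integers(3))],
            ))
        rank = {"rDNA": 0, "ncRNA": 1, "coding": 2}
        for pos in rng.integers(0, 1000, size=50):
            out = mc.annotate_context([self.rec(int(pos))], feats)[0]
            hits = [f.feature_class for f in feats if f.start <= pos < f.end]
            expected = min(hits, key=rank.__getitem__) if hits else "intergenic"
            assert out.context == expected


class TestDirectionAndChisq:
    def test_direction_counts(self):
        recs = [
            DMSRecord(SiteKey("c", i, "+", "a"), e, 0.01, 0.02,
                      "hyper" if e > 0 else "hypo")
            for i, e in enumerate([0.1, -0.2, 0.3])
        ]
        assert mc.direction_proportions(recs) == (1, 2)

    def test_printed_direction_split(self):
        effects = [-0.1] * 146 + [0.1] * 704
        recs = [
            DMSRecord(SiteKey("c", i, "+", "a"), e, 0.01, 0.02,
                      "hyper" if e > 0 else "hypo")
            for i, e in enumerate(effects)
        ]
        assert mc.direction_proportions(recs) == (146, 704)

    def test_reported_chi_squared_value(self):
        res = mc.compare_proportions_chisq((146, 704), (164, 366))
        assert res.statistic == pytest.approx(34.736, abs=0.01)
        assert res.df == 1
        assert res.continuity_corrected

    def test_identical_proportions_zero(self):
        assert mc.compare_proportions_chisq((50, 50), (50, 50)).statistic == 0.0

    def test_uncorrected_matches_four_term_oracle(self, rng):
        for _ in range(20):
            a, b, c, d = (int(x) for x in rng.integers(1, 200, size=4))
            res = mc.compare_proportions_chisq((a, b), (c, d), yates=False)
            n = a + b + c + d
            exp = np.outer([a + b, c + d], [a + c, b + d]) / n
            obs = np.array([[a, b], [c, d]])
            assert res.statistic == pytest.approx(((obs - exp) ** 2 / exp).sum())

    def test_yates_never_exceeds_uncorrected(self, rng):
        for _ in range(30):
            a, b, c, d = (int(x) for x in rng.integers(1, 100, size=4))
            with_y = mc.compare_proportions_chisq((a, b), (c, d), yates=True)
            without = mc.compare_proportions_chisq((a, b), (c, d), yates=False)
            assert with_y.statistic <= without.statistic + 1e-12

    def test_degenerate_margin_error(self):
        with pytest.raises(ValueError):
            mc.compare_proportions_chisq((0, 0), (5, 5))
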