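"""SAR continuity/discontinuity scoring and panel normalization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from svrsar.errors import DegeneratePanelError, UndefinedScoreError, ValidationError
from svrsar.sari import (
    normalize_score,
    pair_weight,
    panel_stats,
    raw_continuity,
    raw_discontinuity,
    score_dataset,
)
from svrsar.similarity import pairwise_matrix
from svrsar.synthetic_data import PanelConfig, generate_reference_panel

from conftest import make_dataset


def naive_continuity(potencies, sim):
    """Brute-force double-loop continuity oracle."""
    num = den = 0.0
    n = len(potencies)
    for i in range(n):
        for j in range(i):
            w = potencies[i] * potencies[j] / (1 + abs(potencies[i] - potencies[j]))
            num += w * sim[i, j]
            den += w
    return 1 - num / den


def naive_discontinuity(potencies, sim, t):
    """Brute-force double-loop discontinuity oracle."""
    vals = [
        abs(potencies[i] - potencies[j]) * sim[i, j]
        for i in range(len(potencies))
        for j in range(i)
        if sim[i, j] >= t
    ]
    return sum(vals) / len(vals)


class TestPairWeight:
    @pytest.mark.parametrize("pi,pj,expected", [(7, 7, 49.0), (5, 9, 9.0)])
    def test_hand_values(self, pi, pj, expected):
        assert pair_weight(pi, pj) == pytest.approx(expected, abs=1e-15)

    @settings(deadline=None, derandomize=True)
    @given(
        p=st.floats(min_value=1, max_value=14),
        q=st.floats(min_value=1, max_value=14),
    )
    def test_symmetric(self, p, q):
        assert pair_weight(p, q) == pair_weight(q, p)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValidationError):
            pair_weight(float("nan"), 7.0)


class TestRawScores:
    def test_equal_potency_pair_continuity(self):
        sim = np.array([[1.0, 0.5], [0.5, 1.0]])
        assert raw_continuity([7.0, 7.0], sim) == pytest.approx(0.5)

    def test_continuity_extremes(self):
        ones = np.ones((3, 3))
        zeros = np.zeros((3, 3))
        np.fill_diagonal(zeros, 1.0)
        p = [6.0, 7.0, 8.0]
        assert raw_continuity(p, ones) == pytest.approx(0.0)
        assert raw_continuity(p, zeros) == pytest.approx(1.0)

    def test_single_qualifying_cliff_pair(self):
        sim = np.array([[1.0, 1.0], [1.0, 1.0]])
        assert raw_discontinuity([5.0, 9.0], sim, 0.56) == pytest.approx(4.0)

    def test_equal_potencies_zero_discontinuity(self):
        sim = np.array([[1.0, 0.9], [0.9, 1.0]])
        assert raw_discontinuity([7.0, 7.0], sim, 0.56) == 0.0

    def test_no_qualifying_pair_is_explicit_error(self):
        sim = np.array([[1.0, 0.2], [0.2, 1.0]])
        with pytest.raises(UndefinedScoreError):
            raw_discontinuity([5.0, 9.0], sim, 0.56)

    def test_scores_match_bruteforce_oracle(self, rng):
        for _ in range(5):
            fps = [
                set(rng.choice(128, size=rng.integers(5, 40), replace=False))
                for _ in range(50)
            ]
            p = rng.uniform(5, 11, size=50)
            ds = make_dataset(fps, p, universe=128)
            sim = pairwise_matrix(ds)
            assert raw_continuity(p, sim) == pytest.approx(
                naive_continuity(p, sim), abs=1e-10
            )
            t = float(np.quantile(sim[np.triu_indices(50, 1)], 0.8))
            assert raw_discontinuity(p, sim, t) == pytest.approx(
                naive_discontinuity(p, sim, t), abs=1e-10
            )

    def test_order_invariance(self, cliff_dataset, rng):
        p = cliff_dataset.potencies()
        sim = pairwise_matrix(cliff_dataset)
        perm = rng.permutation(len(p))
        assert raw_continuity(p[perm], sim[np.ix_(perm, perm)]) == pytest.approx(
            raw_continuity(p, sim), abs=1e-12
        )
        assert raw_discontinuity(
            p[perm], sim[np.ix_(perm, perm)], 0.56
        ) == pytest.approx(raw_discontinuity(p, sim, 0.56), abs=1e-12)

    def test_widening_one_qualifying_gap_does_not_decrease_disc(self):
        sim = np.full((4, 4), 0.8)
        np.fill_diagonal(sim, 1.0)
        p = np.array([6.0, 7.0, 8.0, 9.0])
        base = raw_discontinuity(p, sim, 0.56)
        p2 = p.copy()
        p2[3] += 1.5  # widen every qualifying gap that involves compound 3
        assert raw_discontinuity(p2, sim, 0.56) >= base


class TestNormalization:
    def test_panel_stats_two_points(self):
        s = panel_stats([0.2, 0.4], [0.1, 0.3])
        assert s.cont_mean == pytest.approx(0.3)
        assert s.cont_sd == pytest.approx(0.14142135623730953, abs=1e-15)

    def test_constant_panel_rejected(self):
        with pytest.raises(DegeneratePanelError):
            panel_stats([0.3, 0.3], [0.1, 0.2])

    def test_panel_stats_match_loop(self, rng):
        c = rng.uniform(0, 1, size=120)
        d = rng.uniform(0, 2, size=120)
        s = panel_stats(c, d)
        mean = sum(c) / len(c)
        sd = (sum((x - mean) ** 2 for x in c) / (len(c) - 1)) ** 0.5
        assert s.cont_mean == pytest.approx(mean, abs=1e-12)
        assert s.cont_sd == pytest.approx(sd, abs=1e-12)

    def test_cdf_normalization_values(self):
        assert normalize_score(0.5, 0.5, 0.1) == pytest.approx(0.5)
        assert normalize_score(0.6, 0.5, 0.1) == pytest.approx(
            0.8413447460685429, abs=1e-10
        )

    def test_monotone_in_raw(self, rng):
        raws = np.sort(rng.uniform(-1, 3, size=30))
        out = [normalize_score(r, 0.5, 0.4) for r in raws]
        assert all(a < b for a, b in zip(out, out[1:]))

    def test_degenerate_sd_rejected(self):
        with pytest.raises(DegeneratePanelError):
            normalize_score(0.5, 0.5, 0.0)


class TestScoreDataset:
    def test_cliff_free_set_scores_low_against_mixed_panel(
        self, smooth_dataset, cliff_dataset, small_panel_stats
    ):
        smooth = score_dataset(smooth_dataset, stats=small_panel_stats)
        cliffy = score_dataset(cliff_dataset, stats=small_panel_stats)
        assert smooth.disc_norm < 0.5
        assert cliffy.disc_norm > smooth.disc_norm

    def test_panel_self_scores_center_at_half(self):
        panel = generate_reference_panel(
            PanelConfig(n_sets=30, size_range=(40, 60), seed=9)
        )
        raw = [score_dataset(ds) for ds in panel]
        stats = panel_stats(
            [s.cont_raw for s in raw], [s.disc_raw for s in raw]
        )
        norm = [score_dataset(ds, stats=stats) for ds in panel]
        assert np.mean([s.disc_norm for s in norm]) == pytest.approx(0.5, abs=0.05)
        assert np.mean([s.cont_norm for s in norm]) == pytest.approx(0.5, abs=0.05)

    def test_bookkeeping_fields(self, cliff_dataset):
        s = score_dataset(cliff_dataset)
        assert s.threshold_t == cliff_dataset.scheme.tc_threshold
        assert s.n_qualifying_pairs >= 1
        assert 0.0 <= s.cont_raw <= 1.0 and s.disc_raw >= 0.0
        assert s.cont_norm is None and s.disc_norm is None
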