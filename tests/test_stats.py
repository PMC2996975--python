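"""Exact Mann-Whitney U, one-tailed correlations, meta-combination."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from mitotrna.model import CorrelationError, MitoError
from mitotrna.stats import (
    combine_correlations,
    mann_whitney_u,
    pearson_one_tailed,
    pearson_through_origin,
    spearman_one_tailed,
)


def _brute_force_exact(a, b):
    """Enumerate all C(n1+n2, n1) labelings; tail fractions for U_a."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    n1 = len(a)
    r_a = ranks[:n1].sum()
    u_obs = r_a - n1 * (n1 + 1) / 2
    lows = highs = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        u = ranks[list(combo)].sum() - n1 * (n1 + 1) / 2
        lows += u <= u_obs + 1e-9
        highs += u >= u_obs - 1e-9
        total += 1
    return u_obs, lows / total, highs / total


def test_complete_separation_gives_zero_u():
    res = mann_whitney_u([1, 2], [3, 4])
    assert res.U == 0
    assert res.method == "exact"
    # only 1 of C(4,2)=6 labelings is as extreme in the lower tail
    assert res.p_one_tailed == pytest.approx(1 / 6)


def test_exact_p_matches_enumeration_oracle(rng):
    """DP-based exact tail equals brute-force enumeration, ties included."""
    for trial in range(5):
        a = rng.integers(0, 12, size=8).astype(float)
        b = rng.integers(0, 12, size=8).astype(float)
        u_obs, p_low, p_high = _brute_force_exact(a, b)
        res = mann_whitney_u(a, b)
        u_a = u_obs
        u_b = len(a) * len(b) - u_a
        assert res.U == pytest.approx(min(u_a, u_b))
        assert res.p_one_tailed == pytest.approx(min(p_low, p_high), abs=1e-12)


def test_normal_approx_beyond_exact_limit(rng):
    a = rng.normal(size=20)
    b = rng.normal(loc=1.0, size=20)
    res = mann_whitney_u(a, b)
    assert res.method == "normal_approx"
    ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic",
                           use_continuity=False)
    assert res.p_two_tailed == pytest.approx(ref.pvalue, rel=1e-9)


def test_empty_group_errors():
    with pytest.raises(MitoError):
        mann_whitney_u([], [1.0])


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.lists(st.integers(0, 50), min_size=3, max_size=8),
       st.lists(st.integers(0, 50), min_size=3, max_size=8))
def test_u_invariant_under_monotone_transform(a, b):
    """U depends only on ranks: any strictly monotone map preserves it."""
    base = mann_whitney_u(a, b)
    mapped = mann_whitney_u([math.exp(x / 10) for x in a],
                            [math.exp(x / 10) for x in b])
    assert mapped.U == base.U
    assert mapped.p_two_tailed == pytest.approx(base.p_two_tailed)


def test_pearson_perfect_lines():
    x = [1.0, 2.0, 3.0, 4.0]
    res = pearson_one_tailed(x, [2 * v + 1 for v in x], tail="positive")
    assert res.r == pytest.approx(1.0)
    assert res.p_one_tailed < 1e-6
    res = pearson_one_tailed(x, [-v for v in x], tail="negative")
    assert res.r == pytest.approx(-1.0)


def test_pearson_matches_definitional_oracle(rng):
    x = rng.normal(size=20)
    y = rng.normal(size=20)
    res = pearson_one_tailed(x, y)
    r_def = (np.mean((x - x.mean()) * (y - y.mean()))
             / (x.std(ddof=0) * y.std(ddof=0)))
    assert res.r == pytest.approx(r_def, abs=1e-12)
    assert res.df == 18
    assert res.t == pytest.approx(res.r * math.sqrt(18 / (1 - res.r**2)))


def test_pearson_zero_variance_errors():
    with pytest.raises(CorrelationError):
        pearson_one_tailed([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def test_spearman_monotone_and_hand_ranked():
    res = spearman_one_tailed([1, 2, 5, 9], [2, 8, 9, 30], tail="positive")
    assert res.r == pytest.approx(1.0)
    # x = {1,1,2} -> mean ranks (1.5, 1.5, 3); hand-computed r
    x, y = [1.0, 1.0, 2.0], [1.0, 2.0, 3.0]
    rx, ry = np.array([1.5, 1.5, 3.0]), np.array([1.0, 2.0, 3.0])
    r_hand = float(np.corrcoef(rx, ry)[0, 1])
    assert spearman_one_tailed(x, y, tail="positive").r == pytest.approx(r_hand)


def test_spearman_t_approx_close_to_permutation_p(rng):
    """t-approximated tail within 0.03 of the exhaustive 8! permutation p."""
    x = rng.normal(size=8)
    y = 0.8 * x + rng.normal(size=8)
    res = spearman_one_tailed(x, y, tail="positive")
    rx = sps.rankdata(x)
    count = total = 0
    for perm in itertools.permutations(sps.rankdata(y)):
        r = np.corrcoef(rx, perm)[0, 1]
        count += r >= res.r - 1e-12
        total += 1
    assert res.p_one_tailed == pytest.approx(count / total, abs=0.03)


def test_through_origin_line_and_sign_invariance(rng):
    x = np.array([1.0, -2.0, 3.0, 0.5])
    res = pearson_through_origin(x, 3 * x, tail="positive")
    assert res.r == pytest.approx(1.0)
    assert res.df == 3  # n - 1
    x = rng.normal(size=12)
    y = rng.normal(size=12)
    base = pearson_through_origin(x, y)
    flip = np.where(rng.random(12) < 0.5, -1.0, 1.0)
    flipped = pearson_through_origin(x * flip, y * flip)
    assert flipped.r == pytest.approx(base.r, abs=1e-12)


def test_combine_identical_studies():
    studies = [(f"s{i}", 0.3, 10, 0.5) for i in range(4)]
    meta = combine_correlations(studies)
    assert meta.r_weighted == pytest.approx(0.3)
    assert meta.k == 4


def test_combine_all_half_p_gives_zero_z():
    meta = combine_correlations([("a", 0.1, 10, 0.5), ("b", -0.1, 10, 0.5)])
    assert meta.Z_stouffer == pytest.approx(0.0, abs=1e-12)
    assert meta.p_combined == pytest.approx(0.5)
    assert meta.r_weighted == pytest.approx(0.0, abs=1e-12)


def test_combine_single_study_reduces_to_it():
    meta = combine_correlations([("a", -0.25, 20, 0.12)])
    assert meta.r_weighted == pytest.approx(-0.25)
    assert meta.p_combined == pytest.approx(0.12, abs=1e-12)


def test_combine_drops_small_n_with_warning():
    with pytest.warns(UserWarning, match="n=3"):
        meta = combine_correlations([("a", 0.2, 3, 0.4), ("b", 0.1, 10, 0.3)])
    assert meta.k == 1


def test_combine_perfect_r_rejected():
    with pytest.raises(MitoError):
        combine_correlations([("a", 1.0, 10, 0.01)])
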