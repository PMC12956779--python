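"""Unit and property tests for the nonparametric statistics module."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import friedmanchisquare, rankdata

from cordmorph import (RepeatedMeasures, friedman_test, pairwise_posthoc,
                       segment_summary)


def test_rejects_bad_input():
    with pytest.raises(ValueError):
        RepeatedMeasures(np.zeros((3,)))
    with pytest.raises(ValueError):
        RepeatedMeasures(np.zeros((3, 1)))          # k < 2
    with pytest.raises(ValueError):
        RepeatedMeasures(np.array([[1.0, np.nan], [2.0, 3.0]]))


def test_statistic_matches_scipy():
    rng = np.random.default_rng(42)
    for _ in range(20):
        m = rng.normal(size=(rng.integers(3, 10), rng.integers(3, 6)))
        ours = friedman_test(RepeatedMeasures(m))
        ref = friedmanchisquare(*m.T)
        assert ours.chi2 == pytest.approx(ref.statistic, abs=1e-12)
        assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-12)


def test_tie_correction():
    # within-block ties: scipy applies the same correction
    m = np.array([[1.0, 1.0, 2.0], [3.0, 2.0, 2.0],
                  [1.0, 2.0, 3.0], [2.0, 2.0, 2.0]])
    ours = friedman_test(RepeatedMeasures(m))
    ref = friedmanchisquare(*m.T)
    assert ours.chi2 == pytest.approx(ref.statistic, abs=1e-12)


def test_all_tied_degenerate():
    r = friedman_test(RepeatedMeasures(np.ones((5, 4))), exact=True)
    assert r.chi2 == 0.0
    assert r.p_value == 1.0


def test_exact_enumeration_concordant_blocks():
    # 4 blocks all ranked (1, 2, 3): chi2 = 8, exact p = 6/6^4
    data = RepeatedMeasures(np.tile([1.0, 2.0, 3.0], (4, 1)))
    r = friedman_test(data, exact=True)
    assert r.chi2 == pytest.approx(8.0)
    assert r.exact_method == "enumeration"
    assert r.p_exact == pytest.approx(6 / 6**4)


def test_exact_switches_to_monte_carlo():
    m = np.random.default_rng(0).normal(size=(4, 5))   # (5!)^4 > limit
    r = friedman_test(RepeatedMeasures(m), exact=True)
    assert r.exact_method == "monte-carlo"
    assert 0.0 < r.p_exact <= 1.0


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_permutation_p_invariant_under_monotone_transform(seed):
    rng = np.random.default_rng(seed)
    m = rng.normal(size=(4, 3))
    r1 = friedman_test(RepeatedMeasures(m), exact=True)
    r2 = friedman_test(RepeatedMeasures(np.exp(m)), exact=True)  # monotone
    assert r1.p_exact == pytest.approx(r2.p_exact, abs=1e-12)
    assert r1.chi2 == pytest.approx(r2.chi2, abs=1e-12)


def test_posthoc_bonferroni():
    m = np.random.default_rng(9).normal(size=(8, 4))
    r = pairwise_posthoc(RepeatedMeasures(m))
    assert len(r.pairs) == 6                        # k(k-1)/2
    assert np.all(r.p_adjusted >= r.p_raw - 1e-15)
    assert np.all(r.p_adjusted <= 1.0 + 1e-15)
    # Bonferroni: adjusted = min(1, raw * m)
    assert np.allclose(r.p_adjusted, np.minimum(1.0, r.p_raw * 6))


def test_posthoc_requires_three_treatments():
    with pytest.raises(ValueError):
        pairwise_posthoc(RepeatedMeasures(np.random.default_rng(1)
                                          .normal(size=(5, 2))))


def test_segment_summary_uses_sample_sd():
    import pandas as pd
    # four repeated observations of the same (segment, quantity, side)
    t = pd.DataFrame({
        "segment": ["C3"] * 4,
        "quantity": ["dura_thickness"] * 4,
        "side_or_view": ["dorsal"] * 4,
        "value": [1.0, 2.0, 3.0, 4.0],
        "units": ["um"] * 4,
    })
    s = segment_summary(t)
    row = s.iloc[0]
    assert row["mean"] == pytest.approx(2.5)
    assert row["sd"] == pytest.approx(np.std([1, 2, 3, 4], ddof=1))
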