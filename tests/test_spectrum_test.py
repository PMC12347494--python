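import numpy as np
import pytest
from scipy import stats as sps

from rtmut.profiling import SBSProfile
from rtmut.spectrum_test import (
    fit_null,
    replicate_allocation,
    run_spectrum_analysis,
)
from rtmut.spectrum_test import test_sample as score_sample
from rtmut.synthetic import default_spectrum


def _profiles(counts_matrix, prefix="c", rt_state="all"):
    return [
        SBSProfile(row, sample_id=f"{prefix}{i}", rt_state=rt_state)
        for i, row in enumerate(counts_matrix)
    ]


@pytest.fixture(scope="module")
def spectrum():
    return default_spectrum()


def test_replicate_allocation_equal_and_round_robin():
    assert replicate_allocation(1000, 4) == [250, 250, 250, 250]
    assert replicate_allocation(10, 3) == [4, 3, 3]
    assert sum(replicate_allocation(9999, 4)) == 9999


def test_fit_null_requires_two_nonempty_controls(uniform_trinuc):
    counts = np.zeros((1, 96), dtype=int)
    counts[0, 0] = 5
    with pytest.raises(ValueError, match="at least 2"):
        fit_null(_profiles(counts), uniform_trinuc, B=100, seed=0)
    counts = np.zeros((2, 96), dtype=int)
    counts[0, 0] = 5
    with pytest.raises(ValueError, match="empty control"):
        fit_null(_profiles(counts), uniform_trinuc, B=100, seed=0)


def test_identical_controls_centroid_and_tight_null(uniform_trinuc, spectrum):
    rng = np.random.default_rng(0)
    row = rng.multinomial(20_000, spectrum)
    profs = _profiles(np.vstack([row, row]))
    null = fit_null(profs, uniform_trinuc, B=200, seed=1, centroid_mode="fixed")
    expected = row / row.sum()
    assert np.allclose(null.centroid, expected)
    # degenerate pool with many mutations: null distances concentrate near 0
    assert np.median(null.null_distances) < 0.02


def test_fit_null_deterministic_per_seed(uniform_trinuc, spectrum):
    rng = np.random.default_rng(2)
    counts = rng.multinomial(3000, spectrum, size=4)
    a = fit_null(_profiles(counts), uniform_trinuc, B=300, seed=5)
    b = fit_null(_profiles(counts), uniform_trinuc, B=300, seed=5)
    assert np.array_equal(a.null_distances, b.null_distances)
    c = fit_null(_profiles(counts), uniform_trinuc, B=300, seed=6)
    assert not np.array_equal(a.null_distances, c.null_distances)


def test_score_sample_p_extremes(uniform_trinuc, spectrum):
    rng = np.random.default_rng(3)
    row = rng.multinomial(5000, spectrum)
    profs = _profiles(np.vstack([row, row]))
    null = fit_null(profs, uniform_trinuc, B=500, seed=0, centroid_mode="fixed")
    # a sample identical to the (identical) controls sits at distance 0 -> p = 1
    d, p = score_sample(SBSProfile(row, "ko"), null, uniform_trinuc)
    assert d == pytest.approx(0.0)
    assert p == pytest.approx(1.0)
    # a wildly divergent sample beats every bootstrap replicate
    far = np.zeros(96, dtype=int)
    far[0] = 5000
    d, p = score_sample(SBSProfile(far, "ko2"), null, uniform_trinuc)
    assert p == pytest.approx(1 / (null.B + 1))


def test_p_monotone_in_distance(uniform_trinuc, spectrum):
    rng = np.random.default_rng(4)
    counts = rng.multinomial(3000, spectrum, size=4)
    null = fit_null(_profiles(counts), uniform_trinuc, B=500, seed=0)
    results = []
    for shift_mass in (0.0, 0.05, 0.15, 0.4):
        q = spectrum * (1 - shift_mass)
        q[7] += shift_mass
        ko = rng.multinomial(3000, q / q.sum())
        results.append(score_sample(SBSProfile(ko, "k"), null, uniform_trinuc))
    dists = [r[0] for r in results]
    ps = [r[1] for r in results]
    assert dists == sorted(dists)
    assert ps == sorted(ps, reverse=True)


def test_pool_drawn_rejection_rate_fixed_mode(uniform_trinuc, spectrum):
    """Samples resampled from the control pool are calibrated against the
    fixed-centroid null: rejection rate at raw alpha=0.05 in [0.03, 0.07]."""
    rng = np.random.default_rng(10)
    rejections = 0
    n_rep = 0
    for _cohort in range(10):
        counts = rng.multinomial(3000, spectrum, size=4)
        profs = _profiles(counts)
        null = fit_null(
            profs, uniform_trinuc, B=2000,
            seed=int(rng.integers(2**31)), centroid_mode="fixed",
        )
        p_pool = null.pool_counts / null.pool_counts.sum()
        for _ in range(50):
            draw = rng.multinomial(3000, p_pool)
            _, p = score_sample(SBSProfile(draw, "x"), null, uniform_trinuc)
            rejections += p <= 0.05
            n_rep += 1
    assert 0.03 <= rejections / n_rep <= 0.07


def test_fresh_sample_null_uniformity_resampled_mode(uniform_trinuc, spectrum):
    """With the resampled-centroid null, raw p for independent null samples
    is uniform (KS at alpha=0.01 over 500 draws from 100 cohorts)."""
    rng = np.random.default_rng(20)
    pvals = []
    for _ in range(100):
        counts = rng.multinomial(3000, spectrum, size=4)
        null = fit_null(
            _profiles(counts), uniform_trinuc, B=1000,
            seed=rng.integers(2**31), centroid_mode="resampled",
        )
        for _ in range(5):
            fresh = rng.multinomial(3000, spectrum)
            _, p = score_sample(SBSProfile(fresh, "x"), null, uniform_trinuc)
            pvals.append(p)
    stat = sps.kstest(pvals, "uniform")
    assert stat.pvalue >= 0.01


def test_run_spectrum_analysis_structure_and_determinism(uniform_trinuc, spectrum):
    rng = np.random.default_rng(6)
    profiles = {}
    for state in ("all", "early", "late"):
        profiles[state] = {}
        for i in range(4):
            profiles[state][f"ctrl{i}"] = SBSProfile(
                rng.multinomial(1000, spectrum), f"ctrl{i}", state
            )
        for i in range(2):
            profiles[state][f"ko_rep{i}"] = SBSProfile(
                rng.multinomial(1000, spectrum), f"ko_rep{i}", state
            )
    trinuc = {s: uniform_trinuc for s in ("all", "early", "late")}
    groups = {"control": [f"ctrl{i}" for i in range(4)], "ko": ["ko_rep0", "ko_rep1"]}
    df1 = run_spectrum_analysis(profiles, trinuc, groups, "control", B=300, seed=9)
    df2 = run_spectrum_analysis(profiles, trinuc, groups, "control", B=300, seed=9)
    assert df1.equals(df2)
    assert set(df1["rt_state"]) == {"all", "early", "late"}
    assert len(df1) == 6  # 2 replicates x 3 states
    # combined value is shared within a group and state
    for _, sub in df1.groupby("rt_state"):
        assert sub["p_combined"].nunique() == 1
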