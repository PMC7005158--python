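"""GC bias, predictor importance, and variant-site-density resampling."""

import itertools

import numpy as np
import pandas as pd
import pytest

from covbias import bias, synthetic
from covbias.bias import (
    VariantSite,
    assign_gc_deciles,
    extreme_gc_comparison,
    fit_importance,
    gc_context,
    gc_decile_coverage,
    variant_site_density,
    vsd_resampling_test,
)
from covbias.coverage import CoverageTrack
from covbias.intervals import GenomicInterval, IntervalSet

from conftest import make_universe


# ---------------------------------------------------------------------------
# GC context and deciles
# ---------------------------------------------------------------------------

def test_gc_context_window(tmp_path):
    fa = tmp_path / "g.fa"
    fa.write_text(">c\n" + "A" * 50 + "G" * 11 + "A" * 50 + "\n")
    sites = gc_context([VariantSite("c", 55)], str(fa), flank=5)
    assert sites[0].gc_context == 1.0
    sites = gc_context([VariantSite("c", 55)], str(fa), flank=10)
    # window [45, 66): 5 A + 11 G + 5 A
    assert sites[0].gc_context == pytest.approx(11 / 21)


def test_decile_partition_sizes():
    rng = np.random.default_rng(0)
    for n in [20, 95, 100, 1003]:
        sites = [VariantSite("c", i, gc_context=float(g)) for i, g in enumerate(rng.random(n))]
        assign_gc_deciles(sites)
        counts = pd.Series([s.decile for s in sites]).value_counts()
        assert sorted(counts.index) == list(range(1, 11))
        assert counts.max() - counts.min() <= 1
        assert counts.sum() == n


def test_decile_ranks_follow_gc():
    sites = [VariantSite("c", i, gc_context=i / 100) for i in range(100)]
    assign_gc_deciles(sites)
    assert sites[0].decile == 1 and sites[99].decile == 10


def _decile_study(gc_slope: float, seed: int):
    """Generate a seeded dataset and compute the decile table via the full
    package path (genome FASTA -> GC context -> track depth)."""
    cfg = synthetic.SyntheticConfig(
        seed=seed, n_intervals=150, min_length=150, max_length=300,
        mean_depth=80, gc_slope=gc_slope, mf_zero_prob=1.0, mf_one_prob=0.0,
        between_sigma=0.0, sample_cv=0.0,
    )
    intervals, genome, truth = synthetic.generate_intervals(cfg)
    filt, _, _ = synthetic.generate_coverage(cfg, intervals, truth, sample=0)
    rng = np.random.default_rng(seed + 1)
    sites = []
    for iv in intervals:
        for _ in range(8):
            pos = int(rng.integers(iv.start + 50, iv.end - 50))
            sites.append(VariantSite(iv.chrom, pos))
    import tempfile, os

    with tempfile.TemporaryDirectory() as d:
        fa = os.path.join(d, "g.fa")
        synthetic.write_fasta(genome, fa)
        gc_context(sites, fa)
        return gc_decile_coverage(sites, filt)


def test_gc_bias_detected_when_injected():
    from scipy.stats import spearmanr

    table = _decile_study(gc_slope=0.5, seed=3)
    rho = spearmanr(table["decile"], table["mean_norm"]).statistic
    assert rho < -0.9
    # median GC per decile increases by construction
    assert table["median_gc"].is_monotonic_increasing


def test_sites_outside_universe_excluded(tmp_path):
    fa = tmp_path / "g.fa"
    fa.write_text(">c\n" + "ACGT" * 100 + "\n")
    universe = make_universe(("c", 0, 100))
    track = CoverageTrack(universe, [np.full(100, 20)])
    sites = [VariantSite("c", p) for p in [10, 50, 350]]  # last one outside
    gc_context(sites, str(fa))
    table = gc_decile_coverage(sites, track)
    assert table["n_sites"].sum() == 2
    assert table.attrs["n_excluded"] == 1


# ---------------------------------------------------------------------------
# Extreme-GC comparison
# ---------------------------------------------------------------------------

def test_extreme_gc_empty_bands():
    df = pd.DataFrame({"gc": [0.5] * 20, "norm_mean": [1.0] * 20, "length": [100] * 20})
    out = extreme_gc_comparison(df)
    assert out["low_gc"]["n_intervals"] == 0 and out["high_gc"]["n_intervals"] == 0
    assert np.isnan(out["low_gc"]["p_value"])


def test_extreme_gc_constructed_suppression():
    rng = np.random.default_rng(5)
    gc = rng.uniform(0, 1, 400)
    norm = rng.lognormal(0, 0.1, 400)
    norm[gc >= 0.8] *= 0.5  # suppress high-GC intervals 2x
    df = pd.DataFrame({"gc": gc, "norm_mean": norm, "length": np.full(400, 120)})
    out = extreme_gc_comparison(df)
    assert out["high_gc"]["median"] < out["remainder_median"]
    assert out["high_gc"]["p_value"] < 0.001
    assert out["high_gc"]["total_bp"] == 120 * out["high_gc"]["n_intervals"]


# ---------------------------------------------------------------------------
# Predictor importance
# ---------------------------------------------------------------------------

def _base_table(n=400, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "gc": rng.beta(5, 5, n),
            "length": rng.integers(100, 400, n).astype(float),
            "mf": rng.uniform(0, 1, n),
            "targeted": rng.random(n) < 0.8,
        }
    )


def test_importance_linear_identifies_single_driver():
    tab = _base_table()
    tab["norm_mean"] = 2.0 - 1.5 * tab["mf"]  # exact function of mf only
    res = fit_importance(tab, seed=0, cv_folds=0)
    assert res.linear_regression["mf"] == 100.0
    assert (res.linear_regression.drop("mf") < 1).all()


def test_importance_label_driven_by_targeted():
    rng = np.random.default_rng(1)
    tab = _base_table(seed=1)
    # low coverage essentially determined by the targeted flag, small noise
    tab["norm_mean"] = np.where(
        tab["targeted"], rng.lognormal(0, 0.1, len(tab)), rng.uniform(0, 0.2, len(tab))
    )
    res = fit_importance(tab, seed=1)
    assert res.linear_classification.idxmax() == "targeted"
    assert res.random_forest.idxmax() == "targeted"
    assert res.cv_metrics is not None
    assert res.cv_metrics["accuracy"].mean() > 0.9


def test_importance_deterministic_and_scaled():
    tab = synthetic.generate_importance_table(seed=4, n_intervals=400)
    r1 = fit_importance(tab, seed=9)
    r2 = fit_importance(tab, seed=9)
    for a, b in [
        (r1.linear_regression, r2.linear_regression),
        (r1.random_forest, r2.random_forest),
    ]:
        assert np.allclose(a.to_numpy(), b.to_numpy())
        assert a.max() == 100.0


def test_importance_input_validation():
    tab = _base_table(n=20)
    tab["norm_mean"] = 1.0
    with pytest.raises(ValueError, match=">= 50"):
        fit_importance(tab)
    tab = _base_table(n=100)
    tab["norm_mean"] = 1.0  # single-class label
    res = fit_importance(tab, seed=0)
    assert res.random_forest is None
    assert any("single-class" in n for n in res.notes)


# ---------------------------------------------------------------------------
# Variant-site density
# ---------------------------------------------------------------------------

def test_vsd_examples_and_oracle():
    iset = IntervalSet([GenomicInterval("c", 0, 100), GenomicInterval("c", 200, 300)])
    sites = [("c", p) for p in [5, 10, 20, 30, 40]]
    vsd = variant_site_density(iset, sites)
    assert vsd[0] == pytest.approx(0.05) and vsd[1] == 0.0

    rng = np.random.default_rng(2)
    iset = IntervalSet(
        [GenomicInterval("c", 120 * k, 120 * k + 100) for k in range(30)]
    )
    sites = [("c", int(p)) for p in rng.integers(0, 3600, 500)]
    vsd = variant_site_density(iset, sites)
    for k, iv in enumerate(iset):
        count = sum(1 for c, p in sites if c == "c" and iv.start <= p < iv.end)
        assert vsd[k] == pytest.approx(count / iv.length)


def test_vsd_resampling_extreme_case():
    """Query far below every possible null mean -> p = 1/(n+1)."""
    vsd = np.concatenate([[0.0, 0.0], np.full(50, 0.5)])
    mf = np.concatenate([[0.9, 0.95], np.zeros(50)])
    res = vsd_resampling_test(vsd, mf, n_resamples=999, seed=0)
    assert res.empirical_p == pytest.approx(1 / 1000)
    assert res.set_size == 2


def test_vsd_resampling_matches_exhaustive_enumeration():
    """10 background intervals, query of 3: empirical p converges to the
    exhaustive C(10,3) enumeration."""
    rng = np.random.default_rng(8)
    bg_vsd = rng.uniform(0, 0.1, 10)
    q_vsd = np.array([0.01, 0.02, 0.03])
    vsd = np.concatenate([q_vsd, bg_vsd])
    mf = np.concatenate([np.full(3, 0.8), np.zeros(10)])
    observed = q_vsd.mean()
    null_all = [np.mean(c) for c in itertools.combinations(bg_vsd, 3)]
    exact_p = sum(m <= observed for m in null_all) / len(null_all)

    res = vsd_resampling_test(vsd, mf, n_resamples=40_000, seed=1)
    assert res.observed_mean_vsd == pytest.approx(observed)
    # +1-corrected estimate within Monte-Carlo error of the exact fraction
    se = np.sqrt(exact_p * (1 - exact_p) / res.n_resamples)
    assert abs(res.empirical_p - exact_p) < 3 * se + 1e-4


def test_vsd_resampling_errors():
    with pytest.raises(ValueError, match="strata"):
        vsd_resampling_test(np.ones(5), np.zeros(5))
    with pytest.raises(ValueError, match="smaller than"):
        vsd_resampling_test(np.ones(5), np.array([0.9, 0.9, 0.9, 0.0, 0.0]))


def test_vsd_null_mean_converges_to_background_mean():
    rng = np.random.default_rng(3)
    vsd = rng.uniform(0, 0.1, 200)
    mf = np.where(rng.random(200) < 0.1, 0.9, 0.0)
    res = vsd_resampling_test(vsd, mf, n_resamples=10_000, seed=2)
    bg_mean = vsd[mf <= 0.4].mean()
    assert res.null_means.mean() == pytest.approx(bg_mean, abs=0.002)
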