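"""QQ summaries, rejection-rate estimates, and experiment orchestration."""


import numpy as np
import pandas as pd
import pytest

import triotdt as tdt


def test_qq_single_point_band_is_uniform_quantiles():
    qq = tdt.qq_summary([0.3], band_level=0.95)
    # with one test the order statistic is Uniform(0,1) itself
    assert qq.band_upper[0] == pytest.approx(-np.log10(0.025))
    assert qq.band_lower[0] == pytest.approx(-np.log10(0.975))
    assert qq.expected[0] == pytest.approx(-np.log10(0.5))


def test_qq_observed_is_sorted_transform_of_input():
    rng = np.random.default_rng(0)
    p = rng.random(500)
    qq = tdt.qq_summary(p)
    assert np.allclose(np.sort(qq.observed), np.sort(-np.log10(p)))
    for arr in (qq.expected, qq.observed, qq.band_lower, qq.band_upper):
        assert len(arr) == 500
        assert np.all(np.diff(arr) >= 0)  # monotone in rank
    assert np.all(qq.band_lower <= qq.expected) and np.all(qq.expected <= qq.band_upper)


def test_qq_handles_zero_pvalues_and_rejects_bad_input():
    qq = tdt.qq_summary([0.0, 0.5, 1.0])
    assert np.isfinite(qq.observed).all()
    with pytest.raises(ValueError):
        tdt.qq_summary([])
    with pytest.raises(ValueError):
        tdt.qq_summary([0.5], band_level=1.5)


def test_rate_estimate_bounds_and_trivial_cases():
    r = tdt.estimate_rate(np.ones(100), alpha=0.05)
    assert r.rate == 0.0 and r.n_rejections == 0
    assert r.ci_low == 0.0
    rng = np.random.default_rng(1)
    r = tdt.estimate_rate(rng.random(10_000), alpha=0.05)
    assert 0.04 < r.rate < 0.06
    assert r.ci_low <= r.rate <= r.ci_high
    with pytest.raises(ValueError):
        tdt.estimate_rate([], alpha=0.05)


def _tiny_config(**kw):
    base = dict(
        mode="type1", n_genes=15, variants_per_gene=10, maf_cap=0.05,
        n_trios=40, n_replicates=2,
        conditions=[tdt.ErrorSpec.make(2, 0.10)], seed=123,
    )
    base.update(kw)
    return tdt.ExperimentConfig(**base)


def test_experiment_is_deterministic():
    a = tdt.run_experiment(_tiny_config())
    b = tdt.run_experiment(_tiny_config())
    pd.testing.assert_frame_equal(a.totals, b.totals)
    for lab in a.gene_tables:
        pd.testing.assert_frame_equal(a.gene_tables[lab], b.gene_tables[lab])
    c = tdt.run_experiment(_tiny_config(seed=124))
    assert not a.totals.equals(c.totals)


def test_experiment_null_condition_is_balanced():
    cfg = tdt.ExperimentConfig(
        mode="type1", n_genes=50, variants_per_gene=40, n_trios=200,
        n_replicates=3, conditions=[], seed=5,
    )
    res = tdt.run_experiment(cfg)
    T, U = res.totals.loc["none", ["T", "U"]]
    n = T + U
    assert abs(T / n - 0.5) < 3 * np.sqrt(0.25 / n)
    assert res.totals.loc["none", "pct_transmitted"] == 50


def test_experiment_save_writes_tables(tmp_path):
    res = tdt.run_experiment(_tiny_config())
    res.save(tmp_path)
    assert (tmp_path / "totals.tsv").exists()
    assert (tmp_path / "rejection_rates.tsv").exists()
    assert (tmp_path / "manifest.json").exists()
    qq_files = list(tmp_path.glob("qq_*.tsv"))
    assert len(qq_files) == 2  # no-error condition + one injected condition
    frame = pd.read_csv(qq_files[0], sep="\t")
    assert list(frame.columns) == ["rank", "expected", "observed", "band_lower", "band_upper"]


def test_experiment_power_mode_runs_per_gene():
    cfg = tdt.ExperimentConfig(
        mode="power", variants_per_gene=("poisson", 19.0), maf_cap=0.01,
        n_trios=50, n_replicates=4, conditions=[tdt.ErrorSpec.make(2, 0.10)], seed=6,
    )
    res = tdt.run_experiment(cfg)
    assert len(res.gene_tables["none"]) == 4  # one gene per replicate
    assert (res.gene_tables["none"]["replicate"].value_counts() == 1).all()


def test_experiment_config_validation():
    with pytest.raises(ValueError):
        tdt.ExperimentConfig(mode="bogus")
    with pytest.raises(ValueError):
        tdt.ExperimentConfig(n_replicates=0)
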