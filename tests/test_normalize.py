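"""Normalization, noise imputation and empirical-Bayes batch correction."""

import numpy as np
import pandas as pd
import pytest

from proteosig import (
    AggregatedMatrix,
    eb_batch_correct,
    global_median_normalize,
    impute_noise,
    scale_equal_channel_signal,
)


def _agg(values, index=None):
    data = pd.DataFrame(np.asarray(values, dtype=float), index=index)
    data.columns = [f"f{i}" for i in range(data.shape[1])]
    meta = pd.DataFrame(index=data.index)
    return AggregatedMatrix(data=data, meta=meta)


# --------------------------------------------------------------------------
# equal-signal scaling


def test_scaling_factors_and_totals():
    agg = _agg([[60.0, 40.0], [150.0, 50.0]], index=["s1", "s2"])
    scaled, report = scale_equal_channel_signal(agg)
    assert report.factors["s1"] == pytest.approx(1.5)
    assert report.factors["s2"] == pytest.approx(0.75)
    np.testing.assert_allclose(scaled.data.sum(axis=1), [150.0, 150.0])


def test_scaling_conserves_total_signal():
    rng = np.random.default_rng(5)
    agg = _agg(rng.uniform(0, 100, size=(6, 30)))
    scaled, _ = scale_equal_channel_signal(agg)
    assert scaled.data.to_numpy().sum() == pytest.approx(
        agg.data.to_numpy().sum(), rel=1e-12
    )


def test_scaling_noop_when_totals_equal():
    agg = _agg([[10.0, 20.0], [20.0, 10.0]])
    scaled, report = scale_equal_channel_signal(agg)
    np.testing.assert_allclose(report.factors, 1.0)
    np.testing.assert_allclose(scaled.data.to_numpy(), agg.data.to_numpy())


def test_scaling_names_all_zero_sample():
    agg = _agg([[1.0, 2.0], [0.0, 0.0]], index=["ok", "empty"])
    with pytest.raises(ValueError, match="empty"):
        scale_equal_channel_signal(agg)


# --------------------------------------------------------------------------
# median normalization (peptide arm)


def test_median_normalize_single_sample_unchanged():
    df = pd.DataFrame([[1.0, 10.0, 100.0]], index=["s"])
    out = global_median_normalize(df)
    np.testing.assert_allclose(out.to_numpy(), df.to_numpy())


def test_median_normalize_equalizes_medians():
    df = pd.DataFrame(
        {"a": [10.0, 20.0], "b": [20.0, 40.0], "c": [30.0, 60.0], "d": [np.nan, 80.0]},
        index=["s1", "s2"],
    )
    out = global_median_normalize(df)
    med = np.log10(out).median(axis=1)
    assert med["s1"] == pytest.approx(med["s2"])
    # missingness preserved
    assert out.isna().equals(df.isna())


def test_median_normalize_rejects_empty_sample():
    df = pd.DataFrame([[1.0, 2.0], [np.nan, np.nan]], index=["s1", "s2"])
    with pytest.raises(ValueError, match="s2"):
        global_median_normalize(df)


# --------------------------------------------------------------------------
# down-shifted noise imputation


def test_impute_noop_without_missing():
    df = pd.DataFrame([[1.0, 2.0], [3.0, 4.0]])
    out = impute_noise(df, seed=0)
    np.testing.assert_allclose(out.to_numpy(), df.to_numpy())


def test_impute_preserves_observed_and_is_deterministic():
    rng = np.random.default_rng(8)
    df = pd.DataFrame(10.0 ** rng.normal(5, 1, size=(3, 40)))
    df.iloc[:, ::3] = np.nan
    out1 = impute_noise(df, seed=42)
    out2 = impute_noise(df, seed=42)
    pd.testing.assert_frame_equal(out1, out2)
    observed = ~df.isna()
    np.testing.assert_allclose(
        out1.to_numpy()[observed.to_numpy()], df.to_numpy()[observed.to_numpy()]
    )
    assert not out1.isna().any().any()


def test_imputed_distribution_matches_downshifted_normal():
    """Sample mean of n=10,000 imputed log10 values sits within 3 SE of
    mu - 1.8 sigma with SD 0.3 sigma (the sample's own noise estimates)."""
    rng = np.random.default_rng(17)
    n_obs, n_miss = 4000, 10000
    observed = 10.0 ** rng.normal(6.0, 1.0, size=n_obs)
    row = np.concatenate([observed, np.full(n_miss, np.nan)])
    df = pd.DataFrame([row], index=["s"])
    out = impute_noise(df, downshift=1.8, width=0.3, seed=99)
    log_obs = np.log10(observed)
    mu, sigma = log_obs.mean(), log_obs.std(ddof=1)
    imputed = np.log10(out.to_numpy()[0, n_obs:])
    se = 0.3 * sigma / np.sqrt(n_miss)
    assert abs(imputed.mean() - (mu - 1.8 * sigma)) < 3 * se
    assert imputed.std(ddof=1) == pytest.approx(0.3 * sigma, rel=0.05)


def test_impute_absolute_mode():
    rng = np.random.default_rng(18)
    observed = 10.0 ** rng.normal(6.0, 0.5, size=2000)
    row = np.concatenate([observed, np.full(5000, np.nan)])
    out = impute_noise(pd.DataFrame([row]), downshift=1.8, width=0.3,
                       seed=1, mode="absolute")
    imputed = np.log10(out.to_numpy()[0, 2000:])
    mu = np.log10(observed).mean()
    assert imputed.mean() == pytest.approx(mu - 1.8, abs=3 * 0.3 / np.sqrt(5000) + 0.02)


def test_impute_needs_two_observed_values():
    df = pd.DataFrame([[5.0, np.nan, np.nan]], index=["thin"])
    with pytest.raises(ValueError, match="thin"):
        impute_noise(df, seed=0)


# --------------------------------------------------------------------------
# ComBat-style batch correction


def test_single_batch_is_noop():
    rng = np.random.default_rng(23)
    df = pd.DataFrame(rng.normal(size=(6, 15)))
    out = eb_batch_correct(df, ["A"] * 6)
    np.testing.assert_allclose(out.to_numpy(), df.to_numpy(), atol=1e-12)


def test_singleton_batch_raises():
    df = pd.DataFrame(np.ones((3, 4)))
    with pytest.raises(ValueError, match="single sample"):
        eb_batch_correct(df, ["A", "A", "B"])


def test_additive_offset_removed_exactly():
    """Two batches differing by a per-feature additive offset: corrected
    per-feature batch means agree to 1e-6 relative."""
    rng = np.random.default_rng(29)
    n_feat = 20
    base = rng.normal(5.0, 1.0, size=n_feat)
    gamma = rng.normal(0.0, 1.0, size=n_feat)
    rows = []
    for _ in range(3):
        rows.append(base + rng.normal(0, 1e-5, size=n_feat))
    for _ in range(3):
        rows.append(base + gamma + rng.normal(0, 1e-5, size=n_feat))
    df = pd.DataFrame(rows, index=[f"s{i}" for i in range(6)])
    batches = ["A"] * 3 + ["B"] * 3
    out = eb_batch_correct(df, batches)
    mean_a = out.iloc[:3].mean(axis=0)
    mean_b = out.iloc[3:].mean(axis=0)
    rel = (mean_a - mean_b).abs() / mean_a.abs().clip(lower=1.0)
    assert (rel < 1e-6).all()


def test_batch_correction_preserves_feature_means():
    rng = np.random.default_rng(31)
    df = pd.DataFrame(rng.normal(5, 1, size=(12, 25)))
    df.iloc[6:] += rng.normal(0, 1, size=25)
    out = eb_batch_correct(df, ["A"] * 6 + ["B"] * 6)
    np.testing.assert_allclose(out.mean(axis=0), df.mean(axis=0), atol=0.05)


def test_correction_moves_matrix_toward_ground_truth():
    rng = np.random.default_rng(37)
    n, p = 20, 60
    truth = rng.normal(0, 1, size=(n, p))
    gamma = rng.normal(0, 1, size=p)
    corrupted = truth.copy()
    corrupted[n // 2 :] += gamma
    df = pd.DataFrame(corrupted)
    out = eb_batch_correct(df, ["A"] * (n // 2) + ["B"] * (n // 2))
    err_corrected = np.linalg.norm(out.to_numpy() - truth)
    err_raw = np.linalg.norm(corrupted - truth)
    assert err_corrected < err_raw


def test_constant_features_pass_through():
    rng = np.random.default_rng(41)
    df = pd.DataFrame(rng.normal(size=(6, 5)))
    df["const"] = 7.0
    out = eb_batch_correct(df, ["A"] * 3 + ["B"] * 3)
    np.testing.assert_allclose(out["const"], 7.0)


def test_batch_axis_vanishes_while_population_persists():
    """After correction, PCA no longer separates batches on PC1-2
    (silhouette < 0.1) but the population split remains."""
    from sklearn.metrics import silhouette_score

    from proteosig.analysis import pca, sign_partition_errors

    rng = np.random.default_rng(43)
    n_feat = 120
    pop_effect = np.zeros(n_feat)
    pop_effect[:40] = 1.0
    rows, pops, batches = [], [], []
    for b in range(3):
        gamma = rng.normal(0, 1.5, size=n_feat)
        for i in range(8):
            pop = i % 2
            rows.append(
                5.0 + gamma + pop * pop_effect + rng.normal(0, 0.2, size=n_feat)
            )
            pops.append("P1" if pop else "P0")
            batches.append(f"B{b}")
    df = pd.DataFrame(rows)
    corrected = eb_batch_correct(df, batches)
    result = pca(corrected, log_transform=False, n_components=3)
    pc12 = result.scores[["PC1", "PC2"]].to_numpy()
    assert silhouette_score(pc12, batches) < 0.1
    assert sign_partition_errors(result.scores["PC1"], pops) == 0
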