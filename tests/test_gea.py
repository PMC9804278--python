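"""RDA machinery: imputation, (partial) RDA, outlier detection, batch
removal, PCA."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from conunit.gea import (
    RdaModel,
    check_predictor_correlations,
    detect_outliers_sd,
    fit_rda,
    impute_missing_mode,
    pca_genotypes,
    remove_batch_effect,
)
from conunit.genotypes import MISSING


# ---------------------------------------------------------------------------
# Imputation
# ---------------------------------------------------------------------------

def test_impute_no_missing_identity(make_gm):
    g = np.array([[0, 1], [2, 1], [0, 0], [2, 2]])
    gm = make_gm(g, ["A", "A", "B", "B"])
    np.testing.assert_array_equal(impute_missing_mode(gm), g.astype(float))


def test_impute_site_mode_and_tiebreak(make_gm):
    # col 0: site calls {0,0,1} -> mode 0; col 1: {0,1,1} -> mode 1;
    # col 2: tie {0,1} -> lower code 0
    g = np.array([
        [0, 0, 0],
        [0, 1, 1],
        [1, 1, MISSING],
        [MISSING, MISSING, MISSING],
    ])
    gm = make_gm(g, ["A"] * 4)
    out = impute_missing_mode(gm)
    assert out[3, 0] == 0.0
    assert out[3, 1] == 1.0
    assert out[3, 2] == 0.0 and out[2, 2] == 0.0


def test_impute_all_missing_snp_errors(make_gm):
    g = np.full((3, 1), MISSING)
    gm = make_gm(g, ["A"] * 3)
    with pytest.raises(ValueError):
        impute_missing_mode(gm)


# ---------------------------------------------------------------------------
# RDA
# ---------------------------------------------------------------------------

def test_rda_conditioners_equal_predictors_kill_signal():
    rng = np.random.default_rng(0)
    x = rng.normal(size=(30, 2))
    y = rng.normal(size=(30, 50)) + x @ rng.normal(size=(2, 50))
    model = fit_rda(y, x, conditioners=x)
    assert np.all(model.eigenvalues < 1e-18)


def test_rda_perfect_association_snp_has_max_loading():
    rng = np.random.default_rng(1)
    x = rng.normal(size=(25, 1))
    y = rng.normal(size=(25, 20)) * 0.3
    y[:, 7] = x[:, 0]
    model = fit_rda(y, x)
    assert np.argmax(np.abs(model.loadings[:, 0])) == 7


def test_rda_errors():
    rng = np.random.default_rng(2)
    y = rng.normal(size=(20, 10))
    with pytest.raises(ValueError, match="zero-variance"):
        fit_rda(y, np.ones((20, 1)))
    x = rng.normal(size=(20, 1))
    with pytest.raises(ValueError, match="collinear"):
        fit_rda(y, np.hstack([x, x * 2.0]))
    with pytest.raises(ValueError, match="rows"):
        fit_rda(y[:3], rng.normal(size=(3, 5)))


def test_rda_eigenvalue_properties(small_sim):
    _, gm, truth = small_sim
    from conunit.gea import site_allele_frequencies

    freqs, site_ids = site_allele_frequencies(gm)
    freqs = np.where(np.isnan(freqs), np.nanmean(freqs, axis=0), freqs)
    pred = truth.env_table.set_index("site_id").loc[
        site_ids, ["summer_precip", "autumn_precip"]]
    model = fit_rda(freqs, pred)
    eig = model.eigenvalues
    assert np.all(eig >= 0) and np.all(np.diff(eig) <= 1e-12)
    assert eig.sum() <= model.total_variance + 1e-9


# ---------------------------------------------------------------------------
# Outlier detection
# ---------------------------------------------------------------------------

def _mock_model(loadings):
    loadings = np.asarray(loadings, dtype=float)
    n_ax = loadings.shape[1]
    return RdaModel(
        eigenvalues=np.linspace(2, 1, n_ax),
        row_scores=np.zeros((5, n_ax)),
        loadings=loadings,
        loading_correlations=loadings.copy(),
        predictor_names=["e1"],
        n_conditioners=0,
        total_variance=10.0,
    )


def test_outlier_normal_tail_rate():
    """i.i.d. normal loadings at 40,000 SNPs flag ~ 2*Phi(-3.5) per axis."""
    rng = np.random.default_rng(6)
    n = 40000
    loadings = rng.normal(size=(n, 2))
    response = rng.normal(size=(10, n)) * 0.01
    preds = pd.DataFrame({"e1": rng.normal(size=10)})
    for ax in range(2):
        model = _mock_model(loadings[:, [ax]])
        cand = detect_outliers_sd(model, response, preds, n_axes=1, threshold_sd=3.5)
        frac = len(cand) / n
        target = 2 * norm.sf(3.5)
        assert 0.5 * target <= frac <= 1.5 * target


def test_outlier_all_equal_loadings_empty():
    model = _mock_model(np.ones((100, 2)))
    rng = np.random.default_rng(0)
    cand = detect_outliers_sd(model, rng.normal(size=(5, 100)),
                              pd.DataFrame({"e1": rng.normal(size=5)}))
    assert len(cand) == 0


def test_outlier_sign_flip_invariance():
    rng = np.random.default_rng(7)
    loadings = rng.normal(size=(5000, 2))
    response = rng.normal(size=(8, 5000))
    preds = pd.DataFrame({"e1": rng.normal(size=8)})
    c1 = detect_outliers_sd(_mock_model(loadings), response, preds)
    c2 = detect_outliers_sd(_mock_model(-loadings), response, preds)
    assert set(c1.snp_indices) == set(c2.snp_indices)


def test_candidate_assigned_strongest_predictor():
    rng = np.random.default_rng(8)
    n = 200
    e1 = rng.normal(size=20)
    e2 = rng.normal(size=20)
    response = rng.normal(size=(20, n)) * 0.2
    response[:, 0] = e2  # SNP 0 tracks predictor e2
    loadings = np.zeros((n, 1))
    loadings[0] = 10.0
    loadings[1:] = rng.normal(size=(n - 1, 1)) * 0.5
    cand = detect_outliers_sd(_mock_model(loadings), response,
                              pd.DataFrame({"e1": e1, "e2": e2}), n_axes=1)
    row = cand.table.set_index("snp_index").loc[0]
    assert row.predictor == "e2"
    assert abs(row.r) > 0.9


# ---------------------------------------------------------------------------
# Batch-effect removal
# ---------------------------------------------------------------------------

def test_batch_effect_removal_recovers_planted_snps():
    rng = np.random.default_rng(9)
    n_ind, n_snp, n_shift = 80, 10000, 100
    g = rng.binomial(2, 0.5, size=(n_ind, n_snp)).astype(float)
    batches = np.array(["lane1"] * 40 + ["lane2"] * 40)
    shifted = rng.choice(n_snp, size=n_shift, replace=False)
    g[batches == "lane2"][:, shifted]  # no-op guard
    g[40:, shifted] += 1.0
    kept, removed = remove_batch_effect(g, batches, threshold_sd=4.0)
    hits = len(set(removed) & set(shifted))
    assert hits >= 0.8 * n_shift
    assert kept.shape[1] == n_snp - len(removed)


def test_batch_effect_null_rate_bounded():
    rng = np.random.default_rng(10)
    g = rng.binomial(2, 0.5, size=(60, 8000)).astype(float)
    batches = ["a"] * 30 + ["b"] * 30
    _, removed = remove_batch_effect(g, batches, threshold_sd=4.0)
    expected_tail = 2 * norm.sf(4.0) * 8000
    assert len(removed) <= max(2 * expected_tail, 5)


def test_batch_single_level_errors():
    with pytest.raises(ValueError):
        remove_batch_effect(np.zeros((10, 5)), ["x"] * 10)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def test_pca_duplicated_rows_and_cluster_separation():
    rng = np.random.default_rng(12)
    base = rng.normal(size=(6, 50))
    dup = np.vstack([base, base])
    scores, eig = pca_genotypes(dup, 3)
    np.testing.assert_allclose(scores[:6], scores[6:], atol=1e-8)
    assert np.all(np.diff(eig) <= 1e-9)

    a = rng.normal(size=(10, 40))
    b = rng.normal(size=(10, 40)) + 8.0
    scores, _ = pca_genotypes(np.vstack([a, b]), 2)
    gap = abs(scores[:10, 0].mean() - scores[10:, 0].mean())
    spread = max(scores[:10, 0].std(), scores[10:, 0].std())
    assert gap > 3 * spread


def test_pca_rank_truncation_warns(caplog):
    rng = np.random.default_rng(13)
    y = rng.normal(size=(4, 10))
    scores, eig = pca_genotypes(y, 10)
    assert scores.shape[1] <= 3


def test_predictor_correlation_screen():
    rng = np.random.default_rng(14)
    x = rng.normal(size=100)
    df = pd.DataFrame({"a": x, "b": x + rng.normal(size=100) * 0.1,
                       "c": rng.normal(size=100)})
    with pytest.raises(ValueError, match="correlated"):
        check_predictor_correlations(df, threshold=0.6)
    check_predictor_correlations(df[["a", "c"]], threshold=0.6)
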