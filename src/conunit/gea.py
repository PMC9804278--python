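"""Redundancy-analysis machinery for genotype-environment association.

Ordinary and partial RDA of a genotype response matrix on environmental
predictors, SD-threshold outlier detection on constrained-axis loadings
(the standard RDA-GEA candidate rule), batch-effect removal via an RDA on
batch indicators, a mode-per-site imputer for missing genotypes, and a plain
PCA helper for population-structure conditioning axes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from conunit.genotypes import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Imputation
# ---------------------------------------------------------------------------

def impute_missing_mode(gm: GenotypeMatrix) -> np.ndarray:
    """Fill missing genotypes with the most frequent genotype among called
    individuals of the same site (global mode if a site has no calls at a
    SNP). Ties break to the lower genotype code. Returns a float matrix."""
    g = gm.genotypes.astype(float)
    g[g == MISSING] = np.nan

    def col_modes(block: np.ndarray) -> np.ndarray:
        # mode over axis 0 ignoring NaN; tie -> lowest code; all-NaN -> NaN
        modes = np.full(block.shape[1], np.nan)
        counts = np.stack([np.sum(block == c, axis=0) for c in (0, 1, 2)])
        called = counts.sum(axis=0) > 0
        modes[called] = np.argmax(counts[:, called], axis=0)  # argmax -> lowest on tie
        return modes

    glob = col_modes(g)
    if np.isnan(glob).any():
        raise ValueError("SNP with zero calls anywhere; filter first")
    out = g.copy()
    for sid in gm.site_ids:
        m = gm.site_mask(sid)
        modes = col_modes(g[m])
        modes = np.where(np.isnan(modes), glob, modes)
        block = out[m]
        nanpos = np.isnan(block)
        block[nanpos] = np.broadcast_to(modes, block.shape)[nanpos]
        out[m] = block
    return out


# ---------------------------------------------------------------------------
# RDA
# ---------------------------------------------------------------------------

@dataclass
class RdaModel:
    eigenvalues: np.ndarray  # constrained eigenvalues, non-increasing
    row_scores: np.ndarray  # n x n_axes (site/individual scores)
    loadings: np.ndarray  # SNPs x n_axes raw axis loadings (SVD species scores)
    loading_correlations: np.ndarray  # SNPs x n_axes per-SNP correlation with axis
    predictor_names: list[str]
    n_conditioners: int
    response_centered: np.ndarray = field(repr=False, default=None)
    total_variance: float = 0.0

    @property
    def n_axes(self) -> int:
        return len(self.eigenvalues)

    @property
    def proportion_explained(self) -> np.ndarray:
        return self.eigenvalues / self.total_variance


def _residualize(a: np.ndarray, z: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(z, a, rcond=None)
    return a - z @ beta


def fit_rda(
    response: np.ndarray,
    predictors: pd.DataFrame | np.ndarray,
    conditioners: np.ndarray | None = None,
    scale_response: bool = False,
    collinearity_tol: float = 0.999,
) -> RdaModel:
    """(Partial) redundancy analysis.

    Columns of ``response`` are centred (optionally variance-scaled). With
    conditioners, both response and predictors are replaced by their
    least-squares residuals on the conditioner columns before the constrained
    decomposition. Eigenvalues follow the variance convention (singular value
    squared over n-1).
    """
    y = np.asarray(response, dtype=float)
    if isinstance(predictors, pd.DataFrame):
        pred_names = [str(c) for c in predictors.columns]
        x = predictors.to_numpy(dtype=float)
    else:
        x = np.asarray(predictors, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        pred_names = [f"x{i}" for i in range(x.shape[1])]
    n = y.shape[0]
    n_cond = 0 if conditioners is None else np.atleast_2d(conditioners).shape[1]
    if n <= x.shape[1] + n_cond:
        raise ValueError("need more rows than predictors plus conditioners")

    sd = x.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = [pred_names[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero-variance predictor(s): {bad}")
    corr = np.corrcoef(x, rowvar=False)
    if x.shape[1] > 1:
        iu = np.triu_indices(x.shape[1], k=1)
        worst = np.argmax(np.abs(corr[iu]))
        if np.abs(corr[iu])[worst] >= collinearity_tol:
            i, j = iu[0][worst], iu[1][worst]
            raise ValueError(
                f"collinear predictors: {pred_names[i]} vs {pred_names[j]} "
                f"(|r|={np.abs(corr[iu])[worst]:.4f})"
            )

    y = y - y.mean(axis=0)
    if scale_response:
        ysd = y.std(axis=0, ddof=1)
        y = y / np.where(ysd == 0, 1.0, ysd)
    x = x - x.mean(axis=0)

    if conditioners is not None:
        z = np.atleast_2d(np.asarray(conditioners, dtype=float))
        if z.shape[0] != n:
            z = z.T
        z = z - z.mean(axis=0)
        pre_norm = np.linalg.norm(x, axis=0)
        y = _residualize(y, z)
        x = _residualize(x, z)
        # predictors wholly explained by the conditioners carry no signal;
        # their numerical residue must not be amplified by the regression
        dead = np.linalg.norm(x, axis=0) <= 1e-10 * np.maximum(pre_norm, 1.0)
        x[:, dead] = 0.0

    # fitted values of the multivariate regression of y on x
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    yhat = x @ beta
    u, s, vt = np.linalg.svd(yhat, full_matrices=False)
    n_axes = min(x.shape[1], int(np.sum(s > s[0] * 1e-9 if s.size else 0)))
    n_axes = max(n_axes, 0)
    u, s, vt = u[:, :n_axes], s[:n_axes], vt[:n_axes]
    eig = s**2 / (n - 1)
    row_scores = u * s  # "site scores" (weighted sums of SNP scores)
    loadings = vt.T  # SNPs x axes, orthonormal axis loadings

    # per-SNP correlation of the (conditioned) genotype column with each axis
    with np.errstate(invalid="ignore", divide="ignore"):
        ysd_full = y.std(axis=0, ddof=1)
        axis_sd = row_scores.std(axis=0, ddof=1)
        cov = y.T @ (row_scores - row_scores.mean(axis=0)) / (n - 1)
        loading_corr = cov / np.outer(np.where(ysd_full == 0, np.nan, ysd_full),
                                      np.where(axis_sd == 0, np.nan, axis_sd))

    return RdaModel(
        eigenvalues=eig,
        row_scores=row_scores,
        loadings=loadings,
        loading_correlations=loading_corr,
        predictor_names=pred_names,
        n_conditioners=n_cond,
        response_centered=y,
        total_variance=float(np.sum(y.var(axis=0, ddof=1))),
    )


# ---------------------------------------------------------------------------
# Outlier detection
# ---------------------------------------------------------------------------

@dataclass
class CandidateSet:
    table: pd.DataFrame  # snp_index, axis, loading, z, predictor, r
    threshold_sd: float

    @property
    def snp_indices(self) -> np.ndarray:
        return self.table["snp_index"].to_numpy()

    def __len__(self) -> int:
        return len(self.table)


def detect_outliers_sd(
    model: RdaModel,
    response: np.ndarray,
    predictors: pd.DataFrame | np.ndarray,
    n_axes: int = 2,
    threshold_sd: float = 3.5,
) -> CandidateSet:
    """Flag SNPs whose loading lies beyond ``threshold_sd`` standard
    deviations from the mean loading on any of the first ``n_axes``
    constrained axes; each candidate is assigned the predictor with the
    largest |Pearson correlation| to its genotype column."""
    if model.n_axes < n_axes:
        raise ValueError(f"model has {model.n_axes} axes, need {n_axes}")
    if isinstance(predictors, pd.DataFrame):
        pred_names = [str(c) for c in predictors.columns]
        x = predictors.to_numpy(dtype=float)
    else:
        x = np.asarray(predictors, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        pred_names = [f"x{i}" for i in range(x.shape[1])]
    y = np.asarray(response, dtype=float)
    y = y - y.mean(axis=0)
    x = x - x.mean(axis=0)

    rows = []
    flagged: dict[int, dict] = {}
    for ax in range(n_axes):
        load = model.loadings[:, ax]
        sd = load.std(ddof=0)
        if sd == 0:
            logger.warning("axis %d has zero loading SD; no candidates", ax + 1)
            continue
        z = (load - load.mean()) / sd
        for j in np.flatnonzero(np.abs(z) >= threshold_sd):
            if j in flagged and abs(flagged[j]["z"]) >= abs(z[j]):
                continue
            flagged[j] = dict(snp_index=int(j), axis=ax + 1,
                              loading=float(load[j]), z=float(z[j]))
    with np.errstate(invalid="ignore", divide="ignore"):
        ysd = y.std(axis=0, ddof=1)
        xsd = x.std(axis=0, ddof=1)
    for j, rec in sorted(flagged.items()):
        r = np.array([
            float(np.mean(y[:, j] * x[:, k]) * y.shape[0] / (y.shape[0] - 1)
                  / (ysd[j] * xsd[k])) if ysd[j] > 0 else np.nan
            for k in range(x.shape[1])
        ])
        best = int(np.nanargmax(np.abs(r))) if np.isfinite(r).any() else 0
        rec["predictor"] = pred_names[best]
        rec["r"] = float(r[best]) if np.isfinite(r).any() else np.nan
        rows.append(rec)
    table = pd.DataFrame(rows, columns=["snp_index", "axis", "loading", "z", "predictor", "r"])
    return CandidateSet(table=table, threshold_sd=threshold_sd)


def remove_batch_effect(
    imputed: np.ndarray, batch_labels, threshold_sd: float = 4.0
) -> tuple[np.ndarray, np.ndarray]:
    """RDA with batch indicator(s) as the only predictors; SNPs loading
    beyond ``threshold_sd`` SD on the first constrained axis are removed.
    Returns (reduced matrix, removed SNP column indices)."""
    labels = pd.Series(batch_labels).astype(str)
    levels = sorted(labels.unique())
    if len(levels) < 2:
        raise ValueError("need at least two batches")
    dummies = pd.get_dummies(labels, drop_first=True).astype(float)
    model = fit_rda(imputed, dummies)
    load = model.loadings[:, 0]
    sd = load.std(ddof=0)
    if sd == 0:
        return imputed, np.array([], dtype=int)
    z = (load - load.mean()) / sd
    removed = np.flatnonzero(np.abs(z) >= threshold_sd)
    kept = np.delete(imputed, removed, axis=1)
    return kept, removed


def pca_genotypes(imputed: np.ndarray, n_axes: int) -> tuple[np.ndarray, np.ndarray]:
    """Column-centred PCA. Returns (scores n x k, eigenvalues)."""
    y = np.asarray(imputed, dtype=float)
    if y.shape[0] < 2:
        raise ValueError("need at least two rows")
    y = y - y.mean(axis=0)
    u, s, _ = np.linalg.svd(y, full_matrices=False)
    rank = int(np.sum(s > (s[0] * 1e-9 if s.size else 0)))
    if n_axes > rank:
        logger.warning("requested %d axes but rank is %d; truncating", n_axes, rank)
        n_axes = rank
    eig = s**2 / (y.shape[0] - 1)
    return (u[:, :n_axes] * s[:n_axes]), eig[:n_axes]


def site_allele_frequencies(gm: GenotypeMatrix) -> tuple[np.ndarray, list[str]]:
    """Site x SNP alternate-allele frequency matrix (site-level RDA response).
    NaN where a site has no calls at a SNP."""
    site_ids = gm.site_ids
    out = np.full((len(site_ids), gm.n_snp), np.nan)
    for i, sid in enumerate(site_ids):
        out[i] = gm.allele_freq(gm.site_mask(sid))
    return out, site_ids


def check_predictor_correlations(predictors: pd.DataFrame, threshold: float = 0.6) -> None:
    """Raise if any predictor pair correlates at or beyond |r| threshold."""
    x = predictors.to_numpy(dtype=float)
    if x.shape[1] < 2:
        return
    corr = np.corrcoef(x, rowvar=False)
    iu = np.triu_indices(x.shape[1], k=1)
    for i, j, r in zip(*iu, corr[iu]):
        if abs(r) >= threshold:
            raise ValueError(
                f"predictors {predictors.columns[i]} and {predictors.columns[j]} "
                f"correlated at |r|={abs(r):.3f} >= {threshold}"
            )


__all__ = [
    "CandidateSet",
    "RdaModel",
    "check_predictor_correlations",
    "detect_outliers_sd",
    "fit_rda",
    "impute_missing_mode",
    "pca_genotypes",
    "remove_batch_effect",
    "site_allele_frequencies",
]
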