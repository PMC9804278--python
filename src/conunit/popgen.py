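"""Per-site diversity and between-site differentiation statistics.

Diversity: observed/expected heterozygosity, nucleotide diversity over an
explicit assayed length, private-allele counts. Differentiation: multi-locus
Weir & Cockerham (1984) theta as a ratio of summed variance components, and
Nei (1972) standard genetic distance D = -ln(I).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from conunit.genotypes import MISSING, GenotypeMatrix


@dataclass
class PairwiseMatrix:
    """Symmetric site x site matrix of F_ST (theta) or Nei's D."""

    kind: str  # "fst" | "nei_d"
    site_ids: list[str]
    values: np.ndarray
    loci_used: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.site_ids, columns=self.site_ids)

    def offdiag_mean(self) -> float:
        iu = np.triu_indices(len(self.site_ids), k=1)
        vals = self.values[iu]
        return float(np.nanmean(vals[np.isfinite(vals)]))


def _site_stats(gm: GenotypeMatrix, site_id: str):
    """Per-SNP (n genotyped, alt freq, observed het fraction) within a site."""
    g = gm.genotypes[gm.site_mask(site_id)]
    called = g != MISSING
    n = called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, np.where(called, g, 0).sum(axis=0) / (2 * np.maximum(n, 1)), np.nan)
        het = np.where(n > 0, (g == 1).sum(axis=0) / np.maximum(n, 1), np.nan)
    return n, p, het


def site_diversity(gm: GenotypeMatrix, assayed_length: float) -> pd.DataFrame:
    """Ho, He (unbiased, 2n/(2n-1) factor), nucleotide diversity pi over the
    given assayed length (bp), and private-allele counts, one row per site.

    pi here is the sum over SNPs of unbiased expected heterozygosity divided
    by the total length assayed, mimicking RAD-style estimates where most
    assayed positions are invariant.
    """
    if assayed_length <= 0:
        raise ValueError("assayed_length must be positive")
    site_ids = gm.site_ids
    # allele presence per site for private-allele counting
    presence = {}  # site -> (ref present, alt present) boolean arrays
    for sid in site_ids:
        g = gm.genotypes[gm.site_mask(sid)]
        called = g != MISSING
        alt = np.where(called, g, 0).sum(axis=0)
        tot = 2 * called.sum(axis=0)
        presence[sid] = (alt < tot, alt > 0)  # ref seen, alt seen

    rows = []
    for sid in site_ids:
        n, p, het = _site_stats(gm, sid)
        ok = n > 0
        with np.errstate(invalid="ignore"):
            he = (2 * n[ok] / (2 * n[ok] - 1)) * 2 * p[ok] * (1 - p[ok])
        ho = float(np.mean(het[ok])) if ok.any() else 0.0
        he_mean = float(np.mean(he)) if ok.any() else 0.0
        pi = float(np.sum(he)) / assayed_length

        private = 0
        for allele in (0, 1):
            here = presence[sid][allele]
            elsewhere = np.zeros(gm.n_snp, dtype=bool)
            for other in site_ids:
                if other != sid:
                    elsewhere |= presence[other][allele]
            private += int(np.sum(here & ~elsewhere))

        rows.append(
            dict(site_id=sid, n=int(gm.site_mask(sid).sum()), ho=ho, he=he_mean,
                 pi=pi, private_alleles=private, assayed_length=assayed_length)
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Weir & Cockerham (1984) theta, two populations, multi-locus ratio of sums
# ---------------------------------------------------------------------------

def wc_components(n: np.ndarray, p: np.ndarray, het: np.ndarray):
    """Per-locus variance components (a, b, c) for r populations.

    n, p, het: (r, L) arrays of sample sizes (diploids), alt-allele
    frequencies, and observed heterozygote fractions.
    """
    r = n.shape[0]
    nbar = n.mean(axis=0)
    ssum = n.sum(axis=0)
    nc = (ssum - (n**2).sum(axis=0) / ssum) / (r - 1)
    pbar = (n * p).sum(axis=0) / ssum
    s2 = (n * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    hbar = (n * het).sum(axis=0) / ssum

    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return a, b, c


def pairwise_fst_wc(gm: GenotypeMatrix) -> PairwiseMatrix:
    """Pairwise multi-locus Weir-Cockerham theta between all site pairs.

    Ratio of sums across loci: theta = sum(a) / sum(a+b+c). Loci monomorphic
    within a pair, or with fewer than two genotyped diploids on either side,
    are skipped for that pair. Negative theta is reported as computed.
    """
    site_ids = gm.site_ids
    if len(site_ids) < 2:
        raise ValueError("need at least two sites")
    stats = {sid: _site_stats(gm, sid) for sid in site_ids}
    k = len(site_ids)
    theta = np.zeros((k, k))
    used = np.zeros((k, k), dtype=int)
    for i in range(k):
        for j in range(i + 1, k):
            n1, p1, h1 = stats[site_ids[i]]
            n2, p2, h2 = stats[site_ids[j]]
            ok = (n1 >= 2) & (n2 >= 2)
            # skip loci monomorphic across the pooled pair
            pool = (n1 * p1 + n2 * p2) / np.maximum(n1 + n2, 1)
            ok &= (pool > 0) & (pool < 1)
            if not ok.any():
                theta[i, j] = theta[j, i] = np.nan
                continue
            n = np.vstack([n1[ok], n2[ok]]).astype(float)
            p = np.vstack([p1[ok], p2[ok]])
            h = np.vstack([h1[ok], h2[ok]])
            a, b, c = wc_components(n, p, h)
            denom = (a + b + c).sum()
            theta[i, j] = theta[j, i] = a.sum() / denom if denom != 0 else np.nan
            used[i, j] = used[j, i] = int(ok.sum())
    return PairwiseMatrix("fst", site_ids, theta, used)


def multilocus_fst_wc(gm: GenotypeMatrix) -> float:
    """Global multi-locus Weir-Cockerham theta across all sites."""
    site_ids = gm.site_ids
    stats = [_site_stats(gm, sid) for sid in site_ids]
    n = np.vstack([s[0] for s in stats]).astype(float)
    p = np.vstack([s[1] for s in stats])
    h = np.vstack([s[2] for s in stats])
    ok = (n >= 2).all(axis=0)
    pool = (n * p).sum(axis=0) / n.sum(axis=0)
    ok &= (pool > 0) & (pool < 1)
    a, b, c = wc_components(n[:, ok], p[:, ok], h[:, ok])
    return float(a.sum() / (a + b + c).sum())


# ---------------------------------------------------------------------------
# Nei (1972) standard genetic distance
# ---------------------------------------------------------------------------

def nei_distance_matrix(gm: GenotypeMatrix) -> PairwiseMatrix:
    """Nei standard distance D = -ln(I), I = Jxy / sqrt(Jx Jy), with Jx, Jy,
    Jxy averaged over loci (biallelic: J = p^2 + q^2, Jxy = px py + qx qy)."""
    site_ids = gm.site_ids
    if len(site_ids) < 2:
        raise ValueError("need at least two sites")
    freqs = {sid: _site_stats(gm, sid) for sid in site_ids}
    k = len(site_ids)
    d = np.zeros((k, k))
    used = np.zeros((k, k), dtype=int)
    for i in range(k):
        for j in range(i + 1, k):
            n1, p1, _ = freqs[site_ids[i]]
            n2, p2, _ = freqs[site_ids[j]]
            ok = (n1 > 0) & (n2 > 0)
            if not ok.any():
                d[i, j] = d[j, i] = np.nan
                continue
            px, py = p1[ok], p2[ok]
            jx = np.mean(px**2 + (1 - px) ** 2)
            jy = np.mean(py**2 + (1 - py) ** 2)
            jxy = np.mean(px * py + (1 - px) * (1 - py))
            identity = jxy / np.sqrt(jx * jy)
            d[i, j] = d[j, i] = -np.log(identity) if identity > 0 else np.inf
            used[i, j] = used[j, i] = int(ok.sum())
    return PairwiseMatrix("nei_d", site_ids, d, used)


def nei_identity(px: np.ndarray, py: np.ndarray) -> float:
    """Normalized genetic identity I for two frequency vectors (alt freq per
    locus); exposed for direct evaluation in analyses and tests."""
    px, py = np.atleast_1d(px), np.atleast_1d(py)
    jx = np.mean(px**2 + (1 - px) ** 2)
    jy = np.mean(py**2 + (1 - py) ** 2)
    jxy = np.mean(px * py + (1 - px) * (1 - py))
    return float(jxy / np.sqrt(jx * jy))


def summarize_column(values, stats=("mean", "median", "min", "max"), ndigits: int | None = None) -> dict:
    """Mean/median/min/max of a column of printed or computed values."""
    vals = np.asarray([v for v in np.asarray(values, dtype=float) if np.isfinite(v)])
    if vals.size == 0:
        raise ValueError("no finite values to summarize")
    funcs = {"mean": np.mean, "median": np.median, "min": np.min, "max": np.max}
    out = {}
    for s in stats:
        v = float(funcs[s](vals))
        out[s] = round(v, ndigits) if ndigits is not None else v
    return out


__all__ = [
    "PairwiseMatrix",
    "multilocus_fst_wc",
    "nei_distance_matrix",
    "nei_identity",
    "pairwise_fst_wc",
    "site_diversity",
    "summarize_column",
    "wc_components",
]
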