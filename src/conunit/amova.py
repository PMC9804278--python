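"""Hierarchical AMOVA over individuals nested in sites nested in groups.

Sums of squares are computed from pairwise squared Euclidean distances
between individual genotype vectors (missing entries mean-imputed per SNP
after a missingness prune) and partitioned into among-groups, among-sites-
within-groups and within-sites strata; variance components follow the
standard nested ANOVA coefficients for unbalanced designs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from conunit.genotypes import MISSING, GenotypeMatrix


@dataclass
class Grouping:
    name: str
    assignment: dict[str, str]  # site_id -> group label

    def __post_init__(self) -> None:
        if len(set(self.assignment.values())) < 2:
            raise ValueError(f"grouping {self.name}: need >= 2 groups")

    @property
    def n_groups(self) -> int:
        return len(set(self.assignment.values()))


@dataclass
class AmovaResult:
    grouping: str
    n_groups: int
    components: dict[str, float]  # among_groups, among_sites, within_sites
    percentages: dict[str, float]
    sums_of_squares: dict[str, float] = field(default_factory=dict)
    df: dict[str, int] = field(default_factory=dict)
    degenerate: bool = False
    negative_components: bool = False


def _impute_mean(g: np.ndarray) -> np.ndarray:
    x = g.astype(float)
    x[x == MISSING] = np.nan
    mu = np.nanmean(x, axis=0)
    idx = np.where(np.isnan(x))
    x[idx] = np.take(mu, idx[1])
    return x


def prune_missingness(gm: GenotypeMatrix, max_missing: float = 0.05) -> GenotypeMatrix:
    miss = 1.0 - gm.called().mean(axis=0)
    return gm.take_snps(miss < max_missing)


def run_amova(
    gm: GenotypeMatrix, grouping: Grouping, max_missing: float = 0.05
) -> AmovaResult:
    """Three-level AMOVA of the genotype data under one site grouping."""
    gm = prune_missingness(gm, max_missing)
    if gm.n_snp == 0:
        raise ValueError("no SNPs left after missingness prune")
    x = _impute_mean(gm.genotypes)
    site_of = gm.ind_meta["site_id"].to_numpy()
    missing_sites = set(site_of) - set(grouping.assignment)
    if missing_sites:
        raise ValueError(f"grouping {grouping.name} missing sites: {sorted(missing_sites)}")
    group_of = np.array([grouping.assignment[s] for s in site_of])

    d2 = _sq_euclidean(x)
    n_tot = len(x)
    sites = list(dict.fromkeys(site_of))
    groups = list(dict.fromkeys(group_of))
    n_site = {s: int((site_of == s).sum()) for s in sites}
    n_group = {g: int((group_of == g).sum()) for g in groups}
    p, g_cnt = len(sites), len(groups)
    if g_cnt < 2:
        raise ValueError("need >= 2 groups present in the data")

    def ss_within(labels: np.ndarray, sizes: dict) -> float:
        total = 0.0
        for lab, n in sizes.items():
            m = labels == lab
            total += d2[np.ix_(m, m)].sum() / (2.0 * n)
        return total

    ss_total = d2.sum() / (2.0 * n_tot)
    ss_wp = ss_within(site_of, n_site)  # within sites
    ss_wg = ss_within(group_of, n_group)  # within groups (sites pooled)
    ss_ap = ss_wg - ss_wp  # among sites within groups
    ss_ag = ss_total - ss_wg  # among groups

    df_ag, df_ap, df_wp = g_cnt - 1, p - g_cnt, n_tot - p
    sums = dict(among_groups=ss_ag, among_sites=ss_ap, within_sites=ss_wp)
    dfs = dict(among_groups=df_ag, among_sites=df_ap, within_sites=df_wp)

    if ss_total <= 1e-12:
        comps = dict(among_groups=0.0, among_sites=0.0, within_sites=0.0)
        return AmovaResult(grouping.name, g_cnt, comps,
                           dict.fromkeys(comps, 0.0), sums, dfs, degenerate=True)

    # unbalanced-design coefficients for the nested expected mean squares
    sum_nsq_by_group = {
        g: sum(n_site[s] ** 2 for s in sites if grouping.assignment[s] == g)
        for g in groups
    }
    n_prime = (
        (n_tot - sum(sum_nsq_by_group[g] / n_group[g] for g in groups)) / df_ap
        if df_ap > 0 else 0.0
    )
    n_dprime = (
        sum(sum_nsq_by_group[g] / n_group[g] for g in groups)
        - sum(n_site[s] ** 2 for s in sites) / n_tot
    ) / df_ag
    n_tprime = (n_tot - sum(n_group[g] ** 2 for g in groups) / n_tot) / df_ag

    ms_wp = ss_wp / df_wp if df_wp > 0 else 0.0
    sigma_c = ms_wp
    if df_ap > 0 and n_prime > 0:
        sigma_b = (ss_ap / df_ap - sigma_c) / n_prime
    else:
        sigma_b = 0.0
    sigma_a = (ss_ag / df_ag - sigma_c - n_dprime * sigma_b) / n_tprime

    comps = dict(among_groups=sigma_a, among_sites=sigma_b, within_sites=sigma_c)
    total = sum(comps.values())
    pct = {k: 100.0 * v / total for k, v in comps.items()}
    return AmovaResult(
        grouping.name, g_cnt, comps, pct, sums, dfs,
        negative_components=any(v < 0 for v in comps.values()),
    )


def _sq_euclidean(x: np.ndarray) -> np.ndarray:
    sq = (x**2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * x @ x.T
    np.fill_diagonal(d2, 0.0)
    return np.maximum(d2, 0.0)


def compare_groupings(
    gm: GenotypeMatrix, groupings: list[Grouping], max_missing: float = 0.05
) -> pd.DataFrame:
    """AMOVA per grouping, ranked by among-groups percentage (descending).
    The group count is reported alongside as a parsimony caveat: many tiny
    groups can buy variance explained at the cost of singleton units."""
    if len(groupings) < 2:
        raise ValueError("need >= 2 groupings")
    if len({g.name for g in groupings}) != len(groupings):
        raise ValueError("duplicate grouping names")
    rows = []
    for grp in groupings:
        res = run_amova(gm, grp, max_missing)
        rows.append(
            dict(grouping=grp.name, n_groups=res.n_groups,
                 pct_among_groups=res.percentages["among_groups"],
                 pct_among_sites=res.percentages["among_sites"],
                 pct_within_sites=res.percentages["within_sites"],
                 degenerate=res.degenerate)
        )
    return (
        pd.DataFrame(rows)
        .sort_values("pct_among_groups", ascending=False, kind="stable")
        .reset_index(drop=True)
    )


__all__ = ["AmovaResult", "Grouping", "compare_groupings", "prune_missingness", "run_amova"]
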