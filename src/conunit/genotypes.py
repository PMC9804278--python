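"""Genotype container, VCF I/O and the post-assembly SNP filter cascade.

Genotypes are stored as an individuals x SNPs int8 matrix of alternate-allele
counts (0/1/2) with -1 for missing calls. SNP metadata tracks the RAD locus
each SNP came from so locus-level filters (SNPs-per-locus, one-SNP-per-locus)
can operate; sample metadata binds each individual to a sampling site.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln

logger = logging.getLogger(__name__)

MISSING = -1


@dataclass
class SampleMetadata:
    """One sampling site: four-letter code, projected coordinates (m),
    geographic region, watershed, and current management-unit label."""

    site_id: str
    easting: float = np.nan
    northing: float = np.nan
    region: str = ""
    watershed: str = ""
    mu_label: str = ""


@dataclass
class GenotypeMatrix:
    """individuals x SNPs alternate-allele counts with per-axis metadata.

    ``snp_meta`` columns: snp_id, locus_id, pos (1-based position within the
    locus), ref, alt, mean_depth. ``ind_meta`` columns: ind_id, site_id.
    """

    genotypes: np.ndarray
    snp_meta: pd.DataFrame
    ind_meta: pd.DataFrame
    sites: dict[str, SampleMetadata] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be individuals x SNPs")
        bad = ~np.isin(self.genotypes, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValueError("genotype codes must be in {0,1,2,-1}")
        if len(self.snp_meta) != self.genotypes.shape[1]:
            raise ValueError("snp_meta length mismatch")
        if len(self.ind_meta) != self.genotypes.shape[0]:
            raise ValueError("ind_meta length mismatch")
        if self.snp_meta["snp_id"].duplicated().any():
            raise ValueError("SNP ids must be unique")
        unknown = set(self.ind_meta["site_id"]) - set(self.sites)
        if self.sites and unknown:
            raise ValueError(f"individuals reference unknown sites: {sorted(unknown)}")

    # ---- basic views -------------------------------------------------

    @property
    def n_ind(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snp(self) -> int:
        return self.genotypes.shape[1]

    @property
    def site_ids(self) -> list[str]:
        """Site labels in first-appearance order."""
        return list(dict.fromkeys(self.ind_meta["site_id"]))

    def site_mask(self, site_id: str) -> np.ndarray:
        return (self.ind_meta["site_id"] == site_id).to_numpy()

    def called(self) -> np.ndarray:
        return self.genotypes != MISSING

    def allele_counts(self, mask: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
        """(alt allele count, total called alleles) per SNP, optionally over a
        subset of individuals."""
        g = self.genotypes if mask is None else self.genotypes[mask]
        called = g != MISSING
        alt = np.where(called, g, 0).sum(axis=0)
        return alt, 2 * called.sum(axis=0)

    def allele_freq(self, mask: np.ndarray | None = None) -> np.ndarray:
        alt, tot = self.allele_counts(mask)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, alt / np.maximum(tot, 1), np.nan)

    def minor_allele_count(self) -> np.ndarray:
        alt, tot = self.allele_counts()
        return np.minimum(alt, tot - alt)

    def take_snps(self, keep: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(keep)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            self.genotypes[:, idx],
            self.snp_meta.iloc[idx].reset_index(drop=True),
            self.ind_meta.copy(),
            self.sites,
        )

    def take_inds(self, keep: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(keep)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            self.genotypes[idx],
            self.snp_meta.copy(),
            self.ind_meta.iloc[idx].reset_index(drop=True),
            self.sites,
        )


def read_sites_csv(path: str | Path) -> dict[str, SampleMetadata]:
    """site_id, x, y, region, watershed, mu_label (extra columns ignored)."""
    df = pd.read_csv(path)
    out = {}
    for _, row in df.iterrows():
        out[str(row["site_id"])] = SampleMetadata(
            site_id=str(row["site_id"]),
            easting=float(row.get("x", np.nan)),
            northing=float(row.get("y", np.nan)),
            region=str(row.get("region", "")),
            watershed=str(row.get("watershed", "")),
            mu_label=str(row.get("mu_label", "")),
        )
    return out


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

def read_vcf(
    path: str | Path,
    sites: dict[str, SampleMetadata] | None = None,
    site_of_ind: dict[str, str] | None = None,
) -> GenotypeMatrix:
    """Load diploid biallelic SNPs from a VCF.

    Multi-allelic records are skipped (count logged). Sample-to-site binding
    comes from ``site_of_ind``; by default the site code is taken as the part
    of the sample name before the first underscore.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"{path}: VCF contains no samples")
    rows, meta = [], []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        # gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
        gt = var.gt_types.astype(np.int8)
        codes = np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2], default=MISSING)
        rows.append(codes)
        try:
            depth = var.format("DP")
        except KeyError:
            depth = None
        if depth is not None:
            d = depth.astype(float).ravel()
            mean_depth = float(np.nanmean(np.where(d < 0, np.nan, d)))
        else:
            mean_depth = np.nan
        meta.append(
            dict(
                snp_id=var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}",
                locus_id=str(var.CHROM),
                pos=int(var.POS),
                ref=var.REF,
                alt=var.ALT[0],
                mean_depth=mean_depth,
            )
        )
    if n_multi:
        logger.info("read_vcf: skipped %d multi-allelic records", n_multi)
    if not rows:
        raise ValueError(f"{path}: no biallelic SNP records")
    genotypes = np.vstack(rows).T.astype(np.int8)
    if site_of_ind is None:
        site_of_ind = {s: s.split("_")[0] for s in samples}
    ind_meta = pd.DataFrame(
        {"ind_id": samples, "site_id": [site_of_ind[s] for s in samples]}
    )
    if sites is None:
        sites = {sid: SampleMetadata(site_id=sid) for sid in ind_meta["site_id"].unique()}
    return GenotypeMatrix(genotypes, pd.DataFrame(meta), ind_meta, sites)


def write_vcf(gm: GenotypeMatrix, path: str | Path, depths: np.ndarray | None = None) -> None:
    """Emit VCFv4.2 with GT (and DP when ``depths`` given, individuals x SNPs)."""
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    contigs = list(dict.fromkeys(gm.snp_meta["locus_id"]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=conunit\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if depths is not None:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        cols = "\t".join(gm.ind_meta["ind_id"])
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{cols}\n")
        fmt = "GT:DP" if depths is not None else "GT"
        for j in range(gm.n_snp):
            m = gm.snp_meta.iloc[j]
            if depths is not None:
                calls = "\t".join(
                    f"{gt_str[int(g)]}:{int(depths[i, j])}"
                    for i, g in enumerate(gm.genotypes[:, j])
                )
            else:
                calls = "\t".join(gt_str[int(g)] for g in gm.genotypes[:, j])
            fh.write(
                f"{m.locus_id}\t{m.pos}\t{m.snp_id}\t{m.ref}\t{m.alt}\t.\tPASS\t.\t{fmt}\t{calls}\n"
            )


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_pvalue(n_het: int, n_hom_ref: int, n_hom_alt: int) -> float:
    """Two-sided exact test on the heterozygote count (full enumeration of
    heterozygote counts conditional on allele counts; no mid-p)."""
    n = n_het + n_hom_ref + n_hom_alt
    if n == 0:
        return 1.0
    n_a = 2 * n_hom_ref + n_het  # reference-allele count
    n_b = 2 * n - n_a
    n_minor = min(n_a, n_b)
    # heterozygote count shares parity with the minor allele count
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    hom_minor = (n_minor - hets) // 2
    hom_major = n - hets - hom_minor
    logp = (
        gammaln(n + 1)
        - gammaln(hets + 1)
        - gammaln(hom_minor + 1)
        - gammaln(hom_major + 1)
        + hets * np.log(2.0)
        + gammaln(n_a + 1)
        + gammaln(n_b + 1)
        - gammaln(2 * n + 1)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    p_obs = probs[hets == n_het][0]
    return float(probs[probs <= p_obs * (1 + 1e-12)].sum())


# ---------------------------------------------------------------------------
# Filter cascade
# ---------------------------------------------------------------------------

@dataclass
class FilterConfig:
    max_ind_missing: float = 0.55
    min_global_mac: int = 10  # "MAC > 9"
    depth_range: tuple[float, float] = (6.0, 100.0)
    min_locus_call_rate: float = 0.80
    max_snps_per_locus: int = 7
    hwe_alpha: float = 0.05
    hwe_min_sites: int = 5
    hwe_site_min_n: int = 10
    allhet_site_min_n: int = 7
    min_variable_sites_rda: int = 3
    require_all_sites: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.max_ind_missing < 1:
            raise ValueError("max_ind_missing must be in (0,1)")
        if not 0 < self.min_locus_call_rate < 1:
            raise ValueError("min_locus_call_rate must be in (0,1)")
        for name in ("min_global_mac", "max_snps_per_locus", "hwe_min_sites",
                     "hwe_site_min_n", "allhet_site_min_n", "min_variable_sites_rda"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


@dataclass
class FilterReport:
    steps: list[dict] = field(default_factory=list)

    def add(self, name: str, snps_removed: int, inds_removed: int,
            snps_left: int, inds_left: int) -> None:
        self.steps.append(
            dict(step=name, snps_removed=int(snps_removed),
                 inds_removed=int(inds_removed), snps_remaining=int(snps_left),
                 inds_remaining=int(inds_left))
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.steps, indent=2))

    def __str__(self) -> str:
        lines = [f"{'step':<24}{'-SNPs':>8}{'-inds':>8}{'SNPs':>8}{'inds':>8}"]
        for s in self.steps:
            lines.append(
                f"{s['step']:<24}{s['snps_removed']:>8}{s['inds_removed']:>8}"
                f"{s['snps_remaining']:>8}{s['inds_remaining']:>8}"
            )
        return "\n".join(lines)


def _check_nonempty(gm: GenotypeMatrix, step: str) -> None:
    if gm.n_snp == 0 or gm.n_ind == 0:
        raise ValueError(f"filter step '{step}' removed everything")


def apply_filter_cascade(
    gm: GenotypeMatrix, cfg: FilterConfig | None = None
) -> tuple[GenotypeMatrix, FilterReport]:
    """Run the post-assembly SNP filter cascade in its fixed order.

    Steps: high-missingness individuals; common-across-sites screen; global
    minor-allele-count; mean-depth window; per-SNP call rate; SNPs-per-locus
    ceiling; one SNP per locus (highest MAC, lowest in-locus position on
    ties); site-wise Hardy-Weinberg screen; all-heterozygote paralog screen.
    """
    cfg = cfg or FilterConfig()
    report = FilterReport()

    # (1) individuals with excessive missingness
    miss = 1.0 - gm.called().mean(axis=1)
    keep_ind = miss <= cfg.max_ind_missing
    out = gm.take_inds(keep_ind)
    report.add("ind_missingness", 0, (~keep_ind).sum(), out.n_snp, out.n_ind)
    _check_nonempty(out, "ind_missingness")

    # (1b) SNP present (>=1 call) in every site
    if cfg.require_all_sites:
        site_ids = out.site_ids
        present = np.ones(out.n_snp, dtype=bool)
        for sid in site_ids:
            present &= out.called()[out.site_mask(sid)].any(axis=0)
        out = out.take_snps(present)
        report.add("common_across_sites", (~present).sum(), 0, out.n_snp, out.n_ind)
        _check_nonempty(out, "common_across_sites")

    # (2) global minor allele count
    keep = out.minor_allele_count() >= cfg.min_global_mac
    out = out.take_snps(keep)
    report.add("global_mac", (~keep).sum(), 0, out.n_snp, out.n_ind)
    _check_nonempty(out, "global_mac")

    # (3) mean depth window (inclusive); SNPs without depth info pass
    depth = out.snp_meta["mean_depth"].to_numpy(float)
    lo, hi = cfg.depth_range
    keep = np.isnan(depth) | ((depth >= lo) & (depth <= hi))
    out = out.take_snps(keep)
    report.add("mean_depth", (~keep).sum(), 0, out.n_snp, out.n_ind)
    _check_nonempty(out, "mean_depth")

    # (4) per-SNP call rate
    keep = out.called().mean(axis=0) >= cfg.min_locus_call_rate
    out = out.take_snps(keep)
    report.add("call_rate", (~keep).sum(), 0, out.n_snp, out.n_ind)
    _check_nonempty(out, "call_rate")

    # (5) loci carrying too many SNPs are dropped whole
    counts = out.snp_meta.groupby("locus_id")["snp_id"].transform("size")
    keep = (counts <= cfg.max_snps_per_locus).to_numpy()
    out = out.take_snps(keep)
    report.add("snps_per_locus", (~keep).sum(), 0, out.n_snp, out.n_ind)
    _check_nonempty(out, "snps_per_locus")

    # (6) one SNP per locus: highest MAC, ties to smallest in-locus position
    mac = out.minor_allele_count()
    order = pd.DataFrame(
        {"locus": out.snp_meta["locus_id"], "mac": mac, "pos": out.snp_meta["pos"]}
    )
    best = (
        order.sort_values(["mac", "pos"], ascending=[False, True], kind="stable")
        .groupby("locus", sort=False)
        .head(1)
        .index.to_numpy()
    )
    keep = np.zeros(out.n_snp, dtype=bool)
    keep[best] = True
    out = out.take_snps(keep)
    report.add("one_snp_per_locus", (~keep).sum(), 0, out.n_snp, out.n_ind)
    _check_nonempty(out, "one_snp_per_locus")

    # (7) Hardy-Weinberg screen across sites
    big_sites = [s for s in out.site_ids if out.site_mask(s).sum() >= cfg.hwe_site_min_n]
    n_fail = np.zeros(out.n_snp, dtype=int)
    for sid in big_sites:
        g = out.genotypes[out.site_mask(sid)]
        for j in range(out.n_snp):
            col = g[:, j]
            col = col[col != MISSING]
            if col.size == 0:
                continue
            p = hwe_exact_pvalue(
                int((col == 1).sum()), int((col == 0).sum()), int((col == 2).sum())
            )
            if p < cfg.hwe_alpha:
                n_fail[j] += 1
    keep = n_fail < cfg.hwe_min_sites
    out = out.take_snps(keep)
    report.add("hwe", (~keep).sum(), 0, out.n_snp, out.n_ind)
    _check_nonempty(out, "hwe")

    # (8) all-heterozygote paralog screen
    drop = np.zeros(out.n_snp, dtype=bool)
    for sid in out.site_ids:
        g = out.genotypes[out.site_mask(sid)]
        called = g != MISSING
        n_called = called.sum(axis=0)
        n_het = (g == 1).sum(axis=0)
        drop |= (n_called >= cfg.allhet_site_min_n) & (n_het == n_called)
    out = out.take_snps(~drop)
    report.add("all_het_paralog", drop.sum(), 0, out.n_snp, out.n_ind)
    _check_nonempty(out, "all_het_paralog")

    return out, report


def select_rda_loci(gm: GenotypeMatrix, cfg: FilterConfig | None = None) -> GenotypeMatrix:
    """Keep SNPs polymorphic (both alleles called) in at least
    ``min_variable_sites_rda`` sites — the low-frequency screen applied before
    genotype-environment association."""
    cfg = cfg or FilterConfig()
    site_ids = gm.site_ids
    if len(site_ids) < cfg.min_variable_sites_rda:
        raise ValueError("fewer sites than min_variable_sites_rda")
    n_var = np.zeros(gm.n_snp, dtype=int)
    for sid in site_ids:
        g = gm.genotypes[gm.site_mask(sid)]
        called = g != MISSING
        alt = np.where(called, g, 0).sum(axis=0)
        tot = 2 * called.sum(axis=0)
        n_var += (alt > 0) & (alt < tot)
    out = gm.take_snps(n_var >= cfg.min_variable_sites_rda)
    _check_nonempty(out, "rda_variable_sites")
    return out


__all__ = [
    "MISSING",
    "FilterConfig",
    "FilterReport",
    "GenotypeMatrix",
    "SampleMetadata",
    "apply_filter_cascade",
    "hwe_exact_pvalue",
    "read_sites_csv",
    "read_vcf",
    "select_rda_loci",
    "write_vcf",
]
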