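"""Genotype container, VCF I/O, HWE exact test and the filter cascade."""

import numpy as np
import pytest

from conunit.genotypes import (
    MISSING,
    FilterConfig,
    apply_filter_cascade,
    hwe_exact_pvalue,
    read_vcf,
    select_rda_loci,
    write_vcf,
)


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

VCF_SMALL = """##fileformat=VCFv4.2
##contig=<ID=loc1>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA_01\tA_02
loc1\t10\ts1\tA\tT\t.\tPASS\t.\tGT\t0/1\t1/1
loc1\t20\ts2\tA\tT\t.\tPASS\t.\tGT\t./.\t0/0
loc1\t30\ts3\tA\tT,G\t.\tPASS\t.\tGT\t0/1\t1/2
"""


def test_read_vcf_encoding_missing_and_multiallelic(tmp_path):
    """0/1 -> 1, 1/1 -> 2, ./. -> missing; triallelic rows excluded."""
    path = tmp_path / "small.vcf"
    path.write_text(VCF_SMALL)
    gm = read_vcf(path)
    assert gm.n_snp == 2  # triallelic s3 dropped
    assert list(gm.genotypes[:, 0]) == [1, 2]
    assert gm.genotypes[0, 1] == MISSING and gm.genotypes[1, 1] == 0
    assert list(gm.ind_meta["site_id"]) == ["A", "A"]


def test_vcf_roundtrip(tmp_path, small_sim):
    _, gm, _ = small_sim
    path = tmp_path / "roundtrip.vcf"
    write_vcf(gm, path)
    back = read_vcf(path)
    assert back.n_ind == gm.n_ind and back.n_snp == gm.n_snp
    np.testing.assert_array_equal(back.genotypes, gm.genotypes)
    assert list(back.snp_meta["locus_id"]) == list(gm.snp_meta["locus_id"])


# ---------------------------------------------------------------------------
# HWE exact test
# ---------------------------------------------------------------------------

def _hwe_monte_carlo(n_het, n_hom_ref, n_hom_alt, n_draws=40000, seed=0):
    """Independent oracle: permute the observed alleles into random diploid
    pairings and read off the two-sided tail probability of the het count."""
    rng = np.random.default_rng(seed)
    n = n_het + n_hom_ref + n_hom_alt
    alleles = np.array([0] * (2 * n_hom_ref + n_het) + [1] * (2 * n_hom_alt + n_het))
    het_counts = np.empty(n_draws, dtype=int)
    for d in range(n_draws):
        rng.shuffle(alleles)
        het_counts[d] = int((alleles[0::2] != alleles[1::2]).sum())
    vals, counts = np.unique(het_counts, return_counts=True)
    probs = dict(zip(vals, counts / n_draws))
    p_obs = probs.get(n_het, 0.0)
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-9))


@pytest.mark.parametrize(
    "het,hom_ref,hom_alt",
    [(5, 3, 2), (0, 5, 5), (10, 0, 0), (2, 8, 1), (7, 6, 7)],
)
def test_hwe_exact_matches_permutation_oracle(het, hom_ref, hom_alt):
    p = hwe_exact_pvalue(het, hom_ref, hom_alt)
    p_mc = _hwe_monte_carlo(het, hom_ref, hom_alt)
    assert p == pytest.approx(p_mc, abs=0.02)


def test_hwe_ideal_proportions_pass():
    """25/50/25 genotype counts are the textbook equilibrium: p ~ 1."""
    assert hwe_exact_pvalue(50, 25, 25) > 0.5


# ---------------------------------------------------------------------------
# Filter cascade
# ---------------------------------------------------------------------------

def _cascade_cfg(**over):
    # disable the site-count-gated screens unless a test opts in
    base = dict(hwe_site_min_n=50, allhet_site_min_n=50, require_all_sites=False)
    base.update(over)
    return FilterConfig(**base)


def test_global_mac_boundary(make_gm):
    """Minor allele count 9 is removed, 10 retained (MAC > 9 rule)."""
    n = 40
    col_mac9 = np.array([1] * 9 + [0] * (n - 9))
    col_mac10 = np.array([1] * 10 + [0] * (n - 10))
    col_common = np.array([1] * 20 + [0] * (n - 20))
    g = np.column_stack([col_mac9, col_mac10, col_common])
    gm = make_gm(g, ["X"] * (n // 2) + ["Y"] * (n // 2),
                 locus_ids=["l0", "l1", "l2"])
    out, report = apply_filter_cascade(gm, _cascade_cfg())
    kept = set(out.snp_meta["locus_id"])
    assert "l0" not in kept and "l1" in kept and "l2" in kept
    steps = {s["step"]: s for s in report.steps}
    assert steps["global_mac"]["snps_removed"] == 1


def test_high_missingness_individual_removed(make_gm):
    g = np.tile([0, 1, 2, 0, 1] * 4, (10, 1))
    g[0, :12] = MISSING  # 60% missing
    gm = make_gm(g, ["X"] * 5 + ["Y"] * 5)
    out, report = apply_filter_cascade(
        gm, _cascade_cfg(min_global_mac=1, min_locus_call_rate=0.05))
    assert out.n_ind == 9
    assert report.steps[0]["inds_removed"] == 1


def test_all_heterozygote_site_removed(make_gm):
    """A SNP heterozygous in all 7 genotyped individuals of one site is a
    paralog signature and is dropped."""
    rng = np.random.default_rng(0)
    g = rng.integers(0, 3, size=(14, 10))
    g[:7, 0] = 1  # site X: everyone het at SNP 0
    gm = make_gm(g, ["X"] * 7 + ["Y"] * 7)
    out, report = apply_filter_cascade(
        gm, _cascade_cfg(min_global_mac=1, allhet_site_min_n=7))
    assert "snp0" not in set(out.snp_meta["snp_id"])
    steps = {s["step"]: s for s in report.steps}
    assert steps["all_het_paralog"]["snps_removed"] >= 1


def test_locus_with_too_many_snps_dropped_whole(make_gm):
    rng = np.random.default_rng(1)
    n_ind = 40
    g = rng.integers(0, 3, size=(n_ind, 10))
    loci = ["big"] * 8 + ["ok", "ok2"]
    gm = make_gm(g, ["X"] * 20 + ["Y"] * 20, locus_ids=loci)
    out, _ = apply_filter_cascade(gm, _cascade_cfg(min_global_mac=1))
    assert "big" not in set(out.snp_meta["locus_id"])
    assert {"ok", "ok2"} <= set(out.snp_meta["locus_id"])


def test_one_snp_per_locus_keeps_highest_mac(make_gm):
    n = 40
    low = np.array([1] * 12 + [0] * (n - 12))
    high = np.array([1] * 20 + [0] * (n - 20))
    g = np.column_stack([low, high])
    gm = make_gm(g, ["X"] * 20 + ["Y"] * 20, locus_ids=["L", "L"], pos=[10, 60])
    out, _ = apply_filter_cascade(gm, _cascade_cfg())
    assert out.n_snp == 1
    assert out.snp_meta["pos"].iloc[0] == 60  # the higher-MAC SNP


def test_cascade_idempotent(small_sim):
    _, gm, _ = small_sim
    cfg = FilterConfig(min_global_mac=2, hwe_site_min_n=8, allhet_site_min_n=7)
    once, _ = apply_filter_cascade(gm, cfg)
    twice, rep2 = apply_filter_cascade(once, cfg)
    assert twice.n_snp == once.n_snp and twice.n_ind == once.n_ind
    assert all(s["snps_removed"] == 0 and s["inds_removed"] == 0 for s in rep2.steps)


def test_report_totals_reconcile(small_sim):
    _, gm, _ = small_sim
    cfg = FilterConfig(min_global_mac=2, hwe_site_min_n=8)
    out, report = apply_filter_cascade(gm, cfg)
    total_removed = sum(s["snps_removed"] for s in report.steps)
    assert total_removed + out.n_snp == gm.n_snp


def test_empty_output_names_step(make_gm):
    g = np.full((10, 2), 2, dtype=np.int8)  # fixed for alt: MAC 0
    gm = make_gm(g, ["X"] * 5 + ["Y"] * 5)
    with pytest.raises(ValueError, match="global_mac"):
        apply_filter_cascade(gm, _cascade_cfg())


def test_select_rda_loci_variable_site_boundary(make_gm):
    """Variable in 2 sites -> removed; variable in 3 sites -> retained."""
    sites = ["A"] * 4 + ["B"] * 4 + ["C"] * 4 + ["D"] * 4
    var2 = np.array([0, 1, 0, 0] + [1, 0, 0, 0] + [0] * 8)
    var3 = np.array([0, 1, 0, 0] + [1, 0, 0, 0] + [0, 1, 0, 0] + [0] * 4)
    mono = np.zeros(16, dtype=int)
    gm = make_gm(np.column_stack([var2, var3, mono]), sites)
    out = select_rda_loci(gm, FilterConfig())
    assert list(out.snp_meta["snp_id"]) == ["snp1"]
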