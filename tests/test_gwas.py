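"""Scan, FDR, region clumping, focus selection, fine-mapping."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import landhap as lh
from landhap.gwas import (
    association_scan,
    bh_fdr,
    define_regions,
    fine_map_region,
    marker_r2,
    prefilter_markers,
    select_focus_haplotype,
)
from landhap.lmm import compute_kinship
from landhap.types import HaplotypeMatrix


def _matrix(cols, positions=None, chrom="chr1"):
    cols = np.asarray(cols, np.int8).T  # given as list of columns
    n, k = cols.shape
    positions = positions or [100_000 * (j + 1) for j in range(k)]
    info = pd.DataFrame(
        {
            "window_id": np.arange(k),
            "hap_id": np.zeros(k, int),
            "chrom": chrom,
            "start_bp": positions,
            "end_bp": [p + 900 for p in positions],
        }
    )
    return HaplotypeMatrix([f"L{i}" for i in range(n)], cols, info)


# ---------------------------------------------------------------------------
# Prefilter


def test_prefilter_min_count_and_duplicates():
    base = [0, 0, 2, 2, 2, 0, 0, 0]
    rare = [2, 2, 0, 0, 0, 0, 0, 0]  # 2 carriers -> dropped
    dup = list(base)
    comp = [2 - v for v in base]  # complement: r^2 = 1 with base
    other = [2, 0, 2, 0, 2, 0, 2, 0]
    mat = _matrix([base, rare, dup, comp, other])
    filt, log = prefilter_markers(mat, min_count=3)
    assert filt.n_haps == 2  # base (first by position) and other survive
    assert set(filt.info["window_id"]) == {0, 4}
    reasons = log.set_index("marker_idx")["reason"]
    assert reasons.loc[1] == "min_count"
    assert reasons.loc[2] == "r2_1" and reasons.loc[3] == "r2_1"
    assert (log.set_index("marker_idx")["kept_idx"].loc[[2, 3]] == 0).all()


def test_prefilter_count_matches_bruteforce(small_haplotypes):
    _, _, matrix = small_haplotypes
    filt, _ = prefilter_markers(matrix, min_count=3)
    X = matrix.scores
    carriers = (X == 2).sum(axis=0)
    eligible = (carriers >= 3) & (carriers <= X.shape[0] - 1)
    # brute-force duplicate classes among eligible columns
    seen = set()
    expected = 0
    order = np.lexsort((matrix.info["start_bp"], matrix.info["chrom"].astype(str)))
    for j in order:
        if not eligible[j]:
            continue
        key = X[:, j].tobytes()
        ckey = (2 - X[:, j]).astype(np.int8).tobytes()
        if key not in seen and ckey not in seen:
            seen.add(key)
            expected += 1
    assert filt.n_haps == expected


# ---------------------------------------------------------------------------
# BH-FDR


def bh_oracle(p, q):
    """All-thresholds brute force."""
    p = np.asarray(p)
    m = len(p)
    sp = np.sort(p)
    k_star = 0
    for k in range(1, m + 1):
        if sp[k - 1] <= k * q / m:
            k_star = k
    if k_star == 0:
        return np.zeros(m, bool)
    return p <= sp[k_star - 1]


def test_bh_examples():
    assert bh_fdr(np.array([0.01, 0.02, 0.20]), q=0.15).tolist() == [True, True, False]
    assert not bh_fdr(np.ones(5), q=0.15).any()
    assert bh_fdr(np.array([0.10]), q=0.15).tolist() == [True]


def test_bh_matches_oracle_on_random_vectors():
    rng = np.random.default_rng(0)
    for _ in range(1000):
        m = rng.integers(1, 40)
        p = rng.random(m) ** rng.uniform(0.5, 3.0)
        q = rng.uniform(0.01, 0.5)
        assert np.array_equal(bh_fdr(p, q), bh_oracle(p, q))


def test_bh_cross_checked_against_statsmodels():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(1)
    p = rng.random(200) ** 2
    flags = bh_fdr(p, q=0.15)
    reject, *_ = multipletests(p, alpha=0.15, method="fdr_bh")
    assert np.array_equal(flags, reject)


# ---------------------------------------------------------------------------
# Association scan


def _scan_setup(n=200, n_markers=60, seed=0, h2_marker=0.1):
    rng = np.random.default_rng(seed)
    geno = (rng.random((n, 400)) < rng.uniform(0.1, 0.9, 400)).astype(np.int8) * 2
    K = compute_kinship(geno)
    cols = (rng.random((n_markers, n)) < 0.3).astype(np.int8) * 2
    mat = _matrix(cols)
    return rng, K, mat


def test_null_scan_pvalues_uniform():
    """Permuted/independent phenotypes give uniform p across markers."""
    rng, K, mat = _scan_setup(n=300, n_markers=2000, seed=3)
    L = np.linalg.cholesky(K + 1e-8 * np.eye(300))
    y = 0.7 * (L @ rng.standard_normal(300)) + rng.standard_normal(300)
    res = association_scan(y, np.ones((300, 1)), mat, K)
    p = res.table["p"].dropna().to_numpy()
    ks = stats.kstest(p, "uniform")
    assert ks.pvalue > 0.01


def test_null_marker_effect_within_three_se():
    rng, K, mat = _scan_setup(n=150, n_markers=300, seed=4)
    y = rng.standard_normal(150)
    res = association_scan(y, np.ones((150, 1)), mat, np.eye(150))
    t = res.table.dropna(subset=["beta"])
    frac = (t["beta"].abs() < 3 * t["se"]).mean()
    assert frac >= 0.99


def test_planted_qtl_is_top_marker():
    hits = 0
    for seed in range(25):
        rng, K, mat = _scan_setup(n=600, n_markers=150, seed=100 + seed)
        x = mat.scores[:, 17].astype(float)
        L = np.linalg.cholesky(K + 1e-8 * np.eye(600))
        sd_y = 1.0
        y = 0.25 * x + 0.5 * (L @ rng.standard_normal(600)) \
            + 0.8 * rng.standard_normal(600)  # 2*0.25 = 0.5 SD carrier contrast
        res = association_scan(y, np.ones((600, 1)), mat, K)
        if int(res.table["p"].idxmin()) == 17:
            hits += 1
    assert hits >= 22  # >= ~90% of seeds


def test_scan_skips_monomorphic_markers():
    rng = np.random.default_rng(0)
    cols = [[0] * 10, [0, 2] * 5]
    mat = _matrix(cols)
    y = rng.standard_normal(10)
    res = association_scan(y, np.ones((10, 1)), mat, np.eye(10))
    assert res.table["skipped"].tolist() == [True, False]
    assert np.isnan(res.table["p"].iloc[0])


def test_exact_refit_close_to_approximate():
    """Exact per-marker ML refit and the fixed-ratio approximation agree on
    the signal marker and its significance."""
    rng, K, mat = _scan_setup(n=120, n_markers=30, seed=9)
    L = np.linalg.cholesky(K + 1e-8 * np.eye(120))
    y = 0.4 * mat.scores[:, 2] + L @ rng.standard_normal(120) * 0.5 \
        + rng.standard_normal(120)
    approx = association_scan(y, np.ones((120, 1)), mat, K, exact=False)
    exact = association_scan(y, np.ones((120, 1)), mat, K, exact=True)
    assert int(approx.table["p"].idxmin()) == int(exact.table["p"].idxmin()) == 2
    lp_a = -np.log10(float(approx.table["p"].iloc[2]))
    lp_e = -np.log10(float(exact.table["p"].iloc[2]))
    assert abs(lp_a - lp_e) < 1.0
    assert np.corrcoef(approx.table["beta"], exact.table["beta"])[0, 1] > 0.9


# ---------------------------------------------------------------------------
# Regions / focus


def _sig_table(matrix, cols, pvals, betas):
    info = matrix.info.iloc[cols].reset_index(drop=True).copy()
    info["scan"] = "t|ACROSS"
    info["p"] = pvals
    info["beta"] = betas
    info["se"] = 0.1
    info["fdr_significant"] = True
    return info


def test_region_clumping_distance_and_ld_rule():
    # three haplotypes at 0.2 / 0.5 / 2.0 Mb, all pairwise r^2 ~ 1
    col = [0, 0, 2, 2, 0, 0, 2, 0]
    mat = _matrix([col, col, col], positions=[200_000, 500_000, 2_000_000])
    sig = _sig_table(mat, [0, 1, 2], [1e-8, 1e-6, 1e-7], [0.5, 0.4, 0.45])
    regions = define_regions(sig, mat)
    assert len(regions) == 2
    assert regions["n_members"].tolist() == [2, 1]

    # close but uncorrelated -> separate regions (AND rule)
    other = [2, 2, 0, 0, 2, 0, 0, 0]
    mat2 = _matrix([col, other], positions=[200_000, 300_000])
    assert marker_r2(np.array(col, float), np.array(other, float)) < 0.8
    sig2 = _sig_table(mat2, [0, 1], [1e-8, 1e-7], [0.5, 0.4])
    assert len(define_regions(sig2, mat2)) == 2


def test_region_single_haplotype_spans_own_window():
    col = [0, 0, 2, 2, 0, 0, 2, 0]
    mat = _matrix([col], positions=[750_000])
    sig = _sig_table(mat, [0], [1e-6], [0.3])
    regions = define_regions(sig, mat)
    assert len(regions) == 1
    assert regions["start_bp"].iloc[0] == 750_000
    assert regions["focus_window"].iloc[0] == 0


def test_region_clumping_order_invariant_and_idempotent():
    rng = np.random.default_rng(2)
    cols = [(rng.random(30) < 0.4).astype(int) * 2 for _ in range(6)]
    pos = [100_000, 400_000, 650_000, 3_000_000, 3_200_000, 9_000_000]
    mat = _matrix(cols, positions=pos)
    sig = _sig_table(mat, list(range(6)), rng.random(6) * 1e-3, rng.standard_normal(6))
    r1 = define_regions(sig, mat)
    perm = rng.permutation(6)
    r2 = define_regions(sig.iloc[perm].reset_index(drop=True), mat)
    pd.testing.assert_frame_equal(
        r1.drop(columns="region_id"), r2.drop(columns="region_id")
    )


@pytest.mark.parametrize(
    "pvals,betas,expected_window",
    [
        ([1e-8, 1e-6], [0.1, 0.9], 0),  # distinct p: argmin wins
        ([1e-6, 1e-6], [0.1, 0.9], 1),  # p tie: larger |beta|
        ([1e-6, 1e-6], [-0.5, 0.5], 0),  # full tie: leftmost bp
    ],
)
def test_focus_tie_breaking(pvals, betas, expected_window):
    col = [0, 0, 2, 2, 0, 0]
    mat = _matrix([col, col], positions=[100_000, 300_000])
    sig = _sig_table(mat, [0, 1], pvals, betas)
    focus = select_focus_haplotype(sig)
    assert int(focus["window_id"]) == expected_window


# ---------------------------------------------------------------------------
# Fine-mapping


def _fine_map_case(seed, n=300, m=40, causal=20):
    rng = np.random.default_rng(seed)
    mm = lh.MarkerMap(
        pd.DataFrame(
            {
                "marker": [f"m{i}" for i in range(m)],
                "chrom": "chr1",
                "pos_bp": 10_000 * (1 + np.arange(m)),
            }
        )
    )
    # correlated local genotypes: founder mosaic along the region
    founders = (rng.random((6, m)) < 0.5).astype(np.int8)
    rows = []
    for _ in range(n):
        f = founders[rng.integers(6)].copy()
        for cut in np.sort(rng.integers(1, m, size=rng.poisson(2.5))):
            f[cut:] = founders[rng.integers(6)][cut:]
        rows.append(f)
    geno = np.vstack(rows) * 2
    panel = lh.GenotypePanel([f"L{i}" for i in range(n)], ["p"] * n, geno, mm)
    causal = min(causal, m - 1)
    x = geno[:, causal].astype(float)
    y = 0.4 * x + rng.standard_normal(n)
    return panel, y


def test_fine_map_profile_and_localization():
    region = pd.Series({"chrom": "chr1", "start_bp": 10_000, "end_bp": 400_000})
    hit = 0
    for seed in range(10):
        panel, y = _fine_map_case(seed)
        prof = fine_map_region(region, panel, y, np.ones((panel.n_lines, 1)),
                               np.eye(panel.n_lines))
        assert len(prof) == panel.n_markers - 10 + 1
        best = prof[prof["best_window"]].iloc[0]
        lo = best["start_bp"] / 10_000 - 1
        hi = best["end_bp"] / 10_000 - 1
        if lo <= 20 <= hi:
            hit += 1
    assert hit >= 8


def test_fine_map_exact_window_region_has_profile_length_one():
    panel, y = _fine_map_case(3, m=10)
    region = pd.Series({"chrom": "chr1", "start_bp": 10_000, "end_bp": 100_000})
    prof = fine_map_region(region, panel, y, np.ones((panel.n_lines, 1)),
                           np.eye(panel.n_lines))
    assert len(prof) == 1


def test_fine_map_too_few_snps_rejected():
    panel, y = _fine_map_case(3, m=10)
    region = pd.Series({"chrom": "chr1", "start_bp": 10_000, "end_bp": 50_000})
    with pytest.raises(ValueError, match="at least"):
        fine_map_region(region, panel, y, np.ones((panel.n_lines, 1)),
                        np.eye(panel.n_lines))


def test_snp_and_haplotype_scans_agree_on_top_region(small_study):
    """A planted single-SNP signal is found at the same place by the SNP scan
    and the window-haplotype scan (for a SNP a window haplotype tags well)."""
    _, panel, _, _ = small_study
    dh = panel.subset_lines(np.array([p != "breeding" for p in panel.populations]))
    rng = np.random.default_rng(0)
    # pick a polymorphic SNP strongly tagged by one haplotype of its window
    windows0 = lh.build_windows(dh.marker_map)
    _, hm0 = lh.call_haplotypes(dh, windows0)
    j_snp, best_r2 = None, 0.0
    for j in range(dh.n_markers):
        freq = dh.geno[:, j].mean() / 2
        if not 0.15 <= freq <= 0.85:
            continue
        w = j // 10  # snps_per_chromosome is a multiple of the window size
        cols = np.flatnonzero(hm0.info["window_id"].to_numpy() == w)
        r2 = max(
            marker_r2(dh.geno[:, j].astype(float), hm0.scores[:, c].astype(float))
            for c in cols
        )
        if r2 > best_r2:
            j_snp, best_r2 = j, r2
    assert best_r2 >= 0.6
    x = dh.geno[:, j_snp].astype(float)
    y = 0.6 * x + rng.standard_normal(dh.n_lines)
    K = compute_kinship(dh.geno)
    W = np.ones((dh.n_lines, 1))
    # SNP scan
    t = dh.marker_map.table
    snp_mat = HaplotypeMatrix(
        list(dh.lines), dh.geno,
        pd.DataFrame({"window_id": np.arange(dh.n_markers), "hap_id": 0,
                      "chrom": t["chrom"], "start_bp": t["pos_bp"],
                      "end_bp": t["pos_bp"]}),
    )
    snp_res = association_scan(y, W, snp_mat, K)
    top_snp_bp = int(snp_res.table.loc[snp_res.table["p"].idxmin(), "start_bp"])
    # haplotype scan
    windows = lh.build_windows(dh.marker_map)
    _, hap_mat = lh.call_haplotypes(dh, windows)
    filt, _ = prefilter_markers(hap_mat)
    hap_res = association_scan(y, W, filt, K)
    top = hap_res.table.loc[hap_res.table["p"].idxmin()]
    assert top["start_bp"] - 500_000 <= top_snp_bp <= top["end_bp"] + 500_000
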