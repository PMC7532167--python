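"""Kinship-corrected association scans, FDR, region definition, fine-mapping.

The scan fits, per trait x environment, the single-marker mixed model
y = W alpha + x beta + u + e with u ~ N(0, K sg2). Variance components are
estimated once per scan under the null (no marker) and reused for every
marker; the likelihood-ratio test then profiles the residual scale per
marker with the variance ratio fixed, which is the standard fast
approximation used by genome-scan software. An exact per-marker refit is
available behind ``exact=True``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lmm import SpectralLMM
from .types import HaplotypeMatrix
from scipy import stats


# ---------------------------------------------------------------------------
# Marker prefiltering


def prefilter_markers(matrix: HaplotypeMatrix, min_count: int = 3) -> tuple[HaplotypeMatrix, pd.DataFrame]:
    """Drop markers with carrier count < min_count, then collapse r^2 = 1
    duplicate classes keeping the first marker by genomic position.

    For 0/2 vectors r^2 = 1 means the standardized columns are equal up to
    sign, i.e. identical or complementary carrier patterns.
    """
    X = matrix.scores
    carriers = (X == 2).sum(axis=0)
    non_carriers = (X == 0).sum(axis=0)
    keep_count = (carriers >= min_count) & (non_carriers >= 1)

    order = np.lexsort(
        (matrix.info["start_bp"].to_numpy(), matrix.info["chrom"].to_numpy(str))
    )
    seen: dict[bytes, int] = {}
    keep_dup = np.zeros(matrix.n_haps, bool)
    dup_log = []
    for j in order:
        if not keep_count[j]:
            dup_log.append({"marker_idx": int(j), "kept_idx": -1, "reason": "min_count"})
            continue
        col = X[:, j]
        key = col.tobytes()
        key_c = (2 - col).astype(np.int8).tobytes()
        if key in seen or key_c in seen:
            kept = seen.get(key, seen.get(key_c))
            dup_log.append({"marker_idx": int(j), "kept_idx": int(kept), "reason": "r2_1"})
        else:
            seen[key] = j
            keep_dup[j] = True
    filtered = matrix.subset_columns(np.flatnonzero(keep_dup))
    return filtered, pd.DataFrame(dup_log, columns=["marker_idx", "kept_idx", "reason"])


# ---------------------------------------------------------------------------
# Association scan


@dataclass
class ScanResult:
    table: pd.DataFrame  # window_id, hap_id, chrom, start_bp, end_bp, beta, se, p, fdr_significant
    scan_id: str
    null_fit: object = None


def association_scan(
    y: np.ndarray,
    covariates: np.ndarray,
    matrix: HaplotypeMatrix,
    K: np.ndarray,
    scan_id: str = "scan",
    fdr_q: float = 0.15,
    exact: bool = False,
    spectral: SpectralLMM | None = None,
) -> ScanResult:
    """Scan all markers of ``matrix`` against phenotype ``y`` (one value per line).

    ``covariates`` must include the intercept (and landrace indicators where
    applicable). Markers monomorphic in the scanned lines are skipped.
    """
    y = np.asarray(y, float)
    W = np.atleast_2d(np.asarray(covariates, float))
    model = spectral if spectral is not None else SpectralLMM(K)
    null = model.fit(y, W, method="reml")
    delta = null.extra["delta"]
    w = 1.0 / (delta * model.s + 1.0)
    sw = np.sqrt(w)

    yr = model.rotate(y) * sw
    Wr = model.rotate(W) * sw[:, None]
    Q, _ = np.linalg.qr(Wr)
    y_res = yr - Q @ (Q.T @ yr)
    rss0 = float(y_res @ y_res)
    n, p0 = len(y), W.shape[1]

    X = matrix.scores.astype(float)
    mono = (X == X[0]).all(axis=0)
    Xr = (model.U.T @ X) * sw[:, None]
    X_res = Xr - Q @ (Q.T @ Xr)
    xtx = (X_res**2).sum(axis=0)
    mono |= xtx < 1e-10  # collinear with covariates after projection
    xty = X_res.T @ y_res
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(xtx > 0, xty / np.maximum(xtx, 1e-300), np.nan)
    rss1 = np.maximum(rss0 - beta**2 * xtx, 1e-300)
    lrt = n * (np.log(rss0) - np.log(rss1))
    pvals = stats.chi2.sf(np.clip(lrt, 0.0, None), df=1)
    se = np.sqrt((rss1 / (n - p0 - 1)) / np.maximum(xtx, 1e-300))

    if exact:
        for j in range(matrix.n_haps):
            if mono[j]:
                continue
            fit_alt = model.fit(y, np.column_stack([W, X[:, j]]), method="ml")
            fit_null = model.fit(y, W, method="ml")
            stat = max(0.0, 2.0 * (fit_alt.loglik_ml - fit_null.loglik_ml))
            pvals[j] = stats.chi2.sf(stat, df=1)
            beta[j] = fit_alt.beta[-1]
            se[j] = fit_alt.se[-1]

    tab = matrix.info.copy()
    tab["scan"] = scan_id
    tab["beta"] = beta
    tab["se"] = se
    tab["p"] = pvals
    tab["skipped"] = mono
    tab.loc[mono, ["beta", "se", "p"]] = np.nan
    ok = ~mono
    flags = np.zeros(len(tab), bool)
    flags[ok] = bh_fdr(tab.loc[ok, "p"].to_numpy(), q=fdr_q)
    tab["fdr_significant"] = flags
    return ScanResult(table=tab, scan_id=scan_id, null_fit=null)


def bh_fdr(pvalues: np.ndarray, q: float = 0.15) -> np.ndarray:
    """Benjamini-Hochberg step-up: significant = rank <= largest k with
    p_(k) <= k q / m."""
    p = np.asarray(pvalues, float)
    m = len(p)
    if m == 0:
        return np.zeros(0, bool)
    order = np.argsort(p, kind="mergesort")
    thresh = q * (np.arange(1, m + 1)) / m
    passing = np.flatnonzero(p[order] <= thresh)
    flags = np.zeros(m, bool)
    if len(passing):
        flags[order[: passing[-1] + 1]] = True
    return flags


# ---------------------------------------------------------------------------
# Regions


def marker_r2(x: np.ndarray, z: np.ndarray) -> float:
    """Squared Pearson correlation between two 0/2 marker vectors."""
    xc, zc = x - x.mean(), z - z.mean()
    den = np.sqrt((xc**2).sum() * (zc**2).sum())
    if den == 0:
        return 0.0
    r = float(xc @ zc / den)
    return min(r * r, 1.0)


def define_regions(
    sig_table: pd.DataFrame,
    matrix: HaplotypeMatrix,
    max_dist: int = 1_000_000,
    r2_min: float = 0.8,
) -> pd.DataFrame:
    """Single-linkage clumping of significant haplotypes into genomic regions.

    Two haplotypes join the same region iff they sit on the same chromosome,
    their window start positions are < ``max_dist`` apart AND the r^2 of
    their presence/absence scores is >= ``r2_min``. Region bounds span the
    first and last member windows; the focus haplotype minimizes p (ties:
    larger absolute effect, then smaller bp).
    """
    sig = sig_table.reset_index(drop=True)
    if sig.empty:
        return pd.DataFrame(
            columns=["region_id", "chrom", "start_bp", "end_bp", "n_members",
                     "members", "focus_window", "focus_hap", "focus_p", "focus_beta", "scan"]
        )
    info = matrix.info
    col_of = {
        (w, h): j
        for j, (w, h) in enumerate(zip(info["window_id"], info["hap_id"]))
    }
    cols = [col_of[(w, h)] for w, h in zip(sig["window_id"], sig["hap_id"])]
    X = matrix.scores[:, cols].astype(float)

    k = len(sig)
    parent = list(range(k))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    chroms = sig["chrom"].to_numpy(str)
    pos = sig["start_bp"].to_numpy()
    order = np.lexsort((pos, chroms))
    for ii in range(k):
        i = order[ii]
        for jj in range(ii + 1, k):
            j = order[jj]
            if chroms[j] != chroms[i] or pos[j] - pos[i] >= max_dist:
                break
            if marker_r2(X[:, i], X[:, j]) >= r2_min:
                parent[find(i)] = find(j)

    groups: dict[int, list[int]] = {}
    for i in range(k):
        groups.setdefault(find(i), []).append(i)

    rows = []
    for rid, members in enumerate(
        sorted(groups.values(), key=lambda g: (chroms[g[0]], int(pos[g].min())))
    ):
        sub = sig.iloc[members]
        focus = select_focus_haplotype(sub)
        rows.append(
            {
                "region_id": rid,
                "chrom": sub["chrom"].iloc[0],
                "start_bp": int(sub["start_bp"].min()),
                "end_bp": int(sub["end_bp"].max()),
                "n_members": len(sub),
                "members": ";".join(
                    f"{w}:{h}" for w, h in zip(sub["window_id"], sub["hap_id"])
                ),
                "focus_window": int(focus["window_id"]),
                "focus_hap": int(focus["hap_id"]),
                "focus_p": float(focus["p"]),
                "focus_beta": float(focus["beta"]),
                "scan": sub["scan"].iloc[0] if "scan" in sub else "",
            }
        )
    return pd.DataFrame(rows).sort_values(["chrom", "start_bp"]).reset_index(drop=True)


def select_focus_haplotype(members: pd.DataFrame) -> pd.Series:
    """Most significant member; deterministic tie-break by larger |beta|, then
    smaller bp position."""
    m = members.copy()
    m["_abs_beta"] = -m["beta"].abs()
    m = m.sort_values(["p", "_abs_beta", "start_bp"], kind="mergesort")
    return m.iloc[0].drop("_abs_beta")


# ---------------------------------------------------------------------------
# In-silico fine-mapping


def fine_map_region(
    region: pd.Series,
    panel,
    y: np.ndarray,
    covariates: np.ndarray,
    K: np.ndarray,
    window_size: int = 10,
    min_count: int = 3,
    spectral: SpectralLMM | None = None,
) -> pd.DataFrame:
    """Sliding ten-SNP re-scan across a region; returns the per-window p profile.

    Windows step one SNP at a time; haplotypes are re-called per sliding
    window and each (window, haplotype) is tested with the single-marker
    model at the scan's null variance components. The best window minimizes
    the window-level p (its most significant haplotype).
    """
    t = panel.marker_map.table
    in_region = (
        (t["chrom"] == region["chrom"])
        & (t["pos_bp"] >= region["start_bp"])
        & (t["pos_bp"] <= region["end_bp"])
    )
    snp_idx = np.flatnonzero(in_region.to_numpy())
    if len(snp_idx) < window_size:
        raise ValueError(
            f"region spans {len(snp_idx)} SNPs; need at least {window_size}"
        )
    snp_idx = np.sort(snp_idx)
    model = spectral if spectral is not None else SpectralLMM(K)

    rows = []
    for off in range(len(snp_idx) - window_size + 1):
        sel = snp_idx[off : off + window_size]
        sub = panel.geno[:, sel]
        keys = np.array(["".join(map(str, r // 2)) for r in sub])
        uniq = np.sort(np.unique(keys))
        best_p, best_hap = np.inf, None
        for key in uniq:
            x = (keys == key).astype(float) * 2.0
            c = int((x == 2).sum())
            if c < min_count or c > len(x) - 1:
                continue
            info = HaplotypeMatrix(
                list(panel.lines), x[:, None].astype(np.int8),
                pd.DataFrame([{"window_id": off, "hap_id": 0, "chrom": region["chrom"],
                               "start_bp": int(t["pos_bp"].iloc[sel[0]]),
                               "end_bp": int(t["pos_bp"].iloc[sel[-1]])}]),
            )
            res = association_scan(y, covariates, info, K, scan_id="finemap",
                                   spectral=model)
            p = float(res.table["p"].iloc[0])
            if p < best_p:
                best_p, best_hap = p, key
        rows.append(
            {
                "offset": off,
                "start_bp": int(t["pos_bp"].iloc[sel[0]]),
                "end_bp": int(t["pos_bp"].iloc[sel[-1]]),
                "best_hap": best_hap,
                "p": best_p if np.isfinite(best_p) else np.nan,
            }
        )
    profile = pd.DataFrame(rows)
    profile["best_window"] = False
    if profile["p"].notna().any():
        profile.loc[profile["p"].idxmin(), "best_window"] = True
    return profile
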