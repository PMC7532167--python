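"""Landrace-vs-breeding panel comparison.

Haplotype overlap between panels, frequency enrichment of favorable and
unfavorable haplotypes against random draws, the "common in breeding
material" quartile flag, independence pruning, seeded permutation tests for
group means, and recombination-integrity diagnostics (window cM length, nR,
haplotype similarity 1 - H_hap).
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .gwas import marker_r2
from .popgen import gene_diversity, min_recombination_nr


# ---------------------------------------------------------------------------
# Overlap


def panel_overlap(freq_table: pd.DataFrame, panel_a: str, panel_b: str,
                  extra_pops: list[str] | None = None) -> dict:
    """Shared/private haplotype counts between two panels from a merged
    frequency table (zero rows included for absences)."""
    in_a = freq_table[f"count_{panel_a}"] > 0
    in_b = freq_table[f"count_{panel_b}"] > 0
    out = {
        "n_total": int((in_a | in_b).sum()),
        f"n_{panel_a}": int(in_a.sum()),
        f"n_{panel_b}": int(in_b.sum()),
        "n_shared": int((in_a & in_b).sum()),
        f"private_{panel_a}": int((in_a & ~in_b).sum()),
        f"private_{panel_b}": int((~in_a & in_b).sum()),
    }
    out[f"prop_{panel_a}_absent_in_{panel_b}"] = (
        out[f"private_{panel_a}"] / out[f"n_{panel_a}"] if out[f"n_{panel_a}"] else 0.0
    )
    out[f"prop_{panel_b}_captured_by_{panel_a}"] = (
        out["n_shared"] / out[f"n_{panel_b}"] if out[f"n_{panel_b}"] else 0.0
    )
    if extra_pops:
        private = freq_table[in_a & ~in_b]
        pres = np.stack([(private[f"count_{p}"] > 0).to_numpy() for p in extra_pops])
        n_pops = pres.sum(axis=0)
        if len(private):
            out["private_in_one_population"] = float((n_pops == 1).mean())
            out["private_in_all_populations"] = float((n_pops == len(extra_pops)).mean())
    return out


def cross_panel_frequency_correlation(freq_table: pd.DataFrame, panel_a: str,
                                      panel_b: str) -> float:
    """Pearson correlation of haplotype frequencies between two panels."""
    fa = freq_table[f"freq_{panel_a}"].to_numpy(float)
    fb = freq_table[f"freq_{panel_b}"].to_numpy(float)
    return float(np.corrcoef(fa, fb)[0, 1])


# ---------------------------------------------------------------------------
# Independence pruning and random draws


def prune_independent(
    haps: pd.DataFrame,
    matrix,
    max_dist: int = 1_000_000,
    r2_min: float = 0.8,
) -> pd.DataFrame:
    """Greedy pruning by ascending discovery p: keep a haplotype unless an
    already-kept one is on the same chromosome, within max_dist AND r^2 >=
    r2_min (the 'distance > 1 Mb and/or r^2 < 0.8' independence rule)."""
    if haps.empty:
        return haps
    info = matrix.info
    col_of = {(w, h): j for j, (w, h) in enumerate(zip(info["window_id"], info["hap_id"]))}
    order = haps.sort_values("p", kind="mergesort") if "p" in haps else haps
    kept_rows = []
    for _, cand in order.iterrows():
        xc = matrix.scores[:, col_of[(cand["window_id"], cand["hap_id"])]].astype(float)
        dependent = False
        for k in kept_rows:
            if k["chrom"] != cand["chrom"]:
                continue
            if abs(int(k["start_bp"]) - int(cand["start_bp"])) >= max_dist:
                continue
            xk = matrix.scores[:, col_of[(k["window_id"], k["hap_id"])]].astype(float)
            if marker_r2(xc, xk) >= r2_min:
                dependent = True
                break
        if not dependent:
            kept_rows.append(cand)
    return pd.DataFrame(kept_rows).reset_index(drop=True)


def sample_random_haplotypes(
    catalog_table: pd.DataFrame, n: int = 500, min_count: int = 3,
    seed: int = 0, count_col: str = "count_all",
) -> pd.DataFrame:
    """Uniform draw without replacement from haplotypes with count >= min_count."""
    eligible = catalog_table[catalog_table[count_col] >= min_count]
    if n > len(eligible):
        raise ValueError(f"requested {n} haplotypes but only {len(eligible)} eligible")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(eligible), size=n, replace=False)
    return eligible.iloc[np.sort(idx)].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Tests


def frequency_enrichment_test(class_freqs: np.ndarray, random_freqs: np.ndarray) -> dict:
    """Two-sided Mann-Whitney of a haplotype class against the random draw.

    Exact null distribution for small samples (both n <= 20, no ties),
    tie-corrected normal approximation otherwise.
    """
    a = np.asarray(class_freqs, float)
    b = np.asarray(random_freqs, float)
    small = len(a) <= 20 and len(b) <= 20
    ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if small and not ties else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return {
        "mean_class": float(a.mean()),
        "mean_random": float(b.mean()),
        "U": float(res.statistic),
        "p": float(res.pvalue),
        "method": method,
        "n_class": len(a),
        "n_random": len(b),
    }


def common_haplotype_flag(freqs: np.ndarray, random_freqs: np.ndarray) -> np.ndarray:
    """'Common in the breeding panel' = frequency strictly above the upper
    quartile of the random haplotype frequencies (linear-interpolation
    quartile)."""
    q3 = float(np.quantile(np.asarray(random_freqs, float), 0.75))
    return np.asarray(freqs, float) > q3


def permutation_mean_test(
    group_a: np.ndarray, group_b: np.ndarray, n_perm: int = 10_000, seed: int = 0
) -> dict:
    """Two-sided permutation test on |mean(A) - mean(B)|.

    When the number of distinct assignments is at most ``n_perm`` the full
    enumeration is used (exact p = proportion of assignments at least as
    extreme, the identity included); otherwise Monte Carlo with the add-one
    estimator p = (1 + #{perm >= obs}) / (n_perm + 1).
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    pooled = np.concatenate([a, b])
    n_a, n_tot = len(a), len(pooled)
    obs = abs(a.mean() - b.mean())
    total = comb(n_tot, n_a)
    tol = 1e-12 * max(1.0, abs(obs))
    if total <= n_perm:
        count = 0
        s_all = pooled.sum()
        for pick in combinations(range(n_tot), n_a):
            s_a = pooled[list(pick)].sum()
            stat = abs(s_a / n_a - (s_all - s_a) / (n_tot - n_a))
            if stat >= obs - tol:
                count += 1
        return {"p": count / total, "observed": obs, "exact": True, "n_perm": total}
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        stat = abs(perm[:n_a].mean() - perm[n_a:].mean())
        if stat >= obs - tol:
            count += 1
    return {"p": (1 + count) / (n_perm + 1), "observed": obs, "exact": False,
            "n_perm": n_perm}


# ---------------------------------------------------------------------------
# Recombination-integrity diagnostics


def recombination_integrity_metrics(panel, windows, catalog,
                                    population: str = "all") -> pd.DataFrame:
    """Per-window genetic length (cM), Hudson-Kaplan nR and haplotype
    similarity 1 - H_hap, computed on the given panel."""
    freq_col = f"freq_{population}"
    if freq_col not in catalog.table.columns:
        freq_col = "freq_all"
    rows = []
    X = panel.geno
    for w in windows.table.itertuples(index=False):
        sub = catalog.table[catalog.table["window_id"] == w.window_id]
        f = sub[freq_col].to_numpy(float)
        f = f[f > 0]
        if f.sum() > 0:
            similarity = 1.0 - gene_diversity(f / f.sum())
        else:
            similarity = np.nan
        rows.append({
            "window_id": w.window_id,
            "cm_length": float(getattr(w, "cm_length", np.nan)),
            "nR": min_recombination_nr(X[:, w.start_idx: w.end_idx + 1]),
            "similarity": similarity,
        })
    return pd.DataFrame(rows)
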