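"""Diversity and linkage-disequilibrium statistics.

Covers polymorphism information content (PIC), Nei gene diversity (H), the
Hudson-Kaplan minimum number of historical recombination events (nR),
modified Rogers' distance with principal coordinate analysis, pairwise r^2
and the Hill-Weir LD-decay regression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize


def gene_diversity(freqs: np.ndarray) -> float:
    """Nei gene diversity H = 1 - sum p_i^2."""
    p = _check_freqs(freqs)
    return float(1.0 - np.sum(p**2))


def pic(freqs: np.ndarray) -> float:
    """Botstein polymorphism information content.

    PIC = 1 - sum p_i^2 - sum_{i<j} 2 p_i^2 p_j^2.
    """
    p = _check_freqs(freqs)
    sq = p**2
    cross = (np.sum(sq) ** 2 - np.sum(sq**2)) / 2.0
    return float(1.0 - np.sum(sq) - 2.0 * cross)


def _check_freqs(freqs: np.ndarray) -> np.ndarray:
    p = np.asarray(freqs, float)
    if p.size == 0 or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-8:
        raise ValueError("frequencies must be non-negative and sum to 1")
    return p


def min_recombination_nr(window_geno: np.ndarray) -> int:
    """Hudson-Kaplan lower bound on recombination events within a window.

    ``window_geno``: lines x SNPs, homozygous 0/2. A pair of sites showing
    all four gametic types requires at least one crossover between them;
    the bound is the maximum number of pairwise-disjoint such intervals,
    found by the classic greedy sweep over right endpoints.
    """
    G = np.asarray(window_geno) // 2
    n, m = G.shape
    intervals = []
    for i in range(m - 1):
        for j in range(i + 1, m):
            pair = G[:, i] * 2 + G[:, j]
            if len(np.unique(pair)) == 4:
                intervals.append((i, j))
                break  # nearer right endpoints dominate: (i,j') with j'>j contains (i,j)
    count, last_right = 0, -1
    for left, right in sorted(intervals, key=lambda iv: iv[1]):
        if left >= last_right:
            count += 1
            last_right = right
    return count


def mrd_matrix(geno: np.ndarray) -> np.ndarray:
    """Modified Rogers' distances between fully homozygous lines.

    MRD(a,b) = sqrt( (1/2m) sum_markers sum_alleles (p_a - p_b)^2 ), which for
    0/2-coded homozygotes reduces to the square root of the proportion of
    differing markers.
    """
    X = np.asarray(geno, float) / 2.0
    n, m = X.shape
    # squared Euclidean on allele dosages = number of differing markers
    gram = X @ X.T
    sq = np.diag(gram)[:, None] + np.diag(gram)[None, :] - 2.0 * gram
    D = np.sqrt(np.clip(sq / m, 0.0, 1.0))
    np.fill_diagonal(D, 0.0)
    return (D + D.T) / 2.0


@dataclass
class PCoAResult:
    coordinates: np.ndarray  # n x k
    eigenvalues: np.ndarray
    pct_variance: np.ndarray  # per returned axis, in percent


def pcoa(D: np.ndarray, k: int = 2) -> PCoAResult:
    """Classical (metric) multidimensional scaling of a distance matrix.

    Percent variance uses only positive eigenvalues in the denominator;
    negative eigenvalues (non-Euclidean distances) are dropped.
    """
    D = np.asarray(D, float)
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    w, V = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    pos = w[w > 1e-12]
    k = min(k, len(pos))
    coords = V[:, :k] * np.sqrt(w[:k])
    pct = 100.0 * w[:k] / pos.sum()
    return PCoAResult(coordinates=coords, eigenvalues=w, pct_variance=pct)


def pairwise_r2(
    geno: np.ndarray, marker_map, max_dist: int = 1_000_000
) -> pd.DataFrame:
    """Squared Pearson correlation of 0/2 genotype columns for intra-chromosome
    SNP pairs within ``max_dist`` bp. Monomorphic SNPs are skipped.

    For fully homozygous lines this equals the textbook gametic
    D^2 / (p(1-p)q(1-q)).
    """
    t = marker_map.table
    X = np.asarray(geno, float)
    sd = X.std(axis=0)
    rows = []
    for chrom, grp in t.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        pos = grp["pos_bp"].to_numpy()
        Z = X[:, idx]
        mu = Z.mean(axis=0)
        Zc = Z - mu
        norms = np.sqrt((Zc**2).sum(axis=0))
        for a in range(len(idx)):
            if sd[idx[a]] == 0:
                continue
            hi = np.searchsorted(pos, pos[a] + max_dist, side="right")
            for b in range(a + 1, hi):
                if sd[idx[b]] == 0:
                    continue
                r = float(Zc[:, a] @ Zc[:, b] / (norms[a] * norms[b]))
                rows.append((chrom, int(pos[b] - pos[a]), min(r * r, 1.0)))
    return pd.DataFrame(rows, columns=["chrom", "dist_bp", "r2"])


# ---------------------------------------------------------------------------
# Hill & Weir LD decay


def hill_weir_expectation(dist: np.ndarray, rho: float, n: int) -> np.ndarray:
    """Drift-recombination expectation of r^2 with finite-sample correction.

    E[r^2] = [(10+C)/((2+C)(11+C))] * [1 + ((3+C)(12+12C+C^2))/(n(2+C)(11+C))]
    with C = rho * distance and n the number of sampled sequences. Monotone
    decreasing in distance; approaches 1/n at large C.
    """
    C = rho * np.asarray(dist, float)
    first = (10.0 + C) / ((2.0 + C) * (11.0 + C))
    second = 1.0 + ((3.0 + C) * (12.0 + 12.0 * C + C**2)) / (n * (2.0 + C) * (11.0 + C))
    return first * second


@dataclass
class LDDecayFit:
    rho: float  # fitted recombination-scale parameter (per bp)
    n: int
    threshold: float
    decay_distance_bp: float
    beyond_data_range: bool = False


def fit_ld_decay(
    pairs: pd.DataFrame, n: int, threshold: float = 0.2, min_pairs: int = 10
) -> LDDecayFit:
    """Nonlinear least squares of observed r^2 on the Hill-Weir expectation.

    Decay distance = smallest distance (1-bp grid up to the maximum observed
    distance) at which the fitted curve drops below ``threshold``. If the
    curve never crosses within the data range the distance reports the max
    distance with ``beyond_data_range`` set.
    """
    if len(pairs) < min_pairs:
        raise ValueError(f"need at least {min_pairs} SNP pairs, got {len(pairs)}")
    d = pairs["dist_bp"].to_numpy(float)
    r2 = pairs["r2"].to_numpy(float)
    d = np.maximum(d, 1.0)

    def resid(log_rho: np.ndarray) -> np.ndarray:
        return hill_weir_expectation(d, float(np.exp(log_rho[0])), n) - r2

    best = None
    for start in (-12.0, -9.0, -6.0, -3.0):
        res = optimize.least_squares(resid, x0=[start], method="lm", max_nfev=2000)
        if best is None or res.cost < best.cost:
            best = res
    rho = float(np.exp(best.x[0]))

    max_d = int(d.max())
    grid = np.arange(1, max_d + 1, dtype=float)
    curve = hill_weir_expectation(grid, rho, n)
    below = np.flatnonzero(curve < threshold)
    if len(below) == 0:
        return LDDecayFit(rho, n, threshold, float(max_d), beyond_data_range=True)
    return LDDecayFit(rho, n, threshold, float(grid[below[0]]))


# ---------------------------------------------------------------------------
# Panel-level summaries


def diversity_summary(panel_geno: np.ndarray, catalog, population: str,
                      windows=None) -> dict[str, float]:
    """Mean PIC/H over SNPs and over window haplotypes, plus mean nR per window."""
    X = np.asarray(panel_geno, float)
    p = X.mean(axis=0) / 2.0
    poly = slice(None)
    pic_snp = np.array([pic([q, 1 - q]) for q in p])
    h_snp = np.array([gene_diversity([q, 1 - q]) for q in p])
    out = {"PIC_SNP": float(pic_snp[poly].mean()), "H_SNP": float(h_snp[poly].mean())}

    freq_col = f"freq_{population}" if f"freq_{population}" in catalog.table else "freq_all"
    pics, hs = [], []
    for _, grp in catalog.table.groupby("window_id"):
        f = grp[freq_col].to_numpy(float)
        f = f[f > 0]
        if f.sum() <= 0:
            continue
        f = f / f.sum()
        pics.append(pic(f))
        hs.append(gene_diversity(f))
    out["PIC_hap"] = float(np.mean(pics))
    out["H_hap"] = float(np.mean(hs))

    if windows is not None:
        nrs = [
            min_recombination_nr(X[:, w.start_idx : w.end_idx + 1])
            for w in windows.table.itertuples(index=False)
        ]
        out["mean_nR"] = float(np.mean(nrs))
    return out
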