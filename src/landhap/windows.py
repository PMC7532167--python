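"""Ten-SNP window construction, haplotype calling and frequency tables.

A haplotype is the allele string a (fully homozygous) line carries across
the SNPs of a nonoverlapping window. Haplotypes are recoded as
presence/absence markers with genotype scores 0 and 2, so each line scores
2 for exactly one haplotype per window.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .types import GenotypePanel, HaplotypeCatalog, HaplotypeMatrix, MarkerMap, WindowSet


def build_windows(marker_map: MarkerMap, window_size: int = 10) -> WindowSet:
    """Chop every chromosome into consecutive nonoverlapping windows.

    The trailing remainder (fewer than ``window_size`` SNPs) forms a final
    window flagged ``partial``.
    """
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    t = marker_map.table
    rows = []
    wid = 0
    for chrom, grp in t.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        if len(idx) == 0:
            warnings.warn(f"chromosome {chrom} has no markers; skipped")
            continue
        for lo in range(0, len(idx), window_size):
            sub = idx[lo : lo + window_size]
            row = {
                "window_id": wid,
                "chrom": chrom,
                "start_idx": int(sub[0]),
                "end_idx": int(sub[-1]),
                "start_bp": int(t["pos_bp"].iloc[sub[0]]),
                "end_bp": int(t["pos_bp"].iloc[sub[-1]]),
                "n_snps": len(sub),
                "partial": len(sub) < window_size,
            }
            if marker_map.has_cm:
                row["cm_length"] = float(
                    t["pos_cM"].iloc[sub[-1]] - t["pos_cM"].iloc[sub[0]]
                )
            rows.append(row)
            wid += 1
    return WindowSet(pd.DataFrame(rows), window_size=window_size)


def call_haplotypes(
    panel: GenotypePanel, windows: WindowSet
) -> tuple[HaplotypeCatalog, HaplotypeMatrix]:
    """Call per-window haplotypes and build the 0/2 presence/absence matrix.

    Haplotype keys are the window's allele strings; hap_ids are assigned in
    lexicographic key order within each window so that identical strings get
    identical ids regardless of which panel or line order produced them.
    """
    geno = panel.geno
    pops = np.asarray(panel.populations)
    pop_names = panel.population_names
    cat_rows = []
    score_cols = []
    info_rows = []
    n = geno.shape[0]
    pop_masks = {pop: pops == pop for pop in pop_names}
    pop_sizes = {pop: int(m.sum()) for pop, m in pop_masks.items()}
    for w in windows.table.itertuples(index=False):
        sub = np.ascontiguousarray(geno[:, w.start_idx : w.end_idx + 1] // 2)
        # unique rows; byte-wise sort order == lexicographic allele-string order
        view = sub.view([("", sub.dtype)] * sub.shape[1]).ravel()
        uniq, assign, counts = np.unique(view, return_inverse=True, return_counts=True)
        k = len(uniq)
        alleles = uniq.view(sub.dtype).reshape(k, -1)
        strings = ["".join(map(str, row)) for row in alleles]
        onehot = assign[:, None] == np.arange(k)[None, :]
        pop_counts = {
            pop: onehot[mask].sum(axis=0) for pop, mask in pop_masks.items()
        }
        for h in range(k):
            rec = {
                "window_id": w.window_id,
                "hap_id": h,
                "allele_string": strings[h],
                "chrom": w.chrom,
                "start_bp": w.start_bp,
                "end_bp": w.end_bp,
                "count_all": int(counts[h]),
                "freq_all": float(counts[h] / n),
            }
            for pop in pop_names:
                c = int(pop_counts[pop][h])
                rec[f"count_{pop}"] = c
                rec[f"freq_{pop}"] = c / pop_sizes[pop] if pop_sizes[pop] else 0.0
            cat_rows.append(rec)
            info_rows.append(
                {
                    "window_id": w.window_id,
                    "hap_id": h,
                    "chrom": w.chrom,
                    "start_bp": w.start_bp,
                    "end_bp": w.end_bp,
                    "partial": w.partial,
                }
            )
        score_cols.append(onehot.astype(np.int8) * 2)
    catalog = HaplotypeCatalog(pd.DataFrame(cat_rows), populations=pop_names)
    matrix = HaplotypeMatrix(
        list(panel.lines),
        np.hstack(score_cols) if score_cols else np.zeros((panel.n_lines, 0), np.int8),
        pd.DataFrame(info_rows),
    )
    _check_one_carrier(matrix, windows)
    return catalog, matrix


def _check_one_carrier(matrix: HaplotypeMatrix, windows: WindowSet) -> None:
    wid = matrix.info["window_id"].to_numpy()
    for w in np.unique(wid):
        cols = matrix.scores[:, wid == w]
        if not np.all(cols.sum(axis=1) == 2):
            raise AssertionError(f"window {w}: line carries != 1 haplotype")


def haplotype_frequencies(
    catalogs: dict[str, HaplotypeCatalog],
    include_partial: bool = False,
    windows: WindowSet | None = None,
) -> pd.DataFrame:
    """Merge per-panel catalogs into one frequency table keyed by (window, allele string).

    Haplotypes absent from a panel get explicit zero rows, which is what makes
    cross-panel comparisons (shared/private, frequency correlation) honest.
    Partial trailing windows are excluded by default because their haplotypes
    are not length-comparable across panels.
    """
    frames = []
    for name, cat in catalogs.items():
        t = cat.table[["window_id", "allele_string", "chrom", "start_bp", "end_bp",
                       "count_all", "freq_all"]].copy()
        t = t.rename(columns={"count_all": f"count_{name}", "freq_all": f"freq_{name}"})
        frames.append(t)
    merged = frames[0]
    for t in frames[1:]:
        merged = merged.merge(
            t, on=["window_id", "allele_string", "chrom", "start_bp", "end_bp"], how="outer"
        )
    for name in catalogs:
        merged[f"count_{name}"] = merged[f"count_{name}"].fillna(0).astype(int)
        merged[f"freq_{name}"] = merged[f"freq_{name}"].fillna(0.0)
    if not include_partial and windows is not None:
        partial_ids = set(windows.table.loc[windows.table["partial"], "window_id"])
        merged = merged[~merged["window_id"].isin(partial_ids)]
    return merged.sort_values(["window_id", "allele_string"]).reset_index(drop=True)
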