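"""End-to-end orchestration: haplotyping -> diversity/LD -> scans -> regions
-> multi-environment elimination -> stability classification -> panel
comparison, from a single config, with a reproducibility manifest."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as lio
from .compare import (
    common_haplotype_flag,
    cross_panel_frequency_correlation,
    frequency_enrichment_test,
    panel_overlap,
    prune_independent,
    recombination_integrity_metrics,
    sample_random_haplotypes,
)
from .gwas import association_scan, define_regions, prefilter_markers
from .lmm import SpectralLMM, compute_kinship
from .multienv import (
    DEFAULT_TRAIT_DIRECTIONS,
    assemble_candidates,
    backward_eliminate,
    classify_stability,
    stack_trait,
    variance_explained,
)
from .popgen import diversity_summary, fit_ld_decay, pairwise_r2
from .types import ACROSS_ENV, GenotypePanel, PhenotypeTable
from .windows import build_windows, call_haplotypes, haplotype_frequencies


@dataclass
class PipelineConfig:
    window_size: int = 10
    min_count: int = 3
    fdr_q: float = 0.15
    region_max_dist: int = 1_000_000
    region_r2: float = 0.8
    elimination_p: float = 0.01
    ci_mult: float = 1.96
    trait_directions: dict | None = None  # None: built-in map, restricted to present traits
    random_n: int = 500
    n_perm: int = 10_000
    ld_max_dist: int = 1_000_000
    ld_threshold: float = 0.2
    ld_max_snps_per_chrom: int = 250
    seed: int = 0

    def validate(self, traits: list[str] | None = None) -> None:
        if not (0 < self.fdr_q < 1 and 0 < self.elimination_p < 1):
            raise ValueError("fdr_q and elimination_p must lie in (0, 1)")
        if not (0 <= self.region_r2 <= 1):
            raise ValueError("region_r2 must lie in [0, 1]")
        if self.min_count < 1 or self.random_n < 1 or self.n_perm < 1:
            raise ValueError("counts must be positive")
        if traits is not None and self.trait_directions is not None:
            unknown = set(self.trait_directions) - set(traits)
            if unknown:
                raise ValueError(
                    f"trait direction map names unknown traits: {sorted(unknown)}"
                )

    def directions_for(self, traits: list[str]) -> dict:
        if self.trait_directions is not None:
            return self.trait_directions
        return {t: d for t, d in DEFAULT_TRAIT_DIRECTIONS.items() if t in traits}


@dataclass
class PipelineResult:
    windows: object
    catalogs: dict
    freq_table: pd.DataFrame
    diversity: dict
    ld: dict
    scans: dict
    regions: dict
    models: dict
    classifications: dict
    variance_explained: dict
    comparison: dict
    tables: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def run_pipeline(
    panel: GenotypePanel,
    pheno: PhenotypeTable,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
    skip_ld: bool = False,
) -> PipelineResult:
    cfg = config or PipelineConfig()
    traits = pheno.traits()
    cfg.validate(traits=traits)
    rng_seed = cfg.seed

    # --- haplotyping -------------------------------------------------------
    windows = build_windows(panel.marker_map, cfg.window_size)
    dh = panel.subset_lines(np.array([p != "breeding" for p in panel.populations]))
    breeding = panel.subset_population("breeding")
    cat_dh, matrix_dh = call_haplotypes(dh, windows)
    catalogs = {"landrace": cat_dh}
    if breeding.n_lines:
        cat_bl, _ = call_haplotypes(breeding, windows)
        catalogs["breeding"] = cat_bl
    freq_table = haplotype_frequencies(catalogs, windows=windows)

    # --- diversity & LD ----------------------------------------------------
    diversity = {
        "landrace": diversity_summary(dh.geno, cat_dh, "all", windows=windows)
    }
    if breeding.n_lines:
        diversity["breeding"] = diversity_summary(
            breeding.geno, catalogs["breeding"], "all", windows=windows
        )
    ld = {}
    if not skip_ld:
        ld_panel = _thin_for_ld(dh, cfg.ld_max_snps_per_chrom)
        pairs = pairwise_r2(ld_panel.geno, ld_panel.marker_map, cfg.ld_max_dist)
        if len(pairs) >= 10:
            fit = fit_ld_decay(pairs, n=dh.n_lines, threshold=cfg.ld_threshold)
            ld = {"rho": fit.rho, "decay_distance_bp": fit.decay_distance_bp,
                  "beyond_data_range": fit.beyond_data_range, "n_pairs": len(pairs)}

    # --- GWAS per trait ----------------------------------------------------
    pheno_lines = sorted(set(pheno.table["line"]) & set(dh.lines))
    dh_pheno = dh.subset_lines(pheno_lines)
    K = compute_kinship(dh_pheno.geno)
    spectral = SpectralLMM(K)
    _, matrix_pheno = call_haplotypes(dh_pheno, windows)
    filtered, _ = prefilter_markers(matrix_pheno, min_count=cfg.min_count)
    landraces = sorted({p for p in dh_pheno.populations})
    W = np.column_stack(
        [np.ones(dh_pheno.n_lines)]
        + [
            np.array([p == lr for p in dh_pheno.populations], float)
            for lr in landraces[1:]
        ]
    )
    populations = dict(zip(dh_pheno.lines, dh_pheno.populations))

    scans: dict = {}
    regions: dict = {}
    models: dict = {}
    classifications: dict = {}
    varexp: dict = {}
    for trait in traits:
        scans[trait] = {}
        region_tables = []
        for env in pheno.environments(trait) + [ACROSS_ENV]:
            vals = pheno.values_for(trait, env)
            keep = [l for l in dh_pheno.lines if l in vals.index]
            if len(keep) < 10:
                continue
            idx = np.array([dh_pheno.lines.index(l) for l in keep])
            y = vals.loc[keep].to_numpy(float)
            if len(keep) == dh_pheno.n_lines:
                res = association_scan(y, W, filtered, K, scan_id=f"{trait}|{env}",
                                       fdr_q=cfg.fdr_q, spectral=spectral)
            else:
                res = association_scan(y, W[idx], filtered.subset_lines(idx),
                                       K[np.ix_(idx, idx)], scan_id=f"{trait}|{env}",
                                       fdr_q=cfg.fdr_q)
            scans[trait][env] = res
            sig = res.table[res.table["fdr_significant"]]
            if not sig.empty:
                region_tables.append(
                    define_regions(sig, filtered, cfg.region_max_dist, cfg.region_r2)
                )
        regions[trait] = region_tables
        candidates = assemble_candidates(region_tables, filtered,
                                         cfg.region_max_dist, cfg.region_r2)
        data = stack_trait(pheno, trait, filtered, populations,
                           hap_keys=candidates or [])
        model = backward_eliminate(data, candidates, trait=trait,
                                   p_threshold=cfg.elimination_p,
                                   min_count=cfg.min_count)
        models[trait] = model
        classifications[trait] = classify_stability(
            model, cfg.directions_for(traits).get(trait)
        )
        varexp[trait] = variance_explained(data, model.retained)

    # --- panel comparison --------------------------------------------------
    comparison: dict = {}
    if breeding.n_lines:
        comparison["overlap"] = panel_overlap(freq_table, "landrace", "breeding")
        comparison["freq_correlation"] = cross_panel_frequency_correlation(
            freq_table, "landrace", "breeding"
        )
        random_haps = sample_random_haplotypes(
            freq_table, n=min(cfg.random_n, int((freq_table["count_landrace"] >= cfg.min_count).sum())),
            min_count=cfg.min_count, seed=rng_seed, count_col="count_landrace",
        )
        rand_freq = random_haps["freq_breeding"].to_numpy(float)
        comparison["random_upper_quartile"] = float(np.quantile(rand_freq, 0.75))

        fav_rows, unfav_rows = [], []
        for trait, cls in classifications.items():
            model = models[trait]
            for _, row in cls.iterrows():
                key = (int(row["window_id"]), int(row["hap_id"]))
                disc_p = float(
                    model.wald.set_index(["window_id", "hap_id"]).loc[key, "p"]
                )
                info = filtered.info
                j = np.flatnonzero(
                    (info["window_id"] == key[0]) & (info["hap_id"] == key[1])
                )[0]
                rec = {
                    "window_id": key[0], "hap_id": key[1],
                    "chrom": info["chrom"].iloc[j],
                    "start_bp": int(info["start_bp"].iloc[j]), "p": disc_p,
                    "trait": trait,
                }
                if row["label"] == "favorable":
                    fav_rows.append(rec)
                elif row["label"] == "unfavorable":
                    unfav_rows.append(rec)
        hap_freqs = freq_table.set_index(["window_id", "allele_string"])
        for name, rows in (("favorable", fav_rows), ("unfavorable", unfav_rows)):
            if not rows:
                continue
            df = prune_independent(pd.DataFrame(rows), filtered,
                                   cfg.region_max_dist, cfg.region_r2)
            freqs = _breeding_freqs(df, cat_dh, freq_table)
            comparison[f"{name}_breeding_freqs"] = freqs
            comparison[f"{name}_enrichment"] = frequency_enrichment_test(freqs, rand_freq)
            comparison[f"{name}_common_frac"] = float(
                common_haplotype_flag(freqs, rand_freq).mean()
            )
            comparison[f"{name}_absent_frac"] = float((freqs == 0).mean())
        comparison["integrity"] = recombination_integrity_metrics(
            breeding, windows, catalogs["breeding"]
        ).mean(numeric_only=True).to_dict()

    result = PipelineResult(
        windows=windows, catalogs=catalogs, freq_table=freq_table,
        diversity=diversity, ld=ld, scans=scans, regions=regions, models=models,
        classifications=classifications, variance_explained=varexp,
        comparison=comparison,
    )
    result.tables = _result_tables(result)
    if out_dir is not None:
        meta = {"config": asdict(cfg), "seed": cfg.seed,
                "config_hash": _hash_config(cfg),
                "n_lines": panel.n_lines, "n_markers": panel.n_markers}
        result.manifest = lio.write_results(result.tables, out_dir, meta=meta)
    return result


def _thin_for_ld(panel: GenotypePanel, max_per_chrom: int) -> GenotypePanel:
    t = panel.marker_map.table
    keep = []
    for chrom, grp in t.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        if len(idx) > max_per_chrom:
            idx = idx[np.linspace(0, len(idx) - 1, max_per_chrom).round().astype(int)]
        keep.extend(idx.tolist())
    keep = np.sort(np.array(keep))
    from .types import GenotypePanel as GP, MarkerMap

    sub_map = MarkerMap(t.iloc[keep].reset_index(drop=True))
    return GP(panel.lines, panel.populations, panel.geno[:, keep], sub_map)


def _breeding_freqs(df: pd.DataFrame, cat_dh, freq_table: pd.DataFrame) -> np.ndarray:
    key_str = cat_dh.table.set_index(["window_id", "hap_id"])["allele_string"]
    ft = freq_table.set_index(["window_id", "allele_string"])
    out = []
    for _, r in df.iterrows():
        s = key_str.loc[(r["window_id"], r["hap_id"])]
        try:
            out.append(float(ft.loc[(r["window_id"], s), "freq_breeding"]))
        except KeyError:
            out.append(0.0)
    return np.array(out)


def _result_tables(res: PipelineResult) -> dict:
    tables: dict = {"haplotype_frequencies": res.freq_table}
    scan_frames = [
        s.table.assign(trait=trait, environment=env)
        for trait, per_env in res.scans.items()
        for env, s in per_env.items()
    ]
    if scan_frames:
        tables["scan_results"] = pd.concat(scan_frames, ignore_index=True)
    region_frames = [
        t.assign(trait=trait) for trait, ts in res.regions.items() for t in ts if len(t)
    ]
    if region_frames:
        tables["regions"] = pd.concat(region_frames, ignore_index=True)
    cls_frames = [c.assign(trait=t) for t, c in res.classifications.items() if len(c)]
    if cls_frames:
        tables["classification"] = pd.concat(cls_frames, ignore_index=True)
    eff_frames = [
        m.effects.assign(trait=t) for t, m in res.models.items() if len(m.effects)
    ]
    if eff_frames:
        tables["effects"] = pd.concat(eff_frames, ignore_index=True)
    tables["diversity"] = pd.DataFrame(res.diversity).T.reset_index(names="panel")
    return tables


def _hash_config(cfg: PipelineConfig) -> str:
    return hashlib.sha256(
        json.dumps(asdict(cfg), sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
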