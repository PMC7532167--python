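"""Statistical validation experiments: calibration, coverage, recovery.

These routines re-run the estimators on data simulated under their own
model assumptions and measure operating characteristics (type-I error,
confidence-interval coverage, planted-QTL recovery, LD-decay
self-consistency). They back both the test suite and the reproduction
script; every number they return is computed fresh from the given seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .gwas import association_scan, define_regions, marker_r2, prefilter_markers
from .lmm import HeteroLMM, SpectralLMM, compute_kinship
from .multienv import (
    assemble_candidates,
    backward_eliminate,
    classify_stability,
    stack_trait,
)
from .popgen import LDDecayFit, fit_ld_decay, hill_weir_expectation
from .synthetic import SimConfig, simulate_study
from .types import ACROSS_ENV
from .windows import build_windows, call_haplotypes


def lrt_type1_error(
    n: int = 300,
    n_reps: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
    sigma_g2: float = 0.5,
    sigma_e2: float = 1.0,
    n_markers_k: int = 500,
) -> dict:
    """Empirical type-I error of the scan's likelihood-ratio test.

    Phenotypes follow the single-marker model's null (polygenic background
    plus noise); the tested marker is generated independently of y.
    """
    rng = np.random.default_rng(seed)
    geno = (rng.random((n, n_markers_k)) < rng.uniform(0.1, 0.9, n_markers_k)).astype(
        np.int8
    ) * 2
    K = compute_kinship(geno)
    model = SpectralLMM(K)
    L = np.linalg.cholesky(K + 1e-8 * np.eye(n))
    W = np.ones((n, 1))
    from .types import HaplotypeMatrix

    rejections = 0
    for _ in range(n_reps):
        u = np.sqrt(sigma_g2) * (L @ rng.standard_normal(n))
        y = u + np.sqrt(sigma_e2) * rng.standard_normal(n)
        x = (rng.random(n) < 0.3).astype(np.int8) * 2
        mat = HaplotypeMatrix(
            [f"L{i}" for i in range(n)],
            x[:, None],
            pd.DataFrame([{"window_id": 0, "hap_id": 0, "chrom": "chr1",
                           "start_bp": 1, "end_bp": 10}]),
        )
        res = association_scan(y, W, mat, K, spectral=model)
        if float(res.table["p"].iloc[0]) < alpha:
            rejections += 1
    return {"type1_error": rejections / n_reps, "n_reps": n_reps, "alpha": alpha}


def ci_coverage_multienv(
    n_lines: int = 150,
    n_env: int = 4,
    n_reps: int = 1000,
    seed: int = 0,
    effect: float = 0.3,
    freq: float = 0.25,
    sigma_u2: float = 0.5,
    ci_mult: float = 1.96,
) -> dict:
    """Coverage of the multi-environment model's 95% CIs for per-environment
    haplotype effects, pooled over environments and replicates."""
    rng = np.random.default_rng(seed)
    sigma_e = np.sqrt(np.linspace(0.6, 1.4, n_env))
    line_idx = np.repeat(np.arange(n_lines), n_env)
    env_idx = np.tile(np.arange(n_env), n_lines)
    model = HeteroLMM(line_idx, env_idx, n_lines, n_env)
    covered = total = 0
    for _ in range(n_reps):
        x = (rng.random(n_lines) < freq).astype(float) * 2.0
        if x.sum() == 0 or x.sum() == 2 * n_lines:
            continue
        true_eff = effect * rng.choice([-1.0, 1.0], n_env)
        u = np.sqrt(sigma_u2) * rng.standard_normal(n_lines)
        y = (
            x[line_idx] * true_eff[env_idx]
            + u[line_idx]
            + sigma_e[env_idx] * rng.standard_normal(len(line_idx))
        )
        X = np.column_stack(
            [np.ones(len(y))]
            + [(env_idx == e).astype(float) for e in range(1, n_env)]
            + [np.where(env_idx == e, x[line_idx], 0.0) for e in range(n_env)]
        )
        fit = model.fit(y, X)
        b = fit.beta[-n_env:]
        se = fit.se[-n_env:]
        covered += int(np.sum(np.abs(b - true_eff) <= ci_mult * se))
        total += n_env
    return {"coverage": covered / total, "n_intervals": total}


def qtl_recovery(
    n_seeds: int = 25,
    seed: int = 0,
    dh_per_landrace: int = 200,
    n_env: int = 6,
    effect_size: float = 0.5,
    snps_per_chromosome: int = 400,
    n_chromosomes: int = 3,
    fdr_q: float = 0.15,
    p_threshold: float = 0.01,
    min_count: int = 3,
) -> dict:
    """Planted-QTL recovery through the full scan -> FDR -> region ->
    elimination -> classification chain.

    A planted haplotype counts as detected when a retained haplotype tags it
    (same window, or within 1 Mb at r^2 >= 0.8). Its label counts as correct
    when the classification matches the planted pattern, with the expected
    direction flipped when the tagging haplotype is anti-correlated with the
    planted one (the same signal tracked through the complementary allele).
    """
    seeds = np.random.SeedSequence(seed).generate_state(n_seeds) % (2**31)
    detected = matched = labels_ok = planted_total = 0
    for s in seeds:
        cfg = SimConfig(
            seed=int(s), dh_per_landrace=dh_per_landrace, n_breeding=0,
            n_environments=n_env, snps_per_chromosome=snps_per_chromosome,
            n_chromosomes=n_chromosomes,
        )
        panel, truth, pheno = simulate_study(
            cfg, n_stable=3, n_interacting=1, effect_size=effect_size
        )
        windows = build_windows(panel.marker_map)
        _, matrix = call_haplotypes(panel, windows)
        filtered, _ = prefilter_markers(matrix, min_count=min_count)
        K = compute_kinship(panel.geno)
        spectral = SpectralLMM(K)
        landraces = sorted(set(panel.populations))
        W = np.column_stack(
            [np.ones(panel.n_lines)]
            + [np.array([p == lr for p in panel.populations], float)
               for lr in landraces[1:]]
        )
        region_tables = []
        for env in pheno.environments("TRAIT") + [ACROSS_ENV]:
            y = pheno.values_for("TRAIT", env).loc[panel.lines].to_numpy(float)
            res = association_scan(y, W, filtered, K, scan_id=env, fdr_q=fdr_q,
                                   spectral=spectral)
            sig = res.table[res.table["fdr_significant"]]
            if not sig.empty:
                region_tables.append(define_regions(sig, filtered))
        candidates = assemble_candidates(region_tables, filtered)
        pops = dict(zip(panel.lines, panel.populations))
        data = stack_trait(pheno, "TRAIT", filtered, pops, hap_keys=candidates)
        model = backward_eliminate(data, candidates, p_threshold=p_threshold,
                                   min_count=min_count)
        cls = classify_stability(model, +1)

        info_f = filtered.info
        for _, q in truth.qtls.iterrows():
            planted_total += 1
            jq = np.flatnonzero(
                (matrix.info["window_id"] == q["window_id"])
                & (matrix.info["hap_id"] == q["hap_id"])
            )[0]
            xq = matrix.scores[:, jq].astype(float)
            bpq = int(matrix.info["start_bp"].iloc[jq])
            chromq = matrix.info["chrom"].iloc[jq]
            best = None
            for key in model.retained:
                jr = np.flatnonzero(
                    (info_f["window_id"] == key[0]) & (info_f["hap_id"] == key[1])
                )[0]
                if info_f["chrom"].iloc[jr] != chromq:
                    continue
                if abs(int(info_f["start_bp"].iloc[jr]) - bpq) >= 1_000_000:
                    continue
                xr = filtered.scores[:, jr].astype(float)
                r = np.corrcoef(xq, xr)[0, 1]
                if r * r >= 0.8 and (best is None or abs(r) > abs(best[1])):
                    best = (key, r)
            if best is None:
                continue
            detected += 1
            key, r = best
            label = cls.set_index(["window_id", "hap_id"]).loc[key, "label"]
            expected = {
                "stable+": "favorable", "stable-": "unfavorable",
                "interacting": "interacting",
            }[q["pattern"]]
            if r < 0 and expected != "interacting":
                expected = "unfavorable" if expected == "favorable" else "favorable"
            matched += 1
            labels_ok += int(label == expected)
    return {
        "detection_rate": detected / planted_total,
        "label_accuracy": labels_ok / matched if matched else float("nan"),
        "n_planted": planted_total,
        "n_seeds": n_seeds,
    }


def ld_decay_selfconsistency(
    n_seeds: int = 50,
    seed: int = 0,
    rho: float = 2e-5,
    n_lines: int = 200,
    n_pairs: int = 800,
    max_dist: int = 500_000,
    noise_sd: float = 0.05,
    threshold: float = 0.2,
) -> dict:
    """Recovery of the decay distance when r^2 data are generated from the
    fitted expectation itself at a known recombination scale."""
    grid = np.arange(1, max_dist + 1, dtype=float)
    true_curve = hill_weir_expectation(grid, rho, n_lines)
    below = np.flatnonzero(true_curve < threshold)
    true_decay = float(grid[below[0]])
    rel_errors = []
    seeds = np.random.SeedSequence(seed).generate_state(n_seeds) % (2**31)
    for s in seeds:
        rng = np.random.default_rng(int(s))
        d = rng.integers(1, max_dist, n_pairs).astype(float)
        r2 = hill_weir_expectation(d, rho, n_lines) + noise_sd * rng.standard_normal(n_pairs)
        r2 = np.clip(r2, 0.0, 1.0)
        fit = fit_ld_decay(pd.DataFrame({"dist_bp": d, "r2": r2}), n=n_lines,
                           threshold=threshold)
        rel_errors.append(abs(fit.decay_distance_bp - true_decay) / true_decay)
    return {
        "mean_relative_error": float(np.mean(rel_errors)),
        "max_relative_error": float(np.max(rel_errors)),
        "true_decay_bp": true_decay,
        "n_seeds": n_seeds,
    }
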