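"""Multi-locus multi-environment model, backward elimination and effect
stability classification.

The model, per trait, stacks one observation per (line, environment):

    y_ijk = mu + omega_i + delta_j + sum_q x_kq beta_q^i + u_k + e_ijk

with environment fixed effects omega, landrace fixed effects delta, one
E-vector of environment-specific effects beta_q^i per retained haplotype
(main effect + G x E in one parameterization), a random line effect u_k and
environment-specific residual variances. Candidates are eliminated step by
step on the joint Wald test of beta_q^i, dropping the least significant
haplotype while its P >= threshold (default 0.01).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gwas import marker_r2
from .lmm import HeteroLMM, LMMError, LMMFit, wald_joint_test
from .types import ACROSS_ENV, HaplotypeMatrix, PhenotypeTable

HapKey = tuple[int, int]  # (window_id, hap_id)

#: trait -> +1 if positive effects are favorable, -1 if negative effects are
#: favorable. Traits absent from the map get no favorable/unfavorable call.
DEFAULT_TRAIT_DIRECTIONS: dict[str, int] = {
    "EV_V4": +1, "EV_V6": +1, "PH_V4": +1, "PH_V6": +1,
    "LO": -1, "TILL": -1,
}


@dataclass
class MultiEnvData:
    """Aligned stacked data for one trait."""

    y: np.ndarray
    line_idx: np.ndarray
    env_idx: np.ndarray
    lines: list[str]
    environments: list[str]
    landrace_idx: np.ndarray  # per line
    landraces: list[str]
    hap_scores: dict[HapKey, np.ndarray]  # per line, values in {0,2}


def stack_trait(
    pheno: PhenotypeTable,
    trait: str,
    matrix: HaplotypeMatrix,
    populations: dict[str, str],
    hap_keys: list[HapKey] | None = None,
) -> MultiEnvData:
    """Align phenotype records with haplotype scores for one trait."""
    t = pheno.table
    sub = t[(t["trait"] == trait) & (t["environment"] != ACROSS_ENV)]
    lines = sorted(set(sub["line"]) & set(matrix.lines))
    if not lines:
        raise ValueError(f"no phenotyped lines with genotypes for trait {trait}")
    envs = sorted(sub["environment"].unique())
    line_pos = {l: i for i, l in enumerate(lines)}
    env_pos = {e: i for i, e in enumerate(envs)}
    sub = sub[sub["line"].isin(line_pos)]
    y = sub["value"].to_numpy(float)
    line_idx = sub["line"].map(line_pos).to_numpy()
    env_idx = sub["environment"].map(env_pos).to_numpy()

    landraces = sorted({populations[l] for l in lines})
    lr_idx = np.array([landraces.index(populations[l]) for l in lines])

    mat_pos = {l: i for i, l in enumerate(matrix.lines)}
    row_sel = np.array([mat_pos[l] for l in lines])
    info = matrix.info
    col_of = {(w, h): j for j, (w, h) in enumerate(zip(info["window_id"], info["hap_id"]))}
    keys = hap_keys if hap_keys is not None else list(col_of)
    hap_scores = {k: matrix.scores[row_sel, col_of[k]].astype(float) for k in keys}
    return MultiEnvData(y, line_idx, env_idx, lines, envs, lr_idx, landraces, hap_scores)


def _base_design(data: MultiEnvData) -> tuple[np.ndarray, list[str]]:
    n_obs = len(data.y)
    E, L = len(data.environments), len(data.landraces)
    cols = [np.ones(n_obs)]
    names = ["intercept"]
    for e in range(1, E):
        cols.append((data.env_idx == e).astype(float))
        names.append(f"env:{data.environments[e]}")
    lr_of_obs = data.landrace_idx[data.line_idx]
    for j in range(1, L):
        cols.append((lr_of_obs == j).astype(float))
        names.append(f"landrace:{data.landraces[j]}")
    return np.column_stack(cols), names


def _full_rank(X: np.ndarray, rtol: float = 1e-9) -> bool:
    """Rank check on the Gram matrix (cheap for tall-skinny designs)."""
    G = X.T @ X
    w = np.linalg.eigvalsh(G)
    return bool(w[0] > rtol * max(w[-1], 1.0))


def _hap_columns(data: MultiEnvData, key: HapKey) -> tuple[np.ndarray, list[str]]:
    """E columns per haplotype: x_kq gated by environment, giving beta_q^i directly."""
    x = data.hap_scores[key][data.line_idx]
    E = len(data.environments)
    cols = np.zeros((len(x), E))
    for e in range(E):
        cols[:, e] = np.where(data.env_idx == e, x, 0.0)
    names = [f"hap{key[0]}:{key[1]}@{env}" for env in data.environments]
    return cols, names


@dataclass
class MultiEnvModel:
    trait: str
    environments: list[str]
    retained: list[HapKey]
    effects: pd.DataFrame  # window_id, hap_id, environment, beta, se, ci_lo, ci_hi, significant
    wald: pd.DataFrame  # window_id, hap_id, stat, df, p
    sigma_u2: float
    sigma_e2: np.ndarray
    fit: LMMFit
    trace: list[dict] = field(default_factory=list)


def fit_multienv(
    data: MultiEnvData,
    hap_keys: list[HapKey],
    trait: str = "",
    K: np.ndarray | None = None,
    ci_mult: float = 1.96,
) -> MultiEnvModel:
    """Fit the multi-environment model for a fixed haplotype set."""
    X0, names = _base_design(data)
    blocks, slices = [X0], {}
    kept = []
    for key in hap_keys:
        cols, cn = _hap_columns(data, key)
        cand = np.column_stack(blocks + [cols])
        if not _full_rank(cand):
            # later-entering collinear candidate dropped
            continue
        start = sum(b.shape[1] for b in blocks)
        slices[key] = slice(start, start + cols.shape[1])
        blocks.append(cols)
        names.extend(cn)
        kept.append(key)
    X = np.column_stack(blocks)

    model = HeteroLMM(data.line_idx, data.env_idx, len(data.lines),
                      len(data.environments), K=K)
    fit = model.fit(data.y, X)

    eff_rows, wald_rows = [], []
    for key in kept:
        sl = slices[key]
        b = fit.beta[sl]
        C = fit.beta_cov[sl, sl]
        stat, df, p = wald_joint_test(b, C)
        wald_rows.append({"window_id": key[0], "hap_id": key[1],
                          "stat": stat, "df": df, "p": p})
        se = np.sqrt(np.diag(C))
        for e, env in enumerate(data.environments):
            lo, hi = b[e] - ci_mult * se[e], b[e] + ci_mult * se[e]
            eff_rows.append({
                "window_id": key[0], "hap_id": key[1], "environment": env,
                "beta": float(b[e]), "se": float(se[e]),
                "ci_lo": float(lo), "ci_hi": float(hi),
                "significant": bool(lo > 0 or hi < 0),
            })
    cols_eff = ["window_id", "hap_id", "environment", "beta", "se", "ci_lo",
                "ci_hi", "significant"]
    cols_wald = ["window_id", "hap_id", "stat", "df", "p"]
    return MultiEnvModel(
        trait=trait,
        environments=list(data.environments),
        retained=kept,
        effects=pd.DataFrame(eff_rows, columns=cols_eff),
        wald=pd.DataFrame(wald_rows, columns=cols_wald),
        sigma_u2=fit.sigma_g2,
        sigma_e2=np.asarray(fit.sigma_e2),
        fit=fit,
    )


def assemble_candidates(
    region_tables: list[pd.DataFrame],
    matrix: HaplotypeMatrix,
    max_dist: int = 1_000_000,
    r2_min: float = 0.8,
) -> list[HapKey]:
    """Union of focus haplotypes over all scans of a trait, deduplicated so
    that foci marking the same region (< max_dist AND r^2 >= r2_min) keep
    only the one with the smaller discovery p."""
    foci = []
    for t in region_tables:
        for _, r in t.iterrows():
            foci.append({"window_id": int(r["focus_window"]), "hap_id": int(r["focus_hap"]),
                         "chrom": r["chrom"], "start_bp": int(r["start_bp"]),
                         "p": float(r["focus_p"])})
    if not foci:
        return []
    df = pd.DataFrame(foci).sort_values("p", kind="mergesort")
    df = df.drop_duplicates(["window_id", "hap_id"])
    info = matrix.info
    col_of = {(w, h): j for j, (w, h) in enumerate(zip(info["window_id"], info["hap_id"]))}
    kept: list[dict] = []
    for _, cand in df.iterrows():
        dup = False
        xc = matrix.scores[:, col_of[(cand["window_id"], cand["hap_id"])]].astype(float)
        for k in kept:
            if k["chrom"] != cand["chrom"]:
                continue
            if abs(k["start_bp"] - cand["start_bp"]) >= max_dist:
                continue
            xk = matrix.scores[:, col_of[(k["window_id"], k["hap_id"])]].astype(float)
            if marker_r2(xc, xk) >= r2_min:
                dup = True
                break
        if not dup:
            kept.append(dict(cand))
    return [(int(k["window_id"]), int(k["hap_id"])) for k in kept]


def backward_eliminate(
    data: MultiEnvData,
    candidates: list[HapKey],
    trait: str = "",
    p_threshold: float = 0.01,
    K: np.ndarray | None = None,
    min_count: int = 3,
) -> MultiEnvModel:
    """Step-wise backward elimination at the joint Wald test.

    Each step refits the full model (variance components included), tests
    every haplotype conditional on all others, and removes the single least
    significant one if its P >= threshold.
    """
    current = []
    for key in candidates:
        x = data.hap_scores[key]
        if min_count <= (x == 2).sum() and (x == 0).sum() >= 1:
            current.append(key)
    trace: list[dict] = []
    while True:
        model = fit_multienv(data, current, trait=trait, K=K)
        current = model.retained
        if not current:
            model.trace = trace
            return model
        worst = model.wald.sort_values("p", kind="mergesort").iloc[-1]
        trace.append({"step": len(trace), "n_haps": len(current),
                      "worst": (int(worst["window_id"]), int(worst["hap_id"])),
                      "worst_p": float(worst["p"])})
        if worst["p"] < p_threshold:
            model.trace = trace
            return model
        current = [k for k in current
                   if k != (int(worst["window_id"]), int(worst["hap_id"]))]


# ---------------------------------------------------------------------------
# Stability classification


def classify_stability(
    model: MultiEnvModel,
    direction: int | None,
) -> pd.DataFrame:
    """Label each retained haplotype favorable / unfavorable / interacting / none.

    ``direction``: +1 if positive effects are favorable for this trait, -1 if
    negative, None for traits with no breeding-direction convention (only
    significance counts are reported, label 'unclassified_direction' for
    stable patterns).
    """
    rows = []
    for key in model.retained:
        sub = model.effects[
            (model.effects["window_id"] == key[0]) & (model.effects["hap_id"] == key[1])
        ]
        sig = sub[sub["significant"]]
        n_sig = len(sig)
        if n_sig == 0:
            label = "none"
        else:
            signs = np.sign(sig["beta"].to_numpy())
            if np.all(signs > 0) or np.all(signs < 0):
                if direction is None:
                    label = "unclassified_direction"
                elif signs[0] * direction > 0:
                    label = "favorable"
                else:
                    label = "unfavorable"
            else:
                label = "interacting"
        rows.append({"window_id": key[0], "hap_id": key[1],
                     "n_significant_env": n_sig, "label": label})
    return pd.DataFrame(rows, columns=["window_id", "hap_id", "n_significant_env", "label"])


def variance_explained(
    data: MultiEnvData,
    hap_keys: list[HapKey],
    K: np.ndarray | None = None,
) -> float:
    """Relative reduction in REML genetic variance when haplotype effects are
    added: (su2_null - su2_full) / su2_null, floored at 0."""
    if not hap_keys:
        return 0.0
    null = fit_multienv(data, [], K=K)
    full = fit_multienv(data, hap_keys, K=K)
    if null.sigma_u2 <= 0:
        return 0.0
    return max(0.0, (null.sigma_u2 - full.sigma_u2) / null.sigma_u2)


# ---------------------------------------------------------------------------
# Landrace-specific effect stability


def landrace_effect_stability(
    data: MultiEnvData,
    hap_keys: list[HapKey],
    K: np.ndarray | None = None,
    min_count: int = 3,
    ci_mult: float = 1.96,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Refit with landrace-nested environment-specific haplotype effects.

    Haplotypes need >= min_count carriers in at least two landraces; others
    are excluded (logged with n_landraces = count of qualifying landraces).
    Returns (effects, pair summary): the per-(haplotype, environment,
    landrace) effects with CIs, and for each landrace pair the counts of
    environment effects significant in both/one/neither plus sign concordance.
    """
    X0, names = _base_design(data)
    lr_of_obs = data.landrace_idx[data.line_idx]
    L, E = len(data.landraces), len(data.environments)

    usable: dict[HapKey, list[int]] = {}
    for key in hap_keys:
        x = data.hap_scores[key]
        qual = [j for j in range(L)
                if (x[data.landrace_idx == j] == 2).sum() >= min_count
                and (x[data.landrace_idx == j] == 0).sum() >= 1]
        if len(qual) >= 2:
            usable[key] = qual

    blocks, meta = [X0], []
    for key, lrs in usable.items():
        x_obs = data.hap_scores[key][data.line_idx]
        for j in lrs:
            for e in range(E):
                col = np.where((data.env_idx == e) & (lr_of_obs == j), x_obs, 0.0)
                blocks.append(col[:, None])
                meta.append((key, data.landraces[j], data.environments[e]))
    X = np.column_stack(blocks)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise LMMError("landrace-nested design is rank deficient")
    model = HeteroLMM(data.line_idx, data.env_idx, len(data.lines), E, K=K)
    fit = model.fit(data.y, X)

    p0 = X0.shape[1]
    rows = []
    for i, (key, lr, env) in enumerate(meta):
        b = float(fit.beta[p0 + i])
        se = float(np.sqrt(fit.beta_cov[p0 + i, p0 + i]))
        rows.append({"window_id": key[0], "hap_id": key[1], "landrace": lr,
                     "environment": env, "beta": b, "se": se,
                     "ci_lo": b - ci_mult * se, "ci_hi": b + ci_mult * se,
                     "significant": bool(b - ci_mult * se > 0 or b + ci_mult * se < 0)})
    effects = pd.DataFrame(rows)

    pair_rows = []
    if not effects.empty:
        for (w, h), grp in effects.groupby(["window_id", "hap_id"]):
            lrs = sorted(grp["landrace"].unique())
            for a_i in range(len(lrs)):
                for b_i in range(a_i + 1, len(lrs)):
                    a = grp[grp["landrace"] == lrs[a_i]].set_index("environment")
                    b = grp[grp["landrace"] == lrs[b_i]].set_index("environment")
                    envs = sorted(set(a.index) & set(b.index))
                    both = one = neither = concord_both = concord_any = any_sig = 0
                    for env in envs:
                        sa, sb = bool(a.loc[env, "significant"]), bool(b.loc[env, "significant"])
                        same = np.sign(a.loc[env, "beta"]) == np.sign(b.loc[env, "beta"])
                        if sa and sb:
                            both += 1
                            concord_both += int(same)
                        elif sa or sb:
                            one += 1
                        else:
                            neither += 1
                        if sa or sb:
                            any_sig += 1
                            concord_any += int(same)
                    pair_rows.append({
                        "window_id": w, "hap_id": h,
                        "landrace_a": lrs[a_i], "landrace_b": lrs[b_i],
                        "n_env": len(envs), "sig_both": both, "sig_one": one,
                        "sig_neither": neither,
                        "concordant_of_both": concord_both,
                        "concordant_of_any_sig": concord_any,
                        "n_any_sig": any_sig,
                    })
    summary = pd.DataFrame(pair_rows)
    return effects, summary
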