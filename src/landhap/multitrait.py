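"""Bivariate mixed model for cross-trait haplotype effects and the
focus-vs-alternative window contrast.

The bivariate model stacks two traits observed on the same lines in the same
environments:

    y_tijk = mu_t + omega_ti + delta_tj + x_k beta_t + u_tk + e_tijk

with u ~ N(0, G (x) K) and e ~ N(0, E (x) I) (Kronecker covariances over the
trait dimension). For balanced line-by-environment layouts the likelihood
factorizes through the eigenbasis of K and the Helmert basis of the
environment-mean projector, leaving independent 2x2 trait blocks; REML runs
over the Cholesky factors of G and E, which enforces positive
semidefiniteness by construction. Residual covariance between traits acts
within a (line, environment) observation and observations are independent,
with environments as fixed effects per trait.

The window contrast extends the multi-environment model with a categorical
window-haplotype factor (focus haplotype = reference), so every alternative
haplotype gets per-environment effects relative to the focus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .lmm import LOG2PI, LMMError
from .multienv import MultiEnvData, _base_design, fit_multienv
from .types import ACROSS_ENV, HaplotypeMatrix, PhenotypeTable


def _helmert(E: int) -> np.ndarray:
    """Orthonormal basis whose first column is the normalized environment mean."""
    Q = np.zeros((E, E))
    Q[:, 0] = 1.0 / np.sqrt(E)
    for j in range(1, E):
        Q[:j, j] = 1.0
        Q[j, j] = -j
        Q[:, j] /= np.sqrt(j * (j + 1))
    return Q


class KroneckerTraitLMM:
    """REML for T traits with u ~ N(0, G x K) and e ~ N(0, E x I), balanced."""

    def __init__(self, K: np.ndarray, n_env: int, n_traits: int = 2):
        s, U = np.linalg.eigh(np.asarray(K, float))
        self.s = np.clip(s, 0.0, None)
        self.U = U
        self.n = K.shape[0]
        self.E = n_env
        self.T = n_traits
        self.Q = _helmert(n_env)

    # data enters as Y: (T, n, E), X: (T, n, E, p)

    def rotate(self, Y: np.ndarray, X: np.ndarray):
        Yr = np.einsum("nk,tne,ej->tkj", self.U, Y, self.Q)
        Xr = np.einsum("nk,tnep,ej->tkjp", self.U, X, self.Q)
        return Yr, Xr

    def _pieces(self, G: np.ndarray, Ecov: np.ndarray, Yr: np.ndarray, Xr: np.ndarray):
        T, n, E = self.T, self.n, self.E
        # group A: env-mean direction, per-line blocks  s_k * E * G + Ecov
        MA = self.s[:, None, None] * E * G[None] + Ecov[None]  # (n, T, T)
        signA, logdetA = np.linalg.slogdet(MA)
        if np.any(signA <= 0):
            return None
        MAinv = np.linalg.inv(MA)
        yA = np.moveaxis(Yr[:, :, 0], 0, 1)  # (n, T)
        xA = np.moveaxis(Xr[:, :, 0, :], 0, 1)  # (n, T, p)
        xtvx = np.einsum("ntp,nts,nsq->pq", xA, MAinv, xA)
        xtvy = np.einsum("ntp,nts,ns->p", xA, MAinv, yA)
        ytvy = float(np.einsum("nt,nts,ns->", yA, MAinv, yA))
        logdet_v = float(logdetA.sum())
        if E > 1:
            signB, logdetB = np.linalg.slogdet(Ecov)
            if signB <= 0:
                return None
            MBinv = np.linalg.inv(Ecov)
            yB = np.moveaxis(Yr[:, :, 1:], 0, 2).reshape(-1, T)  # (n*(E-1), T)
            xB = np.moveaxis(Xr[:, :, 1:, :], 0, 2).reshape(-1, T, Xr.shape[-1])
            xtvx += np.einsum("ntp,ts,nsq->pq", xB, MBinv, xB)
            xtvy += np.einsum("ntp,ts,ns->p", xB, MBinv, yB)
            ytvy += float(np.einsum("nt,ts,ns->", yB, MBinv, yB))
            logdet_v += n * (E - 1) * float(logdetB)
        return xtvx, xtvy, ytvy, logdet_v

    def loglik_reml_at(self, G, Ecov, Yr, Xr) -> float:
        pieces = self._pieces(G, Ecov, Yr, Xr)
        if pieces is None:
            return -1e12
        xtvx, xtvy, ytvy, logdet_v = pieces
        sign, logdet_x = np.linalg.slogdet(xtvx)
        if sign <= 0:
            return -1e12
        beta = np.linalg.solve(xtvx, xtvy)
        ytpy = ytvy - float(xtvy @ beta)
        N, p = self.T * self.n * self.E, Xr.shape[-1]
        return -0.5 * ((N - p) * LOG2PI + logdet_v + logdet_x + ytpy)

    def fit(self, Y: np.ndarray, X: np.ndarray, force_zero_cov: bool = False):
        Yr, Xr = self.rotate(Y, X)
        T = self.T
        vy = np.var(Y.reshape(T, -1), axis=1)
        n_off = 0 if force_zero_cov else T * (T - 1) // 2

        def unpack(theta):
            def chol(diag_log, off):
                L = np.zeros((T, T))
                L[np.diag_indices(T)] = np.exp(np.clip(diag_log, -30.0, 30.0))
                if off is not None and len(off):
                    L[np.tril_indices(T, -1)] = off
                return L @ L.T

            g_diag = theta[:T]
            e_diag = theta[T: 2 * T]
            g_off = theta[2 * T: 2 * T + n_off]
            e_off = theta[2 * T + n_off:]
            return chol(g_diag, g_off), chol(e_diag, e_off)

        start = np.concatenate([
            0.5 * np.log(np.maximum(vy / 2, 1e-8)),
            0.5 * np.log(np.maximum(vy / 2, 1e-8)),
            np.zeros(2 * n_off),
        ])

        def neg(theta):
            G, Ecov = unpack(theta)
            return -self.loglik_reml_at(G, Ecov, Yr, Xr)

        res = optimize.minimize(neg, start, method="L-BFGS-B",
                                options={"maxiter": 400, "ftol": 1e-11})
        G, Ecov = unpack(res.x)
        pieces = self._pieces(G, Ecov, Yr, Xr)
        xtvx, xtvy, _, _ = pieces
        cov = np.linalg.inv(xtvx)
        beta = cov @ xtvy
        return beta, (cov + cov.T) / 2.0, G, Ecov, float(-res.fun), bool(res.success)


@dataclass
class BivariateFit:
    traits: tuple[str, str]
    beta: np.ndarray  # per trait
    se: np.ndarray
    ci: np.ndarray  # (2, 2) rows per trait: lo, hi
    G: np.ndarray
    Ecov: np.ndarray
    significant_both: bool
    varexp: np.ndarray  # per trait, relative reduction of diag(G)
    loglik: float
    converged: bool = True
    extra: dict = field(default_factory=dict)


def _bivariate_arrays(
    pheno: PhenotypeTable, traits: tuple[str, str], x_line: np.ndarray,
    lines: list[str], populations: dict[str, str],
):
    t = pheno.table
    envs = None
    Ys = []
    for trait in traits:
        sub = t[(t["trait"] == trait) & (t["environment"] != ACROSS_ENV)]
        piv = sub.pivot(index="line", columns="environment", values="value")
        piv = piv.loc[[l for l in lines if l in piv.index]]
        if piv.isna().any().any():
            warnings.warn("unbalanced phenotypes: subsetting to complete cases")
            piv = piv.dropna()
        if envs is None:
            envs = list(piv.columns)
        Ys.append(piv)
    common = [l for l in lines if all(l in Y.index for Y in Ys)]
    if not common:
        raise LMMError("no overlapping lines between the two traits")
    idx = [lines.index(l) for l in common]
    Y = np.stack([Y.loc[common].to_numpy(float) for Y in Ys])  # (2, n, E)
    x = x_line[idx]
    landraces = sorted({populations[l] for l in common})
    lr = np.array([landraces.index(populations[l]) for l in common])
    return Y, x, common, envs, lr, len(landraces), idx


def _design_tensor(n, E, L, lr_idx, x=None, extra_cols=None):
    """Per-trait design as (n, E, p): intercept, env, landrace, [haplotype, extras]."""
    cols = [np.ones((n, E))]
    for e in range(1, E):
        c = np.zeros((n, E))
        c[:, e] = 1.0
        cols.append(c)
    for j in range(1, L):
        cols.append(np.tile((lr_idx == j).astype(float)[:, None], (1, E)))
    if x is not None:
        cols.append(np.tile(np.asarray(x, float)[:, None], (1, E)))
    if extra_cols is not None:
        cols.extend(extra_cols)
    return np.stack(cols, axis=-1)  # (n, E, p)


def bivariate_haplotype_test(
    pheno: PhenotypeTable,
    traits: tuple[str, str],
    x_line: np.ndarray,
    lines: list[str],
    populations: dict[str, str],
    K: np.ndarray,
    ci_mult: float = 1.96,
    force_zero_cov: bool = False,
) -> BivariateFit:
    """Fit the bivariate model for one haplotype and flag significance on both
    traits (both 95% CIs excluding 0); variance explained per trait is the
    relative reduction of that trait's diagonal of G versus the no-haplotype fit."""
    Y, x, common, envs, lr, L, idx = _bivariate_arrays(
        pheno, traits, np.asarray(x_line, float), lines, populations
    )
    n, E = Y.shape[1], Y.shape[2]
    Ksub = K[np.ix_(idx, idx)]
    model = KroneckerTraitLMM(Ksub, E, n_traits=2)

    Xt = _design_tensor(n, E, L, lr, x=x)  # (n, E, p_t)
    p_t = Xt.shape[-1]
    X = np.zeros((2, n, E, 2 * p_t))
    X[0, :, :, :p_t] = Xt
    X[1, :, :, p_t:] = Xt
    beta, cov, G, Ecov, ll, ok = model.fit(Y, X, force_zero_cov=force_zero_cov)

    hap_pos = np.array([p_t - 1, 2 * p_t - 1])
    b = beta[hap_pos]
    se = np.sqrt(np.diag(cov)[hap_pos])
    ci = np.column_stack([b - ci_mult * se, b + ci_mult * se])
    sig_both = bool(np.all((ci[:, 0] > 0) | (ci[:, 1] < 0)))

    # null fit (haplotype removed) for the G reduction
    X0t = _design_tensor(n, E, L, lr, x=None)
    p0 = X0t.shape[-1]
    X0 = np.zeros((2, n, E, 2 * p0))
    X0[0, :, :, :p0] = X0t
    X0[1, :, :, p0:] = X0t
    _, _, G0, _, _, _ = model.fit(Y, X0, force_zero_cov=force_zero_cov)
    with np.errstate(divide="ignore", invalid="ignore"):
        ve = np.where(np.diag(G0) > 0,
                      np.clip((np.diag(G0) - np.diag(G)) / np.diag(G0), 0, 1), 0.0)
    return BivariateFit(traits=traits, beta=b, se=se, ci=ci, G=G, Ecov=Ecov,
                        significant_both=sig_both, varexp=ve, loglik=ll, converged=ok,
                        extra={"n_lines": n, "environments": envs})


def univariate_env_fit(
    pheno: PhenotypeTable, trait: str, x_line: np.ndarray, lines: list[str],
    populations: dict[str, str], K: np.ndarray, ci_mult: float = 1.96,
):
    """Single-trait counterpart of the bivariate model (same Kronecker path,
    T = 1): used as its own fit and as the cross-check that the bivariate
    model with zero covariances decouples."""
    Y, x, common, envs, lr, L, idx = _bivariate_arrays(
        pheno, (trait, trait), np.asarray(x_line, float), lines, populations
    )
    Y = Y[:1]
    n, E = Y.shape[1], Y.shape[2]
    model = KroneckerTraitLMM(K[np.ix_(idx, idx)], E, n_traits=1)
    Xt = _design_tensor(n, E, L, lr, x=x)[None]  # (1, n, E, p)
    beta, cov, G, Ecov, ll, ok = model.fit(Y, Xt)
    j = Xt.shape[-1] - 1
    b, se = float(beta[j]), float(np.sqrt(cov[j, j]))
    return {"beta": b, "se": se, "ci": (b - ci_mult * se, b + ci_mult * se),
            "G": float(G[0, 0]), "Ecov": float(Ecov[0, 0]), "loglik": ll}


# ---------------------------------------------------------------------------
# Focus-vs-alternative window contrast


@dataclass
class ContrastFit:
    window_id: int
    focus_hap: int
    effects: pd.DataFrame  # hap level x environment relative to focus
    varexp_vs_empty: float
    varexp_vs_background: float
    sigma_u2: float


def window_contrast(
    data: MultiEnvData,
    matrix: HaplotypeMatrix,
    window_id: int,
    focus_hap: int,
    background: list[tuple[int, int]],
    K: np.ndarray | None = None,
    min_count: int = 3,
    ci_mult: float = 1.96,
) -> ContrastFit:
    """Per-environment effects of each alternative window haplotype relative to
    the focus haplotype, with the retained trait haplotypes (minus the focus)
    as background fixed effects.

    Alternatives with fewer than ``min_count`` carriers are pooled into one
    'rare' level. Variance explained by the window is reported against two
    nulls (spec ambiguity documented in the methods note): a model with no
    haplotype terms at all, and a model with only the background terms.
    """
    info = matrix.info
    in_win = np.flatnonzero(info["window_id"].to_numpy() == window_id)
    if len(in_win) == 0:
        raise ValueError(f"window {window_id} not in haplotype matrix")
    mat_pos = {l: i for i, l in enumerate(matrix.lines)}
    row_sel = np.array([mat_pos[l] for l in data.lines])
    scores = matrix.scores[np.ix_(row_sel, in_win)]
    hap_ids = info["hap_id"].to_numpy()[in_win]

    present = scores.sum(axis=0) > 0
    if focus_hap not in hap_ids[present]:
        raise ValueError("focus haplotype absent from the analysed lines")
    if present.sum() < 2:
        raise LMMError("window has a single haplotype among analysed lines: no contrast")

    levels: dict[str, np.ndarray] = {}
    for j, h in enumerate(hap_ids):
        if not present[j] or h == focus_hap:
            continue
        x = scores[:, j].astype(float)
        if (x == 2).sum() < min_count:
            levels["rare"] = levels.get("rare", np.zeros(len(x))) + x
        else:
            levels[f"hap{h}"] = x

    bg = [k for k in background if k != (window_id, focus_hap)]
    X0, names = _base_design(data)
    blocks = [X0]
    for key in bg:
        x = data.hap_scores[key][data.line_idx]
        E = len(data.environments)
        cols = np.zeros((len(x), E))
        for e in range(E):
            cols[:, e] = np.where(data.env_idx == e, x, 0.0)
        blocks.append(cols)
    p_bg_end = sum(b.shape[1] for b in blocks)

    level_names = sorted(levels)
    E = len(data.environments)
    meta = []
    for name in level_names:
        x_obs = levels[name][data.line_idx]
        cols = np.zeros((len(x_obs), E))
        for e in range(E):
            cols[:, e] = np.where(data.env_idx == e, x_obs, 0.0)
        blocks.append(cols)
        meta.extend((name, env) for env in data.environments)
    X = np.column_stack(blocks)

    from .lmm import HeteroLMM

    model = HeteroLMM(data.line_idx, data.env_idx, len(data.lines), E, K=K)
    fit = model.fit(data.y, X)

    rows = []
    for i, (name, env) in enumerate(meta):
        j = p_bg_end + i
        b = float(fit.beta[j])
        se = float(np.sqrt(fit.beta_cov[j, j]))
        rows.append({"level": name, "environment": env, "beta": b, "se": se,
                     "ci_lo": b - ci_mult * se, "ci_hi": b + ci_mult * se,
                     "significant": bool(b - ci_mult * se > 0 or b + ci_mult * se < 0)})
    effects = pd.DataFrame(rows)

    empty = fit_multienv(data, [], K=K)
    bg_only = fit_multienv(data, bg, K=K)
    ve_empty = max(0.0, (empty.sigma_u2 - fit.sigma_g2) / empty.sigma_u2) \
        if empty.sigma_u2 > 0 else 0.0
    ve_bg = max(0.0, (bg_only.sigma_u2 - fit.sigma_g2) / bg_only.sigma_u2) \
        if bg_only.sigma_u2 > 0 else 0.0
    return ContrastFit(window_id=window_id, focus_hap=focus_hap, effects=effects,
                       varexp_vs_empty=ve_empty, varexp_vs_background=ve_bg,
                       sigma_u2=fit.sigma_g2)
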