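"""REML/ML machinery for single-kinship linear mixed models.

Two model families are covered:

* the single-observation-per-line model
  ``y = X beta + u + e``, ``u ~ N(0, K sigma_g^2)``, ``e ~ N(0, I sigma^2)``,
  fit through one eigendecomposition of K and a 1-D profile over the
  variance ratio (the standard EMMA spectral path); and

* the stacked multi-environment model with one observation per
  (line, environment) cell, a single random line effect (iid by default,
  kinship-structured on request) and environment-specific residual
  variances, fit by quasi-Newton on log-variances. Its likelihood uses the
  Woodbury identity / matrix determinant lemma, which is O(N) for the iid
  line effect and needs one n_lines x n_lines solve per evaluation with a
  kinship covariance.

Fixed effects are always generalized least squares at the estimated
variance components; Wald and likelihood-ratio helpers live here too.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize, stats

LOG2PI = float(np.log(2.0 * np.pi))


class LMMError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Kinship


def compute_kinship(geno: np.ndarray, min_maf: float = 0.0) -> np.ndarray:
    """Genomic relationship matrix from 0/2-coded markers.

    K = (1/m) sum_i (x_i - 2 p_i)(x_i - 2 p_i)^T / (2 p_i (1 - p_i)) with
    p_i the allele frequency of marker i. Monomorphic markers are dropped
    (they carry no relatedness information and would divide by zero). For
    fully homozygous lines the diagonal sits near 2.
    """
    X = np.asarray(geno, dtype=float)
    p = X.mean(axis=0) / 2.0
    keep = (p > min_maf) & (p < 1.0 - min_maf)
    n_dropped = int((~keep).sum())
    if n_dropped == X.shape[1]:
        raise LMMError("no polymorphic markers available for kinship")
    if n_dropped:
        X = X[:, keep]
        p = p[keep]
    Z = (X - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    K = Z @ Z.T / Z.shape[1]
    return (K + K.T) / 2.0


def check_psd(K: np.ndarray, tol: float = 1e-8) -> None:
    w = np.linalg.eigvalsh(K)
    if w.min() < -tol * max(1.0, w.max()):
        raise LMMError(f"kinship not positive semi-definite (min eigenvalue {w.min():.3g})")


# ---------------------------------------------------------------------------
# Spectral single-environment fit


@dataclass
class LMMFit:
    beta: np.ndarray
    beta_cov: np.ndarray
    sigma_g2: float
    sigma_e2: np.ndarray  # scalar array for homoscedastic, per-env vector otherwise
    loglik_ml: float
    loglik_reml: float
    converged: bool = True
    boundary: bool = False
    n_iter: int = 0
    extra: dict = field(default_factory=dict)

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.beta_cov))


class SpectralLMM:
    """Eigendecomposition-backed fit of y = X beta + u + e with u ~ N(0, K sg2).

    The decomposition of K is done once and reused across markers/phenotype
    vectors, which is what makes genome scans cheap.
    """

    def __init__(self, K: np.ndarray, check: bool = True):
        K = np.asarray(K, dtype=float)
        if check:
            check_psd(K)
        s, U = np.linalg.eigh(K)
        self.s = np.clip(s, 0.0, None)
        self.U = U
        self.n = K.shape[0]

    def rotate(self, A: np.ndarray) -> np.ndarray:
        return self.U.T @ A

    # -- profiled likelihoods at variance ratio delta = sg2 / se2 ----------

    def _profile(self, delta: float, yr: np.ndarray, Xr: np.ndarray):
        """Weighted LS at V = se2 (delta K + I); returns pieces for both ML and REML."""
        w = 1.0 / (delta * self.s + 1.0)
        Xw = Xr * w[:, None]
        XtWX = Xr.T @ Xw
        XtWy = Xw.T @ yr
        beta = np.linalg.solve(XtWX, XtWy)
        r = yr - Xr @ beta
        rss = float(r @ (w * r))
        logdet_v = float(-np.log(w).sum())
        sign, logdet_xwx = np.linalg.slogdet(XtWX)
        if sign <= 0:
            raise LMMError("X'V^{-1}X not positive definite: rank-deficient design")
        return beta, XtWX, rss, logdet_v, logdet_xwx

    def loglik_ml(self, delta: float, yr: np.ndarray, Xr: np.ndarray) -> float:
        n = self.n
        _, _, rss, logdet_v, _ = self._profile(delta, yr, Xr)
        s2 = rss / n
        return -0.5 * (n * LOG2PI + n * np.log(s2) + logdet_v + n)

    def loglik_reml(self, delta: float, yr: np.ndarray, Xr: np.ndarray) -> float:
        n, p = self.n, Xr.shape[1]
        _, _, rss, logdet_v, logdet_xwx = self._profile(delta, yr, Xr)
        s2 = rss / (n - p)
        return -0.5 * ((n - p) * (LOG2PI + np.log(s2) + 1.0) + logdet_v + logdet_xwx)

    def loglik_ml_at(self, sigma_g2: float, sigma_e2: float, y: np.ndarray, X: np.ndarray) -> float:
        """Exact ML log-density at given variance components (no profiling)."""
        yr, Xr = self.rotate(y), self.rotate(X)
        d = sigma_g2 * self.s + sigma_e2
        beta = np.linalg.solve(Xr.T @ (Xr / d[:, None]), Xr.T @ (yr / d))
        r = yr - Xr @ beta
        return -0.5 * (self.n * LOG2PI + np.log(d).sum() + float(r @ (r / d)))

    def loglik_reml_at(self, sigma_g2: float, sigma_e2: float, y: np.ndarray, X: np.ndarray) -> float:
        """REML log-likelihood at given variance components.

        Convention: -1/2 [ (n-p) log 2pi + log|V| + log|X'V^{-1}X| + y'Py ].
        """
        yr, Xr = self.rotate(y), self.rotate(X)
        d = sigma_g2 * self.s + sigma_e2
        XtWX = Xr.T @ (Xr / d[:, None])
        beta = np.linalg.solve(XtWX, Xr.T @ (yr / d))
        r = yr - Xr @ beta
        _, logdet_xwx = np.linalg.slogdet(XtWX)
        return -0.5 * (
            (self.n - Xr.shape[1]) * LOG2PI + np.log(d).sum() + logdet_xwx + float(r @ (r / d))
        )

    def fit(
        self,
        y: np.ndarray,
        X: np.ndarray,
        method: str = "reml",
        n_grid: int = 64,
        log_delta_range: tuple[float, float] = (-9.0, 9.0),
    ) -> LMMFit:
        y = np.asarray(y, float)
        X = np.atleast_2d(np.asarray(X, float))
        if X.shape[0] != self.n:
            raise LMMError("y/X not aligned with kinship")
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise LMMError(_name_aliased(X))
        yr, Xr = self.rotate(y), self.rotate(X)
        ll = self.loglik_reml if method == "reml" else self.loglik_ml

        lo, hi = log_delta_range
        grid = np.linspace(lo, hi, n_grid)
        vals = np.array([ll(10.0**g, yr, Xr) for g in grid])
        i = int(np.argmax(vals))
        a, b = grid[max(i - 1, 0)], grid[min(i + 1, n_grid - 1)]
        res = optimize.minimize_scalar(
            lambda g: -ll(10.0**g, yr, Xr),
            bounds=(a, b),
            method="bounded",
            options={"xatol": 1e-10},
        )
        log_delta = float(res.x) if -res.fun >= vals[i] else float(grid[i])
        delta = 10.0**log_delta

        beta, XtWX, rss, _, _ = self._profile(delta, yr, Xr)
        n, p = self.n, X.shape[1]
        s2 = rss / (n - p) if method == "reml" else rss / n
        boundary = log_delta <= lo + 1e-6 or log_delta >= hi - 1e-6
        sigma_e2, sigma_g2 = s2, delta * s2
        beta_cov = np.linalg.inv(XtWX) * s2
        return LMMFit(
            beta=beta,
            beta_cov=beta_cov,
            sigma_g2=sigma_g2,
            sigma_e2=np.array([sigma_e2]),
            loglik_ml=self.loglik_ml(delta, yr, Xr),
            loglik_reml=self.loglik_reml(delta, yr, Xr),
            boundary=boundary,
            extra={"delta": delta},
        )


def reml_fit(y: np.ndarray, X: np.ndarray, K: np.ndarray) -> LMMFit:
    """One-shot REML fit of the single-kinship model (convenience wrapper)."""
    return SpectralLMM(K).fit(y, X, method="reml")


def _name_aliased(X: np.ndarray) -> str:
    _, r = np.linalg.qr(X)
    aliased = [j for j in range(X.shape[1]) if abs(r[j, j]) < 1e-10 * max(1.0, abs(r[0, 0]))]
    return f"rank-deficient design: aliased columns {aliased}"


# ---------------------------------------------------------------------------
# Stacked heteroscedastic multi-environment fit


class HeteroLMM:
    """y_obs = X beta + Z u + e with env-specific residual variances.

    Parameters
    ----------
    line_idx : int array mapping each observation to a line (0..n_lines-1)
    env_idx : int array mapping each observation to an environment (0..E-1)
    K : optional line-level covariance of u; None means iid (identity)
    """

    def __init__(self, line_idx: np.ndarray, env_idx: np.ndarray, n_lines: int, n_env: int,
                 K: np.ndarray | None = None):
        self.line_idx = np.asarray(line_idx, int)
        self.env_idx = np.asarray(env_idx, int)
        self.n_obs = len(self.line_idx)
        self.n_lines = n_lines
        self.n_env = n_env
        counts = np.bincount(self.env_idx, minlength=n_env)
        if (counts < 2).any():
            raise LMMError("every environment needs at least 2 observations")
        self.K = None if K is None else np.asarray(K, float)
        self._chol_k = None
        if self.K is not None:
            check_psd(self.K)
            # jitter guards the Cholesky of a PSD-but-singular K
            self.K = self.K + 1e-9 * np.eye(n_lines) * np.trace(self.K) / n_lines
            self._chol_k = np.linalg.cholesky(self.K)
        # grouped observation order for fast per-line sums (add.reduceat)
        self._order = np.argsort(self.line_idx, kind="stable")
        sorted_lines = self.line_idx[self._order]
        first = np.flatnonzero(np.diff(sorted_lines, prepend=-1))
        self._group_starts = first
        self._group_lines = sorted_lines[first]

    # -- Woodbury pieces ----------------------------------------------------

    def _vinv_apply(self, su2: float, se2: np.ndarray, B: np.ndarray):
        """Return V^{-1} B and log|V| via the Woodbury identity.

        V = su2 Z A Z' + D with D = diag(se2[env]) and A = I or K.
        V^{-1} = D^{-1} - D^{-1} Z M^{-1} Z' D^{-1},  M = A^{-1}/su2 + Z'D^{-1}Z.
        """
        d = se2[self.env_idx]
        Dinv_B = B / d[:, None]
        # Z' D^{-1} B  (sum rows per line, via grouped reduceat)
        ZtDinvB = np.zeros((self.n_lines, B.shape[1]))
        ZtDinvB[self._group_lines] = np.add.reduceat(
            Dinv_B[self._order], self._group_starts, axis=0
        )
        m_diag = np.bincount(self.line_idx, weights=1.0 / d, minlength=self.n_lines)
        if self.K is None:
            M_diag = 1.0 / su2 + m_diag
            core = ZtDinvB / M_diag[:, None]
            logdet = float(np.log(d).sum() + np.log(su2 * m_diag + 1.0).sum())
        else:
            # Cholesky form avoids K^{-1}: with Zt = Z L (K = L L'),
            # V^{-1} = D^{-1} - D^{-1} Zt su2 (I + su2 Zt' D^{-1} Zt)^{-1} Zt' D^{-1}
            L = self._chol_k
            S = (L.T * m_diag) @ L  # Zt' D^{-1} Zt
            M = np.eye(self.n_lines) + su2 * S
            cho = linalg.cho_factor(M, lower=True)
            core = L @ (su2 * linalg.cho_solve(cho, L.T @ ZtDinvB))
            logdet_m = 2.0 * np.log(np.diag(cho[0])).sum()
            logdet = float(np.log(d).sum() + logdet_m)
        VinvB = Dinv_B - core[self.line_idx] / d[:, None]
        return VinvB, logdet

    # -- likelihoods ---------------------------------------------------------

    def loglik_reml_at(self, su2: float, se2: np.ndarray, y: np.ndarray, X: np.ndarray) -> float:
        return self._reml_from_yb(su2, se2, np.column_stack([y, X]))

    def _reml_from_yb(self, su2: float, se2: np.ndarray, YB: np.ndarray) -> float:
        y, X = YB[:, 0], YB[:, 1:]
        VinvYB, logdet_v = self._vinv_apply(su2, se2, YB)
        Vinv_y, Vinv_X = VinvYB[:, 0], VinvYB[:, 1:]
        XtVinvX = X.T @ Vinv_X
        XtVinvy = X.T @ Vinv_y
        try:
            cho = linalg.cho_factor(XtVinvX)
        except linalg.LinAlgError as err:
            raise LMMError("rank-deficient design in heteroscedastic fit") from err
        beta = linalg.cho_solve(cho, XtVinvy)
        ytPy = float(y @ Vinv_y - XtVinvy @ beta)
        logdet_xvx = 2.0 * np.log(np.diag(cho[0])).sum()
        n, p = self.n_obs, X.shape[1]
        return -0.5 * ((n - p) * LOG2PI + logdet_v + logdet_xvx + ytPy)

    def loglik_ml_at(self, su2: float, se2: np.ndarray, y: np.ndarray, X: np.ndarray) -> float:
        YB = np.column_stack([y, X])
        VinvYB, logdet_v = self._vinv_apply(su2, se2, YB)
        Vinv_y, Vinv_X = VinvYB[:, 0], VinvYB[:, 1:]
        XtVinvX = X.T @ Vinv_X
        beta = np.linalg.solve(XtVinvX, X.T @ Vinv_y)
        r_quad = float(y @ Vinv_y - (X.T @ Vinv_y) @ beta)
        return -0.5 * (self.n_obs * LOG2PI + logdet_v + r_quad)

    def fit(
        self,
        y: np.ndarray,
        X: np.ndarray,
        max_iter: int = 200,
        tol: float = 1e-6,
        start: np.ndarray | None = None,
    ) -> LMMFit:
        """REML over (sigma_u^2, sigma_e1^2 .. sigma_eE^2) on the log scale."""
        y = np.asarray(y, float)
        X = np.asarray(X, float)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise LMMError(_name_aliased(X))
        vy = float(np.var(y))
        if vy <= 0:
            vy = 1.0
        floor = np.log(1e-8 * vy)
        ceil = np.log(1e4 * vy)
        if start is None:
            start = np.full(1 + self.n_env, np.log(vy / 2.0))
        else:
            start = np.clip(np.log(start), floor, ceil)

        YB = np.column_stack([y, X])

        def neg(theta: np.ndarray) -> float:
            su2 = float(np.exp(theta[0]))
            se2 = np.exp(theta[1:])
            return -self._reml_from_yb(su2, se2, YB)

        res = optimize.minimize(
            neg,
            start,
            method="L-BFGS-B",
            bounds=[(floor, ceil)] * (1 + self.n_env),
            options={"maxiter": max_iter, "ftol": tol * 1e-3, "gtol": 1e-7},
        )
        if not res.success and res.nit >= max_iter:
            raise LMMError(f"heteroscedastic REML did not converge: {res.message}")
        su2 = float(np.exp(res.x[0]))
        se2 = np.exp(res.x[1:])
        boundary = bool(np.any(res.x <= floor + 1e-6) or np.any(res.x >= ceil - 1e-6))

        VinvYB, _ = self._vinv_apply(su2, se2, np.column_stack([y, X]))
        Vinv_y, Vinv_X = VinvYB[:, 0], VinvYB[:, 1:]
        XtVinvX = X.T @ Vinv_X
        beta_cov = np.linalg.inv(XtVinvX)
        beta = beta_cov @ (X.T @ Vinv_y)
        return LMMFit(
            beta=beta,
            beta_cov=(beta_cov + beta_cov.T) / 2.0,
            sigma_g2=su2,
            sigma_e2=se2,
            loglik_ml=self.loglik_ml_at(su2, se2, y, X),
            loglik_reml=float(-res.fun),
            converged=bool(res.success),
            boundary=boundary,
            n_iter=int(res.nit),
        )


def reml_fit_hetero(
    y: np.ndarray,
    X: np.ndarray,
    line_idx: np.ndarray,
    env_idx: np.ndarray,
    n_lines: int,
    n_env: int,
    K: np.ndarray | None = None,
) -> LMMFit:
    """Convenience wrapper for the stacked heteroscedastic model."""
    return HeteroLMM(line_idx, env_idx, n_lines, n_env, K=K).fit(y, X)


# ---------------------------------------------------------------------------
# GLS / tests


def gls_effects(y: np.ndarray, X: np.ndarray, Vinv: np.ndarray):
    """beta = (X'V^{-1}X)^{-1} X'V^{-1} y with cov(beta) = (X'V^{-1}X)^{-1}."""
    XtVinv = X.T @ Vinv
    cov = np.linalg.inv(XtVinv @ X)
    beta = cov @ (XtVinv @ y)
    return beta, (cov + cov.T) / 2.0


def lrt_pvalue(loglik_null: float, loglik_alt: float, df: int = 1) -> float:
    """Likelihood-ratio p from chi-square(df); negative statistics clip to 0."""
    stat = 2.0 * (loglik_alt - loglik_null)
    if stat < 0:
        if stat < -1e-6:
            warnings.warn(
                f"negative LRT statistic {stat:.3g} clipped to 0 (numerical)", RuntimeWarning
            )
        stat = 0.0
    return float(stats.chi2.sf(stat, df))


def wald_joint_test(beta_sub: np.ndarray, cov_sub: np.ndarray):
    """Joint Wald test of a coefficient block: stat = b' C^{-1} b ~ chi2(len(b))."""
    beta_sub = np.atleast_1d(np.asarray(beta_sub, float))
    cov_sub = np.atleast_2d(np.asarray(cov_sub, float))
    stat = float(beta_sub @ np.linalg.solve(cov_sub, beta_sub))
    df = len(beta_sub)
    return stat, df, float(stats.chi2.sf(stat, df))
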