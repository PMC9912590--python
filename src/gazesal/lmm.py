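"""Linear mixed models with crossed random intercepts and Satterthwaite tests.

The analysis model is ``y = X b + Z_1 u_1 + ... + Z_m u_m + e`` with
independent random intercepts per grouping factor (here: participant and
scene) and i.i.d. residuals.  Estimation is profiled REML (or ML for model
comparisons) over the variance ratios ``lambda_f = sigma_f^2 / sigma_e^2``;
all linear algebra runs through the q x q capacitance matrix
``K = I + D Z'Z D`` (D = diag(sqrt(lambda))), so a fit costs
O(q^3 + p^2 q) per likelihood evaluation regardless of the number of
observations.

Denominator degrees of freedom for fixed-effect F tests use Satterthwaite's
approximation: for a contrast L, ``df = 2 f^2 / (g' A g)`` where
``f = L C(theta) L'`` is the contrast variance, ``g`` its gradient in the
variance components, and ``A`` the asymptotic covariance of the variance
components from the observed REML information (numeric Hessian).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

__all__ = ["CrossedLMM", "LMMFit", "fit_crossed_lmm", "satterthwaite_df"]

_LOG2PI = np.log(2 * np.pi)


class CrossedLMM:
    """Design container for a crossed-random-intercept mixed model.

    Parameters
    ----------
    y : (n,) outcome
    X : (n, p) fixed-effect design (include the intercept column yourself)
    groups : mapping factor name -> (n,) integer/str codes; one random
        intercept per factor.  May be empty (plain linear model).
    names : fixed-effect column names
    """

    def __init__(self, y, X, groups: dict, names: list[str] | None = None):
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        if self.X.ndim != 2 or len(self.y) != len(self.X):
            raise ValueError("X must be (n, p) aligned with y")
        self.n, self.p = self.X.shape
        self.names = list(names) if names is not None else [f"x{i}" for i in range(self.p)]
        self.factor_names = list(groups)
        self.levels: dict[str, np.ndarray] = {}
        blocks = []
        sizes = []
        for fac, codes in groups.items():
            codes = np.asarray(codes)
            levels, idx = np.unique(codes, return_inverse=True)
            self.levels[fac] = levels
            Zf = np.zeros((self.n, len(levels)))
            Zf[np.arange(self.n), idx] = 1.0
            blocks.append(Zf)
            sizes.append(len(levels))
        self.block_sizes = np.array(sizes, dtype=int)
        self.q = int(self.block_sizes.sum())
        if blocks:
            Z = np.concatenate(blocks, axis=1)
            self.ZtZ = Z.T @ Z
            self.ZtX = Z.T @ self.X
            self.Zty = Z.T @ self.y
            self._Z = Z
        else:
            self._Z = np.zeros((self.n, 0))
            self.ZtZ = np.zeros((0, 0))
            self.ZtX = np.zeros((0, self.p))
            self.Zty = np.zeros(0)
        self.XtX = self.X.T @ self.X
        self.Xty = self.X.T @ self.y
        self.yty = float(self.y @ self.y)
        # column -> factor expansion for lambdas
        self._expand = np.repeat(np.arange(len(sizes)), sizes) if sizes else np.zeros(0, dtype=int)

    # -- core algebra --------------------------------------------------------

    def _pieces(self, lambdas: np.ndarray):
        """GLS cross-products for given variance ratios (one per factor)."""
        if self.q == 0:
            XtWiX, XtWiy, ytWiy, logdetK = self.XtX, self.Xty, self.yty, 0.0
        else:
            d = np.sqrt(np.maximum(lambdas[self._expand], 0.0))
            K = np.eye(self.q) + (d[:, None] * self.ZtZ) * d[None, :]
            c, low = cho_factor(K, lower=True)
            logdetK = 2.0 * float(np.sum(np.log(np.diag(c))))
            P = d[:, None] * self.ZtX
            qy = d * self.Zty
            KiP = cho_solve((c, low), P)
            Kiq = cho_solve((c, low), qy)
            XtWiX = self.XtX - P.T @ KiP
            XtWiy = self.Xty - P.T @ Kiq
            ytWiy = self.yty - qy @ Kiq
        beta = np.linalg.solve(XtWiX, XtWiy)
        rss = max(float(ytWiy - beta @ XtWiy), 1e-12)
        sign, logdetXtWiX = np.linalg.slogdet(XtWiX)
        if sign <= 0:
            raise np.linalg.LinAlgError("singular fixed-effect GLS cross-product")
        return beta, rss, XtWiX, logdetK, logdetXtWiX

    def neg2_profiled(self, log_lambdas: np.ndarray, reml: bool = True) -> float:
        lambdas = np.exp(np.asarray(log_lambdas, dtype=float))
        try:
            _, rss, _, logdetK, logdetXtWiX = self._pieces(lambdas)
        except np.linalg.LinAlgError:
            return np.inf
        if reml:
            dof = self.n - self.p
            s2 = rss / dof
            return dof * np.log(s2) + logdetK + logdetXtWiX + dof * (1 + _LOG2PI)
        s2 = rss / self.n
        return self.n * np.log(s2) + logdetK + self.n * (1 + _LOG2PI)

    def neg2_reml_full(self, sigma2: np.ndarray) -> float:
        """REML deviance in the full (sigma_1^2, ..., sigma_m^2, sigma_e^2)
        parametrisation, used for the Satterthwaite information matrix."""
        sigma2 = np.asarray(sigma2, dtype=float)
        s2e = sigma2[-1]
        if s2e <= 0 or np.any(sigma2[:-1] < 0):
            return np.inf
        lambdas = sigma2[:-1] / s2e
        try:
            _, rss, _, logdetK, logdetXtWiX = self._pieces(lambdas)
        except np.linalg.LinAlgError:
            return np.inf
        dof = self.n - self.p
        return dof * np.log(s2e) + logdetK + logdetXtWiX + rss / s2e + dof * _LOG2PI

    def cov_beta_at(self, sigma2: np.ndarray) -> np.ndarray:
        s2e = sigma2[-1]
        lambdas = np.asarray(sigma2[:-1], dtype=float) / s2e
        _, _, XtWiX, _, _ = self._pieces(lambdas)
        return s2e * np.linalg.inv(XtWiX)

    # -- fitting -------------------------------------------------------------

    def fit(self, reml: bool = True) -> "LMMFit":
        m = len(self.factor_names)
        converged = True
        if m == 0:
            best = np.zeros(0)
        else:
            starts = [np.full(m, np.log(0.3)), np.full(m, -4.0), np.full(m, 1.0)]
            results = []
            for x0 in starts:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = optimize.minimize(
                        self.neg2_profiled,
                        x0,
                        args=(reml,),
                        method="Nelder-Mead",
                        options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 500},
                    )
                results.append(res)
            res = min(results, key=lambda r: r.fun)
            converged = bool(np.isfinite(res.fun))
            best = res.x
        lambdas = np.exp(best) if m else np.zeros(0)
        beta, rss, XtWiX, logdetK, logdetXtWiX = self._pieces(lambdas)
        dof = self.n - self.p if reml else self.n
        s2e = rss / dof
        cov_beta = s2e * np.linalg.inv(XtWiX)
        sigma2 = {f: float(lambdas[i] * s2e) for i, f in enumerate(self.factor_names)}
        neg2 = self.neg2_profiled(best, reml) if m else self.neg2_profiled(np.zeros(0), reml)
        return LMMFit(
            model=self,
            beta=pd.Series(beta, index=self.names),
            cov_beta=cov_beta,
            sigma2=sigma2,
            sigma2_resid=float(s2e),
            reml=reml,
            neg2loglik=float(neg2),
            converged=converged,
        )


@dataclass
class LMMFit:
    """A fitted crossed-random-intercept model."""

    model: CrossedLMM
    beta: pd.Series
    cov_beta: np.ndarray
    sigma2: dict
    sigma2_resid: float
    reml: bool
    neg2loglik: float
    converged: bool
    _vc_cov: np.ndarray | None = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return self.model.n

    @property
    def loglik(self) -> float:
        return -0.5 * self.neg2loglik

    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_beta)), index=self.beta.index)

    def _sigma_vec(self) -> np.ndarray:
        return np.array(
            [self.sigma2[f] for f in self.model.factor_names] + [self.sigma2_resid]
        )

    def vc_covariance(self) -> np.ndarray:
        """Asymptotic covariance of the variance components (observed REML
        information, numeric Hessian; pseudo-inverse guards boundary fits)."""
        if self._vc_cov is None:
            s = self._sigma_vec()
            h = np.maximum(1e-4 * np.abs(s), 1e-8)
            k = len(s)
            H = np.zeros((k, k))

            def f(v):
                return 0.5 * self.model.neg2_reml_full(v)

            f0 = f(s)
            for i in range(k):
                for j in range(i, k):
                    if i == j:
                        sp = s.copy(); sp[i] += h[i]
                        sm = s.copy(); sm[i] = max(sm[i] - h[i], 0.0 if i < k - 1 else 1e-12)
                        # one-sided fallback at the boundary
                        if sm[i] == s[i]:
                            sp2 = s.copy(); sp2[i] += 2 * h[i]
                            H[i, i] = (f(sp2) - 2 * f(sp) + f0) / h[i] ** 2
                        else:
                            H[i, i] = (f(sp) - 2 * f0 + f(sm)) / ((sp[i] - s[i]) * (s[i] - sm[i]))
                    else:
                        spp = s.copy(); spp[i] += h[i]; spp[j] += h[j]
                        spm = s.copy(); spm[i] += h[i]; spm[j] = max(spm[j] - h[j], 0.0)
                        smp = s.copy(); smp[i] = max(smp[i] - h[i], 0.0); smp[j] += h[j]
                        smm = s.copy(); smm[i] = max(smm[i] - h[i], 0.0); smm[j] = max(smm[j] - h[j], 0.0)
                        di = 0.5 * (spp[i] - smm[i])
                        dj = 0.5 * (spp[j] - smm[j])
                        H[i, j] = H[j, i] = (f(spp) - f(spm) - f(smp) + f(smm)) / (4 * di * dj)
            self._vc_cov = np.linalg.pinv(H)
        return self._vc_cov

    def contrast(self, L: np.ndarray) -> dict:
        """Estimate, SE, Satterthwaite df, t/F and p for a 1-df contrast."""
        L = np.asarray(L, dtype=float)
        est = float(L @ self.beta.to_numpy())
        var = float(L @ self.cov_beta @ L)
        df = satterthwaite_df(self, L)
        tval = est / np.sqrt(var) if var > 0 else np.nan
        p = 2 * stats.t.sf(abs(tval), df) if np.isfinite(tval) else np.nan
        return {
            "estimate": est,
            "se": float(np.sqrt(var)),
            "df": df,
            "t": tval,
            "F": tval**2 if np.isfinite(tval) else np.nan,
            "p": p,
        }

    def anova_satterthwaite(self) -> pd.DataFrame:
        """Per-coefficient F table with Satterthwaite denominator df.

        With the package's coding (deviation-coded factors, z-scored
        continuous predictors) each fixed-effect term is a single column, so
        the numerator df is 1 and F equals the squared t statistic.
        """
        rows = []
        p = len(self.beta)
        for i, name in enumerate(self.beta.index):
            if name == "Intercept":
                continue
            L = np.zeros(p)
            L[i] = 1.0
            c = self.contrast(L)
            rows.append(
                {
                    "term": name,
                    "F": c["F"],
                    "num_df": 1.0,
                    "den_df": c["df"],
                    "p": c["p"],
                }
            )
        return pd.DataFrame(rows).set_index("term")


def satterthwaite_df(fit: LMMFit, L: np.ndarray) -> float:
    """Satterthwaite denominator degrees of freedom for contrast L."""
    s = fit._sigma_vec()
    A = fit.vc_covariance()
    h = np.maximum(1e-4 * np.abs(s), 1e-8)

    def fvar(v):
        return float(L @ fit.model.cov_beta_at(v) @ L)

    g = np.zeros(len(s))
    for i in range(len(s)):
        sp = s.copy(); sp[i] += h[i]
        sm = s.copy(); sm[i] = max(s[i] - h[i], 0.0 if i < len(s) - 1 else 1e-12)
        g[i] = (fvar(sp) - fvar(sm)) / (sp[i] - sm[i])
    f0 = fvar(s)
    denom = float(g @ A @ g)
    nmax = float(fit.model.n - fit.model.p)
    if denom <= 0 or not np.isfinite(denom):
        return nmax
    df = 2.0 * f0**2 / denom
    return float(np.clip(df, 1.0, nmax))


def fit_crossed_lmm(
    y,
    X,
    groups: dict,
    names: list[str] | None = None,
    reml: bool = True,
) -> LMMFit:
    """Convenience one-shot fit of the crossed-random-intercept model."""
    return CrossedLMM(y, X, groups, names=names).fit(reml=reml)
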