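"""Whole-genome prediction models.

RR-BLUP: y = 1 mu + X g + e with g ~ N(0, sigma2_G / m) and
e ~ N(0, sigma2_R / l); the ridge penalty is fixed from the trial variance
components, lambda = (sigma2_R / l) / (sigma2_G / m), and marker effects
solve the mixed-model equations.

BayesCpi: the same linear model with a point-mass-at-zero mixture prior on
marker effects: each effect is zero with probability pi and N(0, sigma2_g)
otherwise; pi has a uniform prior on [0, 1] and both variances carry scaled
inverse chi-squared priors. Inference by Gibbs sampling; posterior-mean
effects are averages over post-burn-in cycles.

Epistatic RR-BLUP: adds product columns X_j * X_l for a declared set of
marker pairs with a separate ridge penalty. The additive-effect variance is
p_G * sigma2_G / m and the interaction-effect variance
(1 - p_G) * sigma2_G / p, where p_G is the cross-validated proportion of
genotypic variance explained by the additive model and p the number of
pairs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["RRBLUP", "BayesCPi", "EpistaticRRBLUP", "MarkerEffectResults",
           "BayesCPiResults"]


def _ridge_solve(Xc: np.ndarray, yc: np.ndarray, penalties: np.ndarray) -> np.ndarray:
    """Solve min ||yc - Xc b||^2 + b' diag(penalties) b.

    Uses the marker-space normal equations when the design is narrow and the
    Woodbury (line-space) form when it is wide; the two are algebraically
    identical.
    """
    n, m = Xc.shape
    if m <= n:
        A = Xc.T @ Xc
        A[np.diag_indices(m)] += penalties
        return np.linalg.solve(A, Xc.T @ yc)
    Xd = Xc / penalties          # X D^-1
    K = Xd @ Xc.T
    K[np.diag_indices(n)] += 1.0
    return Xd.T @ np.linalg.solve(K, yc)


class MarkerEffectResults:
    """Fitted marker-effect model: intercept, per-column effects, penalties."""

    def __init__(self, mu: float, effects: pd.Series, columns: pd.DataFrame | None,
                 meta: dict):
        self.mu = mu
        self.effects = effects
        self._extra_columns = columns   # product columns for epistatic models
        self.meta = meta

    def predict(self, X_new: pd.DataFrame) -> pd.Series:
        """Predicted genotypic values mu + X_new g (+ product terms)."""
        markers = self.meta["markers"]
        missing = [mk for mk in markers if mk not in X_new.columns]
        if missing:
            raise KeyError(f"markers absent from X_new: {missing[:5]}...")
        g = self.effects.loc[markers].to_numpy()
        pred = self.mu + X_new[markers].to_numpy(dtype=float) @ g
        if self.meta.get("pairs"):
            pf = self.meta["pair_effects"]
            for (mj, ml), f in pf.items():
                pred += X_new[mj].to_numpy(dtype=float) * X_new[ml].to_numpy(dtype=float) * f
        return pd.Series(pred, index=X_new.index, name="predicted")

    def summary(self) -> str:
        lines = [f"{self.meta['model']} fit",
                 "=" * (len(self.meta['model']) + 4),
                 f"n = {self.meta['n']}   markers = {len(self.meta['markers'])}",
                 f"mu = {self.mu:.3f}"]
        for key in ("lambda", "lambda_additive", "lambda_epistatic"):
            if key in self.meta:
                lines.append(f"{key} = {self.meta[key]:.4g}")
        eff = self.effects.loc[self.meta["markers"]]
        lines.append(f"max |effect| = {np.abs(eff).max():.4f} at {eff.abs().idxmax()}")
        return "\n".join(lines)


class RRBLUP:
    """Ridge-regression BLUP with the penalty fixed from trial variance
    components.

    Parameters
    ----------
    y : Series of line BLUEs.
    X : DataFrame of dosages (lines x markers), complete (no missing).
    sigma2_G, sigma2_R : genotypic and residual variance components (days^2).
    n_env : number of environments l underlying the BLUEs.
    """

    def __init__(self, y: pd.Series, X: pd.DataFrame, sigma2_G: float,
                 sigma2_R: float, n_env: int):
        if sigma2_G <= 0 or sigma2_R <= 0:
            raise ValueError("variance components must be positive")
        self.y = y
        self.X = X.loc[y.index]
        self.sigma2_G = sigma2_G
        self.sigma2_R = sigma2_R
        self.n_env = n_env
        m = X.shape[1]
        self.sigma2_g = sigma2_G / m
        self.sigma2_e = sigma2_R / n_env
        self.lambda_ = self.sigma2_e / self.sigma2_g

    def fit(self) -> MarkerEffectResults:
        Xm = self.X.to_numpy(dtype=float)
        yv = self.y.to_numpy(dtype=float)
        xbar = Xm.mean(axis=0)
        g = _ridge_solve(Xm - xbar, yv - yv.mean(),
                         np.full(Xm.shape[1], self.lambda_))
        mu = float(yv.mean() - xbar @ g)
        effects = pd.Series(g, index=self.X.columns, name="effect")
        return MarkerEffectResults(mu, effects, None, {
            "model": "RR-BLUP", "markers": list(self.X.columns), "n": len(yv),
            "lambda": self.lambda_, "sigma2_g": self.sigma2_g,
            "sigma2_e": self.sigma2_e})


# ---------------------------------------------------------------------------
# BayesCpi
# ---------------------------------------------------------------------------

def _get_kernel():
    """Compile the Gibbs kernel lazily so importing the package stays cheap."""
    global _BAYESC_KERNEL
    try:
        return _BAYESC_KERNEL
    except NameError:
        pass
    import numba

    @numba.njit(cache=False, fastmath=False)
    def kernel(y, X, cc, nu_g, s_g, nu_e, s_e, cycles, burnin, seed):
        np.random.seed(seed)
        n, m = X.shape
        g = np.zeros(m)
        delta = np.zeros(m, dtype=np.int64)
        mu = y.mean()
        e = y - mu
        pi = 0.5
        sigma_g = s_g * nu_g / (nu_g + 2.0)   # start at the prior mode
        sigma_e = s_e * nu_e / (nu_e + 2.0)
        g_sum = np.zeros(m)
        d_sum = np.zeros(m)
        pi_sum = 0.0
        mu_sum = 0.0
        kept = 0
        for it in range(cycles):
            # intercept
            mu_new = mu + e.sum() / n + np.random.normal() * np.sqrt(sigma_e / n)
            e -= (mu_new - mu)
            mu = mu_new
            # marker effects with inclusion indicators
            k_in = 0
            for j in range(m):
                cj = cc[j]
                if cj <= 0.0:
                    g[j] = 0.0
                    delta[j] = 0
                    continue
                r = 0.0
                for i in range(n):
                    r += X[i, j] * e[i]
                r += cj * g[j]
                # log-likelihood ratio of delta=1 vs delta=0 given r
                v1 = cj * cj * sigma_g + cj * sigma_e
                v0 = cj * sigma_e
                log_lr = 0.5 * (np.log(v0 / v1) + r * r * (1.0 / v0 - 1.0 / v1))
                log_odds = np.log((1.0 - pi) / pi) + log_lr
                if log_odds > 35.0:
                    p_in = 1.0
                elif log_odds < -35.0:
                    p_in = 0.0
                else:
                    p_in = 1.0 / (1.0 + np.exp(-log_odds))
                old = g[j]
                if np.random.random() < p_in:
                    lam = sigma_e / sigma_g
                    mean = r / (cj + lam)
                    sd = np.sqrt(sigma_e / (cj + lam))
                    gnew = mean + sd * np.random.normal()
                    delta[j] = 1
                    k_in += 1
                else:
                    gnew = 0.0
                    delta[j] = 0
                if gnew != old:
                    diff = gnew - old
                    for i in range(n):
                        e[i] -= X[i, j] * diff
                    g[j] = gnew
            # effect variance (scaled inverse chi-squared posterior)
            ssg = 0.0
            for j in range(m):
                if delta[j] == 1:
                    ssg += g[j] * g[j]
            chi_g = np.random.chisquare(nu_g + k_in)
            sigma_g = (nu_g * s_g + ssg) / chi_g
            # residual variance
            sse = 0.0
            for i in range(n):
                sse += e[i] * e[i]
            chi_e = np.random.chisquare(nu_e + n)
            sigma_e = (nu_e * s_e + sse) / chi_e
            # pi: uniform prior -> Beta(m - k + 1, k + 1)
            a = np.random.gamma(m - k_in + 1.0, 1.0)
            b = np.random.gamma(k_in + 1.0, 1.0)
            pi = a / (a + b)
            if it >= burnin:
                kept += 1
                pi_sum += pi
                mu_sum += mu
                for j in range(m):
                    g_sum[j] += g[j]
                    d_sum[j] += delta[j]
        return (g_sum / kept, d_sum / kept, pi_sum / kept, mu_sum / kept)

    _BAYESC_KERNEL = kernel
    return kernel


class BayesCPiResults:
    """Posterior summaries of the BayesCpi fit."""

    def __init__(self, mu, effects: pd.Series, inclusion_prob: pd.Series,
                 pi_mean: float, meta: dict):
        self.mu = mu
        self.effects = effects
        self.inclusion_prob = inclusion_prob
        self.pi_mean = pi_mean      # posterior mean exclusion probability
        self.meta = meta

    def predict(self, X_new: pd.DataFrame) -> pd.Series:
        markers = self.meta["markers"]
        g = self.effects.loc[markers].to_numpy()
        pred = self.mu + X_new[markers].to_numpy(dtype=float) @ g
        return pd.Series(pred, index=X_new.index, name="predicted")

    def summary(self) -> str:
        return "\n".join([
            "BayesCpi fit",
            "============",
            f"n = {self.meta['n']}   markers = {len(self.meta['markers'])}",
            f"cycles = {self.meta['cycles']} (burn-in {self.meta['burnin']})",
            f"posterior mean pi (exclusion probability) = {self.pi_mean:.3f}",
            f"markers with inclusion probability > 0.5: "
            f"{int((self.inclusion_prob > 0.5).sum())}",
        ])


class BayesCPi:
    """BayesCpi marker-effect model fitted by Gibbs sampling.

    Hyperpriors: both scaled inverse chi-squared priors use nu = 4.2; the
    effect-variance scale puts the prior mode at sigma2_G / (m * 0.5)
    (half the markers in the model a priori) and the residual scale at
    sigma2_R / l.
    """

    NU = 4.2

    def __init__(self, y: pd.Series, X: pd.DataFrame, sigma2_G: float,
                 sigma2_R: float, n_env: int):
        self.y = y
        self.X = X.loc[y.index]
        self.sigma2_G = sigma2_G
        self.sigma2_R = sigma2_R
        self.n_env = n_env

    def fit(self, cycles: int = 10000, burnin: int = 1000, seed=0) -> BayesCPiResults:
        if cycles <= 0 or burnin >= cycles:
            raise ValueError("need 0 < burnin < cycles")
        Xm = np.ascontiguousarray(self.X.to_numpy(dtype=float))
        yv = self.y.to_numpy(dtype=float)
        m = Xm.shape[1]
        cc = np.einsum("ij,ij->j", Xm, Xm)
        mode_g = self.sigma2_G / (m * 0.5)
        s_g = mode_g * (self.NU + 2.0) / self.NU
        mode_e = self.sigma2_R / self.n_env
        s_e = mode_e * (self.NU + 2.0) / self.NU
        kernel = _get_kernel()
        g_mean, d_mean, pi_mean, mu_mean = kernel(
            yv, Xm, cc, float(self.NU), float(s_g), float(self.NU), float(s_e),
            int(cycles), int(burnin), int(seed) % (2 ** 31 - 1))
        effects = pd.Series(g_mean, index=self.X.columns, name="effect")
        incl = pd.Series(d_mean, index=self.X.columns, name="inclusion_prob")
        return BayesCPiResults(float(mu_mean), effects, incl, float(pi_mean), {
            "model": "BayesCpi", "markers": list(self.X.columns),
            "n": len(yv), "cycles": cycles, "burnin": burnin, "seed": seed})


# ---------------------------------------------------------------------------
# epistatic RR-BLUP
# ---------------------------------------------------------------------------

class EpistaticRRBLUP:
    """RR-BLUP extended with product columns for declared marker pairs.

    With no pairs the model reduces exactly to additive RR-BLUP. Product
    columns are the raw point-wise dosage products (uncentred); centring
    differences are absorbed by the intercept and main effects.
    """

    def __init__(self, y: pd.Series, X: pd.DataFrame, pairs,
                 sigma2_G: float, sigma2_R: float, n_env: int,
                 p_G_additive: float | None = None):
        self.y = y
        self.X = X.loc[y.index]
        self.pairs = [tuple(p) for p in pairs]
        self.sigma2_G = sigma2_G
        self.sigma2_R = sigma2_R
        self.n_env = n_env
        p = len(self.pairs)
        if p > 0:
            if p_G_additive is None or not (0.0 < p_G_additive < 1.0):
                raise ValueError("p_G_additive must lie in (0, 1) when pairs are given")
        self.p_G_additive = p_G_additive

    def fit(self) -> MarkerEffectResults:
        p = len(self.pairs)
        if p == 0:
            res = RRBLUP(self.y, self.X, self.sigma2_G, self.sigma2_R,
                         self.n_env).fit()
            res.meta["model"] = "Epistatic RR-BLUP (no pairs)"
            res.meta["pairs"] = []
            res.meta["pair_effects"] = {}
            return res
        m = self.X.shape[1]
        pg = self.p_G_additive
        sigma2_e = self.sigma2_R / self.n_env
        sigma2_g = pg * self.sigma2_G / m
        sigma2_f = (1.0 - pg) * self.sigma2_G / p
        lam_g = sigma2_e / sigma2_g
        lam_f = sigma2_e / sigma2_f
        Xm = self.X.to_numpy(dtype=float)
        prods = np.column_stack([
            Xm[:, self.X.columns.get_loc(mj)] * Xm[:, self.X.columns.get_loc(ml)]
            for mj, ml in self.pairs])
        Z = np.column_stack([Xm, prods])
        zbar = Z.mean(axis=0)
        yv = self.y.to_numpy(dtype=float)
        pen = np.concatenate([np.full(m, lam_g), np.full(p, lam_f)])
        b = _ridge_solve(Z - zbar, yv - yv.mean(), pen)
        mu = float(yv.mean() - zbar @ b)
        effects = pd.Series(b[:m], index=self.X.columns, name="effect")
        pair_effects = {pair: float(v) for pair, v in zip(self.pairs, b[m:])}
        return MarkerEffectResults(mu, effects, None, {
            "model": "Epistatic RR-BLUP", "markers": list(self.X.columns),
            "n": len(yv), "lambda_additive": lam_g, "lambda_epistatic": lam_f,
            "pairs": self.pairs, "pair_effects": pair_effects,
            "p_G_additive": pg})
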