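"""Multi-environment trial analysis.

Fits the two-way random model y_ier = mu + G_i + E_e + GE_ie + eps_ier to a
long-format phenotype table (line x environment x replicate), returning REML
variance components, entry-mean broad-sense heritability

    h^2 = sigma2_G / (sigma2_G + sigma2_GE / l + sigma2_R / (l * r)),

and per-line adjusted means (BLUEs) from the companion fixed-genotype model.

For balanced data the variance components are obtained in closed form from
the ANOVA expected mean squares, which coincides with REML on balanced
designs whenever the estimates are interior; unbalanced data are handled by
EM-REML on the mixed-model equations with the method-of-moments solution as
the starting value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["VarianceComponents", "MultiEnvTrial", "TrialResults",
           "heritability_entry_mean", "fit_variance_components", "compute_blues"]

_REQ = ["line_id", "environment", "value"]


@dataclass(frozen=True)
class VarianceComponents:
    """Variance components of the two-way random model, in days^2."""
    sigma2_G: float
    sigma2_E: float
    sigma2_GE: float
    sigma2_R: float

    def __post_init__(self):
        for name in ("sigma2_G", "sigma2_E", "sigma2_GE", "sigma2_R"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def heritability_entry_mean(vc: VarianceComponents, l: int, r: int) -> float:
    """Broad-sense heritability on an entry-mean basis for l environments
    and r replicates per environment."""
    if l < 1 or r < 1:
        raise ValueError("l and r must be >= 1")
    denom = vc.sigma2_G + vc.sigma2_GE / l + vc.sigma2_R / (l * r)
    if denom == 0:
        raise ValueError("all variance components are zero")
    return vc.sigma2_G / denom


def _check_table(pheno: pd.DataFrame):
    missing = set(_REQ) - set(pheno.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
    if pheno["line_id"].nunique() < 2 or pheno["environment"].nunique() < 2:
        raise ValueError("need at least 2 lines and 2 environments")


def _is_balanced(pheno: pd.DataFrame):
    counts = pheno.groupby(["line_id", "environment"], observed=True).size()
    g = pheno["line_id"].nunique()
    e = pheno["environment"].nunique()
    if len(counts) != g * e or counts.nunique() != 1:
        return None
    return g, e, int(counts.iloc[0])


def _anova_components(pheno: pd.DataFrame, g, e, r) -> VarianceComponents:
    """Expected-mean-squares (method-of-moments) solution for balanced data."""
    y = pheno["value"].to_numpy(dtype=float)
    grand = y.mean()
    cell = pheno.groupby(["line_id", "environment"], observed=True)["value"].mean()
    line_m = pheno.groupby("line_id", observed=True)["value"].mean()
    env_m = pheno.groupby("environment", observed=True)["value"].mean()
    ms_g = e * r * ((line_m - grand) ** 2).sum() / (g - 1)
    ms_e = g * r * ((env_m - grand) ** 2).sum() / (e - 1)
    inter = (cell - line_m.reindex(cell.index.get_level_values(0)).to_numpy()
             - env_m.reindex(cell.index.get_level_values(1)).to_numpy() + grand)
    ms_ge = r * (inter ** 2).sum() / ((g - 1) * (e - 1))
    if r > 1:
        cell_fit = cell.reindex(list(zip(pheno["line_id"], pheno["environment"]))).to_numpy()
        ms_r = ((y - cell_fit) ** 2).sum() / (g * e * (r - 1))
        s2_r = ms_r
        s2_ge = max((ms_ge - ms_r) / r, 0.0)
    else:
        s2_r = 0.0  # residual confounded with GxE when unreplicated
        s2_ge = ms_ge
        ms_r = 0.0
    s2_g = max((ms_g - ms_ge) / (e * r), 0.0)
    s2_e = max((ms_e - ms_ge) / (g * r), 0.0)
    return VarianceComponents(s2_g, s2_e, s2_ge, s2_r)


def _em_reml(pheno: pd.DataFrame, start: VarianceComponents,
             max_iter=500, tol=1e-10) -> VarianceComponents:
    """Dense EM-REML on the mixed-model equations (small problems only)."""
    lines = pd.Categorical(pheno["line_id"])
    envs = pd.Categorical(pheno["environment"])
    y = pheno["value"].to_numpy(dtype=float)
    n = len(y)
    gi = lines.codes
    ei = envs.codes
    g, e = len(lines.categories), len(envs.categories)
    cell = gi * e + ei
    cells, cell_idx = np.unique(cell, return_inverse=True)

    def inc(codes, q):
        Z = np.zeros((n, q))
        Z[np.arange(n), codes] = 1.0
        return Z

    X = np.ones((n, 1))
    Zs = [inc(gi, g), inc(ei, e), inc(cell_idx, len(cells))]
    qs = [g, e, len(cells)]
    comp = np.array([max(start.sigma2_G, 1e-3), max(start.sigma2_E, 1e-3),
                     max(start.sigma2_GE, 1e-3)])
    s2e = max(start.sigma2_R, 1e-3)
    W = np.hstack([X] + Zs)
    WtW = W.T @ W
    Wty = W.T @ y
    yty = y @ y
    for _ in range(max_iter):
        C = WtW.copy()
        # block-diagonal ridge on each random block: lambda_k = s2e / comp[k]
        starts = [X.shape[1], X.shape[1] + qs[0], X.shape[1] + qs[0] + qs[1]]
        for k in range(3):
            sl = slice(starts[k], starts[k] + qs[k])
            C[sl, sl] += np.eye(qs[k]) * (s2e / comp[k])
        Cinv = np.linalg.inv(C)
        sol = Cinv @ Wty
        new = comp.copy()
        for k in range(3):
            sl = slice(starts[k], starts[k] + qs[k])
            u = sol[sl]
            new[k] = (u @ u + s2e * np.trace(Cinv[sl, sl])) / qs[k]
        resid_ss = yty - sol @ Wty
        s2e_new = resid_ss / (n - X.shape[1])
        delta = np.max(np.abs(np.append(new, s2e_new) - np.append(comp, s2e))
                       / (np.abs(np.append(comp, s2e)) + 1e-12))
        comp, s2e = new, float(s2e_new)
        if delta < tol:
            break
    return VarianceComponents(max(comp[0], 0.0), max(comp[1], 0.0),
                              max(comp[2], 0.0), max(s2e, 0.0))


def fit_variance_components(pheno: pd.DataFrame) -> VarianceComponents:
    """REML variance components of the two-way random model with interaction."""
    _check_table(pheno)
    bal = _is_balanced(pheno)
    if bal is not None:
        return _anova_components(pheno, *bal)
    start = _unbalanced_start(pheno)
    return _em_reml(pheno, start)


def _unbalanced_start(pheno: pd.DataFrame) -> VarianceComponents:
    """Crude method-of-moments start: ANOVA on cell means plus pooled
    within-cell variance."""
    cell = pheno.groupby(["line_id", "environment"], observed=True)["value"]
    cm = cell.mean()
    within = pheno["value"].var() * 0.1 + 1e-6
    counts = cell.size()
    if (counts > 1).any():
        dev = pheno.set_index(["line_id", "environment"])["value"] - cm
        nres = int((counts - 1).clip(lower=0).sum())
        if nres > 0:
            within = float((dev ** 2).sum() / nres)
    v = float(cm.var())
    return VarianceComponents(v * 0.5 + 1e-6, v * 0.2 + 1e-6, v * 0.3 + 1e-6, within)


def compute_blues(pheno: pd.DataFrame) -> pd.Series:
    """Per-line adjusted means from the two-way fixed model
    (genotype + environment, sum-to-zero environment contrasts).

    For complete balanced data this is the per-line mean across all plots.
    Raises on a disconnected line/environment design.
    """
    _check_table(pheno)
    if _is_balanced(pheno) is not None:
        return pheno.groupby("line_id", observed=True)["value"].mean().rename("blue")
    lines = pd.Categorical(pheno["line_id"])
    envs = pd.Categorical(pheno["environment"])
    _check_connected(lines, envs)
    y = pheno["value"].to_numpy(dtype=float)
    n = len(y)
    g, e = len(lines.categories), len(envs.categories)
    # design: one column per line, e-1 sum-coded environment columns
    from scipy import sparse
    from scipy.sparse.linalg import lsqr
    L = sparse.csr_matrix((np.ones(n), (np.arange(n), lines.codes)), shape=(n, g))
    E = np.zeros((n, e - 1))
    for j in range(e - 1):
        E[envs.codes == j, j] = 1.0
    E[envs.codes == e - 1, :] = -1.0
    D = sparse.hstack([L, sparse.csr_matrix(E)]).tocsr()
    sol = lsqr(D, y, atol=1e-12, btol=1e-12, iter_lim=10000)[0]
    return pd.Series(sol[:g], index=pd.Index(lines.categories, name="line_id"),
                     name="blue")


def _check_connected(lines: pd.Categorical, envs: pd.Categorical):
    g = len(lines.categories)
    e = len(envs.categories)
    import scipy.sparse as sp
    from scipy.sparse.csgraph import connected_components
    A = sp.coo_matrix((np.ones(len(lines.codes)), (lines.codes, envs.codes)),
                      shape=(g, e)).tocsr()
    B = sp.bmat([[None, A], [A.T, None]])
    ncomp, _ = connected_components(B, directed=False)
    if ncomp > 1:
        raise ValueError("disconnected line/environment design; adjusted means undefined")


class MultiEnvTrial:
    """Model object for one multi-environment trial.

    Parameters
    ----------
    pheno : DataFrame with columns line_id, environment, replicate, value.
    """

    def __init__(self, pheno: pd.DataFrame):
        _check_table(pheno)
        self.pheno = pheno.reset_index(drop=True)
        self.n_environments = int(pheno["environment"].nunique())
        if "replicate" in pheno.columns:
            reps = pheno.groupby(["line_id", "environment"], observed=True).size()
            self.n_replicates = int(reps.max())
        else:
            self.n_replicates = 1

    def fit(self) -> "TrialResults":
        vc = fit_variance_components(self.pheno)
        blues = compute_blues(self.pheno)
        return TrialResults(self, vc, blues)


class TrialResults:
    def __init__(self, model: MultiEnvTrial, vc: VarianceComponents, blues: pd.Series):
        self.model = model
        self.variance_components = vc
        self.blues = blues

    def heritability(self, l=None, r=None) -> float:
        l = self.model.n_environments if l is None else l
        r = self.model.n_replicates if r is None else r
        return heritability_entry_mean(self.variance_components, l, r)

    def summary(self) -> str:
        vc = self.variance_components
        lines = [
            "Multi-environment trial analysis",
            "================================",
            f"lines: {self.model.pheno['line_id'].nunique()}   "
            f"environments: {self.model.n_environments}   "
            f"replicates: {self.model.n_replicates}",
            f"sigma2_G  = {vc.sigma2_G:10.4f}",
            f"sigma2_E  = {vc.sigma2_E:10.4f}",
            f"sigma2_GE = {vc.sigma2_GE:10.4f}",
            f"sigma2_R  = {vc.sigma2_R:10.4f}",
            f"entry-mean h2 = {self.heritability():.4f}",
            f"mean BLUE = {self.blues.mean():.2f} days  (SD {self.blues.std():.2f})",
        ]
        return "\n".join(lines)
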