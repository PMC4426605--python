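"""Family-stratified five-fold cross-validation and the cross-validated
proportion of explained genotypic variance.

Each run draws 80% of lines per family as the estimation set and the
remaining 20% as the test set. A model is fitted on the estimation set, the
test lines' genotypic values are predicted, and

    p_G = r^2(predicted, observed BLUEs) / h^2

is recorded, where h^2 is the entry-mean heritability of the full trial.
The final record is the mean p_G over ``runs`` evaluations (20 repetitions
of five-fold CV by default). For scan-based runners, the per-marker count of
significant detections accumulated over runs is the QTL detection rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genmap import GeneticMap
from .gwas import ModelB
from .prediction import RRBLUP, BayesCPi, EpistaticRRBLUP

__all__ = ["make_folds", "compute_pg", "cv_evaluate", "CVResult",
           "FixedMarkerRunner", "GWASPeakRunner", "RRBLUPRunner",
           "BayesCPiRunner", "EpistaticRRBLUPRunner", "model_ladder"]


def make_folds(families: pd.Series, k: int = 5, seed=None) -> pd.Series:
    """Within-family random partition into k folds as equal as possible.

    Within each family fold sizes differ by at most one; the remainder lines
    go to folds drawn at random without replacement.
    """
    rng = np.random.default_rng(seed)
    fold = pd.Series(-1, index=families.index, dtype=int, name="fold")
    for fam, idx in families.groupby(families, observed=True).groups.items():
        nl = len(idx)
        if nl < 1:
            raise ValueError(f"family {fam} has no lines")
        base, rem = divmod(nl, k)
        sizes = np.full(k, base)
        sizes[rng.choice(k, size=rem, replace=False)] += 1
        labels = np.repeat(np.arange(k), sizes)
        rng.shuffle(labels)
        fold.loc[idx] = labels
    return fold


def compute_pg(predicted, observed, h2: float) -> float:
    """Squared Pearson correlation of predicted vs observed genotypic values,
    standardised by the heritability. Values above 1 are reported as-is with
    a warning."""
    pred = np.asarray(predicted, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if len(pred) != len(obs) or len(pred) < 3:
        raise ValueError("need equal-length vectors with >= 3 entries")
    if not (0.0 < h2 <= 1.0):
        raise ValueError("h2 must be in (0, 1]")
    if np.std(pred) == 0 or np.std(obs) == 0:
        raise ValueError("zero variance in predicted or observed values")
    r = stats.pearsonr(pred, obs)[0]
    pg = r ** 2 / h2
    if pg > 1.0:
        warnings.warn(f"p_G = {pg:.3f} exceeds 1", stacklevel=2)
    return float(pg)


@dataclass
class CVResult:
    per_run: pd.DataFrame                 # columns: run, p_G
    detection_counts: pd.Series | None    # per-marker cumulated significances
    runs: int

    @property
    def mean_pg(self) -> float:
        return float(self.per_run["p_G"].mean())

    def summary(self) -> str:
        q = self.per_run["p_G"].quantile([0.25, 0.5, 0.75])
        lines = [f"cross-validation runs: {self.runs}",
                 f"mean p_G = {self.mean_pg:.3f}",
                 f"quartiles: {q.loc[0.25]:.3f} / {q.loc[0.5]:.3f} / {q.loc[0.75]:.3f}"]
        if self.detection_counts is not None:
            top = self.detection_counts.sort_values(ascending=False).head(10)
            lines.append("top detection counts:\n" + top.to_string())
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# runners
# ---------------------------------------------------------------------------

class FixedMarkerRunner:
    """Ordinary least squares on a fixed marker set: y ~ 1 + X[markers]."""

    def __init__(self, markers):
        self.markers = list(markers)

    def run(self, y_est, X_est, fam_est, X_test, gmap):
        D = np.column_stack([np.ones(len(y_est)),
                             X_est[self.markers].to_numpy(dtype=float)])
        coef, *_ = np.linalg.lstsq(D, y_est.to_numpy(dtype=float), rcond=None)
        T = np.column_stack([np.ones(len(X_test)),
                             X_test[self.markers].to_numpy(dtype=float)])
        return pd.Series(T @ coef, index=X_test.index), {}


class GWASPeakRunner:
    """Full Model-B scan inside the estimation set: cofactors re-selected,
    Holm correction redone, QTL groups formed; the per-run peak markers
    carry the prediction and the significant set feeds detection counts."""

    def __init__(self, alpha: float = 0.05, max_cofactors: int = 50,
                 exclusion_cm: float = 1.0, group_cm: float = 5.0):
        self.alpha = alpha
        self.max_cofactors = max_cofactors
        self.exclusion_cm = exclusion_cm
        self.group_cm = group_cm

    def scan(self, y_est, X_est, fam_est, gmap):
        model = ModelB(y_est, X_est, fam_est, gmap)
        res = model.fit(exclusion_cm=self.exclusion_cm, alpha=self.alpha,
                        max_cofactors=self.max_cofactors)
        return res

    def run(self, y_est, X_est, fam_est, X_test, gmap):
        res = self.scan(y_est, X_est, fam_est, gmap)
        groups = res.qtl_groups(self.group_cm)
        peaks = [g.peak_marker for g in groups]
        info = {"significant": list(res.significant["marker"]), "peaks": peaks}
        if not peaks:
            mu = float(y_est.mean())
            return pd.Series(mu, index=X_test.index), info
        pred, _ = FixedMarkerRunner(peaks).run(y_est, X_est, fam_est, X_test, gmap)
        return pred, info


class RRBLUPRunner:
    def __init__(self, sigma2_G, sigma2_R, n_env):
        self.sigma2_G, self.sigma2_R, self.n_env = sigma2_G, sigma2_R, n_env

    def run(self, y_est, X_est, fam_est, X_test, gmap):
        fit = RRBLUP(y_est, X_est, self.sigma2_G, self.sigma2_R, self.n_env).fit()
        return fit.predict(X_test), {}


class BayesCPiRunner:
    def __init__(self, sigma2_G, sigma2_R, n_env, cycles=10000, burnin=1000,
                 seed=0):
        self.sigma2_G, self.sigma2_R, self.n_env = sigma2_G, sigma2_R, n_env
        self.cycles, self.burnin = cycles, burnin
        self.seed = seed
        self._counter = 0

    def run(self, y_est, X_est, fam_est, X_test, gmap):
        self._counter += 1
        fit = BayesCPi(y_est, X_est, self.sigma2_G, self.sigma2_R,
                       self.n_env).fit(self.cycles, self.burnin,
                                       seed=self.seed + self._counter)
        return fit.predict(X_test), {"pi": fit.pi_mean}


class EpistaticRRBLUPRunner:
    """Per run: scan the estimation set, take the peak markers of the QTL
    groups, declare all pairs among them, and fit the epistatic model with
    the additive p_G supplied (the mean additive RR-BLUP p_G)."""

    def __init__(self, sigma2_G, sigma2_R, n_env, p_G_additive,
                 alpha: float = 0.05, max_cofactors: int = 50):
        self.sigma2_G, self.sigma2_R, self.n_env = sigma2_G, sigma2_R, n_env
        self.p_G_additive = p_G_additive
        self.scanner = GWASPeakRunner(alpha=alpha, max_cofactors=max_cofactors)

    def run(self, y_est, X_est, fam_est, X_test, gmap):
        res = self.scanner.scan(y_est, X_est, fam_est, gmap)
        peaks = [g.peak_marker for g in res.qtl_groups()]
        pairs = [(peaks[i], peaks[j]) for i in range(len(peaks))
                 for j in range(i + 1, len(peaks))]
        fit = EpistaticRRBLUP(y_est, X_est, pairs, self.sigma2_G, self.sigma2_R,
                              self.n_env,
                              p_G_additive=self.p_G_additive if pairs else None).fit()
        return fit.predict(X_test), {"pairs": pairs}


# ---------------------------------------------------------------------------
# evaluation loop
# ---------------------------------------------------------------------------

def cv_evaluate(runner, y: pd.Series, X: pd.DataFrame, families: pd.Series,
                h2: float, gmap: GeneticMap | None = None, runs: int = 100,
                k: int = 5, seed=None) -> CVResult:
    """``runs`` evaluations = (runs // k) repetitions of k-fold CV.

    The heritability used for p_G is estimated once from the full trial and
    passed in. Detection counts are accumulated when the runner reports a
    ``significant`` marker list.
    """
    if runs % k != 0:
        raise ValueError("runs must be a multiple of k")
    rng = np.random.default_rng(seed)
    detections = pd.Series(0, index=X.columns, dtype=int)
    any_detect = False
    rows = []
    run_id = 0
    for _ in range(runs // k):
        folds = make_folds(families, k=k, seed=rng.integers(2 ** 31 - 1))
        for fold in range(k):
            test_mask = (folds == fold).to_numpy()
            est_idx = y.index[~test_mask]
            test_idx = y.index[test_mask]
            try:
                pred, info = runner.run(y.loc[est_idx], X.loc[est_idx],
                                        families.loc[est_idx], X.loc[test_idx],
                                        gmap)
            except Exception as err:
                raise RuntimeError(
                    f"runner failed in run {run_id} (fold {fold}): {err}") from err
            pg = compute_pg(pred.to_numpy(), y.loc[test_idx].to_numpy(), h2)
            rows.append((run_id, pg))
            if "significant" in info:
                any_detect = True
                hits = [mk for mk in info["significant"] if mk in detections.index]
                detections.loc[hits] += 1
            run_id += 1
    per_run = pd.DataFrame(rows, columns=["run", "p_G"])
    return CVResult(per_run, detections if any_detect else None, runs)


def model_ladder(y, X, families, h2, sigma2_G, sigma2_R, n_env, gmap,
                 peak_markers, runs: int = 100, seed=0,
                 bayes_cycles: int = 10000, bayes_burnin: int = 1000) -> pd.DataFrame:
    """Mean p_G of the model ladder: strongest single peak marker, all peak
    markers, RR-BLUP, BayesCpi, epistatic RR-BLUP. Returns a summary table
    (one row per model with mean and quartiles of p_G)."""
    rows = []

    def record(name, cvres):
        q = cvres.per_run["p_G"].quantile([0.25, 0.5, 0.75])
        rows.append({"model": name, "mean_p_G": cvres.mean_pg,
                     "q25": q.loc[0.25], "median": q.loc[0.5], "q75": q.loc[0.75]})
        return cvres

    single = [peak_markers[0]]
    record("single peak marker",
           cv_evaluate(FixedMarkerRunner(single), y, X, families, h2, gmap,
                       runs=runs, seed=seed))
    record(f"{len(peak_markers)} peak markers",
           cv_evaluate(FixedMarkerRunner(peak_markers), y, X, families, h2,
                       gmap, runs=runs, seed=seed))
    rr = record("RR-BLUP",
                cv_evaluate(RRBLUPRunner(sigma2_G, sigma2_R, n_env), y, X,
                            families, h2, gmap, runs=runs, seed=seed))
    record("BayesCpi",
           cv_evaluate(BayesCPiRunner(sigma2_G, sigma2_R, n_env,
                                      cycles=bayes_cycles, burnin=bayes_burnin,
                                      seed=seed), y, X, families, h2, gmap,
                       runs=runs, seed=seed))
    record("epistatic RR-BLUP",
           cv_evaluate(EpistaticRRBLUPRunner(sigma2_G, sigma2_R, n_env,
                                             p_G_additive=min(rr.mean_pg, 0.99)),
                       y, X, families, h2, gmap, runs=runs, seed=seed))
    return pd.DataFrame(rows)
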