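"""Model-B association mapping for multi-family (NAM) populations.

The scan model for a tested SNP is

    BLUE ~ intercept + family + cofactors + SNP dosage,

where cofactors are markers chosen by stepwise selection minimising the
Schwarz Bayesian Criterion (SBC) on the family-effect base model, and any
cofactor mapping within 1 cM of the tested SNP (including the SNP itself) is
dropped for that test. Marker P-values come from the partial t-test of the
dosage slope and are adjusted genome-wide by the Bonferroni-Holm step-down
procedure. Reported additive effects are twice the dosage slope, i.e. the
difference between the homozygous donor (wild) and homozygous recurrent
(cultivated) genotype in days.

Extensions: a two-dimensional scan testing the product term of marker pairs,
and a haplotype-based variant where the tested SNP is replaced by a
qualitative haplotype factor whose level means are compared pairwise with
the Tukey-Kramer studentized-range test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genmap import GeneticMap

__all__ = ["ModelB", "GWASResults", "EpistasisResults", "HaplotypeResults",
           "holm_adjust", "group_qtl", "grid_pairs"]


def holm_adjust(p_values):
    """Bonferroni-Holm step-down adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def _family_design(families: pd.Series) -> np.ndarray:
    """Intercept plus dummy columns for all but the first family."""
    cat = pd.Categorical(families)
    n = len(cat)
    k = len(cat.categories)
    D = np.zeros((n, k))
    D[:, 0] = 1.0
    for j in range(1, k):
        D[cat.codes == j, j] = 1.0
    return D


def _residualize(B: np.ndarray, M: np.ndarray):
    """Return M minus its projection onto col(B), via least squares."""
    coef, *_ = np.linalg.lstsq(B, M, rcond=None)
    return M - B @ coef


def _sbc(n, sse, k):
    return n * np.log(sse / n) + k * np.log(n)


class ModelB:
    """Association-scan model for one trait.

    Parameters
    ----------
    y : Series of per-line BLUEs (index = line ids).
    X : DataFrame of dosages, same index, one column per marker.
    families : Series of family labels, same index.
    gmap : GeneticMap covering the columns of X.
    """

    def __init__(self, y: pd.Series, X: pd.DataFrame, families: pd.Series,
                 gmap: GeneticMap):
        if not (y.index.equals(X.index) and y.index.equals(families.index)):
            X = X.loc[y.index]
            families = families.loc[y.index]
        self.y = y.to_numpy(dtype=float)
        self.X = X
        self.markers = list(X.columns)
        self.families = families
        self.gmap = gmap
        self._Xmat = np.ascontiguousarray(X.to_numpy(dtype=float))
        self._base = _family_design(families)
        self._marker_pos = {mk: (gmap.chromosome[gmap.index_of(mk)],
                                 gmap.position[gmap.index_of(mk)])
                            for mk in self.markers if mk in set(gmap.markers)}

    # -- cofactor selection -------------------------------------------------

    def select_cofactors(self, max_cofactors: int = 50) -> list:
        """Stepwise (forward with backward checks) marker selection into the
        family-effect base model, minimising SBC. Returns markers in
        selection order."""
        n = len(self.y)
        B = self._base
        k_base = B.shape[1]
        if n <= k_base + 1:
            raise ValueError("too few lines for the base model")
        yr = _residualize(B, self.y.copy())
        Xr = _residualize(B, self._Xmat.copy())
        sse = float(yr @ yr)
        selected: list[int] = []
        sbc_cur = _sbc(n, sse, k_base)

        def drop_costs():
            """SSE increase from dropping each selected cofactor, all at
            once, from the fitted full model: delta_j = beta_j^2 / C_jj with
            C = (D'D)^{-1} restricted to the cofactor columns."""
            D = np.column_stack([B, self._Xmat[:, selected]])
            DtD_inv = np.linalg.pinv(D.T @ D)
            beta = DtD_inv @ (D.T @ self.y)
            cols = np.arange(k_base, D.shape[1])
            diag = np.diag(DtD_inv)[cols]
            with np.errstate(divide="ignore"):
                return beta[cols] ** 2 / diag

        while len(selected) < max_cofactors:
            ss_x = np.einsum("ij,ij->j", Xr, Xr)
            ok = ss_x > 1e-10 * n
            xty = Xr.T @ yr
            red = np.zeros(len(self.markers))
            red[ok] = xty[ok] ** 2 / ss_x[ok]
            red[selected] = 0.0
            j = int(np.argmax(red))
            sse_new = sse - red[j]
            if sse_new <= 0:
                break
            sbc_new = _sbc(n, sse_new, k_base + len(selected) + 1)
            if sbc_new >= sbc_cur:
                break
            selected.append(j)
            sbc_cur = sbc_new
            sse = sse_new
            xj = Xr[:, j] / np.sqrt(ss_x[j])
            yr = yr - xj * (xj @ yr)
            Xr = Xr - np.outer(xj, xj @ Xr)
            # backward check: drop any cofactor whose removal lowers SBC
            dropped_any = False
            while len(selected) > 1:
                costs = drop_costs()
                sbc_drop = _sbc(n, (sse + costs) / 1.0, k_base + len(selected) - 1)
                best = int(np.argmin(sbc_drop))
                if sbc_drop[best] < sbc_cur - 1e-9 and best != len(selected) - 1:
                    sse = sse + float(costs[best])
                    sbc_cur = float(sbc_drop[best])
                    del selected[best]
                    dropped_any = True
                else:
                    break
            if dropped_any:   # refresh the residualised state
                D = np.column_stack([B, self._Xmat[:, selected]])
                yr = _residualize(D, self.y.copy())
                Xr = _residualize(D, self._Xmat.copy())
                sse = float(yr @ yr)
        return [self.markers[j] for j in selected]

    # -- main-effect scan ---------------------------------------------------

    def _eligible_exclusions(self, cofactors, exclusion_cm):
        """Map marker index -> tuple of excluded cofactors for that test."""
        excl = {}
        cof_pos = [(c, *self._marker_pos[c]) for c in cofactors]
        for idx, mk in enumerate(self.markers):
            chrom, pos = self._marker_pos[mk]
            dropped = tuple(c for c, cchrom, cpos in cof_pos
                            if cchrom == chrom and abs(cpos - pos) < exclusion_cm)
            if dropped:
                excl[idx] = dropped
        return excl

    def fit(self, cofactors=None, exclusion_cm: float = 1.0, alpha: float = 0.05,
            family_effects: bool = False, max_cofactors: int = 50) -> "GWASResults":
        """Scan every marker; returns effects, raw and Holm-adjusted P."""
        if cofactors is None:
            cofactors = self.select_cofactors(max_cofactors=max_cofactors)
        cofactors = list(cofactors)
        n = len(self.y)
        m = len(self.markers)
        excl = self._eligible_exclusions(cofactors, exclusion_cm)
        # group markers by their excluded-cofactor set; empty set is the bulk
        groups: dict[tuple, list[int]] = {}
        for idx in range(m):
            groups.setdefault(excl.get(idx, ()), []).append(idx)
        effect = np.full(m, np.nan)
        p_raw = np.ones(m)
        for dropped, idxs in groups.items():
            cofs = [c for c in cofactors if c not in dropped]
            D = np.column_stack([self._base, self._Xmat[:, [self.markers.index(c) for c in cofs]]]) \
                if cofs else self._base
            k = np.linalg.matrix_rank(D) if D.shape[1] > self._base.shape[1] else D.shape[1]
            yr = _residualize(D, self.y.copy())
            Xr = _residualize(D, self._Xmat[:, idxs])
            ss_x = np.einsum("ij,ij->j", Xr, Xr)
            df = n - k - 1
            ok = (ss_x > 1e-10 * n) & (df > 0)
            slope = np.zeros(len(idxs))
            slope[ok] = (Xr[:, ok].T @ yr) / ss_x[ok]
            sse = float(yr @ yr) - slope ** 2 * ss_x
            with np.errstate(divide="ignore", invalid="ignore"):
                se = np.sqrt(sse / df / ss_x)
                t = slope / se
            pv = np.ones(len(idxs))
            pv[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df)
            eff = np.full(len(idxs), np.nan)
            eff[ok] = 2.0 * slope[ok]
            for local, idx in enumerate(idxs):
                effect[idx] = eff[local]
                p_raw[idx] = pv[local]
        p_holm = holm_adjust(p_raw)
        tab = pd.DataFrame({
            "marker": self.markers,
            "chromosome": [self._marker_pos[mk][0] for mk in self.markers],
            "position_cm": [self._marker_pos[mk][1] for mk in self.markers],
            "effect": effect,
            "p_raw": p_raw,
            "p_holm": p_holm,
            "significant": p_holm < alpha,
        })
        fam_eff = self._family_effects() if family_effects else None
        return GWASResults(tab, cofactors, self.gmap, alpha, fam_eff)

    def _family_effects(self) -> pd.DataFrame:
        """Within-family additive effects (2 x within-family dosage slope),
        for families in which the marker segregates; NaN elsewhere."""
        fams = pd.Categorical(self.families)
        out = np.full((len(fams.categories), len(self.markers)), np.nan)
        for fi, fam in enumerate(fams.categories):
            mask = fams.codes == fi
            yf = self.y[mask]
            Xf = self._Xmat[mask]
            xc = Xf - Xf.mean(axis=0)
            yc = yf - yf.mean()
            ss = np.einsum("ij,ij->j", xc, xc)
            seg = ss > 1e-10
            out[fi, seg] = 2.0 * (xc[:, seg].T @ yc) / ss[seg]
        return pd.DataFrame(out, index=pd.Index(fams.categories, name="family"),
                            columns=self.markers)

    # -- epistasis scan -----------------------------------------------------

    def fit_epistasis(self, pairs, cofactors=None, alpha: float = 0.05,
                      exclusion_cm: float = 1.0) -> "EpistasisResults":
        """Two-dimensional scan: base model + both main effects + product
        term per pair; P from the product term, Holm over the tested pairs."""
        if cofactors is None:
            cofactors = self.select_cofactors()
        n = len(self.y)
        midx = {mk: i for i, mk in enumerate(self.markers)}
        rows, skipped = [], []
        for mj, ml in pairs:
            if mj == ml:
                skipped.append((mj, ml, "identical markers"))
                continue
            dropped = set()
            for mk in (mj, ml):
                chrom, pos = self._marker_pos[mk]
                for c in cofactors:
                    cchrom, cpos = self._marker_pos[c]
                    if cchrom == chrom and abs(cpos - pos) < exclusion_cm:
                        dropped.add(c)
            cofs = [c for c in cofactors if c not in dropped and c not in (mj, ml)]
            xj = self._Xmat[:, midx[mj]]
            xl = self._Xmat[:, midx[ml]]
            D = np.column_stack([self._base]
                                + ([self._Xmat[:, [midx[c] for c in cofs]]] if cofs else [])
                                + [xj, xl])
            prod = xj * xl
            yr = _residualize(D, self.y.copy())
            pr = _residualize(D, prod.copy())
            ss = float(pr @ pr)
            if ss <= 1e-10 * n:
                skipped.append((mj, ml, "product collinear with main effects"))
                continue
            k = np.linalg.matrix_rank(D)
            df = n - k - 1
            slope = float(pr @ yr) / ss
            sse = float(yr @ yr) - slope ** 2 * ss
            se = np.sqrt(sse / df / ss)
            p = 2.0 * stats.t.sf(abs(slope / se), df)
            rows.append((mj, ml, slope, p))
        tab = pd.DataFrame(rows, columns=["marker_j", "marker_l", "effect", "p_raw"])
        if len(tab):
            tab["p_holm"] = holm_adjust(tab["p_raw"].to_numpy())
            tab["significant"] = tab["p_holm"] < alpha
        else:
            tab["p_holm"] = []
            tab["significant"] = []
        return EpistasisResults(tab, pd.DataFrame(skipped, columns=["marker_j", "marker_l", "reason"]))

    # -- haplotype association ----------------------------------------------

    def fit_haplotypes(self, haplotypes: pd.Series, anchor_marker: str,
                       cofactors=None, exclusion_cm: float = 1.0,
                       reference: str | None = None) -> "HaplotypeResults":
        """Model-B with the SNP at ``anchor_marker`` replaced by a
        qualitative haplotype factor; adjusted means per haplotype and
        Tukey-Kramer pairwise comparisons.

        Lines with a missing haplotype label are dropped from this fit.
        """
        hap = haplotypes.reindex(self.X.index)
        keep = hap.notna().to_numpy()
        hap = pd.Categorical(hap[keep])
        if len(hap.categories) < 2:
            raise ValueError("need at least two haplotype levels")
        if cofactors is None:
            cofactors = self.select_cofactors()
        chrom, pos = self._marker_pos[anchor_marker]
        cofs = [c for c in cofactors
                if not (self._marker_pos[c][0] == chrom
                        and abs(self._marker_pos[c][1] - pos) < exclusion_cm)
                and c != anchor_marker]
        levels = list(hap.categories)
        if reference is None:
            reference = levels[0]
        ordered = [reference] + [h for h in levels if h != reference]
        midx = {mk: i for i, mk in enumerate(self.markers)}
        B = self._base[keep]
        C = self._Xmat[np.ix_(keep, [midx[c] for c in cofs])] if cofs else np.empty((keep.sum(), 0))
        H = np.zeros((int(keep.sum()), len(ordered) - 1))
        code_of = {h: i for i, h in enumerate(ordered)}
        codes = np.array([code_of[h] for h in np.asarray(hap)])
        for j in range(1, len(ordered)):
            H[codes == j, j - 1] = 1.0
        D = np.column_stack([B, C, H])
        yv = self.y[keep]
        coef, res_ss, rank, _ = np.linalg.lstsq(D, yv, rcond=None)
        fitted = D @ coef
        resid = yv - fitted
        sse = float(resid @ resid)
        df = len(yv) - np.linalg.matrix_rank(D)
        s2 = sse / df
        XtX_inv = np.linalg.pinv(D.T @ D)
        # adjusted means: population-marginal prediction with the haplotype
        # forced to each level, covariates at their observed values
        base_pred = D[:, :B.shape[1] + C.shape[1]] @ coef[:B.shape[1] + C.shape[1]]
        hap_coefs = np.concatenate([[0.0], coef[B.shape[1] + C.shape[1]:]])
        adj_means = base_pred.mean() + hap_coefs
        # covariance of haplotype contrasts vs reference
        kbc = B.shape[1] + C.shape[1]
        V = s2 * XtX_inv
        counts = np.bincount(codes, minlength=len(ordered))
        k = len(ordered)
        rows = []
        for i in range(k):
            for j in range(i + 1, k):
                ci = np.zeros(D.shape[1])
                cj = np.zeros(D.shape[1])
                if i > 0:
                    ci[kbc + i - 1] = 1.0
                if j > 0:
                    cj[kbc + j - 1] = 1.0
                cc = ci - cj
                se = np.sqrt(cc @ V @ cc)
                diff = adj_means[i] - adj_means[j]
                q = np.abs(diff) / se * np.sqrt(2.0)
                p = stats.studentized_range.sf(q, k, df)
                rows.append((ordered[i], ordered[j], diff, se, float(p)))
        comp = pd.DataFrame(rows, columns=["hap_a", "hap_b", "difference", "se", "p_tukey"])
        means = pd.Series(adj_means, index=pd.Index(ordered, name="haplotype"),
                          name="adjusted_mean")
        return HaplotypeResults(means, comp, pd.Series(counts, index=ordered, name="n_lines"),
                                reference, df)


# ---------------------------------------------------------------------------
# results containers
# ---------------------------------------------------------------------------

@dataclass
class QTLGroup:
    qtl_id: str
    chromosome: str
    peak_marker: str
    peak_cm: float
    cm_min: float
    cm_max: float
    effect: float
    p_holm: float
    members: list = field(default_factory=list)


def group_qtl(assoc: pd.DataFrame, max_gap_cm: float = 5.0) -> list:
    """Chain significant markers into QTL: consecutive significant markers on
    a chromosome belong to one QTL when separated by less than ``max_gap_cm``
    and their effects share a sign. Peak = smallest adjusted P (ties broken
    by smaller position)."""
    sig = assoc[assoc["significant"]].copy()
    out = []
    qid = 0
    for chrom, sub in sig.groupby("chromosome", sort=False):
        sub = sub.sort_values(["position_cm", "marker"], kind="mergesort")
        current = []
        for _, row in sub.iterrows():
            if current and (row["position_cm"] - current[-1]["position_cm"] < max_gap_cm
                            and np.sign(row["effect"]) == np.sign(current[-1]["effect"])):
                current.append(row)
            else:
                if current:
                    out.append(_finalize_group(current, chrom, qid))
                    qid += 1
                current = [row]
        if current:
            out.append(_finalize_group(current, chrom, qid))
            qid += 1
    return out


def _finalize_group(rows, chrom, qid):
    tab = pd.DataFrame(rows)
    peak = tab.sort_values(["p_holm", "position_cm"], kind="mergesort").iloc[0]
    return QTLGroup(
        qtl_id=f"QTL-{qid + 1:02d}", chromosome=chrom,
        peak_marker=peak["marker"], peak_cm=float(peak["position_cm"]),
        cm_min=float(tab["position_cm"].min()), cm_max=float(tab["position_cm"].max()),
        effect=float(peak["effect"]), p_holm=float(peak["p_holm"]),
        members=list(tab["marker"]))


def grid_pairs(gmap: GeneticMap, significant_markers=(), grid_cm: float = 5.0,
               restrict_to=None):
    """Default pair universe for the two-dimensional scan: all pairs among a
    ~grid_cm-spaced thinning of the map plus any supplied significant
    markers. ``restrict_to`` limits candidates to a marker subset."""
    allowed = set(restrict_to) if restrict_to is not None else None
    chosen = []
    for chrom, sl in gmap.chrom_slices():
        last = -np.inf
        for idx in range(sl.start, sl.stop):
            mk = gmap.markers[idx]
            if allowed is not None and mk not in allowed:
                continue
            if gmap.position[idx] - last >= grid_cm:
                chosen.append(mk)
                last = gmap.position[idx]
    pool = list(dict.fromkeys(list(chosen) + list(significant_markers)))
    return [(pool[i], pool[j]) for i in range(len(pool)) for j in range(i + 1, len(pool))]


class GWASResults:
    """Per-marker association results with QTL-grouping and summary."""

    def __init__(self, table: pd.DataFrame, cofactors, gmap, alpha,
                 family_effects=None):
        self.table = table
        self.cofactors = cofactors
        self.gmap = gmap
        self.alpha = alpha
        self.family_effects = family_effects

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]

    def qtl_groups(self, max_gap_cm: float = 5.0):
        return group_qtl(self.table, max_gap_cm)

    def qtl_table(self, max_gap_cm: float = 5.0) -> pd.DataFrame:
        groups = self.qtl_groups(max_gap_cm)
        return pd.DataFrame([{
            "qtl": g.qtl_id, "chromosome": g.chromosome, "peak_cm": g.peak_cm,
            "cm_min": g.cm_min, "cm_max": g.cm_max, "peak_marker": g.peak_marker,
            "effect": g.effect, "p_holm": g.p_holm, "n_markers": len(g.members),
        } for g in groups])

    def summary(self) -> str:
        qtab = self.qtl_table()
        head = [
            "Model-B genome scan",
            "===================",
            f"markers tested: {len(self.table)}   cofactors: {len(self.cofactors)}",
            f"significant markers (Holm < {self.alpha}): {int(self.table['significant'].sum())}",
            f"QTL groups: {len(qtab)}",
        ]
        if len(qtab):
            head.append(qtab.to_string(index=False,
                                       float_format=lambda v: f"{v:.3g}"))
        return "\n".join(head)


@dataclass
class EpistasisResults:
    table: pd.DataFrame
    skipped: pd.DataFrame

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]


@dataclass
class HaplotypeResults:
    adjusted_means: pd.Series
    comparisons: pd.DataFrame
    counts: pd.Series
    reference: str
    df_resid: int

    def contrast(self, hap: str, other: str | None = None) -> float:
        """Adjusted-mean difference hap minus other (default: reference)."""
        other = self.reference if other is None else other
        return float(self.adjusted_means[hap] - self.adjusted_means[other])

    def summary(self) -> str:
        lines = ["Haplotype association (Tukey-Kramer)",
                 "====================================",
                 f"reference haplotype: {self.reference}"]
        tab = pd.DataFrame({"adjusted_mean": self.adjusted_means,
                            "n_lines": self.counts})
        lines.append(tab.to_string(float_format=lambda v: f"{v:.2f}"))
        sig = self.comparisons[self.comparisons["p_tukey"] < 0.05]
        lines.append(f"significant pairwise differences (P < 0.05): {len(sig)}"
                     f" of {len(self.comparisons)}")
        return "\n".join(lines)
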