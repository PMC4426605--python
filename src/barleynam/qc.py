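"""SNP quality control, encoding and diversity diagnostics.

Raw genotype tables are lines x markers DataFrames of calls in
{'AA','AB','BB'} with NA for no-calls (chip-style, arbitrary allele
orientation per marker). The QC chain is: filter (monomorphic first, then
high failure rate), identity-by-state encoding against the family's donor
(homozygous donor -> 2, heterozygous -> 1, homozygous recurrent -> 0;
family-monomorphic markers -> 0 to keep a complete matrix), and per-family
mean imputation of the remaining no-calls. Unmapped markers are placed by
chi-square tests of independence against every mapped marker. Diversity
diagnostics: simple-matching similarity, a parents-only PCA with progeny
projection, and LD decay (r^2 against cM distance, loess-smoothed, against
the 95th percentile of the unlinked-pair r^2 distribution).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genmap import GeneticMap

__all__ = ["SNPFilterReport", "filter_snps", "encode_ibs", "impute_mni",
           "place_unmapped_snp", "genetic_similarity", "pca_parents_project",
           "ld_r2", "ld_decay", "loess_smooth"]

_STATES = ("AA", "AB", "BB")


@dataclass(frozen=True)
class SNPFilterReport:
    n_input: int
    n_monomorphic_removed: int
    n_high_failure_removed: int
    n_kept: int
    disposition: pd.Series    # per marker: kept / monomorphic / high_failure

    def __post_init__(self):
        total = self.n_kept + self.n_monomorphic_removed + self.n_high_failure_removed
        if total != self.n_input:
            raise ValueError("filter report counts do not reconcile")


def filter_snps(raw: pd.DataFrame, max_missing_fraction: float = 0.10):
    """Remove monomorphic markers, then markers with a no-call fraction
    strictly greater than ``max_missing_fraction`` (a marker missing in
    exactly that fraction of lines is kept). Returns (filtered, report)."""
    if raw.shape[1] == 0:
        raise ValueError("empty genotype table")
    notna = raw.notna()
    nunique = raw.nunique(dropna=True)
    mono = (nunique <= 1)
    miss_frac = 1.0 - notna.sum(axis=0) / len(raw)
    high_fail = (~mono) & (miss_frac > max_missing_fraction)
    keep = ~(mono | high_fail)
    disposition = pd.Series("kept", index=raw.columns, name="disposition")
    disposition[mono] = "monomorphic"
    disposition[high_fail] = "high_failure"
    report = SNPFilterReport(raw.shape[1], int(mono.sum()), int(high_fail.sum()),
                             int(keep.sum()), disposition)
    return raw.loc[:, keep], report


def encode_ibs(raw: pd.DataFrame, parents: pd.DataFrame, families: pd.Series,
               recurrent_id: str = "Barke", donor_of=None) -> pd.DataFrame:
    """Identity-by-state dosage encoding against family-specific donors.

    ``parents`` holds calls for the recurrent parent (row ``recurrent_id``)
    and one donor per family; ``donor_of`` maps family label -> donor row id
    (default ``Donor_<family>``). Hom-donor -> 2, het -> 1, hom-recurrent
    -> 0; markers monomorphic within a family (donor call equals recurrent
    call) are set to 0 for that family's lines regardless of the line call,
    keeping the matrix complete at such markers. No-calls at family-
    polymorphic markers stay missing (NaN) for later imputation.
    """
    donor_of = donor_of or {}
    unknown = set(families.unique()) - set(donor_of) - {
        f for f in families.unique() if f"Donor_{f}" in parents.index}
    if unknown:
        raise KeyError(f"no donor genotype for families: {sorted(unknown)}")
    rec = parents.loc[recurrent_id]
    out = pd.DataFrame(np.nan, index=raw.index, columns=raw.columns)
    for fam, idx in families.groupby(families, observed=True).groups.items():
        donor = parents.loc[donor_of.get(fam, f"Donor_{fam}")]
        polymorphic = (donor != rec) & donor.notna() & rec.notna()
        sub = raw.loc[idx]
        enc = np.full(sub.shape, np.nan)
        hom_donor = sub.eq(donor, axis=1).to_numpy()
        hom_rec = sub.eq(rec, axis=1).to_numpy()
        het = sub.eq("AB").to_numpy()
        enc[hom_rec] = 0.0
        enc[het] = 1.0
        enc[hom_donor] = 2.0
        enc[:, ~polymorphic.to_numpy()] = 0.0
        out.loc[idx] = enc
    return out


def impute_mni(encoded: pd.DataFrame, families: pd.Series) -> pd.DataFrame:
    """Mean imputation: each missing dosage becomes the mean of the
    non-missing dosages of that marker within the line's family. A marker
    with no observed value in a family imputes to 0 (the recurrent-parent
    dosage, the majority state of the design)."""
    out = encoded.copy()
    for fam, idx in families.groupby(families, observed=True).groups.items():
        block = out.loc[idx]
        means = block.mean(axis=0, skipna=True).fillna(0.0)
        out.loc[idx] = block.fillna(means)
    return out


def place_unmapped_snp(target: pd.Series, mapped: pd.DataFrame, gmap: GeneticMap,
                       alpha: float = 0.001):
    """Place an unmapped marker by chi-square tests of independence of its
    genotype distribution against every mapped marker.

    Returns (chromosome, position, p_value) of the minimum-P mapped marker if
    that P is below ``alpha``; on P ties, the position is the average of the
    minimum and maximum positions of the tied markers (requiring them to sit
    on one chromosome). Returns None when no test reaches ``alpha``.
    Comparisons whose contingency table collapses to a single row or column
    are skipped. P-values are compared on the log scale, so strongly linked
    markers whose P underflows to zero do not produce spurious ties; ties are
    declared only for (numerically) identical log P.
    """
    logp = {}
    t_codes, t_levels = pd.factorize(target.to_numpy())
    nt = len(t_levels)
    for mk in mapped.columns:
        m_codes, m_levels = pd.factorize(mapped[mk].to_numpy())
        nm = len(m_levels)
        if nt < 2 or nm < 2:
            continue
        table = np.bincount(t_codes * nm + m_codes, minlength=nt * nm).reshape(nt, nm)
        table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
        if table.shape[0] < 2 or table.shape[1] < 2:
            continue
        res = stats.chi2_contingency(table)
        logp[mk] = stats.chi2.logsf(res[0], res[2])
    if not logp:
        return None
    pser = pd.Series(logp)
    logmin = pser.min()
    if logmin >= np.log(alpha):
        return None
    pmin = float(np.exp(logmin))
    best = pser.index[np.isclose(pser.to_numpy(), logmin, rtol=1e-9, atol=1e-9)]
    idxs = [gmap.index_of(mk) for mk in best]
    chroms = {gmap.chromosome[i] for i in idxs}
    positions = [gmap.position[i] for i in idxs]
    chrom = gmap.chromosome[idxs[0]] if len(chroms) == 1 else None
    position = (min(positions) + max(positions)) / 2.0
    return chrom, float(position), float(pmin)


def genetic_similarity(encoded: pd.DataFrame) -> pd.DataFrame:
    """Simple-matching similarity: the fraction of markers at which two
    lines carry the identical genotype state. Symmetric with unit diagonal."""
    if encoded.shape[1] == 0:
        raise ValueError("no markers")
    if encoded.isna().any().any():
        raise ValueError("similarity requires a complete matrix")
    arr = encoded.to_numpy()
    n = len(arr)
    if n * n * arr.shape[1] < 5e7:
        sim = (arr[:, None, :] == arr[None, :, :]).mean(axis=2)
    else:
        sim = np.empty((n, n))
        for i in range(n):
            sim[i] = (arr == arr[i]).mean(axis=1)
    return pd.DataFrame(sim, index=encoded.index, columns=encoded.index)


def pca_parents_project(parents: pd.DataFrame, progeny: pd.DataFrame,
                        n_components: int = 2):
    """PCA fitted on the parents only (centred, unscaled dosages); progeny
    are projected onto the parental component basis.

    Returns (parent_scores, progeny_scores, explained_variance_ratio).
    """
    if list(parents.columns) != list(progeny.columns):
        progeny = progeny[parents.columns]
    if len(parents) < n_components:
        raise ValueError("fewer parents than requested components")
    from sklearn.decomposition import PCA
    pca = PCA(n_components=n_components)
    ps = pca.fit_transform(parents.to_numpy(dtype=float))
    qs = pca.transform(progeny.to_numpy(dtype=float))
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return (pd.DataFrame(ps, index=parents.index, columns=cols),
            pd.DataFrame(qs, index=progeny.index, columns=cols),
            pca.explained_variance_ratio_)


def ld_r2(parents: pd.DataFrame, gmap: GeneticMap, maf_min: float = 0.05,
          max_pairs: int | None = None, seed=0) -> pd.DataFrame:
    """Pairwise r^2 (squared allele-count correlation) among parents.

    Heterozygous calls are set missing and markers with minor allele
    frequency below ``maf_min`` or zero variance are excluded. Pairs are
    annotated with their cM distance, or flagged unlinked when the markers
    sit on different chromosomes. ``max_pairs`` subsamples the (possibly
    huge) pair list reproducibly.
    """
    X = parents.to_numpy(dtype=float).copy()
    X[X == 1] = np.nan                      # exclude heterozygous calls
    keep = []
    for j, mk in enumerate(parents.columns):
        col = X[:, j]
        obs = col[~np.isnan(col)]
        if len(obs) < 2:
            continue
        p = obs.mean() / 2.0
        maf = min(p, 1 - p)
        if maf < maf_min or obs.std() == 0:
            continue
        keep.append(j)
    cols = [parents.columns[j] for j in keep]
    Xk = X[:, keep]
    # complete-case correlation (parents are inbred: few NaNs in practice)
    dfX = pd.DataFrame(Xk, columns=cols)
    corr = dfX.corr().to_numpy()
    idx = [gmap.index_of(mk) for mk in cols]
    chrom = np.array([gmap.chromosome[i] for i in idx])
    pos = np.array([gmap.position[i] for i in idx])
    iu, ju = np.triu_indices(len(cols), k=1)
    if max_pairs is not None and len(iu) > max_pairs:
        sel = np.random.default_rng(seed).choice(len(iu), max_pairs, replace=False)
        iu, ju = iu[sel], ju[sel]
    same = chrom[iu] == chrom[ju]
    dist = np.where(same, np.abs(pos[iu] - pos[ju]), np.nan)
    r2 = corr[iu, ju] ** 2
    out = pd.DataFrame({
        "marker_i": np.array(cols, dtype=object)[iu],
        "marker_j": np.array(cols, dtype=object)[ju],
        "distance_cm": dist,
        "unlinked": ~same,
        "r2": r2,
    })
    return out.dropna(subset=["r2"]).reset_index(drop=True)


def loess_smooth(x, y, x_eval, span: float = 0.5, degree: int = 2):
    """Locally weighted polynomial regression with tricube weights.

    ``span`` is the fraction of points in each local neighbourhood; the
    local polynomial has the given degree (2 = locally quadratic).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    order = np.argsort(x)
    x, y = x[order], y[order]
    n = len(x)
    k = max(int(np.ceil(span * n)), degree + 1)
    out = np.empty(len(x_eval))
    for i, x0 in enumerate(np.asarray(x_eval, dtype=float)):
        d = np.abs(x - x0)
        idx = np.argpartition(d, min(k, n) - 1)[:k]
        dmax = d[idx].max()
        w = (1 - (d[idx] / (dmax if dmax > 0 else 1.0)) ** 3) ** 3
        w = np.clip(w, 0, None)
        V = np.vander(x[idx] - x0, degree + 1, increasing=True)
        W = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(V * W[:, None], y[idx] * W, rcond=None)
        out[i] = coef[0]
    return out


def ld_decay(ld: pd.DataFrame, span: float = 0.5, grid_step: float = 0.1):
    """LD decay distance: where the loess-smoothed intra-chromosomal r^2
    curve first crosses below the unlinked baseline (the 95th percentile of
    inter-chromosomal r^2).

    Returns (baseline, decay_distance_cm, reached). When the smoothed curve
    starts below the baseline the decay distance is 0; when it never crosses
    the maximum evaluated distance is reported with ``reached=False``.
    """
    intra = ld[~ld["unlinked"]]
    inter = ld[ld["unlinked"]]
    if intra.empty or inter.empty:
        raise ValueError("need both intra- and inter-chromosomal pairs")
    baseline = float(np.quantile(inter["r2"].to_numpy(), 0.95))
    d = intra["distance_cm"].to_numpy()
    grid = np.arange(0.0, d.max() + grid_step, grid_step)
    smooth = loess_smooth(d, intra["r2"].to_numpy(), grid, span=span)
    below = smooth < baseline
    if below[0]:
        return baseline, 0.0, True
    cross = np.flatnonzero(below)
    if len(cross) == 0:
        return baseline, float(grid[-1]), False
    j = cross[0]
    # linear interpolation between the straddling grid points
    x0, x1 = grid[j - 1], grid[j]
    y0, y1 = smooth[j - 1], smooth[j]
    t = (y0 - baseline) / (y0 - y1) if y0 != y1 else 0.0
    return baseline, float(x0 + t * (x1 - x0)), True
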