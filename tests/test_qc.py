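"""SNP filtering, IBS encoding, imputation, placement, diversity and LD."""

import numpy as np
import pandas as pd
import pytest

from barleynam import default_map
from barleynam.qc import (encode_ibs, filter_snps, genetic_similarity,
                          impute_mni, ld_decay, ld_r2, loess_smooth,
                          pca_parents_project, place_unmapped_snp)
from barleynam.simulate import to_raw_calls


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def test_filter_chip_fixture_counts(chip_raw):
    """A 7,864-marker chip with 1,027 monomorphic and 1,128 high-failure
    markers keeps exactly 5,709 informative SNPs."""
    raw = chip_raw
    kept, report = filter_snps(raw)
    assert report.n_input == 7864
    assert report.n_monomorphic_removed == 1027
    assert report.n_high_failure_removed == 1128
    assert report.n_kept == kept.shape[1] == 5709
    assert set(kept.columns) <= set(raw.columns)
    counts = report.disposition.value_counts()
    assert counts["kept"] + counts["monomorphic"] + counts["high_failure"] == 7864


def test_filter_boundary_exactly_ten_percent_kept():
    idx = [f"L{i}" for i in range(20)]
    at_limit = ["AA"] * 9 + ["BB"] * 9 + [pd.NA, pd.NA]          # 10.0%
    above = ["AA"] * 9 + ["BB"] * 8 + [pd.NA, pd.NA, pd.NA]      # 15%
    raw = pd.DataFrame({"at": at_limit, "above": above}, index=idx)
    kept, report = filter_snps(raw)
    assert list(kept.columns) == ["at"]
    assert report.n_high_failure_removed == 1


def test_filter_all_monomorphic_empty_output():
    raw = pd.DataFrame({"a": ["AA"] * 5, "b": ["BB"] * 5})
    kept, report = filter_snps(raw)
    assert kept.shape[1] == 0
    assert report.n_monomorphic_removed == 2


def test_monomorphic_assessed_before_missingness():
    # monomorphic AND high-missing counts as monomorphic (disjoint classes)
    raw = pd.DataFrame({"m": ["AA", "AA", pd.NA, pd.NA, pd.NA],
                        "ok": ["AA", "BB", "AA", "BB", "AA"]})
    _, report = filter_snps(raw)
    assert report.n_monomorphic_removed == 1
    assert report.n_high_failure_removed == 0


# ---------------------------------------------------------------------------
# IBS encoding and imputation
# ---------------------------------------------------------------------------

def _tiny_panel():
    parents = pd.DataFrame(
        {"s1": ["AA", "AA"], "s2": ["BB", "AA"], "s3": ["AA", "BB"]},
        index=["Barke", "Donor_F01"])
    raw = pd.DataFrame(
        {"s1": ["AA", "AB", "BB"], "s2": ["BB", "AB", "AA"], "s3": ["BB", "AA", "AB"]},
        index=["l1", "l2", "l3"])
    fam = pd.Series(["F01"] * 3, index=raw.index)
    return raw, parents, fam


def test_encode_ibs_state_mapping():
    raw, parents, fam = _tiny_panel()
    enc = encode_ibs(raw, parents, fam)
    # s1 is family-monomorphic (donor == recurrent): all zero
    assert (enc["s1"] == 0).all()
    # s2: recurrent parent carries BB, donor AA -> BB call is 0, AA call is 2
    assert enc["s2"].tolist() == [0.0, 1.0, 2.0]
    # s3: recurrent AA, donor BB -> BB call is 2, AA 0, het 1
    assert enc["s3"].tolist() == [2.0, 0.0, 1.0]


def test_encode_unknown_family_raises():
    raw, parents, fam = _tiny_panel()
    fam = fam.replace("F01", "F99")
    with pytest.raises(KeyError):
        encode_ibs(raw, parents, fam)


def test_encode_roundtrip_on_simulated_population(small):
    """On complete calls, encoding recovers the simulated dosage matrix."""
    raw, parents = to_raw_calls(small.population, missing_rate=0.0, seed=0)
    enc = encode_ibs(raw, parents, small.families)
    expected = small.genotypes.astype(float)
    # family-monomorphic markers are forced to 0 in both representations
    pd.testing.assert_frame_equal(enc, expected, check_dtype=False,
                                  check_column_type=False)


def test_impute_family_mean():
    enc = pd.DataFrame({"s": [0.0, 2.0, np.nan, 2.0]},
                       index=["a", "b", "c", "d"])
    fam = pd.Series(["F1"] * 4, index=enc.index)
    out = impute_mni(enc, fam)
    assert out.loc["c", "s"] == pytest.approx(4.0 / 3.0)
    assert out.loc[["a", "b", "d"], "s"].tolist() == [0.0, 2.0, 2.0]


def test_impute_identity_when_complete():
    enc = pd.DataFrame({"s": [0.0, 1.0, 2.0]})
    fam = pd.Series(["F1"] * 3)
    pd.testing.assert_frame_equal(impute_mni(enc, fam), enc)


def test_impute_all_missing_family_becomes_zero():
    enc = pd.DataFrame({"s": [np.nan, np.nan, 0.0, 2.0]})
    fam = pd.Series(["F1", "F1", "F2", "F2"])
    out = impute_mni(enc, fam)
    assert out["s"].tolist() == [0.0, 0.0, 0.0, 2.0]


# ---------------------------------------------------------------------------
# chi-square placement
# ---------------------------------------------------------------------------

def _mapped_population(n_lines=400, n_markers=60, seed=0):
    rng = np.random.default_rng(seed)
    gmap = default_map(n_markers)
    X = pd.DataFrame(rng.choice([0, 1, 2], (n_lines, n_markers),
                                p=[0.72, 0.06, 0.22]),
                     columns=gmap.markers)
    return X, gmap, rng


def test_place_identical_marker():
    X, gmap, _ = _mapped_population()
    target_marker = gmap.markers[10]
    res = place_unmapped_snp(X[target_marker], X, gmap)
    assert res is not None
    chrom, pos, p = res
    i = gmap.index_of(target_marker)
    assert chrom == gmap.chromosome[i]
    assert pos == pytest.approx(gmap.position[i])


def test_place_tie_takes_midpoint():
    rng = np.random.default_rng(1)
    gmap = default_map(4, n_chromosomes=1, length_cm=30.0)  # 0, 10, 20, 30 cM
    col = rng.choice([0, 2], 200)
    X = pd.DataFrame({
        gmap.markers[0]: rng.choice([0, 2], 200),
        gmap.markers[1]: col,            # at 10 cM
        gmap.markers[2]: col,            # identical column at 20 cM -> tie
        gmap.markers[3]: rng.choice([0, 2], 200),
    }, columns=gmap.markers)
    res = place_unmapped_snp(pd.Series(col), X, gmap)
    assert res is not None
    assert res[1] == pytest.approx(15.0)


def test_independent_target_stays_unplaced():
    """A target independent of a small mapped set is unplaced in nearly all
    replicates at alpha = 0.001."""
    unplaced = 0
    for rep in range(100):
        rng = np.random.default_rng(500 + rep)
        gmap = default_map(10)
        X = pd.DataFrame(rng.choice([0, 1, 2], (300, 10), p=[0.72, 0.06, 0.22]),
                         columns=gmap.markers)
        target = pd.Series(rng.choice([0, 1, 2], 300, p=[0.72, 0.06, 0.22]))
        if place_unmapped_snp(target, X, gmap) is None:
            unplaced += 1
    assert unplaced >= 97


def test_placement_accuracy_on_linked_markers(small):
    """Markers hidden from the simulated map are re-placed on the correct
    chromosome in >= 95% of cases, with a small median position error."""
    rng = np.random.default_rng(3)
    X = small.genotypes
    gmap = small.gmap
    targets = rng.choice(len(gmap), 20, replace=False)
    mapped_cols = [mk for i, mk in enumerate(gmap.markers) if i not in set(targets)]
    correct_chrom = 0
    errors = []
    for ti in targets:
        mk = gmap.markers[ti]
        res = place_unmapped_snp(X[mk], X[mapped_cols], gmap)
        if res is None:
            continue
        chrom, pos, _ = res
        if chrom == gmap.chromosome[ti]:
            correct_chrom += 1
            errors.append(abs(pos - gmap.position[ti]))
    assert correct_chrom >= 19
    assert np.median(errors) <= 5.0


def test_degenerate_contingency_skipped():
    gmap = default_map(2, n_chromosomes=1)
    X = pd.DataFrame({gmap.markers[0]: [0] * 50,
                      gmap.markers[1]: [0, 2] * 25}, columns=gmap.markers)
    target = pd.Series([0, 2] * 25)
    res = place_unmapped_snp(target, X, gmap)
    assert res is not None          # constant marker skipped, linked one wins
    assert res[1] == pytest.approx(gmap.position[1])


# ---------------------------------------------------------------------------
# similarity and PCA
# ---------------------------------------------------------------------------

def test_similarity_identical_opposite_and_half():
    enc = pd.DataFrame({
        "m1": [0, 0, 2], "m2": [1, 1, 0], "m3": [2, 2, 0],
        "m4": [0, 0, 2], "m5": [1, 1, 2], "m6": [2, 2, 1],
    }, index=["a", "b", "c"])
    sim = genetic_similarity(enc)
    assert sim.loc["a", "b"] == 1.0
    assert sim.loc["a", "c"] == 0.0
    enc2 = enc.copy()
    enc2.loc["c"] = [0, 1, 2, 2, 0, 1]      # matches a at 3 of 6 markers
    sim2 = genetic_similarity(enc2)
    assert sim2.loc["a", "c"] == pytest.approx(0.5)
    assert np.allclose(sim2, sim2.T)
    assert np.allclose(np.diag(sim2), 1.0)


def test_pca_projection_of_training_points_and_recurrent():
    rng = np.random.default_rng(4)
    parents = pd.DataFrame(rng.choice([0.0, 2.0], (26, 80)),
                           index=[f"P{i}" for i in range(26)],
                           columns=[f"m{j}" for j in range(80)])
    progeny = pd.concat([parents.iloc[[0]].rename(index={"P0": "line0"}),
                         parents.sample(5, random_state=1)
                         .set_axis([f"l{i}" for i in range(5)])])
    ps, qs, ratio = pca_parents_project(parents, progeny)
    assert qs.loc["line0"].to_numpy() == pytest.approx(ps.loc["P0"].to_numpy())
    # variance fractions agree with a direct eigen-decomposition oracle
    C = np.cov(parents.to_numpy().T @ np.eye(80), rowvar=True) if False else None
    Xc = parents.to_numpy() - parents.to_numpy().mean(axis=0)
    ev = np.linalg.eigvalsh(Xc @ Xc.T / (len(parents) - 1))[::-1]
    assert ratio[:2] == pytest.approx(ev[:2] / ev.sum(), rel=1e-8)


def test_pca_two_clusters_separated_on_pc1():
    rng = np.random.default_rng(6)
    a = rng.choice([0.0, 2.0], (13, 100), p=[0.8, 0.2])
    b = rng.choice([0.0, 2.0], (13, 100), p=[0.2, 0.8])
    parents = pd.DataFrame(np.vstack([a, b]), columns=[f"m{j}" for j in range(100)])
    ps, _, ratio = pca_parents_project(parents, parents)
    pc1 = ps["PC1"].to_numpy()
    assert (pc1[:13].mean() < 0) != (pc1[13:].mean() < 0)
    assert ratio[0] > ratio[1]


def test_pca_requires_enough_parents():
    parents = pd.DataFrame([[0.0, 2.0]], columns=["a", "b"])
    with pytest.raises(ValueError):
        pca_parents_project(parents, parents, n_components=2)


# ---------------------------------------------------------------------------
# LD
# ---------------------------------------------------------------------------

def _parents_frame(cols, gmap):
    return pd.DataFrame(cols, columns=gmap.markers[:len(cols[0])] if False else None)


def test_ld_identical_and_maf_filter():
    gmap = default_map(3, n_chromosomes=1)
    col = np.array([0.0] * 13 + [2.0] * 13)
    rare = np.array([2.0] + [0.0] * 25)      # MAF 1/26 ~ 0.038 < 0.05
    parents = pd.DataFrame({gmap.markers[0]: col, gmap.markers[1]: col,
                            gmap.markers[2]: rare}, columns=gmap.markers)
    ld = ld_r2(parents, gmap)
    assert len(ld) == 1                       # rare marker excluded entirely
    assert ld["r2"].iloc[0] == pytest.approx(1.0)


def test_ld_hand_computed_haplotype_table():
    """26 parents with haplotype counts AB:10, ab:10, Ab:3, aB:3 give the
    brute-force squared correlation of the two dosage vectors."""
    a = np.array([2.0] * 10 + [0.0] * 10 + [2.0] * 3 + [0.0] * 3)
    b = np.array([2.0] * 10 + [0.0] * 10 + [0.0] * 3 + [2.0] * 3)
    gmap = default_map(2, n_chromosomes=1)
    parents = pd.DataFrame({gmap.markers[0]: a, gmap.markers[1]: b},
                           columns=gmap.markers)
    ld = ld_r2(parents, gmap)
    expected = np.corrcoef(a, b)[0, 1] ** 2
    assert ld["r2"].iloc[0] == pytest.approx(expected)
    assert expected == pytest.approx(((10 * 10 - 3 * 3) / 169) ** 2 / 1.0, rel=0.2)


def test_ld_invariant_to_allele_label_swap():
    rng = np.random.default_rng(8)
    gmap = default_map(6, n_chromosomes=2)
    parents = pd.DataFrame(rng.choice([0.0, 2.0], (26, 6)), columns=gmap.markers)
    ld1 = ld_r2(parents, gmap)
    flipped = parents.copy()
    flipped[gmap.markers[0]] = 2.0 - flipped[gmap.markers[0]]
    ld2 = ld_r2(flipped, gmap)
    merged = ld1.merge(ld2, on=["marker_i", "marker_j"], suffixes=("_a", "_b"))
    assert np.allclose(merged["r2_a"], merged["r2_b"])


def test_ld_heterozygotes_excluded():
    gmap = default_map(2, n_chromosomes=1)
    a = np.array([0.0] * 10 + [2.0] * 10 + [1.0] * 6)
    b = np.array([0.0] * 10 + [2.0] * 10 + [2.0, 0.0] * 3)
    parents = pd.DataFrame({gmap.markers[0]: a, gmap.markers[1]: b},
                           columns=gmap.markers)
    ld = ld_r2(parents, gmap)
    assert ld["r2"].iloc[0] == pytest.approx(1.0)   # hets dropped -> identical


def _planted_ld(baseline=0.1, noise=0.01, seed=0):
    rng = np.random.default_rng(seed)
    d = np.tile(np.arange(0.1, 20.0, 0.1), 3)
    r2 = np.exp(-d / 2.303) + rng.normal(0, noise, len(d))
    intra = pd.DataFrame({"marker_i": "x", "marker_j": "y", "distance_cm": d,
                          "unlinked": False, "r2": np.clip(r2, 0, 1)})
    inter = pd.DataFrame({"marker_i": "u", "marker_j": "v",
                          "distance_cm": np.nan, "unlinked": True,
                          "r2": np.full(200, baseline)})
    return pd.concat([intra, inter], ignore_index=True)


def test_ld_decay_recovers_planted_exponential():
    """r2(d) = exp(-d / 2.303) with a 0.1 baseline decays at
    d = 2.303 ln(10) ~ 5.3 cM."""
    base, dist, reached = ld_decay(_planted_ld())
    assert reached
    assert base == pytest.approx(0.1)
    assert dist == pytest.approx(2.303 * np.log(10.0), abs=0.5)


def test_ld_decay_degenerate_cases():
    ld = _planted_ld()
    ld.loc[ld["unlinked"], "r2"] = 0.99       # baseline above the whole curve
    base, dist, reached = ld_decay(ld)
    assert dist == 0.0 and reached
    ld2 = _planted_ld()
    ld2.loc[~ld2["unlinked"], "r2"] = 0.9     # never crosses the 0.1 baseline
    base2, dist2, reached2 = ld_decay(ld2)
    assert not reached2
    assert dist2 == pytest.approx(ld2.loc[~ld2["unlinked"], "distance_cm"].max(),
                                  abs=0.2)


def test_loess_smooth_tracks_quadratic():
    x = np.linspace(0, 10, 200)
    y = 0.5 * x ** 2 - x + 2
    grid = np.linspace(1, 9, 20)
    sm = loess_smooth(x, y, grid, span=0.3)
    assert sm == pytest.approx(0.5 * grid ** 2 - grid + 2, abs=0.05)
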