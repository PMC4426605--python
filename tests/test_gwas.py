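"""Model-B scan, cofactor selection, Holm adjustment, QTL grouping,
epistasis scan and haplotype association."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from barleynam import ModelB, default_map, group_qtl, holm_adjust
from barleynam.simulate import (BreedingScheme, make_parental_panel,
                                simulate_population)


# ---------------------------------------------------------------------------
# Holm adjustment
# ---------------------------------------------------------------------------

def test_holm_hand_example():
    got = holm_adjust([0.01, 0.04, 0.02])
    assert got == pytest.approx([0.03, 0.04, 0.04])


def test_holm_single_value_unchanged():
    assert holm_adjust([0.037]) == pytest.approx([0.037])


def test_holm_properties():
    rng = np.random.default_rng(0)
    p = rng.random(40)
    adj = holm_adjust(p)
    assert np.all(adj >= p - 1e-15)
    assert np.all(adj <= 1.0)
    order = np.argsort(p)
    assert np.all(np.diff(adj[order]) >= -1e-15)
    # smallest p-value gets the plain Bonferroni factor
    i = int(np.argmin(p))
    assert adj[i] == pytest.approx(min(1.0, p[i] * len(p)))


from hypothesis import given, settings
from hypothesis import strategies as st


@settings(max_examples=50, derandomize=True, deadline=None)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30))
def test_holm_invariants_hold_for_arbitrary_inputs(p):
    adj = holm_adjust(p)
    p = np.asarray(p)
    assert np.all(adj >= p - 1e-12)
    assert np.all(adj <= 1.0 + 1e-12)
    order = np.argsort(p)
    assert np.all(np.diff(adj[order]) >= -1e-12)


def test_holm_rejects_out_of_range():
    with pytest.raises(ValueError):
        holm_adjust([0.1, 1.2])


# ---------------------------------------------------------------------------
# small synthetic populations for scan tests
# ---------------------------------------------------------------------------

def _noise_population(n_lines=500, n_markers=200, n_fam=10, seed=0):
    gmap = default_map(n_markers)
    rng = np.random.default_rng(seed)
    panel = make_parental_panel(gmap, n_fam, seed=rng.integers(2 ** 31))
    sizes = tuple([n_lines // n_fam] * n_fam)
    pop = simulate_population(panel, BreedingScheme(family_sizes=sizes),
                              seed=rng.integers(2 ** 31))
    y = pd.Series(rng.normal(60, 3, len(pop.genotypes)), index=pop.line_ids)
    return y, pop.genotypes, pop.family, gmap, rng


def test_sbc_selects_nothing_under_pure_noise_small_pool():
    """With no planted signal and a modest candidate pool the SBC penalty
    keeps the cofactor set empty in the median replicate."""
    counts = []
    for rep in range(15):
        y, X, fam, gmap, _ = _noise_population(n_markers=20, seed=100 + rep)
        counts.append(len(ModelB(y, X, fam, gmap).select_cofactors()))
    assert np.median(counts) == 0


def test_sbc_null_selection_stays_small_large_pool():
    """Even with 200 candidate markers, pure-noise selection admits only the
    handful of entries whose best-of-pool fit beats the SBC penalty."""
    counts = []
    for rep in range(10):
        y, X, fam, gmap, _ = _noise_population(seed=150 + rep)
        counts.append(len(ModelB(y, X, fam, gmap).select_cofactors()))
    assert np.median(counts) <= 4
    assert max(counts) < 15


def test_planted_qtl_selected_first():
    y, X, fam, gmap, rng = _noise_population(seed=7)
    marker = X.columns[57]
    x = X[marker].to_numpy(dtype=float)
    # scale marker signal to ~30% of total variance
    y = y + x * (y.std() * 1.2 / x.std())
    model = ModelB(pd.Series(y, index=X.index), X, fam, gmap)
    selected = model.select_cofactors()
    assert selected, "no cofactor selected despite a strong QTL"
    i0 = gmap.index_of(selected[0])
    it = gmap.index_of(marker)
    assert gmap.chromosome[i0] == gmap.chromosome[it]
    assert abs(gmap.position[i0] - gmap.position[it]) <= 1.0


def test_selection_only_accepts_sbc_improvements():
    y, X, fam, gmap, _ = _noise_population(seed=3)
    model = ModelB(y, X, fam, gmap)
    from barleynam.gwas import _family_design, _residualize, _sbc
    n = len(y)
    B = _family_design(fam)
    selected = model.select_cofactors()
    base_sse = float((r := _residualize(B, y.to_numpy())) @ r)
    sbc_base = _sbc(n, base_sse, B.shape[1])
    D = np.column_stack([B, X[selected].to_numpy(dtype=float)]) if selected else B
    sse = float((r := _residualize(D, y.to_numpy())) @ r)
    assert _sbc(n, sse, D.shape[1]) <= sbc_base


def test_null_scan_type_one_error():
    """Raw-P rejection rate at alpha = 0.05 is ~5% under the null."""
    rejections, total = 0, 0
    for rep in range(5):
        y, X, fam, gmap, _ = _noise_population(seed=200 + rep)
        res = ModelB(y, X, fam, gmap).fit(cofactors=[])
        rejections += int((res.table["p_raw"] < 0.05).sum())
        total += len(res.table)
    assert rejections / total == pytest.approx(0.05, abs=0.02)


def test_tested_marker_dropped_from_its_own_cofactor_set():
    y, X, fam, gmap, _ = _noise_population(n_lines=200, n_markers=20, n_fam=4, seed=5)
    mk = X.columns[3]
    res_with = ModelB(y, X, fam, gmap).fit(cofactors=[mk])
    res_without = ModelB(y, X, fam, gmap).fit(cofactors=[])
    row_w = res_with.table.set_index("marker").loc[mk]
    row_o = res_without.table.set_index("marker").loc[mk]
    assert row_w["effect"] == pytest.approx(row_o["effect"], abs=1e-10)
    assert row_w["p_raw"] == pytest.approx(row_o["p_raw"], abs=1e-10)


def test_scan_detects_all_planted_qtl(heb, gwas_fit):
    """Every planted QTL with |effect| >= 2.2 days is genome-wide
    significant with the correct effect sign."""
    tab = gwas_fit.table.set_index("marker")
    for _, q in heb.truth["qtl"].iterrows():
        if abs(q["effect_days"]) < 2.2:
            continue
        row = tab.loc[q["marker"]]
        assert row["significant"], f"{q['marker']} not significant"
        assert np.sign(row["effect"]) == np.sign(q["effect_days"])
        if abs(q["effect_days"]) >= 3.0:
            assert row["p_holm"] < 1e-6


def test_constant_marker_gets_p_one():
    y, X, fam, gmap, _ = _noise_population(n_lines=100, n_markers=10, n_fam=2, seed=9)
    X = X.copy()
    X[X.columns[0]] = 0
    res = ModelB(y, X, fam, gmap).fit(cofactors=[])
    row = res.table.iloc[0]
    assert row["p_raw"] == 1.0 and np.isnan(row["effect"])


# ---------------------------------------------------------------------------
# QTL grouping
# ---------------------------------------------------------------------------

def _assoc(rows):
    return pd.DataFrame(rows, columns=["marker", "chromosome", "position_cm",
                                       "effect", "p_holm", "significant"])


def test_group_qtl_gap_rule():
    tab = _assoc([("a", "2H", 16.8, -9.0, 1e-20, True),
                  ("b", "2H", 23.0, -9.5, 1e-130, True)])
    groups = group_qtl(tab)
    assert len(groups) == 2  # 6.2 cM >= 5 cM splits them


def test_group_qtl_same_sign_chains():
    tab = _assoc([("a", "1H", 10.0, -2.0, 1e-5, True),
                  ("b", "1H", 13.0, -1.0, 1e-8, True)])
    groups = group_qtl(tab)
    assert len(groups) == 1
    assert groups[0].peak_marker == "b"


def test_group_qtl_opposite_signs_split():
    tab = _assoc([("a", "1H", 10.0, -2.0, 1e-5, True),
                  ("b", "1H", 13.0, 1.5, 1e-8, True)])
    assert len(group_qtl(tab)) == 2


def test_group_qtl_transitive_chaining_matches_exhaustive_oracle():
    """Chain at 0/4/8 cM groups into one QTL, agreeing with an exhaustive
    connected-components oracle on the <5 cM same-sign graph."""
    import itertools
    import networkx as nx
    rows = [(f"m{i}", "3H", pos, eff, 10.0 ** -(i + 3), True)
            for i, (pos, eff) in enumerate([(0.0, -1), (4.0, -2), (8.0, -1.5)])]
    tab = _assoc(rows)
    groups = group_qtl(tab)
    G = nx.Graph()
    G.add_nodes_from(tab["marker"])
    for a, b in itertools.combinations(tab.index, 2):
        ra, rb = tab.loc[a], tab.loc[b]
        # oracle chains via adjacency of consecutive sorted positions
    sorted_tab = tab.sort_values("position_cm")
    for i in range(len(sorted_tab) - 1):
        ra, rb = sorted_tab.iloc[i], sorted_tab.iloc[i + 1]
        if (rb["position_cm"] - ra["position_cm"] < 5
                and np.sign(ra["effect"]) == np.sign(rb["effect"])):
            G.add_edge(ra["marker"], rb["marker"])
    oracle_groups = list(nx.connected_components(G))
    assert len(groups) == len(oracle_groups) == 1
    assert set(groups[0].members) == set(tab["marker"])


# ---------------------------------------------------------------------------
# epistasis scan
# ---------------------------------------------------------------------------

def test_epistasis_recovers_planted_interaction(small, trial=None):
    """The planted interaction pair is significant with the planted sign
    when scanned among null pairs."""
    from barleynam import MultiEnvTrial
    tr = MultiEnvTrial(small.phenotypes).fit()
    model = ModelB(tr.blues, small.genotypes, small.families, small.gmap)
    planted = [tuple(p) for p in
               small.truth["epistatic_pairs"][["marker_j", "marker_l"]].to_numpy()]
    rng = np.random.default_rng(4)
    others = [mk for mk in small.genotypes.columns]
    null_pairs = [tuple(rng.choice(others, 2, replace=False)) for _ in range(30)]
    res = model.fit_epistasis(planted + null_pairs)
    tab = res.table.set_index(["marker_j", "marker_l"])
    strongest = small.truth["epistatic_pairs"].iloc[0]
    row = tab.loc[(strongest["marker_j"], strongest["marker_l"])]
    assert row["significant"]
    assert np.sign(row["effect"]) == np.sign(strongest["effect_days"])


def test_epistasis_null_family_wise_error():
    """Holm over the tested pair set keeps the family-wise error low under a
    purely additive model."""
    false_positives = 0
    for rep in range(8):
        y, X, fam, gmap, rng = _noise_population(n_lines=300, n_markers=40,
                                                 n_fam=6, seed=300 + rep)
        pairs = [tuple(rng.choice(X.columns, 2, replace=False)) for _ in range(50)]
        res = ModelB(y, X, fam, gmap).fit_epistasis(pairs, cofactors=[])
        false_positives += int(res.table["significant"].any())
    assert false_positives <= 2


def test_epistasis_skips_degenerate_pairs():
    y, X, fam, gmap, _ = _noise_population(n_lines=100, n_markers=10, n_fam=2, seed=1)
    mk = X.columns[0]
    res = ModelB(y, X, fam, gmap).fit_epistasis([(mk, mk)], cofactors=[])
    assert len(res.table) == 0
    assert len(res.skipped) == 1


# ---------------------------------------------------------------------------
# haplotype association
# ---------------------------------------------------------------------------

def test_tukey_kramer_two_groups_equals_t_test():
    """For k = 2 the Tukey-Kramer P equals the pooled two-sample t-test P
    through q = |t| * sqrt(2)."""
    rng = np.random.default_rng(8)
    n = 80
    y = pd.Series(rng.normal(50, 2, n))
    hap = pd.Series(np.where(np.arange(n) < 30, "A", "B"))
    y[hap == "B"] += 1.0
    gmap = default_map(4)
    X = pd.DataFrame(rng.integers(0, 3, (n, 4)).astype(float), columns=gmap.markers)
    fam = pd.Series(["F01"] * n)
    model = ModelB(y, X, fam, gmap)
    res = model.fit_haplotypes(hap, gmap.markers[0], cofactors=[], reference="A")
    t, p_t = stats.ttest_ind(y[hap == "A"], y[hap == "B"])
    expected = stats.studentized_range.sf(abs(t) * np.sqrt(2), 2, n - 2)
    assert res.comparisons["p_tukey"].iloc[0] == pytest.approx(expected, rel=1e-6)
    assert res.comparisons["p_tukey"].iloc[0] == pytest.approx(p_t, rel=1e-6)


def test_equal_means_no_significant_pairs():
    rng = np.random.default_rng(12)
    n = 120
    y = pd.Series(rng.normal(60, 2, n))
    hap = pd.Series(rng.choice(["A", "B", "C"], n))
    gmap = default_map(4)
    X = pd.DataFrame(rng.integers(0, 3, (n, 4)).astype(float), columns=gmap.markers)
    model = ModelB(y, X, pd.Series(["F01"] * n), gmap)
    res = model.fit_haplotypes(hap, gmap.markers[0], cofactors=[], reference="A")
    assert (res.comparisons["p_tukey"] > 0.05).all()


def test_single_line_haplotype_kept_with_large_se(small):
    from barleynam import MultiEnvTrial
    tr = MultiEnvTrial(small.phenotypes).fit()
    model = ModelB(tr.blues, small.genotypes, small.families, small.gmap)
    hap = small.haplotypes.copy()
    lone = hap.dropna().index[0]
    hap[hap.notna() & (hap.index != lone)] = hap.dropna().mode()[0]
    hap[lone] = "H-lone"
    anchor = small.arch.haplotype_locus.marker
    res = model.fit_haplotypes(hap, anchor, cofactors=[], reference=hap.dropna().mode()[0])
    lone_rows = res.comparisons[(res.comparisons["hap_a"] == "H-lone")
                                | (res.comparisons["hap_b"] == "H-lone")]
    assert len(lone_rows) >= 1
    assert (lone_rows["se"] > 0).all()
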