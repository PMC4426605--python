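"""Simulation of a barley nested association mapping (NAM) population.

The generator emulates the HEB-25 design: 25 wild-barley donors each crossed
to one recurrent elite parent (Barke), the F1 backcrossed once to the
recurrent parent and selfed three times by single seed descent (BC1S3),
giving 1,420 lines in 25 families. At a segregating locus the expected
BC1S3 genotype ratio is 0.71875 : 0.0625 : 0.21875 for homozygous
recurrent, heterozygous and homozygous donor genotypes.

Phenotypes (flowering time, days after sowing) are generated from a
configurable trait architecture: additive QTL (wild-minus-cultivated effect
convention), a multi-haplotype locus at the photoperiod gene Ppd-H1, di-genic
epistatic interactions on centred dosage products, a polygenic background,
and environment, genotype-by-environment and plot residual noise calibrated
to a target phenotypic SD and entry-mean heritability.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genmap import GeneticMap, default_map

__all__ = [
    "BreedingScheme", "ParentalPanel", "QTLEffect", "EpistaticPair",
    "HaplotypeLocus", "TraitArchitecture", "SimulatedPopulation",
    "NAMDataset", "expected_genotype_freqs", "meiosis",
    "simulate_single_locus", "make_parental_panel", "simulate_population",
    "simulate_phenotypes", "default_architecture", "simulate_heb25",
    "to_raw_calls",
]

#: Total population size and family count of the emulated design.
N_LINES = 1420
N_FAMILIES = 25

#: Major flowering-time QTL of the emulated study: chromosome, position (cM),
#: additive effect (days, wild minus cultivated) and the number of families in
#: which the locus segregates. The 2H/23.0 entry is the Ppd-H1 locus whose
#: effect is realised through the haplotype series below.
MAJOR_QTL = [
    ("1H", 128.3, -1.4, 25),
    ("2H", 23.0, -9.5, 24),   # Ppd-H1 (haplotype locus)
    ("2H", 57.4, -3.0, 25),
    ("3H", 108.4, -3.1, 23),
    ("4H", 3.5, 3.2, 24),
    ("4H", 113.4, 2.2, 24),
    ("5H", 125.5, 3.8, 24),
    ("7H", 34.3, 4.1, 23),
]

#: Ppd-H1 haplotype effect series (days vs. the recurrent-parent haplotype
#: H-2) and the number of donors carrying each haplotype. All wild haplotypes
#: accelerate flowering; H-6 is the earliest (-11.1 d) and H-45 carries no
#: effect. One donor carries the elite haplotype H-2, so the SNP at the locus
#: segregates in 24 of 25 families; the mean effect over those 24 donors is
#: -9.5 d, the additive SNP effect the locus presents to a biallelic scan.
PPD_H1_HAPLOTYPES = [
    ("H-6", -11.1, 3),
    ("H-1", -10.8, 2),
    ("H-3", -10.5, 2),
    ("H-4", -10.2, 2),
    ("H-5", -9.9, 2),
    ("H-7", -9.875, 4),
    ("H-8", -9.5, 2),
    ("H-9", -9.2, 2),
    ("H-10", -8.9, 2),
    ("H-11", -8.6, 2),
    ("H-45", 0.0, 1),
    ("H-2", 0.0, 1),   # donor carrying the elite haplotype (monomorphic family)
]

RECURRENT_HAPLOTYPE = "H-2"

#: Planted di-genic interactions (chromosome/position anchors and effect in
#: days on the centred dosage product); the 4H-5H pair mirrors the
#: vernalisation-gene interaction highlighted by the study system.
DEFAULT_EPISTATIC_PAIRS = [
    (("4H", 113.4), ("5H", 125.5), 3.0),
    (("3H", 108.4), ("7H", 34.3), 2.0),
]

_ARCH_SEED = 101  # fixed stream for the deterministic parts of the default design


# ---------------------------------------------------------------------------
# breeding scheme and closed-form segregation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BreedingScheme:
    """Backcross/selfing scheme. Defaults give BC1S3 with 1,420 lines in 25
    families (24 families of 57 lines, one of 52)."""
    n_backcrosses: int = 1
    n_selfings: int = 3
    family_sizes: tuple = tuple([57] * 24 + [52])
    n_bc_plants: int = 20   # BC1 plants per cross carried into selfing (SSD)

    def __post_init__(self):
        if self.n_backcrosses < 1 or self.n_selfings < 0:
            raise ValueError("need n_backcrosses >= 1 and n_selfings >= 0")
        if not self.family_sizes or any(s <= 0 for s in self.family_sizes):
            raise ValueError("family sizes must be positive")

    @property
    def n_lines(self):
        return int(sum(self.family_sizes))


def expected_genotype_freqs(n_backcrosses: int, n_selfings: int):
    """Expected genotype frequencies (hom recurrent, het, hom donor) at a
    segregating locus after ``n_backcrosses`` backcrosses to the recurrent
    parent and ``n_selfings`` generations of selfing.

    Each backcross halves the heterozygote fraction and moves the remainder
    to the homozygous recurrent class; each selfing halves it and splits the
    remainder equally between the two homozygous classes.
    """
    if n_backcrosses < 1 or n_selfings < 0:
        raise ValueError("need n_backcrosses >= 1 and n_selfings >= 0")
    het = 0.5 ** n_backcrosses
    hom_rec = 1.0 - het
    hom_don = 0.0
    lost = het * (1.0 - 0.5 ** n_selfings)
    het *= 0.5 ** n_selfings
    hom_rec += lost / 2.0
    hom_don += lost / 2.0
    return hom_rec, het, hom_don


def simulate_single_locus(n_lines: int, n_backcrosses: int = 1,
                          n_selfings: int = 3, rng=None) -> np.ndarray:
    """Simulate donor-allele dosage at one unlinked segregating locus for
    ``n_lines`` independent lines by exact Mendelian transmission.
    Used to confirm the closed-form segregation ratio by Monte Carlo."""
    rng = np.random.default_rng(rng)
    dosage = np.ones(n_lines)  # F1: heterozygous
    for _ in range(n_backcrosses):
        dosage = (rng.random(n_lines) < dosage / 2.0).astype(float)
    for _ in range(n_selfings):
        a1 = rng.random(n_lines) < dosage / 2.0
        a2 = rng.random(n_lines) < dosage / 2.0
        dosage = a1.astype(float) + a2
    return dosage.astype(np.int8)


# ---------------------------------------------------------------------------
# meiosis
# ---------------------------------------------------------------------------

def _gametes(hap_a, hap_b, rec_fractions, rng, size=None):
    """Draw gametes as mosaics of two homologs.

    ``hap_a``/``hap_b`` are allele vectors (or stacks of them, shape
    (..., m)); ``rec_fractions`` is the per-marker recombination fraction
    with the previous marker (0.5 at chromosome starts). A crossover walk
    with cumulative parity selects the source homolog per marker.
    """
    shape = (size, len(rec_fractions)) if size is not None else np.broadcast(hap_a, hap_b).shape
    cross = rng.random(shape) < rec_fractions
    phase = np.logical_xor.accumulate(cross, axis=-1)
    return np.where(phase, hap_b, hap_a)


def meiosis(parent_pair, gmap: GeneticMap, seed=None):
    """One gamete from a parental chromosome-pair under Haldane recombination.

    ``parent_pair`` is a pair of allele vectors covering all mapped markers.
    Chromosomes assort independently; recombination between adjacent markers
    at distance d cM occurs with probability r = (1 - exp(-2d/100)) / 2.
    """
    hap_a, hap_b = (np.asarray(h) for h in parent_pair)
    if hap_a.shape[-1] != len(gmap) or hap_b.shape[-1] != len(gmap):
        raise ValueError("haplotype length does not match the genetic map")
    rng = np.random.default_rng(seed)
    return _gametes(hap_a, hap_b, gmap.recomb_fractions(), rng)


# ---------------------------------------------------------------------------
# parental panel and population
# ---------------------------------------------------------------------------

@dataclass
class ParentalPanel:
    """Recurrent-parent and donor allele vectors over the mapped markers.

    Alleles are coded 0 (recurrent-parent allele) / 1 (donor allele); a
    marker is polymorphic in a family iff the donor carries allele 1 there.
    """
    recurrent: np.ndarray            # (m,) all zeros by construction
    donors: np.ndarray               # (n_families, m) 0/1
    gmap: GeneticMap

    def __post_init__(self):
        self.recurrent = np.asarray(self.recurrent, dtype=np.int8)
        self.donors = np.asarray(self.donors, dtype=np.int8)
        if self.donors.shape[1] != len(self.gmap) or len(self.recurrent) != len(self.gmap):
            raise ValueError("panel/map marker-count mismatch")

    @property
    def n_families(self):
        return self.donors.shape[0]

    @property
    def polymorphic(self):
        """(n_families, m) indicator: marker segregates in that family."""
        return self.donors != self.recurrent


def make_parental_panel(gmap: GeneticMap, n_families: int = N_FAMILIES,
                        polymorphism_prob: float = 0.5, seed=None,
                        force_polymorphic=None) -> ParentalPanel:
    """Random donor panel: each marker is polymorphic in each family
    independently with ``polymorphism_prob`` (the emulated donors share about
    half their marker states with the recurrent parent).

    ``force_polymorphic`` maps marker index -> boolean family mask to pin the
    segregation pattern at anchor loci (used for the planted QTL)."""
    rng = np.random.default_rng(seed)
    m = len(gmap)
    donors = (rng.random((n_families, m)) < polymorphism_prob).astype(np.int8)
    if force_polymorphic:
        for midx, fam_mask in force_polymorphic.items():
            donors[:, midx] = np.asarray(fam_mask, dtype=np.int8)
    return ParentalPanel(np.zeros(m, dtype=np.int8), donors, gmap)


@dataclass
class SimulatedPopulation:
    """Dosage matrix (lines x markers, donor-allele count 0/1/2) with family
    labels. ``true_genetic_value`` is filled by :func:`simulate_phenotypes`."""
    genotypes: pd.DataFrame
    family: pd.Series
    panel: ParentalPanel
    scheme: BreedingScheme
    true_genetic_value: pd.Series | None = None

    @property
    def line_ids(self):
        return self.genotypes.index

    @property
    def gmap(self):
        return self.panel.gmap

    def dosage(self) -> np.ndarray:
        return self.genotypes.to_numpy(dtype=float)


def simulate_population(panel: ParentalPanel, scheme: BreedingScheme = BreedingScheme(),
                        seed=None) -> SimulatedPopulation:
    """Breed the population: F1 -> BC1 (recurrent parent as female) -> SSD
    selfings. Lines of a family descend from a rotating set of BC1 plants.

    Markers monomorphic in a family (donor allele equals the recurrent
    allele) are dosage 0 for all its lines by construction.
    """
    if panel.n_families != len(scheme.family_sizes):
        raise ValueError("family_sizes length must equal the donor count")
    rng = np.random.default_rng(seed)
    gmap = panel.gmap
    rvec = gmap.recomb_fractions()
    m = len(gmap)
    geno = np.empty((scheme.n_lines, m), dtype=np.int8)
    fam_labels = np.empty(scheme.n_lines, dtype=object)
    row = 0
    for fi in range(panel.n_families):
        fam = f"F{fi + 1:02d}"
        nl = int(scheme.family_sizes[fi])
        donor_hap = panel.donors[fi]
        rec_hap = panel.recurrent
        # F1 genotype: one recurrent homolog, one donor homolog. Each
        # backcross pairs a gamete of the current plant with a recurrent
        # gamete (the recurrent parent is inbred, its gametes are constant).
        n_bc = min(scheme.n_bc_plants, nl)
        pairs_a = np.broadcast_to(rec_hap, (n_bc, m))
        pairs_b = _gametes(np.broadcast_to(rec_hap, (n_bc, m)),
                           np.broadcast_to(donor_hap, (n_bc, m)), rvec, rng)
        for _ in range(scheme.n_backcrosses - 1):
            pairs_b = _gametes(pairs_a, pairs_b, rvec, rng)
        # assign each line to a BC plant ancestor (single seed descent below)
        anc = np.arange(nl) % n_bc
        hap1 = pairs_a[anc]
        hap2 = pairs_b[anc]
        for _ in range(scheme.n_selfings):
            g1 = _gametes(hap1, hap2, rvec, rng)
            g2 = _gametes(hap1, hap2, rvec, rng)
            hap1, hap2 = g1, g2
        geno[row:row + nl] = hap1 + hap2
        fam_labels[row:row + nl] = fam
        row += nl
    line_ids = [f"{fam_labels[i]}_{i + 1:04d}" for i in range(scheme.n_lines)]
    gdf = pd.DataFrame(geno, index=pd.Index(line_ids, name="line_id"),
                       columns=gmap.markers)
    fam = pd.Series(fam_labels, index=gdf.index, name="family")
    return SimulatedPopulation(gdf, fam, panel, scheme)


# ---------------------------------------------------------------------------
# trait architecture and phenotypes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QTLEffect:
    marker: str
    effect_days: float          # wild (donor) minus cultivated (recurrent)
    seg_families: tuple         # family labels in which the locus segregates


@dataclass(frozen=True)
class EpistaticPair:
    marker_j: str
    marker_l: str
    effect_days: float          # coefficient of the centred dosage product


@dataclass(frozen=True)
class HaplotypeLocus:
    marker: str
    donor_haplotype: dict       # family label -> haplotype id
    effects: dict               # haplotype id -> effect in days vs recurrent
    recurrent_haplotype: str = RECURRENT_HAPLOTYPE


@dataclass
class TraitArchitecture:
    """Planted genetic architecture and calibration targets.

    ``target_sd`` is the SD of line entry-means (days); ``target_h2`` the
    entry-mean heritability. Polygenic background variance is topped up so
    the realised genotypic variance equals target_h2 * target_sd**2.
    ``gxe_share`` splits the non-genetic entry-mean variance between
    genotype-by-environment interaction and plot residual.
    """
    qtl: list = field(default_factory=list)
    epistatic_pairs: list = field(default_factory=list)
    haplotype_locus: HaplotypeLocus | None = None
    n_polygenic: int = 300
    n_environments: int = 3
    n_replicates: int = 2
    mu: float = 68.1
    target_sd: float = 6.5
    target_h2: float = 0.916
    env_sd: float = 4.0
    gxe_share: float = 0.4

    def __post_init__(self):
        if not (0.0 < self.target_h2 <= 1.0):
            raise ValueError("target_h2 must be in (0, 1]")
        for q in self.qtl:
            if not np.isfinite(q.effect_days):
                raise ValueError("non-finite QTL effect")

    @property
    def sigma2_G(self):
        return self.target_h2 * self.target_sd ** 2


def default_architecture(gmap: GeneticMap, seed: int = _ARCH_SEED) -> TraitArchitecture:
    """Default trait architecture: the eight major QTL of the emulated study
    anchored to the nearest mapped marker, the 12-haplotype Ppd-H1 locus,
    two planted epistatic pairs, and a 300-marker polygenic background.

    The random parts (which families segregate at each QTL, donor-to-
    haplotype assignment) are drawn from a fixed stream so the default
    design is reproducible independently of the breeding-simulation seed.
    """
    rng = np.random.default_rng(seed)
    fams = [f"F{i + 1:02d}" for i in range(N_FAMILIES)]

    # donor haplotypes at Ppd-H1
    hap_of_family = {}
    donor_order = rng.permutation(N_FAMILIES)
    expanded = [h for h, _, mult in PPD_H1_HAPLOTYPES for _ in range(mult)]
    for fam_idx, hap in zip(donor_order, expanded):
        hap_of_family[fams[fam_idx]] = hap
    hap_effects = {h: e for h, e, _ in PPD_H1_HAPLOTYPES}
    ppd_anchor = gmap.nearest_marker("2H", 23.0)
    hap_locus = HaplotypeLocus(ppd_anchor, hap_of_family, hap_effects)

    qtl = []
    for chrom, pos, effect, n_seg in MAJOR_QTL:
        marker = gmap.nearest_marker(chrom, pos)
        if (chrom, pos) == ("2H", 23.0):
            # Ppd-H1 segregates exactly where the donor haplotype is exotic
            seg = tuple(f for f in fams if hap_of_family[f] != RECURRENT_HAPLOTYPE)
        else:
            seg = tuple(sorted(rng.choice(fams, size=n_seg, replace=False)))
        qtl.append(QTLEffect(marker, effect, seg))

    pairs = [EpistaticPair(gmap.nearest_marker(*a), gmap.nearest_marker(*b), f)
             for a, b, f in DEFAULT_EPISTATIC_PAIRS]
    return TraitArchitecture(qtl=qtl, epistatic_pairs=pairs, haplotype_locus=hap_locus)


def panel_for_architecture(gmap: GeneticMap, arch: TraitArchitecture,
                           seed=None, polymorphism_prob: float = 0.5) -> ParentalPanel:
    """Donor panel whose segregation pattern at the planted anchors matches
    the architecture's segregating-family sets."""
    fams = [f"F{i + 1:02d}" for i in range(N_FAMILIES)]
    force = {}
    for q in arch.qtl:
        midx = gmap.index_of(q.marker)
        force[midx] = np.array([f in q.seg_families for f in fams])
    return make_parental_panel(gmap, N_FAMILIES, polymorphism_prob, seed, force)


def _haplotype_of_lines(pop: SimulatedPopulation, locus: HaplotypeLocus) -> pd.Series:
    """Per-line haplotype label at the locus: donor haplotype for homozygous
    donor lines, the recurrent haplotype for homozygous recurrent lines, and
    missing (NA) for heterozygous lines, which carry both sequences and are
    excluded from haplotype grouping."""
    dosage = pop.genotypes[locus.marker]
    donor_hap = pop.family.map(locus.donor_haplotype)
    hap = pd.Series(locus.recurrent_haplotype, index=pop.line_ids, name="haplotype")
    hap[dosage == 2] = donor_hap[dosage == 2]
    hap[dosage == 1] = pd.NA
    return hap


def genetic_values(pop: SimulatedPopulation, arch: TraitArchitecture, rng=None):
    """True genetic value per line (days, deviation from mu) plus the planted
    polygenic effect table. The polygenic component is rescaled so the
    realised genotypic variance equals the architecture's sigma2_G target.
    """
    rng = np.random.default_rng(rng)
    X = pop.genotypes
    n = len(X)
    g_major = np.zeros(n)
    # additive QTL; at the haplotype locus the effect is haplotype-specific
    hap_marker = arch.haplotype_locus.marker if arch.haplotype_locus else None
    for q in arch.qtl:
        if q.marker == hap_marker:
            continue
        g_major += (q.effect_days / 2.0) * X[q.marker].to_numpy(dtype=float)
    if arch.haplotype_locus is not None:
        loc = arch.haplotype_locus
        donor_hap = pop.family.map(loc.donor_haplotype)
        h_eff = donor_hap.map(loc.effects).to_numpy(dtype=float)
        g_major += (X[loc.marker].to_numpy(dtype=float) / 2.0) * h_eff
    for pair in arch.epistatic_pairs:
        # centred at the expected dosage mean (0.5) of the breeding design
        xj = X[pair.marker_j].to_numpy(dtype=float) - 0.5
        xl = X[pair.marker_l].to_numpy(dtype=float) - 0.5
        g_major += pair.effect_days * xj * xl

    var_major = float(np.var(g_major))
    sigma2_G = arch.sigma2_G
    if var_major > sigma2_G:
        raise ValueError(
            f"infeasible calibration: planted major-locus variance {var_major:.2f} "
            f"exceeds the genotypic variance target {sigma2_G:.2f}")

    poly_effects = pd.DataFrame(columns=["marker", "effect"])
    g_poly = np.zeros(n)
    if arch.n_polygenic > 0 and var_major < sigma2_G:
        anchors = {q.marker for q in arch.qtl}
        if hap_marker:
            anchors.add(hap_marker)
        candidates = [mk for mk in X.columns if mk not in anchors]
        chosen = rng.choice(len(candidates), size=min(arch.n_polygenic, len(candidates)),
                            replace=False)
        markers = [candidates[i] for i in sorted(chosen)]
        beta = rng.normal(0.0, 1.0, size=len(markers))
        Xp = X[markers].to_numpy(dtype=float)
        g_poly = (Xp - Xp.mean(axis=0)) @ beta
        # scale so var(g_major + c * g_poly) equals sigma2_G exactly
        v_p = float(np.var(g_poly))
        cov = float(np.mean((g_major - g_major.mean()) * (g_poly - g_poly.mean())))
        disc = cov ** 2 + v_p * (sigma2_G - var_major)
        c = (-cov + np.sqrt(max(disc, 0.0))) / v_p if v_p > 0 else 0.0
        g_poly *= c
        beta *= c
        poly_effects = pd.DataFrame({"marker": markers, "effect": beta})
    g = g_major + g_poly
    return pd.Series(g - g.mean(), index=pop.line_ids, name="genetic_value"), poly_effects


def simulate_phenotypes(pop: SimulatedPopulation, arch: TraitArchitecture,
                        seed=None):
    """Multi-environment phenotypes y_ier = mu + G_i + E_e + GE_ie + eps_ier.

    Non-genetic variances are set from the calibration targets: with entry-
    mean variance target sd^2 and genotypic variance h2*sd^2, the deficit is
    split ``gxe_share`` : (1 - gxe_share) between GxE and plot residual on
    the entry-mean scale. Returns (phenotype table, truth dict) and fills
    ``pop.true_genetic_value``.
    """
    rng = np.random.default_rng(seed)
    g, poly = genetic_values(pop, arch, rng)
    pop.true_genetic_value = g
    n = len(g)
    l, r = arch.n_environments, arch.n_replicates
    deficit = arch.target_sd ** 2 * (1.0 - arch.target_h2)
    sigma2_ge = arch.gxe_share * deficit * l
    sigma2_res = (1.0 - arch.gxe_share) * deficit * l * r
    env_labels = [f"E{e + 1}" for e in range(l)]
    env_eff = rng.normal(0.0, arch.env_sd, size=l)
    ge = rng.normal(0.0, np.sqrt(sigma2_ge), size=(n, l)) if sigma2_ge > 0 else np.zeros((n, l))
    rows = []
    gv = g.to_numpy()
    for e in range(l):
        for rep in range(r):
            eps = rng.normal(0.0, np.sqrt(sigma2_res), size=n) if sigma2_res > 0 else np.zeros(n)
            vals = arch.mu + gv + env_eff[e] + ge[:, e] + eps
            rows.append(pd.DataFrame({
                "line_id": pop.line_ids, "environment": env_labels[e],
                "replicate": f"R{rep + 1}", "value": vals}))
    pheno = pd.concat(rows, ignore_index=True)
    truth = {
        "genetic_value": g,
        "polygenic_effects": poly,
        "qtl": pd.DataFrame([dataclasses.asdict(q) for q in arch.qtl]),
        "epistatic_pairs": pd.DataFrame([dataclasses.asdict(p) for p in arch.epistatic_pairs]),
        "variances": {"sigma2_G": arch.sigma2_G, "sigma2_GE": sigma2_ge,
                      "sigma2_R": sigma2_res},
    }
    return pheno, truth


# ---------------------------------------------------------------------------
# one-call dataset
# ---------------------------------------------------------------------------

@dataclass
class NAMDataset:
    """Bundle of everything one simulated study produces."""
    genotypes: pd.DataFrame
    gmap: GeneticMap
    families: pd.Series
    haplotypes: pd.Series
    phenotypes: pd.DataFrame
    truth: dict
    arch: TraitArchitecture
    population: SimulatedPopulation


def simulate_heb25(seed=0, n_markers: int = 2000, arch: TraitArchitecture | None = None,
                   scheme: BreedingScheme = BreedingScheme()) -> NAMDataset:
    """Simulate a full default study: genome, panel, BC1S3 population,
    phenotypes and haplotype assignments, all descending from one seed."""
    ss = np.random.SeedSequence(seed)
    s_panel, s_pop, s_pheno = ss.spawn(3)
    gmap = default_map(n_markers)
    if arch is None:
        arch = default_architecture(gmap)
    panel = panel_for_architecture(gmap, arch, seed=s_panel)
    pop = simulate_population(panel, scheme, seed=s_pop)
    pheno, truth = simulate_phenotypes(pop, arch, seed=s_pheno)
    hap = (_haplotype_of_lines(pop, arch.haplotype_locus)
           if arch.haplotype_locus else pd.Series(pd.NA, index=pop.line_ids))
    return NAMDataset(pop.genotypes, gmap, pop.family, hap, pheno, truth, arch, pop)


# ---------------------------------------------------------------------------
# raw-call export (for the QC stage)
# ---------------------------------------------------------------------------

def to_raw_calls(pop: SimulatedPopulation, missing_rate: float = 0.0, seed=None):
    """Re-express the dosage matrix as array-style genotype calls.

    Each marker gets a random allele-label orientation (the donor allele is
    'A' or 'B' arbitrarily, as on a genotyping chip), producing line calls in
    {'AA','AB','BB'} with optional missingness (NA). Parent calls are
    returned alongside so identity-by-state encoding can be exercised.
    Returns (raw_calls, parent_calls) DataFrames.
    """
    rng = np.random.default_rng(seed)
    m = pop.genotypes.shape[1]
    flip = rng.random(m) < 0.5            # True: donor allele labelled 'A'
    dos = pop.genotypes.to_numpy()
    donor_count = np.where(flip, dos, 2 - dos)   # count of 'A' alleles
    states = np.array(["BB", "AB", "AA"], dtype=object)
    calls = states[donor_count]
    calls = pd.DataFrame(calls, index=pop.line_ids, columns=pop.genotypes.columns)
    if missing_rate > 0:
        mask = rng.random(calls.shape) < missing_rate
        calls = calls.mask(mask, other=pd.NA)
    # parents: recurrent parent (all dosage 0) then one donor per family
    prows, pidx = [], []
    rec_count = np.where(flip, 0, 2)
    prows.append(states[rec_count]); pidx.append("Barke")
    for fi in range(pop.panel.n_families):
        d = pop.panel.donors[fi] * 2
        cnt = np.where(flip, d, 2 - d)
        prows.append(states[cnt]); pidx.append(f"Donor_F{fi + 1:02d}")
    parents = pd.DataFrame(np.vstack(prows), index=pd.Index(pidx, name="line_id"),
                           columns=pop.genotypes.columns)
    return calls, parents
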