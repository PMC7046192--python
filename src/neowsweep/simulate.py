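"""Forward-in-time generator of synthetic cohorts with the inheritance
structure of the neo-W / male-killer system.

The model: ZW sex determination with achiasmatic female meiosis (mothers
transmit intact chromosomes), a W-chr15 fusion whose haplotype travels only
mother-to-daughter, a maternally inherited male-killing endosymbiont
co-transmitted with the mitochondrion, male immigration from a pool fixed
for the dominant supergene allele, infinite-sites mutation, and a 3-allele
dominance-series supergene with suppressed recombination between allele
classes.

Standing variation is imported from a coalescent simulation of the large
panmictic ancestral species (msprime); the forward process then simulates
the recent generations around the fusion event.  This separation is what
lets a desk-scale run separate the fusion timescale from the background
coalescent by orders of magnitude, as in the real system.  A pure forward
burn-in mode (``standing_variation="forward"``) is kept for validating the
transmission machinery against neutral expectations.

Mutations are identified by integer positions (infinite sites via a global
per-chromosome position registry); haplotypes hold sorted position arrays,
so genotypes can be re-derived from truth exactly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_core import GenomeLayout, GenotypeMatrix, HaplotypeSet

SUPERGENE_ALLELES = ("dorippus", "chrysippus", "orientis")
BASES = np.array([65, 67, 71, 84], dtype=np.uint8)  # A C G T


class PopulationExtinct(Exception):
    """Explicit extinction signal: no sons can be produced."""


def _member(sorted_array: np.ndarray, positions: np.ndarray) -> np.ndarray:
    """Membership of ``positions`` in a sorted int array, vectorised."""
    m = sorted_array
    if len(m) == 0:
        return np.zeros(len(positions), dtype=bool)
    idx = np.minimum(np.searchsorted(m, positions), len(m) - 1)
    return m[idx] == positions


@dataclass
class SimParams:
    """Parameters of the simulated world.

    Defaults are the package's stated desk-scale world: a contact-zone deme
    of 120 breeding adults embedded in a huge panmictic species (ancestral
    Ne sets background diversity near the observed 4-fold level of ~0.04),
    a 300-kb supergene with three anciently diverged low-diversity allele
    classes, full male-killing penetrance and perfect symbiont transmission,
    a 10% survival advantage for daughters of infected broods, and 100
    generations of forward time after the fusion appears.
    """

    n_females: int = 60
    n_males: int = 60
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr15": 1_000_000, "chr2": 500_000,
                                 "mito": 20_000})
    mu: float = 2e-6                   # per-base per-generation
    ancestral_ne: float = 5_000.0      # coalescent import Ne (diploid)
    mito_ne_factor: float = 0.25
    recomb_rate_ancestral: float = 1e-7
    male_crossover_rate: float = 1.0   # expected crossovers / chrom / meiosis
    migration: float = 0.1             # male immigration fraction m
    mk_penetrance: float = 1.0         # k_mk: P(son of infected mother dies)
    transmission_fidelity: float = 1.0  # tau
    daughter_advantage: float = 0.1    # s: infected-brood daughter fitness
    t_fusion: int = 0                  # generations after burn-in
    run_generations: int = 100
    burn_in: int = 10
    supergene: tuple[str, int, int] = ("chr15", 200_000, 500_000)
    colinear_start: int = 600_000
    supergene_init_freqs: dict[str, float] = field(
        default_factory=lambda: {"dorippus": 0.45, "chrysippus": 0.35,
                                 "orientis": 0.20})
    supergene_divergence: int = 7000   # defining mutations per allele class
    supergene_within_pi: float = 0.001
    transiens_penetrance: float = 0.5
    symbiont_length: int = 200_000     # clonal symbiont genome
    allopatric_size: int = 12          # diploids per allopatric panel
    immigrant_pool_size: int = 30
    n_genes: int = 120                 # per coding chromosome
    gene_codons: int = 200
    deleterious_sfs_shape: float = 0.0  # 0 = fully neutral standing variation
    standing_variation: str = "coalescent"  # or "forward"

    def validate(self) -> None:
        if self.n_females <= 0 or self.n_males <= 0:
            raise ValueError("population sizes must be positive")
        if self.mu < 0:
            raise ValueError("mutation rate must be non-negative")
        for name, p in [("migration", self.migration),
                        ("mk_penetrance", self.mk_penetrance),
                        ("transmission_fidelity", self.transmission_fidelity),
                        ("transiens_penetrance", self.transiens_penetrance)]:
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        for c, ln in self.chrom_lengths.items():
            if ln <= 0:
                raise ValueError(f"zero-length chromosome {c}")
        f = self.supergene_init_freqs
        if abs(sum(f.values()) - 1) > 1e-9 or set(f) - set(SUPERGENE_ALLELES):
            raise ValueError("supergene_init_freqs must sum to 1 over the "
                             "three alleles")

    @property
    def coding_chroms(self) -> list[str]:
        return [c for c in self.chrom_lengths if c != "mito"]


class Hap:
    """One haplotype: sorted derived-mutation positions (+ supergene state).

    ``node`` is the haplotype's id in the recorded fused-lineage genealogy
    (None for non-fused haplotypes)."""

    __slots__ = ("muts", "allele", "fused", "node")

    def __init__(self, muts, allele=None, fused=False, node=None):
        self.muts = np.asarray(muts, dtype=np.int64)
        self.allele = allele
        self.fused = fused
        self.node = node

    def with_new(self, new_positions, fused=None):
        muts = (self.muts if len(new_positions) == 0
                else np.sort(np.concatenate([self.muts, new_positions])))
        return Hap(muts, self.allele,
                   self.fused if fused is None else fused)


class Individual:
    __slots__ = ("sex", "chr15", "auto", "mito", "infected", "matriline",
                 "symbiont")

    def __init__(self, sex, chr15, auto, mito, infected, matriline,
                 symbiont=None):
        self.sex = sex              # "female" / "male"
        self.chr15 = chr15          # (maternal Hap, paternal Hap)
        self.auto = auto
        self.mito = mito            # np.int64 positions
        self.infected = infected
        self.matriline = matriline
        self.symbiont = symbiont    # np.int64 positions, None if uninfected


@dataclass
class SimState:
    params: SimParams
    rng: np.random.Generator
    females: list = field(default_factory=list)
    males: list = field(default_factory=list)
    panels: dict = field(default_factory=dict)      # static allopatric demes
    pool_males: list = field(default_factory=list)  # immigrant source
    used: dict = field(default_factory=dict)        # chrom -> set(positions)
    refseq: dict = field(default_factory=dict)      # chrom -> uint8 codes 0-3
    genes: pd.DataFrame | None = None
    generation: int = 0
    extinct: bool = False
    trajectory: list = field(default_factory=list)
    fusion_generation: int | None = None
    foundress_matriline: str | None = None
    foundress_mito: np.ndarray | None = None
    # genealogy of the fused haplotype: node -> (parent node, birth gen)
    fused_tree: dict = field(default_factory=dict)
    _next_node: int = 0

    @property
    def layout(self) -> GenomeLayout:
        return GenomeLayout(dict(self.params.chrom_lengths))


# ---------------------------------------------------------------------------
# initialisation


def _chrom_len(params: SimParams, chrom: str) -> int:
    if chrom == "symbiont":
        return params.symbiont_length
    return params.chrom_lengths[chrom]


def _new_positions(state: SimState, chrom: str, k: int) -> np.ndarray:
    """Draw k never-used integer positions on chrom (infinite sites)."""
    if k == 0:
        return np.empty(0, dtype=np.int64)
    L = _chrom_len(state.params, chrom)
    used = state.used.setdefault(chrom, set())
    out = []
    while len(out) < k:
        p = int(state.rng.integers(0, L))
        if p not in used:
            used.add(p)
            out.append(p)
    return np.array(out, dtype=np.int64)


def _register(state: SimState, chrom: str, positions) -> None:
    state.used.setdefault(chrom, set()).update(int(p) for p in positions)


def _make_reference(state: SimState) -> None:
    """Random reference sequence; gene regions use stop-free codons."""
    from .pnps import STOP_CODONS

    p = state.params
    rows = []
    for chrom in p.coding_chroms:
        L = p.chrom_lengths[chrom]
        seq = state.rng.integers(0, 4, size=L).astype(np.uint8)
        glen = 3 * p.gene_codons
        spacing = max(L // max(p.n_genes, 1), glen + 1)
        for g in range(p.n_genes):
            start = g * spacing
            if start + glen > L:
                break
            for cpos in range(start, start + glen, 3):
                while tuple(seq[cpos:cpos + 3]) in STOP_CODONS:
                    seq[cpos:cpos + 3] = state.rng.integers(0, 4, size=3)
            rows.append((f"{chrom}_g{g:03d}", chrom, start, start + glen, "+"))
        state.refseq[chrom] = seq
    mlen = p.chrom_lengths.get("mito", 0)
    if mlen:
        state.refseq["mito"] = state.rng.integers(0, 4, mlen).astype(np.uint8)
    state.genes = pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "strand"])


def _coalescent_haps(state: SimState, chrom: str, n_haps: int,
                     ne: float, recomb: float) -> list[np.ndarray]:
    """Standing variation: derived-position arrays for n_haps haplotypes."""
    import msprime

    p = state.params
    L = p.chrom_lengths[chrom]
    seed1, seed2 = state.rng.integers(1, 2**31 - 1, size=2)
    ts = msprime.sim_ancestry(
        samples=n_haps, ploidy=1, population_size=ne,
        sequence_length=L, recombination_rate=recomb,
        random_seed=int(seed1))
    ts = msprime.sim_mutations(ts, rate=p.mu, random_seed=int(seed2),
                               discrete_genome=False,
                               model=msprime.BinaryMutationModel())
    used = state.used.setdefault(chrom, set())
    positions = np.empty(ts.num_sites, dtype=np.int64)
    for i, site in enumerate(ts.sites()):
        pos = int(site.position)
        while pos in used:
            pos = (pos + 1) % L
        used.add(pos)
        positions[i] = pos
    G = ts.genotype_matrix()  # (n_sites, n_haps)
    return [np.sort(positions[G[:, h] != 0]) for h in range(n_haps)]


def _shape_deleterious(state: SimState, haps: list[np.ndarray], chrom: str
                       ) -> list[np.ndarray]:
    """Emulate purifying selection on standing variation: thin derived
    variants at 0-fold reference positions with retention probability
    (1 - x)^shape, x the derived frequency.  Leaves 4-fold and non-coding
    variants untouched."""
    from .pnps import reference_degeneracy

    shape = state.params.deleterious_sfs_shape
    if shape <= 0:
        return haps
    deg = reference_degeneracy(state.refseq[chrom],
                               state.genes[state.genes.chrom == chrom])
    zf = np.sort(np.array([p for p, cls in deg.items()
                           if cls == "zero-fold"], dtype=np.int64))
    if zf.size == 0:
        return haps
    hits = [h[np.isin(h, zf)] for h in haps]
    allpos, counts = np.unique(np.concatenate(hits), return_counts=True)
    if allpos.size == 0:
        return haps
    keep_p = (1 - counts / len(haps)) ** shape
    drop = allpos[state.rng.random(allpos.size) > keep_p]
    if drop.size == 0:
        return haps
    return [h[~np.isin(h, drop)] for h in haps]


def _draw_free(state: SimState, chrom: str, lo: int, hi: int,
               k: int) -> np.ndarray:
    """k unused integer positions in [lo, hi), robust to a crowded registry."""
    if k == 0:
        return np.empty(0, dtype=np.int64)
    used = state.used.setdefault(chrom, set())
    out: list[int] = []
    attempts = 0
    while len(out) < k and attempts < 20 * k:
        p = int(state.rng.integers(lo, hi))
        attempts += 1
        if p not in used:
            used.add(p)
            out.append(p)
    if len(out) < k:  # registry nearly saturated: enumerate what is left
        free = np.array([p for p in range(lo, hi) if p not in used],
                        dtype=np.int64)
        if len(free) < k - len(out):
            raise ValueError(
                f"infinite-sites registry exhausted on {chrom}[{lo},{hi}): "
                f"need {k - len(out)} more positions, {len(free)} free")
        extra = state.rng.choice(free, size=k - len(out), replace=False)
        used.update(int(p) for p in extra)
        out.extend(int(p) for p in extra)
    return np.array(out, dtype=np.int64)


def _build_supergene_classes(state: SimState) -> dict[str, np.ndarray]:
    """Class-defining mutation templates for the three supergene alleles.

    Each allele class descends from a single ancient inversion haplotype:
    between-class divergence is injected as private defining mutations,
    within-class diversity is regenerated as a small per-haplotype Poisson
    number of private mutations (see assign_supergene)."""
    chrom, lo, hi = state.params.supergene
    templates = {}
    for allele in SUPERGENE_ALLELES:
        templates[allele] = np.sort(_draw_free(
            state, chrom, lo, hi, state.params.supergene_divergence))
    return templates


def _assign_supergene(state: SimState, hap: Hap, allele: str,
                      templates: dict[str, np.ndarray]) -> Hap:
    """Replace a haplotype's supergene interval with its class haplotype."""
    chrom, lo, hi = state.params.supergene
    keep = hap.muts[(hap.muts < lo) | (hap.muts >= hi)]
    n_priv = state.rng.poisson(state.params.supergene_within_pi / 2 * (hi - lo))
    priv = _draw_free(state, chrom, lo, hi, n_priv)
    muts = np.sort(np.concatenate([keep, templates[allele], priv]))
    return Hap(muts, allele=allele, fused=hap.fused)


def init_population(params: SimParams, seed=None) -> SimState:
    """Initial population (+ static allopatric panels and immigrant pool).

    In ``coalescent`` mode (default), standing variation at mutation-drift
    balance for the ancestral Ne is imported per chromosome and the three
    supergene allele classes are constructed; in ``forward`` mode all
    haplotypes start empty and diversity accrues by forward mutation only.
    """
    params.validate()
    rng = np.random.default_rng(seed)
    state = SimState(params=params, rng=rng)
    _make_reference(state)
    p = params

    n_focal = p.n_females + p.n_males
    coalescent = p.standing_variation == "coalescent"
    panel_demes = list(SUPERGENE_ALLELES) if coalescent else []
    n_panel = p.allopatric_size * len(panel_demes)
    n_pool = p.immigrant_pool_size if coalescent else 0
    n_ind = n_focal + n_panel + n_pool

    hapsets = {}
    for chrom in p.coding_chroms:
        if coalescent:
            haps = _coalescent_haps(state, chrom, 2 * n_ind, p.ancestral_ne,
                                    p.recomb_rate_ancestral)
            haps = _shape_deleterious(state, haps, chrom)
        else:
            haps = [np.empty(0, dtype=np.int64) for _ in range(2 * n_ind)]
        hapsets[chrom] = [Hap(h) for h in haps]
    if coalescent:
        mitos = _coalescent_haps(state, "mito", n_ind,
                                 p.ancestral_ne * p.mito_ne_factor, 0.0)
    else:
        mitos = [np.empty(0, dtype=np.int64) for _ in range(n_ind)]

    templates = _build_supergene_classes(state) if coalescent else None
    sg_chrom = p.supergene[0]
    alleles = list(p.supergene_init_freqs)
    freqs = np.array([p.supergene_init_freqs[a] for a in alleles])

    counter = itertools.count()

    def take(sex, deme_allele=None, matriline=None):
        i = next(counter)
        ind_haps = {}
        for chrom in p.coding_chroms:
            h0, h1 = hapsets[chrom][2 * i], hapsets[chrom][2 * i + 1]
            if chrom == sg_chrom:
                if templates is not None:
                    a0 = deme_allele or str(rng.choice(alleles, p=freqs))
                    a1 = deme_allele or str(rng.choice(alleles, p=freqs))
                    h0 = _assign_supergene(state, h0, a0, templates)
                    h1 = _assign_supergene(state, h1, a1, templates)
                else:
                    h0.allele = str(rng.choice(alleles, p=freqs))
                    h1.allele = str(rng.choice(alleles, p=freqs))
            ind_haps[chrom] = (h0, h1)
        return Individual(sex, ind_haps[sg_chrom],
                          ind_haps.get("chr2", ind_haps[sg_chrom]),
                          mitos[i], False, matriline)

    for j in range(p.n_females):
        state.females.append(take("female", matriline=f"M{j:03d}"))
    for _ in range(p.n_males):
        state.males.append(take("male"))
    for deme in panel_demes:
        panel = []
        half = p.allopatric_size // 2
        for j in range(p.allopatric_size):
            sex = "female" if j < p.allopatric_size - half else "male"
            panel.append(take(sex, deme_allele=deme,
                              matriline=f"{deme[:3]}{j:03d}"))
        state.panels[deme] = panel
    for _ in range(n_pool):
        state.pool_males.append(take("male", deme_allele="dorippus"))

    if p.standing_variation == "forward":
        for _ in range(p.burn_in):
            advance_generation(state)
            if state.extinct:
                break
    else:
        for _ in range(p.burn_in):
            advance_generation(state)
            if state.extinct:
                break
    return state


# ---------------------------------------------------------------------------
# forward process


def _male_meiosis(state: SimState, father: Individual, chrom: str) -> Hap:
    """Recombinant paternal gamete.  Crossovers fall uniformly; within the
    supergene interval they are suppressed when the father is heterozygous
    for different allele classes (inversion model)."""
    p = state.params
    h1, h2 = (father.chr15 if chrom == p.supergene[0] else father.auto)
    L = p.chrom_lengths[chrom]
    n_x = state.rng.poisson(p.male_crossover_rate)
    breaks = np.sort(state.rng.integers(1, L, size=n_x)) if n_x else \
        np.empty(0, dtype=np.int64)
    if chrom == p.supergene[0] and h1.allele != h2.allele and len(breaks):
        lo, hi = p.supergene[1], p.supergene[2]
        breaks = breaks[(breaks < lo) | (breaks >= hi)]
    cur, other = (h1, h2) if state.rng.random() < 0.5 else (h2, h1)
    if len(breaks) == 0:
        gam = Hap(cur.muts.copy(), cur.allele, False)
    else:
        segs = []
        bounds = np.concatenate([[0], breaks, [L]])
        src = cur
        sg_mid = (p.supergene[1] + p.supergene[2]) // 2
        allele = cur.allele
        for a, b in zip(bounds[:-1], bounds[1:]):
            m = src.muts
            segs.append(m[(m >= a) & (m < b)])
            if chrom == p.supergene[0] and a <= sg_mid < b:
                allele = src.allele
            src = other if src is cur else cur
        gam = Hap(np.concatenate(segs), allele, False)
    new = _new_positions(state, chrom, state.rng.poisson(p.mu * L))
    return gam.with_new(new)


def _maternal_hap(state: SimState, mother: Individual, chrom: str,
                  daughter: bool) -> Hap:
    """Intact maternal chromosome (achiasmatic female meiosis).  A fused
    chr15 haplotype travels with the W: always to daughters, never to sons."""
    p = state.params
    pair = mother.chr15 if chrom == p.supergene[0] else mother.auto
    if chrom == p.supergene[0] and pair[0].fused:
        src = pair[0] if daughter else pair[1]
    else:
        src = pair[0] if state.rng.random() < 0.5 else pair[1]
    new = _new_positions(state, chrom, state.rng.poisson(
        p.mu * p.chrom_lengths[chrom]))
    child = src.with_new(new)
    if child.fused:
        child.node = state._next_node
        state.fused_tree[child.node] = (src.node, state.generation + 1)
        state._next_node += 1
    return child


def _make_offspring(state: SimState, mother: Individual, father: Individual,
                    sex: str) -> Individual:
    p = state.params
    daughter = sex == "female"
    chr15 = (_maternal_hap(state, mother, p.supergene[0], daughter),
             _male_meiosis(state, father, p.supergene[0]))
    auto_chrom = "chr2" if "chr2" in p.chrom_lengths else p.supergene[0]
    auto = (_maternal_hap(state, mother, auto_chrom, daughter),
            _male_meiosis(state, father, auto_chrom))
    mito = np.sort(np.concatenate(
        [mother.mito, _new_positions(state, "mito", state.rng.poisson(
            p.mu * p.chrom_lengths.get("mito", 0)))]))
    infected = mother.infected and (state.rng.random()
                                    < p.transmission_fidelity)
    symbiont = None
    if infected:
        symbiont = np.sort(np.concatenate(
            [mother.symbiont, _new_positions(
                state, "symbiont",
                state.rng.poisson(p.mu * p.symbiont_length))]))
    assert not chr15[1].fused, "paternal chr15 can never be fused"
    if sex == "male":
        assert not chr15[0].fused and not chr15[1].fused, \
            "males never carry a fused haplotype"
    return Individual(sex, chr15, auto, mito, infected, mother.matriline,
                      symbiont)


def _pick_father(state: SimState) -> Individual | None:
    p = state.params
    pool_ok = len(state.pool_males) > 0
    res_ok = len(state.males) > 0
    if pool_ok and (not res_ok or state.rng.random() < p.migration):
        return state.pool_males[state.rng.integers(len(state.pool_males))]
    if res_ok:
        return state.males[state.rng.integers(len(state.males))]
    return None


def advance_generation(state: SimState) -> SimState:
    """One non-overlapping generation.

    Mothers of daughters are sampled with weight (1+s) when infected (the
    infected-brood survival compensation); mothers of sons with weight
    (1 - k_mk) when infected (male-killing acts before density regulation).
    If no mother can produce a surviving son the population is flagged
    extinct (explicit signal, not a crash).
    """
    p = state.params
    if state.extinct:
        return state
    if not state.females:
        state.extinct = True
        return state
    inf = np.array([f.infected for f in state.females], dtype=float)
    w_d = 1.0 + p.daughter_advantage * inf
    w_s = 1.0 - p.mk_penetrance * inf
    if not state.males and not state.pool_males:
        state.extinct = True  # no fathers anywhere: true extinction
        return state
    new_f, new_m = [], []
    mothers_d = state.rng.choice(len(state.females), size=p.n_females,
                                 p=w_d / w_d.sum())
    # with every mother infected and full male-killing penetrance no local
    # sons are produced; the deme persists on immigrant fathers
    mothers_s = state.rng.choice(len(state.females), size=p.n_males,
                                 p=w_s / w_s.sum()) if w_s.sum() > 0 else []
    for mi in mothers_d:
        father = _pick_father(state)
        if father is None:
            state.extinct = True
            return state
        new_f.append(_make_offspring(state, state.females[mi], father,
                                     "female"))
    for mi in mothers_s:
        father = _pick_father(state)
        if father is None:
            state.extinct = True
            return state
        new_m.append(_make_offspring(state, state.females[mi], father,
                                     "male"))
    state.females, state.males = new_f, new_m
    state.generation += 1
    return state


def _record_trajectory(state: SimState) -> None:
    females = state.females
    n_hap = 2 * (len(females) + len(state.males)) or 1
    fused = sum(f.chr15[0].fused for f in females)
    infected = sum(i.infected for i in females + state.males)
    counts = {a: 0 for a in SUPERGENE_ALLELES}
    for ind in females + state.males:
        for h in ind.chr15:
            if h.allele in counts:
                counts[h.allele] += 1
    row = {"generation": state.generation,
           "fused_freq_females": fused / max(len(females), 1),
           "infected_freq": infected / max(len(females) + len(state.males), 1)}
    row.update({f"freq_{a}": c / n_hap for a, c in counts.items()})
    state.trajectory.append(row)


def introduce_fusion(state: SimState) -> None:
    """Single infected foundress female carrying the W-chr15 fusion on her
    maternal chr15 copy."""
    if not state.females:
        raise PopulationExtinct("no females to found the neo-W lineage")
    i = int(state.rng.integers(len(state.females)))
    f = state.females[i]
    root = state._next_node
    state._next_node += 1
    state.fused_tree[root] = (None, state.generation)
    f.chr15 = (Hap(f.chr15[0].muts, f.chr15[0].allele, fused=True,
                   node=root),
               f.chr15[1])
    f.infected = True
    f.symbiont = np.empty(0, dtype=np.int64)  # clonal symbiont founding
    state.fusion_generation = state.generation
    state.foundress_matriline = f.matriline
    state.foundress_mito = f.mito.copy()


def run_simulation(params: SimParams, seed=None,
                   require_establishment: bool = True,
                   max_attempts: int = 500) -> SimState:
    """Initialise, introduce the fusion at ``t_fusion`` generations after
    burn-in, and run ``run_generations`` further generations, recording the
    per-generation trajectory of fusion / infection / supergene frequencies.

    A single foundress lineage is usually lost by drift; with
    ``require_establishment`` (default) the fusion is re-introduced into a
    fresh female whenever the lineage dies and the post-fusion clock
    restarts, so a completed run is conditioned on the establishment that
    the observed system implies and always ends exactly
    ``run_generations`` after the successful introduction.
    """
    state = init_population(params, seed=seed)
    for _ in range(params.t_fusion):
        advance_generation(state)
        _record_trajectory(state)
        if state.extinct:
            return state
    attempts = 0
    while True:
        attempts += 1
        introduce_fusion(state)
        _record_trajectory(state)
        lost = False
        for _ in range(params.run_generations):
            advance_generation(state)
            if state.extinct:
                return state
            _record_trajectory(state)
            if require_establishment and \
                    not any(f.chr15[0].fused for f in state.females):
                lost = True
                break
        if not lost or not require_establishment:
            return state
        if attempts >= max_attempts:
            raise RuntimeError(
                f"neo-W failed to establish in {max_attempts} attempts")


def trajectory_frame(state: SimState) -> pd.DataFrame:
    return pd.DataFrame(state.trajectory)


def segregating_sites(state: SimState, chrom: str) -> int:
    """Number of positions polymorphic among the focal deme's haplotypes."""
    haps = []
    for ind in state.females + state.males:
        pair = ind.chr15 if chrom == state.params.supergene[0] else ind.auto
        if chrom == "mito":
            haps.append(ind.mito)
        else:
            haps.extend([pair[0].muts, pair[1].muts])
    if not haps:
        return 0
    allpos, counts = np.unique(np.concatenate(haps), return_counts=True)
    return int(np.sum(counts < len(haps)))


# ---------------------------------------------------------------------------
# cohort sampling


@dataclass
class FragmentSet:
    """Phased sequencing fragments, the desk-scale stand-in for read pairs.

    Per sample and chromosome: arrays of (start, end, haplotype-of-origin).
    Fragment alleles are error-free and derived lazily from the origin
    haplotype (which guarantees the allele-consistency invariant), or from
    explicit derived-position lists when loaded from file.
    """

    frags: dict = field(default_factory=dict)   # sample -> chrom -> dict
    haps: dict = field(default_factory=dict)    # sample -> chrom -> (m0, m1)
    mean_length: float = 500.0
    coverage: float = 20.0

    def n_fragments(self, sample: str, chrom: str) -> int:
        d = self.frags.get(sample, {}).get(chrom)
        return 0 if d is None else len(d["start"])

    def covering(self, sample: str, chrom: str, pos: int) -> np.ndarray:
        d = self.frags.get(sample, {}).get(chrom)
        if d is None:
            return np.empty(0, dtype=int)
        return np.flatnonzero((d["start"] <= pos) & (d["end"] > pos))

    def carries_derived(self, sample: str, chrom: str, idx: np.ndarray,
                        pos: int) -> np.ndarray:
        """For fragments ``idx`` covering ``pos``: does each carry the
        derived (mutant) allele there?"""
        d = self.frags[sample][chrom]
        if "derived" in d:
            return np.array([pos in d["derived"][i] for i in idx])
        m0, m1 = self.haps[sample][chrom]
        in0 = np.searchsorted(m0, pos) < len(m0) and \
            m0[np.searchsorted(m0, pos)] == pos
        in1 = np.searchsorted(m1, pos) < len(m1) and \
            m1[np.searchsorted(m1, pos)] == pos
        carr = np.array([in0, in1])
        return carr[d["hap"][idx]]

    def derived_mask(self, sample: str, chrom: str, frag_index: int,
                     positions: np.ndarray) -> np.ndarray:
        """Derived-allele mask of one fragment over the given positions
        (which must lie within the fragment)."""
        d = self.frags[sample][chrom]
        if "derived" in d:
            dv = d["derived"][frag_index]
            return np.array([p in dv for p in positions.tolist()])
        m = self.haps[sample][chrom][d["hap"][frag_index]]
        return _member(m, positions)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sample, per_chrom in self.frags.items():
            for chrom, d in per_chrom.items():
                if "derived" in d:
                    derived = d["derived"]
                else:
                    m = self.haps[sample][chrom]
                    derived = []
                    for s, e, h in zip(d["start"], d["end"], d["hap"]):
                        mm = m[h]
                        derived.append(mm[(mm >= s) & (mm < e)])
                for s, e, h, dv in zip(d["start"], d["end"], d["hap"],
                                       derived):
                    rows.append((sample, chrom, int(s), int(e), int(h),
                                 ",".join(str(int(x)) for x in dv)))
        return pd.DataFrame(rows, columns=["sample", "chrom", "start", "end",
                                           "hap", "derived"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FragmentSet":
        fs = cls()
        for (sample, chrom), grp in df.groupby(["sample", "chrom"]):
            derived = [set() if not isinstance(s, str) or not s else
                       {int(x) for x in s.split(",")}
                       for s in grp["derived"]]
            fs.frags.setdefault(sample, {})[chrom] = {
                "start": grp["start"].to_numpy(np.int64),
                "end": grp["end"].to_numpy(np.int64),
                "hap": grp["hap"].to_numpy(np.int64),
                "derived": derived}
        return fs


@dataclass
class SimTruth:
    """Ground truth for a sampled cohort: full phase of every chromosome,
    fusion-carrier flags, symbiont status and matrilines; genotype
    re-derivation from these haplotypes matches the emitted matrix exactly.
    """

    samples: list
    haps: dict                      # sample -> chrom -> (Hap, Hap) | mito arr
    fused: dict                     # sample -> bool
    infected: dict
    matriline: dict
    fusion_generation: int | None
    foundress_matriline: str | None
    foundress_mito: np.ndarray | None
    sampled_generation: int = 0
    fused_node: dict = field(default_factory=dict)   # carrier -> node id
    fused_tree: dict = field(default_factory=dict)

    def true_root_age(self, carriers=None) -> int | None:
        """Generations back to the most recent common ancestor of the
        sampled fused haplotypes (the true root of the neo-W genealogy)."""
        nodes = [self.fused_node[s] for s in
                 (carriers or [s for s in self.samples if self.fused[s]])]
        if len(nodes) < 2:
            return None

        def ancestors(n):
            out = {}
            while n is not None:
                out[n] = self.fused_tree[n][1]
                n = self.fused_tree[n][0]
            return out

        common = None
        for n in nodes:
            a = ancestors(n)
            common = a if common is None else \
                {k: v for k, v in a.items() if k in common}
        if not common:
            return None
        mrca_gen = max(common.values())
        return self.sampled_generation - mrca_gen

    def haplotype_set(self, chrom: str, gm: GenotypeMatrix) -> HaplotypeSet:
        """True phased haplotypes aligned to the matrix's site columns."""
        sl = gm.site_slice(chrom)
        pos = gm.pos[sl]
        labels, rows = [], []
        for s in self.samples:
            entry = self.haps[s][chrom]
            hs = [entry] if chrom == "mito" else [entry[0].muts,
                                                  entry[1].muts]
            for k, m in enumerate(hs):
                labels.append(f"{s}_h{k}")
                rows.append(np.isin(pos, m).astype(np.int8))
        return HaplotypeSet(labels, [chrom] * len(pos), pos, np.array(rows))

    def fused_hap_positions(self, sample: str) -> np.ndarray:
        h0, _ = self.haps[sample]["chr15"]
        if not h0.fused:
            raise ValueError(f"{sample} carries no fused haplotype")
        return h0.muts


def _alt_base(ref_code: int, pos: int) -> int:
    return (ref_code + 1 + pos % 3) % 4


@dataclass
class CohortResult:
    gm: GenotypeMatrix
    samples: pd.DataFrame
    fragments: FragmentSet
    truth: SimTruth
    layout: GenomeLayout
    genes: pd.DataFrame
    refseq: dict


def _phenotype_scores(state: SimState, ind: Individual) -> tuple:
    """Phenotype scoring at the B and C loci from the supergene genotype.

    The dominance series is dorippus > orientis > chrysippus.  Heterozygotes
    carrying dorippus show the intermediate transiens form (and are scored
    0.5) with the stated ~50% penetrance, otherwise they are scored as the
    dominant homozygote.  The A locus is not modelled and left unset.
    """
    alleles = [h.allele for h in ind.chr15]
    ndor = alleles.count("dorippus")
    nori = alleles.count("orientis")
    if ndor == 2:
        c = 1.0
    elif ndor == 1:
        c = 0.5 if (state.rng.random()
                    < state.params.transiens_penetrance) else 1.0
    else:
        c = 0.0
    b = {2: 1.0, 1: 0.5, 0: 0.0}[nori] if ndor == 0 else \
        {1: 0.5, 0: 0.0}.get(nori, 0.0)
    return (np.nan, b, c)


def sample_cohort(state: SimState, design=None, mean_depth: float = 20.0,
                  coverage: float = 20.0, fragment_mean_length: float = 500.0,
                  fragment_chroms=("chr15",)) -> CohortResult:
    """Draw a multi-population cohort and emit genotypes, metadata,
    fragments and ground truth.

    ``design`` maps population name -> dict(n_f=..., n_m=...,
    carriers_first=bool); "contact" samples the focal deme, other names the
    static allopatric panels.  The default design mirrors a 42-individual
    resequencing panel: 16 contact-zone individuals plus three allopatric
    populations.
    """
    p = state.params
    rng = state.rng
    if design is None:
        # 42-individual panel: a contact-zone sample dominated by neo-W
        # lineage females plus three allopatric reference populations
        design = {"contact": {"n_f": 15, "n_m": 0, "carriers_first": True},
                  "dorippus": {"n_f": 4, "n_m": 5},
                  "chrysippus": {"n_f": 5, "n_m": 4},
                  "orientis": {"n_f": 5, "n_m": 4}}
    chosen: list[tuple[str, Individual]] = []
    for pop, entry in design.items():
        if pop == "contact":
            fpool, mpool = list(state.females), list(state.males)
        else:
            panel = state.panels.get(pop)
            if panel is None:
                raise KeyError(f"unknown population {pop!r}")
            fpool = [i for i in panel if i.sex == "female"]
            mpool = [i for i in panel if i.sex == "male"]
        n_f, n_m = entry.get("n_f", 0), entry.get("n_m", 0)
        if n_f > len(fpool) or n_m > len(mpool):
            raise ValueError(f"requested more individuals than alive in {pop}")
        if entry.get("carriers_first"):
            fpool.sort(key=lambda i: not i.chr15[0].fused)
            fsel = fpool[:n_f]
        else:
            fsel = [fpool[j] for j in rng.choice(len(fpool), n_f,
                                                 replace=False)]
        msel = [mpool[j] for j in rng.choice(len(mpool), n_m, replace=False)]
        for ind in fsel + msel:
            chosen.append((pop, ind))

    ids = [f"S{i:03d}_{pop[:3].upper()}" for i, (pop, _) in enumerate(chosen)]

    # genotype matrix over sites segregating among the sampled haplotypes
    chroms_all, pos_all, ref_all, alt_all, gt_all = [], [], [], [], []
    for chrom in list(p.coding_chroms) + (["mito"] if "mito"
                                          in p.chrom_lengths else []):
        hap_arrays = []
        for _, ind in chosen:
            if chrom == "mito":
                hap_arrays.append(ind.mito)
            else:
                pair = ind.chr15 if chrom == p.supergene[0] else ind.auto
                hap_arrays.extend([pair[0].muts, pair[1].muts])
        allpos, counts = np.unique(np.concatenate(hap_arrays),
                                   return_counts=True)
        seg = allpos[counts < len(hap_arrays)]  # drop fixed-derived sites
        memb = np.array([np.isin(seg, h) for h in hap_arrays], dtype=np.int8)
        if chrom == "mito":
            gt = np.repeat(memb.T[:, :, None], 2, axis=2)
        else:
            gt = np.stack([memb[0::2].T, memb[1::2].T], axis=2)
        chroms_all.extend([chrom] * len(seg))
        pos_all.append(seg)
        refcodes = state.refseq[chrom][seg]
        ref_all.extend(chr(BASES[c]) for c in refcodes)
        alt_all.extend([chr(BASES[_alt_base(int(c), int(q))])]
                       for c, q in zip(refcodes, seg))
        gt_all.append(gt)
    pos = np.concatenate(pos_all)
    gt = np.concatenate(gt_all, axis=0)
    dp = rng.poisson(mean_depth, size=gt.shape[:2]).astype(np.int32)
    gq = np.full(gt.shape[:2], 99, dtype=np.int32)
    gm = GenotypeMatrix(ids, chroms_all, pos, ref_all, alt_all, gt, dp, gq)

    # metadata
    rows = []
    for sid, (pop, ind) in zip(ids, chosen):
        a, b, c = _phenotype_scores(state, ind)
        rows.append(dict(sample=sid, sex="F" if ind.sex == "female" else "M",
                         population=pop, pheno_A=a, pheno_B=b, pheno_C=c,
                         infected="yes" if ind.infected else "no",
                         neoW="yes" if ind.chr15[0].fused else "no",
                         matriline=ind.matriline or ""))
    from .io_core import load_samples
    import io as _io
    buf = _io.StringIO()
    pd.DataFrame(rows).to_csv(buf, sep="\t", index=False)
    buf.seek(0)
    samples = load_samples(buf)

    # truth
    truth = SimTruth(
        samples=ids,
        haps={sid: {p.supergene[0]: ind.chr15,
                    **({"chr2": ind.auto} if "chr2" in p.chrom_lengths
                       else {}),
                    "mito": ind.mito, "symbiont": ind.symbiont}
              for sid, (_, ind) in zip(ids, chosen)},
        fused={sid: ind.chr15[0].fused for sid, (_, ind) in zip(ids, chosen)},
        infected={sid: ind.infected for sid, (_, ind) in zip(ids, chosen)},
        matriline={sid: ind.matriline for sid, (_, ind) in zip(ids, chosen)},
        fusion_generation=state.fusion_generation,
        foundress_matriline=state.foundress_matriline,
        foundress_mito=state.foundress_mito,
        sampled_generation=state.generation,
        fused_node={sid: ind.chr15[0].node
                    for sid, (_, ind) in zip(ids, chosen)
                    if ind.chr15[0].fused},
        fused_tree=dict(state.fused_tree))

    # fragments
    fs = FragmentSet(mean_length=fragment_mean_length, coverage=coverage)
    if coverage > 0:
        for sid, (_, ind) in zip(ids, chosen):
            for chrom in fragment_chroms:
                L = p.chrom_lengths[chrom]
                pair = ind.chr15 if chrom == p.supergene[0] else ind.auto
                n_frag = int(round(coverage * L / (2 * fragment_mean_length)))
                per_hap = {}
                starts, ends, haporigin = [], [], []
                for h in (0, 1):
                    st = rng.integers(0, L, size=n_frag)
                    ln = rng.geometric(1.0 / fragment_mean_length,
                                       size=n_frag)
                    starts.append(st)
                    ends.append(np.minimum(st + ln, L))
                    haporigin.append(np.full(n_frag, h))
                fs.frags.setdefault(sid, {})[chrom] = {
                    "start": np.concatenate(starts),
                    "end": np.concatenate(ends),
                    "hap": np.concatenate(haporigin)}
                fs.haps.setdefault(sid, {})[chrom] = (pair[0].muts,
                                                      pair[1].muts)

    return CohortResult(gm, samples, fs, truth, state.layout,
                        state.genes, state.refseq)


# ---------------------------------------------------------------------------
# export


def reference_string(state_or_refseq, chrom: str) -> str:
    refseq = (state_or_refseq.refseq if hasattr(state_or_refseq, "refseq")
              else state_or_refseq)
    return bytes(BASES[refseq[chrom]]).decode()


def export(result: CohortResult, directory, trajectory: pd.DataFrame | None
           = None) -> dict:
    """Write the cohort as re-loadable files: VCF, sample/truth/trajectory
    TSVs, fragment TSV, gene GFF3, and FASTAs of the true haplotypes over
    variant-site columns plus the reference coding sequences."""
    import os
    from .io_core import write_vcf, write_samples, write_gff, write_fasta

    os.makedirs(directory, exist_ok=True)
    paths = {k: os.path.join(directory, v) for k, v in {
        "vcf": "genotypes.vcf", "samples": "samples.tsv",
        "truth": "truth.tsv", "fragments": "fragments.tsv",
        "genes": "genes.gff3", "hap_fasta": "truth_haplotypes.fa",
        "cds_fasta": "reference_cds.fa", "layout": "layout.tsv",
        "trajectory": "trajectory.tsv", "symbiont": "symbiont.tsv"}.items()}
    write_vcf(result.gm, paths["vcf"], result.layout)
    write_samples(result.samples.reset_index(drop=True), paths["samples"])
    result.layout.to_table(paths["layout"])
    truth_rows = [dict(sample=s, fused=result.truth.fused[s],
                       infected=result.truth.infected[s],
                       matriline=result.truth.matriline[s])
                  for s in result.truth.samples]
    pd.DataFrame(truth_rows).to_csv(paths["truth"], sep="\t", index=False)
    result.fragments.to_frame().to_csv(paths["fragments"], sep="\t",
                                       index=False)
    sym_rows = []
    for s in result.truth.samples:
        muts = result.truth.haps[s].get("symbiont")
        if muts is not None:
            sym_rows.append((s, ",".join(str(int(x)) for x in muts)))
    pd.DataFrame(sym_rows, columns=["sample", "positions"]).to_csv(
        paths["symbiont"], sep="\t", index=False)
    write_gff(result.genes, paths["genes"])
    if trajectory is not None:
        trajectory.to_csv(paths["trajectory"], sep="\t", index=False)

    recs = {}
    for chrom in dict.fromkeys(result.gm.chrom):
        hs = result.truth.haplotype_set(chrom, result.gm)
        sl = result.gm.site_slice(chrom)
        for label, row in zip(hs.labels, hs.alleles):
            bases = [result.gm.ref[i] if a == 0 else result.gm.alt[i][0]
                     for i, a in zip(range(sl.start, sl.stop), row)]
            recs[f"{label}|{chrom}"] = "".join(bases)
    write_fasta(recs, paths["hap_fasta"])
    cds = {}
    for _, g in result.genes.iterrows():
        seq = reference_string(result.refseq, g.chrom)[g.start:g.end]
        cds[g.gene_id] = seq
    write_fasta(cds, paths["cds_fasta"])
    return paths
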