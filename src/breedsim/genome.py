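"""Genome, founder population, meiosis and burn-in simulation.

The simulated genome is a set of equally sized chromosomes carrying
equidistantly spaced biallelic SNPs on a genetic (Morgan) map; a subset of
the SNPs act as additive QTLs for a single quantitative trait.  Individuals
are fully phased; every haplotype additionally carries, per SNP, the label
of the founder haplotype it descends from, so realised identity-by-descent
(IBD) is available exactly at any generation.

Meiosis follows the Haldane model: crossover counts per chromosome are
Poisson with mean equal to the map length in Morgan, crossover positions
are i.i.d. uniform, and there is no interference.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Union

import numpy as np

MALE = 1
FEMALE = 0

RngLike = Union[int, np.random.Generator]


def as_rng(seed: RngLike) -> np.random.Generator:
    """Return a Generator; integers are used as seeds, generators pass through."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# genome / trait specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeSpec:
    """Layout of the simulated genome and the trait architecture.

    Attributes
    ----------
    n_chr : int
        Number of chromosomes.
    chr_length : float
        Genetic length of every chromosome, in Morgan.
    map_pos : ndarray, shape (n_snp,)
        Genetic position of each SNP within its chromosome, in Morgan.
    chr_index : ndarray, shape (n_snp,)
        Chromosome of each SNP (0-based); SNPs are stored chromosome by
        chromosome in map order.
    qtl_index : ndarray
        Sorted SNP indices acting as QTLs.
    qtl_effects : ndarray
        Additive allele-substitution effect of each QTL (trait units).
    """

    n_chr: int
    chr_length: float
    map_pos: np.ndarray
    chr_index: np.ndarray
    qtl_index: np.ndarray
    qtl_effects: np.ndarray

    @property
    def n_snp(self) -> int:
        return self.map_pos.shape[0]

    @property
    def n_qtl(self) -> int:
        return self.qtl_index.shape[0]

    @property
    def chr_slices(self) -> list[slice]:
        """Half-open SNP-index slice of each chromosome."""
        bounds = np.searchsorted(self.chr_index, np.arange(self.n_chr + 1))
        return [slice(int(bounds[c]), int(bounds[c + 1])) for c in range(self.n_chr)]

    def with_scaled_effects(self, scale: float) -> "GenomeSpec":
        """Return a copy with all QTL effects multiplied by ``scale``."""
        return replace(self, qtl_effects=self.qtl_effects * float(scale))

    def validate(self) -> None:
        if not np.all(np.isfinite(self.qtl_effects)):
            raise ValueError("QTL effects must be finite")
        if self.qtl_index.min(initial=0) < 0 or self.qtl_index.max(initial=0) >= self.n_snp:
            raise ValueError("QTL indices outside SNP range")


def build_genome(
    seed: RngLike,
    n_chr: int = 10,
    chr_length: float = 2.5,
    n_snp: int = 25_000,
    n_qtl: int = 1_000,
) -> GenomeSpec:
    """Build the genome: equidistant SNP map plus a random QTL architecture.

    SNPs are split equally across chromosomes at constant spacing
    ``chr_length / (n_snp / n_chr)`` (0.001 Morgan at the default scale).
    QTL positions are drawn uniformly without replacement among all SNPs and
    QTL effects i.i.d. standard normal.
    """
    rng = as_rng(seed)
    if n_snp % n_chr:
        raise ValueError("n_snp must be divisible by n_chr")
    m = n_snp // n_chr
    spacing = chr_length / m
    within = (np.arange(m) + 0.5) * spacing
    map_pos = np.tile(within, n_chr)
    chr_index = np.repeat(np.arange(n_chr), m)
    qtl_index = np.sort(rng.choice(n_snp, size=n_qtl, replace=False))
    qtl_effects = rng.standard_normal(n_qtl)
    genome = GenomeSpec(n_chr, chr_length, map_pos, chr_index, qtl_index, qtl_effects)
    genome.validate()
    return genome


@dataclass
class TraitModel:
    """Additive trait: heritability plus the environmental variance.

    ``sigma_e2`` is calibrated once on the founder cohort so that the
    founder-generation narrow-sense heritability equals ``h2``:
    ``sigma_e2 = var(g_founders) * (1 - h2) / h2``.
    """

    h2: float
    sigma_e2: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 < self.h2 < 1.0:
            raise ValueError("h2 must be in (0, 1)")

    @classmethod
    def from_founders(cls, pop: "Population", genome: GenomeSpec, h2: float = 0.3) -> "TraitModel":
        g = true_genetic_values(pop, genome)
        var_g = float(np.var(g))
        return cls(h2=h2, sigma_e2=var_g * (1.0 - h2) / h2)


# ---------------------------------------------------------------------------
# pedigree and population containers
# ---------------------------------------------------------------------------

class Pedigree:
    """Growable pedigree: sire/dam/sex/generation per individual.

    Founders carry sire = dam = -1.  Ids are dense 0-based integers in
    registration order; every non-founder's parents were registered earlier.
    """

    def __init__(self) -> None:
        self.sire = np.empty(0, dtype=np.int64)
        self.dam = np.empty(0, dtype=np.int64)
        self.sex = np.empty(0, dtype=np.int8)
        self.generation = np.empty(0, dtype=np.int64)

    def __len__(self) -> int:
        return self.sire.shape[0]

    @property
    def n(self) -> int:
        return len(self)

    def is_founder(self, ids: np.ndarray) -> np.ndarray:
        return self.sire[ids] < 0

    def add(self, sire: np.ndarray, dam: np.ndarray, sex: np.ndarray,
            generation: int) -> np.ndarray:
        """Register individuals; returns their new global ids."""
        n = len(sex)
        start = len(self)
        self.sire = np.concatenate([self.sire, np.asarray(sire, dtype=np.int64)])
        self.dam = np.concatenate([self.dam, np.asarray(dam, dtype=np.int64)])
        self.sex = np.concatenate([self.sex, np.asarray(sex, dtype=np.int8)])
        self.generation = np.concatenate(
            [self.generation, np.full(n, generation, dtype=np.int64)])
        return np.arange(start, start + n, dtype=np.int64)


@dataclass
class Population:
    """One cohort of individuals with phased haplotypes and IBD labels.

    ``haplo`` is (n, 2, n_snp) of 0/1 alleles; ``ibd`` is (n, 2, n_snp) of
    founder-haplotype labels (label = 2 * founder_id + haplotype).  The
    pedigree object is shared across cohorts of the same simulation.
    """

    pedigree: Pedigree
    ids: np.ndarray
    haplo: np.ndarray
    ibd: Optional[np.ndarray]
    generation: int
    phenotypes: Optional[np.ndarray] = None

    @property
    def n(self) -> int:
        return self.ids.shape[0]

    @property
    def sex(self) -> np.ndarray:
        return self.pedigree.sex[self.ids]

    def genotypes(self, snp_subset: Optional[np.ndarray] = None) -> np.ndarray:
        """Allele dosages 0/1/2, (n, n_snp) or the requested SNP subset."""
        if snp_subset is None:
            return self.haplo.sum(axis=1, dtype=np.int8)
        return self.haplo[:, :, snp_subset].sum(axis=1, dtype=np.int8)

    def ibd_segments(self, individual: int, hap: int) -> list[tuple[int, int, int]]:
        """Derive half-open (start, end, founder-label) runs of one haplotype."""
        labels = self.ibd[individual, hap]
        change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [labels.shape[0]]])
        return [(int(s), int(e), int(labels[s])) for s, e in zip(starts, ends)]


def sample_founders(genome: GenomeSpec, n: int = 1000, seed: RngLike = 0,
                    pedigree: Optional[Pedigree] = None,
                    freq: str | float = "uniform") -> Population:
    """Draw the founder cohort with randomly sampled genotypes, sexes 1:1.

    ``freq`` sets the founder allele-frequency spectrum: ``"uniform"``
    (default) draws a per-locus frequency p_j ~ U(0, 1) and alleles
    Bernoulli(p_j); a float uses that frequency at every locus (0.5 gives
    the maximum-heterozygosity spectrum).  Every founder haplotype gets a
    distinct IBD label, so founders have realised inbreeding exactly zero.
    """
    if n <= 0:
        raise ValueError("founder cohort size must be positive")
    rng = as_rng(seed)
    if freq == "uniform":
        p = rng.uniform(0.0, 1.0, size=genome.n_snp)
    else:
        p = np.full(genome.n_snp, float(freq))
        if np.any((p < 0) | (p > 1)):
            raise ValueError("founder allele frequency must be in [0, 1]")
    haplo = (rng.random(size=(n, 2, genome.n_snp)) < p).astype(np.uint8)
    sex = rng.integers(0, 2, size=n).astype(np.int8)
    ped = pedigree if pedigree is not None else Pedigree()
    ids = ped.add(np.full(n, -1), np.full(n, -1), sex, generation=0)
    if 2 * int(ids.max()) + 1 > np.iinfo(np.int16).max:
        raise ValueError("founder cohort too large for int16 IBD labels")
    labels = (2 * ids[:, None] + np.arange(2)[None, :]).astype(np.int16)
    ibd = np.broadcast_to(labels[:, :, None], (n, 2, genome.n_snp)).copy()
    return Population(pedigree=ped, ids=ids, haplo=haplo, ibd=ibd, generation=0)


def true_genetic_values(pop: Population, genome: GenomeSpec) -> np.ndarray:
    """True breeding values: sum of QTL dosages times true effects."""
    z = pop.genotypes(genome.qtl_index).astype(np.float64)
    return z @ genome.qtl_effects


def simulate_phenotypes(pop: Population, genome: GenomeSpec, trait: TraitModel,
                        seed: RngLike) -> np.ndarray:
    """Phenotypes y = g + e with e ~ N(0, sigma_e2)."""
    if trait.sigma_e2 is None:
        raise ValueError("trait not calibrated: sigma_e2 is unset")
    rng = as_rng(seed)
    g = true_genetic_values(pop, genome)
    return g + rng.normal(0.0, np.sqrt(trait.sigma_e2), size=pop.n)


# ---------------------------------------------------------------------------
# meiosis
# ---------------------------------------------------------------------------

def _gametes(haplo: np.ndarray, ibd: Optional[np.ndarray],
             parent_rows: np.ndarray, genome: GenomeSpec,
             rng: np.random.Generator,
             out_h: Optional[np.ndarray] = None,
             out_i: Optional[np.ndarray] = None
             ) -> tuple[np.ndarray, Optional[np.ndarray]]:
    """Vectorised meiosis: one gamete per entry of ``parent_rows``.

    Crossovers: per chromosome Poisson(chr_length) counts, uniform positions,
    Bernoulli(0.5) starting haplotype (Haldane, no interference).  The
    source haplotype per locus is the parity of a single genome-wide toggle
    array: one toggle per crossover plus a per-chromosome correction that
    resets the parity to the chromosome's random starting haplotype.
    """
    n_gam = parent_rows.shape[0]
    L = genome.n_snp
    counts = rng.poisson(genome.chr_length, size=(n_gam, genome.n_chr))
    start = rng.integers(0, 2, size=(n_gam, genome.n_chr), dtype=np.int8)
    delta = np.zeros((n_gam, L), dtype=np.int8)
    gam_arange = np.arange(n_gam)
    k_eff = np.zeros((n_gam, genome.n_chr), dtype=np.int64)
    chr_starts = np.array([sl.start for sl in genome.chr_slices])
    for c, sl in enumerate(genome.chr_slices):
        m = sl.stop - sl.start
        k = counts[:, c]
        total = int(k.sum())
        if not total:
            continue
        pos = rng.uniform(0.0, genome.chr_length, size=total)
        gam_idx = np.repeat(gam_arange, k)
        # a crossover at map position x switches source from the first SNP
        # strictly beyond x onwards; beyond the last SNP it has no effect
        loc = np.searchsorted(genome.map_pos[sl], pos, side="right")
        keep = loc < m
        np.add.at(delta, (gam_idx[keep], sl.start + loc[keep]), 1)
        k_eff[:, c] = np.bincount(gam_idx[keep], minlength=n_gam)
    # per-chromosome toggle so the parity entering each chromosome equals its
    # random starting haplotype: t_b = (s_b - s_{b-1} - k_{b-1}) mod 2
    toggle = np.empty((n_gam, genome.n_chr), dtype=np.int8)
    toggle[:, 0] = start[:, 0]
    toggle[:, 1:] = (start[:, 1:] - start[:, :-1] - k_eff[:, :-1]) & 1
    delta[:, chr_starts] += toggle
    src = np.cumsum(delta, axis=1, dtype=np.int8) & 1
    # branch-free blend: out = h0 ^ ((h0 ^ h1) & mask), mask = 0 / all-ones
    if out_h is None:
        out_h = np.empty((n_gam, L), dtype=haplo.dtype)
    a = haplo[parent_rows, 0, :]
    b = haplo[parent_rows, 1, :].copy()
    np.bitwise_xor(a, b, out=b)
    np.bitwise_and(b, src.view(np.uint8), out=b)
    np.bitwise_xor(a, b, out=out_h)
    if ibd is None:
        return out_h, None
    if out_i is None:
        out_i = np.empty((n_gam, L), dtype=ibd.dtype)
    mask = (-src).astype(ibd.dtype)
    ia = ibd[parent_rows, 0, :]
    ib = ibd[parent_rows, 1, :].copy()
    np.bitwise_xor(ia, ib, out=ib)
    np.bitwise_and(ib, mask, out=ib)
    np.bitwise_xor(ia, ib, out=out_i)
    return out_h, out_i


def meiosis(pop: Population, parent: int, genome: GenomeSpec,
            seed: RngLike) -> tuple[np.ndarray, np.ndarray]:
    """Produce one gamete (alleles, IBD labels) of ``pop``'s row ``parent``."""
    rng = as_rng(seed)
    rows = np.array([parent])
    h, i = _gametes(pop.haplo, pop.ibd, rows, genome, rng)
    return h[0], i[0]


def make_offspring(pop: Population, matings: np.ndarray, genome: GenomeSpec,
                   seed: RngLike, generation: Optional[int] = None,
                   pedigree: Optional[Pedigree] = None,
                   track_ibd: bool = True) -> Population:
    """Create an offspring cohort, one individual per (sire_id, dam_id) pair.

    Ids are global pedigree ids and must belong to ``pop``; sires must be
    male, dams female.  Offspring sexes are i.i.d. 1:1 and the pedigree is
    extended (or a separate ``pedigree`` used, e.g. for production cohorts
    kept out of the breeding line's pedigree).  ``track_ibd=False`` skips
    founder-origin propagation for throwaway cohorts.
    """
    rng = as_rng(seed)
    matings = np.asarray(matings, dtype=np.int64).reshape(-1, 2)
    n = matings.shape[0]
    ped = pedigree if pedigree is not None else pop.pedigree
    gen = generation if generation is not None else pop.generation + 1
    if n == 0:
        return Population(pedigree=ped, ids=np.empty(0, dtype=np.int64),
                          haplo=np.empty((0, 2, genome.n_snp), dtype=np.uint8),
                          ibd=np.empty((0, 2, genome.n_snp), dtype=np.int32),
                          generation=gen)
    id_to_row = {int(g): r for r, g in enumerate(pop.ids)}
    try:
        sire_rows = np.array([id_to_row[int(s)] for s in matings[:, 0]])
        dam_rows = np.array([id_to_row[int(d)] for d in matings[:, 1]])
    except KeyError as exc:  # pragma: no cover - message only
        raise KeyError(f"mating references individual {exc} not in cohort") from exc
    if np.any(pop.pedigree.sex[matings[:, 0]] != MALE):
        raise ValueError("all sires must be male")
    if np.any(pop.pedigree.sex[matings[:, 1]] != FEMALE):
        raise ValueError("all dams must be female")
    haplo = np.empty((n, 2, genome.n_snp), dtype=pop.haplo.dtype)
    src_ibd = pop.ibd if track_ibd else None
    ibd = (np.empty((n, 2, genome.n_snp), dtype=pop.ibd.dtype)
           if track_ibd else None)
    _gametes(pop.haplo, src_ibd, sire_rows, genome, rng,
             out_h=haplo[:, 0], out_i=ibd[:, 0] if track_ibd else None)
    _gametes(pop.haplo, src_ibd, dam_rows, genome, rng,
             out_h=haplo[:, 1], out_i=ibd[:, 1] if track_ibd else None)
    sex = rng.integers(0, 2, size=n).astype(np.int8)
    ids = ped.add(matings[:, 0], matings[:, 1], sex, generation=gen)
    return Population(pedigree=ped, ids=ids, haplo=haplo, ibd=ibd, generation=gen)


def ibd_inbreeding(pop: Population, individual: Optional[int] = None) -> np.ndarray:
    """Realised inbreeding: genome fraction where both haplotypes share the
    same founder-haplotype label."""
    if pop.ibd is None:
        raise ValueError("cohort was created without IBD tracking")
    if individual is not None:
        return float(np.mean(pop.ibd[individual, 0] == pop.ibd[individual, 1]))
    return (pop.ibd[:, 0, :] == pop.ibd[:, 1, :]).mean(axis=1)


# ---------------------------------------------------------------------------
# burn-in
# ---------------------------------------------------------------------------

def burn_in(pop: Population, genome: GenomeSpec, trait: TraitModel,
            n_gen: int = 10, seed: RngLike = 0, n_males: int = 40,
            n_females: int = 100, n_offspring: int = 1000) -> Population:
    """Phenotypic-selection burn-in establishing linkage and family structure.

    Each cycle phenotypes all candidates, truncation-selects the top
    ``n_males`` / ``n_females`` on own phenotype, pairs sires and dams
    uniformly at random with replacement and produces ``n_offspring``.
    """
    rng = as_rng(seed)
    for _ in range(n_gen):
        y = simulate_phenotypes(pop, genome, trait, rng)
        sel_m, sel_f = _select_top_by_sex(y, pop.sex, pop.ids, n_males, n_females)
        sires = rng.choice(sel_m, size=n_offspring, replace=True)
        dams = rng.choice(sel_f, size=n_offspring, replace=True)
        pop = make_offspring(pop, np.column_stack([sires, dams]), genome, rng)
    return pop


def _select_top_by_sex(criterion: np.ndarray, sex: np.ndarray, ids: np.ndarray,
                       n_males: int, n_females: int) -> tuple[np.ndarray, np.ndarray]:
    """Top-n ids per sex by criterion; ties broken by lower id."""
    out = []
    for s, n_sel in ((MALE, n_males), (FEMALE, n_females)):
        mask = sex == s
        if mask.sum() < n_sel:
            raise ValueError(f"need {n_sel} of sex {s}, have {int(mask.sum())}")
        cand_ids = ids[mask]
        crit = criterion[mask]
        order = np.lexsort((cand_ids, -crit))
        out.append(np.sort(cand_ids[order[:n_sel]]))
    return out[0], out[1]
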