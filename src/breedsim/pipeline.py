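"""Scenario orchestration: generations, replicates, metrics.

``run_scenario`` simulates one replicate of a breeding program: founder
sampling, phenotypic-selection burn-in, then ``n_generations`` cycles of
genotyping, GBLUP evaluation, criterion computation, selection (truncation
or OCS), mating (with optional avoidance rules) and offspring production.
A separate production cohort bred from the top plain-EBV parents each
generation provides the genetic-gain readout; genetic gain is expressed in
units of the genetic standard deviation (gSD) of the first post-burn-in
candidate cohort of the same replicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace
from typing import Optional

import numpy as np
import pandas as pd

from .genome import (
    MALE, FEMALE, RngLike, as_rng, GenomeSpec, TraitModel, Pedigree,
    Population, build_genome, sample_founders, true_genetic_values,
    simulate_phenotypes, make_offspring, ibd_inbreeding, burn_in,
)
from .evaluation import (
    KinshipMatrix, vanraden_G, pedigree_kinship, gblup_ebv, estimate_h2_he,
    msv_gamete_sd, accuracy,
)
from .criteria import (
    CriterionSpec, allele_weighting, weighted_criterion, kinship_index,
    msv_index, combined_criterion, truncation_select,
)
from .mating import (
    MatingPlan, avoid_matings_quantile, avoid_sib_matings, sample_matings,
    ocs_deterministic, contributions_to_matings, ocs_evolutionary,
    _largest_remainder,
)

__all__ = [
    "StrategyConfig", "MetricsSeries", "run_generation", "run_scenario",
    "run_replicates", "inbreeding_rate", "fixation_shares",
    "aggregate_replicates", "compare_scenarios",
]

METRIC_COLUMNS = [
    "gain_raw", "gain_gsd", "candidates_mean", "inbreeding",
    "genetic_variance", "snp_fixed", "qtl_fixed", "qtl_fixed_favorable",
    "acc_ebv", "acc_msv",
]


@dataclass
class StrategyConfig:
    """Full parameterisation of one breeding scenario.

    The defaults are the baseline program: truncation selection of the top
    40 males / 100 females among 1000 candidates on single-generation GBLUP
    EBVs, random mating, 50 generations after a 10-generation phenotypic
    burn-in on a 10 x 2.5 Morgan genome with 25,000 SNPs, 1000 QTLs and
    h2 = 0.3.
    """

    criterion: CriterionSpec = field(default_factory=CriterionSpec)
    # mating avoidance
    avoid_sibs: Optional[str] = None       # None | 'full' | 'half'
    q_inbreeding: float = 1.0              # quantile on expected inbreeding
    q_kinship: float = 1.0                 # quantile on expected kinship
    # optimum contribution selection
    ocs: str = "none"                      # 'none' | 'deterministic' | 'evolutionary'
    delta_kin: float = 0.005               # kinship-increase cap (deterministic)
    theta: float = 30.0                    # gain/diversity angle, degrees (evolutionary)
    # cohort structure
    n_males: int = 40
    n_females: int = 100
    n_offspring: int = 1000
    n_founders: int = 1000
    burnin_males: int = 40
    burnin_females: int = 100
    n_generations: int = 50
    burnin_generations: int = 10
    # evaluation
    training_window: int = 1               # generations pooled in GBLUP (1 or 7)
    h2: float = 0.3
    variance_estimation: str = "he"        # 'he' (Haseman-Elston per cycle) | 'fixed'
    compute_msv: bool = True
    pedigree_depth: int = 7
    founder_freq: object = "uniform"       # 'uniform' U(0,1) spectrum | float
    # genome
    n_chr: int = 10
    chr_length: float = 2.5
    n_snp: int = 25_000
    n_qtl: int = 1_000
    # production cohort (gain readout)
    n_production: int = 1000

    def __post_init__(self) -> None:
        if self.ocs not in ("none", "deterministic", "evolutionary"):
            raise ValueError(f"unknown ocs mode {self.ocs!r}")
        if self.variance_estimation not in ("he", "fixed"):
            raise ValueError(
                f"unknown variance estimation {self.variance_estimation!r}")


@dataclass
class MetricsSeries:
    """Per-generation metrics of one simulated replicate."""

    data: pd.DataFrame
    replicate: int = 0

    def final(self, column: str) -> float:
        return float(self.data[column].iloc[-1])

    @property
    def inbreeding(self) -> np.ndarray:
        return self.data["inbreeding"].to_numpy()

    def mean_delta_f(self) -> float:
        """Average normalised inbreeding rate over generations 2..T."""
        return float(np.mean(inbreeding_rate(self.inbreeding)))


def inbreeding_rate(F_series: np.ndarray) -> np.ndarray:
    """Per-generation rate dF_t = (F_t - F_{t-1}) / (1 - F_{t-1})."""
    F = np.asarray(F_series, dtype=np.float64)
    prev = F[:-1]
    if np.any(prev >= 1.0):
        raise ZeroDivisionError("inbreeding already complete (F = 1)")
    return (F[1:] - prev) / (1.0 - prev)


def fixation_shares(pop: Population, genome: GenomeSpec
                    ) -> tuple[float, float, float]:
    """(share of SNPs fixed, share of QTLs fixed, share of fixed QTLs fixed
    for the favorable allele); the last is NaN when no QTL is fixed."""
    freq = pop.genotypes().mean(axis=0) / 2.0
    fixed = (freq == 0.0) | (freq == 1.0)
    snp_share = float(fixed.mean())
    qfixed = fixed[genome.qtl_index]
    qtl_share = float(qfixed.mean())
    if qfixed.any():
        qfreq = freq[genome.qtl_index][qfixed]
        eff = genome.qtl_effects[qfixed]
        favorable = ((qfreq == 1.0) & (eff > 0)) | ((qfreq == 0.0) & (eff < 0))
        fav_share = float(favorable.mean())
    else:
        fav_share = float("nan")
    return snp_share, qtl_share, fav_share


# ---------------------------------------------------------------------------
# simulation state and one generation step
# ---------------------------------------------------------------------------

@dataclass
class SimState:
    """Mutable state threaded through the generation loop."""

    genome: GenomeSpec
    trait: TraitModel
    pop: Population
    config: StrategyConfig
    history: list = field(default_factory=list)   # (genotypes, phenotypes) past cohorts
    gsd_mean: Optional[float] = None
    gsd_sd: Optional[float] = None


def _criterion_values(state: SimState, ebv: np.ndarray, snp_effects: np.ndarray,
                      msv_sd: Optional[np.ndarray], Z: np.ndarray,
                      kin: Optional[KinshipMatrix]) -> np.ndarray:
    """Evaluate the configured selection criterion for all candidates."""
    cfg = state.config
    spec = cfg.criterion
    pop = state.pop
    if spec.scheme == "ebv":
        return ebv
    if spec.scheme in ("goddard", "jannink", "pow_third", "pow_quarter",
                       "capped_jannink", "blend"):
        p_benef = _beneficial_freq(Z, snp_effects)
        w = allele_weighting(p_benef, spec.scheme, spec.d)
        return weighted_criterion(Z, w, snp_effects)
    if spec.scheme in ("kinship_top", "kinship_pop"):
        f = _mean_kinships(state, ebv, kin, spec.scheme)
        return kinship_index(ebv, f, spec.w_f)
    if spec.scheme in ("msv_i5", "msv_i6"):
        if msv_sd is None:
            raise ValueError("MSV index requires compute_msv=True")
        sexes = pop.sex
        p = np.where(sexes == MALE,
                     cfg.n_males / max(int((sexes == MALE).sum()), 1),
                     cfg.n_females / max(int((sexes == FEMALE).sum()), 1))
        return msv_index(ebv, msv_sd, p, spec.scheme.split("_")[1])
    if spec.scheme == "combined":
        p_benef = _beneficial_freq(Z, snp_effects)
        f_top = _mean_kinships(state, ebv, kin, "kinship_top")
        f_pop = _mean_kinships(state, ebv, kin, "kinship_pop")
        return combined_criterion(Z, snp_effects, p_benef, f_top, f_pop, spec.x)
    raise ValueError(f"unknown criterion scheme {spec.scheme!r}")


def _beneficial_freq(Z: np.ndarray, snp_effects: np.ndarray) -> np.ndarray:
    """Frequency of the beneficial allele: the allele whose estimated effect
    is positive, with frequencies taken from the current candidates."""
    p1 = Z.mean(axis=0) / 2.0
    return np.where(snp_effects > 0, p1, 1.0 - p1)


def _mean_kinships(state: SimState, ebv: np.ndarray, kin: KinshipMatrix,
                   which: str) -> np.ndarray:
    """Mean pedigree kinship of each candidate to the cohort or its top set."""
    cfg = state.config
    K = kin.values
    if which == "kinship_pop":
        return K.mean(axis=1)
    m_ids, f_ids = truncation_select(ebv, state.pop.sex, cfg.n_males,
                                     cfg.n_females, ids=state.pop.ids)
    top = np.concatenate([m_ids, f_ids])
    cols = np.array([kin.index_of(i) for i in top])
    return K[:, cols].mean(axis=1)


def _needs_pedigree_kinship(cfg: StrategyConfig) -> bool:
    return (cfg.criterion.scheme in ("kinship_top", "kinship_pop", "combined")
            or cfg.q_inbreeding < 1.0 or cfg.q_kinship < 1.0
            or cfg.ocs == "deterministic")


def _evaluate(state: SimState, rng: np.random.Generator):
    """Phenotype, GBLUP, back-solving and MSV for the current candidates."""
    cfg = state.config
    pop = state.pop
    genome = state.genome
    g_true = true_genetic_values(pop, genome)
    y = simulate_phenotypes(pop, genome, state.trait, rng)
    Z = pop.genotypes()
    if cfg.training_window > 1 and state.history:
        past = state.history[-(cfg.training_window - 1):]
        Z_tr = np.concatenate([z for z, _ in past] + [Z], axis=0)
        y_tr = np.concatenate([p for _, p in past] + [y])
    else:
        Z_tr, y_tr = Z, y
    freqs = Z_tr.mean(axis=0) / 2.0
    G = vanraden_G(Z_tr, allele_freqs=freqs)
    if cfg.variance_estimation == "he":
        # shrinkage re-calibrated each cycle: the genetic variance (and with
        # it the realised h2) erodes over generations
        h2_used = estimate_h2_he(y_tr, G)
    else:
        h2_used = cfg.h2
    res = gblup_ebv(y_tr, G, h2_used)
    ebv = res.ebv[-pop.n:]
    denom = 2.0 * float(np.sum(freqs * (1.0 - freqs)))
    M = Z_tr.astype(np.float32) - (2.0 * freqs).astype(np.float32)
    # minimum-norm back-solve via the GBLUP solution: a = M' V^{-1}(y-mu)/denom
    snp_effects = (M.T @ res.vinv_resid.astype(np.float32)).astype(np.float64) / denom
    msv_est = msv_true = None
    if cfg.compute_msv:
        msv_est = msv_gamete_sd(pop.haplo, snp_effects, genome.map_pos,
                                genome.chr_index)
        qtl = genome.qtl_index
        msv_true = msv_gamete_sd(pop.haplo[:, :, qtl], genome.qtl_effects,
                                 genome.map_pos[qtl], genome.chr_index[qtl])
    if cfg.training_window > 1:
        state.history.append((Z, y))
        del state.history[:-(cfg.training_window - 1) or None]
    return g_true, y, Z, ebv, snp_effects, msv_est, msv_true


def _build_mating_plan(state: SimState, criterion: np.ndarray,
                       ebv: np.ndarray, Z: np.ndarray,
                       kin: Optional[KinshipMatrix],
                       rng: np.random.Generator) -> MatingPlan:
    """Selection plus mating under the configured strategy."""
    cfg = state.config
    pop = state.pop

    if cfg.ocs == "evolutionary":
        G = vanraden_G(Z)
        return ocs_evolutionary(criterion, G, pop.sex, cfg.theta, cfg.n_males,
                                cfg.n_females, cfg.n_offspring, rng,
                                ids=pop.ids)

    sel_f_ids: np.ndarray
    if cfg.ocs == "deterministic":
        _, sel_f_ids = truncation_select(criterion, pop.sex, cfg.n_males,
                                         cfg.n_females, ids=pop.ids)
        male_ids = pop.ids[pop.sex == MALE]
        male_u = criterion[pop.sex == MALE]
        f_bar = float(kin.values.mean())
        sol = ocs_deterministic(male_u, male_ids, sel_f_ids, kin,
                                cfg.delta_kin, f_bar)
        mask, sires, dams = _avoidance_mask(state, sol.male_ids, sel_f_ids, kin)
        if mask is None:
            return contributions_to_matings(sol, sel_f_ids, cfg.n_offspring, rng)
        # respect both the contributions and the allowed set: sample pairs
        # with probability proportional to c_sire, uniform over allowed dams
        probs = (np.maximum(sol.contributions, 0.0)[:, None] * mask).ravel()
        if probs.sum() <= 0:
            raise ValueError("no allowed matings remain under OCS contributions")
        picks = rng.choice(probs.size, size=cfg.n_offspring, p=probs / probs.sum())
        si, di = np.unravel_index(picks, mask.shape)
        return MatingPlan.from_pairs(np.column_stack([sires[si], dams[di]]))

    sel_m_ids, sel_f_ids = truncation_select(criterion, pop.sex, cfg.n_males,
                                             cfg.n_females, ids=pop.ids)
    mask, sires, dams = _avoidance_mask(state, sel_m_ids, sel_f_ids, kin)
    if mask is None:
        # no avoidance rule active: selected parents contribute equally,
        # sire-dam assignment random
        sire_slots = np.repeat(sel_m_ids, _largest_remainder(
            np.ones(sel_m_ids.size), cfg.n_offspring))
        dam_slots = np.repeat(sel_f_ids, _largest_remainder(
            np.ones(sel_f_ids.size), cfg.n_offspring))
        rng.shuffle(dam_slots)
        return MatingPlan.from_pairs(np.column_stack([sire_slots, dam_slots]))
    return sample_matings(mask, sel_m_ids, sel_f_ids, cfg.n_offspring, rng)


def _avoidance_mask(state: SimState, sires: np.ndarray, dams: np.ndarray,
                    kin: Optional[KinshipMatrix]):
    """Combine sib-avoidance and the two quantile rules into one mask."""
    cfg = state.config
    masks = []
    if cfg.avoid_sibs is not None:
        masks.append(avoid_sib_matings(state.pop.pedigree, sires, dams,
                                       cfg.avoid_sibs))
    if cfg.q_inbreeding < 1.0:
        si = np.array([kin.index_of(i) for i in sires])
        di = np.array([kin.index_of(i) for i in dams])
        pair_f = kin.values[np.ix_(si, di)]
        masks.append(avoid_matings_quantile(pair_f, cfg.q_inbreeding))
    if cfg.q_kinship < 1.0:
        mean_k = kin.values.mean(axis=1)
        si = np.array([kin.index_of(i) for i in sires])
        di = np.array([kin.index_of(i) for i in dams])
        pair_k = 0.5 * (mean_k[si][:, None] + mean_k[di][None, :])
        masks.append(avoid_matings_quantile(pair_k, cfg.q_kinship))
    if not masks:
        return None, sires, dams
    mask = np.logical_and.reduce(masks)
    if not mask.any():
        raise ValueError("intersection of mating-avoidance rules is empty")
    return mask, sires, dams


def run_generation(state: SimState, seed: RngLike) -> tuple[SimState, dict]:
    """One breeding cycle; returns the advanced state and its metric record."""
    rng = as_rng(seed)
    cfg = state.config
    pop = state.pop
    genome = state.genome
    g_true, y, Z, ebv, snp_effects, msv_est, msv_true = _evaluate(state, rng)

    if state.gsd_mean is None:
        state.gsd_mean = float(g_true.mean())
        state.gsd_sd = float(g_true.std())

    kin = None
    if _needs_pedigree_kinship(cfg):
        kin = pedigree_kinship(pop.pedigree, pop.ids, depth=cfg.pedigree_depth)

    criterion = _criterion_values(state, ebv, snp_effects, msv_est, Z, kin)
    plan = _build_mating_plan(state, criterion, ebv, Z, kin, rng)
    offspring = make_offspring(pop, plan.pairs, genome, rng)

    # production cohort: plain-EBV parents, random mating, own pedigree
    pm, pf = truncation_select(ebv, pop.sex, cfg.burnin_males,
                               cfg.burnin_females, ids=pop.ids)
    prod_pairs = np.column_stack([rng.choice(pm, cfg.n_production),
                                  rng.choice(pf, cfg.n_production)])
    prod = make_offspring(pop, prod_pairs, genome, rng, pedigree=Pedigree(),
                          track_ibd=False)
    prod_mean = float(true_genetic_values(prod, genome).mean())

    snp_fix, qtl_fix, fav_fix = fixation_shares(pop, genome)
    record = {
        "gain_raw": prod_mean,
        "gain_gsd": (prod_mean - state.gsd_mean) / state.gsd_sd,
        "candidates_mean": float(g_true.mean()),
        "inbreeding": float(np.mean(ibd_inbreeding(pop))),
        "genetic_variance": float(np.var(g_true)),
        "snp_fixed": snp_fix,
        "qtl_fixed": qtl_fix,
        "qtl_fixed_favorable": fav_fix,
        "acc_ebv": accuracy(ebv, g_true),
        "acc_msv": (accuracy(msv_est, msv_true)
                    if msv_est is not None else float("nan")),
    }
    state.pop = offspring
    return state, record


def run_scenario(config: StrategyConfig, seed: RngLike, replicate: int = 0,
                 on_generation=None) -> MetricsSeries:
    """Simulate one replicate of a scenario and collect per-generation metrics.

    ``on_generation``, if given, is called with each generation's metric
    record as it completes (e.g. for progress logging).
    """
    rng = as_rng(seed)
    genome = build_genome(rng, n_chr=config.n_chr, chr_length=config.chr_length,
                          n_snp=config.n_snp, n_qtl=config.n_qtl)
    pop = sample_founders(genome, n=config.n_founders, seed=rng,
                          freq=config.founder_freq)
    g0 = true_genetic_values(pop, genome)
    sd0 = float(np.std(g0))
    if sd0 > 0:
        genome = genome.with_scaled_effects(1.0 / sd0)  # founder gSD = 1
    trait = TraitModel.from_founders(pop, genome, h2=config.h2)
    pop = burn_in(pop, genome, trait, n_gen=config.burnin_generations, seed=rng,
                  n_males=config.burnin_males, n_females=config.burnin_females,
                  n_offspring=config.n_offspring)
    state = SimState(genome=genome, trait=trait, pop=pop, config=config)
    records = []
    for t in range(1, config.n_generations + 1):
        state, record = run_generation(state, rng)
        record["generation"] = t
        records.append(record)
        if on_generation is not None:
            on_generation(record)
    df = pd.DataFrame(records, columns=["generation"] + METRIC_COLUMNS)
    df["replicate"] = replicate
    return MetricsSeries(data=df, replicate=replicate)


def run_replicates(config: StrategyConfig, n_replicates: int,
                   base_seed: int) -> list[MetricsSeries]:
    """Independent replicates; replicate r uses seed ``base_seed + r``."""
    return [run_scenario(config, base_seed + r, replicate=r)
            for r in range(n_replicates)]


# ---------------------------------------------------------------------------
# aggregation and comparison
# ---------------------------------------------------------------------------

def aggregate_replicates(series: list[MetricsSeries]) -> pd.DataFrame:
    """Per-generation mean and standard error of every metric.

    The SE of a single replicate is reported as 0.
    """
    if not series:
        raise ValueError("need at least one replicate")
    lengths = {len(s.data) for s in series}
    if len(lengths) != 1:
        raise ValueError("replicates cover different generation grids")
    stacked = pd.concat([s.data for s in series], ignore_index=True)
    grouped = stacked.groupby("generation")[METRIC_COLUMNS]
    mean = grouped.mean()
    n = grouped.count()
    se = grouped.std(ddof=1).fillna(0.0) / np.sqrt(n.clip(lower=1))
    se = se.fillna(0.0)
    out = mean.join(se, lsuffix="", rsuffix="_se").reset_index()
    out["n_replicates"] = len(series)
    return out


def compare_scenarios(baseline: pd.DataFrame, scenario: pd.DataFrame) -> dict:
    """Per-generation differences (scenario minus baseline) and break-even.

    Returns absolute and percentage differences in genetic gain (gSD) and
    inbreeding, and the break-even generation: the first generation from
    which the scenario's gain stays at or above the baseline's.
    """
    if not np.array_equal(baseline["generation"], scenario["generation"]):
        raise ValueError("summaries are on different generation grids")
    gens = baseline["generation"].to_numpy()
    d_gain = scenario["gain_gsd"].to_numpy() - baseline["gain_gsd"].to_numpy()
    d_inb = scenario["inbreeding"].to_numpy() - baseline["inbreeding"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        pct_gain = 100.0 * d_gain / np.abs(baseline["gain_gsd"].to_numpy())
        pct_inb = 100.0 * d_inb / np.abs(baseline["inbreeding"].to_numpy())
    ahead = d_gain >= 0
    break_even = None
    for i in range(len(gens)):
        if ahead[i:].all():
            break_even = int(gens[i])
            break
    table = pd.DataFrame({
        "generation": gens, "gain_diff_gsd": d_gain, "gain_diff_pct": pct_gain,
        "inbreeding_diff": d_inb, "inbreeding_diff_pct": pct_inb,
    })
    return {"table": table, "break_even_generation": break_even}
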