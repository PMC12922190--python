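"""Mating-plan construction: mating avoidance, random mate sampling,
deterministic optimum contribution selection (OCS) and an evolutionary,
angle-parameterised OCS.

Deterministic OCS maximises the contribution-weighted merit of male
candidates under a cap on the next generation's expected mean kinship
(group coancestry ``c' K c``), with female contributions fixed and uniform.
The evolutionary variant instead selects equal-contribution parent sets,
trading normalised gain against normalised group coancestry as
``cos(theta) * gain - sin(theta) * coancestry``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.optimize

from .genome import RngLike, as_rng, Pedigree
from .evaluation import KinshipMatrix

__all__ = [
    "MatingPlan", "OCSSolution", "expected_offspring_inbreeding",
    "expected_offspring_kinship_to_population", "avoid_matings_quantile",
    "avoid_sib_matings", "sample_matings", "ocs_deterministic",
    "contributions_to_matings", "ocs_evolutionary",
]


@dataclass
class MatingPlan:
    """Planned matings: one (sire id, dam id) pair per offspring."""

    pairs: np.ndarray                      # (n_offspring, 2) global ids
    contributions: dict = field(default_factory=dict)  # id -> offspring count

    @classmethod
    def from_pairs(cls, pairs: np.ndarray) -> "MatingPlan":
        pairs = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
        ids, counts = np.unique(pairs, return_counts=True)
        return cls(pairs=pairs,
                   contributions={int(i): int(c) for i, c in zip(ids, counts)})


@dataclass
class OCSSolution:
    """Optimal male contributions from deterministic OCS."""

    male_ids: np.ndarray
    contributions: np.ndarray      # per male, sums to 0.5
    achieved_gain: float           # c_m' u_hat
    achieved_kinship: float        # c' K c with the full contribution vector
    feasible: bool = True          # False: constraint unattainable, min-kinship returned


def expected_offspring_inbreeding(sire: int, dam: int,
                                  kinship: KinshipMatrix) -> float:
    """Expected inbreeding of a hypothetical offspring = parental kinship."""
    return kinship.get(sire, dam)


def expected_offspring_kinship_to_population(sire: int, dam: int,
                                             mean_kinship: dict) -> float:
    """Expected mean kinship of a hypothetical offspring to the current
    population = average of its parents' mean kinships."""
    return 0.5 * (float(mean_kinship[sire]) + float(mean_kinship[dam]))


def avoid_matings_quantile(pair_values: np.ndarray, q: float) -> np.ndarray:
    """Allow pairs whose value does not exceed the empirical q-quantile.

    Uses the type-7 (linear interpolation) estimator; exclusion is strict,
    so with all values equal no pair is excluded and ``q = 1`` allows all.
    """
    values = np.asarray(pair_values, dtype=np.float64)
    if not 0.0 < q <= 1.0:
        raise ValueError("quantile must be in (0, 1]")
    thr = np.quantile(values, q)  # numpy default = type 7
    allowed = values <= thr
    if not allowed.any():
        raise ValueError("no allowed matings remain")
    return allowed


def avoid_sib_matings(pedigree: Pedigree, sires: np.ndarray, dams: np.ndarray,
                      level: str) -> np.ndarray:
    """Mask matings between full sibs ('full') or full and half sibs ('half').

    Founders (unknown parents) never count as sharing a parent.
    """
    if level not in ("full", "half"):
        raise ValueError("level must be 'full' or 'half'")
    sires = np.asarray(sires, dtype=np.int64)
    dams = np.asarray(dams, dtype=np.int64)
    ss, sd = pedigree.sire[sires][:, None], pedigree.dam[sires][:, None]
    ds, dd = pedigree.sire[dams][None, :], pedigree.dam[dams][None, :]
    share_sire = (ss == ds) & (ss >= 0)
    share_dam = (sd == dd) & (sd >= 0)
    if level == "full":
        allowed = ~(share_sire & share_dam)
    else:
        allowed = ~(share_sire | share_dam)
    if not allowed.any():
        raise ValueError("no allowed matings remain")
    return allowed


def sample_matings(allowed: np.ndarray, sires: np.ndarray, dams: np.ndarray,
                   n_offspring: int, seed: RngLike) -> MatingPlan:
    """Draw matings i.i.d. uniformly (with replacement) over allowed pairs."""
    rng = as_rng(seed)
    allowed = np.asarray(allowed, dtype=bool)
    sires = np.asarray(sires, dtype=np.int64)
    dams = np.asarray(dams, dtype=np.int64)
    flat = np.flatnonzero(allowed.ravel())
    if flat.size == 0:
        raise ValueError("allowed mating set is empty")
    picks = rng.choice(flat, size=n_offspring, replace=True)
    si, di = np.unravel_index(picks, allowed.shape)
    return MatingPlan.from_pairs(np.column_stack([sires[si], dams[di]]))


# ---------------------------------------------------------------------------
# deterministic OCS
# ---------------------------------------------------------------------------

def ocs_deterministic(male_ebv: np.ndarray, male_ids: np.ndarray,
                      female_ids: np.ndarray, kinship: KinshipMatrix,
                      delta_kin: float, current_mean_kinship: float,
                      tol: float = 1e-8) -> OCSSolution:
    """Maximise male contribution-weighted merit under a kinship cap.

    Female contributions are fixed and uniform (0.5 / n_females over the
    pre-selected dams); male contributions ``c_m >= 0`` with
    ``sum c_m = 0.5`` are optimised so that the offspring generation's
    expected mean kinship ``c' K c`` does not exceed
    ``current_mean_kinship + delta_kin``.  Solved as a linear objective with
    one quadratic constraint (SLSQP with analytic gradients); if even the
    minimum-coancestry contribution vector violates the cap, that minimiser
    is returned with ``feasible=False``.
    """
    male_ids = np.asarray(male_ids, dtype=np.int64)
    female_ids = np.asarray(female_ids, dtype=np.int64)
    u = np.asarray(male_ebv, dtype=np.float64)
    n_m, n_f = male_ids.size, female_ids.size
    mi = np.array([kinship.index_of(i) for i in male_ids])
    fi = np.array([kinship.index_of(i) for i in female_ids])
    K = kinship.values
    Kmm = K[np.ix_(mi, mi)]
    Kmf = K[np.ix_(mi, fi)]
    Kff = K[np.ix_(fi, fi)]
    cf = np.full(n_f, 0.5 / n_f)
    q0 = float(cf @ Kff @ cf)
    b = 2.0 * (Kmf @ cf)
    thr = current_mean_kinship + delta_kin

    def coancestry(c: np.ndarray) -> float:
        return float(c @ Kmm @ c + b @ c + q0)

    def finish(c: np.ndarray, feasible: bool) -> OCSSolution:
        c = np.maximum(c, 0.0)
        c *= 0.5 / c.sum()
        return OCSSolution(male_ids=male_ids, contributions=c,
                           achieved_gain=float(c @ u),
                           achieved_kinship=coancestry(c), feasible=feasible)

    # LP corner: all male contribution on the top-merit male (lowest id tie-break)
    order = np.lexsort((male_ids, -u))
    corner = np.zeros(n_m)
    corner[order[0]] = 0.5
    if coancestry(corner) <= thr + tol:
        return finish(corner, True)

    uscale = np.max(np.abs(u)) or 1.0
    cons_sum = {"type": "eq", "fun": lambda c: c.sum() - 0.5,
                "jac": lambda c: np.ones(n_m)}
    cons_kin = {"type": "ineq", "fun": lambda c: thr - coancestry(c),
                "jac": lambda c: -(2.0 * (Kmm @ c) + b)}
    bounds = [(0.0, 0.5)] * n_m
    x0 = np.full(n_m, 0.5 / n_m)
    res = scipy.optimize.minimize(
        lambda c: -(u @ c) / uscale, x0, jac=lambda c: -u / uscale,
        method="SLSQP", bounds=bounds, constraints=[cons_sum, cons_kin],
        options={"maxiter": 500, "ftol": 1e-12})
    if res.success and coancestry(res.x) <= thr + 1e-6:
        return finish(res.x, True)
    # infeasible (or solver failure): fall back to the minimum-kinship vector
    res_min = scipy.optimize.minimize(
        coancestry, x0, jac=lambda c: 2.0 * (Kmm @ c) + b,
        method="SLSQP", bounds=bounds, constraints=[cons_sum],
        options={"maxiter": 500, "ftol": 1e-14})
    c_min = np.maximum(res_min.x, 0.0)
    c_min *= 0.5 / c_min.sum()
    if coancestry(c_min) <= thr + 1e-6:
        # constraint feasible after all; re-run gain maximisation from there
        res2 = scipy.optimize.minimize(
            lambda c: -(u @ c) / uscale, c_min, jac=lambda c: -u / uscale,
            method="SLSQP", bounds=bounds, constraints=[cons_sum, cons_kin],
            options={"maxiter": 500, "ftol": 1e-12})
        if res2.success and coancestry(res2.x) <= thr + 1e-6:
            return finish(res2.x, True)
        return finish(c_min, True)
    return finish(c_min, False)


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer counts proportional to weights summing exactly to ``total``."""
    w = np.asarray(weights, dtype=np.float64)
    exact = w / w.sum() * total
    counts = np.floor(exact).astype(np.int64)
    short = total - int(counts.sum())
    if short > 0:
        frac = exact - counts
        # largest fractional parts first; ties to earlier entries
        top = np.lexsort((np.arange(w.size), -frac))[:short]
        counts[top] += 1
    return counts


def contributions_to_matings(solution: OCSSolution, dams: np.ndarray,
                             n_offspring: int, seed: RngLike) -> MatingPlan:
    """Turn optimal contributions into a concrete mating list.

    Per-sire offspring counts are the largest-remainder rounding of
    ``2 * c_m * n_offspring``; dams contribute as evenly as possible and the
    sire-dam assignment is a random permutation without further structure.
    """
    rng = as_rng(seed)
    dams = np.asarray(dams, dtype=np.int64)
    sire_counts = _largest_remainder(solution.contributions, n_offspring)
    dam_counts = _largest_remainder(np.ones(dams.size), n_offspring)
    sire_slots = np.repeat(solution.male_ids, sire_counts)
    dam_slots = np.repeat(dams, dam_counts)
    rng.shuffle(dam_slots)
    return MatingPlan.from_pairs(np.column_stack([sire_slots, dam_slots]))


# ---------------------------------------------------------------------------
# evolutionary OCS (angle-parameterised)
# ---------------------------------------------------------------------------

def _group_coancestry(K2: np.ndarray, males: np.ndarray, females: np.ndarray) -> float:
    """c' (K/2-style kinship) c for equalised contributions per sex."""
    n_m, n_f = males.size, females.size
    smm = K2[np.ix_(males, males)].sum()
    sff = K2[np.ix_(females, females)].sum()
    smf = K2[np.ix_(males, females)].sum()
    return float(0.25 * smm / n_m**2 + 0.25 * sff / n_f**2 + 0.5 * smf / (n_m * n_f))


def _set_gain(ebv: np.ndarray, males: np.ndarray, females: np.ndarray) -> float:
    return float(0.5 * ebv[males].mean() + 0.5 * ebv[females].mean())


def _ea_select_sets(objective, male_pool: np.ndarray, female_pool: np.ndarray,
                    n_males: int, n_females: int, rng: np.random.Generator,
                    pop_size: int = 50, n_elite: int = 5,
                    max_iter: int = 1000, stop_after: int = 50,
                    init_sets: Optional[list] = None):
    """(mu + lambda) search over (male set, female set) with swap mutation."""
    def random_ind():
        return (np.sort(rng.choice(male_pool, n_males, replace=False)),
                np.sort(rng.choice(female_pool, n_females, replace=False)))

    def mutate(ind):
        # one swap per sex, occasionally two, to escape single-swap optima
        out = []
        for sel, pool in zip(ind, (male_pool, female_pool)):
            sel = sel.copy()
            unsel = np.setdiff1d(pool, sel, assume_unique=False)
            n_swap = 1 + int(rng.random() < 0.3)
            for _ in range(min(n_swap, unsel.size)):
                i = rng.integers(sel.size)
                j = rng.integers(unsel.size)
                sel[i], unsel[j] = unsel[j], sel[i]
            out.append(np.sort(sel))
        return tuple(out)

    pop = list(init_sets or [])
    while len(pop) < pop_size:
        pop.append(random_ind())
    scores = np.array([objective(m, f) for m, f in pop])
    best = float(scores.max())
    trace = [best]
    stall = 0
    for _ in range(max_iter):
        order = np.argsort(-scores)
        elite = [pop[i] for i in order[:n_elite]]
        children = [random_ind() if rng.random() < 0.1
                    else mutate(elite[rng.integers(n_elite)])
                    for _ in range(pop_size - n_elite)]
        child_scores = np.array([objective(m, f) for m, f in children])
        pop = elite + children
        scores = np.concatenate([scores[order[:n_elite]], child_scores])
        new_best = float(scores.max())
        trace.append(new_best)
        if new_best > best + 1e-12:
            best, stall = new_best, 0
        else:
            stall += 1
            if stall >= stop_after:
                break
    i = int(np.argmax(scores))
    return pop[i], best, trace


def ocs_evolutionary(ebv: np.ndarray, G: KinshipMatrix, sexes: np.ndarray,
                     theta: float, n_males: int, n_females: int,
                     n_offspring: int, seed: RngLike,
                     ids: Optional[np.ndarray] = None,
                     max_iter: int = 1000, stop_after: int = 50) -> MatingPlan:
    """Angle-parameterised OCS over equal-contribution parent sets.

    ``theta`` (degrees) trades genetic gain against group coancestry:
    0 deg reduces to truncation selection on merit, 90 deg minimises group
    coancestry alone.  Gain and coancestry are min-max normalised against
    the pure-gain and pure-diversity corner solutions and combined as
    ``cos(theta) * gain_norm - sin(theta) * coancestry_norm``; the set
    search is a (mu + lambda) evolutionary algorithm with elitism.
    """
    from .criteria import truncation_select

    rng = as_rng(seed)
    ebv = np.asarray(ebv, dtype=np.float64)
    sexes = np.asarray(sexes)
    if ids is None:
        ids = np.arange(ebv.shape[0])
    ids = np.asarray(ids, dtype=np.int64)
    male_pool = np.flatnonzero(sexes == 1)
    female_pool = np.flatnonzero(sexes == 0)
    if n_males > male_pool.size or n_females > female_pool.size:
        raise ValueError("requested more parents than candidates of a sex")
    K2 = (G.values if isinstance(G, KinshipMatrix) else np.asarray(G)) / 2.0

    m_ids, f_ids = truncation_select(ebv, sexes, n_males, n_females, ids=ids)
    pos = {int(g): i for i, g in enumerate(ids)}
    gain_m = np.array([pos[int(i)] for i in m_ids])
    gain_f = np.array([pos[int(i)] for i in f_ids])
    gain_corner = (gain_m, gain_f)
    gain_max = _set_gain(ebv, *gain_corner)
    coan_at_gain = _group_coancestry(K2, *gain_corner)

    th = np.deg2rad(theta)
    if abs(theta) < 1e-12:
        sel = gain_corner
    else:
        # pure-diversity corner
        div_corner, _, _ = _ea_select_sets(
            lambda m, f: -_group_coancestry(K2, m, f),
            male_pool, female_pool, n_males, n_females, rng,
            max_iter=max_iter, stop_after=stop_after,
            init_sets=[gain_corner])
        coan_min = _group_coancestry(K2, *div_corner)
        gain_at_div = _set_gain(ebv, *div_corner)
        g_span = gain_max - gain_at_div or 1.0
        c_span = coan_at_gain - coan_min or 1.0
        if abs(theta - 90.0) < 1e-12:
            sel = div_corner
        else:
            def objective(m, f):
                gn = (_set_gain(ebv, m, f) - gain_at_div) / g_span
                cn = (_group_coancestry(K2, m, f) - coan_min) / c_span
                return np.cos(th) * gn - np.sin(th) * cn
            sel, _, _ = _ea_select_sets(objective, male_pool, female_pool,
                                     n_males, n_females, rng,
                                     max_iter=max_iter, stop_after=stop_after,
                                     init_sets=[gain_corner, div_corner])
    sel_m_ids = ids[sel[0]]
    sel_f_ids = ids[sel[1]]
    sire_slots = np.repeat(sel_m_ids, _largest_remainder(np.ones(n_males), n_offspring))
    dam_slots = np.repeat(sel_f_ids, _largest_remainder(np.ones(n_females), n_offspring))
    rng.shuffle(dam_slots)
    return MatingPlan.from_pairs(np.column_stack([sire_slots, dam_slots]))
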