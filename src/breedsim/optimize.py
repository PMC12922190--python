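"""Joint optimisation of breeding-program designs.

A design is a 9-parameter vector: four selection-criterion weights
(Goddard-weighted score, p^-1/3-weighted score, kinship to top individuals,
kinship to the cohort), a selection-proportion scale, two mating-avoidance
quantiles (expected inbreeding, expected kinship), the OCS kinship-increase
cap and a binary OCS switch.  Designs are scored by a target function
combining cumulative genetic gain, the final genetic standard deviation and
the final inbreeding level, and searched with a generational evolutionary
algorithm with elitism.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .genome import RngLike, as_rng
from .criteria import CriterionSpec
from .pipeline import StrategyConfig, MetricsSeries, run_scenario

__all__ = [
    "DesignVector", "TargetFunctionSpec", "target_function",
    "decode_design", "evolutionary_optimize", "INIT_RANGES",
]

# initialization ranges of the design space (x9 is Bernoulli(0.5))
INIT_RANGES = {
    "x1": (0.0, 0.2), "x2": (0.0, 0.2), "x3": (0.0, 0.2), "x4": (0.0, 0.2),
    "x5": (0.7, 1.3), "x6": (0.4, 1.0), "x7": (0.9, 1.0),
    "x8": (0.0035, 0.0065),
}
# hard evaluable domain (evolution may drift outside the init ranges)
EVAL_BOUNDS = {
    "x1": (-1.0, 2.0), "x2": (-1.0, 2.0), "x3": (-1.0, 2.0), "x4": (-1.0, 2.0),
    "x5": (0.3, 2.0), "x6": (0.05, 1.0), "x7": (0.05, 1.0),
    "x8": (1e-4, 0.05),
}
CONTINUOUS = ("x1", "x2", "x3", "x4", "x5", "x6", "x7", "x8")


@dataclass
class DesignVector:
    """One point of the design space (see module docstring)."""

    x1: float = 0.0
    x2: float = 0.0
    x3: float = 0.0
    x4: float = 0.0
    x5: float = 1.0
    x6: float = 1.0
    x7: float = 1.0
    x8: float = 0.005
    x9: bool = False

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in CONTINUOUS] + [float(self.x9)])


@dataclass
class TargetFunctionSpec:
    """Weights and scalings of the design target function.

    The longer-term variant weights cumulative gain 2/3 (scaled by 1/25),
    the final genetic SD 1/6 (scaled by 9/200) and the final inbreeding
    level -1/6 (scaled by 3/10).  The shorter-term variant discounts each
    generation's gain by 3% per generation and rescales the gain term by
    1/10.
    """

    variant: str = "longer_term"
    discount: float = 1.03

    def __post_init__(self) -> None:
        if self.variant not in ("longer_term", "shorter_term"):
            raise ValueError(f"unknown target variant {self.variant!r}")


def target_function(metrics, variant: str = "longer_term") -> float:
    """Evaluate the design target function on a scenario's metric series.

    ``metrics`` may be a MetricsSeries, its DataFrame, or a dict with keys
    ``gbar`` (per-generation breeding-population mean true genetic values),
    ``sigma_g_final`` (final-generation genetic SD) and ``f_final`` (final
    inbreeding level).
    """
    spec = TargetFunctionSpec(variant=variant)
    if isinstance(metrics, MetricsSeries):
        metrics = metrics.data
    if isinstance(metrics, pd.DataFrame):
        if len(metrics) == 0:
            raise ValueError("empty metric series")
        gbar = metrics["candidates_mean"].to_numpy(dtype=float)
        sigma = float(np.sqrt(metrics["genetic_variance"].iloc[-1]))
        f_final = float(metrics["inbreeding"].iloc[-1])
    else:
        gbar = np.asarray(metrics["gbar"], dtype=float)
        sigma = float(metrics["sigma_g_final"])
        f_final = float(metrics["f_final"])
    if gbar.size == 0:
        raise ValueError("empty genetic-gain series")
    t = np.arange(1, gbar.size + 1)
    if spec.variant == "longer_term":
        gain_term = (2.0 / 3.0) * (1.0 / 25.0) * gbar.sum()
    else:
        gain_term = (2.0 / 3.0) * (1.0 / 10.0) * np.sum(gbar / spec.discount ** t)
    return float(gain_term + (1.0 / 6.0) * (9.0 / 200.0) * sigma
                 - (1.0 / 6.0) * (3.0 / 10.0) * f_final)


def decode_design(x: DesignVector,
                  base: Optional[StrategyConfig] = None) -> StrategyConfig:
    """Translate a design vector into a runnable scenario configuration.

    ``base`` supplies the non-optimised knobs (genome, cohort sizes,
    generations); its male/female counts are scaled by x5 keeping the 2:5
    ratio.  The all-null design decodes to the unmodified base config.
    """
    base = base if base is not None else StrategyConfig()
    if any((x.x1, x.x2, x.x3, x.x4)):
        criterion = CriterionSpec(scheme="combined", x=(x.x1, x.x2, x.x3, x.x4))
    else:
        criterion = CriterionSpec(scheme="ebv")
    n_males = int(round(base.n_males * x.x5))
    n_females = int(round(base.n_females * x.x5))
    if n_males < 1 or n_females < 1:
        raise ValueError("selection-proportion scale leaves no parents")
    return dc_replace(
        base, criterion=criterion, n_males=n_males, n_females=n_females,
        q_inbreeding=float(x.x6), q_kinship=float(x.x7),
        ocs="deterministic" if x.x9 else "none", delta_kin=float(x.x8))


def _simulation_evaluator(variant: str, base: StrategyConfig,
                          n_replicates: int) -> Callable:
    def evaluate(x: DesignVector, seed: int) -> float:
        cfg = decode_design(x, base)
        vals = [target_function(run_scenario(cfg, seed + r, replicate=r), variant)
                for r in range(n_replicates)]
        return float(np.mean(vals))
    return evaluate


def _clip(x: DesignVector) -> DesignVector:
    kw = {}
    for k in CONTINUOUS:
        lo, hi = EVAL_BOUNDS[k]
        kw[k] = float(np.clip(getattr(x, k), lo, hi))
    kw["x9"] = bool(x.x9)
    return DesignVector(**kw)


def evolutionary_optimize(
    variant: str = "longer_term",
    budget: int = 200,
    seed: RngLike = 0,
    pop_size: int = 20,
    elite_frac: float = 0.25,
    evaluator: Optional[Callable] = None,
    base_config: Optional[StrategyConfig] = None,
    n_replicates: int = 3,
) -> tuple[DesignVector, pd.DataFrame]:
    """Generational evolutionary search over the design space.

    Designs are initialised uniformly over the per-parameter initialisation
    ranges (the OCS switch Bernoulli(0.5)), evaluated by
    ``evaluator(design, seed)``
    (default: reduced-scale simulation of the decoded scenario, target
    function averaged over ``n_replicates``), and evolved by Gaussian
    perturbation of the top ``elite_frac`` parents with per-parameter
    standard deviation equal to 10% of the initialisation range.  The
    incumbent best design is retained (elitism).  Returns the best design
    and a per-iteration trace.
    """
    rng = as_rng(seed)
    if budget < pop_size:
        raise ValueError("budget must cover at least one population")
    if evaluator is None:
        evaluator = _simulation_evaluator(
            variant, base_config if base_config is not None else StrategyConfig(),
            n_replicates)
    eval_seed = int(rng.integers(2 ** 31 - 1))

    def new_design() -> DesignVector:
        kw = {k: float(rng.uniform(*INIT_RANGES[k])) for k in CONTINUOUS}
        kw["x9"] = bool(rng.random() < 0.5)
        return DesignVector(**kw)

    def perturb(parent: DesignVector, scale: float) -> DesignVector:
        kw = {}
        for k in CONTINUOUS:
            lo, hi = INIT_RANGES[k]
            kw[k] = getattr(parent, k) + rng.normal(0.0, scale * (hi - lo))
        kw["x9"] = (not parent.x9) if rng.random() < 0.1 else parent.x9
        return _clip(DesignVector(**kw))

    n_elite = max(1, int(round(elite_frac * pop_size)))
    population = [new_design() for _ in range(pop_size)]
    scores = np.array([evaluator(d, eval_seed) for d in population])
    used = pop_size
    best_i = int(np.argmax(scores))
    best, best_score = population[best_i], float(scores[best_i])
    trace = [{"iteration": 0, "best_m": best_score,
              **{k: getattr(best, k) for k in CONTINUOUS}, "x9": best.x9}]
    it = 0
    while used + pop_size <= budget:
        it += 1
        # mutation scale anneals from 10% of the initialisation range down to
        # a 0.5% floor so late iterations refine rather than re-explore
        scale = 0.1 * max(0.93 ** it, 0.05)
        order = np.argsort(-scores)
        parents = [population[i] for i in order[:n_elite]]
        children = [perturb(parents[int(rng.integers(n_elite))], scale)
                    for _ in range(pop_size - 1)]
        population = [best] + children          # elitism: incumbent retained
        child_scores = np.array([evaluator(d, eval_seed) for d in children])
        scores = np.concatenate([[best_score], child_scores])
        used += pop_size - 1
        i = int(np.argmax(scores))
        if float(scores[i]) > best_score:
            best, best_score = population[i], float(scores[i])
        trace.append({"iteration": it, "best_m": best_score,
                      **{k: getattr(best, k) for k in CONTINUOUS},
                      "x9": best.x9})
    return best, pd.DataFrame(trace)
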