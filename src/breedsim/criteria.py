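"""Selection criteria: allele-frequency weighting of SNP effects,
kinship-penalised indices, Mendelian-sampling-variance indices, the combined
multi-strategy criterion, and truncation selection.

All criteria return one score per candidate; only the induced ranking (per
sex) matters for selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import norm

from .genome import MALE, FEMALE, _select_top_by_sex

__all__ = [
    "CriterionSpec", "allele_weighting", "weighted_criterion",
    "kinship_index", "selection_intensity", "msv_index",
    "combined_criterion", "truncation_select",
]

WEIGHTING_SCHEMES = (
    "ebv", "goddard", "jannink", "pow_third", "pow_quarter",
    "capped_jannink", "blend",
)


@dataclass
class CriterionSpec:
    """Parameterisation of one selection criterion.

    scheme:
        'ebv' plain GBLUP EBVs; 'goddard' / 'jannink' / 'pow_third' /
        'pow_quarter' / 'capped_jannink' / 'blend' allele-frequency-weighted
        EBVs; 'kinship_top' / 'kinship_pop' kinship-penalised index;
        'msv_i5' / 'msv_i6' MSV-augmented indices; 'combined' the
        four-weight joint criterion.
    """

    scheme: str = "ebv"
    d: float = 0.5                      # blend weight on the unweighted part
    w_f: float = 0.175                  # index weight on mean kinship
    x: tuple = (0.0, 0.0, 0.0, 0.0)     # combined-criterion weights x1..x4

    def __post_init__(self) -> None:
        if self.scheme == "blend" and not 0.0 <= self.d <= 1.0:
            raise ValueError("blend weight d must be in [0, 1]")
        if self.scheme.startswith("kinship") and not 0.0 <= self.w_f <= 1.0:
            raise ValueError("index weight w_f must be in [0, 1]")


def allele_weighting(p: np.ndarray, scheme: str, d: Optional[float] = None) -> np.ndarray:
    """Per-SNP weight as a function of the beneficial-allele frequency.

    Schemes: 'goddard' ``(pi/2 - arcsin(sqrt p)) / sqrt(p (1-p))``;
    'jannink' ``p^-1/2``; 'pow_third' ``p^-1/3``; 'pow_quarter' ``p^-1/4``;
    'capped_jannink' ``min(5, p^-1/2)``; 'blend' ``d + (1-d) p^-1/2``;
    'ebv' constant 1.  Fixed loci (p in {0, 1}) get weight 1: their term is
    constant across candidates, so the ranking is unaffected.
    """
    p = np.asarray(p, dtype=np.float64)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("allele frequencies must lie in [0, 1]")
    fixed = (p <= 0.0) | (p >= 1.0)
    ps = np.where(fixed, 0.5, p)  # placeholder to keep formulas finite
    if scheme == "ebv":
        w = np.ones_like(p)
    elif scheme == "goddard":
        w = (np.pi / 2 - np.arcsin(np.sqrt(ps))) / np.sqrt(ps * (1.0 - ps))
    elif scheme == "jannink":
        w = ps ** -0.5
    elif scheme == "pow_third":
        w = ps ** (-1.0 / 3.0)
    elif scheme == "pow_quarter":
        w = ps ** -0.25
    elif scheme == "capped_jannink":
        w = np.minimum(5.0, ps ** -0.5)
    elif scheme == "blend":
        if d is None:
            raise ValueError("blend scheme requires d")
        w = d + (1.0 - d) * ps ** -0.5
    else:
        raise ValueError(f"unknown weighting scheme {scheme!r}")
    return np.where(fixed, 1.0, w)


def weighted_criterion(genotypes: np.ndarray, weights: np.ndarray,
                       snp_effects: np.ndarray) -> np.ndarray:
    """Weighted genomic score ``sum_j z_ij w_j a_j`` per candidate."""
    Z = np.asarray(genotypes)
    w = np.asarray(weights, dtype=np.float64)
    a = np.asarray(snp_effects, dtype=np.float64)
    if Z.shape[1] != w.shape[0] or w.shape != a.shape:
        raise ValueError("genotypes, weights and effects are not aligned")
    return Z.astype(np.float64) @ (w * a)


def _standardize(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    s = x.std()
    if s == 0.0:
        raise ValueError("zero-variance component cannot be standardized")
    return (x - x.mean()) / s


def kinship_index(ebv: np.ndarray, f: np.ndarray, w_f: float) -> np.ndarray:
    """Index trading EBV against mean kinship to the breeding population.

    Both components are standardised to zero mean / unit variance across
    candidates; returns ``-w_f * f_std + (1 - w_f) * ebv_std``.
    """
    return -w_f * _standardize(f) + (1.0 - w_f) * _standardize(ebv)


def selection_intensity(p: float) -> tuple[float, float]:
    """Truncation point ``x_p`` and selection intensity ``i_p = phi(x_p)/p``
    of standard-normal truncation at the upper proportion ``p``."""
    if not 0.0 < p < 1.0:
        raise ValueError("selection proportion must be in (0, 1)")
    x_p = norm.isf(p)
    i_p = norm.pdf(x_p) / p
    return float(x_p), float(i_p)


def msv_index(ebv: np.ndarray, msv_sd: np.ndarray, p: float | np.ndarray,
              variant: str) -> np.ndarray:
    """Gamete-variance-augmented indices.

    'i5': ``EBV + sqrt(2) x_p sigma_g`` (probability of offspring selection);
    'i6': ``EBV + sqrt(2) i_p sigma_g`` (response to recurrent selection).
    ``p`` is the selection proportion (scalar or per-candidate, e.g. by sex).
    """
    ebv = np.asarray(ebv, dtype=np.float64)
    sd = np.asarray(msv_sd, dtype=np.float64)
    pa = np.broadcast_to(np.asarray(p, dtype=np.float64), ebv.shape)
    scale = np.empty_like(ebv)
    for pv in np.unique(pa):
        x_p, i_p = selection_intensity(float(pv))
        scale[pa == pv] = x_p if variant == "i5" else i_p
    if variant not in ("i5", "i6"):
        raise ValueError(f"unknown MSV index variant {variant!r}")
    return ebv + np.sqrt(2.0) * scale * sd


def combined_criterion(genotypes: np.ndarray, snp_effects: np.ndarray,
                       p: np.ndarray, f_top: np.ndarray, f_pop: np.ndarray,
                       x: Sequence[float]) -> np.ndarray:
    """Joint criterion mixing allele-weighted scores, kinship penalties and
    the plain EBV score.

    ``x = (x1, x2, x3, x4)``: weight on the Goddard-weighted score, on the
    ``p^-1/3``-weighted score, on mean kinship to top individuals, and on
    mean kinship to the whole candidate cohort; the plain genomic score gets
    the residual weight ``1 - x1 - x2 - x3 - x4``.  Every component is
    standardised over the candidates before weighting so the x-weights are
    comparable across scales; weights are deliberately unconstrained.
    """
    x1, x2, x3, x4 = (float(v) for v in x)
    Z = np.asarray(genotypes)
    base = weighted_criterion(Z, np.ones_like(snp_effects), snp_effects)
    out = (1.0 - x1 - x2 - x3 - x4) * _standardize(base)
    if x1:
        w = allele_weighting(p, "goddard")
        out = out + x1 * _standardize(weighted_criterion(Z, w, snp_effects))
    if x2:
        w = allele_weighting(p, "pow_third")
        out = out + x2 * _standardize(weighted_criterion(Z, w, snp_effects))
    if x3:
        out = out - x3 * _standardize(f_top)
    if x4:
        out = out - x4 * _standardize(f_pop)
    return out


def truncation_select(criterion: np.ndarray, sexes: np.ndarray,
                      n_males: int, n_females: int,
                      ids: Optional[np.ndarray] = None
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Top-n males and females by criterion; ties broken by lower id.

    Returns (male ids, female ids); ``ids`` defaults to positions.
    """
    criterion = np.asarray(criterion, dtype=np.float64)
    if ids is None:
        ids = np.arange(criterion.shape[0])
    return _select_top_by_sex(criterion, np.asarray(sexes), np.asarray(ids),
                              n_males, n_females)
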