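"""Genomic and pedigree evaluation: GBLUP, kinship matrices, SNP-effect
back-solving and Mendelian-sampling-variance (MSV) prediction.

GBLUP fits the single-trait animal model ``y = 1*mu + g + e`` with
``var(g) = sigma_g^2 * G`` and known variance ratio
``lambda = sigma_e^2 / sigma_g^2 = (1 - h2) / h2``; the BLUP of ``g`` is
``G (G + lambda I)^{-1} (y - 1*mu_hat)`` with ``mu_hat`` the GLS mean.

The MSV of a candidate is the variance of breeding values among its gametes.
With per-locus terms ``v_j = a_j (h1_j - h2_j) / 2`` (phase difference times
effect, halved), the gamete-BV variance under Haldane recombination is
``sum_jk v_j v_k (1 - 2 r_jk)`` where ``1 - 2 r_jk = exp(-2 |d_j - d_k|)``
within a chromosome and 0 across chromosomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.linalg

from .genome import GenomeSpec, Pedigree

__all__ = [
    "EvalResult", "KinshipMatrix", "vanraden_G", "pedigree_kinship",
    "estimate_h2_he", "gblup_ebv", "backsolve_snp_effects", "msv_gamete_sd",
    "accuracy",
]


@dataclass
class EvalResult:
    """Outcome of one round of genetic evaluation."""

    ebv: np.ndarray
    mu: float = 0.0
    snp_effects: Optional[np.ndarray] = None
    msv_sd: Optional[np.ndarray] = None
    training_ids: Optional[np.ndarray] = None
    # V^{-1}(y - 1 mu); g_hat = G @ vinv_resid, and SNP effects back-solve
    # reduces to M' vinv_resid / denom for G = M M' / denom
    vinv_resid: Optional[np.ndarray] = None


@dataclass
class KinshipMatrix:
    """Symmetric pairwise kinship/relationship matrix with an id order.

    ``kind == 'pedigree'`` stores kinships f (diagonal 0.5*(1+F));
    ``kind == 'genomic'`` stores the VanRaden method-1 relationship matrix
    (diagonal around 1), whose kinship analogue is ``values / 2``.
    """

    values: np.ndarray
    kind: str
    ids: Optional[np.ndarray] = None
    _index: Optional[dict] = field(default=None, repr=False)

    def index_of(self, individual: int) -> int:
        if self._index is None:
            if self.ids is None:
                raise KeyError("kinship matrix carries no ids")
            self._index = {int(g): i for i, g in enumerate(self.ids)}
        return self._index[int(individual)]

    def get(self, a: int, b: int) -> float:
        """Kinship between two individuals looked up by id."""
        return float(self.values[self.index_of(a), self.index_of(b)])


def vanraden_G(genotypes: np.ndarray,
               allele_freqs: Optional[np.ndarray] = None,
               ids: Optional[np.ndarray] = None) -> KinshipMatrix:
    """VanRaden method-1 genomic relationship matrix.

    ``G = M M' / (2 * sum_j p_j (1 - p_j))`` with ``M`` the allele-dosage
    matrix centered by twice the allele frequencies.  Frequencies default to
    estimates from the given genotypes themselves.
    """
    Z = np.asarray(genotypes)
    if allele_freqs is None:
        allele_freqs = Z.mean(axis=0) / 2.0
    p = np.asarray(allele_freqs, dtype=np.float64)
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom <= 0.0:
        raise ValueError("all loci fixed: VanRaden denominator is zero")
    # float32 matmul for large cohorts; the quadratic form is benign
    dtype = np.float32 if Z.size > 2_000_000 else np.float64
    M = Z.astype(dtype) - (2.0 * p).astype(dtype)
    G = (M @ M.T).astype(np.float64) / denom
    return KinshipMatrix(values=G, kind="genomic", ids=ids)


def pedigree_kinship(pedigree: Pedigree, ids: np.ndarray,
                     depth: int = 7) -> KinshipMatrix:
    """Pedigree kinship among ``ids`` by the tabular method.

    The pedigree is truncated ``depth`` generations above the target ids;
    ancestors at the truncation boundary are treated as unrelated and
    non-inbred.  Returned values are kinships (additive relationship / 2).
    """
    ids = np.asarray(ids, dtype=np.int64)
    dist: dict[int, int] = {int(i): 0 for i in ids}
    frontier = set(int(i) for i in ids)
    for d in range(1, depth + 1):
        nxt = set()
        for i in frontier:
            for par in (int(pedigree.sire[i]), int(pedigree.dam[i])):
                if par >= 0 and dist.get(par, depth + 1) > d:
                    dist[par] = d
                    nxt.add(par)
        frontier = nxt
    members = np.array(sorted(dist), dtype=np.int64)
    local = {int(g): i for i, g in enumerate(members)}
    n = members.shape[0]
    # parents within the truncated pedigree (-1 at the boundary)
    ps = np.full(n, -1, dtype=np.int64)
    pd = np.full(n, -1, dtype=np.int64)
    for i, g in enumerate(members):
        if dist[int(g)] >= depth:
            continue  # boundary ancestor: treated as unknown-parent founder
        s, d_ = int(pedigree.sire[g]), int(pedigree.dam[g])
        ps[i] = local.get(s, -1) if s >= 0 else -1
        pd[i] = local.get(d_, -1) if d_ >= 0 else -1
        if ps[i] >= i or pd[i] >= i:
            raise ValueError("pedigree is not ordered parents-before-offspring")
    A = np.zeros((n, n))
    for i in range(n):
        row = np.zeros(i)
        if ps[i] >= 0:
            row += 0.5 * A[ps[i], :i]
        if pd[i] >= 0:
            row += 0.5 * A[pd[i], :i]
        A[i, :i] = row
        A[:i, i] = row
        a_sd = A[ps[i], pd[i]] if (ps[i] >= 0 and pd[i] >= 0) else 0.0
        A[i, i] = 1.0 + 0.5 * a_sd
    sub = np.array([local[int(g)] for g in ids])
    K = A[np.ix_(sub, sub)] / 2.0
    return KinshipMatrix(values=K, kind="pedigree", ids=ids)


def estimate_h2_he(phenotypes: np.ndarray, G: KinshipMatrix | np.ndarray,
                   lo: float = 0.02, hi: float = 0.98) -> float:
    """Haseman-Elston estimate of the heritability captured by G.

    Regresses off-diagonal phenotypic cross-products on the corresponding
    relationship coefficients: ``sigma_g^2 = sum_{i!=j} G_ij y~_i y~_j /
    sum_{i!=j} G_ij^2`` with centred phenotypes, then
    ``h2 = sigma_g^2 * mean(diag G) / var(y)``, clamped to [lo, hi].  A
    moment estimator: fast (two quadratic forms), deterministic and
    adequate for re-calibrating the GBLUP shrinkage each generation as
    genetic variance is depleted.
    """
    Gv = G.values if isinstance(G, KinshipMatrix) else np.asarray(G)
    y = np.asarray(phenotypes, dtype=np.float64)
    yt = y - y.mean()
    diag = np.diag(Gv)
    num = float(yt @ Gv @ yt) - float(np.sum(diag * yt * yt))
    den = float(np.sum(Gv * Gv)) - float(np.sum(diag**2))
    if den <= 0:
        return lo
    sg2 = num / den
    sp2 = float(np.var(yt))
    if sp2 <= 0:
        return lo
    return float(min(max(sg2 * float(diag.mean()) / sp2, lo), hi))


def gblup_ebv(phenotypes: np.ndarray, G: KinshipMatrix | np.ndarray,
              h2: float, training_ids: Optional[np.ndarray] = None) -> EvalResult:
    """GBLUP breeding values with the variance ratio treated as known.

    Solves the animal model on the training set defined by ``G`` and
    ``phenotypes`` (same order) and returns the BLUP of ``g`` for all of
    them.
    """
    if not 0.0 < h2 < 1.0:
        raise ValueError("h2 must be in (0, 1)")
    Gv = G.values if isinstance(G, KinshipMatrix) else np.asarray(G)
    y = np.asarray(phenotypes, dtype=np.float64)
    if Gv.shape[0] != y.shape[0]:
        raise ValueError("G and phenotypes are not aligned")
    lam = (1.0 - h2) / h2
    V = Gv + lam * np.eye(Gv.shape[0])
    cho = scipy.linalg.cho_factor(V, lower=True)
    ones = np.ones_like(y)
    Vi_y = scipy.linalg.cho_solve(cho, y)
    Vi_1 = scipy.linalg.cho_solve(cho, ones)
    mu = float(ones @ Vi_y) / float(ones @ Vi_1)
    w = scipy.linalg.cho_solve(cho, y - mu)
    ghat = Gv @ w
    return EvalResult(ebv=ghat, mu=mu, training_ids=training_ids, vinv_resid=w)


def backsolve_snp_effects(ebv: np.ndarray, centered_genotypes: np.ndarray,
                          MMt: Optional[np.ndarray] = None) -> np.ndarray:
    """Minimum-norm SNP effects reproducing the individual EBVs.

    ``a = M' (M M')^{-1} g_hat`` for the centered genotype matrix ``M``
    (n individuals x m SNPs, n < m typically); near-singular ``M M'`` gets a
    ridge of ``1e-8 * trace / n``.
    """
    M = np.asarray(centered_genotypes)
    g = np.asarray(ebv, dtype=M.dtype)
    if MMt is None:
        MMt = M @ M.T
    MMt = np.asarray(MMt, dtype=np.float64)
    gg = g.astype(np.float64)
    alpha = None
    try:
        cho = scipy.linalg.cho_factor(MMt, lower=True, check_finite=False)
        alpha = scipy.linalg.cho_solve(cho, gg, check_finite=False)
        resid = np.linalg.norm(MMt @ alpha - gg)
        if not np.all(np.isfinite(alpha)) or resid > 1e-6 * max(np.linalg.norm(gg), 1.0):
            alpha = None
    except np.linalg.LinAlgError:
        alpha = None
    if alpha is None:  # near-singular M M': escalating ridge fallback
        eps = 1e-8 * np.trace(MMt) / MMt.shape[0]
        eye = np.eye(MMt.shape[0])
        for _ in range(4):
            try:
                cho = scipy.linalg.cho_factor(MMt + eps * eye, lower=True)
                alpha = scipy.linalg.cho_solve(cho, gg)
                break
            except np.linalg.LinAlgError:
                eps *= 100.0
        else:
            alpha = scipy.linalg.lstsq(MMt, gg)[0]
    return (M.T @ alpha.astype(M.dtype)).astype(np.float64)


def msv_gamete_sd(haplo: np.ndarray, effects: np.ndarray, map_pos: np.ndarray,
                  chr_index: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Standard deviation of gamete breeding values per individual.

    Parameters are aligned over the same loci: ``haplo`` is (n, 2, m),
    ``effects`` (m,), ``map_pos`` the within-chromosome Morgan positions and
    ``chr_index`` the chromosome of each locus.  The quadratic form with the
    exponential linkage kernel is evaluated in O(m) per chromosome via
    prefix sums.
    """
    haplo = np.asarray(haplo)
    v = 0.5 * np.asarray(effects, dtype=np.float64) * (
        haplo[:, 0, :].astype(np.float64) - haplo[:, 1, :].astype(np.float64))
    var = np.einsum("ij,ij->i", v, v)
    chr_index = np.asarray(chr_index)
    for c in np.unique(chr_index):
        cols = chr_index == c
        d = map_pos[cols]
        vc = v[:, cols]
        up = np.exp(2.0 * (d - d[0]))        # relative to chromosome start
        down = np.exp(-2.0 * (d - d[0]))
        prefix = np.cumsum(vc * up, axis=1)
        # sum_{j<k} v_j v_k exp(-2 (d_k - d_j))
        inner = np.einsum("ij,ij->i", vc[:, 1:] * down[1:], prefix[:, :-1])
        var += 2.0 * inner
    if np.any(var < -tol):
        raise FloatingPointError("negative gamete variance beyond tolerance")
    return np.sqrt(np.maximum(var, 0.0))


def accuracy(predicted: np.ndarray, true: np.ndarray) -> float:
    """Pearson correlation between predictions and true values."""
    predicted = np.asarray(predicted, dtype=np.float64)
    true = np.asarray(true, dtype=np.float64)
    if predicted.shape != true.shape or predicted.size < 3:
        raise ValueError("need equal-length vectors of at least 3 values")
    if np.std(predicted) == 0.0 or np.std(true) == 0.0:
        raise ValueError("zero-variance input")
    return float(np.corrcoef(predicted, true)[0, 1])
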