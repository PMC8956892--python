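"""Rst via AMOVA on squared repeat-length distances, and classical MDS.

The molecular distance between two haplotypes is the sum over loci of the
squared difference in repeat counts (Slatkin's convention for
microsatellites).  A one-level analysis of molecular variance partitions
the total sum of squared deviations into among- and within-population
components; the intraclass correlation of the variance components is the
Phi-statistic, which on this metric estimates Rst.  Significance comes
from permuting individuals across population labels.

Classical (Torgerson) multidimensional scaling double-centres the squared
distance matrix, B = -1/2 J D^2 J, and embeds populations on the leading
non-negative eigenpairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .haplotypes import Haplotype, PopulationDataset
from .panels import LocusPanel

__all__ = [
    "AmovaResult",
    "DistanceMatrix",
    "MDSResult",
    "haplotype_distance",
    "amova",
    "pairwise_rst",
    "classical_mds",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class AmovaResult:
    """One-level AMOVA table and its permutation test."""

    ssd_among: float
    ssd_within: float
    df_among: int
    df_within: int
    sigma2_a: float
    sigma2_w: float
    phi_st: float
    p_value: float
    n_permutations: int
    seed: int

    @property
    def ssd_total(self) -> float:
        return self.ssd_among + self.ssd_within

    def summary(self) -> str:
        return (
            f"{'Source':<22}{'df':>5}{'SSD':>12}{'Variance':>12}\n"
            f"{'Among populations':<22}{self.df_among:>5}{self.ssd_among:>12.5f}"
            f"{self.sigma2_a:>12.5f}\n"
            f"{'Within populations':<22}{self.df_within:>5}{self.ssd_within:>12.5f}"
            f"{self.sigma2_w:>12.5f}\n"
            f"Phi_st (Rst) = {self.phi_st:.5f}   "
            f"p = {self.p_value:.4f} ({self.n_permutations} permutations, seed {self.seed})"
        )


@dataclass(frozen=True)
class DistanceMatrix:
    """Pairwise Rst between populations with permutation p-values."""

    labels: tuple[str, ...]
    rst: np.ndarray
    p_values: np.ndarray

    def clamped(self) -> np.ndarray:
        """Rst with negative estimates clamped to 0 (for MDS input)."""
        return np.maximum(self.rst, 0.0)


@dataclass(frozen=True)
class MDSResult:
    labels: tuple[str, ...]
    coordinates: np.ndarray
    eigenvalues: np.ndarray


def _numeric_profile(
    h: Haplotype,
    panel: LocusPanel,
    include_dys385: bool,
    dys389_subtract: bool,
) -> tuple[list[float], list[tuple[float, float]]]:
    """(single-copy values in panel order, multi-copy sorted pairs)."""
    singles: list[float] = []
    pairs: list[tuple[float, float]] = []
    for locus in panel.loci:
        call = h.calls.get(locus)
        if call is None:
            raise ValueError(f"sample {h.sample_id}: missing locus {locus}")
        if locus in panel.multi_copy:
            if include_dys385:
                a, b = call
                pairs.append((a.value, b.value))
            continue
        v = call.value
        if dys389_subtract and locus == "DYS389II":
            inner = h.calls.get("DYS389I")
            if inner is None:
                raise ValueError(
                    f"sample {h.sample_id}: DYS389I needed for DYS389II subtraction"
                )
            v -= inner.value
        singles.append(v)
    return singles, pairs


def haplotype_distance(
    a: Haplotype,
    b: Haplotype,
    panel: LocusPanel,
    *,
    include_dys385: bool = False,
    dys389_subtract: bool = False,
) -> float:
    """Sum of squared repeat differences over the panel's loci.

    Micro-variants contribute variant/10 to the repeat value.  The
    unordered DYS385a/b pair (when included) contributes the minimum over
    its two copy-to-copy pairings.  DYS389II is used as typed unless
    ``dys389_subtract`` removes the embedded DYS389I stretch.
    """
    sa, pa = _numeric_profile(a, panel, include_dys385, dys389_subtract)
    sb, pb = _numeric_profile(b, panel, include_dys385, dys389_subtract)
    d = sum((x - y) ** 2 for x, y in zip(sa, sb))
    for (a1, a2), (b1, b2) in zip(pa, pb):
        d += min(
            (a1 - b1) ** 2 + (a2 - b2) ** 2,
            (a1 - b2) ** 2 + (a2 - b1) ** 2,
        )
    return d


def _distance_matrix(
    samples: list[Haplotype],
    panel: LocusPanel,
    include_dys385: bool,
    dys389_subtract: bool,
) -> np.ndarray:
    """Full n x n matrix of squared repeat-length distances."""
    singles = []
    pairs = []
    for h in samples:
        s, p = _numeric_profile(h, panel, include_dys385, dys389_subtract)
        singles.append(s)
        pairs.append(p)
    n = len(samples)
    d = np.zeros((n, n))
    if singles and singles[0]:
        v = np.asarray(singles)
        d += squareform(pdist(v, metric="sqeuclidean"))
    if include_dys385 and pairs and pairs[0]:
        for k in range(len(pairs[0])):
            x = np.array([p[k][0] for p in pairs])
            y = np.array([p[k][1] for p in pairs])
            straight = (x[:, None] - x[None, :]) ** 2 + (y[:, None] - y[None, :]) ** 2
            crossed = (x[:, None] - y[None, :]) ** 2 + (y[:, None] - x[None, :]) ** 2
            d += np.minimum(straight, crossed)
    return d


def _ssd_components(d: np.ndarray, sizes: list[int]) -> tuple[float, float]:
    """(ssd_total, ssd_within) from a full distance matrix and group sizes."""
    n = d.shape[0]
    ssd_total = d.sum() / (2.0 * n)
    ssd_within = 0.0
    start = 0
    for nk in sizes:
        block = d[start : start + nk, start : start + nk]
        ssd_within += block.sum() / (2.0 * nk)
        start += nk
    return ssd_total, ssd_within


def _phi_from_ssd(
    ssd_total: float, ssd_within: float, sizes: list[int]
) -> tuple[float, float, float]:
    """(sigma2_a, sigma2_w, phi_st) from SSDs and group sizes."""
    n = sum(sizes)
    k = len(sizes)
    df_among = k - 1
    df_within = n - k
    ssd_among = ssd_total - ssd_within
    sigma2_w = ssd_within / df_within
    n_bar = (n - sum(s * s for s in sizes) / n) / df_among
    sigma2_a = (ssd_among / df_among - sigma2_w) / n_bar
    denom = sigma2_a + sigma2_w
    phi = sigma2_a / denom if denom > 0 else 0.0
    return sigma2_a, sigma2_w, phi


def amova(
    groups: list[PopulationDataset],
    n_perm: int = 1000,
    seed: int = 0,
    *,
    include_dys385: bool = False,
    dys389_subtract: bool = False,
) -> AmovaResult:
    """One-level AMOVA across populations with a permutation test.

    SSD_total is the sum over all unordered sample pairs of d_ij divided
    by N; SSD_within sums the analogous per-group terms; variance
    components follow the standard unequal-size weighting with
    n_bar = (N - sum n_k^2 / N)/(K-1).  The permutation test shuffles
    individuals across population labels; the p-value is (b+1)/(m+1)
    with the observed statistic included.
    """
    if len(groups) < 2:
        raise ValueError("AMOVA requires at least 2 populations")
    if any(g.n < 2 for g in groups):
        raise ValueError("every population needs at least 2 samples")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    panel = groups[0].panel
    samples = [h for g in groups for h in g.haplotypes]
    sizes = [g.n for g in groups]
    d = _distance_matrix(samples, panel, include_dys385, dys389_subtract)

    ssd_total, ssd_within = _ssd_components(d, sizes)
    sigma2_a, sigma2_w, phi_obs = _phi_from_ssd(ssd_total, ssd_within, sizes)

    rng = np.random.default_rng(seed)
    n = sum(sizes)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        dp = d[np.ix_(perm, perm)]
        _, ssd_w = _ssd_components(dp, sizes)
        _, _, phi = _phi_from_ssd(ssd_total, ssd_w, sizes)
        if phi >= phi_obs - 1e-12:
            hits += 1
    p = (hits + 1) / (n_perm + 1)

    n_groups = len(sizes)
    return AmovaResult(
        ssd_among=ssd_total - ssd_within,
        ssd_within=ssd_within,
        df_among=n_groups - 1,
        df_within=n - n_groups,
        sigma2_a=sigma2_a,
        sigma2_w=sigma2_w,
        phi_st=phi_obs,
        p_value=p,
        n_permutations=n_perm,
        seed=seed,
    )


def pairwise_rst(
    populations: list[PopulationDataset],
    n_perm: int = 1000,
    seed: int = 0,
    *,
    include_dys385: bool = False,
    dys389_subtract: bool = False,
) -> DistanceMatrix:
    """Matrix of pairwise Rst (Phi_st) with permutation p-values.

    Negative estimates are retained; :meth:`DistanceMatrix.clamped`
    zeroes them for MDS input.
    """
    if len(populations) < 2:
        raise ValueError("need at least 2 populations")
    k = len(populations)
    rst = np.zeros((k, k))
    pvals = np.ones((k, k))
    seeds = np.random.SeedSequence(seed).generate_state(k * k)
    for i in range(k):
        for j in range(i + 1, k):
            res = amova(
                [populations[i], populations[j]],
                n_perm=n_perm,
                seed=int(seeds[i * k + j] % (2**31)),
                include_dys385=include_dys385,
                dys389_subtract=dys389_subtract,
            )
            rst[i, j] = rst[j, i] = res.phi_st
            pvals[i, j] = pvals[j, i] = res.p_value
    return DistanceMatrix(
        labels=tuple(p.name for p in populations), rst=rst, p_values=pvals
    )


def classical_mds(
    dm: DistanceMatrix | np.ndarray,
    dims: int = 2,
    labels: tuple[str, ...] | None = None,
) -> MDSResult:
    """Torgerson's classical scaling of a distance matrix.

    Double-centres B = -1/2 J D^2 J and returns coordinates on the top
    ``dims`` eigenpairs with positive eigenvalues; if fewer positive
    eigenvalues exist, fewer columns are returned with a logged warning.
    Negative eigenvalues (non-Euclidean distances) are reported but
    never embedded.
    """
    if isinstance(dm, DistanceMatrix):
        d = dm.clamped()
        labels = dm.labels
    else:
        d = np.asarray(dm, dtype=float)
        if labels is None:
            labels = tuple(str(i) for i in range(d.shape[0]))
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")
    if dims < 1:
        raise ValueError("dims must be >= 1")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = 1e-9 * max(1.0, float(np.abs(evals).max(initial=0.0)))
    if (evals < -tol).any():
        log.warning(
            "MDS: %d negative eigenvalue(s) dropped (non-Euclidean input)",
            int((evals < -tol).sum()),
        )
    n_pos = int((evals > tol).sum())
    use = min(dims, n_pos)
    if use < dims:
        log.warning("MDS: only %d positive eigenvalue(s); returning %d dims", n_pos, use)
    coords = evecs[:, :use] * np.sqrt(evals[:use])
    return MDSResult(labels=tuple(labels), coordinates=coords, eigenvalues=evals)
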