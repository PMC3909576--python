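"""Codominant genotypic distances and downstream multivariate analyses.

A diploid single-locus genotype is scored as an additive dosage vector
over the locus's allele set (homozygote AiAi -> 2 at i; heterozygote
AiAj -> 1 at i and j).  The squared genotypic distance between two
individuals at one locus is one-half the squared Euclidean distance
between their dosage vectors, which confines single-locus values to
{0, 1, 2, 3, 4}; multilocus distance sums over loci assuming
independence.

Also provided: the cultivar-level distance summary (between-cultivar
means off the diagonal, mean within-cultivar pairwise dissimilarity on
it), principal coordinates analysis of a squared-distance matrix via
Gower double-centering, an AMOVA-based PhiPT permutation test, and a
permutation screen for pairwise linkage disequilibrium between loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import GenotypeCall, GenotypeTable, Locus, SSRKitError


class DistanceError(SSRKitError):
    pass


def score_vector(call: GenotypeCall, locus: Locus) -> np.ndarray:
    """Additive dosage vector over the locus's registered allele set."""
    vec = np.zeros(locus.n_alleles, dtype=float)
    if call.is_missing:
        return vec
    index = {a: k for k, a in enumerate(locus.allele_sizes)}
    for allele in call.alleles():
        if allele not in index:
            raise DistanceError(
                f"allele {allele} not registered at locus {locus.name}"
            )
        vec[index[allele]] += 1.0
    return vec


def pair_distance(
    x, y, loci: list[Locus], rescale_missing: bool = False
) -> float:
    """Multilocus squared genotypic distance between two samples.

    Loci where either call is missing are dropped (pairwise deletion);
    with ``rescale_missing`` the sum is scaled by L / loci_used.  A pair
    with no shared typed locus raises :class:`DistanceError`.
    """
    total = 0.0
    used = 0
    for locus in loci:
        cx, cy = x.call(locus.name), y.call(locus.name)
        if cx.is_missing or cy.is_missing:
            continue
        diff = score_vector(cx, locus) - score_vector(cy, locus)
        total += 0.5 * float(diff @ diff)
        used += 1
    if used == 0:
        raise DistanceError(
            f"samples {x.sample_id} and {y.sample_id} share no typed locus"
        )
    if rescale_missing and used < len(loci):
        total *= len(loci) / used
    return total


@dataclass
class DistanceResult:
    sample_ids: list[str]
    matrix: np.ndarray  # symmetric squared distances, zero diagonal
    loci_used: np.ndarray  # shared typed loci per pair

    def index(self, sample_id: str) -> int:
        return self.sample_ids.index(sample_id)


def distance_matrix(table: GenotypeTable, rescale_missing: bool = False) -> DistanceResult:
    """Individual-by-individual squared distance matrix, vectorized per locus."""
    n = table.n_samples
    total = np.zeros((n, n))
    used = np.zeros((n, n), dtype=int)
    L = len(table.loci)
    for locus in table.loci:
        X = np.zeros((n, locus.n_alleles))
        typed = np.zeros(n, dtype=bool)
        for i, s in enumerate(table.samples):
            call = s.call(locus.name)
            if call.is_missing:
                continue
            typed[i] = True
            X[i] = score_vector(call, locus)
        sq = (X * X).sum(axis=1)
        d2 = 0.5 * (sq[:, None] + sq[None, :] - 2.0 * (X @ X.T))
        pair_typed = typed[:, None] & typed[None, :]
        total += np.where(pair_typed, np.clip(d2, 0.0, None), 0.0)
        used += pair_typed
    np.fill_diagonal(used, L)
    if np.any(used == 0):
        i, j = np.argwhere(used == 0)[0]
        raise DistanceError(
            f"samples {table.samples[i].sample_id} and "
            f"{table.samples[j].sample_id} share no typed locus"
        )
    if rescale_missing:
        total *= L / used
    np.fill_diagonal(total, 0.0)
    return DistanceResult(
        sample_ids=[s.sample_id for s in table.samples],
        matrix=total,
        loci_used=used,
    )


@dataclass
class CultivarDistanceSummary:
    cultivars: list[str]
    matrix: np.ndarray  # off-diagonal: between means; diagonal: within means
    singletons: list[str] = field(default_factory=list)  # within mean undefined, set to 0


def cultivar_matrix(dist: DistanceResult, cultivar_labels: list[str]) -> CultivarDistanceSummary:
    """Average individual distances between and within cultivars."""
    if len(cultivar_labels) != len(dist.sample_ids):
        raise ValueError("one cultivar label required per sample")
    cultivars: list[str] = []
    for c in cultivar_labels:
        if c not in cultivars:
            cultivars.append(c)
    idx = {c: np.flatnonzero(np.asarray(cultivar_labels, dtype=object) == c) for c in cultivars}
    k = len(cultivars)
    out = np.zeros((k, k))
    singletons = []
    for a, ca in enumerate(cultivars):
        ia = idx[ca]
        if len(ia) < 2:
            singletons.append(ca)
            out[a, a] = 0.0
        else:
            sub = dist.matrix[np.ix_(ia, ia)]
            out[a, a] = sub[np.triu_indices(len(ia), k=1)].mean()
        for b in range(a + 1, k):
            ib = idx[cultivars[b]]
            mean = dist.matrix[np.ix_(ia, ib)].mean()
            out[a, b] = out[b, a] = mean
    return CultivarDistanceSummary(cultivars=cultivars, matrix=out, singletons=singletons)


@dataclass
class PCoAResult:
    ids: list[str]
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives reported)
    coordinates: np.ndarray  # n x k over positive eigenvalues
    pct_variation: np.ndarray  # per positive axis, sums to 100
    cumulative_pct: np.ndarray


def pcoa(matrix, ids: list[str] | None = None) -> PCoAResult:
    """Principal coordinates of a squared-distance matrix.

    Gower-centers ``-0.5 * D2``, eigendecomposes, and scales eigenvectors
    by the square root of their (positive) eigenvalues.  When given a
    :class:`CultivarDistanceSummary` only the off-diagonal elements are
    embedded (the diagonal is treated as zero self-distance).
    """
    if isinstance(matrix, CultivarDistanceSummary):
        ids = list(matrix.cultivars)
        D2 = matrix.matrix.copy()
        np.fill_diagonal(D2, 0.0)
    elif isinstance(matrix, DistanceResult):
        ids = list(matrix.sample_ids)
        D2 = matrix.matrix.copy()
    else:
        D2 = np.asarray(matrix, dtype=float).copy()
        if ids is None:
            ids = [str(i) for i in range(D2.shape[0])]
    n = D2.shape[0]
    if n < 3:
        raise ValueError("PCoA needs at least 3 entities")
    if not np.allclose(D2, D2.T):
        raise ValueError("distance matrix must be symmetric")
    if np.isnan(D2).any():
        raise ValueError("distance matrix contains NaN")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    eigval, eigvec = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(abs(eigval[0]), 1.0) * 1e-12
    pos = eigval > tol
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    pct = 100.0 * eigval[pos] / eigval[pos].sum()
    return PCoAResult(
        ids=ids,
        eigenvalues=eigval,
        coordinates=coords,
        pct_variation=pct,
        cumulative_pct=np.cumsum(pct),
    )


@dataclass
class PhiPTResult:
    phi_pt: float
    n_permutations: int
    p_value: float
    ss_among: float
    ss_within: float
    var_among: float
    var_within: float


def _phi_stat(matrix: np.ndarray, labels: np.ndarray) -> tuple[float, float, float, float, float]:
    """AMOVA variance components from a squared-distance matrix."""
    N = matrix.shape[0]
    groups = np.unique(labels)
    G = len(groups)
    iu = np.triu_indices(N, k=1)
    ss_total = matrix[iu].sum() / N
    ss_within = 0.0
    sizes = []
    for g in groups:
        idx = np.flatnonzero(labels == g)
        n_g = len(idx)
        if n_g == 0:
            raise ValueError(f"empty group {g!r}")
        sizes.append(n_g)
        if n_g > 1:
            sub = matrix[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(n_g, k=1)].sum() / n_g
    ss_among = ss_total - ss_within
    df_among, df_within = G - 1, N - G
    sizes = np.asarray(sizes)
    n0 = (N - (sizes**2).sum() / N) / df_among
    ms_within = ss_within / df_within if df_within > 0 else 0.0
    ms_among = ss_among / df_among
    var_within = ms_within
    var_among = (ms_among - ms_within) / n0
    denom = var_among + var_within
    phi = var_among / denom if denom > 0 else 0.0
    return phi, ss_among, ss_within, var_among, var_within


def phipt(
    dist: DistanceResult,
    groups: list[str],
    n_perm: int = 999,
    seed: int | None = None,
) -> PhiPTResult:
    """AMOVA PhiPT with a label-permutation test (add-one p-value rule)."""
    labels = np.asarray(groups, dtype=object)
    if len(labels) != len(dist.sample_ids):
        raise ValueError("one group label required per sample")
    if len(np.unique(labels)) < 2:
        raise ValueError("PhiPT needs at least 2 groups")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    phi, ss_among, ss_within, va, vw = _phi_stat(dist.matrix, labels)
    rng = np.random.default_rng(seed)
    hits = 0
    perm_labels = labels.copy()
    for _ in range(n_perm):
        rng.shuffle(perm_labels)
        phi_p = _phi_stat(dist.matrix, perm_labels)[0]
        if phi_p >= phi:
            hits += 1
    return PhiPTResult(
        phi_pt=phi,
        n_permutations=n_perm,
        p_value=(1 + hits) / (n_perm + 1),
        ss_among=ss_among,
        ss_within=ss_within,
        var_among=va,
        var_within=vw,
    )


def ld_screen(
    table: GenotypeTable, n_perm: int = 999, seed: int | None = None
) -> dict[tuple[str, str], float]:
    """Permutation screen for genotypic association between locus pairs.

    Statistic per unordered locus pair: the sum over allele pairs of the
    squared covariance between allele-dosage vectors, computed over
    individuals typed at both loci; the null is built by permuting one
    locus's genotypes across individuals.  Returns C(L,2) p-values
    (add-one rule).
    """
    if len(table.loci) < 2:
        raise ValueError("LD screen needs at least 2 loci")
    rng = np.random.default_rng(seed)
    n = table.n_samples
    dosage: dict[str, np.ndarray] = {}
    typed: dict[str, np.ndarray] = {}
    for locus in table.loci:
        X = np.zeros((n, locus.n_alleles))
        t = np.zeros(n, dtype=bool)
        for i, s in enumerate(table.samples):
            call = s.call(locus.name)
            if call.is_missing:
                continue
            t[i] = True
            X[i] = score_vector(call, locus)
        dosage[locus.name], typed[locus.name] = X, t

    def stat(X: np.ndarray, Y: np.ndarray) -> float:
        Xc = X - X.mean(axis=0)
        Yc = Y - Y.mean(axis=0)
        C = Xc.T @ Yc / (X.shape[0] - 1)
        return float((C * C).sum())

    pvals: dict[tuple[str, str], float] = {}
    names = table.locus_names
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            la, lb = names[a], names[b]
            both = typed[la] & typed[lb]
            X, Y = dosage[la][both], dosage[lb][both]
            if X.shape[0] < 3:
                pvals[(la, lb)] = 1.0
                continue
            observed = stat(X, Y)
            hits = 0
            for _ in range(n_perm):
                if stat(X, Y[rng.permutation(X.shape[0])]) >= observed:
                    hits += 1
            pvals[(la, lb)] = (1 + hits) / (n_perm + 1)
    return pvals
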