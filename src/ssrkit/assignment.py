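"""Maximum-likelihood assignment of unknown trees to candidate cultivars.

Per locus the likelihood ratio compares "candidate is the single parent
of the query" against "query is an unrelated individual drawn from the
population".  The numerator is the Mendelian single-parent transition
probability with the missing parent drawn from population allele
frequencies; the denominator is the Hardy-Weinberg genotype frequency.
Genotyping error is modeled as a per-locus mistyping that replaces the
observed genotype with a random HWE draw, so the per-locus likelihood is
``(1-e) * T + e * P(g)`` and a Mendelian mismatch contributes ``ln(e)``
rather than minus infinity when ``e > 0``.  The LOD score is the sum of
per-locus log ratios.

Confidence is calibrated by Monte-Carlo simulation of true offspring:
the delta (best minus second-best *cultivar* LOD) distribution yields
critical values at the strict and relaxed confidence levels; profiles of
the same cultivar never penalize each other's delta.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model import (
    FrequencyTable,
    GenotypeCall,
    GenotypeTable,
    SampleRecord,
    SSRKitError,
)
from .keying import consensus_profile

FREQ_FLOOR = 1e-6  # frequency assigned to alleles absent from the reference table


class AssignmentError(SSRKitError):
    pass


@dataclass
class AssignmentConfig:
    error_rate: float = 0.01
    n_sim: int = 10000
    strict_conf: float = 0.95
    relaxed_conf: float = 0.80
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.error_rate < 1.0):
            raise ValueError("error_rate must lie in [0, 1)")
        if self.n_sim < 100:
            raise ValueError("n_sim must be >= 100")
        if not (0.5 < self.relaxed_conf < self.strict_conf < 1.0):
            raise ValueError("need 0.5 < relaxed_conf < strict_conf < 1")


@dataclass
class CandidateProfile:
    cultivar: str
    profile_id: str
    calls: dict[str, GenotypeCall]


@dataclass
class CriticalDeltas:
    strict_delta: float
    relaxed_delta: float
    strict_rate: float  # fraction of simulated trials at or above the critical delta
    relaxed_rate: float
    n_sim: int


@dataclass
class AssignmentResult:
    query_id: str
    best_cultivar: str | None
    best_profile_id: str | None
    lod: float
    delta: float
    confidence: str  # "strict" | "relaxed" | "none"
    per_candidate_lods: dict[str, float] = field(default_factory=dict)
    reason: str | None = None


def transition_prob(
    parent: GenotypeCall, offspring: GenotypeCall, freqs: dict[int, float]
) -> float:
    """Single-parent Mendelian transition probability T(g_o | g_p).

    Sums over the gametes the parent can transmit (probability 1/2 each,
    1 if homozygous), multiplying by the population frequency of the
    complementary allele of the unordered offspring genotype; 0 if the
    parent shares no allele with the offspring.
    """
    if parent.is_missing or offspring.is_missing:
        raise AssignmentError("transition_prob requires non-missing calls")
    pa, pb = parent.alleles()
    oa, ob = offspring.alleles()

    def transmit(x: int) -> float:
        return ((pa == x) + (pb == x)) / 2.0

    def freq(x: int) -> float:
        return max(freqs.get(x, 0.0), FREQ_FLOOR)

    if oa == ob:
        return transmit(oa) * freq(oa)
    return transmit(oa) * freq(ob) + transmit(ob) * freq(oa)


def genotype_freq(call: GenotypeCall, freqs: dict[int, float]) -> float:
    """HWE genotype frequency: 2*p_a*p_b heterozygote, p_a^2 homozygote."""
    a, b = call.alleles()
    pa = max(freqs.get(a, 0.0), FREQ_FLOOR)
    pb = max(freqs.get(b, 0.0), FREQ_FLOOR)
    return 2.0 * pa * pb if a != b else pa * pa


def lod_score(
    query: SampleRecord,
    candidate: CandidateProfile,
    freqs: FrequencyTable,
    error_rate: float = 0.01,
) -> float:
    """Sum over shared typed loci of ln[((1-e)T + e P(g)) / P(g)].

    With ``e = 0`` a Mendelian mismatch yields ``-inf`` (flagged by the
    caller); with ``e > 0`` it contributes the finite ``ln(e)``.
    """
    total = 0.0
    shared = 0
    for locus, lf in freqs.per_locus.items():
        q = query.call(locus)
        c = candidate.calls.get(locus)
        if q.is_missing or c is None or c.is_missing:
            continue
        shared += 1
        T = transition_prob(c, q, lf.freqs)
        P = genotype_freq(q, lf.freqs)
        numerator = (1.0 - error_rate) * T + error_rate * P
        total += math.log(numerator / P) if numerator > 0 else -math.inf
    if shared == 0:
        raise AssignmentError(
            f"query {query.sample_id} and candidate {candidate.profile_id} "
            "share no typed locus"
        )
    return total


def candidate_profiles(table: GenotypeTable, loci: list[str] | None = None) -> list[CandidateProfile]:
    """Distinct complete multilocus profiles within each cultivar.

    Mirrors running assignment against every observed within-cultivar
    profile rather than one consensus per cultivar; profiles missing a
    call at any assignment locus are dropped.
    """
    loci = loci or table.locus_names
    out: list[CandidateProfile] = []
    for cultivar in table.cultivars():
        members = [s for s in table.samples if s.cultivar == cultivar]
        seen: dict[tuple, str] = {}
        k = 0
        for s in members:
            calls = {l: s.call(l) for l in loci}
            if any(c.is_missing for c in calls.values()):
                continue
            sig = tuple(calls[l].alleles() for l in loci)
            if sig in seen:
                continue
            k += 1
            pid = f"{cultivar}/p{k}"
            seen[sig] = pid
            out.append(CandidateProfile(cultivar=cultivar, profile_id=pid, calls=calls))
        if not seen and members:
            # fall back to the consensus profile when every member has gaps
            cons = consensus_profile(table.subset([m.sample_id for m in members]), cultivar)
            if all(l in cons for l in loci):
                out.append(
                    CandidateProfile(cultivar=cultivar, profile_id=f"{cultivar}/p1",
                                     calls={l: cons[l] for l in loci})
                )
    return out


# -- vectorized likelihood engine ------------------------------------------


class _LocusEngine:
    """Per-locus lookup tables over unordered genotypes for fast LOD sums."""

    def __init__(self, alleles: list[int], p: np.ndarray, candidates: list[GenotypeCall], e: float):
        self.alleles = alleles
        self.index = {a: i for i, a in enumerate(alleles)}
        A = len(alleles)
        self.p = p
        pairs = [(i, j) for i in range(A) for j in range(i, A)]
        self.geno_id = np.full((A, A), -1, dtype=int)
        for g, (i, j) in enumerate(pairs):
            self.geno_id[i, j] = self.geno_id[j, i] = g
        gi = np.array([i for i, _ in pairs])
        gj = np.array([j for _, j in pairs])
        P = np.where(gi == gj, p[gi] * p[gj], 2.0 * p[gi] * p[gj])
        self.P = np.maximum(P, FREQ_FLOOR**2)
        # transition matrix candidates x genotypes
        T = np.zeros((len(candidates), len(pairs)))
        self.cand_idx = []
        for c, call in enumerate(candidates):
            u, v = (self.index[a] for a in call.alleles())
            self.cand_idx.append((u, v))
            tr = np.zeros(A)
            tr[u] += 0.5
            tr[v] += 0.5
            T[c] = np.where(
                gi == gj, tr[gi] * p[gi], tr[gi] * p[gj] + tr[gj] * p[gi]
            )
        with np.errstate(divide="ignore"):
            self.contrib = np.log(((1.0 - e) * T + e * self.P[None, :]) / self.P[None, :])

    def genotype_index(self, call: GenotypeCall) -> int:
        a, b = call.alleles()
        return int(self.geno_id[self.index[a], self.index[b]])


class AssignmentEngine:
    """Precomputed per-locus tables shared by simulation and assignment."""

    def __init__(self, candidates: list[CandidateProfile], freqs: FrequencyTable,
                 config: AssignmentConfig):
        if len(candidates) < 2:
            raise AssignmentError("need at least 2 candidate profiles")
        self.candidates = candidates
        self.config = config
        self.cultivars = []
        for c in candidates:
            if c.cultivar not in self.cultivars:
                self.cultivars.append(c.cultivar)
        self.cult_of = np.array([self.cultivars.index(c.cultivar) for c in candidates])
        self.loci = [l for l in freqs.per_locus if all(l in c.calls for c in candidates)]
        if not self.loci:
            raise AssignmentError("no locus is typed in every candidate profile")
        self.engines: dict[str, _LocusEngine] = {}
        for locus in self.loci:
            lf = freqs.per_locus[locus]
            alleles = sorted(
                set(lf.freqs) | {a for c in candidates for a in c.calls[locus].alleles()}
            )
            p = np.array([max(lf.freqs.get(a, 0.0), FREQ_FLOOR) for a in alleles])
            self.engines[locus] = _LocusEngine(
                alleles, p, [c.calls[locus] for c in candidates], config.error_rate
            )

    def lod_matrix(self, geno_ids: dict[str, np.ndarray]) -> np.ndarray:
        """(n_queries, n_candidates) LOD matrix from per-locus genotype ids.

        A genotype id of -1 marks a missing call at that locus (skipped).
        """
        n_q = len(next(iter(geno_ids.values())))
        lods = np.zeros((n_q, len(self.candidates)))
        for locus in self.loci:
            g = geno_ids[locus]
            ok = g >= 0
            lods[ok] += self.engines[locus].contrib.T[g[ok]]
        return lods

    def cultivar_deltas(self, lods: np.ndarray):
        """Collapse profile LODs to cultivar level; return best, lod, delta."""
        n_q = lods.shape[0]
        k = len(self.cultivars)
        cult_lod = np.full((n_q, k), -np.inf)
        for c in range(k):
            cols = np.flatnonzero(self.cult_of == c)
            cult_lod[:, c] = lods[:, cols].max(axis=1)
        order = np.argsort(cult_lod, axis=1)
        best = order[:, -1]
        second = order[:, -2]
        best_lod = cult_lod[np.arange(n_q), best]
        delta = best_lod - cult_lod[np.arange(n_q), second]
        delta = np.where(np.isfinite(delta), delta, np.inf)
        return best, best_lod, delta

    def genotype_ids_for(self, queries: list[SampleRecord]) -> dict[str, np.ndarray]:
        ids: dict[str, np.ndarray] = {}
        for locus in self.loci:
            eng = self.engines[locus]
            g = np.full(len(queries), -1, dtype=int)
            for i, q in enumerate(queries):
                call = q.call(locus)
                if call.is_missing:
                    continue
                a, b = call.alleles()
                if a not in eng.index or b not in eng.index:
                    continue  # allele unseen in reference pool: skip this locus
                g[i] = eng.genotype_index(call)
            ids[locus] = g
        return ids


def simulate_critical_deltas(
    candidates: list[CandidateProfile],
    freqs: FrequencyTable,
    config: AssignmentConfig,
) -> CriticalDeltas:
    """Monte-Carlo calibration of the delta confidence criterion.

    Each trial generates a true offspring of a uniformly drawn candidate
    (one gamete from the candidate, one from the population frequencies),
    applies per-locus mistyping at the configured error rate, assigns it,
    and records delta plus a success flag.  The critical delta at
    confidence ``c`` is the smallest value such that the success
    proportion among trials with delta at or above it reaches ``c``
    (+inf if unreachable).
    """
    engine = AssignmentEngine(candidates, freqs, config)
    rng = np.random.default_rng(config.seed)
    n = config.n_sim
    true_idx = rng.integers(len(candidates), size=n)
    geno_ids: dict[str, np.ndarray] = {}
    for locus in engine.loci:
        eng = engine.engines[locus]
        A = len(eng.alleles)
        u = np.array([eng.cand_idx[t][0] for t in true_idx])
        v = np.array([eng.cand_idx[t][1] for t in true_idx])
        maternal = np.where(rng.random(n) < 0.5, u, v)
        p = eng.p / eng.p.sum()
        paternal = rng.choice(A, size=n, p=p)
        mistyped = rng.random(n) < config.error_rate
        ra = rng.choice(A, size=n, p=p)
        rb = rng.choice(A, size=n, p=p)
        i = np.where(mistyped, ra, maternal)
        j = np.where(mistyped, rb, paternal)
        geno_ids[locus] = eng.geno_id[np.minimum(i, j), np.maximum(i, j)]
    lods = engine.lod_matrix(geno_ids)
    best, _, delta = engine.cultivar_deltas(lods)
    success = best == engine.cult_of[true_idx]

    def critical(conf: float) -> tuple[float, float]:
        order = np.argsort(delta)[::-1]
        sorted_d = delta[order]
        cum = np.cumsum(success[order]) / np.arange(1, n + 1)
        # a threshold set {delta >= d} must contain whole tie groups, so only
        # prefixes ending at a distinct-value boundary are admissible cuts
        boundary = np.append(sorted_d[:-1] > sorted_d[1:], True)
        qualifying = np.flatnonzero(boundary & (cum >= conf))
        if len(qualifying) == 0:
            return math.inf, 0.0
        k = qualifying[-1] + 1
        d = 0.0 if k == n else float(sorted_d[k - 1])
        return d, float(k) / n

    strict_d, strict_rate = critical(config.strict_conf)
    relaxed_d, relaxed_rate = critical(config.relaxed_conf)
    relaxed_d = min(relaxed_d, strict_d)
    return CriticalDeltas(
        strict_delta=strict_d,
        relaxed_delta=relaxed_d,
        strict_rate=strict_rate,
        relaxed_rate=max(relaxed_rate, strict_rate),
        n_sim=n,
    )


def assign(
    queries: list[SampleRecord],
    candidates: list[CandidateProfile],
    freqs: FrequencyTable,
    config: AssignmentConfig,
    critical: CriticalDeltas | None = None,
) -> list[AssignmentResult]:
    """Assign each query to its best cultivar with a delta confidence tier.

    Results are sorted by (locality, query id).  Queries typed at zero
    assignment loci come back unassigned with a reason.
    """
    engine = AssignmentEngine(candidates, freqs, config)
    if critical is None:
        critical = simulate_critical_deltas(candidates, freqs, config)
    results: list[AssignmentResult] = []
    typed_queries = []
    for q in queries:
        if all(q.call(l).is_missing for l in engine.loci):
            results.append(
                AssignmentResult(
                    query_id=q.sample_id, best_cultivar=None, best_profile_id=None,
                    lod=math.nan, delta=math.nan, confidence="none",
                    reason="query typed at zero assignment loci",
                )
            )
        else:
            typed_queries.append(q)
    if typed_queries:
        geno_ids = engine.genotype_ids_for(typed_queries)
        lods = engine.lod_matrix(geno_ids)
        best_cult, best_lod, delta = engine.cultivar_deltas(lods)
        for i, q in enumerate(typed_queries):
            cult = engine.cultivars[best_cult[i]]
            cols = np.flatnonzero(engine.cult_of == best_cult[i])
            best_col = cols[np.argmax(lods[i, cols])]
            d = float(delta[i])
            if d >= critical.strict_delta:
                conf = "strict"
            elif d >= critical.relaxed_delta:
                conf = "relaxed"
            else:
                conf = "none"
            results.append(
                AssignmentResult(
                    query_id=q.sample_id,
                    best_cultivar=cult,
                    best_profile_id=candidates[best_col].profile_id,
                    lod=float(best_lod[i]),
                    delta=d,
                    confidence=conf,
                    per_candidate_lods={
                        c.profile_id: float(lods[i, j]) for j, c in enumerate(candidates)
                    },
                )
            )
    by_id = {q.sample_id: q for q in queries}
    results.sort(key=lambda r: (by_id[r.query_id].locality, r.query_id))
    return results
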