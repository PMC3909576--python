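"""Synthetic genotype tables emulating clonally propagated cultivars.

Each cultivar descends from a single founder genotype drawn from an
oasis-wide background allele pool; clones copy the founder exactly,
variant clones move one allele a single step along the locus's sorted
allele ladder (the SSR stepwise-mutation picture), mislabeled clones
copy a different cultivar's founder, and seed-propagated cultivars draw
members as independent Hardy-Weinberg genotypes from a pool mixing the
founder's alleles with the background.  Male trees are seed offspring of
a uniformly chosen cultivar founder, with the non-maternal gamete drawn
from the background (mixed pollen pool) and optional per-locus typing
error.  Every generated sample carries a ground-truth record, and all
generation is a pure function of the configuration's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import (
    UNKNOWN,
    FrequencyTable,
    GenotypeCall,
    GenotypeTable,
    LocusFrequencies,
    SampleRecord,
)

LOCALITIES = ("loc_A", "loc_B", "loc_C")

PROPAGATION_KINDS = ("clone", "variant_clone", "mislabeled", "seed")


@dataclass
class SimPopConfig:
    n_loci: int = 16
    alleles_per_locus: tuple[int, int] = (4, 11)
    freq_concentration: float = 1.0
    n_cultivars: int = 18
    clones_per_cultivar: int | tuple[int, int] = 20
    founder_het_prob: float = 1.0
    seed_propagated: frozenset[int] = field(default_factory=frozenset)
    variant_clone_rate: float = 0.0
    mislabel_rate: float = 0.0
    seed_background_weight: float = 0.5  # background share of the seed-propagation pool
    n_males: int = 0
    typing_error_rate: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.alleles_per_locus
        if not (2 <= lo <= hi <= 40):
            raise ValueError("alleles_per_locus must lie within [2, 40]")
        if self.n_loci < 1 or self.n_cultivars < 1:
            raise ValueError("counts must be >= 1")
        for p in (
            self.founder_het_prob,
            self.variant_clone_rate,
            self.mislabel_rate,
            self.typing_error_rate,
            self.seed_background_weight,
        ):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.freq_concentration <= 0:
            raise ValueError("freq_concentration must be positive")
        self.seed_propagated = frozenset(self.seed_propagated)
        if any(i < 0 or i >= self.n_cultivars for i in self.seed_propagated):
            raise ValueError("seed_propagated indices out of range")

    def clones_range(self) -> tuple[int, int]:
        if isinstance(self.clones_per_cultivar, int):
            if self.clones_per_cultivar < 1:
                raise ValueError("clones_per_cultivar must be >= 1")
            return (self.clones_per_cultivar, self.clones_per_cultivar)
        lo, hi = self.clones_per_cultivar
        if lo < 1 or hi < lo:
            raise ValueError("invalid clones_per_cultivar range")
        return (lo, hi)


@dataclass
class TruthRecord:
    sample_id: str
    true_cultivar: str
    propagation: str  # one of PROPAGATION_KINDS
    male_source_cultivar: str | None = None

    def __post_init__(self) -> None:
        if self.propagation not in PROPAGATION_KINDS:
            raise ValueError(f"unknown propagation kind {self.propagation!r}")


def _rng(config: SimPopConfig, stream: int) -> np.random.Generator:
    # distinct deterministic stream per stage so each stage is independently reproducible
    return np.random.default_rng([config.rng_seed, stream])


def cultivar_name(i: int) -> str:
    return f"CV{i + 1:02d}"


def simulate_background(config: SimPopConfig) -> FrequencyTable:
    """Oasis-wide allele pool: per-locus sizes on a 2-bp ladder, Dirichlet freqs."""
    rng = _rng(config, 0)
    lo, hi = config.alleles_per_locus
    per_locus: dict[str, LocusFrequencies] = {}
    for i in range(config.n_loci):
        k = int(rng.integers(lo, hi + 1))
        base = 100 + 40 * i
        sizes = [base + 2 * j for j in range(k)]
        freqs = rng.dirichlet(np.full(k, config.freq_concentration))
        per_locus[f"L{i + 1:02d}"] = LocusFrequencies(
            freqs={s: float(p) for s, p in zip(sizes, freqs)}, n=1
        )
    return FrequencyTable(group="ALL", per_locus=per_locus)


def _draw_allele(rng: np.random.Generator, freqs: dict[int, float]) -> int:
    alleles = list(freqs)
    p = np.array([freqs[a] for a in alleles])
    return int(alleles[rng.choice(len(alleles), p=p / p.sum())])


def _draw_genotype(rng, freqs: dict[int, float]) -> GenotypeCall:
    return GenotypeCall(_draw_allele(rng, freqs), _draw_allele(rng, freqs))


def _draw_founder_call(rng, freqs: dict[int, float], force_het: bool) -> GenotypeCall:
    call = _draw_genotype(rng, freqs)
    if force_het and len(freqs) >= 2:
        tries = 0
        while not call.is_heterozygous:
            call = _draw_genotype(rng, freqs)
            tries += 1
            if tries > 1000:  # pathological frequency vector; pick two distinct alleles
                a, b = sorted(freqs, key=freqs.get, reverse=True)[:2]
                return GenotypeCall(a, b)
    return call


def _draw_founders(
    rng, config: SimPopConfig, background: FrequencyTable
) -> list[dict[str, GenotypeCall]]:
    for _ in range(100):
        founders = []
        for _c in range(config.n_cultivars):
            calls = {}
            for locus, lf in background.per_locus.items():
                force = rng.random() < config.founder_het_prob
                calls[locus] = _draw_founder_call(rng, lf.freqs, force)
            founders.append(calls)
        profiles = [tuple(sorted((l, c.allele_a, c.allele_b) for l, c in f.items())) for f in founders]
        if len(set(profiles)) == len(profiles):
            return founders
    raise RuntimeError(
        "could not draw distinct founders for all cultivars after 100 attempts; "
        "increase loci or alleles per locus"
    )


def _mutate_one_step(rng, calls: dict[str, GenotypeCall], background: FrequencyTable) -> dict[str, GenotypeCall]:
    """Move one random allele of one random locus one step on its ladder."""
    out = dict(calls)
    loci = list(calls)
    locus = loci[int(rng.integers(len(loci)))]
    ladder = sorted(background.per_locus[locus].freqs)
    a, b = calls[locus].alleles()
    which = int(rng.integers(2))
    allele = (a, b)[which]
    pos = ladder.index(allele)
    if pos == 0:
        new = ladder[1] if len(ladder) > 1 else allele
    elif pos == len(ladder) - 1:
        new = ladder[pos - 1]
    else:
        new = ladder[pos + (1 if rng.random() < 0.5 else -1)]
    pair = (new, b) if which == 0 else (a, new)
    out[locus] = GenotypeCall(*pair)
    return out


def _seed_pool(founder_call: GenotypeCall, lf: LocusFrequencies, w_bg: float) -> dict[int, float]:
    """Founder-allele-enriched pool: (1-w_bg) founder alleles + w_bg background."""
    pool = {a: w_bg * p for a, p in lf.freqs.items()}
    for allele in founder_call.alleles():
        pool[allele] = pool.get(allele, 0.0) + (1.0 - w_bg) / 2.0
    total = sum(pool.values())
    return {a: p / total for a, p in pool.items()}


def simulate_cultivars(
    config: SimPopConfig, background: FrequencyTable
) -> tuple[GenotypeTable, list[TruthRecord]]:
    """Founders plus clones / variant clones / mislabels / seed offspring.

    The first emitted member of every cultivar is its founder genotype
    (always a pure clone), a property :func:`simulate_males` relies on.
    """
    rng = _rng(config, 1)
    founders = _draw_founders(rng, config, background)
    lo, hi = config.clones_range()
    samples: list[SampleRecord] = []
    truth: list[TruthRecord] = []
    for c in range(config.n_cultivars):
        name = cultivar_name(c)
        n_members = int(rng.integers(lo, hi + 1))
        is_seed = c in config.seed_propagated
        pools = None
        if is_seed:
            pools = {
                locus: _seed_pool(founders[c][locus], lf, config.seed_background_weight)
                for locus, lf in background.per_locus.items()
            }
        for j in range(n_members):
            sid = f"{name}_{j + 1:03d}"
            locality = LOCALITIES[int(rng.integers(len(LOCALITIES)))]
            if is_seed:
                calls = {locus: _draw_genotype(rng, pool) for locus, pool in pools.items()}
                kind, true_cv = "seed", name
            elif j > 0 and rng.random() < config.mislabel_rate and config.n_cultivars > 1:
                other = int(rng.integers(config.n_cultivars - 1))
                if other >= c:
                    other += 1
                calls = dict(founders[other])
                kind, true_cv = "mislabeled", cultivar_name(other)
            elif j > 0 and rng.random() < config.variant_clone_rate:
                calls = _mutate_one_step(rng, founders[c], background)
                kind, true_cv = "variant_clone", name
            else:
                calls = dict(founders[c])
                kind, true_cv = "clone", name
            samples.append(
                SampleRecord(sample_id=sid, cultivar=name, locality=locality,
                             sex="female", calls=calls)
            )
            truth.append(TruthRecord(sample_id=sid, true_cultivar=true_cv, propagation=kind))
    return GenotypeTable.from_samples(samples, list(background.per_locus)), truth


def simulate_males(
    config: SimPopConfig, cultivars: GenotypeTable, background: FrequencyTable
) -> tuple[list[SampleRecord], list[TruthRecord]]:
    """Males as seed offspring of a uniformly chosen cultivar founder."""
    rng = _rng(config, 2)
    founders: dict[str, SampleRecord] = {}
    for s in cultivars.samples:  # first member per cultivar is the founder
        founders.setdefault(s.cultivar, s)
    names = list(founders)
    samples: list[SampleRecord] = []
    truth: list[TruthRecord] = []
    for m in range(config.n_males):
        source = names[int(rng.integers(len(names)))]
        calls: dict[str, GenotypeCall] = {}
        for locus, lf in background.per_locus.items():
            founder_call = founders[source].call(locus)
            maternal = founder_call.alleles()[int(rng.integers(2))]
            paternal = _draw_allele(rng, lf.freqs)
            call = GenotypeCall(maternal, paternal)
            if rng.random() < config.typing_error_rate:
                call = _draw_genotype(rng, lf.freqs)
            calls[locus] = call
        sid = f"M{m + 1:03d}"
        samples.append(
            SampleRecord(sample_id=sid, cultivar=UNKNOWN,
                         locality=LOCALITIES[int(rng.integers(len(LOCALITIES)))],
                         sex="male", calls=calls)
        )
        truth.append(
            TruthRecord(sample_id=sid, true_cultivar=UNKNOWN, propagation="seed",
                        male_source_cultivar=source)
        )
    return samples, truth


def simulate_dataset(
    config: SimPopConfig,
) -> tuple[GenotypeTable, list[TruthRecord], FrequencyTable]:
    """Background -> cultivars -> males, combined into one table."""
    background = simulate_background(config)
    table, truth = simulate_cultivars(config, background)
    males, male_truth = simulate_males(config, table, background)
    combined = GenotypeTable.from_samples(
        table.samples + males, list(background.per_locus)
    )
    return combined, truth + male_truth, background
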