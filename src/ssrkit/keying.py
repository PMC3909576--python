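"""Minimal multilocus identification keys for cultivars.

A key is built on cultivar *consensus* profiles (the modal genotype per
locus, ties broken toward the lexicographically smaller allele pair)
rather than on individuals, since cultivars may contain variant clones.
Alleles at the key's loci are relabeled ``a1..``, ``b1..``, ... by
ascending fragment size, and the key certifies whether all cultivar
profiles are pairwise distinct.

Search for the key is exhaustive over locus subsets up to size 4
(C(16,4) = 1820 subsets); past that a greedy forward selection extends
the best exhaustive prefix.
"""

from __future__ import annotations

import itertools
import string
from collections import Counter
from dataclasses import dataclass, field

from .model import GenotypeCall, GenotypeTable, SSRKitError

EXHAUSTIVE_LIMIT = 4


class KeyError_(SSRKitError):
    pass


def consensus_profile(table: GenotypeTable, cultivar: str) -> dict[str, GenotypeCall]:
    """Modal genotype per locus for one cultivar.

    Ties break toward the smaller allele pair (lexicographically on the
    canonical ordered pair).  Loci with no non-missing call are omitted.
    """
    members = [s for s in table.samples if s.cultivar == cultivar]
    if not members:
        raise KeyError_(f"cultivar {cultivar!r} has no samples")
    profile: dict[str, GenotypeCall] = {}
    for locus in table.loci:
        counts: Counter[tuple[int, int]] = Counter()
        for s in members:
            call = s.call(locus.name)
            if not call.is_missing:
                counts[call.alleles()] += 1
        if not counts:
            continue
        best = min(counts, key=lambda g: (-counts[g], g))
        profile[locus.name] = GenotypeCall(*best)
    return profile


def variant_fraction(table: GenotypeTable, cultivar: str) -> float:
    """Fraction of member calls deviating from the consensus profile."""
    members = [s for s in table.samples if s.cultivar == cultivar]
    profile = consensus_profile(table, cultivar)
    total = deviant = 0
    for s in members:
        for locus, cons in profile.items():
            call = s.call(locus)
            if call.is_missing:
                continue
            total += 1
            if call != cons:
                deviant += 1
    return deviant / total if total else 0.0


@dataclass
class AlleleLabeling:
    locus: str
    prefix: str
    label_map: dict[int, str]  # allele size -> e.g. "a3"

    def label(self, allele: int) -> str:
        return self.label_map[allele]


@dataclass
class IdentificationKey:
    loci: list[str]
    labelings: list[AlleleLabeling]
    profiles: dict[str, dict[str, tuple[str, str]]]  # cultivar -> locus -> label pair
    unique: bool
    total_alleles: int
    collisions: list[tuple[str, str]] = field(default_factory=list)
    variant_warnings: dict[str, float] = field(default_factory=dict)


def label_alleles(
    table: GenotypeTable, loci_subset: list[str]
) -> list[AlleleLabeling]:
    """Label alleles observed among cultivar consensus profiles.

    Prefixes a, b, c, ... follow the subset order; indices ascend by
    fragment size within each locus.
    """
    if not loci_subset:
        raise KeyError_("locus subset must be non-empty")
    if len(loci_subset) > 26:
        raise KeyError_("at most 26 loci can be letter-prefixed")
    consensus = {cv: consensus_profile(table, cv) for cv in table.cultivars()}
    labelings = []
    for k, locus in enumerate(loci_subset):
        observed: set[int] = set()
        for profile in consensus.values():
            if locus in profile:
                observed.update(profile[locus].alleles())
        prefix = string.ascii_lowercase[k]
        labelings.append(
            AlleleLabeling(
                locus=locus,
                prefix=prefix,
                label_map={a: f"{prefix}{i + 1}" for i, a in enumerate(sorted(observed))},
            )
        )
    return labelings


def _profiles_for(
    consensus: dict[str, dict[str, GenotypeCall]], subset: tuple[str, ...]
) -> dict[str, tuple]:
    return {
        cv: tuple(
            profile[locus].alleles() if locus in profile else None for locus in subset
        )
        for cv, profile in consensus.items()
    }


def _distinct_count(consensus, subset) -> int:
    return len(set(_profiles_for(consensus, subset).values()))


def _subset_total_alleles(consensus, subset) -> int:
    total = 0
    for locus in subset:
        observed = set()
        for profile in consensus.values():
            if locus in profile:
                observed.update(profile[locus].alleles())
        total += len(observed)
    return total


def find_key(
    table: GenotypeTable,
    max_size: int = 4,
    force_loci: list[str] | None = None,
) -> IdentificationKey:
    """Smallest locus subset whose consensus profiles separate all cultivars.

    Ties break toward fewer total labeled alleles, then lexicographic
    locus names.  If no subset within ``max_size`` discriminates, the
    best-separating subset is returned with ``unique=False`` and the
    colliding cultivar pairs listed.  ``force_loci`` skips the search and
    evaluates the given subset.
    """
    if max_size < 1:
        raise KeyError_("max_size must be >= 1")
    cultivars = table.cultivars()
    if len(cultivars) < 2:
        raise KeyError_("need at least 2 cultivars to build a key")
    consensus = {cv: consensus_profile(table, cv) for cv in cultivars}
    names = sorted(table.locus_names)

    chosen: tuple[str, ...] | None = None
    if force_loci is not None:
        chosen = tuple(force_loci)
    else:
        n_target = len(cultivars)
        best_partial: tuple[str, ...] | None = None
        best_partial_score = -1
        for size in range(1, min(max_size, EXHAUSTIVE_LIMIT, len(names)) + 1):
            candidates = []
            for subset in itertools.combinations(names, size):
                distinct = _distinct_count(consensus, subset)
                if distinct == n_target:
                    candidates.append(subset)
                elif distinct > best_partial_score:
                    best_partial_score, best_partial = distinct, subset
            if candidates:
                chosen = min(
                    candidates,
                    key=lambda s: (_subset_total_alleles(consensus, s), s),
                )
                break
        if chosen is None and max_size > EXHAUSTIVE_LIMIT and best_partial is not None:
            # greedy forward extension of the best exhaustive subset
            current = list(best_partial)
            while len(current) < min(max_size, len(names)):
                remaining = [n for n in names if n not in current]
                nxt = max(
                    remaining,
                    key=lambda n: (_distinct_count(consensus, tuple(current + [n])), n),
                )
                current.append(nxt)
                if _distinct_count(consensus, tuple(current)) == n_target:
                    chosen = tuple(current)
                    break
            if chosen is None:
                chosen = tuple(current)
        elif chosen is None:
            chosen = best_partial if best_partial is not None else tuple(names[:1])

    labelings = label_alleles(table, list(chosen))
    by_locus = {lab.locus: lab for lab in labelings}
    profiles: dict[str, dict[str, tuple[str, str]]] = {}
    raw = _profiles_for(consensus, chosen)
    for cv in cultivars:
        profiles[cv] = {}
        for locus in chosen:
            geno = consensus[cv].get(locus)
            if geno is None:
                continue
            a, b = geno.alleles()
            profiles[cv][locus] = (by_locus[locus].label(a), by_locus[locus].label(b))
    collisions = [
        (x, y)
        for x, y in itertools.combinations(cultivars, 2)
        if raw[x] == raw[y]
    ]
    used_labels = {
        lab
        for profile in profiles.values()
        for pair in profile.values()
        for lab in pair
    }
    warnings = {
        cv: vf
        for cv in cultivars
        if (vf := variant_fraction(table, cv)) > 0.2
    }
    return IdentificationKey(
        loci=list(chosen),
        labelings=labelings,
        profiles=profiles,
        unique=not collisions,
        total_alleles=len(used_labels),
        collisions=collisions,
        variant_warnings=warnings,
    )


def render_key(key: IdentificationKey) -> str:
    """One row per cultivar: cultivar, then per-locus label pairs (a3/a7)."""
    lines = ["\t".join(["cultivar"] + key.loci)]
    for cv in sorted(key.profiles):
        cells = [cv]
        for locus in key.loci:
            pair = key.profiles[cv].get(locus)
            cells.append("/".join(pair) if pair else "-")
        lines.append("\t".join(cells))
    return "\n".join(lines) + "\n"
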