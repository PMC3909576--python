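"""Per-locus and per-group diversity indices for codominant SSR data.

Indices: observed heterozygosity (fraction of typed samples heterozygous),
expected heterozygosity under Hardy-Weinberg equilibrium ``1 - sum(p_i^2)``,
its small-sample unbiased correction ``2n/(2n-1)``, the fixation index
``(Hexp - Hobs)/Hexp`` (negative = heterozygote excess), and the effective
allele count ``1/sum(p_i^2)``.

Group summaries average over loci, *including* monomorphic loci (which
contribute 0 to the heterozygosities and 1 to the allele counts).  The
summary fixation index is the ratio of the locus means,
``(mean Hexp - mean Hobs) / mean Hexp``; the arithmetic mean of per-locus
F over polymorphic loci is reported alongside as ``mean_F_polymorphic``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model import FrequencyTable, GenotypeTable, allele_frequencies


def hexp(freqs: dict[int, float]) -> float:
    """Expected heterozygosity ``1 - sum(p_i^2)``."""
    if not freqs:
        raise ValueError("empty frequency map")
    return 1.0 - sum(p * p for p in freqs.values())


def uhexp(hexp_value: float, n: int) -> float:
    """Unbiased expected heterozygosity ``2n/(2n-1) * Hexp``."""
    if n < 1:
        raise ValueError(f"diploid sample count must be >= 1, got {n}")
    return (2 * n) / (2 * n - 1) * hexp_value


def fixation_index(hobs: float, hexp_value: float) -> float | None:
    """``(Hexp - Hobs)/Hexp``; None (undefined) when Hexp is 0."""
    if hexp_value == 0:
        return None
    return (hexp_value - hobs) / hexp_value


def effective_alleles(freqs: dict[int, float]) -> float:
    """Number of effective alleles ``1/sum(p_i^2)``."""
    if not freqs:
        raise ValueError("empty frequency map")
    return 1.0 / sum(p * p for p in freqs.values())


@dataclass
class LocusStats:
    locus: str
    group: str
    n: int
    Na: int
    Ne: float
    Hobs: float
    Hexp: float
    UHexp: float
    F: float | None
    n_genotypes: int = 0  # distinct unordered genotypes observed


@dataclass
class GroupSummary:
    group: str
    N: float
    mean_Na: float
    mean_Ne: float
    mean_Hobs: float
    mean_Hexp: float
    mean_UHexp: float
    F_summary: float | None
    mean_F_polymorphic: float | None
    P_pct: float
    fixed_alleles: list[tuple[str, int]] = field(default_factory=list)


def locus_table(table: GenotypeTable, group_by: str = "all") -> list[LocusStats]:
    """All indices per locus per group; Hobs over non-missing calls only."""
    members = table.group_members(group_by)
    out: list[LocusStats] = []
    for ftab in allele_frequencies(table, group_by):
        group = ftab.group
        for locus_name, lf in ftab.per_locus.items():
            he = hexp(lf.freqs)
            het = 0
            genotypes: set[tuple[int, int]] = set()
            for sample in members[group]:
                call = sample.call(locus_name)
                if call.is_missing:
                    continue
                if call.is_heterozygous:
                    het += 1
                genotypes.add(call.alleles())
            ho = het / lf.n
            out.append(
                LocusStats(
                    locus=locus_name,
                    group=group,
                    n=lf.n,
                    Na=len(lf.freqs),
                    Ne=effective_alleles(lf.freqs),
                    Hobs=ho,
                    Hexp=he,
                    UHexp=uhexp(he, lf.n),
                    F=fixation_index(ho, he),
                    n_genotypes=len(genotypes),
                )
            )
    return out


def group_summary(
    stats: list[LocusStats], table: GenotypeTable, group_by: str = "cultivar"
) -> list[GroupSummary]:
    """Arithmetic means over loci per group, Table-style."""
    members = table.group_members(group_by)
    by_group: dict[str, list[LocusStats]] = {}
    for st in stats:
        by_group.setdefault(st.group, []).append(st)
    out: list[GroupSummary] = []
    for group, rows in by_group.items():
        L = len(rows)
        mean_hobs = sum(r.Hobs for r in rows) / L
        mean_hexp = sum(r.Hexp for r in rows) / L
        poly = [r for r in rows if r.Na >= 2]
        per_locus_f = [r.F for r in poly if r.F is not None]
        out.append(
            GroupSummary(
                group=group,
                N=sum(r.n for r in rows) / L,
                mean_Na=sum(r.Na for r in rows) / L,
                mean_Ne=sum(r.Ne for r in rows) / L,
                mean_Hobs=mean_hobs,
                mean_Hexp=mean_hexp,
                mean_UHexp=sum(r.UHexp for r in rows) / L,
                F_summary=fixation_index(mean_hobs, mean_hexp),
                mean_F_polymorphic=(sum(per_locus_f) / len(per_locus_f))
                if per_locus_f
                else None,
                P_pct=100.0 * len(poly) / L,
                fixed_alleles=[
                    (r.locus, _group_alleles(members[group], r.locus)[0])
                    for r in rows
                    if r.Na == 1
                ],
            )
        )
    return out


def _group_alleles(members, locus: str) -> list[int]:
    alleles: set[int] = set()
    for s in members:
        call = s.call(locus)
        if not call.is_missing:
            alleles.update(call.alleles())
    return sorted(alleles)


def fixed_alleles(table: GenotypeTable) -> list[tuple[str, int, list[str]]]:
    """(locus, allele) pairs for which some cultivar is entirely homozygous.

    Returns one entry per (locus, allele) with the sorted list of cultivars
    fixed for it.  Cultivars with no non-missing call at a locus do not
    count as fixed there.
    """
    found: dict[tuple[str, int], set[str]] = {}
    for cultivar, members in table.group_members("cultivar").items():
        for locus in table.loci:
            alleles: set[int] = set()
            n = 0
            for s in members:
                call = s.call(locus.name)
                if call.is_missing:
                    continue
                n += 1
                alleles.update(call.alleles())
            if n >= 1 and len(alleles) == 1:
                found.setdefault((locus.name, alleles.pop()), set()).add(cultivar)
    return [
        (locus, allele, sorted(cvs))
        for (locus, allele), cvs in sorted(found.items())
    ]
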