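"""Core data model for codominant diploid SSR genotype tables.

An allele is identified by its exact integer fragment size in base pairs;
no automatic size binning is performed (readers accept an optional bin
width which defaults to 0, i.e. off).  A genotype call is an unordered
pair of allele sizes; missing data is a call with *both* alleles absent —
half-missing calls are rejected rather than imputed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator

UNKNOWN = "UNKNOWN"

SEXES = ("female", "male", "unknown")

GROUP_BY_CHOICES = ("cultivar", "locality", "all")


class SSRKitError(Exception):
    """Base class for all package errors."""


class ValidationError(SSRKitError):
    """Raised when a table violates a structural invariant."""


class ParseError(SSRKitError):
    """Raised by readers on malformed input; names row and column."""


@dataclass(frozen=True)
class GenotypeCall:
    """Unordered diploid call: two allele sizes in bp, or both missing.

    Canonical form has ``allele_a <= allele_b``; equality of ``(150, 140)``
    and ``(140, 150)`` therefore holds by construction.
    """

    allele_a: int | None = None
    allele_b: int | None = None

    def __post_init__(self) -> None:
        a, b = self.allele_a, self.allele_b
        if (a is None) != (b is None):
            raise ValidationError(
                f"half-missing genotype call ({a!r}/{b!r}); "
                "either both alleles or neither must be present"
            )
        if a is not None:
            if a <= 0 or b <= 0:
                raise ValidationError(f"allele sizes must be positive, got {a}/{b}")
            if a > b:
                object.__setattr__(self, "allele_a", b)
                object.__setattr__(self, "allele_b", a)

    @property
    def is_missing(self) -> bool:
        return self.allele_a is None

    @property
    def is_heterozygous(self) -> bool:
        return not self.is_missing and self.allele_a != self.allele_b

    def alleles(self) -> tuple[int, int]:
        if self.is_missing:
            raise ValidationError("missing call has no alleles")
        return (self.allele_a, self.allele_b)


MISSING_CALL = GenotypeCall(None, None)


@dataclass
class Locus:
    """A microsatellite locus and the allele sizes registered for it."""

    name: str
    allele_sizes: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("locus name must be a non-empty string")
        sizes = tuple(sorted(set(int(s) for s in self.allele_sizes)))
        if any(s <= 0 for s in sizes):
            raise ValidationError(f"locus {self.name}: allele sizes must be positive")
        self.allele_sizes = sizes

    def register(self, size: int) -> None:
        if size not in self.allele_sizes:
            self.allele_sizes = tuple(sorted(self.allele_sizes + (size,)))

    @property
    def n_alleles(self) -> int:
        return len(self.allele_sizes)


@dataclass
class SampleRecord:
    """One sampled tree: id, group labels, sex, and per-locus calls."""

    sample_id: str
    cultivar: str = UNKNOWN
    locality: str = UNKNOWN
    sex: str = "unknown"
    calls: dict[str, GenotypeCall] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValidationError("sample_id must be a non-empty string")
        if self.sex not in SEXES:
            raise ValidationError(
                f"sample {self.sample_id}: sex must be one of {SEXES}, got {self.sex!r}"
            )
        if not self.cultivar or not self.locality:
            raise ValidationError(f"sample {self.sample_id}: empty group label")

    def call(self, locus: str) -> GenotypeCall:
        return self.calls.get(locus, MISSING_CALL)


@dataclass
class GenotypeTable:
    """Samples-by-loci table of codominant calls; the pipeline's currency."""

    loci: list[Locus]
    samples: list[SampleRecord]

    def __post_init__(self) -> None:
        names = [l.name for l in self.loci]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate locus names in table")
        by_name = {l.name: l for l in self.loci}
        for sample in self.samples:
            for locus_name, call in sample.calls.items():
                if locus_name not in by_name:
                    raise ValidationError(
                        f"sample {sample.sample_id}: call at unknown locus {locus_name}"
                    )
                if not call.is_missing:
                    for allele in call.alleles():
                        by_name[locus_name].register(allele)

    @classmethod
    def from_samples(
        cls, samples: Iterable[SampleRecord], locus_names: Iterable[str] | None = None
    ) -> "GenotypeTable":
        """Build a table, deriving the locus list from the calls if needed."""
        samples = list(samples)
        if locus_names is None:
            seen: dict[str, None] = {}
            for s in samples:
                for name in s.calls:
                    seen.setdefault(name)
            locus_names = list(seen)
        return cls(loci=[Locus(n) for n in locus_names], samples=samples)

    @property
    def locus_names(self) -> list[str]:
        return [l.name for l in self.loci]

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def locus(self, name: str) -> Locus:
        for l in self.loci:
            if l.name == name:
                return l
        raise KeyError(name)

    def cultivars(self) -> list[str]:
        out: dict[str, None] = {}
        for s in self.samples:
            out.setdefault(s.cultivar)
        return list(out)

    def localities(self) -> list[str]:
        out: dict[str, None] = {}
        for s in self.samples:
            out.setdefault(s.locality)
        return list(out)

    def subset(self, sample_ids: Iterable[str]) -> "GenotypeTable":
        wanted = set(sample_ids)
        return GenotypeTable(
            loci=[Locus(l.name, l.allele_sizes) for l in self.loci],
            samples=[s for s in self.samples if s.sample_id in wanted],
        )

    def group_members(self, group_by: str) -> dict[str, list[SampleRecord]]:
        if group_by not in GROUP_BY_CHOICES:
            raise ValueError(f"group_by must be one of {GROUP_BY_CHOICES}")
        groups: dict[str, list[SampleRecord]] = {}
        for s in self.samples:
            if group_by == "all":
                key = "ALL"
            elif group_by == "cultivar":
                key = s.cultivar
            else:
                key = s.locality
            groups.setdefault(key, []).append(s)
        return groups


@dataclass
class LocusFrequencies:
    """Allele frequencies at one locus plus the diploid sample count n."""

    freqs: dict[int, float]
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError("LocusFrequencies requires n >= 1")
        total = sum(self.freqs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"frequencies sum to {total}, expected 1")


@dataclass
class FrequencyTable:
    """Per-group allele frequency maps keyed by locus name."""

    group: str
    per_locus: dict[str, LocusFrequencies]

    def loci(self) -> list[str]:
        return list(self.per_locus)


def allele_frequencies(table: GenotypeTable, group_by: str = "all") -> list[FrequencyTable]:
    """Count allele copies among non-missing calls, divided by 2n.

    A group with zero non-missing calls at every locus is skipped with a
    warning; a locus with zero non-missing calls in a group is omitted
    from that group's map.
    """
    results: list[FrequencyTable] = []
    for group, members in table.group_members(group_by).items():
        per_locus: dict[str, LocusFrequencies] = {}
        for locus in table.loci:
            counts: dict[int, int] = {}
            n = 0
            for sample in members:
                call = sample.call(locus.name)
                if call.is_missing:
                    continue
                n += 1
                for allele in call.alleles():
                    counts[allele] = counts.get(allele, 0) + 1
            if n == 0:
                continue
            total = 2 * n
            per_locus[locus.name] = LocusFrequencies(
                freqs={a: c / total for a, c in sorted(counts.items())}, n=n
            )
        if not per_locus:
            warnings.warn(f"group {group!r} has no non-missing calls; skipped")
            continue
        results.append(FrequencyTable(group=group, per_locus=per_locus))
    return results


@dataclass
class Issue:
    severity: str  # "error" | "warning" | "info"
    code: str
    message: str
    sample_id: str | None = None
    locus: str | None = None


@dataclass
class ValidationReport:
    issues: list[Issue] = field(default_factory=list)

    @property
    def errors(self) -> list[Issue]:
        return [i for i in self.issues if i.severity == "error"]

    @property
    def ok(self) -> bool:
        return not self.errors

    def __iter__(self) -> Iterator[Issue]:
        return iter(self.issues)


def validate(table: GenotypeTable, declared_ranges: dict[str, tuple[int, int]] | None = None) -> ValidationReport:
    """Report duplicate ids, out-of-range alleles, and per-locus missingness.

    ``declared_ranges`` optionally maps locus name to an (lo, hi) allelic
    range in bp; alleles outside it are flagged as warnings.
    """
    report = ValidationReport()
    seen: set[str] = set()
    for sample in table.samples:
        if sample.sample_id in seen:
            report.issues.append(
                Issue("error", "duplicate-sample-id",
                      f"sample_id {sample.sample_id!r} occurs more than once",
                      sample_id=sample.sample_id)
            )
        seen.add(sample.sample_id)
    if declared_ranges:
        for locus in table.loci:
            if locus.name not in declared_ranges:
                continue
            lo, hi = declared_ranges[locus.name]
            for allele in locus.allele_sizes:
                if not (lo <= allele <= hi):
                    report.issues.append(
                        Issue("warning", "allele-out-of-range",
                              f"allele {allele} at {locus.name} outside declared "
                              f"range {lo}-{hi}", locus=locus.name)
                    )
    n = table.n_samples
    if n:
        for locus in table.loci:
            missing = sum(1 for s in table.samples if s.call(locus.name).is_missing)
            if missing:
                report.issues.append(
                    Issue("info", "missingness",
                          f"{locus.name}: {missing}/{n} calls missing "
                          f"({100.0 * missing / n:.1f}%)", locus=locus.name)
                )
    return report
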