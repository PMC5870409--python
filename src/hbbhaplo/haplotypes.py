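"""Classification of five-site RFLP profiles into beta-globin haplotypes.

Five classical, region-named haplotypes (Benin, Bantu/CAR, Senegal,
Cameroon, Arab-Indian) are each defined by an exact five-site cut pattern;
any other pattern is a recombinant, "atypical" haplotype, of which the five
most common carry names of their own (atypical I..V).  The patterns ship as
a versioned JSON table so alternative published tables can be swapped in.

Besides per-chromosome classification the module tabulates per-population
haplotype frequencies (denominator: resolved chromosomes) and per-individual
haplotype-pair combinations (denominator: individuals with both chromosomes
resolved), matching how such cohorts are conventionally reported.
"""

from __future__ import annotations

import json
from collections import Counter
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .rflp import LOCI, MISSING, RFLPProfile

__all__ = [
    "ATYPICAL_OTHER",
    "UNRESOLVED",
    "HaplotypeTable",
    "HaplotypeCall",
    "CombinationRecord",
    "FrequencyTable",
    "default_table",
    "classify",
    "haplotype_frequencies",
    "atypical_subtype_frequencies",
    "pair_combinations",
]

ATYPICAL_OTHER = "atypical-other"
UNRESOLVED = "unresolved"
ATYPICAL_GROUP = "atypical"


@dataclass(frozen=True)
class HaplotypeTable:
    """Five-site patterns for classical haplotypes and named atypical subtypes."""

    classical: dict[str, tuple[str, ...]]
    atypical: dict[str, tuple[str, ...]]
    version: str = "unversioned"

    def __post_init__(self) -> None:
        patterns: list[tuple[str, ...]] = []
        for name, pat in {**self.classical, **self.atypical}.items():
            if len(pat) != len(LOCI):
                raise ValueError(f"pattern for {name!r} must have {len(LOCI)} states")
            if MISSING in pat:
                raise ValueError(f"pattern for {name!r} contains a missing state")
            patterns.append(pat)
        if len(set(patterns)) != len(patterns):
            raise ValueError("haplotype patterns must be pairwise distinct")

    @property
    def labels(self) -> list[str]:
        return list(self.classical) + list(self.atypical)

    def pattern(self, label: str) -> tuple[str, ...]:
        if label in self.classical:
            return self.classical[label]
        if label in self.atypical:
            return self.atypical[label]
        raise KeyError(f"unknown haplotype label: {label!r}")

    def is_classical(self, label: str) -> bool:
        return label in self.classical

    @classmethod
    def from_json(cls, path: str | Path) -> "HaplotypeTable":
        return cls.from_dict(json.loads(Path(path).read_text()))

    @classmethod
    def from_dict(cls, d: Mapping) -> "HaplotypeTable":
        order = d.get("locus_order")
        if order is not None and tuple(order) != LOCI:
            raise ValueError(f"table locus order {order} != expected {list(LOCI)}")
        return cls(
            classical={k: tuple(v) for k, v in d["classical"].items()},
            atypical={k: tuple(v) for k, v in d.get("atypical", {}).items()},
            version=d.get("version", "unversioned"),
        )

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "locus_order": list(LOCI),
            "classical": {k: "".join(v) for k, v in self.classical.items()},
            "atypical": {k: "".join(v) for k, v in self.atypical.items()},
        }


def default_table() -> HaplotypeTable:
    """The packaged five-site haplotype table ("table-ref16-default")."""
    text = resources.files("hbbhaplo.data").joinpath("haplotype_table.json").read_text()
    return HaplotypeTable.from_dict(json.loads(text))


@dataclass(frozen=True)
class HaplotypeCall:
    """A profile's classification: classical label, named atypical subtype,
    "atypical-other", or "unresolved" when any site state is missing."""

    label: str
    matched_pattern: tuple[str, ...]

    @property
    def resolved(self) -> bool:
        return self.label != UNRESOLVED


def classify(profile: RFLPProfile, table: HaplotypeTable) -> HaplotypeCall:
    """Map a five-site profile to its haplotype label by exact pattern match."""
    if profile.has_missing:
        return HaplotypeCall(UNRESOLVED, profile.states)
    for name, pat in table.classical.items():
        if profile.states == pat:
            return HaplotypeCall(name, profile.states)
    for name, pat in table.atypical.items():
        if profile.states == pat:
            return HaplotypeCall(name, profile.states)
    return HaplotypeCall(ATYPICAL_OTHER, profile.states)


def _coarse_label(call_label: str, table: HaplotypeTable) -> str:
    return call_label if table.is_classical(call_label) else ATYPICAL_GROUP


@dataclass(frozen=True)
class FrequencyTable:
    """Counts and proportions per category over a stated denominator."""

    counts: dict[str, int]
    denominator: int
    unit: str  # "chromosomes" or "individuals"
    population: str | None = None
    n_excluded: int = 0

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.denominator:
            raise ValueError("counts must sum to the denominator")

    @property
    def proportions(self) -> dict[str, float]:
        return {k: v / self.denominator for k, v in self.counts.items()}

    def percent(self, category: str, ndigits: int = 1) -> float:
        """Percentage of one category, rounded (default one decimal place)."""
        return round(100.0 * self.counts.get(category, 0) / self.denominator, ndigits)


def haplotype_frequencies(
    calls: Iterable[HaplotypeCall],
    grouping: str = "fine",
    table: HaplotypeTable | None = None,
    population: str | None = None,
) -> FrequencyTable:
    """Per-chromosome haplotype frequencies over resolved calls.

    grouping="fine" keeps every label; "classical-vs-atypical" collapses all
    atypical subtypes (named or other) into one "atypical" category.
    Unresolved calls are excluded from the denominator and counted in
    ``n_excluded``.
    """
    if grouping not in ("fine", "classical-vs-atypical"):
        raise ValueError(f"unknown grouping: {grouping!r}")
    if grouping == "classical-vs-atypical" and table is None:
        raise ValueError("classical-vs-atypical grouping requires the haplotype table")
    calls = list(calls)
    resolved = [c for c in calls if c.resolved]
    if not resolved:
        raise ValueError("no resolved haplotype calls to tabulate")
    if grouping == "fine":
        labels = [c.label for c in resolved]
    else:
        labels = [_coarse_label(c.label, table) for c in resolved]
    return FrequencyTable(
        counts=dict(Counter(labels)),
        denominator=len(resolved),
        unit="chromosomes",
        population=population,
        n_excluded=len(calls) - len(resolved),
    )


def atypical_subtype_frequencies(
    calls: Iterable[HaplotypeCall],
    table: HaplotypeTable,
    denominator: str = "all",
    population: str | None = None,
) -> FrequencyTable:
    """Frequencies of the named atypical subtypes.

    ``denominator`` chooses the reporting convention: "all" divides by all
    resolved chromosomes, "atypical" by atypical chromosomes only.  Both
    conventions occur in the cohort literature.
    """
    resolved = [c for c in calls if c.resolved]
    atypical = [c for c in resolved if not table.is_classical(c.label)]
    if denominator == "all":
        denom_calls = resolved
    elif denominator == "atypical":
        denom_calls = atypical
    else:
        raise ValueError(f"denominator must be 'all' or 'atypical', got {denominator!r}")
    if not denom_calls:
        raise ValueError("empty denominator for atypical subtype frequencies")
    counts = Counter(c.label for c in atypical)
    if denominator == "all":
        counts["non-atypical"] = len(resolved) - len(atypical)
    return FrequencyTable(
        counts=dict(counts),
        denominator=len(denom_calls),
        unit="chromosomes",
        population=population,
    )


@dataclass(frozen=True)
class CombinationRecord:
    """Unordered pair of haplotype labels carried by one individual."""

    individual: str
    labels: frozenset[str] = field()
    # frozenset collapses {x, x}; keep the sorted pair for display
    pair: tuple[str, str] = ()

    @staticmethod
    def make(individual: str, a: str, b: str) -> "CombinationRecord":
        pair = tuple(sorted((a, b)))
        return CombinationRecord(individual, frozenset(pair), pair)

    @property
    def label(self) -> str:
        return "/".join(self.pair)


def pair_combinations(
    calls_by_individual: Mapping[str, Sequence[HaplotypeCall]],
    table: HaplotypeTable,
    collapse_atypical: bool = True,
) -> tuple[list[CombinationRecord], FrequencyTable]:
    """Per-individual haplotype-pair combinations and their frequencies.

    Each individual must contribute exactly two chromosome calls.  By default
    all atypical subtypes collapse to "atypical", the granularity at which
    pair combinations are conventionally reported.  Individuals with an
    unresolved chromosome are excluded from the denominator.
    """
    records: list[CombinationRecord] = []
    n_excluded = 0
    for ind, calls in calls_by_individual.items():
        if len(calls) != 2:
            raise ValueError(
                f"individual {ind!r} has {len(calls)} chromosome calls, expected 2"
            )
        if not all(c.resolved for c in calls):
            n_excluded += 1
            continue
        a, b = (
            (_coarse_label(c.label, table) if collapse_atypical else c.label)
            for c in calls
        )
        records.append(CombinationRecord.make(ind, a, b))
    if not records:
        raise ValueError("no individuals with both chromosomes resolved")
    freq = FrequencyTable(
        counts=dict(Counter(r.label for r in records)),
        denominator=len(records),
        unit="individuals",
        n_excluded=n_excluded,
    )
    return records, freq
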