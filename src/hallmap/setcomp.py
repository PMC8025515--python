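"""Term-selection frequencies, consensus terms, and exclusive set intersections.

These statistics quantify how much the published hallmark mapping schemes
agree: how often each term is selected across schemes (overall and per
hallmark), which fraction of a scheme's terms nobody else selected, which
terms reach consensus (selected for the same hallmark by at least
``min_schemes`` schemes), and the exclusive intersection structure of the
hallmark gene sets — the cell counts an UpSet plot displays.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Sequence, TextIO

from .schemes import HallmarkGeneSets, MappingScheme


@dataclass
class SelectionFrequency:
    """Per-term scheme-selection counts, overall and per hallmark."""

    overall: dict[str, int] = field(default_factory=dict)
    per_hallmark: dict[str, dict[str, int]] = field(default_factory=dict)
    n_schemes: int = 0


@dataclass
class IntersectionProfile:
    """Exclusive (UpSet-style) intersection cells over named sets.

    ``exclusive`` maps each non-empty combination of set names to the elements
    that belong to *every* set in the combination and to *no* other set; the
    cells therefore partition the global union.
    """

    exclusive: dict[frozenset[str], set[str]] = field(default_factory=dict)
    set_totals: dict[str, int] = field(default_factory=dict)

    def counts(self) -> dict[frozenset[str], int]:
        return {combo: len(members) for combo, members in self.exclusive.items()}

    @property
    def union_size(self) -> int:
        return sum(len(m) for m in self.exclusive.values())


def term_selection_frequency(schemes: Sequence[MappingScheme]) -> SelectionFrequency:
    """Count, per term, how many schemes selected it.

    Counting is scheme-level: a term one scheme maps to two hallmarks counts
    once in the overall tally.  Per-hallmark tallies count schemes selecting
    the term *for that hallmark*.
    """
    onto = [s for s in schemes if s.source_kind == "ontology_terms"]
    if len(onto) < 2:
        raise ValueError(f"need at least 2 ontology-kind schemes, got {len(onto)}")
    freq = SelectionFrequency(n_schemes=len(onto))
    for scheme in onto:
        for term in scheme.all_terms:
            freq.overall[term] = freq.overall.get(term, 0) + 1
        for hallmark, terms in scheme.selections.items():
            bucket = freq.per_hallmark.setdefault(hallmark, {})
            for term in terms:
                bucket[term] = bucket.get(term, 0) + 1
    return freq


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Half-up decimal rounding (report parity with conventional percentages)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def unique_term_fraction(scheme: MappingScheme, schemes: Sequence[MappingScheme]) -> float:
    """Percentage of a scheme's terms selected by no other scheme (1 decimal)."""
    own = scheme.all_terms
    if not own:
        raise ValueError(f"scheme {scheme.scheme_id} selects zero terms")
    others: set[str] = set()
    for other in schemes:
        if other.scheme_id == scheme.scheme_id or other.source_kind != "ontology_terms":
            continue
        others |= other.all_terms
    unique = own - others
    return round_half_up(100.0 * len(unique) / len(own), 1)


def consensus_terms(
    schemes: Sequence[MappingScheme],
    min_schemes: int = 3,
) -> tuple[dict[str, set[str]], set[str], set[str]]:
    """Consensus terms: selected for the *same* hallmark by >= min_schemes schemes.

    Pathway schemes must already have been converted to term selections via a
    pathway-to-term correspondence table before they can vote here.

    Returns
    -------
    per_hallmark : hallmark -> consensus term set
    overall : union of the per-hallmark sets (each term counted once globally)
    overall_with_multiplicity is exposed as the third element: the multiset
    union flattened to (hallmark, term) pairs, for the tally that counts a
    term once per hallmark it reaches consensus in.
    """
    onto = [s for s in schemes if s.source_kind == "ontology_terms"]
    if min_schemes > len(onto):
        raise ValueError(f"min_schemes={min_schemes} exceeds the {len(onto)} voting schemes")
    counts: dict[str, dict[str, int]] = {}
    for scheme in onto:
        for hallmark, terms in scheme.selections.items():
            bucket = counts.setdefault(hallmark, {})
            for term in terms:
                bucket[term] = bucket.get(term, 0) + 1
    per_hallmark = {
        h: {t for t, c in bucket.items() if c >= min_schemes}
        for h, bucket in counts.items()
    }
    per_hallmark = {h: terms for h, terms in per_hallmark.items()}
    overall: set[str] = set()
    pairs: set[tuple[str, str]] = set()
    for h, terms in per_hallmark.items():
        overall |= terms
        pairs |= {(h, t) for t in terms}
    return per_hallmark, overall, {f"{h}::{t}" for h, t in pairs}


def exclusive_intersections(sets: Mapping[str, Iterable[str]]) -> IntersectionProfile:
    """Exclusive intersection cells of >=2 named sets (UpSet counts).

    Each element is assigned to the single cell keyed by its exact membership
    signature, so cells are pairwise disjoint and their sizes sum to the size
    of the global union — asserted on every call.
    """
    named = {name: set(members) for name, members in sets.items()}
    if len(named) < 2:
        raise ValueError("need at least 2 sets")
    signature: dict[str, frozenset[str]] = {}
    union: set[str] = set()
    for name, members in named.items():
        union |= members
    cells: dict[frozenset[str], set[str]] = {}
    for element in union:
        combo = frozenset(name for name, members in named.items() if element in members)
        cells.setdefault(combo, set()).add(element)
    profile = IntersectionProfile(
        exclusive=cells,
        set_totals={name: len(members) for name, members in named.items()},
    )
    assert profile.union_size == len(union), "exclusive cells must partition the union"
    return profile


def per_hallmark_gene_comparison(
    gene_sets: Sequence[HallmarkGeneSets],
    hallmark: str,
) -> IntersectionProfile:
    """Exclusive intersections of one hallmark's gene sets across schemes.

    Schemes without a (non-empty) gene set for the hallmark are omitted from
    the profile rather than contributing empty sets.
    """
    sets = {
        gs.scheme_id: gs.per_hallmark[hallmark]
        for gs in gene_sets
        if gs.per_hallmark.get(hallmark)
    }
    if len(sets) < 2:
        raise ValueError(
            f"hallmark {hallmark!r} is covered by {len(sets)} scheme(s); need >= 2"
        )
    return exclusive_intersections(sets)


def write_upset_tsv(profile: IntersectionProfile, stream: TextIO) -> None:
    """Write (combination, count) rows; combination is '&'-joined sorted names."""
    stream.write("combination\tcount\n")
    for combo in sorted(profile.exclusive, key=lambda c: (len(c), sorted(c))):
        stream.write("&".join(sorted(combo)) + f"\t{len(profile.exclusive[combo])}\n")


def write_consensus_tsv(per_hallmark: Mapping[str, Iterable[str]], stream: TextIO,
                        schemes: Sequence[MappingScheme] | None = None) -> None:
    """Write (hallmark, term_id, n_schemes) rows for the consensus table."""
    counts: dict[tuple[str, str], int] = {}
    if schemes:
        for scheme in schemes:
            if scheme.source_kind != "ontology_terms":
                continue
            for h, terms in scheme.selections.items():
                for t in terms:
                    counts[(h, t)] = counts.get((h, t), 0) + 1
    stream.write("hallmark\tterm_id\tn_schemes\n")
    for h in sorted(per_hallmark):
        for t in sorted(per_hallmark[h]):
            stream.write(f"{h}\t{t}\t{counts.get((h, t), '')}\n")
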