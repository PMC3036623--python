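"""Core domain objects shared across the package.

All residue coordinates are 1-based inclusive, matching the CATH/SCOP
range dialect used for domain definitions; conversion to 0-based Python
indices happens only at the point of use.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: Ambiguity codes spread uniformly over their member residues.
AMBIGUITY = {
    "X": tuple(AMINO_ACIDS),
    "B": ("D", "N"),
    "Z": ("E", "Q"),
    "J": ("I", "L"),
}
GAP = "-"

SS_STATES = "HEC"  # helix, strand, loop
SA_STATES = "be"  # buried, exposed


class ValidationError(ValueError):
    """Raised when an input object violates a structural invariant."""


@dataclass(frozen=True)
class QueryProtein:
    """An ungapped query sequence that anchors an MSA."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError(f"query {self.id!r}: empty sequence")
        if GAP in self.sequence:
            raise ValidationError(f"query {self.id!r}: gap character in sequence")
        bad = set(self.sequence) - set(AMINO_ACIDS) - set(AMBIGUITY)
        if bad:
            raise ValidationError(
                f"query {self.id!r}: non-amino-acid characters {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AlignedHit:
    """One homolog rendered in query coordinates (gap = '-').

    ``aligned`` has exactly the query length; hit residues inserted
    relative to the query are not represented.
    """

    hit_id: str
    e_value: float
    aligned: str

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ValidationError(f"hit {self.hit_id!r}: negative e-value")


@dataclass
class AnchoredMSA:
    """Query plus hits stacked in query coordinates, sorted by e-value."""

    query: QueryProtein
    hits: list[AlignedHit] = field(default_factory=list)

    def __post_init__(self) -> None:
        L = self.query.length
        for h in self.hits:
            if len(h.aligned) != L:
                raise ValidationError(
                    f"hit {h.hit_id!r}: aligned length {len(h.aligned)} != query length {L}"
                )
        evs = [h.e_value for h in self.hits]
        if any(a > b for a, b in zip(evs, evs[1:])):
            raise ValidationError("hits not sorted by non-decreasing e-value")


@dataclass(frozen=True)
class DomainDefinition:
    """Ordered, non-overlapping 1-based inclusive residue ranges."""

    chain_id: str
    ranges: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        for s, e in self.ranges:
            if s > e:
                raise ValidationError(
                    f"chain {self.chain_id!r}: inverted range {s}-{e}"
                )
            if s < 1:
                raise ValidationError(f"chain {self.chain_id!r}: range start {s} < 1")
        starts = [s for s, _ in self.ranges]
        if starts != sorted(starts):
            raise ValidationError(f"chain {self.chain_id!r}: ranges not sorted")
        for (_, e1), (s2, _) in zip(self.ranges, self.ranges[1:]):
            if s2 <= e1:
                raise ValidationError(
                    f"chain {self.chain_id!r}: overlapping ranges at {e1}/{s2}"
                )

    @property
    def n_domains(self) -> int:
        return len(self.ranges)

    @property
    def is_multi_domain(self) -> bool:
        return len(self.ranges) > 1


@dataclass(frozen=True)
class StructuralAnnotation:
    """Predicted 3-state secondary structure and 2-state accessibility."""

    ss: str
    sa: str

    def __post_init__(self) -> None:
        if len(self.ss) != len(self.sa):
            raise ValidationError(
                f"ss length {len(self.ss)} != sa length {len(self.sa)}"
            )
        bad_ss = set(self.ss) - set(SS_STATES)
        if bad_ss:
            raise ValidationError(f"ss contains invalid states {sorted(bad_ss)}")
        bad_sa = set(self.sa) - set(SA_STATES)
        if bad_sa:
            raise ValidationError(f"sa contains invalid states {sorted(bad_sa)}")


class Side(Enum):
    """Which terminus of the hit row the gap run starts from."""

    N_TERMINAL = "N"
    C_TERMINAL = "C"


class SiteLabel(Enum):
    FALSE_BOUNDARY = "false"
    NEAR = "near"
    AWAY = "away"


class ProteinClass(Enum):
    SINGLE_DOMAIN = "single"
    MULTI_DOMAIN = "multi"
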