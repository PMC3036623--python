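"""Domain-boundary signal extraction from terminal gaps in an anchored MSA.

A *boundary signal* is a gap run that begins at the N or C terminus of one
MSA row and extends continuously for at least ``min_gap`` residues, provided
the row retains at least ``min_aligned`` non-gap residues once all gaps are
removed.  Such a terminal gap suggests the homolog lacks a domain present
in the query, so the gap-adjacent aligned residue is a putative boundary.

Rows are processed in order of increasing e-value and collection halts as
soon as signals have accumulated at ``max_unique_sites`` distinct residue
positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .types import AlignedHit, AnchoredMSA, DomainDefinition, GAP, Side, SiteLabel


@dataclass(frozen=True)
class SignalParams:
    """Tunable parameters of the signal-generation rules.

    min_gap
        Minimum length (residues) of the continuous terminal gap run.
    min_aligned
        Minimum number of non-gap residues remaining in the row after
        removing every gap, for the row to generate any signal.
    max_unique_sites
        Collection halts once signals exist at this many distinct
        residue positions.
    near_tol
        A signal within this many residues of a true boundary on a
        multi-domain chain is labelled *near*.
    """

    min_gap: int = 45
    min_aligned: int = 45
    max_unique_sites: int = 35
    near_tol: int = 20

    def __post_init__(self) -> None:
        for name in ("min_gap", "min_aligned", "max_unique_sites", "near_tol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class BoundarySignal:
    """One raw signal event from one hit row."""

    position: int  # 1-based query residue index
    source_hit: str
    side: Side


@dataclass
class SignalSite:
    """All signal events aggregated at one residue position."""

    position: int
    multiplicity: int = 1
    sources: list[BoundarySignal] = field(default_factory=list)


def scan_hit(hit: AlignedHit, params: SignalParams = SignalParams()) -> list[BoundarySignal]:
    """Scan one anchored row for terminal-gap boundary signals.

    Returns 0, 1 or 2 signals: an N-side signal at the first non-gap
    residue if the row starts with >= ``min_gap`` gaps, and a C-side
    signal at the last non-gap residue if it ends with >= ``min_gap``
    gaps — in either case only if the row's total non-gap count is
    >= ``min_aligned``.
    """
    row = hit.aligned
    n_aligned = len(row) - row.count(GAP)
    if n_aligned < params.min_aligned:
        return []
    lead = len(row) - len(row.lstrip(GAP))
    trail = len(row) - len(row.rstrip(GAP))
    out: list[BoundarySignal] = []
    if lead >= params.min_gap:
        out.append(BoundarySignal(lead + 1, hit.hit_id, Side.N_TERMINAL))
    if trail >= params.min_gap:
        out.append(BoundarySignal(len(row) - trail, hit.hit_id, Side.C_TERMINAL))
    return out


def extract_signals(
    msa: AnchoredMSA, params: SignalParams = SignalParams()
) -> list[SignalSite]:
    """Collect signal sites from an MSA, capped at ``max_unique_sites``.

    Hits are processed in the MSA's stored order (non-decreasing e-value);
    each signal event accumulates multiplicity at its position.  The loop
    halts immediately when the number of distinct positions reaches the
    cap — mid-row, so the C-side signal of a row may be skipped after its
    N-side signal filled the last slot.

    Returns sites sorted by position; raw events are kept on each site's
    ``sources`` list.
    """
    sites: dict[int, SignalSite] = {}
    done = False
    for hit in msa.hits:
        for sig in scan_hit(hit, params):
            site = sites.get(sig.position)
            if site is None:
                site = SignalSite(sig.position, 0)
                sites[sig.position] = site
            site.multiplicity += 1
            site.sources.append(sig)
            if len(sites) >= params.max_unique_sites:
                done = True
                break
        if done:
            break
    return [sites[p] for p in sorted(sites)]


def boundary_points(definition: DomainDefinition) -> set[int]:
    """Residue positions flanking each inter-domain transition.

    For adjacent ranges (s1,e1),(s2,e2) both e1 and s2 are boundary
    points.  The chain termini (first range's start, last range's end)
    are never included; a single-domain definition yields the empty set.
    """
    points: set[int] = set()
    for (_, e1), (s2, _) in zip(definition.ranges, definition.ranges[1:]):
        points.add(e1)
        points.add(s2)
    return points


def label_sites(
    sites: list[SignalSite],
    definition: DomainDefinition,
    params: SignalParams = SignalParams(),
) -> list[SiteLabel]:
    """Label each site false (single-domain chain), near, or away.

    On a multi-domain chain a site is *near* iff its distance to the
    closest boundary point is <= ``near_tol`` (inclusive), else *away*.
    """
    if not definition.is_multi_domain:
        return [SiteLabel.FALSE_BOUNDARY] * len(sites)
    points = boundary_points(definition)
    labels = []
    for site in sites:
        d = min(abs(site.position - p) for p in points)
        labels.append(SiteLabel.NEAR if d <= params.near_tol else SiteLabel.AWAY)
    return labels


def minimum_signal_length(
    params: SignalParams = SignalParams(), max_length: int = 200
) -> int | None:
    """Smallest query length admitting any signal, by exhaustive search.

    For each length L, every terminal-gap row layout (g gaps then L-g
    residues, and its mirror) is constructed and scanned; the first L
    for which any layout yields a signal is returned (None if none up
    to ``max_length``).
    """
    for L in range(1, max_length + 1):
        for g in range(1, L):
            for row in (GAP * g + "A" * (L - g), "A" * (L - g) + GAP * g):
                if scan_hit(AlignedHit("probe", 0.0, row), params):
                    return L
    return None
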