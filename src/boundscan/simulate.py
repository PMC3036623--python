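"""Synthetic protein families with planted domain architectures.

The generator emulates the evolutionary situation the signal rules
exploit: a multi-domain query whose homologs include full-length
relatives, *partial* relatives carrying only a contiguous subset of the
query's domains (gene fission / fusion products — their missing domains
become terminal gaps in the anchored MSA, with alignment endpoints
jittered around the true boundaries), and random fragments whose
truncation points fall anywhere (the source of away and false signals).
Single-domain decoy families produce only fragment-derived signals.

Sequence content is i.i.d. over the 20 amino acids with a per-domain
compositional bias; secondary structure is loop-enriched around true
boundaries and solvent accessibility exposure-enriched there, mimicking
linkers.  E-values are rank-assigned so that the least corrupted hit has
the lowest e-value, making the capped, e-value-ordered collection loop
meaningful.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as bio
from .types import (
    AMINO_ACIDS,
    AlignedHit,
    AnchoredMSA,
    DomainDefinition,
    GAP,
    QueryProtein,
    StructuralAnnotation,
)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic-family generator.

    All lengths are residues; fractions are in [0, 1].  ``fragment_prob``
    is the probability that a non-partial hit is a randomly truncated
    fragment rather than a full-length homolog — fragments are what
    produce away signals (multi-domain chains) and false signals
    (single-domain chains).
    """

    seed: int = 0
    n_chains: int = 100
    multi_fraction: float = 0.5
    domain_length_range: tuple[int, int] = (100, 180)
    hits_per_chain_range: tuple[int, int] = (10, 25)
    boundary_jitter_sd: float = 2.0
    partial_hit_prob: float = 0.6
    fragment_prob: float = 0.5
    substitution_rate: float = 0.05
    loop_enrichment: float = 0.95
    boundary_halfwidth: int = 3
    exposed_fraction: float = 0.45
    evalue_decade_per_rank: float = 1.0

    def __post_init__(self) -> None:
        for name in ("multi_fraction", "partial_hit_prob", "fragment_prob",
                     "substitution_rate", "loop_enrichment", "exposed_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be a fraction in [0, 1]")
        for name in ("domain_length_range", "hits_per_chain_range"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 1:
                raise ValueError(f"{name}: invalid range ({lo}, {hi})")


PRESETS = {
    "easy": SimConfig(),
    "hard": SimConfig(
        boundary_jitter_sd=8.0,
        substitution_rate=0.15,
        loop_enrichment=0.6,
        partial_hit_prob=0.4,
        hits_per_chain_range=(6, 15),
    ),
}


@dataclass
class SyntheticChain:
    query: QueryProtein
    msa: AnchoredMSA
    ann: StructuralAnnotation
    truth: DomainDefinition


def _contiguous_proper_subsets(k: int) -> list[tuple[int, int]]:
    """All contiguous proper domain subsets [i, j] of a k-domain chain."""
    return [
        (i, j) for i in range(k) for j in range(i, k) if not (i == 0 and j == k - 1)
    ]


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    # per-domain compositional bias via a Dirichlet-drawn composition
    comp = rng.dirichlet(np.full(20, 2.0))
    return "".join(rng.choice(list(AMINO_ACIDS), size=length, p=comp))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = AMINO_ACIDS[rng.integers(20)]
    return "".join(out)


def simulate_chain(
    config: SimConfig, rng: np.random.Generator, chain_id: str = "sim"
) -> SyntheticChain:
    """Generate one chain: query, anchored hits, SS/SA, and truth ranges."""
    for _ in range(100):
        k = 1 if rng.random() >= config.multi_fraction else int(rng.integers(2, 4))
        lo, hi = config.domain_length_range
        dom_lens = [int(rng.integers(lo, hi + 1)) for _ in range(k)]
        if k == 1 or sum(dom_lens) >= 90:
            break
    else:  # pragma: no cover - unreachable with sane configs
        raise RuntimeError("could not draw a multi-domain chain of >= 90 residues")

    starts = np.cumsum([0] + dom_lens[:-1]) + 1
    ends = np.cumsum(dom_lens)
    ranges = tuple((int(s), int(e)) for s, e in zip(starts, ends))
    seq = "".join(_random_sequence(rng, n) for n in dom_lens)
    L = len(seq)
    query = QueryProtein(chain_id, seq)
    truth = DomainDefinition(chain_id, ranges)

    n_hits = int(rng.integers(*config.hits_per_chain_range, endpoint=True))
    subsets = _contiguous_proper_subsets(k)
    if subsets:
        rng.shuffle(subsets)
    subset_cursor = 0

    raw_hits = []
    for h in range(n_hits):
        if k > 1 and subsets and rng.random() < config.partial_hit_prob:
            # partial homolog: contiguous domain subset, endpoints jittered
            # around the true boundaries; cycled so every subset occurs
            i, j = subsets[subset_cursor % len(subsets)]
            subset_cursor += 1
            a = int(starts[i])
            b = int(ends[j])
            if i > 0:
                a += int(round(rng.normal(0, config.boundary_jitter_sd)))
            if j < k - 1:
                b += int(round(rng.normal(0, config.boundary_jitter_sd)))
            a = max(1, min(a, L - 1))
            b = max(a, min(b, L))
        elif rng.random() < config.fragment_prob:
            # random fragment: truncation points anywhere in the chain
            frag_len = int(rng.integers(45, max(46, L - 30)))
            a = int(rng.integers(1, max(2, L - frag_len + 2)))
            b = min(L, a + frag_len - 1)
        else:
            a, b = 1, L
        covered = _mutate(rng, seq[a - 1 : b], config.substitution_rate)
        aligned = GAP * (a - 1) + covered + GAP * (L - b)
        corruption = (L - (b - a + 1)) / L + config.substitution_rate * rng.random()
        raw_hits.append((corruption, h, aligned))

    raw_hits.sort(key=lambda t: (t[0], t[1]))
    hits = [
        AlignedHit(
            f"{chain_id}_h{orig:03d}",
            10.0 ** (-40 + rank * config.evalue_decade_per_rank),
            aligned,
        )
        for rank, (_, orig, aligned) in enumerate(raw_hits)
    ]

    ann = _simulate_annotation(config, rng, truth, L)
    return SyntheticChain(query, AnchoredMSA(query, hits), ann, truth)


def _simulate_annotation(
    config: SimConfig, rng: np.random.Generator, truth: DomainDefinition, L: int
) -> StructuralAnnotation:
    """SS/SA strings: loop- and exposure-enriched around true boundaries."""
    ss = rng.choice(list("HEC"), size=L, p=[0.35, 0.25, 0.40])
    exposed = rng.random(L) < config.exposed_fraction
    from .signals import boundary_points

    for b in boundary_points(truth):
        lo = max(0, b - 1 - config.boundary_halfwidth)
        hi = min(L, b + config.boundary_halfwidth)
        for i in range(lo, hi):
            if rng.random() < config.loop_enrichment:
                ss[i] = "C"
                exposed[i] = True
    sa = np.where(exposed, "e", "b")
    return StructuralAnnotation("".join(ss), "".join(sa))


def simulate_dataset(config: SimConfig) -> tuple[list[SyntheticChain], dict]:
    """Generate ``n_chains`` chains and a manifest of seed/config/truth."""
    rng = np.random.default_rng(config.seed)
    chains = [
        simulate_chain(config, rng, chain_id=f"sim{i:04d}")
        for i in range(config.n_chains)
    ]
    manifest = {
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "chains": {
            c.truth.chain_id: {
                "length": c.query.length,
                "n_domains": c.truth.n_domains,
                "ranges": list(c.truth.ranges),
                "n_hits": len(c.msa.hits),
            }
            for c in chains
        },
    }
    return chains, manifest


def write_dataset(
    chains: list[SyntheticChain], manifest: dict, outdir: str | Path
) -> None:
    """Write a dataset in the package's external formats.

    Produces ``queries.fasta``, per-chain ``<id>.afa`` (anchored MSA) and
    ``<id>.ann`` (SS/SA), ``truth.tsv`` (domain ranges) and
    ``manifest.json`` — the exact inputs the CLI pipeline consumes.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "queries.fasta", "w") as fh:
        for c in chains:
            fh.write(f">{c.query.id}\n{c.query.sequence}\n")
    for c in chains:
        bio.write_anchored_msa(c.msa, outdir / f"{c.query.id}.afa")
        bio.write_annotation(c.query.id, c.ann, outdir / f"{c.query.id}.ann")
    bio.write_domain_ranges([c.truth for c in chains], outdir / "truth.tsv")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)


def read_dataset(outdir: str | Path) -> list[SyntheticChain]:
    """Re-read a written dataset into in-memory chains (round-trip)."""
    outdir = Path(outdir)
    defs = {d.chain_id: d for d in bio.read_domain_ranges(outdir / "truth.tsv")}
    chains = []
    for query in bio.read_fasta(outdir / "queries.fasta"):
        msa = bio.read_anchored_msa(outdir / f"{query.id}.afa")
        ann = bio.read_annotation(outdir / f"{query.id}.ann", query)
        chains.append(SyntheticChain(query, msa, ann, defs[query.id]))
    return chains
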