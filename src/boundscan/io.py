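"""Readers and writers for every external format the tool touches.

Formats:

* plain FASTA for query sequences (via Biopython);
* NCBI BLAST XML (``-outfmt 5``) reports, anchored onto the query;
* aligned FASTA for pre-anchored MSAs — first record is the ungapped
  query, each hit row carries its e-value in the description as
  ``E=<float>``;
* domain ranges as whitespace-separated lines ``chain  s1-e1, s2-e2``;
* SS/SA annotations as a 3-line flat file: id, SS string, SA string.
"""

from __future__ import annotations

import io as _io
import os
from typing import Iterable

from Bio import SeqIO
from Bio.Blast import NCBIXML

from .types import (
    AlignedHit,
    AnchoredMSA,
    DomainDefinition,
    GAP,
    QueryProtein,
    StructuralAnnotation,
    ValidationError,
)


class ParseError(ValueError):
    """Raised when an input file cannot be parsed."""


def read_fasta(path: str | os.PathLike) -> list[QueryProtein]:
    """Read query proteins from a FASTA file (order preserved)."""
    proteins = []
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            seq = str(rec.seq).strip().upper()
            proteins.append(QueryProtein(rec.id, seq))
    except (ValueError, ValidationError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    return proteins


def anchor_psiblast(
    report: str | os.PathLike | _io.TextIOBase,
    query: QueryProtein,
    iteration: int | None = None,
) -> AnchoredMSA:
    """Project the HSPs of a BLAST XML report onto query coordinates.

    Each HSP becomes one :class:`AlignedHit`: hit residues aligned to a
    query position are placed at that position, hit residues inserted
    relative to the query are discarded, and query positions outside the
    HSP are gap-filled.  Hits are sorted by ascending e-value, ties
    broken by order of appearance.

    PSI-BLAST reports contain one alignment round per iteration;
    ``iteration`` selects a 1-based round (default: the final one).
    Multiple HSPs from one database sequence become separate rows with
    an ``/1``, ``/2``, ... ordinal suffix on the hit id.
    """
    handle = open(report) if isinstance(report, (str, os.PathLike)) else report
    try:
        records = list(NCBIXML.parse(handle))
    except Exception as exc:  # lxml/expat errors vary
        raise ParseError(f"cannot parse BLAST XML: {exc}") from exc
    finally:
        if isinstance(report, (str, os.PathLike)):
            handle.close()
    if not records:
        raise ParseError("BLAST XML report contains no iterations")
    if iteration is None:
        record = records[-1]
    else:
        if not 1 <= iteration <= len(records):
            raise ParseError(
                f"iteration {iteration} out of range 1..{len(records)}"
            )
        record = records[iteration - 1]
    if record.query_length and record.query_length != query.length:
        raise ParseError(
            f"report query length {record.query_length} != query {query.id!r} "
            f"length {query.length}"
        )

    rows: list[tuple[float, int, AlignedHit]] = []
    order = 0
    for aln in record.alignments:
        multi = len(aln.hsps) > 1
        for k, hsp in enumerate(aln.hsps, start=1):
            hid = f"{aln.hit_id}/{k}" if multi else aln.hit_id
            aligned = _project_hsp(hsp, query.length)
            rows.append((hsp.expect, order, AlignedHit(hid, hsp.expect, aligned)))
            order += 1
    rows.sort(key=lambda t: (t[0], t[1]))
    return AnchoredMSA(query, [r[2] for r in rows])


def _project_hsp(hsp, query_length: int) -> str:
    """Render one HSP in query coordinates, dropping hit insertions."""
    row = [GAP] * query_length
    qpos = hsp.query_start  # 1-based
    for qc, hc in zip(hsp.query, hsp.sbjct):
        if qc == GAP:
            continue  # insertion in the hit relative to the query
        if hc != GAP:
            row[qpos - 1] = hc.upper()
        qpos += 1
    return "".join(row)


def read_domain_ranges(path: str | os.PathLike) -> list[DomainDefinition]:
    """Parse domain definitions, one chain per line.

    Line format: chain id, whitespace, comma-separated ``start-end``
    ranges (1-based inclusive), e.g. ``T0529  7-339, 364-561``.
    """
    defs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected 'chain ranges'")
            chain_id, spec = parts
            ranges = []
            for chunk in spec.split(","):
                chunk = chunk.strip()
                try:
                    s, e = chunk.split("-")
                    ranges.append((int(s), int(e)))
                except ValueError as exc:
                    raise ParseError(
                        f"{path}:{lineno}: bad range {chunk!r} for chain {chain_id}"
                    ) from exc
            try:
                defs.append(DomainDefinition(chain_id, tuple(ranges)))
            except ValidationError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return defs


def write_domain_ranges(defs: Iterable[DomainDefinition], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for d in defs:
            spec = ", ".join(f"{s}-{e}" for s, e in d.ranges)
            fh.write(f"{d.chain_id}\t{spec}\n")


def read_annotation(
    path: str | os.PathLike, query: QueryProtein
) -> StructuralAnnotation:
    """Read a 3-line flat file (id, SS string, SA string) for ``query``."""
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if len(lines) != 3:
        raise ParseError(f"{path}: expected 3 non-empty lines, found {len(lines)}")
    _id, ss, sa = lines
    for name, s in (("ss", ss), ("sa", sa)):
        if len(s) != query.length:
            raise ParseError(
                f"{path}: {name} length {len(s)} != query length {query.length}"
            )
    try:
        return StructuralAnnotation(ss, sa)
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_annotation(
    chain_id: str, ann: StructuralAnnotation, path: str | os.PathLike
) -> None:
    with open(path, "w") as fh:
        fh.write(f"{chain_id}\n{ann.ss}\n{ann.sa}\n")


def read_anchored_msa(path: str | os.PathLike) -> AnchoredMSA:
    """Read an anchored MSA from aligned FASTA (first record = query)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ParseError(f"{path}: empty aligned FASTA")
    qrec = records[0]
    query = QueryProtein(qrec.id, str(qrec.seq).upper())
    hits = []
    for rec in records[1:]:
        e_value = None
        for token in rec.description.split():
            if token.startswith("E="):
                try:
                    e_value = float(token[2:])
                except ValueError:
                    pass
        if e_value is None:
            raise ParseError(
                f"{path}: hit {rec.id!r} missing 'E=<float>' in description"
            )
        hits.append(AlignedHit(rec.id, e_value, str(rec.seq).upper()))
    try:
        return AnchoredMSA(query, hits)
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_anchored_msa(msa: AnchoredMSA, path: str | os.PathLike) -> None:
    """Write an anchored MSA in the aligned-FASTA dialect (round-trips)."""
    with open(path, "w") as fh:
        fh.write(f">{msa.query.id}\n{msa.query.sequence}\n")
        for hit in msa.hits:
            fh.write(f">{hit.hit_id} E={hit.e_value!r}\n{hit.aligned}\n")
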