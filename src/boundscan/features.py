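"""Per-site feature encoding.

Each signal site is encoded as a fixed-order real vector: for every
position of a 41-residue window centred on the site, 21 sequence-profile
values (normalised frequencies of the 20 amino acids plus the gap over
the MSA column) and 5 structure indicators (helix/strand/loop one-hot,
buried/exposed one-hot); then three signal-specific features (N-terminal
position / 100, C-terminal position / 100, count of signal sites within
5 residues); the chain length / 100; and finally the z-score of the
local signal density at the site.  At the defaults this is
41 x (21 + 5) + 3 + 1 + 1 = 1071 features.

The feature order is frozen: trained models depend on it, so a schema
(:func:`feature_schema`) and its hash travel with every model.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import numpy as np

from .signals import SignalSite
from .types import (
    AMBIGUITY,
    AMINO_ACIDS,
    AnchoredMSA,
    GAP,
    SA_STATES,
    SS_STATES,
    StructuralAnnotation,
    ValidationError,
)

PROFILE_ALPHABET = AMINO_ACIDS + GAP  # 21 symbols, frozen order
_AA_INDEX = {a: i for i, a in enumerate(PROFILE_ALPHABET)}


@dataclass(frozen=True)
class EncodingParams:
    """Window size and feature-scaling constants.

    window
        Odd number of residues centred on the signal site (default 41).
    density_radius
        Neighbourhood half-width, in residues, for both the local
        signal-density sum and the neighbouring-site count (default 5).
    scale
        Divisor applied to positional and length features (default 100).
    """

    window: int = 41
    density_radius: int = 5
    scale: float = 100.0

    def __post_init__(self) -> None:
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError("window must be odd and positive")
        if self.density_radius < 0:
            raise ValueError("density_radius must be non-negative")

    @property
    def n_features(self) -> int:
        """window x (21 profile + 5 structure) + 3 signal + length + z."""
        return self.window * (len(PROFILE_ALPHABET) + 5) + 3 + 1 + 1


def column_profile(msa: AnchoredMSA, position: int) -> np.ndarray:
    """Normalised symbol frequencies of MSA column ``position`` (1-based).

    Counts run over the query row plus every hit row; ambiguity codes
    (X, B, Z, J) are spread uniformly over their member residues.  The
    result has 21 components (20 amino acids then gap) summing to 1.
    """
    if not 1 <= position <= msa.query.length:
        raise ValueError(
            f"position {position} out of range 1..{msa.query.length}"
        )
    counts = np.zeros(len(PROFILE_ALPHABET))
    col = position - 1
    for ch in [msa.query.sequence[col]] + [h.aligned[col] for h in msa.hits]:
        idx = _AA_INDEX.get(ch)
        if idx is not None:
            counts[idx] += 1.0
        elif ch in AMBIGUITY:
            members = AMBIGUITY[ch]
            counts[[_AA_INDEX[m] for m in members]] += 1.0 / len(members)
        else:
            raise ValidationError(f"unknown symbol {ch!r} in MSA column {position}")
    return counts / counts.sum()


def signal_density_zscores(
    sites: list[SignalSite], query_length: int, radius: int = 5
) -> np.ndarray:
    """Z-scores of the local signal-density profile, one per residue.

    local_sum(i) is the total signal multiplicity at positions within
    ``radius`` of residue i; z-scores are taken over all residues with
    the population standard deviation.  A flat profile (sd = 0) maps
    to all zeros.
    """
    local = np.zeros(query_length)
    for site in sites:
        lo = max(0, site.position - 1 - radius)
        hi = min(query_length, site.position + radius)
        local[lo:hi] += site.multiplicity
    sd = local.std()
    if sd == 0:
        return np.zeros(query_length)
    return (local - local.mean()) / sd


def _structure_onehot(ann: StructuralAnnotation, col: int) -> np.ndarray:
    v = np.zeros(5)
    v[SS_STATES.index(ann.ss[col])] = 1.0
    v[3 + SA_STATES.index(ann.sa[col])] = 1.0
    return v


def encode_site(
    msa: AnchoredMSA,
    site: SignalSite,
    ann: StructuralAnnotation,
    all_sites: list[SignalSite],
    params: EncodingParams = EncodingParams(),
) -> np.ndarray:
    """Encode one signal site as the fixed-order feature vector.

    Window positions falling outside the chain contribute all-zero
    26-value blocks.  The neighbouring-site count includes the site
    itself (distinct positions within ``density_radius``).
    """
    L = msa.query.length
    if len(ann.ss) != L:
        raise ValidationError(
            f"annotation length {len(ann.ss)} != query length {L}"
        )
    half = params.window // 2
    blocks = []
    for pos in range(site.position - half, site.position + half + 1):
        if 1 <= pos <= L:
            blocks.append(column_profile(msa, pos))
            blocks.append(_structure_onehot(ann, pos - 1))
        else:
            blocks.append(np.zeros(len(PROFILE_ALPHABET) + 5))
    r = params.density_radius
    neighbors = sum(
        1 for s in all_sites if abs(s.position - site.position) <= r
    )
    z = signal_density_zscores(all_sites, L, r)[site.position - 1]
    tail = np.array(
        [
            site.position / params.scale,
            (L - site.position) / params.scale,
            float(neighbors),
            L / params.scale,
            z,
        ]
    )
    return np.concatenate(blocks + [tail])


def encode_dataset(
    chains: list[tuple[str, AnchoredMSA, list[SignalSite], StructuralAnnotation]],
    params: EncodingParams = EncodingParams(),
) -> tuple[np.ndarray, list[str], list[int]]:
    """Encode every site of every chain into one feature matrix.

    Rows are ordered by chain (input order) then site position.  Returns
    the matrix, the per-row chain id, and the per-row site position —
    the chain ids double as groups for protein-level cross-validation.
    """
    rows, chain_ids, positions = [], [], []
    for chain_id, msa, sites, ann in chains:
        try:
            for site in sorted(sites, key=lambda s: s.position):
                rows.append(encode_site(msa, site, ann, sites, params))
                chain_ids.append(chain_id)
                positions.append(site.position)
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"chain {chain_id!r}: {exc}") from exc
    X = np.array(rows) if rows else np.empty((0, params.n_features))
    return X, chain_ids, positions


def feature_schema(params: EncodingParams = EncodingParams()) -> dict:
    """Machine-readable description of the frozen feature layout."""
    half = params.window // 2
    names = []
    for off in range(-half, half + 1):
        names += [f"w{off:+d}.prof.{a}" for a in PROFILE_ALPHABET]
        names += [f"w{off:+d}.ss.{s}" for s in SS_STATES]
        names += [f"w{off:+d}.sa.{s}" for s in SA_STATES]
    names += ["n_pos", "c_pos", "neighbor_sites", "chain_length", "density_z"]
    return {
        "version": 1,
        "window": params.window,
        "density_radius": params.density_radius,
        "scale": params.scale,
        "n_features": params.n_features,
        "feature_names": names,
    }


def schema_hash(schema: dict) -> str:
    payload = json.dumps(schema, sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()
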