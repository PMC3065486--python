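"""Kimura 2-parameter divergences with pairwise deletion.

The K2P distance between two aligned sequences is

    d = -(1/2) * ln((1 - 2P - Q) * sqrt(1 - 2Q))

where P and Q are the proportions of comparable sites differing by a
transition (A<->G, C<->T) and by a transversion, respectively.  Comparable
sites are the positions where *both* sequences carry an unambiguous
A/C/G/T (pairwise deletion): gaps, Ns and other IUPAC ambiguity codes are
excluded per pair, never per column, so mixing full-length barcodes with
short fragments does not discard the alignment.

Distances are stored as proportions; reports multiply by 100.  Saturation
(a non-positive logarithm argument) raises :class:`SaturationError` rather
than emitting NaN, because a silently clamped distance would corrupt every
downstream summary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    SaturationError,
    UndefinedDistanceError,
    ValidationError,
)
from .records import Dataset

# A=0, C=1, G=2, T=3; anything else (gap, N, R, Y, ...) = 4.  The encoding
# is chosen so that transitions flip bit 1 only: x ^ 2 maps A<->G and C<->T,
# and two bases are a transition pair iff they differ while sharing parity.
_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _LUT[_b] = _i


def encode_sequences(seqs: list[str]) -> np.ndarray:
    """Encode equal-length sequences as an (n, L) uint8 array (A0 C1 G2 T3,
    ambiguous/gap 4)."""
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise AlignmentError(f"sequences of unequal length: {sorted(lengths)}")
    raw = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    return _LUT[raw].reshape(len(seqs), lengths.pop())


def k2p_from_counts(n_transitions: int, n_transversions: int, n_sites: int) -> float:
    """Evaluate the K2P closed form from per-pair difference counts."""
    if n_sites <= 0:
        raise UndefinedDistanceError("no comparable sites")
    p = n_transitions / n_sites
    q = n_transversions / n_sites
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(
            f"saturated pair: P={p:.4f}, Q={q:.4f} over {n_sites} sites"
        )
    return -0.5 * math.log(w1 * math.sqrt(w2)) + 0.0  # +0.0 normalizes -0.0


def k2p_pair(seq_a: str, seq_b: str) -> tuple[float, int]:
    """K2P distance and comparable-site count for one aligned pair.

    Returns ``(distance, n_comparable_sites)``.  Raises
    :class:`UndefinedDistanceError` when no site is comparable and
    :class:`SaturationError` when the model's logarithm is undefined.
    """
    enc = encode_sequences([seq_a, seq_b])
    a, b = enc[0], enc[1]
    valid = (a < 4) & (b < 4)
    sites = int(valid.sum())
    if sites == 0:
        raise UndefinedDistanceError("sequence pair shares no comparable sites")
    diff = valid & (a != b)
    ts = int((diff & ((a & 1) == (b & 1))).sum())
    tv = int(diff.sum()) - ts
    return k2p_from_counts(ts, tv, sites), sites


def pairwise_counts(enc: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All-pairs comparable sites, differences and transitions.

    Computed as 0/1 matrix products in float32 (exact for counts far below
    2**24), which keeps the all-pairs pass in BLAS.  Returns integer
    matrices ``(sites, n_diff, n_transitions)`` of shape (n, n).
    """
    valid = (enc < 4)
    vf = valid.astype(np.float32)
    sites = vf @ vf.T
    match = np.zeros_like(sites)
    trans = np.zeros_like(sites)
    base = [None] * 4
    for b in range(4):
        base[b] = (enc == b).astype(np.float32)
    for b in range(4):
        match += base[b] @ base[b].T
        trans += base[b] @ base[b ^ 2].T
    sites = np.rint(sites).astype(np.int64)
    match = np.rint(match).astype(np.int64)
    trans = np.rint(trans).astype(np.int64)
    return sites, sites - match, trans


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise K2P divergences (proportions) over specimens."""

    ids: tuple[str, ...]
    d: np.ndarray                 # (n, n) float64, zero diagonal
    comparable_sites: np.ndarray  # (n, n) int64

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.d.shape != (n, n) or self.comparable_sites.shape != (n, n):
            raise ValueError("matrix shapes do not match the ID list")

    def __len__(self) -> int:
        return len(self.ids)

    def index(self, specimen_id: str) -> int:
        try:
            return self._idx[specimen_id]
        except AttributeError:
            object.__setattr__(self, "_idx", {s: i for i, s in enumerate(self.ids)})
            return self._idx[specimen_id]

    def get(self, id_a: str, id_b: str) -> tuple[float, int]:
        i, j = self.index(id_a), self.index(id_b)
        return float(self.d[i, j]), int(self.comparable_sites[i, j])

    def submatrix(self, subset: list[str]) -> "DistanceMatrix":
        idx = np.array([self.index(s) for s in subset])
        return DistanceMatrix(
            ids=tuple(subset),
            d=self.d[np.ix_(idx, idx)],
            comparable_sites=self.comparable_sites[np.ix_(idx, idx)],
        )

    def to_tsv(self, path: str | Path) -> None:
        """Square distance matrix as TSV with a specimen-ID header row/column."""
        frame = pd.DataFrame(self.d, index=list(self.ids), columns=list(self.ids))
        frame.to_csv(path, sep="\t", index_label="specimen_id")


def distance_matrix(d: Dataset) -> DistanceMatrix:
    """Full symmetric K2P matrix over a dataset, in record order."""
    if len(d) < 2:
        raise ValidationError(f"distance analysis needs >= 2 records, got {len(d)}")
    enc = encode_sequences(d.sequences)
    sites, ndiff, nts = pairwise_counts(enc)
    n = len(d)
    off = ~np.eye(n, dtype=bool)

    empty = off & (sites == 0)
    if empty.any():
        i, j = np.argwhere(empty)[0]
        raise UndefinedDistanceError(
            f"no comparable sites between {d.ids[i]} and {d.ids[j]}"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(sites > 0, nts / np.maximum(sites, 1), 0.0)
        q = np.where(sites > 0, (ndiff - nts) / np.maximum(sites, 1), 0.0)
        w1 = 1.0 - 2.0 * p - q
        w2 = 1.0 - 2.0 * q
        bad = off & ((w1 <= 0.0) | (w2 <= 0.0))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise SaturationError(
                f"saturated pair {d.ids[i]} / {d.ids[j]}: "
                f"P={p[i, j]:.4f}, Q={q[i, j]:.4f}"
            )
        dist = -0.5 * np.log(np.where(bad | ~off, 1.0, w1 * np.sqrt(np.abs(w2))))
    dist = dist + 0.0  # normalize IEEE -0.0 for identical pairs
    np.fill_diagonal(dist, 0.0)
    return DistanceMatrix(ids=tuple(d.ids), d=dist, comparable_sites=sites)
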