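"""Positional k-mer fold-change featurization.

A segment is represented as an L x |K| array: for every core position i and
every odd k in the k set, the window of length k centered on position i
(drawing (k-1)/2 bases from each side, reaching into the flanks at the edges)
is looked up in that k's fold-change dictionary.  Aligning windows of
different k at their central nucleotide is why only odd k are allowed, and
why a flank of (max(k)-1)/2 bases is required on each side — 5 bp for the
default k set (5, 7, 9, 11).

Windows that are unstored in a dictionary, or that contain a non-ACGT
character (e.g. a masked flank), take the dictionary's default fold change so
the array shape stays fixed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .genome_io import EnhancerSegment
from .kmers import DEFAULT_KS, KmerDictionary

_VALID = frozenset("ACGT")


@dataclass(frozen=True)
class KSet:
    """Ascending odd k-mer lengths used for featurization."""

    ks: tuple[int, ...] = DEFAULT_KS

    def __post_init__(self) -> None:
        if not self.ks:
            raise ValueError("k set must be non-empty")
        if any(k < 1 or k % 2 == 0 for k in self.ks):
            raise ValueError("all k must be positive odd integers")
        if list(self.ks) != sorted(set(self.ks)):
            raise ValueError("k set must be strictly ascending")

    def __len__(self) -> int:
        return len(self.ks)

    @property
    def flank(self) -> int:
        return required_flank(self)


def required_flank(ks: KSet | Sequence[int]) -> int:
    """Flank width (bp per side) needed to center the largest k on every core
    position: (max(k) - 1) / 2."""
    if not isinstance(ks, KSet):
        ks = KSet(tuple(ks))
    return (max(ks.ks) - 1) // 2


@dataclass
class FeatureArray:
    """L x |K| positional fold changes for one segment."""

    values: np.ndarray
    segment_id: str = ""
    cell_type: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("feature values must be a 2-D array")

    @property
    def L(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]


def featurize(
    segment: EnhancerSegment,
    dicts: Mapping[int, KmerDictionary],
    ks: KSet = KSet(),
    cell_type: str = "",
    log2: bool = False,
) -> FeatureArray:
    """Positional fold-change array for one segment.

    Requires ``segment.flank >= required_flank(ks)`` and a dictionary for
    every k.  With ``log2=True`` values are log2-transformed (default off:
    models consume raw fold changes).
    """
    F_needed = required_flank(ks)
    if segment.flank < F_needed:
        raise ValueError(
            f"segment flank {segment.flank} < required flank {F_needed} "
            f"for k set {ks.ks}")
    missing = [k for k in ks.ks if k not in dicts]
    if missing:
        raise ValueError(f"missing dictionaries for k = {missing}")

    seq = segment.with_flanks
    F = segment.flank
    L = len(segment.core)
    values = np.empty((L, len(ks)), dtype=np.float64)
    for j, k in enumerate(ks.ks):
        d = dicts[k]
        default = d.default_fc
        fc = d.fold_change
        half = (k - 1) // 2
        for i in range(L):
            w = seq[F + i - half:F + i + half + 1]
            if _VALID.issuperset(w):
                values[i, j] = fc.get(w, default)
            else:
                values[i, j] = default
    out = FeatureArray(values, segment_id=segment.segment_id, cell_type=cell_type)
    if log2:
        out.values = np.log2(out.values)
    return out


def featurize_all(
    segments: Sequence[EnhancerSegment],
    dicts: Mapping[int, KmerDictionary],
    ks: KSet = KSet(),
    cell_type: str = "",
    log2: bool = False,
) -> list[FeatureArray]:
    return [featurize(s, dicts, ks, cell_type, log2) for s in segments]


def flatten(features: FeatureArray) -> np.ndarray:
    """Row-major (position-major) flattening to a vector of length L * |K|;
    invertible given L and |K| (see :func:`unflatten`)."""
    return features.values.reshape(-1).copy()


def unflatten(vector: np.ndarray, L: int, n_channels: int) -> FeatureArray:
    vector = np.asarray(vector, dtype=np.float64)
    if vector.size != L * n_channels:
        raise ValueError(f"vector of size {vector.size} != {L} * {n_channels}")
    return FeatureArray(vector.reshape(L, n_channels))


def stack(features: Sequence[FeatureArray]) -> np.ndarray:
    """Stack homogeneous feature arrays into (N, L, |K|)."""
    if not features:
        raise ValueError("no feature arrays to stack")
    return np.stack([f.values for f in features])


def save_features(features: Sequence[FeatureArray], path: str | Path) -> None:
    """Persist feature arrays (.npz) with segment ids and cell type."""
    arr = stack(features)
    np.savez(
        path,
        values=arr,
        segment_ids=np.array([f.segment_id for f in features]),
        cell_types=np.array([f.cell_type for f in features]),
    )


def load_features(path: str | Path) -> list[FeatureArray]:
    with np.load(path, allow_pickle=False) as data:
        return [
            FeatureArray(v, segment_id=str(s), cell_type=str(c))
            for v, s, c in zip(data["values"], data["segment_ids"],
                               data["cell_types"])
        ]


def export_tsv(features: FeatureArray, path: str | Path,
               ks: KSet = KSet()) -> None:
    """Human-readable export: one row per position, one column per k."""
    header = "position\t" + "\t".join(f"k{k}" for k in ks.ks)
    with open(path, "w") as fh:
        fh.write(header + "\n")
        for i, row in enumerate(features.values):
            fh.write(str(i) + "\t" + "\t".join(repr(v) for v in row) + "\n")
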