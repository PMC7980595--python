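"""k-mer counting and fold-change dictionaries.

For each odd k (default 5, 7, 9, 11) the pipeline counts k-mers separately in
the positive (enhancer) and control sets and stores, for every k-mer seen in
either, the ratio of its pseudocount-smoothed relative frequencies:

    fc(w) = ((c_pos(w) + alpha) / T_pos) / ((c_ctrl(w) + alpha) / T_ctrl)

where T_pos, T_ctrl are the total window counts of each set.  k-mers observed
in neither set fall back to ``default_fc = T_ctrl / T_pos`` (exactly 1 when
the sets are balanced), so unseen sequence is scored as neutral.

Counting is strand-specific (forward strand only), stride 1, per sequence;
windows containing a non-ACGT character are skipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

_VALID = frozenset("ACGT")

DEFAULT_KS = (5, 7, 9, 11)


class DictionaryFormatError(ValueError):
    """A dictionary file is malformed or inconsistent with expectations."""


@dataclass
class KmerCounts:
    """Occurrence counts of the length-k windows of a sequence set."""

    k: int
    counts: dict[str, int] = field(default_factory=dict)
    total: int = 0

    def __post_init__(self) -> None:
        if self.k < 1 or self.k % 2 == 0:
            raise ValueError("k must be a positive odd integer")


def count_kmers(sequences: Iterable[str], k: int) -> KmerCounts:
    """Count all ACGT-pure length-k windows, stride 1, per sequence.

    Windows never span sequence boundaries; windows containing a non-ACGT
    character are skipped.  Sequences shorter than k contribute nothing.
    """
    kc = KmerCounts(k=k)
    counts = kc.counts
    total = 0
    for seq in sequences:
        n = len(seq) - k + 1
        if n <= 0:
            continue
        if _VALID.issuperset(seq):
            for i in range(n):
                w = seq[i:i + k]
                counts[w] = counts.get(w, 0) + 1
            total += n
        else:
            # positions of invalid characters; skip windows covering them
            bad = [i for i, c in enumerate(seq) if c not in _VALID]
            bad_ptr = 0
            for i in range(n):
                while bad_ptr < len(bad) and bad[bad_ptr] < i:
                    bad_ptr += 1
                if bad_ptr < len(bad) and bad[bad_ptr] < i + k:
                    continue
                w = seq[i:i + k]
                counts[w] = counts.get(w, 0) + 1
                total += 1
    kc.total = total
    return kc


@dataclass
class KmerDictionary:
    """Per-k map from k-mer to positive/control enrichment ratio."""

    k: int
    fold_change: dict[str, float]
    default_fc: float
    alpha: float

    def __post_init__(self) -> None:
        if self.default_fc <= 0:
            raise ValueError("default_fc must be positive")

    def lookup(self, kmer: str) -> float:
        """Fold change of ``kmer``; the default for unstored or ambiguous windows."""
        return self.fold_change.get(kmer, self.default_fc)


def fold_changes(pos: KmerCounts, ctrl: KmerCounts, alpha: float = 1.0) -> KmerDictionary:
    """Build the fold-change dictionary from positive and control counts."""
    if pos.k != ctrl.k:
        raise ValueError(f"k mismatch: positives k={pos.k}, controls k={ctrl.k}")
    if pos.total < 1 or ctrl.total < 1:
        raise ValueError("both count sets must contain at least one window")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    fc: dict[str, float] = {}
    tp, tc = pos.total, ctrl.total
    for w in pos.counts.keys() | ctrl.counts.keys():
        cp = pos.counts.get(w, 0)
        cc = ctrl.counts.get(w, 0)
        fc[w] = ((cp + alpha) / tp) / ((cc + alpha) / tc)
    return KmerDictionary(k=pos.k, fold_change=fc, default_fc=tc / tp, alpha=alpha)


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def build_dictionaries(
    positives: Sequence[str],
    controls: Sequence[str],
    ks: Sequence[int] = DEFAULT_KS,
    alpha: float = 1.0,
    revcomp: bool = False,
) -> dict[int, KmerDictionary]:
    """Fold-change dictionaries for every k, from raw positive/control cores.

    Counting is forward-strand only by default (positional lookups are
    strand-specific); with ``revcomp=True`` each corpus is augmented with its
    reverse complements so a k-mer and its reverse complement share counts.
    """
    pos = list(positives)
    ctrl = list(controls)
    if revcomp:
        pos = pos + [reverse_complement(s) for s in pos]
        ctrl = ctrl + [reverse_complement(s) for s in ctrl]
    return {
        k: fold_changes(count_kmers(pos, k), count_kmers(ctrl, k), alpha)
        for k in ks
    }


def save_dictionary(dictionary: KmerDictionary, path: str | Path) -> None:
    """Write a dictionary as TSV: header line with k/alpha/default_fc, then
    lexicographically ordered ``kmer<TAB>fold_change`` rows."""
    with open(path, "w") as fh:
        fh.write(f"#k={dictionary.k}\talpha={dictionary.alpha!r}"
                 f"\tdefault_fc={dictionary.default_fc!r}\n")
        for w in sorted(dictionary.fold_change):
            fh.write(f"{w}\t{dictionary.fold_change[w]!r}\n")


def load_dictionary(path: str | Path, k: int | None = None) -> KmerDictionary:
    """Load a TSV dictionary; value-exact round trip with :func:`save_dictionary`.

    Raises :class:`DictionaryFormatError` on a missing/invalid header, a
    duplicate k-mer, a k-mer whose length disagrees with the header, or (when
    ``k`` is given) a header k mismatch.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header.startswith("#"):
            raise DictionaryFormatError(f"{path}: missing header line")
        try:
            meta = dict(item.split("=", 1) for item in header[1:].split("\t"))
            file_k = int(meta["k"])
            alpha = float(meta["alpha"])
            default_fc = float(meta["default_fc"])
        except (KeyError, ValueError) as exc:
            raise DictionaryFormatError(f"{path}: malformed header") from exc
        if k is not None and file_k != k:
            raise DictionaryFormatError(
                f"{path}: expected k={k}, file has k={file_k}")
        fc: dict[str, float] = {}
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            try:
                w, value = line.split("\t")
                fcv = float(value)
            except ValueError as exc:
                raise DictionaryFormatError(f"{path} line {lineno}") from exc
            if len(w) != file_k or not _VALID.issuperset(w):
                raise DictionaryFormatError(
                    f"{path} line {lineno}: k-mer {w!r} inconsistent with k={file_k}")
            if w in fc:
                raise DictionaryFormatError(
                    f"{path} line {lineno}: duplicate k-mer {w!r}")
            fc[w] = fcv
    return KmerDictionary(k=file_k, fold_change=fc, default_fc=default_fc, alpha=alpha)


def save_dictionaries(dicts: Mapping[int, KmerDictionary], directory: str | Path,
                      prefix: str = "dict") -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for k in sorted(dicts):
        p = directory / f"{prefix}_k{k}.tsv"
        save_dictionary(dicts[k], p)
        paths.append(p)
    return paths


def load_dictionaries(directory: str | Path, ks: Sequence[int] = DEFAULT_KS,
                      prefix: str = "dict") -> dict[int, KmerDictionary]:
    directory = Path(directory)
    return {k: load_dictionary(directory / f"{prefix}_k{k}.tsv", k=k) for k in ks}
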