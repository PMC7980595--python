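"""GC-matched background sampling.

Two disjoint background sets are drawn from masked, enhancer-excluded genome
space: *control* sequences calibrate the k-mer fold-change dictionaries, and
*negative* sequences serve as the classifier's negative class.  Keeping the
two roles disjoint prevents the dictionaries from having seen the very
sequences the classifier is tested against.

Matching is done on GC content: positives are binned into a GC histogram and
background windows are accepted until each bin's quota (largest-remainder
apportionment of the requested count over the positive profile) is filled.
Matching composition this way forces the classifier to learn motif content
rather than a GC shortcut.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from intervaltree import IntervalTree

from .genome_io import EnhancerSegment, GenomicInterval, MaskedGenome

_VALID = frozenset("ACGT")


class UndefinedGcError(ValueError):
    """GC content is undefined for a sequence with no unambiguous bases."""


class InsufficientBackgroundError(RuntimeError):
    """Quota filling failed within the attempt budget."""


def gc_content(seq: str) -> float:
    """Fraction (#G + #C) / (#A + #C + #G + #T); 'N' bases are excluded
    from both numerator and denominator."""
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T")
    if gc + at == 0:
        raise UndefinedGcError("sequence has no unambiguous bases")
    return gc / (gc + at)


@dataclass
class GcProfile:
    """Histogram of positive-segment core GC over bins [0,w), [w,2w), ..., [1-w, 1]."""

    bin_width: float
    counts: np.ndarray  # one entry per bin

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    def bin_index(self, gc: float) -> int:
        # the final bin is closed above so gc == 1.0 lands in it
        return min(int(gc / self.bin_width), self.n_bins - 1)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def build_gc_profile(
    positives: Sequence[EnhancerSegment] | Sequence[str],
    bin_width: float = 0.02,
) -> GcProfile:
    """Bin the core GC content of positive segments (or raw sequences)."""
    if not positives:
        raise ValueError("need at least one positive segment")
    if not (0 < bin_width <= 1):
        raise ValueError("bin_width must be in (0, 1]")
    n_bins = math.ceil(1.0 / bin_width)
    counts = np.zeros(n_bins, dtype=np.int64)
    for p in positives:
        seq = p.core if isinstance(p, EnhancerSegment) else p
        gc = gc_content(seq)
        counts[min(int(gc / bin_width), n_bins - 1)] += 1
    return GcProfile(bin_width=bin_width, counts=counts)


def largest_remainder_quotas(weights: np.ndarray, n: int) -> np.ndarray:
    """Apportion ``n`` items over bins proportionally to ``weights``
    (largest-remainder / Hamilton rounding)."""
    weights = np.asarray(weights, dtype=float)
    if n == 0:
        return np.zeros(len(weights), dtype=np.int64)
    total = weights.sum()
    if total <= 0:
        raise ValueError("weights must have positive sum")
    exact = weights * (n / total)
    quotas = np.floor(exact).astype(np.int64)
    remainder = n - quotas.sum()
    if remainder > 0:
        order = np.argsort(-(exact - quotas), kind="stable")
        quotas[order[:remainder]] += 1
    return quotas


@dataclass
class BackgroundSet:
    """Sampled background windows playing one of the two roles."""

    role: str  # "control" or "negative"
    segments: list[EnhancerSegment]
    seed: int
    quotas: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))

    def __post_init__(self) -> None:
        if self.role not in ("control", "negative"):
            raise ValueError("role must be 'control' or 'negative'")

    def __len__(self) -> int:
        return len(self.segments)


def _exclusion_trees(exclude: Sequence[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in exclude:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    return trees


def sample_background(
    genome: MaskedGenome,
    exclude: Sequence[GenomicInterval],
    profile: GcProfile,
    n_control: int,
    n_negative: int,
    L: int = 200,
    F: int = 5,
    seed: int = 0,
    max_attempts_factor: int = 1000,
) -> tuple[BackgroundSet, BackgroundSet]:
    """Draw GC-matched control and negative window sets from masked genome space.

    Candidate windows are length-L ACGT-pure cores (with room for length-F
    flanks on the chromosome) that do not intersect any excluded interval.
    Windows are drawn uniformly at random, assigned to GC bins, and accepted
    until each bin's quota is met — control set first, then negative.  The two
    sets are disjoint at window granularity and the draw is deterministic
    given ``seed``.

    The genome is expected to be exon/repeat-masked already; ``exclude``
    should carry the enhancer intervals of every cell type in the run.

    Raises :class:`InsufficientBackgroundError` (naming the starved GC bins)
    if quotas cannot be filled within ``max_attempts_factor * (n_control +
    n_negative)`` draws.
    """
    rng = np.random.default_rng(seed)
    trees = _exclusion_trees(exclude)

    quotas_ctrl = largest_remainder_quotas(profile.counts, n_control)
    quotas_neg = largest_remainder_quotas(profile.counts, n_negative)
    need_ctrl = quotas_ctrl.copy()
    need_neg = quotas_neg.copy()

    # uniform over valid start positions across chromosomes
    chroms = [c for c in genome.chroms if genome.length(c) >= L + 2 * F]
    if not chroms:
        raise InsufficientBackgroundError("no chromosome long enough for L + 2F")
    n_starts = np.array([genome.length(c) - L - 2 * F + 1 for c in chroms],
                        dtype=float)
    chrom_p = n_starts / n_starts.sum()

    taken: set[tuple[str, int]] = set()
    control: list[EnhancerSegment] = []
    negative: list[EnhancerSegment] = []
    requested = n_control + n_negative
    budget = max_attempts_factor * max(requested, 1)

    attempts = 0
    while (need_ctrl.sum() > 0 or need_neg.sum() > 0) and attempts < budget:
        attempts += 1
        ci = rng.choice(len(chroms), p=chrom_p)
        chrom = chroms[ci]
        start = F + int(rng.integers(0, int(n_starts[ci])))
        if (chrom, start) in taken:
            continue
        seq = genome.sequences[chrom]
        core = seq[start:start + L]
        if not _VALID.issuperset(core):
            continue
        tree = trees.get(chrom)
        if tree is not None and tree.overlaps(start, start + L):
            continue
        b = profile.bin_index(gc_content(core))
        if need_ctrl[b] > 0:
            bucket, counts = control, need_ctrl
        elif need_neg[b] > 0:
            bucket, counts = negative, need_neg
        else:
            continue
        counts[b] -= 1
        taken.add((chrom, start))
        bucket.append(EnhancerSegment(
            core=core,
            left_flank=seq[start - F:start],
            right_flank=seq[start + L:start + L + F],
            origin=GenomicInterval(chrom, start, start + L, "background"),
        ))

    if need_ctrl.sum() > 0 or need_neg.sum() > 0:
        starved = sorted(set(np.nonzero(need_ctrl)[0]) | set(np.nonzero(need_neg)[0]))
        bins = ", ".join(
            f"[{b * profile.bin_width:.2f},{(b + 1) * profile.bin_width:.2f})"
            for b in starved
        )
        raise InsufficientBackgroundError(
            f"could not fill GC-bin quotas after {attempts} draws; starved bins: {bins}"
        )

    return (
        BackgroundSet("control", control, seed, quotas_ctrl),
        BackgroundSet("negative", negative, seed, quotas_neg),
    )
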