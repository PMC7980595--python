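"""Synthetic genome and enhancer-annotation generator.

Produces a toy genome (i.i.d. background at a chosen GC), BED masks standing
in for exon and repeat annotations, and per-pseudo-cell-type enhancer BEDs in
which each enhancer window carries a few motif instances drawn from that
type's motif vocabulary.  A JSON truth record stores every planted instance,
so downstream claims (dictionary enrichment of planted motifs, classifier
signal recovery) can be verified against ground truth.

The generator is a benchmark substrate, not a biophysical model: no PWM
degeneracy, no nucleosome structure, and i.i.d. background by default (an
order-1 Markov background flag exists to stress GC matching).  Everything is
deterministic given the seed, down to byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
from intervaltree import IntervalTree

from .genome_io import (GenomicInterval, MaskedGenome, write_bed, write_fasta)
from .kmers import KmerDictionary

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: chromatin-state label given to simulated enhancer intervals
ENHANCER_LABEL = "4_Strong_Enhancer"


class PlacementError(RuntimeError):
    """Could not place non-overlapping windows within the retry budget."""


@dataclass
class SimConfig:
    """Study conditions for the synthetic benchmark.

    Defaults emulate a small two-cell-type study: a 1 Mb genome split over
    two chromosomes at background GC 0.5, 500 enhancers of 200 bp per type,
    and per-type vocabularies of three 7-mers and three 9-mers (disjoint
    between types), three instances planted per enhancer.
    """

    genome_length: int = 1_000_000
    n_chromosomes: int = 2
    gc: float = 0.5
    cell_types: tuple[str, ...] = ("typeA", "typeB")
    vocabularies: dict[str, tuple[str, ...]] | None = None
    motif_lengths: tuple[int, ...] = (7, 9)
    motifs_per_length: int = 3
    motifs_per_enhancer: int = 3
    enhancers_per_type: int = 500
    enhancer_length: int = 200
    mask_fraction: float = 0.05
    mask_length_range: tuple[int, int] = (100, 500)
    markov_background: bool = False
    mutation_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.gc <= 1):
            raise ValueError("gc must be in [0, 1]")
        if not (0 <= self.mask_fraction < 1):
            raise ValueError("mask_fraction must be in [0, 1)")
        total = (len(self.cell_types) * self.enhancers_per_type
                 * self.enhancer_length)
        if total > self.genome_length // 2:
            raise ValueError(
                "requested enhancers would cover more than half the genome")
        if self.vocabularies is not None:
            for ct, vocab in self.vocabularies.items():
                for m in vocab:
                    if not set(m) <= set("ACGT") or not (6 <= len(m) <= 12):
                        raise ValueError(
                            f"motif {m!r} for {ct} must be ACGT of length 6-12")


@dataclass
class SimResult:
    """Simulated genome, annotations, and the planted-motif truth record."""

    genome: MaskedGenome
    exon_mask: list[GenomicInterval]
    repeat_mask: list[GenomicInterval]
    enhancers: dict[str, list[GenomicInterval]]
    truth: dict
    config: SimConfig = field(repr=False, default=None)

    @property
    def all_enhancer_intervals(self) -> list[GenomicInterval]:
        return [iv for ivs in self.enhancers.values() for iv in ivs]

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write genome.fa, exons.bed, repeats.bed, per-type enhancer BEDs and
        truth.json; byte-identical across runs with the same config."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {"genome": outdir / "genome.fa",
                 "exons": outdir / "exons.bed",
                 "repeats": outdir / "repeats.bed",
                 "truth": outdir / "truth.json"}
        write_fasta(self.genome, paths["genome"])
        write_bed(self.exon_mask, paths["exons"])
        write_bed(self.repeat_mask, paths["repeats"])
        for ct, ivs in self.enhancers.items():
            p = outdir / f"enhancers_{ct}.bed"
            write_bed(ivs, p)
            paths[f"enhancers_{ct}"] = p
        paths["truth"].write_text(
            json.dumps(self.truth, indent=2, sort_keys=True) + "\n")
        return paths


def _random_motifs(rng: np.random.Generator, config: SimConfig) -> dict[str, tuple[str, ...]]:
    """Disjoint per-type vocabularies; no motif is a substring of another."""
    chosen: list[str] = []
    vocab: dict[str, list[str]] = {ct: [] for ct in config.cell_types}
    for ct in config.cell_types:
        for length in config.motif_lengths:
            need = config.motifs_per_length
            while need:
                m = "".join("ACGT"[b] for b in rng.integers(0, 4, size=length))
                if len(set(m)) < 3:  # avoid near-homopolymers
                    continue
                if any(m in other or other in m for other in chosen):
                    continue
                chosen.append(m)
                vocab[ct].append(m)
                need -= 1
    return {ct: tuple(v) for ct, v in vocab.items()}


def _draw_background(rng: np.random.Generator, n: int, gc: float,
                     markov: bool) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    if not markov:
        return rng.choice(4, size=n, p=p).astype(np.uint8)
    # order-1 Markov chain with mild CG avoidance but stationary GC ~ gc
    out = np.empty(n, dtype=np.uint8)
    trans = np.tile(p, (4, 1))
    trans[1, 2] *= 0.25  # deplete CpG
    trans /= trans.sum(axis=1, keepdims=True)
    out[0] = rng.choice(4, p=p)
    for i in range(1, n):
        out[i] = rng.choice(4, p=trans[out[i - 1]])
    return out


def _place_windows(rng: np.random.Generator, chrom_lengths: dict[str, int],
                   n: int, length: int, occupied: dict[str, IntervalTree],
                   margin: int = 10, retries_per_window: int = 200,
                   ) -> list[tuple[str, int]]:
    chroms = [c for c, ln in chrom_lengths.items()
              if ln >= length + 2 * margin]
    if not chroms:
        raise PlacementError("no chromosome can hold a window of this length")
    weights = np.array([chrom_lengths[c] - length - 2 * margin + 1
                        for c in chroms], dtype=float)
    weights /= weights.sum()
    placed: list[tuple[str, int]] = []
    budget = retries_per_window * max(n, 1)
    attempts = 0
    while len(placed) < n:
        if attempts >= budget:
            raise PlacementError(
                f"placed only {len(placed)}/{n} windows after {attempts} attempts")
        attempts += 1
        ci = rng.choice(len(chroms), p=weights)
        chrom = chroms[ci]
        start = margin + int(rng.integers(
            0, chrom_lengths[chrom] - length - 2 * margin + 1))
        tree = occupied.setdefault(chrom, IntervalTree())
        if tree.overlaps(start, start + length):
            continue
        tree.addi(start, start + length)
        placed.append((chrom, start))
    return placed


def simulate(config: SimConfig) -> SimResult:
    """Generate the synthetic study substrate; deterministic given the seed."""
    rng = np.random.default_rng(config.seed)
    vocab = (dict(config.vocabularies) if config.vocabularies is not None
             else _random_motifs(rng, config))

    base_len = config.genome_length // config.n_chromosomes
    chrom_lengths = {
        f"chr{i + 1}": base_len + (config.genome_length % config.n_chromosomes
                                   if i == config.n_chromosomes - 1 else 0)
        for i in range(config.n_chromosomes)
    }
    buffers = {c: _BASES[_draw_background(rng, ln, config.gc,
                                          config.markov_background)].copy()
               for c, ln in chrom_lengths.items()}

    # enhancer placement: non-overlapping across all types
    occupied: dict[str, IntervalTree] = {}
    L = config.enhancer_length
    enhancers: dict[str, list[GenomicInterval]] = {}
    instances: list[dict] = []
    for ct in config.cell_types:
        spots = _place_windows(rng, chrom_lengths, config.enhancers_per_type,
                               L, occupied)
        ivs = []
        for chrom, start in sorted(spots):
            ivs.append(GenomicInterval(chrom, start, start + L, ENHANCER_LABEL))
            taken: list[tuple[int, int]] = []
            for _ in range(config.motifs_per_enhancer):
                motif = vocab[ct][int(rng.integers(0, len(vocab[ct])))]
                m = len(motif)
                for _try in range(200):
                    off = int(rng.integers(0, L - m + 1))
                    if all(off + m <= lo or off >= hi for lo, hi in taken):
                        break
                else:
                    raise PlacementError("could not place motif inside enhancer")
                taken.append((off, off + m))
                planted = list(motif)
                if config.mutation_rate > 0:
                    for j in range(m):
                        if rng.random() < config.mutation_rate:
                            planted[j] = "ACGT"[int(rng.integers(0, 4))]
                planted_s = "".join(planted)
                buffers[chrom][start + off:start + off + m] = \
                    np.frombuffer(planted_s.encode(), dtype=np.uint8)
                instances.append({
                    "cell_type": ct, "chrom": chrom,
                    "enhancer_start": start, "offset": off,
                    "start": start + off, "motif": motif,
                    "planted": planted_s,
                })
        enhancers[ct] = ivs

    # exon/repeat masks outside enhancers (half the mask budget each)
    def _mask_set(target_bp: int) -> list[GenomicInterval]:
        ivs: list[GenomicInterval] = []
        covered = 0
        lo, hi = config.mask_length_range
        while covered < target_bp:
            ln = int(rng.integers(lo, hi + 1))
            (chrom, start), = _place_windows(rng, chrom_lengths, 1, ln, occupied)
            ivs.append(GenomicInterval(chrom, start, start + ln))
            covered += ln
        return sorted(ivs, key=lambda iv: (iv.chrom, iv.start))

    half = int(config.mask_fraction * config.genome_length / 2)
    exon_mask = _mask_set(half)
    repeat_mask = _mask_set(half)

    genome = MaskedGenome(
        sequences={c: b.tobytes().decode("ascii") for c, b in buffers.items()})

    truth = {
        "seed": config.seed,
        "vocabularies": {ct: list(v) for ct, v in vocab.items()},
        "instances": instances,
        "config": {k: v for k, v in asdict(config).items()
                   if k != "vocabularies"},
    }
    return SimResult(genome=genome, exon_mask=exon_mask,
                     repeat_mask=repeat_mask, enhancers=enhancers,
                     truth=truth, config=config)


def empirical_motif_enrichment(
    truth: dict,
    dicts: Mapping[int, KmerDictionary],
    cell_type: str,
) -> list[dict]:
    """Dictionary fold changes of the planted motifs of one pseudo cell type.

    For each vocabulary motif whose length is in the dictionary k set, report
    its fold change and its percentile among all stored fold changes for that
    k; motifs of other lengths are skipped with a note.
    """
    report = []
    for motif in truth["vocabularies"][cell_type]:
        k = len(motif)
        if k not in dicts:
            report.append({"motif": motif, "k": k, "note": "length not in k set"})
            continue
        d = dicts[k]
        fc = d.lookup(motif)
        stored = np.fromiter(d.fold_change.values(), dtype=float)
        percentile = float(np.mean(stored <= fc)) if len(stored) else 1.0
        report.append({"motif": motif, "k": k, "fold_change": float(fc),
                       "percentile": percentile})
    return report
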