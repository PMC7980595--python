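"""End-to-end glue: from genome + annotations to segments, backgrounds and
dictionaries for one cell type.

This is the programmatic counterpart of the CLI stages and the entry point
used by the evaluation drivers: mask the genome, cut enhancer intervals into
fixed-length segments, sample GC-matched control/negative backgrounds
(excluding every cell type's enhancers), and build the per-k fold-change
dictionaries from all positives versus controls.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .background import BackgroundSet, build_gc_profile, sample_background
from .features import KSet, required_flank
from .genome_io import (EnhancerSegment, GenomicInterval, MaskedGenome,
                        extract_segments, mask_regions)
from .kmers import KmerDictionary, build_dictionaries
from .simulate import SimResult


@dataclass
class CellTypeData:
    """Everything needed to train/evaluate classifiers for one cell type."""

    cell_type: str
    positives: list[EnhancerSegment]
    control: BackgroundSet
    negative: BackgroundSet
    dicts: dict[int, KmerDictionary]


def prepare_cell_type(
    genome: MaskedGenome,
    enhancers: Mapping[str, Sequence[GenomicInterval]],
    cell_type: str,
    ks: KSet = KSet(),
    L: int = 200,
    alpha: float = 1.0,
    gc_bin_width: float = 0.02,
    seed: int = 0,
    exon_mask: Sequence[GenomicInterval] = (),
    repeat_mask: Sequence[GenomicInterval] = (),
) -> CellTypeData:
    """Build positives, GC-matched control/negative sets, and dictionaries.

    ``genome`` is the raw genome; exon/repeat masks are applied here.
    Background sampling excludes the enhancer intervals of EVERY cell type in
    ``enhancers``.  Control and negative sets are sized to match the positive
    count (equal class sizes).
    """
    F = required_flank(ks)
    masked = genome
    if exon_mask:
        masked = mask_regions(masked, list(exon_mask), name="exons")
    if repeat_mask:
        masked = mask_regions(masked, list(repeat_mask), name="repeats")

    positives = extract_segments(list(enhancers[cell_type]), masked, L=L, F=F)
    if not positives:
        raise ValueError(f"no usable segments for cell type {cell_type}")

    exclude = [iv for ivs in enhancers.values() for iv in ivs]
    profile = build_gc_profile(positives, bin_width=gc_bin_width)
    control, negative = sample_background(
        masked, exclude, profile,
        n_control=len(positives), n_negative=len(positives),
        L=L, F=F, seed=seed,
    )
    dicts = build_dictionaries(
        [s.core for s in positives], [s.core for s in control.segments],
        ks=ks.ks, alpha=alpha,
    )
    return CellTypeData(cell_type=cell_type, positives=positives,
                        control=control, negative=negative, dicts=dicts)


def prepare_from_sim(sim: SimResult, cell_type: str, ks: KSet = KSet(),
                     alpha: float = 1.0, gc_bin_width: float = 0.02,
                     seed: int = 0) -> CellTypeData:
    """Convenience wrapper running :func:`prepare_cell_type` on a simulation."""
    return prepare_cell_type(
        genome=sim.genome,
        enhancers=sim.enhancers,
        cell_type=cell_type,
        ks=ks,
        L=sim.config.enhancer_length,
        alpha=alpha,
        gc_bin_width=gc_bin_width,
        seed=seed,
        exon_mask=sim.exon_mask,
        repeat_mask=sim.repeat_mask,
    )
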