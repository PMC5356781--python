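"""Copy-number discretization into parsimony characters.

Segments are thresholded into AMP (copy >= 3), DEL (copy <= 0.5) or
NEUTRAL, then projected onto a fixed 100-kb tiling of the genome: a bin
takes the state of the segment covering its midpoint. Two encodings are
provided: a pair of binary characters per bin (amplified?, deleted?) and a
single ordered ternary character (DEL=0 < NEUTRAL=1 < AMP=2).
"""
from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .matrix import CharacterMatrix, ROOT_TAXON
from .types import SegmentCNV, ValidationError, check_no_overlap

#: discretization thresholds, inclusive on both sides
AMP_THRESHOLD = 3.0
DEL_THRESHOLD = 0.5
#: genomic bin size in bp
DEFAULT_BIN_SIZE = 100_000

Genome = Sequence[Tuple[str, int]]


class CNState(enum.IntEnum):
    """Ordered copy-number state of a locus (loss < neutral < gain)."""

    DEL = 0
    NEUTRAL = 1
    AMP = 2


def call_segment_state(
    copy: float,
    amp_threshold: float = AMP_THRESHOLD,
    del_threshold: float = DEL_THRESHOLD,
) -> CNState:
    if copy < 0:
        raise ValidationError(f"negative copy value {copy}")
    if copy >= amp_threshold:
        return CNState.AMP
    if copy <= del_threshold:
        return CNState.DEL
    return CNState.NEUTRAL


@dataclass(frozen=True)
class GenomicBin:
    chrom: str
    start: int
    end: int

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    @property
    def label(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


def tile_genome(genome: Genome, bin_size: int = DEFAULT_BIN_SIZE) -> List[GenomicBin]:
    """Tile each chromosome with half-open bins of ``bin_size`` bp; the last
    bin is clipped at the chromosome end. Bins cover the chromosome without
    gaps or overlaps."""
    if bin_size <= 0:
        raise ValidationError("bin size must be positive")
    bins = []
    for chrom, length in genome:
        if length <= 0:
            raise ValidationError(f"non-positive chromosome length for {chrom}")
        for start in range(0, length, bin_size):
            bins.append(GenomicBin(chrom, start, min(start + bin_size, length)))
    return bins


def _bin_states(
    segments: Sequence[SegmentCNV],
    bins: Sequence[GenomicBin],
    amp_threshold: float,
    del_threshold: float,
) -> np.ndarray:
    """State of each bin for one sample: the state of the segment covering
    the bin midpoint, NEUTRAL when no segment covers it."""
    check_no_overlap(list(segments))
    by_chrom: Dict[str, List[SegmentCNV]] = {}
    for seg in segments:
        by_chrom.setdefault(seg.chrom, []).append(seg)
    starts = {c: np.array([s.start for s in sorted(v, key=lambda s: s.start)])
              for c, v in by_chrom.items()}
    sorted_segs = {c: sorted(v, key=lambda s: s.start) for c, v in by_chrom.items()}
    out = np.full(len(bins), int(CNState.NEUTRAL), dtype=np.int64)
    for j, b in enumerate(bins):
        if b.chrom not in sorted_segs:
            continue
        mid = b.midpoint
        i = int(np.searchsorted(starts[b.chrom], mid, side="right")) - 1
        if i >= 0:
            seg = sorted_segs[b.chrom][i]
            if seg.start <= mid < seg.end:
                out[j] = int(call_segment_state(seg.copy, amp_threshold, del_threshold))
    return out


def binarize_bins(
    segments_by_sample: Mapping[str, Sequence[SegmentCNV]],
    genome: Genome,
    bin_size: int = DEFAULT_BIN_SIZE,
    encoding: str = "binary-pair",
    include_root: bool = False,
    drop_constant: bool = True,
    amp_threshold: float = AMP_THRESHOLD,
    del_threshold: float = DEL_THRESHOLD,
) -> CharacterMatrix:
    """Build the binned copy-number character matrix.

    encoding="binary-pair": two binary characters per bin, AMP-presence and
    DEL-presence. encoding="ordered-ternary": one additive character per
    bin with DEL=0 < NEUTRAL=1 < AMP=2. Bins neutral in every sample are
    dropped by default (they cannot change parsimony lengths). With
    ``include_root`` an all-neutral NORMAL taxon is appended after the
    constant-bin filter.
    """
    if encoding not in ("binary-pair", "ordered-ternary"):
        raise ValidationError(f"unknown encoding {encoding!r}")
    genome_chroms = {c for c, _ in genome}
    for sample, segs in segments_by_sample.items():
        missing = {s.chrom for s in segs} - genome_chroms
        if missing:
            raise ValidationError(
                f"sample {sample}: segment chromosomes {sorted(missing)} "
                f"absent from genome"
            )
    bins = tile_genome(genome, bin_size)
    taxa = list(segments_by_sample)
    grid = np.vstack([
        _bin_states(segments_by_sample[s], bins, amp_threshold, del_threshold)
        for s in taxa
    ]) if taxa else np.zeros((0, len(bins)), dtype=np.int64)

    if drop_constant:
        keep = (grid != int(CNState.NEUTRAL)).any(axis=0)
    else:
        keep = np.ones(len(bins), dtype=bool)
    grid = grid[:, keep]
    kept_bins = [b for b, k in zip(bins, keep) if k]

    if encoding == "ordered-ternary":
        m = CharacterMatrix(taxa, [b.label for b in kept_bins], grid, "ordered-ternary")
        if include_root:
            m = m.with_taxon(ROOT_TAXON,
                             np.full(len(kept_bins), int(CNState.NEUTRAL)))
        return m

    labels, cols = [], []
    for j, b in enumerate(kept_bins):
        labels.append(b.label + ":AMP")
        cols.append((grid[:, j] == int(CNState.AMP)).astype(np.int64))
        labels.append(b.label + ":DEL")
        cols.append((grid[:, j] == int(CNState.DEL)).astype(np.int64))
    states = np.column_stack(cols) if cols else np.zeros((len(taxa), 0), dtype=np.int64)
    m = CharacterMatrix(taxa, labels, states, "binary")
    if include_root:
        m = m.with_taxon(ROOT_TAXON, np.zeros(len(labels), dtype=np.int64))
    return m


def cnv_counts_per_chromosome(
    segments_by_sample: Mapping[str, Sequence[SegmentCNV]],
    chromosomes: Sequence[str] = (),
    amp_threshold: float = AMP_THRESHOLD,
    del_threshold: float = DEL_THRESHOLD,
) -> pd.DataFrame:
    """Count altered (non-neutral) segments per sample per chromosome.

    Rows are samples, columns chromosomes. ``chromosomes`` fixes the column
    set (e.g. the full genome) so all-neutral chromosomes appear as zeros;
    by default the columns are the chromosomes seen in any sample.
    """
    chroms = list(chromosomes) if chromosomes else sorted(
        {s.chrom for segs in segments_by_sample.values() for s in segs}
    )
    table = pd.DataFrame(
        0, index=list(segments_by_sample), columns=chroms, dtype=int
    )
    for sample, segs in segments_by_sample.items():
        for seg in segs:
            state = call_segment_state(seg.copy, amp_threshold, del_threshold)
            if state is not CNState.NEUTRAL and seg.chrom in table.columns:
                table.loc[sample, seg.chrom] += 1
    return table


def altered_bins(
    segments_by_sample: Mapping[str, Sequence[SegmentCNV]],
    genome: Genome,
    bin_size: int = DEFAULT_BIN_SIZE,
) -> List[Tuple[str, GenomicBin, CNState]]:
    """Flat (sample, bin, state) list of non-neutral bins, for BED export."""
    bins = tile_genome(genome, bin_size)
    out = []
    for sample, segs in segments_by_sample.items():
        states = _bin_states(segs, bins, AMP_THRESHOLD, DEL_THRESHOLD)
        for b, s in zip(bins, states):
            if s != int(CNState.NEUTRAL):
                out.append((sample, b, CNState(s)))
    return out
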