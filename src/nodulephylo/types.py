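"""Core domain types shared across the pipeline.

Coordinate conventions are fixed once, here, and never converted elsewhere:
variant positions are 1-based (VCF convention); copy-number segments are
0-based half-open intervals (BED convention). Chromosome names are opaque
strings — no "chr" prefix is ever added or stripped.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import NamedTuple, Optional


class ValidationError(ValueError):
    """Raised when a record violates a domain invariant."""


class Grade(enum.IntEnum):
    """Pathological grade of a liver nodule, ordered by progression.

    Cirrhotic background tissue < low-grade dysplastic nodule (LGDN)
    < high-grade dysplastic nodule (HGDN) < hepatocellular carcinoma (HCC).
    The integer values encode the progression order used by the trend test.
    """

    CIRRHOSIS = 0
    LGDN = 1
    HGDN = 2
    HCC = 3

    @classmethod
    def parse(cls, text: str) -> "Grade":
        try:
            return cls[text.strip().upper()]
        except KeyError:
            raise ValidationError(
                f"unknown grade {text!r}; expected one of "
                f"{[g.name for g in cls]}"
            ) from None

    @property
    def is_tumor(self) -> bool:
        return self is not Grade.CIRRHOSIS

    @property
    def is_dysplastic(self) -> bool:
        return self in (Grade.LGDN, Grade.HGDN)


GRADE_ORDER = tuple(Grade)


class MutationKey(NamedTuple):
    """Identity of a somatic SNV, comparable across samples."""

    chrom: str
    pos: int
    ref: str
    alt: str


@dataclass
class VariantCall:
    """One somatic SNV observation in one sample.

    ``pos`` is 1-based. ``vaf`` is derived from the read counts and raises
    when the site has zero depth (an undefined allele fraction is an error,
    not a NaN).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    depth: int
    alt_count: int
    func_class: Optional[str] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValidationError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")
        if self.depth < 0:
            raise ValidationError(f"negative depth {self.depth} at {self.chrom}:{self.pos}")
        if not 0 <= self.alt_count <= self.depth:
            raise ValidationError(
                f"alt_count {self.alt_count} outside [0, depth={self.depth}] "
                f"at {self.chrom}:{self.pos}"
            )

    @property
    def vaf(self) -> float:
        if self.depth == 0:
            raise ValidationError(
                f"VAF undefined at zero depth ({self.chrom}:{self.pos})"
            )
        return self.alt_count / self.depth

    @property
    def key(self) -> MutationKey:
        return MutationKey(self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class SegmentCNV:
    """One copy-number segment: half-open interval [start, end) with a
    non-negative real copy value (callers may emit integer calls or
    continuous ratios; interpretation is deferred to the discretization
    thresholds downstream)."""

    chrom: str
    start: int
    end: int
    copy: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(
                f"segment start {self.start} >= end {self.end} on {self.chrom}"
            )
        if self.start < 0:
            raise ValidationError(f"negative segment start {self.start}")
        if self.copy < 0:
            raise ValidationError(f"negative copy value {self.copy} on {self.chrom}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class NoduleSample:
    """One tissue sample: a nodule or the cirrhotic background of a patient."""

    patient_id: str
    sample_id: str
    grade: Grade


def check_no_overlap(segments: list) -> None:
    """Raise if any two same-chromosome segments overlap.

    Segments within one sample represent a partition of the genome into
    copy-number states, so overlap indicates a malformed profile.
    """
    by_chrom: dict = {}
    for seg in segments:
        by_chrom.setdefault(seg.chrom, []).append(seg)
    for chrom, segs in by_chrom.items():
        segs = sorted(segs, key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if b.start < a.end:
                raise ValidationError(
                    f"overlapping segments on {chrom}: "
                    f"[{a.start},{a.end}) and [{b.start},{b.end})"
                )
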