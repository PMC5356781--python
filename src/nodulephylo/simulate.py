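"""Synthetic multifocal-nodule cohorts with known clonal history.

Two generating models for the tumor nodules of one cirrhotic liver:

``linear``
    All tumor nodules descend from one transformed clone. Trunk SNVs and
    trunk CNV events are shared by every nodule; each nodule additionally
    acquires private mutations on its terminal branch. This is the
    stepwise clonal-succession picture.

``independent``
    Every nodule is founded separately: its whole mutation set is drawn
    privately, with genomic positions drawn without replacement across the
    patient so distinct nodules share zero true SNVs by construction. This
    is the nonlinear / independent-origin picture.

Observation noise follows a standard diploid heterozygous model: a clonal
mutation in a tumor of purity p is expected at allele fraction p/2;
sequencing depth per site is a rounded normal truncated at one read
(matching a reported mean +/- sd of target depth), and the alternate read
count is binomial at the expected allele fraction. The cirrhotic
background sample carries no somatic events.
"""
from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .types import Grade, NoduleSample, SegmentCNV, ValidationError, VariantCall

logger = logging.getLogger(__name__)

_BASES = ("A", "C", "G", "T")
#: functional-class mix of coding point mutations (roughly exome-like)
_FUNC_CLASSES = ("nonsynonymous", "synonymous", "stopgain")
_FUNC_PROBS = (0.70, 0.25, 0.05)


def default_genome(n_chrom: int = 22, length: int = 3_000_000) -> List[Tuple[str, int]]:
    """Small synthetic exome stand-in: 22 chromosomes x 3 Mb. Downstream
    logic depends only on coordinates, so a compact genome keeps simulation
    and binning fast without changing behavior."""
    return [(f"chr{i}", length) for i in range(1, n_chrom + 1)]


@dataclass
class SimulationConfig:
    """Stated world of the generator.

    Depth defaults (mean 106.2, sd 30.3) reproduce the reported
    whole-exome target-depth moments; each nodule carries about 7 CNV
    events; a linear patient shares 50 trunk SNVs and each nodule adds
    private SNVs on top.
    """

    model: str = "linear"  # "linear" | "independent"
    n_patients: int = 4
    samples_per_patient: Tuple[Grade, ...] = (
        Grade.CIRRHOSIS, Grade.LGDN, Grade.HGDN, Grade.HCC
    )
    n_trunk_snv: float = 50.0
    n_private_snv: float = 10.0
    n_cnv_events: float = 7.0
    cnv_event_length: float = 500_000.0
    genome: Sequence[Tuple[str, int]] = field(default_factory=default_genome)
    mean_depth: float = 106.2
    sd_depth: float = 30.3
    purity: float = 0.7
    seed: int = 0
    #: draw event counts from a Poisson (True) or use them exactly (False)
    poisson_counts: bool = True
    #: private mutations get a subclonal cancer-cell fraction ~ U(lo, hi);
    #: trunk mutations are clonal (CCF = 1)
    subclonal_private: bool = True
    private_ccf_range: Tuple[float, float] = (0.2, 1.0)
    #: per-grade multiplier on private SNV and CNV rates (stepwise-increase
    #: scenarios); grades absent from the map default to 1.0
    grade_rate_multipliers: Dict[Grade, float] = field(default_factory=dict)
    #: fraction of a linear patient's CNV rate placed on the trunk
    trunk_cnv_fraction: float = 0.5
    #: gaussian noise on emitted copy values (0 = caller emits clean calls)
    cnv_copy_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.model not in ("linear", "independent"):
            raise ValidationError(f"unknown model {self.model!r}")
        if self.n_patients < 1:
            raise ValidationError("need >= 1 patient")
        for v, name in [(self.n_trunk_snv, "n_trunk_snv"),
                        (self.n_private_snv, "n_private_snv"),
                        (self.n_cnv_events, "n_cnv_events")]:
            if v < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not 0 < self.purity <= 1:
            raise ValidationError("purity must be in (0, 1]")
        if not self.genome or any(l <= 0 for _, l in self.genome):
            raise ValidationError("genome must have positive chromosome lengths")

    @property
    def genome_size(self) -> int:
        return sum(l for _, l in self.genome)

    def multiplier(self, grade: Grade) -> float:
        return float(self.grade_rate_multipliers.get(grade, 1.0))


@dataclass
class SimulatedTruth:
    """Ground truth behind one simulated patient."""

    model: str
    #: sample_id -> {MutationKey-tuple -> cancer-cell fraction}
    snv: Dict[str, Dict[tuple, float]]
    #: sample_id -> true integer-copy CNV segments
    cnv: Dict[str, List[SegmentCNV]]
    #: sample_id -> parent lineage node ("trunk" or "root")
    lineage: Dict[str, str]

    def shared_snv_keys(self, sample_ids: Sequence[str]) -> Set[tuple]:
        sets = [set(self.snv[s]) for s in sample_ids]
        out = sets[0].copy()
        for s in sets[1:]:
            out &= s
        return out


def expected_vaf(purity: float, ccf: float) -> float:
    """Expected allele fraction of a heterozygous diploid somatic mutation
    carried by a fraction ``ccf`` of tumor cells in a sample of tumor
    purity ``purity``: purity * ccf / 2."""
    if not 0 <= purity <= 1:
        raise ValidationError(f"purity {purity} outside [0, 1]")
    if not 0 <= ccf <= 1:
        raise ValidationError(f"CCF {ccf} outside [0, 1]")
    return purity * ccf / 2.0


def _sample_rng(seed: int, patient_index: int, stream: str) -> np.random.Generator:
    """Independent stream per (patient, sample): adding a sample never
    perturbs the draws of any other."""
    tag = zlib.crc32(stream.encode()) & 0xFFFFFFFF
    return np.random.default_rng(np.random.SeedSequence([seed, patient_index, tag]))


def _draw_count(rng: np.random.Generator, rate: float, poisson: bool) -> int:
    if poisson:
        return int(rng.poisson(rate))
    return int(round(rate))


def _draw_positions(
    rng: np.random.Generator,
    genome: Sequence[Tuple[str, int]],
    n: int,
    taken: Set[Tuple[str, int]],
) -> List[Tuple[str, int]]:
    """Draw ``n`` distinct genomic positions (1-based), uniform over the
    genome, avoiding positions already assigned elsewhere in the patient."""
    lengths = np.array([l for _, l in genome], dtype=np.int64)
    cum = np.concatenate([[0], np.cumsum(lengths)])
    total = int(cum[-1])
    out: List[Tuple[str, int]] = []
    guard = 0
    while len(out) < n:
        guard += 1
        if guard > 1000 * (n + 1):
            raise ValidationError("could not place mutations; genome too small")
        flat = int(rng.integers(0, total))
        ci = int(np.searchsorted(cum, flat, side="right")) - 1
        pos = (genome[ci][0], flat - int(cum[ci]) + 1)
        if pos not in taken:
            taken.add(pos)
            out.append(pos)
    return out


def _make_snv_keys(rng, positions: List[Tuple[str, int]]) -> List[tuple]:
    keys = []
    for chrom, pos in positions:
        ref = _BASES[int(rng.integers(0, 4))]
        alt = [b for b in _BASES if b != ref][int(rng.integers(0, 3))]
        keys.append((chrom, pos, ref, alt))
    return keys


def inject_cnv_events(
    rng: np.random.Generator,
    config: SimulationConfig,
    n_events: int,
    existing: Optional[List[SegmentCNV]] = None,
) -> List[SegmentCNV]:
    """Place ``n_events`` non-overlapping CNV events on the genome.

    Amplifications (about 5 in 6 events, mirroring the observed excess of
    gains over losses) take integer copy 3-5; deletions take copy 0 or
    0.5. Event lengths are exponential around the configured mean; events
    running past a chromosome end are clipped with a logged warning.
    Collisions with already-placed events are redrawn.
    """
    placed: List[SegmentCNV] = list(existing) if existing else []
    out: List[SegmentCNV] = []
    lengths = {c: l for c, l in config.genome}
    chroms = [c for c, _ in config.genome]
    weights = np.array([lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    for _ in range(n_events):
        for _attempt in range(200):
            chrom = chroms[int(rng.choice(len(chroms), p=weights))]
            clen = lengths[chrom]
            length = max(10_000, int(round(rng.exponential(config.cnv_event_length))))
            start = int(rng.integers(0, clen))
            end = start + length
            if end > clen:
                logger.warning(
                    "CNV event on %s clipped at chromosome end (%d > %d)",
                    chrom, end, clen,
                )
                end = clen
            if end <= start:
                continue
            if rng.random() < 58 / 70:  # gains dominate losses ~5:1
                copy = float(rng.choice([3.0, 4.0, 5.0], p=[0.6, 0.3, 0.1]))
            else:
                copy = float(rng.choice([0.0, 0.5]))
            seg = SegmentCNV(chrom, start, end, copy)
            if all(not (s.chrom == chrom and s.start < end and start < s.end)
                   for s in placed):
                placed.append(seg)
                out.append(seg)
                break
        else:
            logger.warning("dropped a CNV event after 200 placement attempts")
    return out


def _sample_ids(config: SimulationConfig, patient_id: str) -> List[NoduleSample]:
    counts: Dict[Grade, int] = {}
    samples = []
    for grade in config.samples_per_patient:
        counts[grade] = counts.get(grade, 0) + 1
        suffix = f"{counts[grade]}" if config.samples_per_patient.count(grade) > 1 else ""
        samples.append(NoduleSample(patient_id, f"{patient_id}_{grade.name}{suffix}", grade))
    return samples


def simulate_patient(
    config: SimulationConfig, patient_index: int
) -> Tuple[SimulatedTruth, Dict[str, List[VariantCall]], Dict[str, List[SegmentCNV]],
           List[NoduleSample]]:
    """Simulate one patient: ground truth plus noisy observed tables.

    Deterministic given (config.seed, patient_index). Tumor samples are the
    non-cirrhosis entries of ``config.samples_per_patient``; the cirrhosis
    sample is emitted with empty variant and segment tables.
    """
    patient_id = f"P{patient_index + 1:02d}"
    samples = _sample_ids(config, patient_id)
    tumor = [s for s in samples if s.grade.is_tumor]

    taken: Set[Tuple[str, int]] = set()
    true_snv: Dict[str, Dict[tuple, float]] = {s.sample_id: {} for s in samples}
    true_cnv: Dict[str, List[SegmentCNV]] = {s.sample_id: [] for s in samples}
    lineage: Dict[str, str] = {}

    trunk_rng = _sample_rng(config.seed, patient_index, "trunk")
    trunk_keys: List[tuple] = []
    trunk_cnv: List[SegmentCNV] = []
    if config.model == "linear":
        n_trunk = _draw_count(trunk_rng, config.n_trunk_snv, config.poisson_counts)
        trunk_keys = _make_snv_keys(
            trunk_rng, _draw_positions(trunk_rng, config.genome, n_trunk, taken)
        )
        n_trunk_cnv = _draw_count(
            trunk_rng, config.n_cnv_events * config.trunk_cnv_fraction,
            config.poisson_counts,
        )
        trunk_cnv = inject_cnv_events(trunk_rng, config, n_trunk_cnv)

    for s in tumor:
        rng = _sample_rng(config.seed, patient_index, s.sample_id)
        mult = config.multiplier(s.grade)
        if config.model == "linear":
            lineage[s.sample_id] = "trunk"
            for k in trunk_keys:
                true_snv[s.sample_id][k] = 1.0
            n_priv = _draw_count(rng, config.n_private_snv * mult,
                                 config.poisson_counts)
            priv_cnv_rate = config.n_cnv_events * (1 - config.trunk_cnv_fraction) * mult
        else:
            lineage[s.sample_id] = "root"
            n_priv = _draw_count(rng, config.n_private_snv * mult,
                                 config.poisson_counts)
            priv_cnv_rate = config.n_cnv_events * mult
        priv_keys = _make_snv_keys(
            rng, _draw_positions(rng, config.genome, n_priv, taken)
        )
        for k in priv_keys:
            ccf = float(rng.uniform(*config.private_ccf_range)) \
                if config.subclonal_private else 1.0
            true_snv[s.sample_id][k] = ccf
        n_cnv = _draw_count(rng, priv_cnv_rate, config.poisson_counts)
        own_cnv = inject_cnv_events(rng, config, n_cnv, existing=trunk_cnv)
        true_cnv[s.sample_id] = sorted(
            trunk_cnv + own_cnv, key=lambda g: (g.chrom, g.start)
        )

    for s in samples:
        if not s.grade.is_tumor:
            lineage[s.sample_id] = "root"

    truth = SimulatedTruth(config.model, true_snv, true_cnv, lineage)

    observed_variants: Dict[str, List[VariantCall]] = {}
    observed_segments: Dict[str, List[SegmentCNV]] = {}
    for s in samples:
        rng = _sample_rng(config.seed, patient_index, s.sample_id + "/obs")
        calls: List[VariantCall] = []
        for key in sorted(true_snv[s.sample_id]):
            chrom, pos, ref, alt = key
            ccf = true_snv[s.sample_id][key]
            depth = max(1, int(round(rng.normal(config.mean_depth, config.sd_depth))))
            p = expected_vaf(config.purity, ccf)
            alt_count = int(rng.binomial(depth, p))
            if alt_count == 0:
                continue  # a somatic caller emits no record without alt reads
            func_class = str(rng.choice(_FUNC_CLASSES, p=_FUNC_PROBS))
            calls.append(VariantCall(chrom, pos, ref, alt, depth, alt_count,
                                     func_class))
        observed_variants[s.sample_id] = sorted(calls, key=lambda v: (v.chrom, v.pos))
        segs = []
        for seg in true_cnv[s.sample_id]:
            copy = seg.copy
            if config.cnv_copy_noise_sd > 0:
                copy = max(0.0, copy + float(rng.normal(0, config.cnv_copy_noise_sd)))
            segs.append(SegmentCNV(seg.chrom, seg.start, seg.end, copy))
        observed_segments[s.sample_id] = segs

    return truth, observed_variants, observed_segments, samples


def simulate_cohort(config: SimulationConfig):
    """Simulate all patients of the cohort; returns a list of
    ``simulate_patient`` results."""
    return [simulate_patient(config, i) for i in range(config.n_patients)]


def truth_to_json(truth: SimulatedTruth) -> str:
    doc = {
        "model": truth.model,
        "lineage": truth.lineage,
        "snv": {
            s: [{"chrom": k[0], "pos": k[1], "ref": k[2], "alt": k[3], "ccf": c}
                for k, c in sorted(kv.items())]
            for s, kv in truth.snv.items()
        },
        "cnv": {
            s: [{"chrom": g.chrom, "start": g.start, "end": g.end, "copy": g.copy}
                for g in segs]
            for s, segs in truth.cnv.items()
        },
    }
    return json.dumps(doc, indent=2, sort_keys=True)
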