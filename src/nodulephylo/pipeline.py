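"""Per-patient and cohort orchestration.

One patient is one analysis unit: high-confidence SNV filtering, landscape
statistics, DN-vs-HCC VAF comparison and overlap, SNV and CNV parsimony
trees, a per-patient trend test across grades, and an evolution-mode call
(linear vs nonlinear vs indeterminate) from the trunk-shared fraction of
the observed mutation sets. The cohort runner aggregates per-patient
reports and applies the trend test across all samples of the cohort.
"""
from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from . import cnv as cnvmod
from . import snv as snvmod
from .matrix import ROOT_TAXON
from .io import check_chrom_naming, write_newick
from .parsimony import search_mpt
from .simulate import SimulationConfig, simulate_patient
from .tree import strict_consensus
from .trend import TrendTestResult, assemble_trend_inputs, permutation_trend_test
from .types import Grade, NoduleSample, SegmentCNV, ValidationError, VariantCall

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Analysis-side knobs (simulation knobs live in SimulationConfig)."""

    min_depth: int = snvmod.MIN_DEPTH
    min_vaf: float = snvmod.MIN_VAF
    bin_size: int = cnvmod.DEFAULT_BIN_SIZE
    cnv_encoding: str = "binary-pair"
    include_root_taxon: bool = True
    #: trunk-shared-fraction / pairwise-Jaccard threshold of the
    #: evolution-mode classifier (an invented operational cutoff, not a
    #: published quantity)
    evolution_threshold: float = 0.05
    n_perm: int = 10_000
    trend_statistic: str = "jonckheere"
    #: callable-region size (Mb) used as the mutation-rate denominator;
    #: defaults to the synthetic exome size when run from a simulation
    callable_mb: float = 66.0
    seed: int = 0
    genome: Optional[Sequence[Tuple[str, int]]] = None


@dataclass
class EvolutionCall:
    """Operational classification of the per-patient evolution mode.

    nonlinear: essentially no mutations shared along the whole lineage
    (trunk fraction < threshold) and every DN-HCC pair nearly disjoint.
    linear: a substantial trunk. indeterminate: empty data or mixed signal.
    """

    trunk_shared_fraction: Optional[float]
    threshold: float
    call: str  # "linear" | "nonlinear" | "indeterminate"


def classify_evolution(
    keys_by_tumor_sample: Mapping[str, set],
    dn_hcc_jaccards: Sequence[float],
    threshold: float = 0.05,
) -> EvolutionCall:
    sets = list(keys_by_tumor_sample.values())
    union = set().union(*sets) if sets else set()
    if not union:
        return EvolutionCall(None, threshold, "indeterminate")
    inter = sets[0].copy()
    for s in sets[1:]:
        inter &= s
    frac = len(inter) / len(union)
    if frac >= threshold:
        call = "linear"
    elif all(j < threshold for j in dn_hcc_jaccards):
        call = "nonlinear"
    else:
        call = "indeterminate"
    return EvolutionCall(frac, threshold, call)


@dataclass
class PatientReport:
    patient_id: str
    sample_grades: Dict[str, str]
    snv_counts_raw: Dict[str, int]
    snv_counts_filtered: Dict[str, int]
    snv_rates_per_mb: Dict[str, float]
    class_counts: Dict[str, Dict[str, int]]
    vaf_comparison_p: Optional[float]
    overlap_matrix: Dict[str, Dict[str, float]]
    dn_hcc_overlap: Optional[dict]
    snv_trees_newick: List[str]
    snv_consensus_newick: Optional[str]
    snv_tree_length: Optional[int]
    cnv_trees_newick: List[str]
    cnv_consensus_newick: Optional[str]
    cnv_tree_length: Optional[int]
    cnv_counts_per_chromosome: Dict[str, Dict[str, int]]
    trend_mutation_rate: Optional[dict]
    trend_cnv: Optional[dict]
    evolution: dict

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def _mpt_summary(matrix, include_root: bool, root_label: str):
    """Exhaustive parsimony search -> (newick list, consensus newick, length).

    Returns (None, None, None) when the matrix is too small or empty.
    """
    if matrix.n_taxa < 2 or matrix.n_characters == 0:
        return [], None, None
    mpts = search_mpt(matrix)
    newicks = [write_newick(t, root_label=root_label) for t in mpts.trees]
    consensus = None
    if matrix.n_taxa >= 3:
        consensus = write_newick(
            strict_consensus(mpts.trees), root_label=root_label, lengths=False
        )
    return newicks, consensus, mpts.length


def run_patient(
    variants_by_sample: Mapping[str, Sequence[VariantCall]],
    segments_by_sample: Mapping[str, Sequence[SegmentCNV]],
    samples: Sequence[NoduleSample],
    config: Optional[PipelineConfig] = None,
    genome: Optional[Sequence[Tuple[str, int]]] = None,
) -> PatientReport:
    """Run the full per-patient analysis. Requires exactly one cirrhosis
    sample; aborts naming the failing stage on any error."""
    config = config or PipelineConfig()
    genome = genome or config.genome
    patient_ids = {s.patient_id for s in samples}
    if len(patient_ids) != 1:
        raise ValidationError(f"expected one patient, got {sorted(patient_ids)}")
    patient_id = samples[0].patient_id
    cirrhosis = [s for s in samples if s.grade is Grade.CIRRHOSIS]
    if len(cirrhosis) != 1:
        raise ValidationError(
            f"patient {patient_id}: expected exactly one CIRRHOSIS sample, "
            f"found {len(cirrhosis)}"
        )
    tumor = [s for s in samples if s.grade.is_tumor]
    sample_ids = [s.sample_id for s in samples]
    for sid in sample_ids:
        if sid not in variants_by_sample or sid not in segments_by_sample:
            raise ValidationError(f"stage input: missing tables for sample {sid}")

    chrom_sets = [
        [v.chrom for v in variants_by_sample[sid]] for sid in sample_ids
    ] + [[s.chrom for s in segments_by_sample[sid]] for sid in sample_ids]
    check_chrom_naming(*chrom_sets)

    def stage(name):
        logger.info("patient %s: stage %s", patient_id, name)

    # -- SNV landscape -----------------------------------------------------
    stage("filter")
    filtered = {
        sid: snvmod.filter_high_confidence(
            variants_by_sample[sid], config.min_depth, config.min_vaf
        )
        for sid in sample_ids
    }
    counts_raw = {sid: len(variants_by_sample[sid]) for sid in sample_ids}
    counts_filt = {sid: len(filtered[sid]) for sid in sample_ids}
    rates = {sid: counts_filt[sid] / config.callable_mb for sid in sample_ids}
    class_counts = {sid: snvmod.count_by_class(filtered[sid]) for sid in sample_ids}

    stage("vaf-comparison")
    dn_samples = [s.sample_id for s in tumor if s.grade.is_dysplastic]
    hcc_samples = [s.sample_id for s in tumor if s.grade is Grade.HCC]
    dn_vafs = [v.vaf for sid in dn_samples for v in filtered[sid]]
    hcc_vafs = [v.vaf for sid in hcc_samples for v in filtered[sid]]
    vaf_p = None
    if dn_vafs and hcc_vafs:
        vaf_p = snvmod.vaf_comparison(dn_vafs, hcc_vafs, config.n_perm, config.seed)

    stage("overlap")
    keys = {sid: snvmod.mutation_keys(filtered[sid]) for sid in sample_ids}
    tumor_ids = [s.sample_id for s in tumor]
    overlap_matrix: Dict[str, Dict[str, float]] = {}
    for a in tumor_ids:
        overlap_matrix[a] = {}
        for b in tumor_ids:
            if a == b or (not keys[a] and not keys[b]):
                overlap_matrix[a][b] = float("nan") if a != b else 1.0
            else:
                overlap_matrix[a][b] = snvmod.overlap_stats(keys[a], keys[b]).jaccard
    dn_union = set().union(*(keys[sid] for sid in dn_samples)) if dn_samples else set()
    hcc_union = set().union(*(keys[sid] for sid in hcc_samples)) if hcc_samples else set()
    dn_hcc = None
    if dn_union or hcc_union:
        st = snvmod.overlap_stats(dn_union, hcc_union)
        dn_hcc = {"n_dn": st.n_a, "n_hcc": st.n_b, "n_shared": st.n_shared,
                  "jaccard": st.jaccard}

    # -- trees -------------------------------------------------------------
    stage("snv-tree")
    snv_matrix = snvmod.build_snv_matrix(
        {sid: keys[sid] for sid in sample_ids},
        include_root=config.include_root_taxon,
    ).drop_constant()
    snv_newicks, snv_cons, snv_len = _mpt_summary(
        snv_matrix, config.include_root_taxon,
        ROOT_TAXON if config.include_root_taxon else sample_ids[0],
    )

    stage("cnv-tree")
    seg_genome = genome
    if seg_genome is None:
        # fall back to a genome inferred from the observed segments
        ends: Dict[str, int] = {}
        for sid in sample_ids:
            for seg in segments_by_sample[sid]:
                ends[seg.chrom] = max(ends.get(seg.chrom, 0), seg.end)
        seg_genome = sorted(ends.items())
    cnv_matrix = cnvmod.binarize_bins(
        {sid: list(segments_by_sample[sid]) for sid in sample_ids},
        seg_genome, config.bin_size, config.cnv_encoding,
        include_root=config.include_root_taxon,
    )
    cnv_newicks, cnv_cons, cnv_len = _mpt_summary(
        cnv_matrix, config.include_root_taxon,
        ROOT_TAXON if config.include_root_taxon else sample_ids[0],
    )

    # -- trend test --------------------------------------------------------
    stage("trend")
    chrom_names = [c for c, _ in seg_genome] if seg_genome else ()
    cnv_table = cnvmod.cnv_counts_per_chromosome(
        {sid: list(segments_by_sample[sid]) for sid in sample_ids},
        chromosomes=chrom_names,
    )
    (rate_vec, rate_grades), (cnv_vec, cnv_grades) = assemble_trend_inputs(
        samples, counts_filt, cnv_table, config.callable_mb
    )
    trend_rate = trend_cnv = None
    if len(set(rate_grades)) >= 2:
        trend_rate = permutation_trend_test(
            rate_vec, rate_grades, config.n_perm, config.seed,
            config.trend_statistic,
        ).to_dict()
    if len(set(cnv_grades)) >= 2:
        trend_cnv = permutation_trend_test(
            cnv_vec, cnv_grades, config.n_perm, config.seed,
            config.trend_statistic,
        ).to_dict()

    # -- evolution-mode classification ------------------------------------
    stage("classify")
    dn_hcc_pairs = [
        overlap_matrix[a][b]
        for a in dn_samples for b in hcc_samples
        if not np.isnan(overlap_matrix[a][b])
    ]
    evo = classify_evolution(
        {sid: keys[sid] for sid in tumor_ids}, dn_hcc_pairs,
        config.evolution_threshold,
    )

    return PatientReport(
        patient_id=patient_id,
        sample_grades={s.sample_id: s.grade.name for s in samples},
        snv_counts_raw=counts_raw,
        snv_counts_filtered=counts_filt,
        snv_rates_per_mb=rates,
        class_counts=class_counts,
        vaf_comparison_p=vaf_p,
        overlap_matrix=overlap_matrix,
        dn_hcc_overlap=dn_hcc,
        snv_trees_newick=snv_newicks,
        snv_consensus_newick=snv_cons,
        snv_tree_length=snv_len,
        cnv_trees_newick=cnv_newicks,
        cnv_consensus_newick=cnv_cons,
        cnv_tree_length=cnv_len,
        cnv_counts_per_chromosome={
            sid: {c: int(cnv_table.loc[sid, c]) for c in cnv_table.columns}
            for sid in cnv_table.index
        },
        trend_mutation_rate=trend_rate,
        trend_cnv=trend_cnv,
        evolution={
            "trunk_shared_fraction": evo.trunk_shared_fraction,
            "threshold": evo.threshold,
            "call": evo.call,
        },
    )


@dataclass
class CohortReport:
    reports: List[PatientReport]
    summary: dict

    def to_json(self) -> str:
        return json.dumps(
            {"summary": self.summary,
             "patients": [r.to_dict() for r in self.reports]},
            indent=2, sort_keys=True,
        )


def _mean_sd(values: List[float]) -> Tuple[float, float]:
    if not values:
        return float("nan"), float("nan")
    arr = np.asarray(values, dtype=float)
    return float(arr.mean()), float(arr.std(ddof=1)) if arr.size > 1 else 0.0


def run_cohort(
    sim_config: SimulationConfig,
    pipeline_config: Optional[PipelineConfig] = None,
) -> CohortReport:
    """Simulate a cohort under ``sim_config`` and analyze every patient.

    The cohort summary mirrors the per-study bookkeeping: mean +/- sd
    filtered SNV counts per dysplastic nodule and per carcinoma, total CNV
    counts, cohort-level trend p-values, and the per-patient evolution
    calls with a majority cohort call.
    """
    pipeline_config = pipeline_config or PipelineConfig(
        callable_mb=sim_config.genome_size / 1e6, seed=sim_config.seed,
        genome=list(sim_config.genome),
    )
    reports: List[PatientReport] = []
    all_samples: List[NoduleSample] = []
    all_counts: Dict[str, int] = {}
    all_cnv_tables = []
    for i in range(sim_config.n_patients):
        truth, variants, segments, samples = simulate_patient(sim_config, i)
        report = run_patient(variants, segments, samples, pipeline_config,
                             genome=list(sim_config.genome))
        reports.append(report)
        all_samples.extend(samples)
        all_counts.update(report.snv_counts_filtered)
        all_cnv_tables.append(report.cnv_counts_per_chromosome)

    import pandas as pd

    cnv_table = pd.DataFrame(
        {sid: row for tab in all_cnv_tables for sid, row in tab.items()}
    ).T.fillna(0).astype(int)
    (rate_vec, rate_grades), (cnv_vec, cnv_grades) = assemble_trend_inputs(
        all_samples, all_counts, cnv_table, pipeline_config.callable_mb
    )
    trend_rate = permutation_trend_test(
        rate_vec, rate_grades, pipeline_config.n_perm, pipeline_config.seed,
        pipeline_config.trend_statistic,
    )
    trend_cnv = permutation_trend_test(
        cnv_vec, cnv_grades, pipeline_config.n_perm, pipeline_config.seed,
        pipeline_config.trend_statistic,
    )

    grade_of = {s.sample_id: s.grade for s in all_samples}
    dn_counts = [c for sid, c in all_counts.items()
                 if grade_of[sid].is_dysplastic]
    hcc_counts = [c for sid, c in all_counts.items()
                  if grade_of[sid] is Grade.HCC]
    dn_mean, dn_sd = _mean_sd(dn_counts)
    hcc_mean, hcc_sd = _mean_sd(hcc_counts)
    calls = [r.evolution["call"] for r in reports]
    majority = max(("linear", "nonlinear", "indeterminate"),
                   key=lambda c: calls.count(c))

    summary = {
        "n_patients": sim_config.n_patients,
        "model": sim_config.model,
        "seed": sim_config.seed,
        "snv_per_dn_mean": dn_mean,
        "snv_per_dn_sd": dn_sd,
        "snv_per_hcc_mean": hcc_mean,
        "snv_per_hcc_sd": hcc_sd,
        "total_cnv_count": int(cnv_table.to_numpy().sum()),
        "trend_mutation_rate": trend_rate.to_dict(),
        "trend_cnv_per_chromosome": trend_cnv.to_dict(),
        "evolution_calls": calls,
        "cohort_evolution_call": majority,
    }
    return CohortReport(reports, summary)


def write_cohort_outputs(cohort: CohortReport, outdir: str) -> None:
    """Write the cohort report and per-patient artifacts under ``outdir``."""
    os.makedirs(outdir, exist_ok=True)
    with open(os.path.join(outdir, "cohort_report.json"), "w") as fh:
        fh.write(cohort.to_json() + "\n")
    for rep in cohort.reports:
        pdir = os.path.join(outdir, rep.patient_id)
        os.makedirs(pdir, exist_ok=True)
        with open(os.path.join(pdir, "report.json"), "w") as fh:
            fh.write(rep.to_json() + "\n")
        for kind, trees in (("snv", rep.snv_trees_newick),
                            ("cnv", rep.cnv_trees_newick)):
            if trees:
                with open(os.path.join(pdir, f"{kind}_trees.nwk"), "w") as fh:
                    fh.write("\n".join(trees) + "\n")
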