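"""Readers and writers for every external representation the pipeline
touches.

Variant tables come either as a 7-column TSV dialect
(chrom, pos, ref, alt, depth, alt_count, func_class — the canonical
internal format) or as VCF 4.x (read-only, biallelic SNVs only, using the
per-sample DP and AD fields and ignoring all other annotations).
Copy-number segments are SEG/BED-like TSV with 0-based half-open
coordinates. Character matrices use a relaxed PHYLIP shape (count header,
then name + digit string). Newick is written natively from
:class:`~nodulephylo.tree.PhyloTree` and parsed back through dendropy.
"""
from __future__ import annotations

import os
import warnings
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .matrix import CharacterMatrix
from .tree import PhyloTree
from .types import (Grade, NoduleSample, SegmentCNV, ValidationError,
                    VariantCall, check_no_overlap)

VARIANT_COLUMNS = ("chrom", "pos", "ref", "alt", "depth", "alt_count", "func_class")
SEGMENT_COLUMNS = ("sample", "chrom", "start", "end", "copy")


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


def _is_vcf(path: str) -> bool:
    if str(path).endswith((".vcf", ".vcf.gz")):
        return True
    try:
        with open(path, "rb") as fh:
            return fh.read(16).startswith(b"##fileformat=VCF")
    except OSError:
        return False


def _read_variants_vcf(path: str, sample_id: Optional[str]) -> List[VariantCall]:
    import pysam

    calls: List[VariantCall] = []
    with pysam.VariantFile(os.fspath(path)) as vcf:
        vcf_samples = list(vcf.header.samples)
        target = None
        if vcf_samples:
            target = sample_id if sample_id in vcf_samples else vcf_samples[0]
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                continue
            ref, alt = rec.ref, rec.alts[0]
            if len(ref) != 1 or len(alt) != 1:
                continue  # SNVs only
            depth = alt_count = None
            if target is not None:
                fmt = rec.samples[target]
                if "AD" in fmt and fmt["AD"] is not None and fmt["AD"][0] is not None:
                    ad = fmt["AD"]
                    alt_count = int(ad[1])
                    depth = int(fmt["DP"]) if fmt.get("DP") is not None else int(sum(ad))
                elif fmt.get("DP") is not None:
                    depth = int(fmt["DP"])
            if depth is None and "DP" in rec.info:
                depth = int(rec.info["DP"])
            if depth is None or alt_count is None:
                raise ParseError(
                    f"{path}: record {rec.chrom}:{rec.pos} lacks usable DP/AD fields"
                )
            calls.append(VariantCall(rec.chrom, rec.pos, ref, alt, depth, alt_count))
    return sorted(calls, key=lambda v: (v.chrom, v.pos))


def read_variants(path: str, sample_id: Optional[str] = None) -> List[VariantCall]:
    """Read one sample's somatic SNVs from VCF or the TSV dialect.

    Rows are validated (a zero-depth row is an error: its VAF is
    undefined) and returned sorted by (chrom, pos).
    """
    if _is_vcf(path):
        return _read_variants_vcf(path, sample_id)
    calls: List[VariantCall] = []
    with open(path) as fh:
        header: Optional[List[str]] = None
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = [f.strip().lower() for f in fields]
                if header[:6] != list(VARIANT_COLUMNS[:6]):
                    raise ParseError(
                        f"{path}:{lineno}: expected header starting "
                        f"{VARIANT_COLUMNS[:6]}, got {tuple(header[:6])}"
                    )
                continue
            if len(fields) < 6:
                raise ParseError(f"{path}:{lineno}: expected >= 6 columns, "
                                 f"got {len(fields)}")
            try:
                chrom, pos, ref, alt = fields[0], int(fields[1]), fields[2], fields[3]
                depth, alt_count = int(fields[4]), int(fields[5])
            except ValueError as e:
                raise ParseError(f"{path}:{lineno}: {e}") from None
            func = fields[6].strip() if len(fields) > 6 else ""
            func_class = None if func in ("", ".", "NA") else func
            try:
                call = VariantCall(chrom, pos, ref, alt, depth, alt_count, func_class)
                call.vaf  # zero depth -> undefined VAF -> reject the row
            except ValidationError as e:
                raise ValidationError(f"{path}:{lineno}: {e}") from None
            calls.append(call)
    return sorted(calls, key=lambda v: (v.chrom, v.pos))


def write_variants(variants: Sequence[VariantCall], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(VARIANT_COLUMNS) + "\n")
        for v in variants:
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t{v.depth}\t{v.alt_count}\t"
                f"{v.func_class if v.func_class else '.'}\n"
            )


def read_segments(path: str, sample_id: Optional[str] = None) -> List[SegmentCNV]:
    """Read copy-number segments from SEG-like TSV.

    Accepts 4 columns (chrom, start, end, copy) or 5 with a leading sample
    column (filtered to ``sample_id`` when given). Segments are validated,
    required non-overlapping per chromosome, and returned sorted by
    (chrom, start).
    """
    segs: List[SegmentCNV] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            low = [f.strip().lower() for f in fields]
            if low[0] in ("sample", "chrom", "chromosome"):  # header row
                continue
            try:
                if len(fields) >= 5:
                    sample, chrom = fields[0], fields[1]
                    start, end, copy = int(fields[2]), int(fields[3]), float(fields[4])
                    if sample_id is not None and sample != sample_id:
                        continue
                elif len(fields) == 4:
                    chrom = fields[0]
                    start, end, copy = int(fields[1]), int(fields[2]), float(fields[3])
                else:
                    raise ParseError(f"{path}:{lineno}: expected 4 or 5 columns")
            except ValueError as e:
                raise ParseError(f"{path}:{lineno}: {e}") from None
            try:
                segs.append(SegmentCNV(chrom, start, end, copy))
            except ValidationError as e:
                raise ValidationError(f"{path}:{lineno}: {e}") from None
    segs.sort(key=lambda s: (s.chrom, s.start))
    check_no_overlap(segs)
    return segs


def write_segments(segments: Sequence[SegmentCNV], path: str,
                   sample_id: str = ".") -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(SEGMENT_COLUMNS) + "\n")
        for s in segments:
            fh.write(f"{sample_id}\t{s.chrom}\t{s.start}\t{s.end}\t{s.copy:g}\n")


def read_sample_sheet(path: str) -> List[NoduleSample]:
    """Read the cohort sample sheet (patient_id, sample_id, grade TSV)."""
    samples: List[NoduleSample] = []
    seen = set()
    with open(path) as fh:
        header: Optional[List[str]] = None
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = [f.strip() for f in line.split("\t")]
            if header is None:
                header = [f.lower() for f in fields]
                if header[:3] != ["patient_id", "sample_id", "grade"]:
                    raise ParseError(
                        f"{path}:{lineno}: expected columns "
                        f"patient_id, sample_id, grade"
                    )
                continue
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected 3 columns")
            patient, sample, grade_text = fields[:3]
            try:
                grade = Grade.parse(grade_text)
            except ValidationError as e:
                raise ValidationError(f"{path}:{lineno}: {e}") from None
            if (patient, sample) in seen:
                raise ValidationError(
                    f"{path}:{lineno}: duplicate sample ({patient}, {sample})"
                )
            seen.add((patient, sample))
            samples.append(NoduleSample(patient, sample, grade))
    return samples


def write_sample_sheet(samples: Sequence[NoduleSample], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("patient_id\tsample_id\tgrade\n")
        for s in samples:
            fh.write(f"{s.patient_id}\t{s.sample_id}\t{s.grade.name}\n")


def check_chrom_naming(*name_sets: Sequence[str]) -> None:
    """Warn when inputs mix chr-prefixed and bare chromosome names;
    chromosome names are compared as opaque strings everywhere, so a mixed
    convention silently yields empty intersections."""
    styles = set()
    for names in name_sets:
        for n in names:
            styles.add(n.startswith("chr"))
    if len(styles) > 1:
        warnings.warn(
            "mixed chromosome naming (chr-prefixed and bare) across inputs; "
            "names are compared verbatim and will not match each other"
        )


# -- character matrices (relaxed PHYLIP) ----------------------------------

def write_character_matrix(matrix: CharacterMatrix, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"{matrix.n_taxa} {matrix.n_characters} {matrix.semantics}\n")
        width = max((len(t) for t in matrix.taxa), default=0) + 2
        for taxon, row in zip(matrix.taxa, matrix.states):
            fh.write(taxon.ljust(width) + "".join(str(int(s)) for s in row) + "\n")


def read_character_matrix(path: str) -> CharacterMatrix:
    with open(path) as fh:
        lines = [l.rstrip("\n") for l in fh if l.strip()]
    if not lines:
        raise ParseError(f"{path}: empty matrix file")
    head = lines[0].split()
    try:
        n_taxa, n_char = int(head[0]), int(head[1])
    except (IndexError, ValueError):
        raise ParseError(f"{path}:1: expected 'ntaxa nchar [semantics]' header") from None
    semantics = head[2] if len(head) > 2 else "binary"
    taxa, rows = [], []
    for lineno, line in enumerate(lines[1:], start=2):
        parts = line.split()
        if len(parts) != 2 or len(parts[1]) != n_char:
            raise ParseError(f"{path}:{lineno}: expected 'name {n_char}-digit string'")
        taxa.append(parts[0])
        rows.append([int(c) for c in parts[1]])
    if len(taxa) != n_taxa:
        raise ParseError(f"{path}: header promises {n_taxa} taxa, found {len(taxa)}")
    states = np.array(rows, dtype=np.int64) if rows else np.zeros((0, n_char), int)
    return CharacterMatrix(taxa, [f"c{j}" for j in range(n_char)], states, semantics)


# -- Newick ----------------------------------------------------------------

def write_newick(tree: PhyloTree, root_label: Optional[str] = None,
                 lengths: bool = True) -> str:
    """Serialize a tree to Newick; branch lengths are the per-edge change
    counts when a reconstruction is attached."""
    return tree.newick(root_label=root_label, lengths=lengths)


def read_newick(text: str) -> PhyloTree:
    """Parse a Newick string back into a PhyloTree (via dendropy).

    Degree-2 nodes introduced by rooted display conventions are suppressed,
    with their branch lengths summed, so write -> read reproduces the
    unrooted topology and the per-edge change counts.
    """
    import dendropy

    dt = dendropy.Tree.get(data=text, schema="newick")

    ids: Dict[object, int] = {}

    def nid(node) -> int:
        if node not in ids:
            ids[node] = len(ids)
        return ids[node]

    edges: List[Tuple[int, int]] = []
    changes: Dict[frozenset, float] = {}
    labels: Dict[int, str] = {}
    any_length = False
    for node in dt.preorder_node_iter():
        n = nid(node)
        if node.taxon is not None:
            labels[n] = node.taxon.label
        if node.parent_node is not None:
            p = nid(node.parent_node)
            edges.append((p, n))
            if node.edge.length is not None:
                any_length = True
            changes[frozenset((p, n))] = node.edge.length or 0

    # suppress degree-<3 unlabeled nodes (display roots)
    def degree(n):
        return sum(1 for e in edges if n in e)

    changed = True
    while changed:
        changed = False
        for n in {x for e in edges for x in e}:
            if n in labels or degree(n) != 2:
                continue
            (a,), (b,) = [tuple(set(e) - {n}) for e in edges if n in e]
            length = sum(changes.get(frozenset((n, x)), 0) for x in (a, b))
            edges = [e for e in edges if n not in e]
            changes = {frozenset(e): l for e, l in changes.items() if n not in e}
            edges.append((a, b))
            changes[frozenset((a, b))] = length
            changed = True
            break

    edge_changes = {frozenset(e): int(changes.get(frozenset(e), 0))
                    for e in edges} if any_length else None
    return PhyloTree(edges, labels, edge_changes)
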