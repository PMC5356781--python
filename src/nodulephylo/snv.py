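"""Somatic-SNV landscape analysis.

High-confidence filtering (depth >= 20 reads and VAF >= 20%, both
inclusive), per-class tallies, permutation comparison of VAF
distributions between dysplastic nodules and carcinoma, cross-nodule
overlap statistics on exact mutation identity, and the binary
presence/absence character matrix used for SNV phylogenies.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb
from typing import Dict, Iterable, List, Mapping, Sequence, Set

import numpy as np

from .matrix import CharacterMatrix, ROOT_TAXON
from .types import MutationKey, ValidationError, VariantCall

#: defaults of the high-confidence filter
MIN_DEPTH = 20
MIN_VAF = 0.20

_EPS = 1e-12


def filter_high_confidence(
    variants: Sequence[VariantCall],
    min_depth: int = MIN_DEPTH,
    min_vaf: float = MIN_VAF,
) -> List[VariantCall]:
    """Keep exactly the calls with depth >= min_depth and VAF >= min_vaf
    (inclusive thresholds), preserving input order."""
    return [
        v for v in variants
        if v.depth >= min_depth and v.vaf >= min_vaf - _EPS
    ]


def count_by_class(variants: Sequence[VariantCall]) -> Dict[str, int]:
    """Tally variants by functional class; missing classes count as
    ``"unknown"``. Counts always sum to the input length."""
    out: Dict[str, int] = {}
    for v in variants:
        cls = v.func_class if v.func_class else "unknown"
        out[cls] = out.get(cls, 0) + 1
    return out


def mutation_keys(variants: Iterable[VariantCall]) -> Set[MutationKey]:
    return {v.key for v in variants}


@dataclass(frozen=True)
class OverlapStats:
    n_a: int
    n_b: int
    n_shared: int

    @property
    def jaccard(self) -> float:
        union = self.n_a + self.n_b - self.n_shared
        return self.n_shared / union


def overlap_stats(keys_a: Set[MutationKey], keys_b: Set[MutationKey]) -> OverlapStats:
    """Exact set overlap between two samples' mutation identities."""
    if not keys_a and not keys_b:
        raise ValidationError("overlap undefined for two empty mutation sets")
    return OverlapStats(len(keys_a), len(keys_b), len(keys_a & keys_b))


def _rank_sum_u(a: np.ndarray, b: np.ndarray) -> float:
    """Mann-Whitney U counting pairs (x in a, y in b) with y > x, ties 1/2."""
    gt = (b[None, :] > a[:, None]).sum()
    ties = (b[None, :] == a[:, None]).sum()
    return float(gt) + 0.5 * float(ties)


def vaf_comparison(
    vafs_a: Sequence[float],
    vafs_b: Sequence[float],
    n_perm: int = 10_000,
    seed: int = 0,
) -> float:
    """Two-sided permutation p-value for a location difference between two
    VAF samples, using the rank-sum (Mann-Whitney U) statistic under label
    shuffling.

    When the number of distinct label splits C(n_a+n_b, n_a) is at most
    ``n_perm`` the test is exact by full enumeration (p = count/total);
    otherwise Monte-Carlo with the plus-one convention
    p = (1 + #{|U* - E| >= |U - E|}) / (1 + n_perm).
    """
    a = np.asarray(vafs_a, dtype=float)
    b = np.asarray(vafs_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("VAF comparison requires two non-empty samples")
    pooled = np.concatenate([a, b])
    na, n = a.size, pooled.size
    expected = na * b.size / 2.0
    obs_dev = abs(_rank_sum_u(a, b) - expected)

    if comb(n, na) <= n_perm:
        hits = total = 0
        for idx_a in itertools.combinations(range(n), na):
            mask = np.zeros(n, dtype=bool)
            mask[list(idx_a)] = True
            dev = abs(_rank_sum_u(pooled[mask], pooled[~mask]) - expected)
            hits += dev >= obs_dev - _EPS
            total += 1
        return hits / total

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        dev = abs(_rank_sum_u(perm[:na], perm[na:]) - expected)
        hits += dev >= obs_dev - _EPS
    return (1 + hits) / (1 + n_perm)


def build_snv_matrix(
    keys_by_sample: Mapping[str, Set[MutationKey]],
    include_root: bool = True,
) -> CharacterMatrix:
    """Binary presence/absence matrix over the union of mutation identities.

    One character per MutationKey in the union (columns sorted by genomic
    key for determinism); state 1 = mutation observed in the sample. With
    ``include_root`` an all-zero NORMAL taxon is appended to represent the
    unmutated ancestral (non-neoplastic) state.
    """
    if len(keys_by_sample) < 2:
        raise ValidationError("need >= 2 samples to build a character matrix")
    union = sorted(set().union(*keys_by_sample.values()))
    taxa = list(keys_by_sample)
    states = np.zeros((len(taxa), len(union)), dtype=np.int64)
    col = {k: j for j, k in enumerate(union)}
    for i, sample in enumerate(taxa):
        for k in keys_by_sample[sample]:
            states[i, col[k]] = 1
    m = CharacterMatrix(
        taxa, [f"{k.chrom}:{k.pos}{k.ref}>{k.alt}" for k in union], states, "binary"
    )
    if include_root:
        m = m.with_taxon(ROOT_TAXON, np.zeros(len(union), dtype=np.int64))
    return m
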