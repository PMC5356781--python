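"""Permutation test for a stepwise increase across ordered grades.

The default statistic is Jonckheere-Terpstra: over every pair of groups
(k, l) with k earlier than l in the grade order, count value pairs
(x in k, y in l) with y > x, ties counting one half. Its permutation null
(values shuffled against the fixed grade labels) gives a one-sided p-value
for "increasing alternatives". A linear contrast of values against grade
ranks is available as an alternative statistic. When the number of
distinct assignments of values to groups is small the test switches to
exact full enumeration.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from math import factorial
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .types import Grade, ValidationError

_EPS = 1e-9

STATISTIC_KINDS = ("jonckheere", "linear-contrast")


def _grade_ranks(grades: Sequence, order: Optional[Sequence] = None) -> np.ndarray:
    """Map group labels to integer ranks under the declared order (default:
    sorted unique labels, which for :class:`Grade` is progression order)."""
    if order is None:
        order = sorted(set(grades))
    rank = {g: i for i, g in enumerate(order)}
    try:
        return np.array([rank[g] for g in grades], dtype=np.int64)
    except KeyError as e:
        raise ValidationError(f"grade {e.args[0]!r} not in declared order") from None


def _cross_pairs(ranks: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Index pairs (i, j) with rank[i] < rank[j]."""
    ii, jj = np.where(ranks[:, None] < ranks[None, :])
    return ii, jj


def jonckheere_statistic(values: Sequence[float], grades: Sequence,
                         order: Optional[Sequence] = None) -> float:
    """JT = sum over ordered group pairs of #{y > x} + 1/2 #{y == x}."""
    v = np.asarray(values, dtype=float)
    ranks = _grade_ranks(grades, order)
    if len(set(ranks.tolist())) < 2:
        raise ValidationError("need >= 2 non-empty groups")
    ii, jj = _cross_pairs(ranks)
    return float((v[jj] > v[ii]).sum() + 0.5 * (v[jj] == v[ii]).sum())


def linear_contrast_statistic(values: Sequence[float], grades: Sequence,
                              order: Optional[Sequence] = None) -> float:
    """Sum of (grade rank - mean rank) * value; positive under an
    increasing trend."""
    v = np.asarray(values, dtype=float)
    ranks = _grade_ranks(grades, order).astype(float)
    if len(set(ranks.tolist())) < 2:
        raise ValidationError("need >= 2 non-empty groups")
    return float(((ranks - ranks.mean()) * v).sum())


@dataclass
class TrendTestResult:
    statistic: float
    p_value: float
    n_perm: int
    seed: Optional[int]
    statistic_kind: str
    group_sizes: List[int]
    exhaustive: bool = False

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n_perm": self.n_perm,
            "seed": self.seed,
            "statistic_kind": self.statistic_kind,
            "group_sizes": self.group_sizes,
            "exhaustive": self.exhaustive,
        }


def n_distinct_assignments(group_sizes: Sequence[int]) -> int:
    n = sum(group_sizes)
    total = factorial(n)
    for s in group_sizes:
        total //= factorial(s)
    return total


def _enumerate_label_vectors(ranks: np.ndarray):
    """Yield every distinct assignment of the observation indices to the
    groups (as a rank vector), one per multiset permutation of the labels."""
    n = len(ranks)
    order = sorted(set(ranks.tolist()))
    sizes = [(ranks == g).sum() for g in order]

    def rec(avail: Tuple[int, ...], gi: int, out: np.ndarray):
        if gi == len(order) - 1:
            res = out.copy()
            res[list(avail)] = order[gi]
            yield res
            return
        for combo in itertools.combinations(avail, int(sizes[gi])):
            res = out.copy()
            res[list(combo)] = order[gi]
            remaining = tuple(i for i in avail if i not in set(combo))
            yield from rec(remaining, gi + 1, res)

    yield from rec(tuple(range(n)), 0, np.full(n, -1, dtype=np.int64))


def permutation_trend_test(
    values: Sequence[float],
    grades: Sequence,
    n_perm: int = 10_000,
    seed: int = 0,
    statistic: str = "jonckheere",
    order: Optional[Sequence] = None,
) -> TrendTestResult:
    """One-sided permutation p-value for an increasing trend across grades.

    Monte-Carlo mode uses the plus-one convention
    p = (1 + #{T* >= T_obs}) / (1 + n_perm); when the number of distinct
    assignments of values to groups is <= n_perm the test instead
    enumerates them all and reports the exact p = #{T* >= T_obs} / total.
    Degenerate all-equal values return p = 1 with a warning.
    """
    if statistic not in STATISTIC_KINDS:
        raise ValidationError(f"unknown statistic {statistic!r}")
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    v = np.asarray(values, dtype=float)
    ranks = _grade_ranks(grades, order)
    groups = sorted(set(ranks.tolist()))
    if len(groups) < 2:
        raise ValidationError("need >= 2 non-empty groups")
    sizes = [int((ranks == g).sum()) for g in groups]

    if statistic == "jonckheere":
        ii, jj = _cross_pairs(ranks)

        def stat(vm: np.ndarray) -> np.ndarray:  # vm: (m, n) value rows
            return (vm[:, jj] > vm[:, ii]).sum(axis=1) + \
                0.5 * (vm[:, jj] == vm[:, ii]).sum(axis=1)
    else:
        w = ranks.astype(float) - ranks.mean()

        def stat(vm: np.ndarray) -> np.ndarray:
            return vm @ w

    t_obs = float(stat(v[None, :])[0])

    if np.ptp(v) == 0:
        warnings.warn("all values identical; trend test is degenerate (p = 1)")
        return TrendTestResult(t_obs, 1.0, 0, seed, statistic, sizes, True)

    total = n_distinct_assignments(sizes)
    if total <= n_perm:
        # exact test: enumerate distinct label assignments over fixed values
        hits = 0
        for lab in _enumerate_label_vectors(ranks):
            if statistic == "jonckheere":
                i2, j2 = _cross_pairs(lab)
                t = float((v[j2] > v[i2]).sum() + 0.5 * (v[j2] == v[i2]).sum())
            else:
                w2 = lab.astype(float) - lab.mean()
                t = float(v @ w2)
            hits += t >= t_obs - _EPS
        return TrendTestResult(t_obs, hits / total, total, seed, statistic,
                               sizes, True)

    rng = np.random.default_rng(seed)
    hits = 0
    # permute compact value codes (comparisons only need the ordering) and
    # chunk so the (chunk x pairs) comparison grid stays cache-friendly
    if statistic == "jonckheere":
        codes = np.unique(v, return_inverse=True)[1].astype(np.int32)
        n_pairs = len(_cross_pairs(ranks)[0])
    else:
        codes = v
        n_pairs = len(v)
    chunk = max(1, min(n_perm, int(2e6 // max(1, n_pairs))))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        vm = rng.permuted(np.tile(codes, (m, 1)), axis=1)
        hits += int((stat(vm) >= t_obs - _EPS).sum())
        done += m
    p = (1 + hits) / (1 + n_perm)
    return TrendTestResult(t_obs, p, n_perm, seed, statistic, sizes, False)


def assemble_trend_inputs(
    samples: Sequence,
    snv_counts: dict,
    cnv_counts,
    callable_mb: float,
) -> Tuple[Tuple[List[float], List[Grade]], Tuple[List[float], List[Grade]]]:
    """Build the two value/grade vectors the trend test is applied to.

    Vector 1: per-sample high-confidence mutation rate, mutations per Mb of
    the callable region. Vector 2: per-sample per-chromosome altered-segment
    counts, flattened, each carrying its sample's grade.
    """
    if callable_mb <= 0:
        raise ValidationError("callable region size must be positive")
    grade_of = {}
    for s in samples:
        if s.grade is None:
            raise ValidationError(f"sample {s.sample_id} has no grade")
        grade_of[s.sample_id] = s.grade
    missing = set(snv_counts) - set(grade_of)
    if missing:
        raise ValidationError(f"samples without grades: {sorted(missing)}")

    rate_values = [snv_counts[sid] / callable_mb for sid in snv_counts]
    rate_grades = [grade_of[sid] for sid in snv_counts]

    cnv_values: List[float] = []
    cnv_grades: List[Grade] = []
    for sid in cnv_counts.index:
        for chrom in cnv_counts.columns:
            cnv_values.append(float(cnv_counts.loc[sid, chrom]))
            cnv_grades.append(grade_of[sid])
    return (rate_values, rate_grades), (cnv_values, cnv_grades)
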