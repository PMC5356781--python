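# Methods

This note documents the models, defaults and numerical choices behind
`nodulephylo`, and what the synthetic-data tests do and do not establish.

## Problem setting

One patient contributes several tissue samples: a cirrhotic background
sample and two or more neoplastic nodules graded
CIRRHOSIS < LGDN < HGDN < HCC. Inputs per sample are somatic SNV calls
(chrom, 1-based pos, ref, alt, total depth, alt-allele depth, optional
functional class) and copy-number segments (0-based half-open intervals
with a non-negative real copy value; callers may emit integer calls or
continuous ratios — interpretation is deferred to the discretization
thresholds). Chromosome names are opaque strings; a warning is emitted
when inputs mix `chr`-prefixed and bare names, but nothing is rewritten.

## SNV landscape

**High-confidence filter.** depth ≥ 20 *and* VAF ≥ 0.20, both inclusive
(a small epsilon guards the VAF comparison against floating-point
representation of 0.2). The filter is order-preserving, idempotent and
distributes over concatenation.

**VAF comparison (DN vs HCC).** A two-sided permutation test on the
rank-sum (Mann–Whitney U) statistic under label shuffling. The exact test
by full enumeration of label splits is used whenever C(n, n_a) ≤ n_perm
(p = count/total); otherwise Monte-Carlo with the plus-one convention
p = (1 + #{|U* − E| ≥ |U − E|}) / (1 + n_perm), which keeps the test
valid. A permutation rank-sum was chosen over the normal-approximation
test because per-nodule variant counts are small; it is a documented
substitute, not a claim about which test any particular study used.

**Overlap.** Mutation identity is the exact tuple (chrom, pos, ref, alt).
Group-level overlap (all DNs vs HCC) is computed on the union of the
group's mutation sets; the full pairwise matrix is also reported.
Jaccard is undefined (an error) when both sets are empty.

## Copy-number characters

Segments are discretized per locus: AMP at copy ≥ 3, DEL at copy ≤ 0.5,
NEUTRAL otherwise (thresholds inclusive and configurable). The genome is
tiled with 100-kb bins; a bin takes the state of the segment covering its
**midpoint** (NEUTRAL if none). Midpoint assignment rather than a
fractional-overlap rule is deterministic, independent of segment order,
and requires no extra tie-break parameter. Bins neutral in every sample
are dropped before tree search — they cannot affect parsimony lengths.

Two encodings are implemented because both views of the data are useful:
`binary-pair` (two presence/absence characters per bin: amplified?,
deleted?) is the default; `ordered-ternary` (one additive character,
DEL = 0 < NEUTRAL = 1 < AMP = 2) treats loss→neutral→gain as an ordered
series. Both agree on which (sample, bin) cells are non-neutral, and the
report records which encoding produced a tree.

## Wagner parsimony

Characters are ordered/additive: the cost of an edge is the absolute
state difference. Lengths are computed by Farris interval propagation on
the tree rooted at an arbitrary leaf; each internal node carries, per
character, the interval of states attainable in a minimal reconstruction
of its subtree, and disjoint child intervals contribute their gap to the
length. The implementation contract is equality with brute-force
minimization over all internal state assignments, which the test suite
enforces on hundreds of random instances; on binary characters the length
provably coincides with Fitch parsimony (cross-checked against an
independent Fitch implementation).

**Search** is exhaustive over all (2n−5)!! unrooted binary topologies,
capped at 10 leaves. Per-patient taxon counts here are at most a handful
of nodules plus the cirrhotic background and the `NORMAL` outgroup, so
exactness is affordable and removes all search stochasticity. Every
minimum-length topology is returned; ties are summarized by a strict
consensus (the bipartitions common to all MPTs).

**Edge changes.** One minimal reconstruction is attached per tree: root
at `NORMAL` (or the first taxon), then in preorder assign each internal
node the state in its down-pass interval closest to its parent's assigned
state. For additive characters this clipping rule is length-preserving
and deterministic; it is one of possibly many minimal reconstructions,
and per-edge counts always sum to the Wagner length (tested). Trees are
serialized as Newick with change counts as branch lengths, displayed from
the node adjacent to the root taxon.

An explicit all-ancestral `NORMAL` taxon (all-zero SNV row, all-neutral
CNV row) is included by default, so trees are displayed from the
non-neoplastic state; it is switchable off.

## Trend test

The stepwise-increase hypothesis across grades is tested by permutation
(default n_perm = 10,000). The default statistic is Jonckheere–Terpstra
(cross-grade concordant pairs, ties ½); a linear contrast of values
against centred grade ranks is available behind a flag, and the output
records which statistic was used. Values are shuffled against the fixed
grade labels; the one-sided Monte-Carlo p uses the plus-one convention.
Whenever the number of distinct assignments n!/(n₁!…n_k!) is ≤ n_perm the
test switches to exact full enumeration and reports p = count/total (no
plus-one; the observed assignment is one of the enumerated ones).
All-equal input values are degenerate and return p = 1 with a warning.

The test is applied to (1) per-sample high-confidence mutation rates —
counts divided by a configured callable-region size in Mb, since no
universal denominator exists for exome panels — and (2) per-sample
per-chromosome altered-segment counts, flattened with grade labels.
Calibration (null rejection at 5 % within [0.03, 0.07]) and power
monotonicity in effect size are asserted in the acceptance suite. No
multiple-testing correction is applied across chromosomes.

## Synthetic cohorts

The generator emulates a four-patient multifocal design (one cirrhosis,
LGDN, HGDN and HCC sample each) with controllable event rates.

- **linear** model: one transformed ancestor; trunk SNVs (default
  expected 50) and trunk CNV events are shared by all tumor nodules, and
  each nodule adds private SNVs (default 10) and CNV events on its
  terminal branch. The lineage is recorded as a parent map. The trunk is
  a single shared ancestor rather than a grade-ordered chain of
  inheritance: private mutations stay private to their nodule, so two
  nodules with a fixed 50-SNV trunk and 10 private SNVs each have
  true Jaccard exactly 50/70.
- **independent** model: every nodule's whole SNV set (default expected
  50 when studying this model) is drawn privately, with positions drawn
  without replacement across the patient — distinct nodules share zero
  true SNVs by construction.

Positions are uniform over a small synthetic exome (22 chromosomes ×
3 Mb) rather than a real capture design; downstream logic depends only on
coordinates. Counts are Poisson by default (`poisson_counts=False` makes
them exact for worked examples). CNV events have exponential lengths
(mean 500 kb, floor 10 kb — large enough that a typical event spans
several 100-kb bins, as segment-level calls from read-depth callers do),
are clipped at chromosome ends with a logged warning, redrawn on
collision, and split ~5:1 between amplifications (integer copy 3–5) and
deletions (copy 0 or 0.5), mirroring the observed excess of gains over
losses in liver nodules; each nodule carries about 7 events.

**Observation model.** Per site, depth ~ round(Normal(106.2, 30.3))
truncated at 1 read — matching the two reported moments of
whole-exome target depth; the distribution itself is a modeling choice.
Alt reads ~ Binomial(depth, purity·CCF/2), the standard diploid
heterozygous expectation; default purity 0.7. Trunk mutations are clonal
(CCF 1); private mutations are subclonal with CCF ~ Uniform(0.2, 1) by
default — a stand-in for unquantified dysplastic-nodule subclonality,
exposed as `subclonal_private` / `private_ccf_range`. Sites with zero
observed alt reads are not emitted (a somatic caller produces no record
there). Emitted copy values equal the true integer calls by default
(`cnv_copy_noise_sd` adds Gaussian noise when continuous ratios are
wanted). Optional per-grade rate multipliers scale private SNV and CNV
rates to create stepwise-increase scenarios for the trend test.

**Reproducibility.** Each (patient, sample) pair gets its own RNG stream
keyed by (seed, patient index, CRC32 of the stream name), so adding a
sample never changes another sample's draws; identical configurations
produce byte-identical outputs. Cross-nodule position uniqueness is
enforced by rejection against the patient-wide set of used positions,
which preserves per-sample streams except in the (vanishingly rare)
event of a collision.

**What a green test does not establish.** The generator has no
trinucleotide mutation signatures, no FFPE deamination artifacts, no
germline contamination, no mapping or calling error model, and uniform —
not capture-biased — positions. Recovery results therefore speak to the
statistical machinery under the stated noise model, not to robustness
against real-data artifact spectra.

## Evolution-mode classification

Per patient, on the *observed, filtered* mutation sets of the tumor
nodules: trunk-shared fraction = |intersection| / |union|. The call is
`linear` when the fraction ≥ threshold, `nonlinear` when the fraction is
below threshold *and* every pairwise DN–HCC Jaccard is below threshold,
`indeterminate` otherwise (including an empty union). The threshold
(default 0.05) is an invented operational cutoff — the underlying
biological argument is qualitative — and is config-exposed. Cohort-level
calls are the majority over patients. Under the default simulation world
the two models are separated by two orders of magnitude in trunk-shared
fraction (~0.8 vs 0.0), so the classification is insensitive to the
precise cutoff.

## Numerical and degenerate-input conventions

- VAF at zero depth is an error, never NaN; `ref == alt`, overlapping
  same-sample segments, `start ≥ end`, negative copy values, unknown
  grades and duplicate (patient, sample) pairs are all rejected at parse
  time with the line number.
- Threshold comparisons (filter, CNV discretization) are inclusive.
- Two-taxon matrices yield the degenerate single-edge tree with length
  equal to the Manhattan distance between the rows.
- All-constant matrices tie every topology at length 0; ties are
  reported in full plus strict consensus.
- Jaccard of two empty sets, a single-group trend test, and a VAF
  comparison with an empty side are errors, not silent defaults.

## Known limitations

- Exhaustive tree search is exponential; the 10-leaf cap reflects the
  intended per-patient use. No heuristic search is provided.
- The permutation trend test is one-sided (increasing) by design;
  umbrella or two-sided ordered alternatives are out of scope.
- VCF input is limited to biallelic SNVs with DP/AD-style fields; indels
  and annotation fields are ignored.
- The classifier's threshold semantics assume at least one dysplastic
  and one carcinoma sample per patient; patients missing a grade fall
  back to trunk-fraction-only behavior.
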