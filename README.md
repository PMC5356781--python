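# nodulephylo

Clonal-evolution analysis for multifocal liver nodules.

Cirrhotic livers frequently carry several neoplastic nodules at once:
low- and high-grade dysplastic nodules (LGDN, HGDN) alongside
hepatocellular carcinoma (HCC). A central question for these patients is
whether the carcinoma arose *linearly* — by stepwise clonal succession
from the dysplastic nodules, so that all lesions share a mutational trunk
— or *nonlinearly*, with each nodule founded independently and the
malignant clone expanding on its own ("big-bang"-like). The two
hypotheses make sharply different predictions about multi-region somatic
sequencing data: a shared trunk of SNVs and conserved copy-number
breakpoints under linear evolution, versus nearly disjoint mutation sets
and discordant copy-number profiles under independent origins.

`nodulephylo` implements the full analysis that discriminates the two,
for whole-exome-style somatic variant calls and copy-number segment
profiles from multiple nodules per patient:

- **High-confidence SNV filtering** — keep calls with read depth ≥ 20 and
  variant allele frequency (VAF) ≥ 20 % (both inclusive), plus per-class
  tallies and a permutation rank-sum comparison of VAF distributions
  between dysplastic nodules and carcinoma.
- **Overlap statistics** — exact mutation-identity intersections and
  Jaccard indices between nodules, per pair and for the pooled DN set
  against HCC.
- **Copy-number characters** — segments are discretized (amplified at
  copy ≥ 3, deleted at copy ≤ 0.5) and projected onto a fixed 100-kb
  genomic tiling; each bin takes the state of the segment covering its
  midpoint. Both a binary-pair encoding (amplified?, deleted?) and an
  ordered ternary encoding (loss < neutral < gain) are available.
- **Wagner parsimony trees** — per patient, an exact exhaustive search
  over all (2n−5)!! unrooted binary topologies under the ordered-character
  (additive) criterion, edge cost |i−j|. All maximum-parsimony trees are
  reported with per-edge change counts plus a strict consensus, rooted for
  display at an all-ancestral `NORMAL` taxon.
- **Trend test** — a one-sided permutation test (10,000 permutations by
  default, exact enumeration when feasible) of a stepwise *increase*
  across the ordered grades cirrhosis < LGDN < HGDN < HCC, using the
  Jonckheere–Terpstra statistic

  JT = Σ_{k<l} #{(x ∈ grade k, y ∈ grade l) : y > x} + ½·#ties,

  applied to per-sample mutation rates (per Mb) and per-chromosome CNV
  counts.
- **Evolution-mode classifier** — the trunk-shared fraction
  |∩ tumor SNV sets| / |∪ tumor SNV sets| together with the pairwise
  DN–HCC Jaccard indices yields a `linear` / `nonlinear` /
  `indeterminate` call per patient.
- **Synthetic cohorts** — a generator that simulates multifocal patients
  under either model with known ground truth: trunk/private SNVs, CNV
  events, binomial read sampling at ~106× (± 30) depth, tumor purity, and
  optional subclonal cell fractions. Every downstream stage is exercised
  against it.

## Worked example

Simulate a four-patient cohort under the independent-origin model and run
the whole pipeline:

```python
from nodulephylo import SimulationConfig, PipelineConfig, run_cohort

sim = SimulationConfig(model="independent", n_private_snv=50, seed=1)
pconf = PipelineConfig(callable_mb=sim.genome_size / 1e6, seed=1,
                       genome=list(sim.genome))
cohort = run_cohort(sim, pconf)
rep = cohort.reports[0]
print(rep.snv_counts_filtered)
print(rep.dn_hcc_overlap)
print(rep.snv_trees_newick[0])
print(rep.evolution)
print(cohort.summary["cohort_evolution_call"])
```

prints

```
{'P01_CIRRHOSIS': 0, 'P01_LGDN': 28, 'P01_HGDN': 29, 'P01_HCC': 23}
{'n_dn': 57, 'n_hcc': 23, 'n_shared': 0, 'jaccard': 0.0}
(NORMAL:0,P01_LGDN:28,(P01_HGDN:29,(P01_CIRRHOSIS:0,P01_HCC:23):0):0);
{'trunk_shared_fraction': 0.0, 'threshold': 0.05, 'call': 'nonlinear'}
nonlinear
```

Each nodule carries a few dozen high-confidence SNVs, none of which are
shared between the dysplastic nodules and the carcinoma (`n_shared: 0`),
so every lesion hangs off the tree on its own long branch (branch lengths
are parsimony change counts) and the patient — and cohort — is classified
`nonlinear`. Rerunning with `model="linear"` yields a dominant shared
trunk (trunk-shared fraction ≈ 0.8) and a `linear` call.

The same pipeline is available from the shell:

```sh
nodulephylo simulate --model independent --n-patients 4 --seed 1 --out sim/
nodulephylo run-patient --dir sim/ --patient P01 --out P01.json
nodulephylo run-cohort --model independent --seed 1 --out run/
```

plus stage-level subcommands `snv`, `cnv`, `tree` and `trend` for
file-based inputs (TSV/VCF variant tables, SEG segment tables, PHYLIP-like
character matrices).

## Acceptance script

`scripts/acceptance.py` re-runs the package end to end from scratch:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

It simulates a four-patient cohort (cirrhosis + LGDN + HGDN + HCC per
patient) under each generating model at the default depth/purity world,
runs the complete analysis — filtering, overlap, parsimony trees, trend
tests, evolution-mode classification — prints a one-line summary per
model, and writes the results manifest to `--out`.

See `docs/methods.md` for the model assumptions, parameter defaults and
numerical choices.
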