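# Methods

## Scope and model

`denovotest` implements a single-gene de novo mutation (DNM) significance
framework for trio cohorts, plus the summary statistics that typically
accompany such an analysis. The core assumption throughout is that DNM counts
per consequence class are Poisson: mutations arise independently per
transmitted gene copy with a small class-specific probability, so for a class
rate `r_c` (probability per transmission per generation) and `N` probands the
count is `Poisson(2·N·r_c)`. This ignores inter-individual rate variation,
sex-specific and parental-age effects, and assumes complete, unbiased DNM
ascertainment in all sub-cohorts.

### Class rates from trinucleotide contexts

Rather than consuming opaque per-gene rate estimates, the package re-derives
class rates from a 64×3 trinucleotide-context table by exhaustively
classifying all `3L` possible coding substitutions of a gene (standard genetic
code) and summing context rates per class. Conventions:

* Coordinates are 0-based half-open for exons, 0-based spliced CDS positions
  in translation order internally; user-facing variant files are 1-based
  (HGVS-like `c.` positions) and converted at parse time. Minus-strand genes
  are stored already reverse-complemented.
* CDS-edge positions use supplied flank bases for context; when flanks are
  absent, each edge site contributes the gene's mean interior per-site rate
  (split evenly over the three alternates) rather than being dropped.
* Canonical splice sites: 4 essential dinucleotide positions per intron
  (GT donor + AG acceptor), each at the gene's mean per-site SNV rate;
  configurable via `splice_positions_per_intron`.
* Indels carry no positional model: `frameshift = 1.25 × nonsense` and
  `inframe_indel = 0.1 × frameshift` by default (`IndelParams`), echoed in the
  output provenance block. These are conventional scalings of the kind used in
  published constraint models and are meant to be overridden when calibrated
  estimates exist.
* Stop-lost and start-lost substitutions default to missense (configurable),
  keeping the synonymous/missense/nonsense partition exhaustive.

An invariant worth stating: the synonymous + missense + nonsense rates always
sum to the total per-site rate mass of the gene (conservation), and the
aggregation is tested against a brute-force per-substitution enumeration.

### Enrichment, clustering, and model combination

* `P(X ≥ k)` uses the exact Poisson survivor function; `k = 0` returns 1. λ is
  never rounded.
* The missense clustering statistic is the geometric mean over all unordered
  pairs of `|pᵢ − pⱼ| + 1` in spliced CDS coordinates. The +1 offset keeps the
  geometric mean defined when two DNMs hit the same base; because it is a
  monotone transform applied identically to observed and simulated values,
  the empirical p-value is unchanged for configurations without coincident
  hits and well-defined for those with them.
* Null placements are drawn **with replacement** (independent mutational
  events may recur at a site), weighted by the context-specific rate of each
  missense-producing (position, alternate) pair. Default 1,000,000
  simulations; the add-one-smoothed p `(count + 1)/(n_sim + 1)` is reported
  alongside the raw proportion and is the value fed into Fisher combination,
  so a zero count never produces `ln 0`.
* Fisher's method uses the exact χ² survivor function with `2m` degrees of
  freedom. Empirical p-values of exactly 0 from other sources must be floored
  explicitly (conventionally `1/(n_sim + 1)`); the package refuses silent
  zeros.
* Model selection takes the smaller of the LoF-only and combined
  functional+clustering p-values and doubles it (Bonferroni for two models),
  capped at 1. Ties select the LoF model, making output deterministic. When a
  cohort has fewer than two positioned missense SNVs there is no clustering
  test; the combined statistic then falls back to the functional enrichment p
  alone rather than combining with a fictitious p = 1.

### Phenotype similarity

Information content uses the natural logarithm (base only rescales scores; the
most-informative-common-ancestor choice and the permutation p are invariant).
A term's ancestor set includes the term itself, so identical terms are their
own MICA (standard Resnik convention). Usage counts are set-semantic: a
proband contributes at most once to a term however many of its terms descend
from it. Query terms never used in the reference cohort take the fallback
`IC = ln(N + 1)` (singleton usage in a cohort of N + 1); zero-usage terms are
otherwise excluded as MICA candidates since they carry no cohort evidence.
Null sets are drawn uniformly without replacement within each set from the
full annotated cohort, 100,000 sets by default. The model class vectorises the
whole computation (term-pair MICA matrix + padded term-index arrays); the
scalar reference implementations remain in the module and the test suite pins
the two paths together.

### Gene-set and DE summaries

The hypergeometric test is one-tailed (over-representation), exact, and query
genes absent from the expressed-gene background are dropped (with a count
recorded) before overlap counting. BH adjustment across sets is available.
Percentages in DE summaries are rounded half-to-even at one decimal;
cross-tissue union/concordance arithmetic validates its own consistency
(shared ≤ min totals, concordant ≤ union).

### Clinical matrix and behavior

Feature frequencies are reported over informative (non-missing) individuals
only and **truncated** toward zero — this is deliberate: the published table's
own summary percentages (e.g. 87% from 7/8, 55% from 5/9, 62% from 5/8) are
floored, not rounded. Qualified cells ("retro", "broad based", "ataxia")
count as present for their binary feature, matching the table's own summary
column. Milestone intervals (`24-30`) contribute their midpoint; annotated
non-numeric cells are treated as missing.

Preference indices are `(t₁ − t₂)/(t₁ + t₂)`, antisymmetric and bounded in
[−1, 1]; the three-chamber variant subtracts the habituation-phase (innate)
preference index — subtraction being the simplest transform consistent with
the reported 0.15 innate offset, though the original normalisation is not
fully specified.

Movement-bout segmentation is hysteretic: a bout opens at the first of two
consecutive frames ≥ 2.0 cm/s and closes at the first frame < 1.75 cm/s whose
successor is also < 1.75 cm/s *or* which ends the trace. The two-frame
persistence is counted on the pair straddling the event (one documented
reading of "over two frames"); the end-of-trace closing rule makes appending
sub-stop-threshold frames a strict no-op. Thresholds are configurable; frame
rate is metadata, not hard-coded.

## Synthetic data: what it does and does not emulate

The generators reproduce the *statistical structure* the tests assume —
Poisson class counts at configurable enrichment factors γ, rate-weighted or
window-clustered positional sampling, rooted-DAG ontologies with a rare shared
"syndrome" term, velocity traces with known bout schedules — under a single
root seed fanned out into independent substreams (`spawn_seeds`), so outputs
are bit-reproducible and adding a generator never perturbs another's stream.

They do **not** imitate real human mutation-rate maps (the `cpg_elevated` mode
is a one-parameter caricature of CpG hypermutability), real HPO term
frequencies, ascertainment bias, or tracking artifacts in behavioral data.
Passing calibration tests therefore demonstrates correctness of the
*machinery* under its stated model, not robustness to the ways real cohorts
violate it.

Default study conditions used by the calibration tests and the acceptance
script, chosen once as field-realistic: a 500-codon gene on a uniform
3 × 10⁻⁹ per-site per-alternate table (per-gene missense rate ≈ 10⁻⁵, LoF
≈ 1.6 × 10⁻⁶ — the scale of published per-gene estimates), a combined cohort
of 12,689 trios (4,295 + 2,206 + 50 + 6,138), 2,000 null replicates for
type-I-error calibration with 2,000 clustering simulations per replicate that
needs one, 200 replicates for the clustered alternative, 10,000 permutation
samples against exhaustively enumerable N = 6 cohorts, and 100 seeds × 10
scheduled bouts for noisy bout recovery. The clustering default of 10⁶
simulations and the permutation default of 10⁵ sets are kept for production
use; calibration loops use smaller, stated sizes.

## Numerical notes

* Exact-tail agreement targets: Poisson vs direct series summation to 1e−12
  absolute; Fisher vs closed-form even-df χ² tail to 1e−12; hypergeometric vs
  exhaustive enumeration to 1e−12 for backgrounds up to M = 20.
* Monte-Carlo checks use 3-standard-error bands around enumeration oracles.
* Proximity keys in the exact enumeration are rounded at 12 decimals to merge
  floating-point-identical statistics.
* Degenerate inputs fail loudly: empty weight tables, all-missing clinical
  rows, unannotated probands, p = 0 without a floor, stop threshold above
  start threshold.

## Known limitations

* The published *BCL11A* headline p-value (6.4 × 10⁻¹⁵) is not reproducible
  from first principles: it depends on externally estimated per-gene class
  rates and an unstated model choice. The package instead verifies each
  component of that statistic exactly and calibrates the pipeline end-to-end
  on synthetic nulls.
* No genome-wide multi-gene FDR, no Bayesian (TADA-style) integration, no
  3D-structure clustering, no ortholog mapping, and no re-analysis of the
  RNA-seq itself — published DE counts enter only as inputs to summary
  arithmetic.
* The indel and splice-site rate models are conventions, not calibrated fits;
  both are parameters, reported in output, and should be replaced when better
  estimates are available.
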