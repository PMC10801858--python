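# Methods

This note documents the models, estimators and numerical choices behind
`ribofitscape`, and what the synthetic-data generator does and does not
emulate.

## Fitness statistic

For genotype *v* in replicate *r*, fitness is the log enrichment relative
to the wild type:

    f_vr = ln[ ((c_post,v + a) / (c_post,wt + a)) / ((c_pre,v + a) / (c_pre,wt + a)) ]

* **Log base.** Natural log by default; any base via `log_base`. Only the
  scale changes.
* **Pseudocount.** `a = 0.5` by default, applied symmetrically to all four
  counts. The half-count is the classical correction that cancels the
  first-order concavity bias of `E[ln(C + a)]` around `ln λ` for Poisson-like
  counts, so fitness estimates are effectively unbiased once expected counts
  exceed ~15. With `a = 0`, genotypes with zero post-selection counts are
  censored at −∞ and flagged; censored replicates are excluded from
  aggregation.
* **Replicate aggregation.** Unweighted mean across replicates in which the
  genotype was observed pre-selection; SE from replicate scatter
  (`sd/√n`, ddof = 1), undefined below two replicates. A pooled-counts mode
  (sum counts across replicates, then one ratio) is available; per-replicate
  is the default because it yields a replicate-based error estimate.
* **Filtering.** Default `min_pre = 10` in all replicates. Ten pre-selection
  reads bound the Poisson noise of the enrichment ratio at roughly 1/√10 ≈ 0.3
  log units per replicate; the threshold is exposed, not baked in.

The wild type scores exactly 0 in every replicate by construction, and the
statistic is invariant to uniform depth scaling within any
(replicate, phase) — both are asserted in the test suite.

## Genotype calling

Reads are assumed merged, oriented and full-length. Calling is global
alignment against the subunit reference with affine gaps
(match +1, mismatch −1, gap open −4, gap extend −2): library variants are
full-length with rare single-nucleotide deletions, so end-to-end alignment
with expensive gaps is the right prior. Reads of exactly reference length
take a direct positional-comparison fast path, which is the optimal global
alignment under this scoring whenever the mutation count is small; a
pathological equal-length read containing a compensating insertion+deletion
pair is rejected as `too_many_mutations` rather than `insertion` (either
way it is rejected). Reads longer than the reference necessarily contain an
insertion and are rejected outright; reads shorter than
`L − max_mutations` cannot be explained by allowed single-nt deletions and
are rejected as incomplete coverage.

`max_mutations` should match the expected library order. This is what makes
accuracy-among-accepted-reads high: at per-base error 10⁻³ and L = 152,
~14% of reads carry at least one sequencing error, so demanding the exact
true genotype of *all* reads is impossible (bounded at (1−e)^L ≈ 86%); with
`max_mutations` at the library order those reads fail the threshold and are
rejected instead of being miscalled, and >99% of accepted reads receive
their true genotype.

Deletions inside homopolymer runs have no unique coordinate; the caller's
alignment output is the canonical form, and calling is a fixed point
(re-calling a called genotype's rendered sequence returns it unchanged).

## Epistasis

For a double mutant *ab* with constituent singles *a* and *b*:

    ε = f_ab − f_a − f_b

Additivity in log space is the standard multiplicative null given that
fitness is already a log enrichment. SE by error propagation,
`se_ε = √(se_ab² + se_a² + se_b²)`.

**Significance.** `t = ε/se_ε` against a Student-t reference with
Welch–Satterthwaite effective degrees of freedom combining the three
replicate-variance estimates, then Benjamini–Hochberg FDR across all tested
pairs (default 5%). With triplicate data each SE carries only 2 df; a
normal reference would be badly anti-conservative (P(|t₂| > 1.96) ≈ 0.18)
and the BH-significant fraction on a truly additive landscape would exceed
the FDR level several-fold. With the t reference the null calibration test
(additive landscape, FDR 10%) yields ~0% significant calls and a mean-ε
z-score near 0.

**Structure classes.** A double whose two positions form an annotated base
pair is classified by its mutant bases: Watson-Crick complementary →
`WC_pair`, G·U → `wobble_pair`, otherwise `pair_disrupting`; doubles at
non-annotated position pairs are `unpaired`. The same base-combination rule
applied to a single mutation and its wild-type partner base classifies
partner states for the wobble-versus-disrupting contrast. Doubles involving
deletions are excluded by default: pair classification and residue-distance
assignment are ill-defined for a deleted residue.

**Distance annotation.** 3D residue distances come from a
`DistanceMatrix`; the default metric is the minimum heavy-atom distance
(contacts — pairs, stacks, A-minor interactions — act through closest
approach), with C1′–C1′ available. The metric is recorded in the output
metadata. Distance bins are right-open on user-supplied edges; empty bins
are reported with n = 0.

**Known bias of the end-to-end pipeline.** Read misassignment at sequencing
error e moves a fraction ~e/3 of wild-type reads into each single-mutant
count at the mutated position. Because the wild type is the most abundant
and fittest genotype, this inflates single-mutant fitness slightly, which
propagates into a *negative* bias of mean ε of order 0.1 at e = 10⁻³ and
realistic depths. This is a property of naive count-based enrichment
pipelines generally, not of the ε statistic: the calibration tests
therefore draw multinomial counts directly, while the recovery tests run
the full read-level pipeline. Correcting misassignment (e.g., by
error-aware count deconvolution) is out of scope.

## Structure I/O

PDB and mmCIF are read through gemmi: model 1 only, hydrogens ignored,
alternate locations resolved to highest occupancy. Chains map to subunit
coordinate systems via `ChainMap` (chain → subunit id + numbering offset).
B-factor export writes each residue's mean fitness into every atom record,
clamped to the fixed-width field range [−99.99, 999.99]; unmapped residues
get a 0.00 sentinel and are returned for reporting, so files stay loadable
in standard viewers. Coordinates are untouched and values round-trip to the
2 decimals the format carries.

## FidelitySeq

Each read is validated by exact matches to the two constant anchors
flanking the randomized substrate k-mer (exact by default — anchors are
short constant flanks and an error there should reject the read, not
distort the estimate). The extracted k-mer is compared base-by-base to the
complement of the template-encoded bases at the junction. Substrate
positions are numbered N1..Nk, 5′→3′ of the 5′-triphosphorylated substrate,
in both synthesis modes; reads show the product strand 5′→3′, so in the
reverse (3′→5′) mode extracted bases map onto substrate positions in
reverse order. Applied to mode-consistent data the two modes give
identical tables after this relabeling, which is tested.

Per-position fraction correct carries a Wilson 95% interval
(n = 10,000-read simulations cover the true value in ~94–95% of runs). The
per-nucleotide fidelity is the arithmetic mean of the per-position
fractions; the aggregation is not uniquely determined by the assay, so a
geometric mean (the per-k-mer success interpretation) is available behind a
flag.

Substrate-competition experiments reduce to per-replicate fractions
correct/(correct+incorrect), reported as mean ± SD (ddof = 1) across
experiment replicates. Composition bias reports per-k-mer
log₂(observed/expected) against a uniform or encoded-spectrum expectation,
with a −∞ sentinel for unobserved k-mers, plus the mean log₂ ratio as a
function of A+U content — AU-rich substrate depletion shows up as a
monotone decline of that trend.

## Synthetic-data generator

The generator is first-class, tested code; it defines the conditions under
which every recovery and calibration property is evaluated.

* **References.** Random sequences, 152 nt for the catalytic-subunit-like
  case and 124 nt for the accessory-subunit-like case, with annotated stem
  pairs forced Watson-Crick in the wild type. The default structure is 8
  stems of 4 pairs (64 of 152 positions paired).
* **Single effects.** Mixture per (position, alternative): 30% neutral
  N(0, 0.1), 55% deleterious N(−2, 0.8), 15% lethal point mass at the floor
  f_min = −5; all values floored at f_min. Substitutions that leave a G·U
  wobble with the wild-type partner are scaled by (1 − wobble_rescue),
  default rescue 0.5 — wobbles partially preserve helix geometry.
* **Pair terms.** ε_true = +2 for mutant combinations restoring a
  Watson-Crick pair at an annotated position pair, +2 × 0.5 for
  wobble-restoring combinations, 0 otherwise. Unpaired doubles are exactly
  additive before flooring.
* **Library and selection.** Class fractions wt 0.2 / singles 0.4 /
  doubles 0.4, uniform within class. A realistically doped library at
  ~0.3% per-position mutagenesis would leave ~2% of reads for doubles,
  making pairwise epistasis unmeasurable at desk-scale depth; the class
  balance is therefore a deliberate idealization. Selection is one round of
  exponential enrichment, post ∝ pre·e^{s·f}, matching a single pre/post
  comparison per replicate; multi-round dynamics, PCR jackpots and
  bottlenecks are not modeled. Counts are multinomial at configured depth
  (default 5×10⁵ reads per phase, 3 replicates, s = 1).
* **Sequencing error.** Uniform substitutions at 10⁻³ per base; indel
  errors are deliberately absent so the deletion-calling surface is tested
  only by true deletions. Quality scores are constant.
* **Toy structure.** One residue (C1′ + P pseudo-atoms) per position;
  annotated pair partners sit 5 Å apart in a private cluster on a 40 Å
  grid, all other residue pairs ≥ 35 Å. This makes the epistasis-distance
  decay recoverable by construction, with occupied bins at <8 Å and ≥15 Å.
* **Fidelity reads.** The substrate k-mer distribution is computed exactly
  from the per-position error vector (mismatch probability e_p, uniform
  over the three alternatives), optionally multiplied by per-k-mer
  incorporation weights, then sampled multinomially — so generated data
  match the estimator's error model exactly, by design.

Everything is deterministic given the seed, and truth tables accompany all
generated reads.

**What passing these tests shows — and does not.** Recovery and calibration
on this generator demonstrate that the estimators are correct under their
own assumptions at realistic depths. Real selection data add effects the
generator omits: PCR amplification bias, quality-dependent and indel
sequencing errors, template switching, multi-round selection, epistasis
beyond pairwise terms, and library composition far from class-balanced.
Numbers obtained on real data inherit those confounders; the
misassignment-induced negative ε bias described above is the one such
effect large enough that we quantify it here.

## Problem sizes in the standard runs

The test suite and the acceptance script run the full read-level pipeline
at 5×10⁵ reads per phase × 2 phases × 3 replicates (3×10⁶ reads) for
recovery, 3×10⁵-read multinomial count tables for null calibration, 100 ×
10,000 reads for fidelity coverage, and 40,000 reads for calling accuracy —
sizes at which the measured properties are stable across seeds.
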