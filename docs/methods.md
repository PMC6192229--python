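# Methods and design notes

This note documents the models implemented in `wrkyevol`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions that matter for reproducing output.

## Domain detection and classification

A candidate WRKY domain is assembled from two independent motif scans.

**Heptapeptide seeds.** Every 7-residue window is compared against
`WRKYGQK`. The tryptophan at position 1 must match exactly; the remaining
six positions tolerate up to `max_mismatch` substitutions (default 2).
The default budget reflects how family variants behave in practice: known
variants differ from the canonical heptapeptide at one or two positions,
with W (and usually K and Y) conserved, and a budget of 2 keeps variant
domains such as `WRKYGKK` while a W-less window can never seed a domain.
Overlapping candidate windows are resolved by fewest mismatches, then
leftmost position; the budget is configurable for sensitivity analysis.

**Zinc fingers.** Downstream of each seed, within a 120-residue window
(covers the longest pattern span of ~35 residues plus generous linker
slack), the scanner looks for C-X(x1)-C-X(x2)-H-X-H with x1 ∈ {4,5}, x2 ∈
{22,23} (C2H2) or C-X(7)-C-X(23)-H-X-C (C2HC). Matching is
case-insensitive on exact letters; the X positions accept any amino-acid
letter including X. At the same start position C2H2 is tried before C2HC
and smaller spacers first, so the leftmost-ending complete match wins
deterministically. All four C2H2 spacer combinations are held to the same
exact length constraints for every subgroup; nothing in the family
definition suggests looser spacers for IId/IIe, and exact spacers keep the
call unambiguous.

**Assembly.** Seeds claim zinc fingers greedily from the N-terminus: each
seed takes the nearest downstream zinc finger not claimed by an earlier
seed. A seed with no available zinc finger produces an invalid domain;
proteins whose domains are all invalid are excluded from the family and
listed in a separate report with the missing motif named. The domain span
runs from the heptapeptide start to the last zinc-finger residue — the
minimal motif-complete span, since the family literature does not fix
domain boundaries.

**Groups.** Two valid domains → group I (first = N-terminal, second =
C-terminal); one valid C2H2 → group II; one valid C2HC → group III; three
or more → `multi_domain` (such proteins exist but are rare, so they are
counted in their own column of the census rather than forced into group
I); zero → `unclassified`/excluded.

**Subgroups.** Group II subgroups are anchored to labeled reference
domains rather than to a phylogeny: the query domain's k-mer count vector
(k = 3) is compared to each reference by cosine similarity and the
best-scoring label wins. Ties break alphabetically and are flagged; a
best score below the floor (default 0.5) yields the mixed/unresolved label
`IIm`. Nearest-labeled-reference scoring is a deliberate replacement for
tree placement: it is deterministic, fast, needs no alignment, and reduces
to exactly the same answer when references are the true generating
templates (the recovery tests exercise this).

## Homology criteria

A pair passes when coverage of **each** sequence exceeds 0.8, identity
exceeds 80%, and — only when a hit table supplies one — E ≤ 1e-10. No
reciprocal-best-hit step is applied by default (an `rbh` option exists for
stricter orthology). With a hit table, the single best-E-value row per
unordered pair is used; HSP chaining is out of scope.

The internal aligner is Needleman–Wunsch with affine gaps (match +1,
mismatch −1, open −5, extend −2) and **free end gaps**: a length
difference then shows up as reduced coverage while identity is measured
over the aligned core, which is the semantics the coverage criterion
assumes (a 10% 3'-truncated copy gives coverage 0.9/1.0 at identity 100).
Identity is matches over aligned columns excluding end gaps; coverage is
each sequence's residues inside that region over its full length. In
internal mode the E-value criterion is waived (a global aligner has no
search statistics); the waiver is recorded in the report parameters.

## Ka/Ks estimation

The estimator is the Nei–Gojobori (1986) counting method with equal
pathway weighting and Jukes–Cantor correction.

- **Codon alignment.** The protein pair is globally aligned (BLOSUM62,
  open −10, extend −0.5) and each residue column is replaced by its source
  codon (`---` at gaps), after verifying that each CDS translates exactly
  to its protein (trailing stop trimmed; X matches anything; any mismatch
  is a hard error naming gene and position). Columns containing a gap, an
  N or a stop codon are skipped and counted.
- **Sites.** Each codon position contributes (synonymous one-step
  changes)/3 synonymous sites; changes to stop codons count as
  nonsynonymous, so N + S = 3 × compared codons exactly. Site counts are
  averaged over the two sequences.
- **Differences.** Codon pairs differing at 2–3 positions are scored by
  averaging Sd/Nd over all minimal pathways with equal weights; pathways
  through stop codons are discarded, and in the rare case that every
  pathway is blocked, all pathways are used so the pair still contributes.
- **Correction.** pN = Nd/N and pS = Sd/S are corrected by
  d = −(3/4)·ln(1 − 4p/3). The ratio is undefined (filter `undefined`,
  selection `NA`) when Ks = 0 or a proportion reaches the 3/4 ceiling.
- **Filters.** Ks < 0.01 → `excluded_low` (low divergence gives unstable
  estimates); Ks > 3 → `excluded_high` (saturation). The exclusion is
  applied on either Ks condition alone — requiring a simultaneously
  near-zero Ka would almost never trigger — with "Ka nearly 0"
  (operationalized as Ka < 1e-6) noted in the exclusion report.
- **Selection classes.** purifying / neutral / positive at Ka/Ks below,
  at (tolerance 1e-9) or above 1.

Class comparisons (ortholog vs paralog, duplicate vs singleton) use the
two-sided Mann–Whitney U test: rate and feature distributions are skewed
and the test is calibrated without distributional assumptions (the
acceptance suite checks its type-I error). p is NA when either class has
fewer than two observations.

An adapter (`kaks --import-rates`) accepts externally computed Ka/Ks
tables so results from ML codon models can be swapped into the downstream
statistics for fidelity checks; ML estimation itself is out of scope.

## Codon-usage features

Fop is optimal codons over codons with a synonymous choice; ATG, TGG and
stops never enter the denominator. The bundled default optimal set
(`plant-generic-v1`, one preferred codon per synonymous family chosen to
reflect dicot codon-usage surveys) is a pragmatic default, not an
organism-calibrated table; the set id is recorded in every output and the
set is user-replaceable (JSON). GCk is percent G+C at codon position k
with N bases excluded from numerator and denominator position-wise
(counting N as non-GC would bias GC downward under ambiguity).

## Expression statistics

RPKM values are log2-transformed with a pseudocount (default 1, because
zero RPKM is common and the transform must be defined there). A duplicate
pair's per-tissue divergence is |Δ log2|, called divergent at ≥ 1 (a
two-fold difference); the cohort statistic is the fraction of pairs with
at least one divergent tissue, plus per-tissue fractions. For correlation
grids, a pair's feature or expression value is the mean of its two members
(switchable to min/max/first and recorded in output metadata). Pearson r
is reported with stars at 0.05/0.01 and no multiple-testing correction by
default, matching the field's reporting convention; a Benjamini–Hochberg
flag and Spearman alternative are available. Near-constant inputs give
NaN rather than a spurious coefficient.

## The synthetic-data generator

The generator produces cohorts with exactly the structure the pipeline
assumes, with machine-readable truth for every planted property. Defaults
are the study conditions the package is validated under:

| parameter | default | rationale |
| --- | --- | --- |
| species × genes | 3 × 60 | mid-size multi-genome family survey |
| composition | I .14, IIa–IIe .12 each, III .14, multi .02, decoy .10 | all groups represented, rare multi-domain class, real decoy load |
| heptapeptide variant rate | 0.13 | matches the observed share of mutated domains in legume-scale family censuses |
| variant position weights | Q-position (6) 0.50, others 0.08–0.14; Q→K 0.7 | Q is the preferentially mutated site, K the preferred replacement |
| paralog omega / Ks | 0.34 / 0.19 | within-species duplicate conditions of legume WRKY pairs |
| ortholog omega / Ks | 0.28 / 0.34 | between-species conditions of the same surveys |
| expression | 14 tissues, lognormal(μ=3, σ=1.5) RPKM | seed-to-nodule tissue panel scale |
| divergence fraction / effect | 0.5 / U(1.5, 3) log2 units | "more than half of duplicate pairs two-fold divergent somewhere" |
| Fop→rate, expression→rate couplings | 1.5, 0.8 | plant codon-bias and E–R anticorrelation with clearly recoverable sign |

Design points worth knowing:

- **Planted truth is exact by construction.** Flanks, linkers and
  zinc-finger spacer filler are drawn from an alphabet without W, C or H,
  so the planted motifs are the only motifs; decoys are built to lack one
  motif provably (no W anywhere, or no C downstream of the heptapeptide).
  Copy evolution rejects nonsynonymous changes inside planted domain spans
  and never introduces W/C/H elsewhere, so labels (and subgroup templates)
  survive divergence exactly. Consequently classifier recovery on
  noise-free cohorts is a sharp 100%-or-bug test, not a benchmark.
- **The evolver is an accept/reject codon process.** Point mutations are
  proposed uniformly over positions and alternative bases (a kappa
  parameter adds transition bias; default 1 for analytic transparency),
  accepted with probability 1 if synonymous and omega if nonsynonymous,
  stop-creating proposals rejected; the process stops when oracle-counted,
  JC-corrected synonymous divergence reaches the target Ks. Because
  stop-directed changes can never happen but still count as nonsynonymous
  sites in NG86, the realized and estimated Ka/Ks sit ~5–8% below the
  nominal omega at omega = 1 (the acceptance tolerance comfortably covers
  this); acceptance probabilities cap realizable omega at 1.
- **Cohort copies evolve one-sided** (the ancestor is kept verbatim and
  only the copy mutates to the full pairwise target) so truth recorded for
  earlier pairs can never be invalidated by later duplications. The
  two-descendant `evolve_pair` is used for estimator validation.
- **Expression** is gene-level abundance (lognormal, shared by a family's
  members across tissues) times per-tissue variation, the marginal kept at
  lognormal(3, 1.5); without the shared gene-level component, per-tissue
  expression would carry no recoverable rate–expression signal.
  Divergence is planted on an exact count (largest-remainder style) of
  duplicate pairs — one to three tissues, one member multiplied by 2^e —
  so recovery error is measurement error, not binomial noise. Composition
  counts are likewise exact.
- **What it does not emulate:** indels (so coverage/identity stresses come
  from truncation fixtures, not the evolver), intron structure,
  phylogenetically correlated multi-species evolution, genome-scale
  paralogy depth, and real tissue-specific expression programs. Passing
  tests therefore demonstrate correctness of the implemented rules and
  estimators under their own assumptions, not performance on real
  annotation pipelines' noise.

Identical configurations (including the seed) are byte-identical on
re-run; all randomness flows from one `numpy` generator.

## Problem sizes in the validation suite

The bundled suite validates at sizes chosen to make the statistics sharp
while keeping a laptop run comfortable: the NG86 oracle sweep covers all
3721 sense codon pairs; dN/dS recovery uses 100 pairs × 500 codons per
condition; classifier recovery a ~640-protein three-species cohort;
null-calibration 1000 replicates; expression-divergence recovery ~200
pairs × 14 tissues. The whole test suite runs in well under a minute.

## Known limitations

- NG86 assumes equal base frequencies and no transition/transversion bias;
  with biased mutation the counting estimator is itself biased (the
  evolver's kappa lets you explore this, but no correction is applied).
- Subgroup assignment is only as good as the reference set; with
  references distant from the query clade, scores fall toward the IIm
  floor by design rather than guessing.
- The internal aligner is quadratic; for genome-scale all-vs-all searches
  supply a precomputed hit table instead.
- Group I N/C-terminal domain labels are positional, not phylogenetic.
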