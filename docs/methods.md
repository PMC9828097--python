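# Methods

This note records the statistical definitions the package implements, the
design choices made where conventions genuinely diverge, what the
synthetic generator does and does not emulate, and the numerical rules
applied to degenerate inputs.

## Coding sequences and expression groups

Annotations (GenBank or GFF3, 1-based inclusive) are converted to 0-based
half-open coordinates at the parsing boundary; internally exons are kept
in coding order (descending genome coordinates on the minus strand) and
concatenated after per-exon reverse complementation. Multi-exon and
trans-spliced genes are taken from the curated exon list as-is — no
splice inference. A CDS whose length is not divisible by three is an
error; an internal stop codon is a warning by default (configurable to an
error) because curated organellar annotations occasionally carry such
artifacts. The trailing stop codon is retained on the record but excluded
from every sense-codon statistic except the stop-usage report.

Expression groups use strict FPKM comparisons: Top7 (> 10 000), Top18
(> 5 000, a superset of Top7), Low8 (< 500), intermediate otherwise.
Genes with no expression value fall into the intermediate group with a
warning rather than being dropped, so genome-wide statistics stay
complete. A default exclusion list (`i-cre`, `wendy`, `orf528` substring
matches) removes non-native or uncharacterised ORFs from analyses;
duplicated gene annotations (e.g. a twice-encoded photosystem gene)
produce two records and are counted twice downstream, deliberately.

## Usage descriptors

RSCU, W and CAI follow the classical definitions (see README). Choices
worth stating:

- **Reference-absent codons.** When building reference W vectors,
  zero-count codons receive a pseudocount of 0.5 (configurable). A zero W
  would send the CAI of any gene containing that codon to exactly 0,
  which is not a usable summary; with the pseudocount, rare-codon-bearing
  genes are penalised smoothly instead.
- **CAI product.** Stop codons never enter the product; single-codon
  boxes (Met, Trp) are excluded by default because W = 1 there carries no
  information about codon choice. The geometric mean is computed in log
  space, so thousand-codon genes cannot underflow.
- **Optimality classification.** A codon is optimal when its W in the
  high-expression reference is at or above a threshold (default 0.5);
  single-codon boxes are always optimal. The threshold is exposed because
  no universal cut-off exists; the realized optimal list is always
  emitted so users can substitute a curated list.
- **Codon demand** is Σ<sub>g</sub> X<sub>g</sub>(c)·FPKM<sub>g</sub>,
  linear in both counts and FPKM. Group contrasts use demand *shares*
  (scale-invariant); the per-kind summary averages max(r, 1/r) over the
  codons of each box kind so over- and underuse both register.
- **Fold differences** between group profiles cap at a flagged sentinel
  (default 100) when a codon is absent from one group, rather than
  reporting infinities.

## Composition

GC per codon position is reported two ways: the unweighted per-gene mean
± population sd (dispersion across genes, the natural companion to
per-gene CAI), and the codon-pooled value. Family-box GC3 groups codons
by box kind — NNU/C duets, NNA/G duets, quartets, the isoleucine triplet
— with six-codon amino acids split across their duet and quartet boxes,
and supports amino-acid exclusion (e.g. cysteine, whose U-preference
inverts the duet rule). The expected GC3 under neutral evolution is an
affine map of genomic GC; the default calibration is the line through the
anchor points (39.0 % → 34 %) and (30.9 % → 19 %) and is exposed as
configuration since published regressions differ. Positively charged
residues are Lys, Arg, His.

## Codon pair bias

Pairs are indexed (P-site codon, A-site codon) and never span gene
boundaries. The expectation chain is

e<sub>raw</sub> = c<sub>i</sub>·F<sub>j</sub> →
e<sub>norm</sub> = e<sub>raw</sub>·DiPB<sub>kl</sub> →
e<sub>used</sub>,

with F computed over sense codons of the same scope (Σ<sub>j</sub>
e<sub>raw,ij</sub> = c<sub>i</sub> exactly), and DiPB<sub>kl</sub> =
P<sub>kl</sub>/Q<sub>kl</sub>, Q<sub>kl</sub> =
F<sub>k</sub>F<sub>l</sub>N<sub>P</sub> from amino-acid frequencies of
the same scope. Undefined cells (absent amino acids or dipeptides)
propagate as explicit missing values, never 0 or ∞.

The rare/common split evaluates, for each codon *i*, the unweighted mean
over all 61 partners of P(X ≤ 1) = (1+λ)e<sup>−λ</sup> with λ =
c<sub>i</sub>F<sub>j</sub>; strictly above 0.75 means the codon is
essentially limited to single pair occurrences (deterministic regime).
In the mixed model e<sub>used</sub> = ⌈e<sub>norm</sub>⌉ for **all**
pairs — the literal reading of the ceiling rule — with a variant that
ceils only rare-classified rows available, since the rule is motivated by
rare codons; the naive comparator applies no ceiling, which is precisely
what produces the artificial inflation it illustrates. Bias is
(o − e<sub>used</sub>)/e<sub>used</sub>, ≥ −1 everywhere; in mixed mode
no pair with e<sub>norm</sub> < 1 and o ≤ 4 can exceed 3-fold bias, which
is the structural guarantee the mixed model exists for. Overrepresentation
calls use strict bias > fold (default 3); underrepresented pairs
(o < e/fold) are reported separately because the deterministic floor
makes underrepresentation pervasive and uninteresting.

A caveat the package reports rather than hides: on a null genome the
mixed model still makes occasional *genuine* Poisson-tail calls (o ≥ 5 at
λ near 1, per-cell probability 10⁻⁴–10⁻³ over ~2000 rare-involving
cells). These are false positives of the significance convention, not the
sub-one-expectation inflation artifact; the two are distinguished in the
acceptance outputs.

Junction dinucleotides are (third base of P-site codon, first base of
A-site codon). Out-of-frame stop scans count junctions spelling TAA/TGA
in the +1 (cP3 + cA1,2) and +2 (cP2,3 + cA1) frames. Repeat scans count
homopolymer runs ≥ 6 and tetra/penta/hexanucleotide windows overlapping
codon junctions, with expectations from the base composition over the
same windows (a window spanning two junctions counts once per junction —
the observed and expected sides use identical window sets).

## Positional analyses

Cluster detection flags every window of 30 codons containing ≥ 3
unfavorable codons, merges strictly overlapping qualifying windows, and
reports each merged region as a span from its first to its last flagged
codon. Ramp statistics use the first 30 codons (the ramp definition spans
30–50; 30 matches the cumulative-GC analysis and is the parameter
default) against the remainder, excluding genes of ≤ 150 nt. Densities
are pooled over codons across genes — a single enrichment percentage per
group — with the per-gene mean variant reported alongside. The initiator
codon is skipped in both windows: every CDS begins with a forced ATG that
carries no codon-choice information and would otherwise dilute the ramp
density by a deterministic 1/30. SD motifs are derived from the anti-SD
written 3′→5′ (UCCUCC → AGGAGG) and counted with overlaps on the coding
strand in any frame. `recode_ramp` substitutes unfavorable ramp codons
with their best optimal synonym for external RNA-folding comparisons; the
package does not compute RNA structure.

## Pausing aggregation

The input schema assumes scores already normalised per gene; read
processing is upstream. A record contributes once per selected site its
codon occupies (P, EP or EPA). Box contrasts are fixed by pairing
chemistry: NNA/G duets compare G- against A-ending codons, NNU/C duets
U- against C-ending (the G₃₄:U₃ wobble against the Watson-Crick pair),
quartets non-optimal against optimal per the supplied classification.
Codon means are averaged unweighted within each side (an
occurrence-weighted variant can be formed from the reported per-codon
means and counts); boxes with a missing side are flagged undefined, never
silently dropped.

## Synthetic generator

The generator is the package's no-download test surface. It emulates:

- **Two usage regimes.** Designed W vectors anchor to the observed group
  statistics of an AT-rich plastome: the high vector favors C-ending duet
  codons ~2:1 (cysteine excepted, which prefers U), keeps G-ending NNA/G
  and C/G-ending quartet codons at a few percent GC3, and uses U-only
  glycine/arginine quartets; the low vector follows the mutational bias
  (NNA/G GC3 ≈ 11 %, overall GC3 ≈ 16 %). Boundary-relevant design values
  keep a ≥ 0.05 margin from the 0.5 optimality threshold so classification
  recovery is well-posed under sampling noise.
- **Expression coupling.** FPKM is log-uniform per group (high
  5×10³–5×10⁴, low 10–500) and, by default, each gene's codon-choice
  profile interpolates between the low and high vectors by its normalised
  log-FPKM. This mirrors the continuous CAI-expression correlation seen
  in real plastomes, and it is what makes rank-correlation recovery
  meaningful: with only two hard profiles and two FPKM values, 20/20 ties
  cap the achievable Spearman ρ at 0.866 regardless of implementation.
  Coupling softens group contrasts (realized optimal-codon fractions
  differ less between groups than the pure vectors would); disable it for
  hard two-regime designs.
- **Gene sizes.** High-expression genes draw 150–550 codons, low 400–1800
  (photosystem-sized versus polymerase-sized CDSs), matching the order of
  real group codon totals.
- **Structure knobs.** Dipeptide bias by first-order Markov reweighting
  of residue sampling; ramp enrichment by scaling each family's rare-codon
  probability mass by the ramp factor (capped at 0.9) over the first 30
  codons, so the designed factor *is* the expected pooled density ratio;
  GC3 targets by a single exponential tilt on third-position GC solved by
  bisection (infeasible targets raise an error); pair injection by
  swapping both codons of dipeptide-matched junctions — the protein and
  the dipeptide structure are untouched — until the pair reaches
  fold × max(e<sub>norm</sub>, 1). The fold is defined against the
  mixed-model floor because for rare pairs the frequency expectation is
  below one occurrence and a multiple of it would be unobservable.
- **Genome layout.** Genes on both strands with AT-rich spacers, every
  fifth gene split into two exons, so extraction and coordinate handling
  are exercised end to end. One seeded generator drives all sampling;
  identical specs produce byte-identical files.

It does **not** emulate sequencing noise, annotation errors, operon
structure, secondary-structure constraints, or selection at specific
positions; passing tests therefore demonstrate the statistics and their
implementations, not robustness to real-data mess.

Null genomes for pair-model calibration are i.i.d. sense codons from a
stylized total-CDS frequency vector (an even blend of the two designed
profiles weighted by amino-acid frequencies), split into 20 genes of
~20 kb total — scaled down from full-plastome size; the rare/common
boundary of the Poisson classification scales with this size, which is
why calibration claims are stated per problem size.

## Problem sizes and numerics

Monte Carlo checks use sizes at which their tolerance bands are several
estimator standard deviations wide: ramp recovery uses 200 genes × 300
codons (pooled-enrichment sd ≈ 3.6 points against a ±10 band), GC3
recovery ≥ 30 kb (sd ≈ 0.5 points against ±2), dipeptide convergence is
asserted on cells with ≥ 500 expected pairs at 10⁵ codons. Geometric
means are computed in log space; matrix operations propagate NaN for
undefined cells and never divide by zero; all cross-gene aggregations use
population (divisor-n) standard deviations, stated wherever printed.

## Known limitations

- The pair-bias significance rule (bias > 3) is a fixed fold criterion,
  not a calibrated test; on null data it admits rare Poisson-tail false
  positives (quantified above), and on real data its calls depend on the
  annotation version through the codon counts.
- CAI depends on the reference set; Top7 and Top18 references give very
  similar rankings on coupled synthetic data, but the package makes no
  attempt to choose a reference automatically.
- Pausing contrasts on real data inherit whatever normalisation the
  upstream ribosome-profiling pipeline applied; the package only fixes
  the aggregation arithmetic.
- tAI, effective number of codons, RNA secondary-structure energies and
  anti-SD hybridization energies are out of scope.
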