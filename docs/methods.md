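# Methods

This note documents the models implemented in `chromoevol`, the
assumptions and numerical choices behind them, what the synthetic-data
generator does and does not emulate, and the package's known
limitations.

## Codon substitution model

The substitution process is GY94-style: states are the 61 sense codons
of the standard nuclear code (indexed alphabetically), and the
instantaneous rate from codon *i* to *j* is zero unless they differ at
exactly one nucleotide, in which case

    q_ij = pi_j * (kappa if transition) * (omega if nonsynonymous)

with transition/transversion ratio κ > 0, selection parameter
ω = dN/dS > 0 and stationary codon frequencies π (equal frequencies by
default; F3x4 from the data optionally). The process is reversible;
transition matrices are computed from the eigendecomposition of the
symmetrized generator, which makes P(t) two 61×61 matrix products per
branch and is exact to machine precision (verified against `scipy`'s
generic matrix exponential to ~1e-14).

### Site-class models

* **M0** — one ω for all sites and branches.
* **M1a** — nearly neutral: proportion p0 of sites with ω0 ∈ (0,1), the
  remainder neutral (ω = 1).
* **Model A** (branch-site) — four classes: 0 (ω0 everywhere), 1
  (neutral everywhere), 2a (ω0 on background, ω2 on foreground) and 2b
  (1 on background, ω2 on foreground), with ω2 ≥ 1 and mixing weights
  p2a = (1−p0−p1)·p0/(p0+p1), p2b = (1−p0−p1)·p1/(p0+p1). The null for
  the branch-site test is the same model with ω2 ≡ 1.
* **Extended clade model C** — three classes: 0 (ω0), 1 (neutral) and a
  divergent class 2 carrying one free ω per *branch type*, including the
  background; any number of branch types is allowed. With one foreground
  type this model has 5 free ω-distribution parameters against M1a's 2,
  hence the df = 3 clade-site LRT.

Branch types come from the tree: every branch carries a label (default
`background`), set either by a `#TYPE` suffix in newick input or by
`label_branches`, which labels the stem branch of a named monophyletic
leaf set.

### Rate scaling

Within a model, all class generators are divided by the common factor
Σ_c p_c · rate(Q_c at background ω), so branch lengths are expected
substitutions per codon site under the background mixture. For M0 this
is the usual unit-rate scaling. The simulator uses the identical
convention, so simulated branch lengths and fitted ones are on the same
scale.

### Likelihood and fitting

Site likelihoods use Felsenstein pruning with per-node rescaling (log
accumulators), vectorised across sites; the mixture likelihood is a
log-sum-exp over classes. Pruning is checked against explicit
state-enumeration oracles on 3- and 4-taxon trees to 1e-10.

Fitting maximises the likelihood with bounded L-BFGS-B on transformed
parameters (log for κ and ω's, stick-breaking logits for proportions),
with bounds ω ∈ [1e-4, 999], κ ∈ [0.01, 100]. Multi-start defaults to 3
jittered starts; the simulation-calibration loops use a single start,
which the calibration results justify at these problem sizes. A fitted
ω2 within 5 % of the upper bound is reported as "unbounded" — the
analogue of an ω̂2 = ∞ entry in published branch-site tables. ω2 at the
lower bound 1 is flagged as such.

**Branch lengths.** Site-class fits hold branch lengths fixed from an M0
stage. When the input tree carries lengths, the M0 stage estimates a
single rescaling factor (plus κ and ω); a tree without lengths gets free
per-branch M0 estimates. This one-factor protocol is a deliberate
simplification of per-model branch-length re-estimation: it reduces the
dimensionality of every site-class fit to ≤ 6 free parameters, which is
what makes the multi-replicate calibration loops tractable, and it
leaves LRT statistics essentially unchanged when the input lengths are
near the M0 optimum (the usual case for trees estimated from the same
data). A rescaled tree whose scale hits the lower bound signals a
no-substitution alignment, where ω is unidentifiable; the fit is flagged
rather than failed.

## Hypothesis tests

* **Branch-site test**: model A vs its ω2 = 1 null. Because the null
  pins ω2 at a boundary, 2Δℓ is referred to the ½χ²₀ + ½χ²₁ mixture
  (p = ½·Pr(χ²₁ ≥ 2Δℓ), p = 1 at 2Δℓ ≤ 0); a conservative χ²₁ fallback
  is available. Negative statistics beyond −1e-6 (optimizer noise) are
  clamped to 0 with a warning.
* **Clade-site test**: extended clade model C vs M1a on χ² with df equal
  to the free-parameter difference (3 for one foreground type).
* **Branch scans**: each candidate branch type is treated as foreground
  in turn; the raw p-vector is adjusted with the **Hommel (1988)**
  step-up procedure (closed testing with Simes local tests, implemented
  in its closed stepwise form and verified against a brute-force closure
  oracle over all 2^n − 1 intersections, and against R's `p.adjust`).
  Rejection sets are reported at the chosen α.
* **Site identification**: per-site posterior probabilities of the
  positively selected classes (2a ∪ 2b). The default `NEB` evaluates
  Bayes' rule at the MLEs. `grid_EB` additionally averages the posterior
  over a uniform-prior grid on (p0, p1, ω2) weighted by marginal
  likelihood — a light-weight approximation to Bayes empirical Bayes
  that acknowledges mixture-parameter uncertainty without its full
  integration; site reports are labelled with the method used. Flags are
  reported at the 0.90 and 0.95 cutoffs.
* **Saturation guard**: every test reports the mean pairwise synonymous
  distance (NG86 counting with equal-path averaging, Jukes-Cantor
  corrected); values above 3 trigger a warning that positive-selection
  inference may be unreliable.

## Structural annotation

LTR pairs are found by seed-and-extend: exact 20-mer matches at a common
diagonal offset are chained (12-mers as a fallback on sub-20 kb inputs),
extended outwards until four consecutive copy-vs-copy mismatches, and
the boundaries snapped within a ±120 bp window to the best-supported
position where **both** copies carry the TG (start) / CA (end) terminus.
The snap score counts copy-vs-copy matches inside minus outside a 20 bp
flank, plus 2 points per base of target-site-duplication consistency
(the 4–6 bp host repeat flanking the prospective element) — the same
signal real annotators use to resolve ambiguous termini. Candidates are
filtered to 100–1500 bp repeats, ≤ 10 kb interior, ≥ 80 % identity, and
deduplicated by identity-then-length rank.

Identity everywhere means matches / alignment length (gaps count
against) from a global alignment with match +1, mismatch −1, gap open
−2, gap extend −0.5; this definition is printed in every report since
"percent identity" is not otherwise well defined.

TSD detection is adjacency-anchored: the longest L ∈ {6,5,4} for which
the L-bp suffix of the 5′ flank equals the L-bp prefix of the 3′ flank.
PBS: longest reverse-complement match to a configured tRNA 3′-end
library (a synthetic tRNA-Met fixture by default) starting ≤ 2 bp after
the 5′LTR, minimum 11 bp — the smallest PBS the package is designed to
report. PPT: longest A/G run ≥ 12 bp ending ≤ 2 bp before the 3′LTR.
ORFs are ATG-to-stop spans ≥ 300 nt on both strands; pseudo-ORF
translation runs through internal stops and records their positions
without repairing frameshifts. PR/RT/RNH/INT domains are located by
fixed sentinel peptides (similarity-search domain assignment is out of
scope); the CCHC Zn-finger is matched by its literal
C-X2-C-X4-H-X4-C pattern and the chromodomain by chromo-box scanning,
so those two detectors are exercised for real.

Families are single-linkage clusters at > 80 % global identity with an
additional ≥ 50 % LTR-identity requirement against the family exemplar;
consensus sequences are column-majority with ties to the first-listed
copy and gaps winning only above 50 %.

## Chromodomain classification

Peptides are anchored by the best chromo-box placement; alignment
position 1 is the first box residue and the W45/Y48 homologue slots sit
at offsets 27 and 30 (configurable — the full alignment-column mapping
beyond these three anchors is not hard-coded). Classification is a
total function of the three flags: W45 absent → unclassified; otherwise
CHD_I with Y24 (Y or F at position 1) and CHD_II without. Y48 is
recorded as evidence but never decides the group. Motif scoring is
weighted consensus (prominent 1.0, minor 0.5) with a threshold of 70 %
of the maximal score, exposed in configuration.

## Phylogenetics

Distances: p (mismatch fraction over shared ungapped columns), Poisson
(−ln(1−p), proteins) and Jukes-Cantor (DNA); saturation (p beyond the
model's bound) is an error naming the offending pair, never a silent
infinity. NJ is the classical Studier-Keppler formulation; negative
branch lengths are clamped to zero with the deficit moved to the sister
branch (changes lengths, never topology), and Q-criterion ties break on
the lexicographically smallest pair of cluster keys so output is
deterministic. Additive matrices are inverted exactly. Bootstrap support
resamples columns with replacement and reports the percentage of
replicate trees containing each internal bipartition of the point tree.
ML tree search is out of scope; externally built trees enter through
newick.

## Synthetic data: what it emulates and what it does not

The codon simulator draws a class per site from the model proportions
and evolves each site by the exact process of the likelihood engine
(foreground classes switch to ω2 only on labeled branches; root states
from the stationary law), recording per-site classes and all ancestral
states. One integer seed makes outputs bit-reproducible.

The default study tree for calibration has 8 taxa in a balanced
topology, 0.25 expected substitutions per codon site per branch — a
typical within-clade divergence for retroelement domains — with the stem
of one four-taxon clade as the 0.4-length labeled foreground. Default
simulation regimes are p0 = 0.5, p1 = 0.3, ω0 = 0.1, κ = 2, with ω2 = 6
for positive-selection data and ω2 = 1 for null data, at 500 codons.
Calibration at these conditions (20 replicates per regime in the test
suite; single-start fits) gives branch-site rejection in ≥ 80 % of
positive replicates and ≤ 15 % of null replicates at α = 0.05.

Planted genomes assemble each element as 5′LTR + spacer + PBS (reverse
complement of the configured tRNA 3′ end) + Gag-Pol ORF with sentinel
domains + PPT + 3′LTR, mutate the LTR pair to the requested divergence
(TG/CA termini protected), and insert it flanked by its TSD into i.i.d.
uniform background with ≥ 1 kb margins; truth records exact coordinates.
The default inventory mirrors the structural variety the annotator
targets: LTRs of 112–919 bp, divergences 0.3–2.7 %, TSDs including the
5 bp CCTAT and 6 bp GTTTCT cases, PBS lengths 11–13 bp with 0–2 nt
spacers, and 13–14-purine PPTs.

What the generator does **not** emulate — and hence what passing tests
do not show about real data: indels and nested/fragmented insertions,
solo LTRs, compositional bias in the background (i.i.d. uniform is the
simplest null for motif false positives), rate heterogeneity beyond the
discrete site classes, and real domain sequences (sentinels stand in for
similarity search). Real-genome performance of the LTR boundary
heuristics is therefore untested; they are validated on synthetic truth
only.

## Numerical choices and degenerate inputs

* Alignment cleaning: any codon column containing a gap, ambiguous
  nucleotide or stop codon in any taxon is removed before likelihood
  work; removed original column indices are recorded so site numbers can
  be reported in the input frame.
* Coordinates are 0-based half-open internally and 1-based inclusive in
  GFF3/reports, converted in a single layer.
* Optimizer convergence: relative function tolerance 1e-11; LRT
  statistics in (−1e-6, 0) are clamped to zero with a warning.
* Impossible site patterns (probability underflow) are guarded at
  1e-300 before the log, giving large negative finite values.
* Zero-length trees simulate identical sequences with a warning; the M0
  scale at its lower bound flags the alignment as uninformative.

## Problem sizes

The test suite and acceptance script run at desk scale by design: 500
codons × 8 taxa for codon-model calibration (20 replicates per regime in
the suite, 10 in the acceptance script), 40 kb genomes with four planted
elements for annotation (3 genome seeds in the suite; 100 × 10 kb
backgrounds for the false-positive rate), 50 seeded draws for the
likelihood oracle and 20 for NJ exactness. Published branch-site
statistics are used as printed inputs to the multiple-testing layer; the
underlying real alignments are not part of the package, so their model
fits are not reproduced here.

## Known limitations

* The exact Bayes-empirical-Bayes integration is approximated by the
  grid-averaged EB described above; NEB is the default and reports are
  labelled accordingly.
* Branch lengths are not re-estimated per site-class model (see above);
  2Δℓ values can differ slightly from per-model re-estimation.
* The clade-model reading "one free ω per branch type in the divergent
  class, background included" is one concrete extension of clade model C
  to multiple branch types; other parameterisations exist.
* The annotator's seed-and-extend boundary delimitation is a
  reconstruction validated on synthetic truth; divergences above ~20 %
  defeat the exact-k-mer seeding by design.
* Codon frequency estimation is limited to equal and F3x4; no empirical
  exchangeability matrices, gamma rates, or ancestral reconstruction.
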