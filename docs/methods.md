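# Methods

This note documents the models, defaults and design decisions behind
`xtalfate`, in the spirit of a statistical-software methods appendix. It
states no empirical number that the test suite or `scripts/acceptance.py`
does not itself compute.

## Problem setting and assumptions

The predictor maps a single amino-acid sequence to propensities for four
terminal outcomes of a production/crystallization pipeline: MF
(material-production failure), PF (purification failure), CF
(crystallization failure, including crystals that diffract poorly) and CR
(diffraction-quality crystallization). The core assumptions are:

* the outcome signal is carried by sequence-intrinsic properties
  (composition, physicochemistry, disorder, complexity) — inter-molecular
  factors such as tags, buffers or screening strategy are deliberately out
  of model;
* features must be alignment-free, so a batch of a thousand sequences
  scores in minutes on one CPU;
* the four outcomes are modelled as independent one-vs-rest binary
  problems; no multinomial coupling is imposed, because each outcome has
  its own informative feature subset.

## Feature space (1276 dimensions)

Group sizes are asserted at catalog construction (420/336/448/4/68,
total 1276); the catalog order is fixed across runs and platforms.

**Composition (420).** Amino-acid fractions (20, alphabetical one-letter
order) and adjacent-dipeptide fractions (400, first residue major); each
block sums to 1.

**Three-class CTD descriptors (336 = 7 properties × 48).** Each of seven
properties (hydrophobicity, van der Waals volume, polarity, polarizability,
charge, secondary-structure propensity, solvent accessibility) partitions
the alphabet into three classes (`features/data/property_alphabets.tsv`,
editable without code change; groupings are the conventional CTD ones).
Per property: class composition (3), between-class transition frequencies
over the L−1 adjacent pairs (3), normalized positions of the
1st/25%/50%/75%/100% occurrence of each class (15, 0 when the class is
absent), and nine run statistics per class (27): run count, longest,
shortest and mean run (each /L), residue coverage, runs ≥ 2 and ≥ 3 (/L),
first and last occurrence position (/L). The k%-occurrence is the
⌈k·n⌉-th occurrence of the class (1-based positions).

**Residue-scale statistics (448 = 64 scales × 7).** Each scale maps
residues to numbers; features are the sequence mean plus min/max of
sliding-window means at window lengths 5, 15 and 31. Windows longer than
the sequence clip to one full-length window, so length-30 sequences still
produce all features. Note the min/max of *sliding* windows bracket the
sequence mean only when disjoint windows tile the sequence; the test suite
asserts the bracket for tiling lengths only.

The 64-scale set is a documented package choice: 16 classical published
scales (Kyte–Doolittle, Hopp–Woods, Eisenberg consensus, Fauchère–Pliska,
Janin, Engelman GES, Wimley–White interface, Rose burial, Cornette,
Hessa TM, residue mass and volume, average flexibility, Grantham polarity,
Chou–Fasman helix/sheet) bundled in `base_scales.tsv`, plus 48 *synthetic*
scales (`synthetic_scales.tsv`) constructed once as seeded unit-norm random
linear combinations of the z-scored classical scales. The synthetic rows
are labelled as such in their file and carry no literature provenance; they
mimic the strong mutual correlation of real hydrophobicity-scale families
and exercise the redundancy-handling stages realistically.

**Whole-protein physicochemistry (4).** Aliphatic index (Ikai:
X(A) + 2.9 X(V) + 3.9 (X(I)+X(L)) in mole percent); instability index
(Guruprasad dipeptide weights, via biopython's `ProteinAnalysis`); net
charge at pH 7 and isoelectric point from a Henderson–Hasselbalch sum over
D/E/C/Y/H/K/R side chains and free termini with the EMBOSS pKa set
(`pka_set.tsv`; N-term 8.6, C-term 3.6, C 8.5, D 3.9, E 4.1, H 6.5,
K 10.8, R 12.5, Y 10.1). The pI is the zero crossing of that monotone
charge curve, found by bisection on [0, 14] to 1e-3 pH.

**Disorder and low-complexity summaries (68 = 2 × 34).** Disorder uses a
built-in windowed charge–hydropathy score: with H the window-21 mean of
Kyte–Doolittle hydropathy rescaled to [0, 1] and q the window mean net
residue charge, the FoldIndex-style quantity 2.785·H − |q| − 1.151 is
positive for fold-prone segments; it is mapped through a sigmoid of
slope 6 to a per-residue propensity in [0, 1]. Low complexity is a 0/1
mask: a residue is flagged when any covering window of 12 residues has
composition Shannon entropy below 2.2 bits. Both are deterministic stand-ins
for external disorder/complexity predictors, chosen to keep the package
alignment-free and dependency-free; externally computed per-residue scores
can be injected from a 2-column text file and are used verbatim after
clipping to [0, 1]. Each signal is condensed to the same 34 statistics:
five moments/extrema; window-mean extrema (w = 5/15/31); fraction above
0.5; run count, longest run, mean run and coverage at minimum run lengths
1/4/10 of the >0.5-thresholded signal; five occurrence-position quantiles;
threshold crossings /L; terminal means (first/last 30 residues); and the
mean of above- and below-threshold values.

## Feature selection

Per outcome, three deterministic stages:

1. **Relevance.** "Biserial correlation" is implemented as point-biserial —
   the Pearson correlation between a feature and the 0/1 labels — which is
   the computable form for observed binary labels; constant features get
   r = 0. The filter keeps |r| ≥ 2 × mean |r| (absolute values, since an
   informative feature may correlate in either direction). Because the
   rule can in principle keep arbitrarily few features, a fallback retains
   the top `min_retained` (default 10) by |r| whenever the survivor set is
   smaller; catalog order breaks exact ties.
2. **Redundancy.** Greedy scan in decreasing |r|: a feature is dropped when
   its absolute Pearson correlation with any already-kept feature exceeds
   0.7. Keeping the more relevant member preserves the ranking semantics
   for the wrapper.
3. **Wrapper.** Initialized with the top-ranked candidate; a single forward
   pass over the remaining candidates in rank order, each scored by the
   mean AUC of a logistic model under stratified 5-fold cross-validation
   (fold assignment seeded; a single-class fold triggers a reseeded
   refold). Acceptance requires a *strictly* greater mean AUC — ties
   reject, biasing toward smaller subsets. No revisiting and no backward
   elimination. The full accept/reject trace is retained and serializable
   for audit.

## Outcome models and calibration

Features are standardized (training mean/std; constant columns get std 1)
and fitted by Newton/IRLS from a zero start, converging when the largest
coefficient update falls below 1e-8 (cap 100 iterations). Training is
therefore deterministic. On (quasi-)separation — common at strong synthetic
effect sizes — the fit is repeated with a small ridge (1e-4) on the
standardized weights and the event is logged; propensities saturate but
remain well-defined.

Confidence tiers come from the empirical 20th/80th percentiles
(linear-interpolation definition) of the fitted training propensities:
strictly below the 20th → *low*, strictly above the 80th → *high*, else
*medium* (boundary values are medium). On a continuous training
distribution this splits 20/60/20 by construction. The overall call is the
argmax propensity; exact ties resolve toward the later pipeline stage,
a deterministic and optimistic convention. Models serialize to versioned
plain-text JSON (feature names/indices, standardization, weights,
thresholds) so a trained bundle is portable and diffable.

## Evaluation protocol

AUC is the Mann–Whitney statistic (ties credited ½); MCC and accuracy are
computed from the 2×2 table at a decision threshold defaulting to 0.5 (the
threshold is a parameter, since percentile tiers — not a fixed cutoff —
are the intended interpretation layer). The resampling protocol draws 100
random subsets of 25% of the proteins *without replacement* — "randomly
chosen proteins", i.e. subsampling rather than the classical bootstrap;
with-replacement drawing is available as an option. Single-class subsets
are redrawn so the replicate count stays fixed. Paired comparisons between
predictors use the classical paired t-test on matched replicates, with an
Anderson–Darling normality check (scipy's tabulated small-sample critical
values) at α = 0.05. All resampling is bit-reproducible from the seed.

## Synthetic data generator

`generate_dataset` emulates a labeled training corpus: per class, sequences
are drawn residue-by-residue from composition vectors
`uniform(1/20) + effect_size × direction`, with fixed zero-sum direction
vectors (+0.3 total mass spread over the favoured residues): MF toward
hydrophobic/aromatic residues (FILMVWY), PF toward charged (DEKR), CF
toward polar repeat-prone residues (NPQS), CR toward small/ordered
residues (ADGSTV). The directions are loosely motivated by published
crystallizability trends but make no claim of realism; they exist to give
each outcome a learnable, distinct signature. Lengths are log-normal with
median 300 and log-dispersion 0.4, clipped to [30, 2000] — desk-scale and
consistent with validation. Effect sizes large enough to drive a
probability negative are clipped and renormalized (logged). Defaults
(400 sequences per class, effect size 0.5) are the package's standard
study conditions.

What the generator does *not* emulate: real residue-order structure
(sequences are i.i.d. draws given composition, so dipeptide/CTD/disorder
features carry only composition-level signal), homology between records,
class imbalance of real registries, and any inter-molecular determinants of
crystallization. A pass on synthetic data therefore demonstrates that the
pipeline recovers planted compositional structure — not field performance
on real trial registries.

`generate_feature_table` provides the numeric analogue (standard-normal
informative columns entering a known logistic label model, plus noise
columns) for parameter- and selection-recovery tests.

## Numerical and protocol choices

* Percentiles: numpy linear interpolation between order statistics.
* Ties in relevance ranking and redundancy scanning break by catalog order.
* `roc_auc` delegates to scikit-learn; tests verify it against brute-force
  pair enumeration at 1e-12, and correlation functions against the direct
  formulas at 1e-12.
* The IRLS implementation is cross-checked against statsmodels' Logit MLE
  in the test suite; scikit-learn is used only for fold assignment and
  metric computation, never for fitting.
* Held-out self-checks split each class 50/50 (train/test) with a seeded
  RNG. At effect size 0 the held-out AUC of any trained model is exactly
  Wilcoxon-null distributed (σ ≈ 0.024 at 200 positives / 600 negatives),
  so the chance-level check in the acceptance suite averages three
  replicate runs at consecutive seeds rather than trusting a single draw.
* Status matching in annotation is exact (after lower-casing and
  whitespace collapsing), not substring-based: registry status values are
  literal phrases, and substring matching would over-capture. Both
  registry-era spellings of the duplicate-structure statuses map to CR;
  the mapping lives in an editable table.

## Known limitations

* The 48 synthetic residue scales are placeholders for a curated scale
  collection; swapping in a different 64-scale set changes the AAPHYS
  block's meaning but not its shape or the pipeline's behaviour.
* The built-in disorder and complexity estimators are fast heuristics, not
  replacements for dedicated predictors; the injection hook exists for
  users who want externally computed profiles.
* Trained weights published for the original family of
  crystallization-outcome predictors are not reproduced here; models must
  be trained on a user-supplied labeled corpus (or the synthetic
  generator).
* Similarity-based redundancy reduction of training corpora (e.g. 25%
  identity clustering) is delegated to external tools; the annotation
  module deduplicates exact sequence matches only.
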