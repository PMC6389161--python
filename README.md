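# xtalfate

Sequence-only prediction of how far a protein will make it through a
structure-determination pipeline.

Structural-genomics consortia attempt thousands of targets, and most fail
long before a diffraction-quality crystal: material production (cloning,
expression) fails, purification fails, or crystallization fails. Because wet-lab
trials are expensive, target-selection tools that rank candidate proteins
*before* any experiment — from the amino-acid sequence alone, with no
alignments, profiles or templates — are a standard part of pipeline triage.
`xtalfate` implements such a predictor end to end: feature extraction,
per-outcome feature selection, logistic-regression scoring with calibrated
confidence tiers, and the statistical protocol for evaluating it. A synthetic
data generator with controllable class structure makes the whole pipeline
testable on a desktop with no external downloads.

## The model

Every validated sequence (standard 20-letter alphabet, length ≥ 30) is mapped
to a fixed **1276-dimension feature vector** in five groups:

| group | size | content |
|---|---|---|
| AAC | 420 | amino-acid composition (20) + dipeptide composition (400) |
| CLUSTER | 336 | composition/transition/distribution + segment statistics over 3-class recodings of 7 physicochemical properties |
| AAPHYS | 448 | mean and sliding-window extrema (w = 5/15/31) of 64 per-residue numeric scales |
| PROTPHYS | 4 | isoelectric point, aliphatic index, instability index, net charge at pH 7 |
| CXDIS | 68 | 34 summary statistics each for a disorder propensity profile and a low-complexity mask |

Four binary outcomes are modelled one-vs-rest: **MF** (material-production
failure), **PF** (purification failure), **CF** (crystallization failure,
including poor diffraction) and **CR** (diffraction-quality crystallization
success). For each outcome the 1276 features are reduced in three stages —

1. keep features with |point-biserial r| ≥ 2 × mean |r| (ranked fallback if
   the survivor set is too small),
2. greedily drop features with |Pearson r| > 0.7 to an already-kept,
   more relevant feature,
3. one forward wrapper pass in relevance order, accepting a candidate only if
   it strictly improves the mean 5-fold cross-validated AUC of a logistic
   model —

and a maximum-likelihood logistic regression (IRLS on standardized features)
is fitted on the selected subset. A query protein gets four propensities
`p = σ(β₀ + Σ βⱼ zⱼ)`, an overall call (highest propensity; exact ties go to
the later pipeline stage) and a low/medium/high confidence tier per outcome,
calibrated so the lowest/highest 20% of *training* propensities map to
low/high.

Labels for training can be derived from crystallization-trial registries: a
fixed table maps trial stop/current status strings (e.g. "purification
failed", "in PDB") to the four outcomes, and a sequence with several trials
receives the label of the trial that progressed farthest.

## Worked example

Everything below is driven by one seed and reproduces byte-for-byte.

```bash
xtalfate simulate --output train.fasta --labels labels.tsv \
         --n-per-class 100 --effect-size 0.5 --seed 7
xtalfate train    --input train.fasta --labels labels.tsv \
         --model-dir bundle --seed 7
xtalfate simulate --output query.fasta --labels qlabels.tsv \
         --n-per-class 3 --effect-size 0.5 --seed 99
xtalfate predict  --input query.fasta --model-dir bundle --output pred.tsv
```

`pred.tsv` (first columns):

```
id       p_MF      p_PF      p_CF      p_CR      overall  conf_MF ...
MF_0000  0.973582  0.000000  0.000000  0.000000  MF       medium
MF_0001  1.000000  0.000000  0.000000  0.000000  MF       high
PF_0000  0.000000  1.000000  0.000000  0.000000  PF       medium
CF_0000  0.000000  0.000000  1.000000  0.000000  CF       medium
CR_0000  0.000000  0.000000  0.000000  1.000000  CR       medium
```

At this generator effect size the four class compositions are strongly
shifted, so every query is called correctly with near-saturated propensity.
The confidence column contextualizes each propensity against the training
distribution of its own model — a propensity can be extreme yet only
"medium" if most training propensities were equally extreme. The trained
bundle is plain text; e.g. the CR model here selected 4 of 1276 features
(`CTD_polarizability_comp_c1`, `IDX_SYN010_mean`,
`CTD_polarity_trans_c1c3`, `DPC_TG`), and `bundle/selection_CR.txt` records
the full accept/reject AUC trace of the wrapper.

`xtalfate evaluate` adds the assessment protocol: AUC, MCC and accuracy
summarized as mean ± standard deviation over 100 random 25% subsets, the
companion `paired_t_test` / `anderson_darling_normal` functions support
comparing two predictors on matched replicates.

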