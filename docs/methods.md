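# Methods

This note records the models and procedures implemented in `tposcreen`, the
assumptions behind them, the defaults and why they were chosen, and what the
synthetic validation does and does not demonstrate.

## Dose–response model and AC50 → IC50 conversion

Assay readouts are four-parameter Hill curves in % of control enzyme
activity: bottom plateau *a*, top plateau *b*, slope *c*, and a relative
half-maximal concentration AC50 (the concentration at half of the compound's
*own* maximal effect).  An absolute IC50 (inhibition to 50 % of control)
exists only when the curve actually crosses 50 % response, i.e. *a* < 50 <
*b*; equivalently the maximum inhibition (100 − *a*) exceeds 50 %.

The default conversion scales the *logarithm* of AC50 by the Hill factor:

    log10 IC50 = log10 AC50 × ((a − 50) / (50 − b))^(1/c)

This log-domain form is dimensionally awkward (the factor multiplies a log
concentration, so the result depends on the concentration unit; μM is fixed
throughout) but is retained as the default for fidelity to common practice
in the assay literature from which this workflow derives; a linear-domain
variant, `IC50 = AC50 × factor`, is exposed as `mode="linear"`.  Both modes
coincide on a full-range curve (*a* = 0, *b* = 100), where the factor is
exactly 1.  The inverse functions are exact, which the generator exploits
(below).  Numerically, the log-domain form explodes for curves that barely
cross 50 % with shallow slopes (factor → 0 maps moderate IC50s outside
floating-point range); inversion round-trip guarantees therefore hold on the
curve ranges the package generates and tests (*a* ≤ 45, *b* ≥ 60,
0.5 ≤ *c* ≤ 3), and the converter raises cleanly outside the valid domain.

Boundary conventions for labeling: binary A at max inhibition ≥ 20 %
(inclusive); ternary B covers 20–50 % inclusive on both ends and A requires
strictly > 50 %; quaternary A1 includes exactly 10 μM.  A compound above
50 % inhibition with no IC50 available is a hard labeling error rather than
a silent C.

## Structure curation

Salt stripping keeps the unique carbon-containing fragment of a
multi-fragment input; carbon-free fragments and fragments on a bundled
counter-ion list (common inorganic ions plus small organic acid
counter-ions such as acetate, tosylate, oxalate, TFA) are discarded.
Neutral organic solvents are deliberately *not* on the list, so two neutral
organic fragments are always a mixture and are excluded — erring toward
exclusion rather than guessing a parent.  Deduplication keys on the
canonical SMILES of the desalted parent (deterministic, registry-free);
among duplicates the record with the most complete curve data wins, ties
broken by lower AC50, then first occurrence.  No tautomer or stereo
normalization is attempted.

## Features

* Topological fingerprints: Morgan radius 2, RDKit path length ≤ 7, and
  atom-pair counts, each hashed/folded to 2048 slots.  The atom-pair
  fingerprint counts (atom type, atom type, topological distance) triples
  using RDKit's stable atom-pair encoding, so columns are reproducible
  across platforms and runs.  Widths are conventional defaults; nothing in
  the pipeline depends on them.
* Substructure keys: match counts against an ordered SMARTS library.  The
  bundled `chemotypes.tsv` covers the alert families relevant to TPO
  inhibition (primary/secondary aromatic amine, phenol, enol/thioenol
  ether, thioether, carbothioic S-ester, thiocyanate, sulfenic derivatives,
  carbodithioic ester, heterocyclic N/S, vinylogous carbonyl, phosphate
  ester, disulfide, quinone).  It is a compact stand-in curated for this
  package, not a reproduction of any proprietary chemotype set; users can
  drop in any library in the same format.
* The classifier feature set is the column-wise concatenation
  `<topo>_Sub`; every column name carries its source block, so provenance
  survives concatenation.
* The descriptor table is a fixed 16-descriptor 2D set (size, lipophilicity,
  H-bonding, rings, connectivity/shape indices) used only for the
  chemical-space check.

## Modeling protocol

Split: 80:20, stratified.  The total test size is the ceiling of
0.2 × N; per-class test slots are the floors of the proportional shares with
the remainder assigned by largest fractional part (ties toward the larger
class, then class name).  On the 587-compound reference class totals this
allocation reproduces the published subset sizes exactly (binary 388/97 and
81/21; ternary adds 283/71 and 105/26; quaternary splits the actives into
100/25 and 183/46).

Per CV fold, fit strictly on the training fold: min–max scaling (constant
features map to 0), variance filter dropping post-scaling variance < 0.01
(population variance, so a binary feature needs ≳ 1 % prevalence to
survive), PCA (default 10 components, sign-fixed so the largest-magnitude
loading is positive) or LDA (components capped at classes − 1), then SMOTE.
Validation rows are transformed with stored parameters, never refit and
never clipped; SMOTE never sees validation data.  The leakage guard is
asserted in the test suite: perturbing validation rows cannot change any
fitted statistic.

SMOTE is implemented in-package (each synthetic sample interpolates
uniformly between a minority row and one of its k = 5 nearest same-class
neighbours; k shrinks to class size − 1 for tiny classes; all classes are
raised to the majority count).  k = 5 is the classic default.

Learners and compact grids (full/reduced): RF trees {100, 500} × depth
{None, 10}; RBF-SVM C {0.1, 1, 10}; one-hidden-layer MLP {64, 256} × L2
{1e−4, 1e−2}; AdaBoost estimators {100, 500}; XGBoost estimators
{100, 500} × depth {3, 6} × η {0.1, 0.3}.  These desk-scale grids are the
package's defaults, chosen to explore capacity and regularization without
multiplying runtime; any grid can be passed in.  The SVM obtains class
probabilities by sigmoid (Platt) calibration of its decision values, which
soft voting requires.

Scoring is macro-F1 (0/0 → 0 per class).  Macro rather than weighted
averaging because the endpoint is imbalanced and the minority inactive
class is exactly what a screening model must not ignore; a weighted option
is exposed.  The specificity reported for a selected model is the recall of
the inactive class C.

Voting ensembles take the four best of the five base learners by CV score
(ties broken by the fixed order RF < SVM < ANN < AdaB < XGB).  Hard voting
resolves split votes with the highest-CV member's prediction, which makes
the output independent of member order; soft voting averages calibrated
probabilities.  An ensemble's CV score is the mean of its members', used
only when ensembles compete with base learners during selection.

Selection is two-stage: within each (grouping, feature set) the highest CV
score survives; across surviving candidates the highest test macro-F1 wins.
One master seed fans out deterministically to the split, the folds, SMOTE
and every learner.

## Substructure frequency analysis

For key *x* and group *g*: `freq_g = (f_g × C) / (f × C_g)`.  "Number of
fragments" is presence-based by default (compounds containing ≥ 1 match):
this makes a key with identical prevalence in every group score exactly 1
everywhere and reads naturally as over-representation; occurrence-based
counting (distinct matches) is a flag.  A key is an active substructure
when `freq_A1 > 1.2` and `freq_A1/freq_C > 1.2`; a key absent from C but
enriched in A1 is active with ratio +∞.  The group of interest is a
parameter (the same statistic is meaningful for A2, e.g. phosphates).  No
significance testing is attached — the statistic is a ranking heuristic,
not an inference procedure.

## Consensus screening and applicability

A candidate is consensus-active iff binary = A ∧ ternary = A ∧ quaternary =
A1 — agreement of all three winners on the strongest-activity call.  Each
bundle stores its featurization recipe, so candidates are featurized exactly
as the training set was; a recipe/feature-set mismatch is a hard error.
The applicability check is deliberately simple and labeled advisory: min–max
scaled descriptors, 3 principal components fit on the training set, and a
bounding box expanded by 10 % of each component's range.  It flags gross
extrapolation, not subtle domain shift.  External annotations (e.g. Cramer
classes computed by other tools) are joined, never computed.

## Synthetic data: what it emulates, what it does not

The generator assembles compounds from carbocyclic aromatic scaffolds
(benzene, naphthalene, biphenyl, cyclohexyl-benzene; 1–5 substitution
slots) decorated with motif fragments — aromatic amine, phenol, enol ether,
thioether, phosphate ester — or inert alkyl/halogen decorators, rejecting
canonical-SMILES duplicates.  Motif presence is sampled per class: the
default prevalences give the aromatic amine a strong active/inactive
contrast (0.80 vs 0.05) and the remaining motifs mild contrasts
(≈ 0.15–0.28 vs 0.05–0.08), mirroring an alert hierarchy with one dominant
toxicophore.  Active compounds are guaranteed at least one motif: in this
generative model activity is *caused* by substructure, and an active
compound with no structural cause would be unlearnable label noise.

Latent potency is `log10 IC50 = 2 + Σ effect + N(0, 0.4)` (baseline 100 μM;
amine −1.5, others −0.5 to −0.8), truncated to the class band (≤ 10 μM for
A1, > 10 μM for A2), so the class mix is controlled while motif load still
shapes potency within classes.  Plateaus are drawn inside the band implied
by the class (active bottoms 5–45 %, moderate 50–80 %, inactive > 80 %; top
≈ 100; slope clipped to [0.6, 1.8] to keep the log-domain AC50 inversion
well-conditioned), and the emitted AC50 is the exact inverse of the IC50
conversion, so curation recovers planted IC50s to the rounding of the CSV
(≲ 1e−4 in log10 units).  The default class mix (A1/A2/B/C =
0.21/0.39/0.22/0.18) mirrors the strong active-heavy imbalance of curated
TPO assay collections.

Because the bundled motif SMARTS define exactly the planted chemistry, the
SMARTS-based frequency table equals the truth-based oracle identically —
that is a designed property, verified by test, not an approximation.

What passing on synthetic data shows: the pipeline wiring is correct (no
leakage, exact conversion algebra, faithful counting), and the learners can
recover a planted signal of realistic strength through the full
preprocessing stack.  What it does not show: performance on real chemistry.
Real datasets carry activity cliffs, assay noise uncorrelated with
structure, scaffold families far richer than this grammar, and alerts with
context-dependent effects; multiclass scores here (binary ≈ 0.93, ternary
≈ 0.64, quaternary ≈ 0.40 macro-F1 at n = 600) therefore characterize the
synthetic task, not any laboratory dataset.  The declining score with finer
grouping is structural: A1/A2/B share motif chemistry and differ mainly in
potency bands that structure only partially determines — the same reason
multiclass models on real inhibition data score well below their binary
counterparts while classifying the inactive minority better.

## Problem sizes and numerical choices

Default study sizes are 600 compounds for end-to-end validation and 300 for
screening candidates, with the reduced grids and 5-fold CV — large enough
for stable class counts after an 80:20 split (≈ 21 inactive test compounds,
matching the reference dataset's scale) and small enough for interactive
runs.  Ties everywhere break deterministically (first grid point, fixed
learner order, first class in sorted order for probability ties).  Degenerate
inputs raise rather than guess: single-member classes, folds missing a
class, empty groups, single-class training data, non-crossing curves.
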