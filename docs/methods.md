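# Methods

This note records the models implemented in `bsepscreen`, the defaults and
why they were chosen, what the synthetic data generator does and does not
emulate, and the numerical conventions that matter for reproducing results.

## Activity classes and curation

A compound is an **inhibitor** when its mean IC50 is ≤ 10 μM (inclusive),
a **non-inhibitor** when it is strictly above 300 μM, and **excluded**
otherwise. The wide excluded band deliberately keeps only strong inhibitors
and clear negatives in the modelling classes; all partition tests assume
these boundary semantics (≤ inclusive at 10, > strict at 300).

Cross-set deduplication compares canonical structure keys produced by a
minimal standardization pipeline: keep the largest organic fragment,
neutralize charges where valence allows, write canonical SMILES with
stereochemistry retained. Tautomer canonicalization is intentionally *not*
applied: tautomer enumeration belongs to ligand preparation, which this
package does not do, and folding tautomers into one key would silently merge
records that the upstream preparation treated as distinct. This pipeline is
a documented stand-in for full published standardization protocols; users
with stricter requirements can pre-standardize and feed canonical SMILES
directly.

## Descriptors

- **MW** is the average-atomic-mass molecular weight (RDKit `MolWt`).
- **logP** is the Crippen atom-contribution estimate. Atom-contribution
  schemes from different software packages disagree by up to about one log
  unit on lipophilic molecules, so all comparisons against externally
  reported logP values use a ±1.0 tolerance, and the 3.6 logP cut-off of the
  OR-rule should be refit if training values came from another estimator.
- **Fingerprints** are RDKit MACCS keys: 167 bits of which bit 0 is a
  placeholder, encoding the standard 166-key set. Fingerprint length is
  constant, so Tanimoto similarities and network construction are
  unaffected by the placeholder.
- **Functional groups** are matched with a bundled, versioned catalog of 88
  Daylight-style SMARTS patterns (`resources/functional_groups.csv`);
  users may supply their own two-column CSV. Group *presence* (≥ 1 match),
  not occurrence count, defines the per-class frequency profiles, because
  the profiles answer "what fraction of molecules carry this group".
  A class with zero members yields missing fractions, never 0.

## Intersection-point classification

Scores are binned into half-open intervals `[edge, edge + w)` aligned to an
anchor (default 0), covering the observed range. Each class's bin counts
are normalized to relative frequencies before the crossing is sought:
with 113 inhibitors against 295 non-inhibitors, raw-count curves would be
dominated by the majority class and the crossing would drift toward the
inhibitor mode. The two frequency polylines over bin centers are
intersected by linear interpolation. Conventions:

- Empty bins (both classes zero) carry no curve; the gap between two fully
  separated distributions is therefore *not* a crossing, and perfectly
  separated or identical curves raise `NoIntersectionError` carrying both
  curves for inspection.
- With multiple crossings, the one whose threshold maximizes the training
  G-mean is kept; ties go to the lowest score.
- A score exactly at the threshold is classified as inhibitor — the
  conservative call in a toxicity screen. This is configurable in the sense
  that the fitted threshold object is a plain value that callers may nudge.

Default bin widths: 5 score units for GOLD-type scores (ChemScore,
GoldScore), 1 for Glide/XScore-type scales, 1/40 of the observed range for
single molecular properties. Widths are ordinary estimator parameters.

On two Gaussian classes with equal variance the procedure estimates the
equal-prior Bayes boundary (midpoint of means); the test suite checks
recovery within 0.1 score units and within 0.02 G-mean of the closed-form
optimum at n = 20 000 per class.

## Bin probabilities

P(inhibitor | bin) is the raw count ratio in the bin. Each bin's p-value
comes from the 2×2 table {in-bin vs out-of-bin} × {inhibitor vs
non-inhibitor}, Pearson χ² with 1 degree of freedom and **no Yates
correction** by default (a flag enables it). Empty bins report a missing
probability and p = 1 by convention; a bin holding every compound has no
association and also reports p = 1.

## Physicochemical and combined models

The OR-rule calls a compound an inhibitor when MW ≥ 390 Da *or*
logP ≥ 3.6, both cut-offs inclusive. The combined model first sign-adjusts
the docking score so that higher is always inhibitor-like, min-max
normalizes score, MW and logP on the training data, averages the three
clipped features with **equal weights** (the minimal assumption; no
published weighting exists to reproduce), and fits an intersection
threshold on the composite (default bin width 0.05 on the [0, 1] scale).
Zero-width normalization ranges raise a typed error rather than dividing
by zero.

## Performance measures

All metrics live on an explicit TP/TN/FP/FN container with inhibitor as the
positive class. Undefined ratios (zero denominator) raise a typed
`UndefinedMetricError` instead of returning NaN, because silent NaNs
corrupt summary tables; MCC with a zero denominator factor returns 0 by the
standard convention, logged. AUC is the Mann–Whitney rank statistic —
P(inhibitor score beats non-inhibitor score) + ½·P(tie) — which equals
trapezoidal ROC integration and is exact under ties. Rounding for
comparisons against published tables (half-up, 2 decimals) happens only in
the test layer, never inside the metrics.

## PLIF analysis

Interaction records are consumed from flat CSV/JSON tables
(`compound_id, residue, interaction_type, functional_group, strength`);
geometric contact detection from 3D poses is out of scope, which keeps the
analysis independent of any particular modelling suite. The closed
interaction vocabulary is hydrophobic, hbond_donor, hbond_acceptor, ionic,
surface_contact. Records below the strength minima — 1% for molecular
interactions, 20% for surface contacts, mirroring the thresholds commonly
used when exporting such records — are dropped before bit-setting;
`strength` is interpreted as a normalized fraction in [0, 1] and records
without one are kept. Fingerprints are binary over a key universe fixed
from the training collection, in three flavors (residue, residue × type,
residue × ligand group); the residues of a residue × type fingerprint always
project onto those of the plain residue fingerprint built from the same
records.

Heat-map cells count *distinct compounds*, not record occurrences, because
the question is how many ligands realize a residue–group contact. The
similarity predictor uses the **maximum** Tanimoto to any known inhibitor
(nearest-neighbor reading) with a configurable decision threshold; the mean
over references was rejected as it dilutes sharp matches to one scaffold.

## Chemical-space network and applicability domain

CSN nodes are compounds, with an edge when fingerprint Tanimoto ≥ 0.7 (the
conventional MACCS threshold); pIC50, when available, is attached as a
node-size attribute. Communities come from Louvain modularity maximization
with an explicit seed — deterministic under the seed, standard, and robust
on planted-partition benchmarks (adjusted Rand ≥ 0.9 in the tests); "major"
communities have ≥ 5 members.

The applicability domain follows the Euclidean-distance APD construction:
auto-scale descriptor columns (constant columns dropped with a warning),
compute all pairwise training distances, keep those not exceeding the
global mean, and set the domain radius to their mean plus Z times their
standard deviation (Z = 0.5 default; the radius is non-decreasing in Z). A
query is in domain when its nearest scaled training neighbor is within the
radius. The default descriptor block is MW, logP and the functional-group
count columns; which descriptors feed the AD is an open choice and is a
plain parameter here. Fitting accepts n ≥ 2 training compounds (the
two-point case is the hand-checkable degenerate case: radius = scaled
distance 2 when σ = 0).

## Sequential combination

`cascade(first, second)` is a positive only when both stages are; first-
stage negatives never reach the second stage. Consequently the cascade's
positives are a subset of the first stage's, so FP and TP cannot increase —
specificity and precision can only rise, sensitivity only fall. Consensus
is a majority vote; with an even model count a tie goes to non-inhibitor,
the conservative choice for a toxicity screen (configurable reading: pass
an odd number of models to avoid ties entirely). Unpredicted entries
propagate explicitly and are excluded from metric counts with a reported
`n_unpredicted`.

The ligand-based first-stage classifier itself is not reimplemented: the
cascade consumes any prediction table, which is the interoperability point.

## Synthetic data generator

The generator draws a panel with the statistical structure the analyses
assume, under fixed study conditions:

- 113 inhibitors, 295 non-inhibitors (defaults);
- Gaussian class-conditional docking scores per scoring function —
  ChemScore-like inhibitors N(37.5, 5) (centered in the 35–40 band) vs
  non-inhibitors N(25, 7); GoldScore-like N(60, 10) vs N(47, 11);
  GlideXP-like (lower is better) N(−8.5, 1.5) vs N(−5.5, 1.8);
  XScore-like N(6.6, 0.55) vs N(5.6, 0.65);
- MW N(480, 80) vs N(300, 80) Da and logP N(4.6, 1.5) vs N(2.6, 1.5),
  straddling the 390 / 3.6 cut-offs;
- 166 fingerprint bits, the first 20 biased (P = 0.6 inhibitor vs 0.2
  non-inhibitor), the rest at 0.15 for both classes;
- functional-group presence probabilities favouring halide, ether,
  carbonyl, vinyl and amide groups in inhibitors, with arene nearly
  ubiquitous in both classes (0.95 vs 0.85);
- residue-contact probabilities with hydrophobic Phe334/Tyr772 contacts at
  0.8 for inhibitors (above the 75% anchor) vs ~0.3 for non-inhibitors, and
  hydrogen-bond contacts more frequent in non-inhibitors;
- IC50s log-uniform on [0.1, 10] μM (inhibitors) and (300, ~3160] μM
  (non-inhibitors), so labels are re-derivable from the emitted IC50s.

Identical config + seed gives byte-identical output. Because the score
model is Gaussian, the Bayes-optimal threshold and error rates exist in
closed form (`bayes_optimal_metrics`) and serve as independent oracles.

What the generator does **not** emulate: correlated descriptors, multimodal
or skewed score distributions, activity cliffs, pose-level noise, scaffold
structure in the random fingerprint bits. Passing parameter-recovery tests
therefore demonstrates correctness of the estimators under the stated
model, not performance on real screening panels. For descriptor- and
network-path demonstrations the generator can attach real structures from
a small built-in pool of 30 drugs (cycled), which is a demonstration aid,
not a statistical model of chemical space.

## Problem sizes

The test suite and the acceptance script run the default 408-compound panel
for pipeline checks, 20 000 compounds per class for Gaussian parameter
recovery, 5 000 per class for property-threshold recovery, and a
150-compound subsample for the O(n²) network pair scan — sizes at which the
sampling error of every checked quantity is far below its test tolerance.

## Known limitations

- The intersection threshold inherits histogram noise of order one bin
  width; the G-mean tie-break makes the multiple-crossing case
  deterministic but data-dependent.
- The χ² p-values are per-bin and not corrected for testing multiple bins;
  they rank bins rather than certify significance.
- Crippen logP offsets of ~1 log unit against other estimators shift the
  OR-rule's effective operating point; refit `fit_property_threshold` on
  your own descriptor source.
- The applicability-domain radius depends on the chosen descriptor block;
  with highly correlated descriptors the Euclidean distance overweights the
  shared direction (no whitening is applied).
- CompoundSet curation assumes parsable SMILES for deduplication;
  unparsable target records are kept (with a warning) rather than dropped,
  which can retain duplicates that a structure comparison would have
  removed.
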