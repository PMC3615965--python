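# Methods

## Problem and model

`cppred` is a binary sequence classifier for cell-penetrating ability.
The working assumption, well supported by the composition of known
CPPs, is that penetrating peptides are separable from generic protein
fragments by residue usage (strong Arg/Lys enrichment, elevated Trp and
Pro), by position-specific terminal preferences, and by recurring
sequence motifs (poly-arginine blocks, spaced R-x-R patterns,
amphipathic Leu/Lys repeats). The classifier makes no use of structure,
cargo, cell line or assay conditions; it predicts an intrinsic
sequence propensity only.

## Feature encodings

All encodings index residues in fixed alphabetical one-letter order
(A, C, D, …, Y), so feature vectors and trained models are portable.

* **Composition** (20 features): Compᵢ = Rᵢ/N × 100; components sum to
  100. Reported in percent; the dipeptide vector is reported as
  fractions summing to 1 — the asymmetry is deliberate and documented
  rather than harmonised, because downstream models were defined
  against exactly these scales.
* **Dipeptide composition** (400 features): each ordered pair's count
  divided by the N−1 overlapping pairs. The overlapping-pair
  denominator is the only reading that makes the vector a composition
  (non-negative, summing to 1); a fixed denominator of 400 would not.
  Length-1 peptides are rejected for this encoding.
* **Binary profiles** (20·W features): one 20-bit one-hot block per
  window position; N-terminal blocks precede C-terminal blocks in the
  joined schemes (N5-C5, N10-C10). Peptides shorter than a window
  leave the missing positions as all-zero blocks — padding keeps the
  dimension fixed (an SVM requirement) while encoding absence
  distinctly from every residue. When the combined windows exceed the
  peptide length the N and C windows are extracted independently and
  may overlap, duplicating central residues; this is the literal join
  of the two windows.
* **Physicochemical** (11 features): mean amphipathicity
  (amphiphilicity index, AAindex MITS020101), mean Kyte–Doolittle
  hydropathy (KYTJ820101), net charge at physiological pH
  (Arg = Lys = +1, Asp = Glu = −1, His = 0; the termini contribute
  +1/−1 and cancel), molecular weight (sum of average residue masses
  plus one water), length, isoelectric point (bisection on the
  Henderson–Hasselbalch net-charge function with the Bjellqvist pKa
  set, via Biopython ProtParam), mean Zimmerman bulkiness
  (ZIMJ680102), mean Charton steric parameter (CHAM810101), total
  hydrogen-bond donors, and polar / non-polar residue counts (polar =
  S, T, C, Y, N, Q, D, E, K, R, H). The scale tables ship as
  plain-text resources with their provenance identifiers; swapping a
  scale is a one-file change. No specific published predictor's
  physicochemical model is claimed to be reproduced exactly, since
  the exact scale entries used elsewhere are generally unstated.

## SVM protocol

The classifier is a soft-margin RBF-kernel SVM (scikit-learn SVC; the
contract is the protocol, not the solver). Hyper-parameters are chosen
by exhaustive grid search: γ ∈ {10⁻⁴, 10⁻³, 10⁻², 10⁻¹, 1, 10},
integer cost c ∈ 1..15, integer positive-class cost factor j ∈ 1..5
(implemented as a class weight on the positive class). The selection
criterion is mean stratified k-fold CV accuracy (k = 5 by default);
ties break deterministically toward smaller c, then γ, then j, and the
winner is refit on all data. Fold assignment derives from a
caller-supplied seed stored in the model metadata, so training is a
pure function of its inputs. Decision scores are signed distances from
the separating surface; classification is score ≥ threshold (default
0), with the threshold exposed so users can trade sensitivity for
specificity. No probability calibration is applied.

In `cross_validate` the grid search is nested inside each outer
training fold, so model selection never sees the held-out fold.
Metrics are computed per fold and averaged (pooled-prediction metrics
are reported alongside). Nested estimates are the honest ones; the
grid search's own selected maximum is optimistically biased and is
reported only as training metadata.

## Motif scanning and E-values

Motifs are position probability matrices parsed from MEME minimal text
format (protein alphabet; the parser is in-package because the
available library parsers cover nucleotide alphabets only). Motif
*discovery* is out of scope — motifs come from an external discovery
tool or from the bundled synthetic fixture of three CPP-like PWMs
(poly-Arg block, spaced R-x-R, amphipathic LK repeat), which is
constructed, not discovered from any database.

A window of motif width w scores Σ log₂(pwm/background) in bits, with
probabilities floored at 10⁻⁴ before the log. The null distribution of
the window score for background-random sequence is computed exactly by
dynamic-programming convolution after rounding each per-position score
to a 0.01-bit step; p-values are exact tail masses of this discretized
model (verified against exhaustive enumeration for width-2 motifs).
The per-peptide E-value is Bonferroni-style:
E = best-window p × number of windows × number of motifs. This is a
deliberately simple, documented surrogate for database-search E-values;
the threshold ladder 10 … 10⁻⁷ keeps the conventional semantics
(coverage is non-increasing as the threshold tightens), but absolute
coverage at a given rung is not comparable to a database-search tool.
In particular E ≤ 10 is nearly always satisfiable for 15–30-mers
(the maximum possible E is windows × motifs), so the loosest rung
covers almost everything; informative motif evidence starts around
E ≤ 1 and below.

The motif-only classifier predicts CPP for any covered peptide.
Coverage is the percent of peptides with ≥1 hit; PCP ("probability of
correct prediction") is operationalized as precision among covered
peptides — the natural reading of a precision-like measure that is
rarely given a formula in the applied literature — and is NaN when
nothing is covered.

## Hybrid rule

If any motif hits at the chosen E-threshold, the SVM score is raised
by exactly +5, once, regardless of hit count. Since SVM decision
scores on realistic inputs lie well inside (−5, +5), a motif-bearing
peptide is in practice always called positive at threshold 0. The
consequence of the rule is asymmetric: sensitivity can only rise, and
specificity can only fall, relative to the pure SVM. At strict
E-thresholds (where background peptides essentially never hit) the
hybrid is a safe sensitivity boost; at the loosest rung the bonus
reaches many background peptides and costs specificity — the
acceptance script reports both operating points.

## Synthetic data generator

The generator emulates, at configurable scale, the structure of curated
CPP training sets: balanced positives and negatives; negatives sampled
i.i.d. from a bundled SwissProt-like residue frequency table at lengths
15–30 (mirroring the convention of sampling random protein fragments as
presumed non-CPPs); positives sampled from the same table with
frequency multipliers Arg ×8, Lys ×5, Trp ×2, Pro ×1.5 (renormalized)
at lengths 5–30. The multipliers preserve the qualitative abundance
ordering seen in real CPP collections and were calibrated once, using
the nested-CV protocol, so that the default conditions reproduce the
separability level published composition-based CPP models achieve
(cross-validated accuracy in the low-to-mid 90s, AUC ≈ 0.97–0.99);
the resulting positive-class Arg fraction (≈27%) is realistic for
collections dominated by polyarginine- and Tat-family peptides.

Optionally a consensus (e.g. `RRRRRRR`) is planted into each positive
with a configured probability at a uniform random feasible offset;
peptides selected for planting draw their length from the feasible
upper part of the length range so planting always succeeds, and a
consensus longer than the maximum positive length is an error.
`hard_mode()` resets all multipliers to 1, leaving only the length
difference between classes — composition separability collapses toward
chance, emulating the much harder problem of separating high- from
low-efficiency penetrating peptides.

What the generator does **not** emulate: real peptide families
(truncation and Ala-scan series with their internal redundancy),
position-specific terminal preferences beyond what composition bias
induces, uptake-efficiency annotations, and assay noise. Passing tests
on synthetic data therefore demonstrate that the pipeline's machinery
is correct and that it recovers the planted signal structure — not
that any particular accuracy will transfer to real peptides.

## Numerical and design choices

* Stratified folds (all study datasets are balanced; stratification
  reduces fold variance). Leave-one-out is provided as singleton folds.
* MCC returns 0 when any marginal of the confusion matrix is zero —
  the standard degenerate-case convention.
* AUC is the Mann–Whitney rank statistic with midranks for ties; the
  reported ROC curve's trapezoidal integral equals it to 1e-9.
* PWM p-value discretization step: 0.01 bits (per-position rounding;
  the DP is exact for the discretized model).
* Mutant enumeration order is position-major, then substitute residue
  alphabetical, so design reports are diffable; user-facing
  coordinates are 1-based inclusive, internal offsets 0-based.
* Default protein-scan window is 10 (matching the N10 terminal window
  span), user-settable from 5 upward.
* Problem sizes in the test suite and acceptance script (200+200
  peptides, 5 outer folds, the full 450-point grid nested per fold)
  are the package's default scaled-down study; they complete in
  minutes on a single core while exercising the complete protocol.

## Known limitations

* The SVM feature space treats peptides as bags of residues or
  terminal windows; internal sequence order beyond dipeptides and
  terminal one-hots is invisible.
* The E-value model is per-peptide Bonferroni, not a database-search
  E-value; thresholds are comparable across runs of this package but
  not across tools.
* Physicochemical scale choices are documented but not unique;
  alternative AAindex entries would shift model coefficients.
* Trained models are persisted with joblib and are portable across
  machines but not guaranteed across major scikit-learn versions (a
  format-version check fails loudly rather than mis-scoring).
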