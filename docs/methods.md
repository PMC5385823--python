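# Methods

## Signed network and propagation

The curated network (`tp53mir/data/tp53_normal.tsv`) encodes the normal-state
TP53–miRNA regulation: TP53 activates miR-107, miR-215 and miR-34b/c and
represses miR-125b and miR-155, plus repression edges from each miRNA to its
validated gene targets (AGTR1, MEIS1 and LDOC1 under miR-155; BAK1 under
miR-125b; DTL and TYMS under miR-215; CDK6 under miR-107; MET under
miR-34b/c). A second fixture (`tp53_feedback.tsv`) adds the
IRF6 → AKT1 → MDM2 ⊣ TP53 / TP53 → PHLDA3 ⊣ AKT1 feedback circuitry and an
AKT1 ⊣ miR-125b edge.

Propagation is breadth-first from a set of clamped nodes: a child's
direction is the parent's direction multiplied by the edge sign, `unchanged`
absorbs any sign, and nodes unreachable from a clamp stay `unknown`. The
graph must be acyclic once clamped/overridden nodes' in-edges are removed;
feedback loops are therefore handled by *overrides* — forced (node,
direction, reason) annotations that win over any incoming signal and
propagate downstream — rather than by fixed-point iteration. This matches
how the miR-125b paradox is argued: with TP53 lost, the direct edge says
miR-125b should rise, but AKT1 (derepressed) pushes it down, and the
biological record says down. With the feedback fixture and no override, the
two paths genuinely conflict and propagation raises an error listing both —
a deliberate design choice: contradictory un-annotated signals indicate a
modeling gap, not something to resolve silently. A dynamical (ODE/Boolean)
treatment of the loop is out of scope.

## p53 response-element scanner

A response element is two `RRRCWWGYYY` decamers in tandem with a 0–13 nt
spacer. The scanner matches the IUPAC classes position by position (`N`
never matches), enumerates every decamer start, and reports every pair whose
spacer falls in range — overlapping pairings included, since a shared
half-site can participate in two elements and completeness is cheaper to
post-filter than to recover. Coordinates are 0-based half-open in the API
and in BED output. The forward strand is scanned by default; the motif is
not its own reverse complement, so `both_strands` additionally scans the
reverse complement and maps hits back to forward coordinates with a `-`
strand flag. Spacers are counted exclusively (nucleotides strictly between
the decamers). Scoring binding affinity (PWMs, thermodynamics) is out of
scope: the element is treated as a hard pattern.

## Microarray meta-analysis

Per gene and dataset, a Welch two-sample *t* (tumor − normal) with
Welch–Satterthwaite degrees of freedom. Welch rather than pooled-variance
Student: tumor and normal pools in public series are heterogeneous and
unbalanced, and Welch is the safer default. The *t* is mapped to a
standard-normal *z* preserving the one-sided tail area,
*z* = Φ⁻¹(F_t(t; df)), computed in the upper tail with `isf`/`sf` for
numerical stability, and combined across datasets with the unweighted
Stouffer statistic Σzᵢ/√k. A √n-weighted variant exists but is off by
default — nothing in the design motivates differential study weights, and
the unweighted form is exact under the null. Genes missing from a dataset
contribute no term (k counts observed datasets); genes observed nowhere go
to a skipped-gene report instead of being dropped silently. Filtering is
two-sided at the normal critical values 1.959964 (95%) and 2.575829 (99%);
ranks order |combined z| descending with lexicographic gene-id tie-breaks
for determinism. An optional per-dataset 95% prescreen before combination is
exposed (`prescreen_per_dataset`) but off by default, combining all
observed evidence being the less lossy reading.

## Preprocessing

* **log2 harmonization**: matrices whose maximum exceeds 50 are treated as
  raw intensities and log2(x+1)-transformed (log2 microarray data
  essentially never exceeds ~16; raw Affymetrix intensities run to tens of
  thousands). Negative values under the raw signature are an error.
* **Quantile normalization**: the classic algorithm — replace each column's
  order statistics by the mean sorted profile. Ties receive the mean of
  their would-be quantile values (average ranks + linear interpolation), so
  the "identical sorted columns" contract is exact only for tie-free
  columns; it is idempotent up to that same tie handling.
* **Outlier removal**: k-means (k = 2, k-means++ init, 10 restarts, fixed
  seed) on samples in the normalized space; clusters holding < 10% of the
  samples are declared outliers and dropped. k and the threshold are
  configuration, not science: the goal is flagging stray arrays, not
  subtyping. Removal that empties a class is an error. Sample-space
  Euclidean clustering is a documented choice; gene-space clustering would
  answer a different question.
* **Merged differential expression**: Welch *t* per gene on the cleaned
  merged matrix, two-sided *p*, Benjamini–Hochberg adjustment. Degenerate
  genes yield NA rows with a reason rather than aborting the table.

## Stability selection

Each of `n_repeats` (default 100) repeats: a stratified random split keeps
1/3 of each class for training (rounded, with at least one train and one
test sample per class), repeat *i* seeded by `base_seed + i`. Features are
standardized on training statistics only and the same transform is applied
to the test block. SVM-RFE fits a linear soft-margin SVM (C = 1), ranks
features by squared weight, and drops the weakest ⌈drop_frac · current⌉
(default halving — the standard speed compromise over drop-1, which remains
available via `drop_frac`), never descending below `n_features` (default
20). Ties break by gene id. The survivors are refit and test accuracy is
the plain proportion correct (balanced accuracy is reported alongside).
Failed repeats are recorded and skipped; more than 10% failures aborts.

Abundance bookkeeping: per-gene abundance = selections / n_repeats, so
Σ_genes abundance × n_repeats = 20 × successful repeats exactly. The
abundance of a designated gene set is the mean over repeats of
|selected ∩ set| / |set| — average fractional presence — which keeps a
single-figure summary interpretable when the set is larger or smaller than
the selection budget.

## RNA-seq class prediction and NB test

Counts are normalized to counts per million using column-sum library sizes.
The classifier composition table reports, per gene: Welch *t* and two-sided
*p* on log2(CPM + pseudocount); % CV support — the percentage of
leave-one-out folds in which the gene's Welch *p* on the fold's training
samples beats a selection threshold (default 0.001); per-class geometric
means of CPM (pseudocount applied only when zeros are present); and fold
change = geomean(case)/geomean(control). Rows sort ascending by *t* and
round to reporting precision (*p* to 2 significant figures, *t* to 3
decimals, means and fold change to 2 decimals). The LOOCV-selection
definition of CV support is this package's own operationalization of a
cross-validated gene-level support score.

The negative binomial test models Var = μ + αμ² on the normalized scale.
Per gene, α is estimated by method of moments within each class,
(s² − μ)/μ², pooled with df weights and floored at 1e-8. The Wald statistic
tests log(μ̂₁/μ̂₂) with delta-method variance
(μ + αμ²)/(nμ²) summed over classes. P-values use a *t* reference with
df = n₁ + n₂ − 2 rather than the asymptotic normal: with four controls the
normal reference is visibly anticonservative, and the *t* reference brings
the null rejection rate inside the binomial band around 0.05 (verified by
simulation in the test suite). q-values are Benjamini–Hochberg adjusted
p-values; Storey-type estimation is not implemented. All-zero genes yield
NA rows with a reason.

One consequence of plain library-size normalization worth knowing: a fold
change planted in a large fraction of the transcriptome shifts the library
sizes themselves and is partially absorbed by CPM. Fold-change recovery is
therefore quantified on designs where planted genes are a small minority —
the situation the method targets. Median-of-ratios normalization would relax
this but is out of scope.

## qPCR (comparative Ct)

Livak assumptions throughout: amplification efficiency exactly 2 for target
and reference, so RQ = 2^(−ΔΔCt) and log2(RQ) = −ΔΔCt identically.
ΔCt = Ct_target − Ct_reference per record; the calibrator (a pool of normal
tissues) is summarized by its mean ΔCt per gene; per-gene summaries are
geometric mean RQs over samples (the natural mean for a ratio scale).
Efficiency-corrected (Pfaffl) quantification and multi-reference
normalization are out of scope.

## Synthetic data generator

The generator emulates the study conditions, not an instrument:

* **Microarray collections**: intensities are generated directly on the
  log2 scale (generating raw and logging would be equivalent; direct log2
  is exact). Per gene, a baseline ~ N(8, 1.5) shared across datasets plus a
  per-dataset batch shift ~ N(0, 0.5) — enough heterogeneity that
  cross-dataset combination is genuinely exercised without swamping planted
  effects — plus the class effect and N(0, noise_sd) noise. The default
  design is 90 candidate genes with the six study genes planted at
  |log2 effect| = 2 (BAK1 and DTL up; MEIS1, LDOC1, AGTR1, TYMS down),
  noise_sd = 1, and six datasets of (7,7)×4 and (6,6)×2 tumor/normal
  samples — 40 per class overall. Per-dataset sample sizes are this
  package's choice of a realistic public-series scale.
* **Counts**: NB with Var = μ + αμ², default 22 cases / 4 controls,
  baseline mean 500, α = 0.05 — typical bulk RNA-seq overdispersion — and
  per-gene planted fold changes (defaults 4.0 up / 0.25 down, the magnitude
  scale of the reference classifier table).
* **Promoters**: random (or fixed-base) backgrounds with tandem decamer
  pairs sampled uniformly from the IUPAC classes, planted at requested
  (position, spacer) sites; ground truth returned alongside.
* **Ct tables**: calibrator pool at fixed Ct levels; sample target Ct
  shifted by −log2(true RQ) plus optional Gaussian noise.

What the generator does *not* emulate: probe-level artifacts, GC or length
bias, batch effects beyond per-dataset baseline shifts, correlated genes,
or library-composition structure. Passing tests therefore demonstrate that
the statistical machinery is correct and calibrated under its stated
assumptions, not that it is robust to every pathology of real public data.

## Determinism

Every stochastic component takes an explicit seed (numpy `default_rng`;
repeat *i* of stability selection uses `base_seed + i`; the pipeline derives
stage seeds from the single config seed). Re-running a pipeline config
reproduces every output file byte for byte. Ranking and feature-elimination
ties break lexicographically by gene id.

## Problem sizes

Defaults run the complete workflow in seconds on one core: the 100-repeat
stability selection on the 90-gene, 80-sample merged matrix dominates
(~1 s); calibration checks in the test suite use 2,500 null genes for the
NB type-I error and 10,000 genes (200 planted) for fold-change recovery.
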