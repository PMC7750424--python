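# Methods

## Essential amino-acid profiling of signal peptides

Sequences are validated against the 20-letter amino-acid alphabet
(case-insensitive; `U`, `O` and `X` are rejected rather than dropped, so a
selenocysteine or placeholder never silently skews a count). The essential
set is fixed to the nine classical human essential amino acids
{F, H, I, K, L, M, T, V, W}; histidine is counted as essential. An EAA
profile is the pair (variety, total): the number of distinct essential types
present and the number of essential residues. Because each residue is either
essential or not, `total_eaa + neaa_count == length` holds for every
sequence, and `variety <= min(9, total_eaa)`; both are enforced as property
tests over random sequences.

Per-family consensus assumes pre-aligned, equal-length members (family SPs
share a fixed length); the consensus residue at each position is the most
frequent one, with ties broken toward the alphabetically smaller residue and
logged, so ambiguous positions are auditable. A single-member family passes
through unchanged. No alignment or cleavage-site prediction is attempted.

## Media stoichiometry

A media formulation stores raw molecule counts per free amino acid, either
given directly or derived from a concentration as `c·V/M·N_A` with
average free-amino-acid molar masses (glutamine 146.14 g/mol, etc.; the mass
table is configurable) and a default volume of 1 L. The capacity of amino
acid `a` is `supply_a / demand_a` protein copies (+∞ when `a` is not
demanded); capacities scale linearly with supply and the argmin is invariant
to boosting any non-limiting amino acid — both are tested properties.

Two limiting amino acids are reported: the minimum over essential amino
acids only (the medium's actionable bottleneck — a cell line cannot make
EAAs) and the minimum over all demanded amino acids, which for DMEM is any
of the five absent non-essential amino acids at zero copies. Ratios are kept
as reals; the 2-decimal ×10¹⁸ presentation is display-only, rounded half-up.
Precursor gaps flag a missing non-essential amino acid whose biosynthetic
precursor is missing as well (S → C, G; D → N; E → Q, P, R, pairing
configurable): for DMEM these are (N, D) and (P, E). The model is pure
stoichiometry — no uptake kinetics, growth coupling, or competing cellular
protein demand.

## Production-rate predictor

Rates are percentages of a fixed reference construct and may exceed 100.
Classes are low (< 20%), medium (20–70%) and high (> 70%); both boundary
values are medium, forced by the strict inequalities that define low and
high, and `categorize` is monotone in the rate.

The predictor is one sigmoid per class on an affine score of the features —
a literal one-vs-rest model, not a softmax; a normalized view (scores
divided by their sum) exists solely for ranking metrics. Fitting minimizes
the class-weighted, L2-penalized binary negative log-likelihood per class
with L-BFGS (analytic gradient, intercept unpenalized, convergence at
projected-gradient norm ≤ 1e-6 or 1000 iterations; the objective trajectory
is non-increasing and tested as such). Features are z-scored on the training
portion only — unstandardized counts would make the ridge penalty
scale-dependent. Sample weights default to inverse class frequency to
counter the minority of high producers; any explicit class→weight map is
accepted.

The regularization strength λ (penalty `λ/2·‖β‖²`, so λ→∞ shrinks
coefficients to zero) is chosen from a grid of 10 values log-spaced
10⁻⁴…10⁴ by 20-fold cross-validation (each cycle trains on 95% and
validates on 5% of the model set) maximizing mean held-out weighted
precision; ties prefer the smaller λ; folds whose training part lacks a
class are skipped with a warning. The final model is refit on the whole
model set at the chosen λ.

Protocol: the dataset is split uniformly at random into a model set and two
test sets at the reference sizes 118:30:20 (other dataset sizes scale
proportionally with largest-remainder rounding), the split/fit/evaluate
cycle runs in triplicate with replicate seeds derived from one base seed,
and every replicate is compared with a stratified dummy baseline whose
class scores are the training priors (constant scores, hence pairwise AUC
exactly 0.5; a most-frequent strategy is available by configuration).
Metrics: support-weighted precision and F1 (an unpredicted class
contributes 0, logged) and the mean one-vs-one ROC AUC — for each class
pair, the Mann–Whitney AUC of each class's own score column among the
pair's samples, averaged over the two directions, then over the three
pairs. All three match scikit-learn reference computations to 1e-10 in the
test suite. Prediction is the argmax of the class scores with ties to the
lower class index, so reruns are bit-identical.

## Synthetic data generator

The generator emulates the statistical shape of a variant-production
experiment whose raw table is unpublished; its defaults are the study
conditions. Per variant, the 20 counts are a representative full-length
antibody composition plus a symmetric Poisson-difference integer
perturbation (mean 0.1 of the base count per amino acid, clipped at zero),
mimicking count variation across CDR/SP variants. A latent production score
is a planted affine function of the z-scored counts; the planted signs
follow the qualitative composition trends observed across variant panels
(W, L, R, S positive; F, H, I, A, N negative; K, D weakly negative). The
measured rate is an affine-logistic squashing of the score onto [0, 250]%
— rates around 240% occur in practice — calibrated by quantile matching so
the noiseless class shares equal the configured proportions (default
0.40/0.40/0.20 with high deliberately the minority), plus Gaussian noise of
SD 10 percentage points, a typical transient-transfection variability,
clipped at zero. Realized class shares stay within ±5 points of the
targets; this, determinism from the single seed, and a
law-of-large-numbers check of the mean composition at n = 2000 are tested.

What the generator does *not* emulate: transfection biology, secretion
kinetics, chain pairing, codon effects, or the real (unknown) effect sizes.
Passing the recovery tests therefore shows the pipeline is correct and
well-posed under a known ground truth — not that real production data are
this predictable. Recovery is scored as the fraction of planted effects of
magnitude ≥ 0.5 SD whose sign matches the fitted high-class minus
low-class coefficient difference — the contrast that orders the classes in
a one-vs-rest model.

## Problem sizes and numerical choices

The recovery study runs at n = 500 (fit, in-sample pairwise AUC, sign
recovery) and the triplicate protocol at the same n; both finish in seconds.
The fixture tables are pinned by checksum. Degenerate inputs are rejected
early with named errors: empty sequence sets, unequal consensus lengths,
non-positive volumes/masses/references, all-zero demand, infeasible class
proportions, degenerate latent scores. Zero-variance features standardize
with SD 1 to avoid division by zero. Capacity argmin ties break
alphabetically for deterministic reports.

## Known limitations

- Consensus requires pre-aligned equal-length family members; repertoires
  with indels must be aligned upstream.
- The stoichiometric bound ignores all non-antibody amino-acid demand and
  serum contributions, so it is an upper bound in the strict sense.
- The predictor is linear in counts; interactions or position effects are
  out of scope by design.
- Reported discrimination on synthetic data reflects the planted structure
  and noise level, not expected performance on new experimental datasets.
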