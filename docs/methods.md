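# Methods

## The prediction problem

MHC class II molecules present peptides of highly variable length (typically
11–20 residues) in an open-ended groove; the bound stretch is a nonamer
"binding core" that can sit anywhere in the peptide. Binding strength is
measured as IC50 (nM) and modelled on the transformed scale

    t = 1 − log(IC50) / log(50000),

so 50000 nM → 0, 1 nM → 1, and the conventional 500 nM binder cutoff sits at
t ≈ 0.4256 (a peptide is a *binder* iff IC50 < 500 nM, strictly). Because MHC
molecules are extremely polymorphic and most alleles have little or no
binding data, the practically important task is *pan-specific* prediction:
predicting binding for an allele with known protein sequence by pooling data
across alleles.

## Kernels

All kernels act on peptides encoded residue-wise by φ: each of the 20
standard amino acids maps to its raw 20-entry BLOSUM62 row (integer half-bit
scores as reals, no scaling — the convention of spectrum-RBF string-kernel
work; any substitution-style table can be substituted from file). The
primitive is the RBF similarity of two equal-length substrings,

    k_l(s, s′) = exp(− Σ_i ‖φ(s_i) − φ(s′_i)‖² / (2σ_c²)).

* **SRBF** sums k_l over all substring pairs of one fixed length l.
* **GS** sums over lengths 1..L with a Gaussian penalty
  exp(−(i−j)²/(2σ_p²)) on the start-position difference of the two
  substrings.
* **MHC2SK** sums over lengths from a *minimum* L′ up to min(|y|, |y′|) with
  no positional penalty. The design reflects two facts about MHC-II data:
  binding cores of two peptides routinely start at different offsets (so a
  start-position penalty suppresses genuine matches), and very short
  substring matches are noise (so lengths below L′ are dropped while all
  longer lengths, up to the shorter peptide, are kept). As a sum of SRBF
  kernels, MHC2SK is positive semi-definite.
* **MHC2SKpan** represents an allele by its pseudosequence — the 21
  polymorphic residues in potential contact with the peptide — and defines
  a kernel on (allele, peptide) pairs as the product
  K_allele(x, x′) · K_MHC2SK(y, y′), where K_allele is the single-term RBF
  on the full pseudosequences with bandwidth σ_a. σ_a controls pooling:
  small values share data only between near-identical alleles, large values
  pool everything.

Conventions: substring indexing is 0-based half-open internally (the
positional penalty depends only on i−j and is base-invariant). When the
shorter peptide is below L′ the MHC2SK sum is empty and the kernel is 0
(warned once per run); peptides of 11+ residues with L′ ≤ 9 never hit this.
Gram matrices are unnormalized by default, matching the kernel definitions
as written; an optional cosine normalization K(a,b)/√(K(a,a)K(b,b)) is
available (the GS authors' implementation normalizes) and is recorded in
the Gram/model provenance. Pseudosequences are opaque fixed-length inputs
supplied by file; deriving them from full-length HLA sequences is out of
scope.

### Fast evaluation

A literal implementation is a triple loop. The production path instead
computes, per peptide pair, the matrix E₁ of single-residue similarities
(a lookup of exp(−‖φ(a)−φ(b)‖²/(2σ_c²)) over the 400 residue pairs) and
uses the recurrence E_{l+1}[i,j] = E_l[i,j] · E₁[i+l, j+l], so only |y||y′|
exponentials are taken per pair. Gram assembly batches pairs with equal
length signatures into vectorised blocks (upper triangle only, mirrored).
A brute-force nested-loop oracle with no shared algebra guards all of this
in the test suite at 1e-10 relative tolerance.

For model selection, per-length SRBF Gram "stacks" are kept: the MHC2SK
Gram at any L′ is a suffix sum over fixed-length layers, so a grid over L′
costs one stack per σ_c; the GS Gram at any L is a prefix sum of penalised
layers per (σ_c, σ_p); the pan Gram multiplies a cached peptide layer by a
per-σ_a allele factor. Kernel values carry no label information, so stacks
are computed once over a dataset and sliced per cross-validation fold.

## Regression and model selection

Models are ε-insensitive SVR on precomputed Gram matrices (libsvm via
scikit-learn, stopping tolerance 1e-3, recorded in provenance). C and ε are
not searched; they default to the libsvm defaults C = 1, ε = 0.1 and are
exposed as configuration. Grid search covers kernel hyperparameters only,
discretised as σ_c ∈ {0.5, 1, …, 5}, σ_p and σ_a ∈ {0.5, 1, …, 15},
L′ ∈ {1..9}, L ∈ {1..20} (all overridable); each point is scored by the
cross-validated mean per-allele objective (AUC by default, PCC optionally),
with predictions pooled per allele across folds before the metric is
computed (a per-fold-averaged alternative exists behind a flag). Ties break
to the first point in lexicographic grid order (σ_c, then the length
cutoff, then σ_a; for GS σ_c, σ_p, L).

Cross-validation schemes: k-fold over records (seeded shuffle), fixed
partitions from file, and leave-one-allele-out (LOO), whose folds are
exactly the distinct alleles — the test of generalization to novel alleles.
When nested selection is requested, the inner scheme mirrors the outer one:
k-fold outer CV tunes by inner 4-fold CV on the training records; LOO outer
CV tunes by LOO over the training alleles, since novel-allele
generalization is what is being selected for. Duplicate (allele, peptide)
records keep the first occurrence with a warning (loud if the values
conflict).

## Evaluation

Per-allele ROC AUC uses the Mann–Whitney formulation with midrank ties;
PCC is the Pearson correlation of predictions against transformed observed
values. Single-class or zero-variance alleles yield NaN markers that macro
averaging skips with a warning — never silent zeros. The "average" row is
the unweighted per-allele mean. Two methods are compared by the exact
one-tailed per-allele sign test: ties (common at three printed decimals)
are excluded, and p = Σ_{i≥k} C(n,i) 0.5ⁿ over the n non-tied alleles.

## Synthetic benchmark generator

The generator reproduces the structural regime of real MHC-II data without
any external download, with full ground truth for testing:

* **Pseudosequences.** A common ancestor 21-mer is mutated per allele;
  allele i receives round((1−s)·21·(i+1)/n) point mutations, where
  s = `allele_similarity` (default 0.7; s = 1 gives identical alleles,
  s = 0 fully independent uniform sequences). This plants a known
  similarity gradient.
* **Binding preferences.** Each allele scores nonamer windows with a PSSM
  equal to a shared base (i.i.d. standard normal entries) plus a
  perturbation with s.d. = (Hamming distance to ancestor)/21 — so
  pseudosequence distance and preference divergence are positively
  correlated by construction (verified by a property test, r > 0.5).
* **Peptides.** Length uniform on 11–20; a core start is drawn uniformly;
  with probability ½ the nonamer core is sampled favorably
  (residue ∝ softmax(PSSM row / 0.5)) or unfavorably (softmax of the
  negated row); flanks are uniform random residues.
* **Affinity.** The noiseless transformed affinity is the max over all
  nonamer windows of the window's mean PSSM score, mapped affinely by
  t = clip(0.1 + 0.45·raw, 0, 1). The offset and slope come from the
  analytic scale of the generator (favorably sampled cores score ≈ +1.5
  per position, the best background window ≈ +0.3), centring binders near
  0.75 and non-binders near 0.25 so the 500 nM threshold (t ≈ 0.426)
  splits the two populations roughly evenly. Gaussian noise
  (`noise_sd`, default 0.1) is added on the transformed scale — where the
  SVR operates — and the IC50 column is back-computed by inverting the
  transform.

The max-over-windows rule mirrors the hidden-core structure the kernels
must capture implicitly; the generator never reveals the core position to
the models, so cross-validated recovery is evidence about the kernel/SVR
implementation rather than label leakage. Default study conditions: 10
alleles × 150 peptides (pan) and 1 allele × 200 peptides (allele-specific),
noise 0.1, seed 42.

What the generator does **not** emulate: realistic amino-acid background
frequencies, locus-specific pseudosequence structure, assay noise that
depends on affinity, or the specific allele panels of the public
benchmarks. Passing the recovery tests therefore demonstrates that the
implementation extracts planted PSSM-with-hidden-core signal — not that
the method attains any particular accuracy on real HLA data.

## Problem sizes and numerical choices

The shipped analyses use nested model selection at coarse grids chosen to
span the search ranges at desk scale: for the pan LOO benchmark,
σ_c ∈ {2.5, 5}, L′ ∈ {1, 3, 5, 9}, σ_a ∈ {2, 6.5, 15} (inner LOO over the
nine training alleles); for GS, σ_c ∈ {2.5, 5}, σ_p ∈ {1, 5, 15},
L ∈ {5, 10}; the allele-specific benchmark uses the full default
σ_c × L′ grid. The label-shuffled control reuses fixed parameters
(σ_c = 5, L′ = 1, σ_a = 6.5) — with shuffled labels no parameter setting
carries information, and 6.5 is a natural anchor for σ_a as a mid-range
value of the sweep. All randomness flows from explicit integer seeds
(numpy `SeedSequence`); identical configuration and seed reproduce every
dataset, Gram matrix, model and prediction table byte for byte.

Degenerate inputs: empty kernel sums return 0; single-class AUC and
zero-variance PCC are NaN markers; an SRBF substring length exceeding every
peptide makes that grid point degenerate and it is skipped; a grid whose
every point is degenerate is a fatal error. Accumulation is double
precision throughout; the Gram symmetry check tolerance is 1e-10, PSD
checks allow min eigenvalue ≥ −1e-8 × max.

## Known limitations

* The generator's binder fraction (~0.5–0.6) is more balanced than real
  per-allele panels, which are often skewed; per-allele metric variance is
  correspondingly optimistic.
* σ_a is tuned globally, not per target allele; the sensitivity sweep
  (`sigma_a_sensitivity_curve`) quantifies what a per-allele choice could
  gain, but automatic per-allele tuning is out of scope, as are ensembles
  and classification-mode SVMs.
* GS model selection is quadratic in its extra bandwidth grid; at full
  grid resolution it is markedly more expensive than MHC2SK, which is one
  of the arguments for dropping σ_p.
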