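# Methods

## Model

`graphanno` treats cross-modality annotation as semi-supervised node
classification on a pair of coupled graphs. The reference (RNA) cells are
labeled nodes; the target (ATAC) cells are unlabeled nodes; anchor cells —
reciprocal cross-modality nearest neighbors in a shared CCA space — join
the two modalities.

Two variational graph auto-encoders are trained in parallel:

* **Hybrid branch.** Nodes: the n1 RNA cells plus the |𝔸| distinct ATAC
  anchors. Edges: the RNA mutual-kNN graph plus each anchor's reciprocal
  CCA pairs. Features: standardized log-normalized expression stacked over
  the anchors' standardized log-normalized gene activity (same gene
  columns).
* **ATAC branch.** Nodes: all n2 target cells; edges: the LSI-space
  mutual-kNN graph; features: the TF-IDF peak matrix.

Each branch is a two-layer GCN encoder with a shared first layer
(`H = ReLU(Â X W1)`, `Â = D̃^{-1/2}(A+I)D̃^{-1/2}`) and separate heads for
`μ = Â H W_μ` and `log σ = Â H W_logσ`; sampling uses
`Z = μ + exp(log σ) ⊙ ε`. The latent dimension equals the number of cell
types k, because the row-softmax of the merged latent
`Z^M = [Z^H rows 1..n1 ; Z^atac]` *is* the label-probability matrix. This
is a hard structural constraint of the design: adding a type means
retraining with k+1 latent dimensions.

Four losses are summed:

| term | form | default |
|---|---|---|
| KL | `½Σ(μ² + σ² − 1 − 2logσ)`, per-element mean per branch | `kl_mode="element"` |
| reconstruction | class-weighted BCE of `σ((Z^M)ᵀZ^M)` vs the merged graph, `pos_weight=(N²−E)/E`, scaled by `N²/(2(N²−E))` | `bce_mode="weighted"` |
| alignment | mean L2 distance between the two views of each anchor | `λ=1`, `align_norm="l2"` |
| classification | cross-entropy over the n1 labeled reference rows, mean | — |

Training is full-batch Adam (lr 1e-4, 500 epochs, no weight decay or
dropout), implemented in NumPy with hand-derived analytic gradients; a
finite-difference check in the test suite guards every term. Evaluation
uses `Z = μ`. Prediction is the per-row argmax of `Ẑ^M`; whether the
winning probability reaches the 0.5 decision level is recorded alongside.

### Loss normalization

The KL term is normalized by the full tensor size (nodes × latent dims),
the mean-reduction convention of the standard deep-learning frameworks.
The alternatives — per-node normalization or the raw sum — make the KL
pull strong enough, relative to the per-cell classification and
reconstruction gradients, that the latent equilibrium stays below ‖z‖ ≈ 1:
in that regime no cell's softmax probability can reach the 0.5 decision
level, every decoded edge probability hugs 0.5, and the reliability
mechanism below degenerates. Both alternatives remain available
(`kl_mode="mean"|"sum"`) for ablation.

Unweighted reconstruction BCE (`bce_mode="unweighted"`, normalized by N)
is likewise available but collapses toward the empty graph on sparse
inputs; the class-weighted form is the default.

## Reliability scoring

After training, the decoded reference–target block of `Ĝ^M` is
binarized at threshold τ: for each target cell c and reference type group
𝕂, the edge density is `d_c^𝕂 = e_c^𝕂/|𝕂|` and the edge weight `w_c^𝕂`
is the mean decoded probability over kept edges (0 when there is none).
A prediction is **confident** iff the argmax of the probability vector,
the density vector and the weight vector agree (ties to the lowest
index); a cell with no kept cross edge at all is **ambiguous** by
definition.

**Choice of τ = 0.6.** The inner-product decoder assigns p = 0.5 exactly
at z·z′ = 0. A target cell with no matching reference type equilibrates
near the latent origin — the reconstruction loss can attach it to
nothing — so its inner products with *every* reference cell hover around
zero. At τ = 0.5 (boundary inclusive) the sign noise of those near-zero
products manufactures saturated pseudo-densities to several reference
groups at once, and the argmax test loses its meaning. Any τ that demands
a margin over the boundary while staying below the saturated same-type
probabilities behaves equivalently (the behaviour is flat across
τ ∈ [0.55, 0.7] in our experiments); 0.6 is the default, configurable.

A summary table (fraction ambiguous per predicted type) supports the
diagnostic that a predicted type *dominated* by ambiguous cells signals
a cell type missing from the reference, in which case switching
references is preferable to dropping cells.

## Peak-level interpretability

With `single_layer=True` each encoder collapses to one GCN layer wired
directly from the input features to the k latent/label dimensions, and
`peak_importance` exposes |W_μ| of the ATAC branch as a peaks × types
score matrix. The single-layer weights are initialized at **zero** rather
than Glorot: under Adam at lr 1e-4 the cumulative per-weight movement
over a few hundred epochs is comparable to a Glorot draw, so with random
initialization the magnitude ranking would reflect the init, not the
data. Zero initialization is safe here — the one linear layer receives
distinct gradients per input feature, so no symmetry needs breaking —
and makes |W| a pure record of accumulated learning signal. Two-layer
encoders keep Glorot initialization.

## Preprocessing conventions

* Highly variable genes: top-g variance of log1p counts-per-10k.
* TF-IDF: Signac dialect `log1p(1e4 · TF · IDF)`, `TF = x/rowsum`,
  `IDF = n_cells/(1+df)`; all-zero cells are dropped with a warning.
* Gene activity: sum of peak counts over gene body plus strand-aware 2 kb
  upstream extension, restricted to the HVG set.
* PCA 30 components; LSI 30 components with the first (depth-correlated)
  component dropped; all embeddings carry a fixed sign convention
  (largest-|loading| entry positive) for bit-reproducibility.
* CCA: SVD of `X̃^rna (X̃^gam)ᵀ`; the cell coordinates are the singular
  vectors **scaled by their singular values**, then row-L2-normalized.
  Unscaled singular vectors give the ~k signal components and the
  remaining noise components equal per-cell weight, which measurably
  degrades anchor purity (to ~0.7–0.86 on well-separated synthetic data);
  with singular-value weighting purity is ~1.0.
* Mutual kNN throughout, `k1 = k2 = 15` (midpoint of the robust 5–25
  range), exact all-pairs search, distance ties broken by ascending index.
  When the target is much larger than the reference, k2 of 20–25 is
  recommended.

## Synthetic data

The generator emulates the regime the method assumes rather than
read-level realism:

* **RNA:** negative binomial (gamma–Poisson) counts; each of k types owns
  a disjoint random 10% of genes as markers whose log-means are shifted
  upward by `sigma_sep × U(0.5, 1)` (natural-log scale, default
  `sigma_sep = 4`); lognormal per-cell size factors.
* **ATAC:** each gene links to `peaks_per_gene = 3` peaks placed inside
  its body/2 kb-upstream window (one per gene in the upstream extension,
  exercising strand logic); peaks linked to a type's markers form its
  *planted peak set*, accessible at `q1 = 0.4` in that type vs background
  `q0 = 0.06`, thinned by capture efficiency 0.8, magnitudes
  `1 + Poisson(0.3)`. A cell detects ~5–7% of peaks, matching the
  sparsity of real scATAC-seq.
* Gene activity correlates with expression *structurally* (through peak
  placement), never by copying values, so the CCA bridge does honest work.

What the generator does not emulate — batch effects, doublets, fragment-
level noise, shared/overlapping marker programs, unbalanced type
frequencies — bounds what passing tests show: recovery on this generator
demonstrates the machinery is correct and the mechanisms behave as
designed, not that performance on real tissue atlases matches any
particular number.

Default conditions are five types, 1500 cells per modality, 2000 genes
and 10000 peaks. The test suite and the acceptance script run the same
generator at a reduced scale (400+400 cells, 600 genes, 3000 peaks,
300 HVGs) — the package's standard evaluation size, chosen so the entire
suite runs comfortably on a laptop core; recovery behaviour is unchanged
between the two scales in our experiments.

## Numerical choices

* Decoded probabilities are clipped to `[1e-7, 1−1e-7]` inside the BCE;
  the analytic gradient is zeroed in the clipped (flat) regions.
* Alignment gradients guard the `‖diff‖ = 0` singularity at 1e-12.
* Standardization treats features whose spread is ≤ 1e-12 relative to
  their mean as constant (mapped to zero) to avoid amplifying float
  residue.
* Divergence (non-finite loss) aborts training and returns the last
  finite-loss weights.
* kNN ties and argmax ties resolve to the lowest index, everywhere.

## Limitations

* Exact O(n²) neighbor search and a dense N×N decode bound practical
  sizes to a few tens of thousands of cells.
* The latent-dimension-equals-k coupling precludes discovering novel
  types; a missing reference type can only be *flagged*, not named.
* Single-reference only; no batch integration across multiple references.
* Reliability thresholding assumes the weighted-BCE decoder; a different
  reconstruction mode may need a different τ.
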