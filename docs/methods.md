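# Methods

`camsda` implements class-aware multi-source domain adaptation with
reweighted first/second-order moment matching: N labeled source domains
and one unlabeled target domain are embedded by a shared feature
extractor M, aligned by weighted moment distances, and classified by an
ensemble of per-domain heads.  This note records the model, the
numerical choices, and what the synthetic benchmark does and does not
show.

## Problem setting

Each source domain i carries labels from its own class set; the target
label space is the union of the source class sets.  Class shift means
the sets differ: a core of classes is shared by all sources while each
source also owns private classes absent elsewhere.  Transferring
indiscriminately lets a source's private classes interfere with target
classes it knows nothing about (negative transfer); the two devices
below counteract that.

## Losses

**Class-aware joint relabeling.**  With N domains and Q classes in the
union space, source sample (domain i, class c) receives the joint label
`i*Q + c` (row-major; any bijection works, one is fixed for
reproducibility).  A head A maps features to N·Q probabilities and is
trained with cross-entropy

    L_class = mean over source samples of -ln A(x)[joint label].

Joint labels for (i, c) pairs a domain never exhibits are allocated but
never observed, keeping the output width fixed at N·Q for every
scenario.  Probabilities are floored at 1e-12 before the log.

**Reweighted moment matching.**  A feature batch X is summarised by its
element-wise raw moments m1[d] = E[f_d] and m2[d] = E[f_d^2] (the
moment-matching convention of the M3SDA family), and two batches are
compared by the unsquared distance

    AWMD(a, b) = ||m1_a - m1_b||_2 + ||m2_a - m2_b||_2.

The source/source term averages over all pairs, each pair weighted by
the arithmetic mean of the two sources' contribution weights (the mean
keeps the loss symmetric in the pair):

    L_ss = 2/(N(N-1)) * sum_{i<j} (w_i + w_j)/2 * AWMD(S_i, S_j)

and the source/target term, in the default "simplified" mode, weights
each source's distance to the whole target batch:

    L_st = 2/N * sum_i w_i * AWMD(S_i, T).

A "paper-literal" mode instead splits the target batch into N
sub-batches and sums all N x N source/sub-batch pairs with coefficient
2/N^2; the two modes are config-switchable because the double-sum
formulation admits both readings.  L_awmd = L_ss + L_st.  With a single
source the empty pair sum is defined as 0 (config-guarded; an error by
default, since silent zeros hide mistakes).

**Adaptive contribution weights.**  Each iteration, the unweighted
AWMD from every source batch to the target batch is computed on the
current features, smoothed across iterations by an exponential schedule
(momentum 0.9 by default; 0 disables smoothing and reproduces raw
per-batch weights), inverted with an epsilon guard,

    w_a^i = 1 / (d_i + 1e-8),      w_i = w_a^i / sum_j w_a^j,

and then held constant inside the weighted losses — weights are
computed *from* distances but gradients do not flow *through* them,
which breaks the circular definition of weight and distance.  The
epsilon makes an exact distribution match yield the maximal, not an
undefined, weight.

**Per-domain classification.**  Each domain's classifier C_i is trained
with cross-entropy on its own labeled batch; the term is a *sum* over
domains of per-domain means.  The total objective is the unweighted sum

    L_total = L_class + L_awmd + L_cls,

with optional coefficients (default 1.0) that exist only to express the
ablations; the training log stores the coefficient-scaled terms so the
identity L_total = L_class + L_awmd + L_cls holds at every iteration,
ablations included.

## Training loop

Every iteration samples m labeled samples per source domain plus m
unlabeled target samples (m = 32 by default; domains smaller than m are
resampled with replacement, with a warning), runs one forward pass,
assembles the losses, and applies one SGD step with learning rate
0.001, momentum 0.9 and weight decay 0.0005 — the standard protocol for
this method family; no learning-rate schedule is used because none is
specified for it.  Training runs a fixed K iterations; an optional
stopping rule halts when the relative change between consecutive
50-iteration moving averages of L_total falls below a tolerance
(disabled by default — a concrete rule is provided because "until
convergence" is otherwise untestable).  All heads share the extractor
and are trained jointly on L_total.

Divergence (a non-finite loss) raises a dedicated error with the
iteration index.  With a fixed seed and config the whole pipeline is
bitwise deterministic on one platform: data generation, batch sampling
and parameter init all derive from `numpy` generators seeded from the
config.

## Inference

Target predictions ensemble the per-domain classifiers.  In the default
"sample" mode each sample is routed individually:

    w_hat_i(x) ∝ w_i * r_i(x),       score(x) = sum_i w_hat_i(x) C_i(M(x)),

where r_i(x) is the class-aware head's probability mass on domain i's
block of joint labels for that sample.  The per-sample form matters
under class shift: a global mixture concentrated on the most
target-like source systematically misclassifies every other source's
private classes, because no single set of mixture weights can serve
samples whose true class only one (down-weighted) classifier knows.
Routing by the head's per-sample attribution removes that failure mode
while reducing to the global blend when the head is uninformative.
Global modes remain available by config: "product" (w ⊙ w^c,
renormalised, with w^c the batch-averaged relevance vector), "weights"
(w alone — also the automatic fallback when the class-aware head is
disabled) and "relevance" (w^c alone).  Ties in the argmax resolve to
the lowest class index.

## Networks

The backbone contract is minimal — any callable with `parameters()` and
a declared `output_dim` — so an externally trained feature extractor
can be plugged in.  Two desk-scale defaults are bundled:

* a two-layer perceptron (hidden width 128, ReLU, 32 output features)
  for feature-vector inputs;
* a three-layer strided convolutional net with global average pooling
  for grayscale images of side ≥ 32 (image-folder inputs are resized to
  128 x 128; training applies random crop after 4-pixel reflect padding
  and horizontal flips with p = 0.5).

The extractor's output layer is initialised at a tenth of the He scale.
This matters: with full-scale init the randomly initialised features
have large, badly mismatched moments, L_awmd dominates the first SGD
steps, and momentum can drive the features into total collapse (all
zeros — a global minimum of the alignment terms alone).  Starting small
lets discriminative structure and alignment grow together.

Gradients come from a small reverse-mode tape over numpy arrays
(`camsda.autodiff`) implementing exactly the primitives the losses
need; its correctness is pinned by central finite-difference tests at
1e-4 (the moment losses) and 1e-5 (network primitives, convolution
included).  The Euclidean-norm primitive uses subgradient 0 at the
origin, so identical moment pairs contribute zero gradient rather than
NaN.

## Synthetic benchmark

Real multi-site imaging corpora are too large to ship, so
`camsda.synthetic` generates the class-shift structure directly.
Feature mode: class c has a global prototype vector; domain i draws
class-c samples from Normal(scale_i·prototype_c + t_i, noise_sd²·I);
the target uses unshifted prototypes.  Image mode: classes are
grayscale shapes (disc, full-width bar, ring, cross, square, stripes,
blob) and the domain shift is a brightness offset, a contrast scale and
a faint per-domain background texture — a cartoon of scanner and
protocol differences; identity-shift domains render exactly like the
target.

The standard fixture has 3 sources and 7 classes — 4 shared plus one
private class per source — with 200 samples per class in 16 feature
dimensions, prototype scale 3.0, within-class noise 0.5, and domain
shifts of Euclidean norm 4 for sources 1 and 2 (source 2 additionally
rescaled by 1.2) while source 0 matches the target exactly; the seed is
fixed.  The regime is deliberately well-separated (inter-class
distances ≈ 34 noise-sd, shifts ≈ 8 noise-sd): classes are
identifiable, the shift is strong but recoverable, and the matched
source is the nearest to the target in raw moment distance.  Target
ground-truth labels live only in the generator's metadata, preserving
the unsupervised protocol while allowing accuracy scoring.

What passing on this fixture shows: the joint relabeling, weighting and
alignment machinery interact as designed, the matched source is
recognised, and removing either strategy does not improve the median
result.  What it does not show: performance on real images, where the
shift is not affine in any observed space, class boundaries are
ambiguous, and labels are noisy.  With shifts much larger than the
inter-class distances the private target classes become near
unidentifiable — no labeled anchor exists at their location, and a
*shared* extractor cannot undo per-domain shifts it cannot attribute —
so adaptation accuracy degrades gracefully toward the shared-class
ceiling; this is a property of the problem, not of the implementation.

## Evaluation conventions

Per-class accuracy is within-class recall in percent (the definition
behind per-disease accuracy columns; classes absent from the truth
vector yield a flagged NaN).  Row summaries use the arithmetic mean and
the sample standard deviation (n-1 denominator — the convention that
exactly reproduces the published 4.08 and 11.95).  Method deltas quoted
against a reference are differences of the two-decimal printed
averages, matching the published convention (93.50 − 77.64 = 15.86 even
though the full-precision difference rounds to 15.85); `summarize`
keeps full precision and `printed_delta` applies the printed-table
rounding.  Paired comparisons use the two-sided paired Student t-test
(scipy) with df = n − 1; zero-variance difference vectors raise a
degenerate-test error instead of returning an infinite statistic.  The
published t statistics for the benchmark tables are *not* asserted
anywhere: they cannot be reproduced from the printed per-class rows
(they were presumably computed over unpublished repeated runs), so the
t-test implementation is validated against closed-form arithmetic
instead.  Rendered tables round half-up to two decimals and bold one
maximum per column (first index on ties).

## Known limitations

* Single-label multi-class classification only; a per-class sigmoid
  (multi-label) head is out of scope.
* No open-set handling: target labels are assumed inside the union of
  source label spaces.
* The desk-scale backbones are not a substitute for a pretrained deep
  feature extractor on real imaging data; the backbone contract exists
  precisely so one can be supplied.
* Moment matching uses orders 1 and 2 only; kernel discrepancies and
  adversarial alignment are non-goals.
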