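# Methods

## Model

The predictor is a fuzzy inference network whose aggregation operations are
deformed along a tropical (Maslov) interpolation. Every feature `x_i`
(min–max normalized to [0,1] with statistics of the training fold) is
encoded into D ordered linguistic concepts — low / medium / high for the
default D = 3 — by smoothed trapezoid/triangle membership functions built
from logistic flanks:

    low(x)  = s((b1 - x)/(tau*eps)) / s(b1/(tau*eps))
    med(x)  = s((x - b1)/(tau*eps)) * s((b2 - x)/(tau*eps)) / peak
    high(x) = s((x - b2)/(tau*eps)) / s((1 - b2)/(tau*eps))

with `s` the logistic function, `tau = 0.1`, and trainable breakpoints
`0 < b1 < b2 < 1`. Each concept is normalized by its own peak so it attains
1 somewhere in [0,1] (no degenerate concepts for any `eps`). Breakpoints
are kept ordered by parametrizing D softplus gaps and normalizing their
cumulative sum; they are initialized at the empirical training quantiles.

Aggregations are parametrized families with endpoints required by the
tropical construction:

* conjunction (t-norm): `T(v; w, eps) = exp(-(sum_i w_i (-ln v_i)^(1/eps))^eps)`
  — the weighted geometric product at `eps = 1`, the minimum over active
  inputs as `eps -> 0`. A zero weight removes its input exactly (identity
  element 1); an all-zero weight set returns the empty-conjunction
  identity 1.
* disjunction (conorm): `C(v; w, eps) = (sum_i (w_i v_i)^(1/eps))^eps`
  — weighted sum at `eps = 1`, weighted maximum in the tropical limit.

The forward pass is: (1) membership encoding; (2) per feature and rule,
conorm-union of the D concept degrees weighted by the attention tensor
`A (H, D, K)`, clamped at 1 (the power sum can exceed 1 at `eps = 1`;
`min(.,1)` with a pass-through sub-gradient below the clamp). The union
semantics lets a rule express "not low" as medium-or-high. (3) t-norm
conjunction over features weighted by the connection matrix `M (H, K)`
gives rule activations `r_1..r_K`; a feature with `M = 0` contributes the
identity and simply does not appear in the rule. (4) conorm over rules
weighted by the non-negative inference weights `W (K, C)` gives class
scores `o_c`.

Constraints: `A` and `M` are `|tanh|` of raw weights (range [0,1)); `W` is
a softplus; `eps = eps_min + (1 - eps_min) * sigmoid(raw)` with
`eps_min = 1e-3`, one raw value per aggregation site (encoding + concept
union, rule conjunction, class disjunction). Whether the original design
shares one `eps` across layers is not determinable from its description;
per-site smoothness is the more general choice and is what we train.

Class probabilities are the scores normalized to unit sum,
`p_c = (o_c + 1e-12) / sum_c' (o_c' + 1e-12)` (equivalently a softmax on
`log o`). This bridge keeps `W` on an interpretable scale; the alternative
softmax-on-`o` would exponentiate an already multiplicative quantity.

## Loss and training

`total = CE + lambda1 * sparse + lambda2 * corr (+ lambda_eps * sum(eps))`

* CE: mean cross-entropy of the bridged probabilities.
* sparse: `||vec(A)||_i + ||vec(M)||_i` for i = 1 or 0. The l0 count is
  non-differentiable, so the training loss uses the surrogate
  `sum(1 - exp(-w/gamma))`, `gamma = 0.01`, which converges to the exact
  count as `gamma -> 0`; exact counts are used only for reporting.
* corr: redundancy penalty `sum_{k<k'} <vec(S_k), vec(S_k')>` over rule
  pairs of the contribution tensor `S = A (.) M`. (The summation runs over
  rules — the slices being compared are rule slices.)
* Optional `lambda_eps * (eps_enc + eps_rule + eps_inf)` anneals the model
  toward the piecewise-linear regime; default 0 (the smoothness is learned
  freely).

All raw parameters — weights, breakpoint gaps, and the three smoothness
raws — are trained jointly with Adam via reverse-mode automatic
differentiation (a small tape-based engine over numpy arrays ships in
`tfnn.autodiff`; its gradients are validated against central finite
differences to < 1e-4 relative error). Defaults: learning rate 1e-2,
500 epochs, full batch up to n = 4000, `lambda2 = 1e-3`, `lambda1 = 0`
unless sparsity is requested (then 1e-3). Runs are deterministic given the
seed. The t-norm and conorm are evaluated in the log domain with a
detached max shift, so the `1/eps` powers never overflow even at
`eps = 1e-3`; memberships and t-norm inputs are floored at 1e-12 before
logarithms.

## Rule extraction

`S_{i,d,k} = A_{i,d,k} M_{i,k}` measures the contribution of concept d of
feature i to rule k; `W_{k,c}` measures the importance of rule k for class
c. For a target class, rules are ordered by importance; concepts with
`S < theta_concept * max(S_k)` are dropped (default `theta_concept = 0.2`,
relative to each rule's strongest concept); among rule pairs with cosine
similarity of flattened slices above `theta_corr = 0.9` only the more
important rule is kept. Surviving medium+high pairs on one feature merge
into "not low" (dually low+medium into "not high"). Numeric thresholds are
the 0.5-crossings of the learned memberships, solved by bisection to 1e-6
and mapped back to original units; shoulders give one cut ("<t" / ">t"),
medium an interval. Coverage counting is crisp: a row satisfies a rule iff
every retained concept's threshold condition holds with strict
inequalities — the same audit style used when checking extracted rules
against a cohort. The pruning thresholds are package defaults; the
original study prunes but does not publish its cutoffs.

Recovery of a planted rule is judged on (feature, crisp-region) pairs:
"high" and "not low" both denote a one-sided region above a learned cut
and are counted as the same concept (dually "low" / "not high"). A model
that learns the exact planted cut but labels the region via the union
concept is a correct recovery.

## Synthetic benchmark cohort

The generator emulates an admission-time clinical table: mixed-scale
non-negative marginals (uniform "age" on 18–90, an 11-level ordinal score,
a Beta(2,2) lab value on 5–18, a continuous 0–4 severity scale, plus four
distractors of similar families), a binary outcome equal to the
disjunction of planted crisp conjunctions on the normalized scale, and
symmetric label-flip noise. Defaults: n = 2000, H = 8, two two-concept
rules over features 0–3 (age high & motor score low; lab value high &
severity high), flip rate rho = 0.1, seed 20220801. The planted
thresholds put the positive prevalence near 0.5, which both mirrors a
roughly balanced clinical cohort and maximizes the noise-limited AUC
ceiling: with symmetric flips no scorer can exceed
`a(1-b) + (ab + (1-a)(1-b))/2` where `a = P(rule | y=1)`,
`b = P(rule | y=0)` — about 0.90 at rho = 0.1. Cross-validated AUC of the
trained network should therefore be read against that ceiling, not
against 1.

What the generator does not emulate: correlated features, missingness,
class-dependent noise, and the long-tailed count distributions of real
radiology variables. Passing the recovery benchmark shows the pipeline
can find planted crisp structure under label noise; it does not certify
performance on real clinical data.

## Numerical and design choices

* The exact functional families are a design choice (the tropical
  construction fixes only the endpoints): Aczel–Alsina-type weighted
  t-norm and Maslov power-sum conorm, selected because their `eps`
  endpoints are exactly product/min and sum/max. They sit behind plain
  functions (`fuzzy_core.tnorm/conorm`) so another family can be swapped.
* The family is discontinuous in a weight at 0 for small `eps`
  (`w^eps -> 1`), so gating is crisp: exactly-zero weights are removed
  from the reduction before the power transform.
* Ties in hyperparameter selection break toward smaller K (parsimony);
  ties in concept ordering break by feature index.
* Degenerate inputs: constant features normalize to 0 and fall to the
  lowest concept; rules referencing them are harmless. Test rows outside
  the training range are clamped into [0,1] (logged).
* Cross-validation is stratified with per-fold normalization; inner K
  selection (grid e.g. {5, 10, 15}) uses a stratified 80/20 split of the
  training fold only.
* Regularization-path demonstrations (simpler rules under l0 sparsity,
  decorrelated rules under the redundancy penalty) apply each penalty at
  10x its enabled default: at 1e-3 the pull on the scale-invariant cosine
  statistic is within seed-to-seed noise, while 1e-2 shows the mechanism
  cleanly without degrading discrimination.
* Problem sizes used by the shipped benchmark runs (10 rules, 500 epochs,
  n = 2000) are chosen so a full 10-fold evaluation completes in a few
  minutes on one core while sitting well past the convergence knee of the
  training loss.

## Known limitations

* The l0 surrogate's gamma trades bias against gradient signal; very
  small gamma makes the penalty step-like and stalls shrinkage.
* With strongly overlapping planted rules the correlation penalty can
  merge them into one broader rule; the redundancy/coverage trade-off is
  data-dependent.
* AUC near the noise ceiling has fold-level variance of roughly ±0.02 at
  n = 2000; single-fold comparisons against the ceiling are noisy.
* The membership family is monotone-flank; multimodal concepts (e.g.
  "abnormal at either extreme") require D > 3 rather than a single
  concept.
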