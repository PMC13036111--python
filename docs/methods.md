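# Methods

## The model

`symptomnet` analyses binary symptom data with a pairwise Markov random
field (an Ising model in its {0,1} parameterization). For p symptoms, a
state x ∈ {0,1}^p has probability

    P(x) ∝ exp( Σᵢ τᵢ xᵢ + Σ_{i<j} ω_{ij} xᵢ xⱼ )

where τᵢ is symptom i's autonomous activation tendency (log-odds scale)
and ω_{ij} is the conditional association between symptoms i and j given
all others. The {0,1} state convention is deliberate and matters: under
the {−1,+1} physics convention the same distribution has different
parameter values, so thresholds and weights are not transferable between
the two. We use {0,1} because it matches the presence/absence coding of
questionnaire items and makes the full conditional of each symptom a
plain logistic regression, P(xⱼ=1 | rest) = logistic(τⱼ + Σ_k ω_{jk}x_k).

Edges of this model are sometimes loosely described as "partial
correlations" in the applied literature. They are conditional log-odds
weights; this package reports them on that scale and does not rescale.

## Data coding

Likert responses 1–5 are dichotomized: the scale minimum (1, "almost
never") codes to 0 = symptom absent, anything above codes to 1 =
present. Rows with any missing cell are removed listwise at load time
and counted; there is no imputation. Scale bounds are configurable but
out-of-range values are always an error, never clamped — a 6 in a 1–5
file indicates corruption, not severity.

## Estimation

The network is estimated by nodewise penalized pseudo-likelihood
("eLasso"): each symptom is regressed on all the others with an L1
penalty along a descending path of 100 log-spaced penalty values from
λ_max (the smallest penalty yielding the empty model) down to
10⁻³·λ_max. Predictors are standardized internally before the penalty
is applied, so items with different endorsement rates face comparable
penalties (the glmnet convention); returned coefficients are on the
original 0/1 scale. Per node, the penalty is chosen by the extended BIC

    EBIC(λ) = −2ℓ + k·log n + 2γ·k·log(p−1),  γ = 0.25 by default,

with k the number of nonzero neighborhood coefficients and ℓ the
logistic log-likelihood at the penalized fit; ties go to the sparser
model. Directed coefficients are symmetrized by averaging, with an AND
rule by default (an edge survives only if both regressions retain it;
OR available). Thresholds are the selected penalized intercepts, without
debiasing, matching common practice. Intercepts are unpenalized (a large
`intercept_scaling` makes their penalty contribution ≤ |τ|/1000, which
is negligible at these magnitudes).

Numerical notes: the liblinear coordinate-descent solver is run at
tolerance 10⁻⁶ with a fixed internal seed, so estimates are
reproducible; permutation equivariance of items holds to roughly the
solver tolerance (~10⁻⁴ on coefficients), not to machine precision.
Constant (all-0 or all-1) items abort estimation with an error naming
them rather than being dropped silently, so output tables always align
with input items.

Because the L1 penalty shrinks retained coefficients, estimated weights
are biased toward zero. With n ≈ 2000 respondents and moderately strong
true weights, the correlation between true and estimated weights over
the union of supports plateaus around 0.75–0.85 — a bound set by the
information in the data, not by the optimizer: an oracle handed the true
edge set and fitting unpenalized maximum likelihood does no better than
≈ 0.83 under the same conditions. Edge *detection* (which pairs are
connected, with which sign) is much better behaved, and rank-based
conclusions (which symptom is the strongest bridge) are robust to the
shared shrinkage.

## Bridge centrality

Against the fixed two-community partition (communities come from the
instruments, never from community detection):

* **expected influence** EI(i) = Σⱼ ω_{ij} (one-step, signed);
* **bridge strength** Σ_{j∉comm(i)} |ω_{ij}|;
* **bridge expected influence** Σ_{j∉comm(i)} ω_{ij};
* **bridge betweenness**: the number of shortest paths between
  cross-community node pairs passing through i, with edge length
  1/|ω| (the standard distance convention in network psychometrics);
  each unordered pair contributes 1, split equally among tied shortest
  paths;
* **bridge closeness**: inverse mean shortest-path distance from i to
  all nodes outside its community; unreachable nodes give infinite mean
  distance and hence closeness 0, so an isolated node scores 0 on all
  indices.

Raw and z-standardized (n−1 denominator) columns are reported. The
implementation (networkx Dijkstra / path enumeration) is verified in the
test suite against an independent brute-force oracle built on scipy's
shortest-path matrix with an explicit path-count dynamic program.

## Stability

Case-dropping bootstrap: for each drop proportion q, persons are
subsampled without replacement to ⌈(1−q)n⌉, the network is re-estimated
*from scratch*, the index recomputed, and its Spearman correlation with
the full-sample index recorded. Replicates with undefined correlations
(constant index) or failed estimation are counted and excluded. The CS
coefficient is the largest q such that at every tested proportion ≤ q at
least 95% of successful replicates correlate ≥ 0.7 with the full-sample
index; a non-monotone profile stops at the first failing proportion.
Defaults (grid 0.05–0.75 by 0.05, B = 500) follow the field convention;
the analysis driver uses a reduced desk-scale configuration (4
proportions, B = 12, shorter penalty path) because full re-estimation
per replicate is the expensive-but-correct choice. With B = 12 the 95%
rule means "all replicates", so desk-scale CS values are conservative.

## Intervention simulation

The intervention screen perturbs one symptom's threshold by
± m·SD(τ̂), with m = 2 by default and SD the sample standard deviation
(n−1) of the estimated threshold vector across nodes — the scale on
which thresholds vary in that network. Decreasing the threshold
simulates alleviation of the symptom, increasing it aggravation. For
each scenario, 5000 observations are drawn from the perturbed network
(exact inversion sampling from the enumerated distribution for p ≤ 20;
single-site Gibbs with ascending scan, 1000 burn-in sweeps, beyond) and
summarized by a sum score — the count of active symptoms in a
configurable outcome set. Scenarios are compared to one shared baseline
simulation by Welch two-sided t-tests; Benjamini–Hochberg FDR correction
is applied across candidate targets within each direction; targets are
ranked by |mean sum-score difference|. The reported 95% CI is the Welch
interval of the mean difference; baseline and perturbed means are also
reported.

Two outcome definitions are supported and both appear in the analysis
drivers: the whole-network sum score (the method's native
overall-severity measure) and a community subset (e.g. the PSVU sum, to
ask which MW symptom most moves the other community). The subset
variant measures only the *propagated* part of an intervention, which
after shrinkage of bridge weights is small (≈ −0.05 to −0.1 on a
13-item sum under the default synthetic conditions) and sits near the
detection limit of 5000 draws; the whole-network variant includes the
target's own activation change and separates targets decisively. The
validation experiments therefore use the whole-network outcome, and
results on subset outcomes should be read with their wide relative
noise in mind.

Every simulation seed is derived from one master seed through a
SeedSequence counter scheme (spawn key = scenario index), so scenarios
are mutually independent but the whole run reproduces bit-for-bit.

These are computational predictions about network structure: they rank
targets by projected leverage and say nothing about the efficacy of any
concrete clinical technique.

## The synthetic ground truth

Because the motivating study's raw data are available on request only,
validation rests on a generator with known truth emulating its
structure: 18 items in two communities (5 "MW", 13 "PSVU");
within-community edges drawn independently with probability 0.35 and
weights Uniform(0.3, 0.9), all positive; exactly three cross-community
bridge edges, MW5–PSVU8 at 0.8 (dominant), MW5–PSVU3 at 0.4, MW1–PSVU5
at 0.35; thresholds Uniform(−2, 0). The density and threshold band
place endorsement rates in the 0.5–0.9 range typical of such
questionnaire items. The default sample size, 1989, mirrors a realistic
effective sample for a large survey of this kind. An all-positive
("attractive") truth also makes exact intervention monotonicity
provable by enumeration, which the tests exploit.

The generator's Likert expansion maps 0 → 1 and 1 → a draw from
{2,3,4,5} (uniform by default); the binarization rule inverts it
exactly, which lets the whole load→binarize path be tested end to end.
What the generator does *not* emulate: ordinal severity structure
(expansion categories are noise, since the pipeline discards them),
item wording effects, response styles, and any marginal matching to the
source study's item means. Passing tests therefore demonstrate
correctness of the machinery and recoverability under plausible
conditions — not that any particular empirical dataset would yield the
same substantive conclusions.

## Degenerate inputs and tie-breaks (summary)

* empty network (p = 0): refused everywhere.
* p = 1: distribution and sampling fine; perturbation refused (SD of a
  single threshold is undefined).
* zero-variance sum scores in both arms of a comparison: t undefined by
  policy, reported as NaN with p = 1.
* EBIC ties: sparser (larger λ) model.
* equal-length shortest paths: fractional betweenness credit.
* correlation of a constant index: failed bootstrap replicate, counted
  and excluded.

## Problem sizes used in validation

The test suite and the reproduction script run 20 simulated studies of
n = 2000 respondents for recovery and target-recovery experiments, 10
random 6-node networks at 50,000 Gibbs draws for sampler fidelity, 50
random networks (p ≤ 10) for the centrality oracle, and enumerated
networks up to p = 12 for exactness and monotonicity checks — sizes at
which every claim is either exact or has narrow Monte-Carlo error.
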