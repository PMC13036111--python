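# symptomnet

Ising symptom-network analysis for questionnaire data: estimate a
network of conditionally dependent binary symptoms, find the *bridge
symptoms* that connect two symptom communities, and rank intervention
targets by simulating threshold perturbations on the fitted network.

The package is built around the study design in which two instruments —
five mind-wandering items (MW) and thirteen problematic-short-video-use
items (PSVU) — are administered to ~2000 respondents, responses are
dichotomized (1 → absent, 2–5 → present), and the question is which MW
symptom is the most effective leverage point for reducing overall
severity. Because such raw questionnaire data are typically not
deposited, the package ships a synthetic-data module that generates the
same structure from a *known* ground-truth network, so every stage of
the pipeline is validated against planted truth.

## The model and the pipeline

Binary symptoms x ∈ {0,1}^p follow an Ising distribution
P(x) ∝ exp(Σᵢ τᵢxᵢ + Σ_{i<j} ω_{ij}xᵢxⱼ), with per-symptom thresholds τ
(activation tendency, log-odds) and symmetric pairwise weights ω
(conditional associations).

1. **Estimation** (`estimate_network`): nodewise L1 logistic regression
   (each symptom on all others), EBIC model selection (γ = 0.25),
   AND-rule symmetrization — the standard eLasso recipe.
2. **Bridge centrality** (`bridge_indices`): expected influence plus
   bridge strength / bridge expected influence / bridge betweenness /
   bridge closeness against the fixed MW/PSVU partition, with
   case-dropping bootstrap stability and the CS coefficient.
3. **Intervention simulation** (`run_nira`): shift one symptom's
   threshold by ±2 SD of the threshold vector (alleviating /
   aggravating), draw 5000 observations from the perturbed network
   (exact sampling up to p = 20, Gibbs beyond), and compare sum scores
   to baseline with Welch t-tests, BH-FDR correction, and ranking by
   absolute mean difference.
4. **Synthetic truth** (`make_ground_truth`, `generate_dataset`,
   `expand_to_likert`): 18 items, two communities, three planted bridge
   edges with MW5–PSVU8 dominant, and a Likert expansion the
   binarization rule inverts exactly.

See `docs/methods.md` for assumptions, conventions, tie-breaks, and
known limitations.

## Worked example

The `analysis/` drivers run the whole study on synthetic data:

```bash
python analysis/01_simulate_data.py       # plant truth, simulate 1989 respondents
python analysis/02_estimate_network.py    # binarize + eLasso estimation
python analysis/03_bridge_centrality.py   # bridge indices + stability
python analysis/04_intervention_simulation.py
```

Output from a run with the default seeds:

```
Planted network: 18 items, 32 edges, bridges ['MW5-PSVU8 (0.8)', 'MW5-PSVU3 (0.4)', 'MW1-PSVU5 (0.35)']
Simulated 1989 respondents -> scratch/likert_data.csv
Read 1989 rows, dropped 0 incomplete
Estimated network: 28 edges (28 with |weight| > 0.1 displayed)
Recovery vs planted truth: sensitivity 0.844, specificity 0.992, weight r 0.719, threshold r 0.935
Top bridge symptoms by bridge expected influence:
PSVU8    0.656
MW5      0.656
CS coefficient (bridge_expected_influence): 0.25
CS coefficient (bridge_strength): 0.25
Strongest bridge symptom: MW5

Outcome = full sum score:
  top alleviating target: MW5 (mean diff -0.399, t = -9.02, FDR p = 1.1e-18)
  top aggravating target: MW4 (mean diff +0.358, t = 8.07, FDR p = 1.9e-15)
```

Reading this: estimation recovered 84% of planted edges with almost no
false positives (weights shrink toward zero under the L1 penalty, hence
the lower weight correlation — see the methods note). The two endpoints
of the dominant planted bridge, MW5 and PSVU8, come out as the top
bridge symptoms, and the intervention screen identifies alleviating MW5
as the most effective simulated intervention: its projected effect is a
0.4-symptom drop in the 18-item sum score, FDR-significant at 5000
simulated observations. Note the alleviation/aggravation asymmetry —
the best symptom to treat need not be the riskiest to worsen. Tables
land in `results/` (centrality, stability, intervention screens under
both outcome definitions).

Library use in four lines:

```python
import symptomnet as sn
net   = sn.estimate_network(binary_data)          # BinaryDataset -> IsingNetwork
bridges = sn.bridge_indices(net)                  # per-item bridge centrality
screen  = sn.run_nira(net, candidates, outcome_items, master_seed=7)
```

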