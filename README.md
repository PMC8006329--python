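# venomnet

Prognostic Bayesian-network modeling of functional recovery from Crotalinae
(pit viper) snakebite envenoming.

Snakebite recovery is highly variable and hard to predict from clinical
features alone. `venomnet` implements a pipeline that links clinical
variables (age, sex, comorbidities, antihistamine use, white blood cell
count, respiratory rate, CO2) and a 35-analyte serum cytokine/chemokine
panel (Luminex 35-plex, sampled pre- and post-antivenom) to a
patient-reported functional outcome, for biostatisticians and clinical
researchers studying envenoming cohorts.

The method, end to end:

1. **Outcome.** Each patient's Patient-Specific Functional Scale (PSFS,
   0–10) trajectory over days 0–28 is summarized by the area under the
   patient curve, AUPC = ∫ PSFS(t) dt / 280 ∈ [0, 1]; the cohort is split
   at the median AUPC into *good* (≥ median) and *poor* recovery.
2. **Preprocessing.** Analytes are natural-log transformed; variables
   missing in > 20% of records are dropped; continuous variables are cut
   at training-fold tertiles (no leakage; missing values are never imputed).
3. **Network learning.** A discrete Bayesian belief network is learned by
   greedy hill climbing under a two-part Minimum Description Length score
   with a sparsity gate λ = 0.01; nodes are features plus the recovery
   label, arcs carry Laplace-smoothed conditional probability tables and
   encode associations, not causes.
4. **Selection.** Networks are learned on the full cohort and per
   leave-one-out fold; variables adjacent to the recovery node
   (first-degree associates) in any model are selected and a final network
   is refitted on them.
5. **Evaluation.** Leave-one-out cross-validation scores every patient by
   P(good recovery | their evidence) from a model trained without them;
   scores feed a tie-corrected ROC/AUC, with AUC ≥ 0.6 reported as a good
   differentiator.

Because no patient-level envenoming dataset is public, the package ships a
seeded synthetic cohort generator (`venomnet.simulate`) with a planted
severity→analyte/outcome dependency structure, so the entire pipeline is
testable and demonstrable offline. See `docs/methods.md` for the model,
all conventions, and what the synthetic cohorts do and do not emulate.

## Worked example

```python
from venomnet import (
    CohortConfig, generate_cohort, RecoveryNetworkModel, PipelineConfig,
)

cohort, truth = generate_cohort(
    CohortConfig(n_patients=24, seed=1, severity_effect=2.0)
)
res = RecoveryNetworkModel(
    cohort, "post_antivenom", config=PipelineConfig(selection="full_only")
).fit()
res.cross_validate()
print(res.summary())
```

```
               Prognostic recovery network
==========================================================
Timepoint:            post_antivenom
Patients:             24 (12 good / 12 poor)
PSFS AUPC:            median 0.700, range (0.360, 0.914)
Dropped (missing):    IL3
Selected associates:  CCL4, CXCL10, HGF, IL10, IL12, IL17F, IL5, IL8, VEGF, co2, resp_rate, wbc
Network:              13 nodes, 11 arcs, outcome degree 5
LOO-CV AUC:           0.812 (good differentiator; nested selection)
==========================================================
```

Reading this: of 24 synthetic patients, half recovered well (AUPC at or
above the cohort median of 0.70). IL-3 was dropped for excess missingness.
Across the full-cohort and leave-one-out networks, twelve variables —
severity-coupled analytes such as HGF, CXCL10, CCL4 and VEGF among them —
were adjacent to the recovery node at least once and entered the final
13-node network, in which five variables touch recovery directly. Held-out
patients were ranked by their posterior probability of good recovery with
AUC 0.81, above the 0.6 bar for a useful discriminator.

`res.plot_roc()` and `res.plot_network()` draw the ROC curve and the
network; `res.contrasts()` returns per-analyte good-vs-poor log summaries.

The same pipeline is scriptable from a shell:

```sh
venomnet simulate --n 24 --seed 1 --severity-effect 2.0 --out cohort/
venomnet run --cohort cohort/ --timepoint post --out run/
venomnet report --run run/ --out report.md
```

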