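# dsskit

Quantitative drug sensitivity scoring for multi-dose viability screens.

High-throughput drug testing — ex vivo screens of patient-derived cancer
cells or cell-line panels against hundreds of compounds at a handful of
doses — produces sample x drug x dose response matrices that have to be
collapsed into one number per sample-drug pair before any cohort-level
question ("which drugs hit this patient's cells selectively?", "which
patients form a responsive sub-group?") can be asked. Single-parameter
summaries such as the IC50 discard most of the dose-response shape and are
unstable on sparsely sampled ranges. `dsskit` implements the model-based
alternative: fit a four-parameter logistic (4PL) curve per pair and
integrate it, in closed form, above an activity threshold.

## The score

With inhibition modeled as `R(x) = R_min + (R_max - R_min)/(1 + 10^(s(m-x)))`
over log10 concentration `x`, the integral response above a minimum activity
level `A_min` on the tested window `[x_lo, x_hi]` is

    I = int_{x1}^{x_hi} (R(x) - A_min) dx,   x1 = R^{-1}(A_min),

evaluated analytically. Three normalizations put it on a 0-100 scale:

    DSS1 = 100 I / ((100 - A_min)(x_hi - x_lo))        # raw normalized area
    DSS2 = DSS1 * log10(max(R_max, 1)) / 2             # penalizes low efficacy
    DSS3 = DSS2 * (x2 - x1) / (x_hi - x_lo)            # penalizes narrow windows

The differential score dDSS = DSS(sample) - mean DSS(healthy controls)
isolates cancer-selective activity. On top of the scores the package
provides the discrete Activity Area and relative-IC50 comparators,
responder sub-group detection by one-sided D'Agostino skewness testing with
right-tail peeling, Wilcoxon/AUROC/DeLong evaluation utilities,
Ward/Spearman drug clustering with an adaptive branch cut and
pair-counting cluster indices plus a permutation test for index gains,
kinase addiction (KISS) profiles from drug-target matrices, and seeded
synthetic-screen generators with planted ground truth.

See `docs/methods.md` for the model, the algebraic choices and their
rationale, and known limitations.

## Worked example

```python
import numpy as np
from dsskit import (CohortSpec, PlantedSubgroup, simulate_cohort,
                    DrugSensitivityScorer, detect_responder_subgroup)

# a synthetic screen: 22 patients + 4 healthy controls, 5-point 10-fold
# dilutions, one drug carrying a planted 4-sample responder sub-group
responders = ("patient_03", "patient_08", "patient_15", "patient_21")
spec = CohortSpec(n_drugs=4, planted_subgroups=(
    PlantedSubgroup("drug_01", responders, effect=25.0),))
table, truth = simulate_cohort(spec, seed=11)

scorer = DrugSensitivityScorer(metric="DSS2", a_min=10.0, x_lo=0.0, x_hi=4.0,
                               control_sample_ids=truth["control_ids"])
ddss = scorer.fit_transform(table)          # samples x drugs dDSS matrix

found, skew = detect_responder_subgroup(ddss["drug_01"])
print(sorted(found))
print(f"gamma = {skew.gamma:.2f}, one-sided p = {skew.p_one_sided:.2e}")
```

Output:

```
['patient_03', 'patient_08', 'patient_15', 'patient_21']
gamma = 1.60, one-sided p = 6.02e-04
```

The detector returns exactly the four planted samples: their dDSS sits ~25
score units above the drug's background level, the drug's score
distribution is strongly right-skewed (gamma = 1.6), and peeling the four
maxima restores a non-significant skew. The same pipeline is scriptable from the shell:

```bash
dsskit simulate --seed 11 --out-dir sim
dsskit score --input sim/drt.csv --metric dss2 --window 0 4 \
       --controls control_01,control_02,control_03,control_04 --out-dir scored
dsskit subgroups --scores scored/ddss.csv --out subgroups.csv
dsskit run --config config.yaml        # full 7-stage pipeline + manifest
```

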