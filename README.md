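# crancoda

Factor-specific nutrient diagnosis and next-year yield prediction for
cranberry (*Vaccinium macrocarpon*) tissue tests, built on compositional
data analysis and random-forest classification.

Tissue nutrient concentrations are parts of a whole — ten nutrients plus
a filling value Fv = 1000 − Σ nutrients on the 1000 g kg⁻¹ dry-weight
simplex — so `crancoda` works in log-ratio coordinates throughout:
centred log-ratios (clr), isometric log-ratios (ilr) under a sequential
binary partition separating macro- from micronutrients, and the
Aitchison distance

    ε = ‖clr(X) − clr(X*)‖

between a defective specimen X and a successful reference X*. A random
forest classifies bed-years about a 40 t ha⁻¹ yield cutoff; the
out-of-fold confusion matrix keeps only *true negatives* (high-yielding
and predicted balanced) as diagnostic standards, discarding the false
positives that bias classical DRIS-style norms. Diagnosis compares the
specimen with its nearest successful neighbour (local scale, giving an
attainable yield) or with the bank average (regional scale), and the
perturbation vector p = X ⊖ x* = {N/N*, P/P*, …} ranks nutrients by
|ln ratio| as relative excess (>1) or shortage (<1). A lagged panel
links year *t* composition, fertilization and yield to year *t+1* yield
to capture carbohydrate/nutrient carryover.

The package is aimed at agronomists and researchers working with
perennial-crop tissue surveys; because such surveys are rarely public,
it ships a synthetic-survey generator with the same schema and
statistical structure, against which the whole pipeline is tested.

## Worked example

The worked diagnostic case from the published tables: a low-yielding
(26.7 t ha⁻¹) 'Stevens' bed in Quebec against its closest successful
neighbour (57.6 t ha⁻¹).

```python
from crancoda import (
    BankSpecimen, ReferenceBank, close_composition,
    aitchison_distance, perturbation, rank_nutrients,
)

defective  = close_composition([12.1, 1.1, 4.0, 1.5, 8.2,
                                0.030, 0.005, 0.030, 0.220, 0.090])
successful = close_composition([10.1, 1.0, 4.7, 1.9, 9.0,
                                0.029, 0.006, 0.018, 0.222, 0.097])

print(round(defective.filling_value, 1))                  # 972.7
print(round(aitchison_distance(defective, successful), 2)) # 0.66

ranking = rank_nutrients(perturbation(defective, successful))
print(ranking.excess)    # ['Zn', 'N', 'P', 'B']
print(ranking.shortage)  # ['Mg', 'Cu', 'K', 'Ca', 'Fe']
```

The filling value 972.7 g kg⁻¹ closes the ten nutrients to the
dry-weight unit; the distance 0.66 is the specimen's compositional gap
to the best comparable high-yielder; and the ranking reads as relative
Zn and N excess against Mg, Cu and K shortage — the nutrients to
correct, in order, to move the bed toward the 57.6 t ha⁻¹ attainable
yield (Mn, whose |ln ratio| is below the 0.01 balance tolerance, is
tagged balanced and appears in neither list).

The full survey workflow is available from the shell:

```sh
crancoda simulate --seed 0 --out survey.csv
crancoda train     --input survey.csv --cutoff 40 --folds 10 --seed 0 --out metrics.json
crancoda diagnose  --input survey.csv --specimen-row 1 --seed 0 --out report.json
crancoda carryover --input survey.csv --folds 5 --seed 0 --out carryover.json
```

## Layout

| module | contents |
| --- | --- |
| `crancoda.coda` | compositions, clr/ilr, SBPs, Aitchison distance, perturbation, ranking |
| `crancoda.simulate` | synthetic survey generator, planted defects |
| `crancoda.classify` | yield classifier, CV metrics, confusion quadrants, ablation |
| `crancoda.diagnose` | reference banks, local/regional diagnosis, quartile ranges |
| `crancoda.carryover` | lagged panel, next-year yield functions, predictive diagnosis |
| `crancoda.io` | CSV/SBP/JSON readers and writers, run configuration |
| `crancoda.cli` | `crancoda` command-line workflow |

See `docs/methods.md` for the model assumptions, generator design and
numerical conventions.
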