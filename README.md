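# wntcrd

Linear binding-energy models for Wnt interactions with Frizzled-type
cysteine-rich domains (CRDs), and the constrained model-search procedure
used to build them.

## The problem

Wnt ligands bind the CRD of Frizzled receptors (and of several other
CRD-bearing proteins) with affinities spanning low-nanomolar to
micromolar. Direct measurement is laborious, so binding affinity is
often estimated from modelled complex structures via a linear scoring
function over interface descriptors:

```
ΔG = β₀ + Σᵢ βᵢ · xᵢ        ΔG = RT ln K_d
```

where each `xᵢ` is either a **protein–protein** descriptor (a docking or
statistical-potential score of the protein interface) or a
**lipid–protein** descriptor (an MM-GB/SA energy component capturing the
Wnt palmitoleate–CRD interaction). Because Wnt lipidation is essential
for receptor binding, a physically sensible model should have a
*favourable* (ΔG-lowering) lipid term. This package implements:

- **thermo** — `ΔG = RT ln K_d` conversions (R = 1.987×10⁻³ kcal K⁻¹ mol⁻¹,
  T = 298 K) and the ordinal affinity ranges `++++` (<10 nM) … `−` (>400 nM);
- **models** — linear affinity models over named descriptors, including
  the four published Wnt–Fzd CRD models with their exact coefficients;
- **search** — exhaustive k-descriptor least-squares model search with
  the sign constraint that the lipid–protein contribution be favourable
  (non-positive) on every training complex, evaluated on a fixed
  training/test split (RMSE and within-experimental-error counts);
- **evaluate** — per-complex evaluation tables, RMSE, and the
  same/adjacent/farther affinity-range agreement statistic between two
  models;
- **synthetic** — a descriptor-matrix generator with a planted sparse
  linear model, for testing the pipeline end to end, plus the packaged
  table of 23 experimental mouse Wnt–Fzd CRD affinities with published
  model-1 predictions;
- **io / cli** — CSV/TSV/JSON artifacts and a thin `wntcrd` subcommand
  CLI (`predict`, `evaluate`, `search`, `compare`, `simulate`).

## Worked example

```python
from wntcrd import fixture_table2, evaluation_table, rmse

measurements, predictions = fixture_table2()   # the 23 measured complexes
rows = evaluation_table(predictions, measurements)
train = [r for r in rows if r.set_label == "training"]
test = [r for r in rows if r.set_label == "test"]
print(round(rmse([r.dg_pred for r in train], [r.dg_exp for r in train]), 2))
print(round(rmse([r.dg_pred for r in test], [r.dg_exp for r in test]), 2))
print([r.complex_id for r in rows if r.range_mismatch])
```

prints

```
0.33
0.36
['mWnt5–mFzd2', 'mWnt5–mFzd7', 'mWnt5b–mFzd4', 'mWnt5b–mFzd8']
```

— the training and test RMSE (kcal/mol) of the published model-1
predictions against the experimental binding energies, and the four
complexes whose experimental and predicted K_d fall in different
affinity ranges. The `examples/` directory holds one short script per
capability; `examples/search_synthetic_study.py`, for instance, plants a
4-descriptor model in a synthetic study and shows the constrained search
ranking it first.

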