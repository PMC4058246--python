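# phytoscreen

A ligand-based virtual-screening toolkit for natural-product libraries,
built around the computational chain used to hunt PPAR-γ agonists in
traditional-Chinese-medicine compound collections: topological descriptor
computation from 2-D structure, QSAR activity models, genetic-algorithm
descriptor selection, a drug-likeness → activity → dock-score screening
funnel, and post-analysis statistics for the molecular-dynamics follow-up.
It is aimed at cheminformaticians who want each stage as a tested,
composable Python function rather than a vendor GUI pipeline.

## The model at the core

Agonist potency is expressed as pEC50 = log₁₀(1/EC50). The frozen published
linear model relates it to six topological descriptors:

```
pEC50 = −5.987 + 1.987·ES_Sum_sssCH − 0.812·ES_Count_aaN + 8.608·BIC
        − 2.047·IAC_Mean + 0.812·CHI_3_P + 2.159·JY
```

* **ES_Sum_sssCH / ES_Count_aaN** — electrotopological-state aggregates.
  Each heavy atom i gets an intrinsic state Iᵢ = ((2/Lᵢ)²·δᵥᵢ + 1)/δᵢ (L the
  principal quantum number, δ the heavy-atom degree, δᵥ the valence
  connectivity) and an E-state Sᵢ = Iᵢ + Σⱼ (Iᵢ − Iⱼ)/(dᵢⱼ + 1)²; the
  descriptors sum S over `sssCH` methines and count `aaN` pyridine-type
  nitrogens.
* **CHI_3_P** — third-order path connectivity: Σ(δₐδᵦδ꜀δ𝒹)^(−1/2) over all
  3-bond simple paths.
* **JY** — Balaban distance-connectivity index J = q/(μ+1)·Σ(sᵢsⱼ)^(−1/2)
  on an (optionally Sanderson-electronegativity-weighted) distance matrix.
* **BIC / IAC_Mean** — information-content descriptors: Shannon entropy of
  atom equivalence classes normalized by graph size, and the entropy of the
  elemental composition including hydrogens.

Around the frozen equation the package fits its own models (OLS with
LOO-q², ε-SVR via libsvm, Bayesian linear regression), selects descriptor
subsets by a genetic algorithm scored on training R² or Friedman LOF, and
screens libraries through the rule-of-five filter, a min-over-models
activity gate, and dock-score ranking (dock scores are injected inputs —
docking engines are out of scope). The `trajstat` module covers the MD
post-analysis: Kabsch-superposed RMSD, radius of gyration, RMSF, H-bond
occupancy under a distance cutoff, GROMOS conformational clustering with a
medoid ("middle-RMSD") representative, torsion series and moving-average
smoothing.

## Worked example

```python
from phytoscreen import DS_EMULATION, descriptor_vector, eq1_predict, fixture_library

library = {g.name: g for g in fixture_library()}
for name in ("5-hydroxy-L-tryptophan", "abrine"):
    vec = descriptor_vector(library[name], DS_EMULATION)
    print(name, round(eq1_predict(vec), 2))
```

prints

```
5-hydroxy-L-tryptophan 5.78
abrine 6.41
```

— the predicted potencies of the two top screening candidates under the
calibrated vendor-emulation descriptor conventions (the original vendor
software's BIC/IAC/JY variants are undocumented; `docs/methods.md` explains
the convention knobs and the residual ≈0.1 log-unit deviation from the
published 5.89/6.31). A pEC50 of 5.78 corresponds to a predicted EC50 of
about 1.7 μM.

The `examples/` directory holds one short narrative script per capability
(descriptors + frozen model, model fitting, GA descriptor selection, the
screening funnel, trajectory analysis), and the `phytoscreen` CLI exposes
the same stages for shell use (`phytoscreen descriptors|fit|predict|gfa|
screen|traj|simulate --help`).

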