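# sarcoscreen

Analysis toolkit for multi-omic drug-discovery studies of osteosarcoma-style
tumors. It covers the computational stages such a study chains together:

* **High-throughput screen processing** — 384-well luminescence plates are
  normalized against DMSO control wells (relative viability = drug-well
  signal / mean control signal), and drugs are called hits when inhibition
  (1 − viability) strictly exceeds 60% in at least one cell line.
* **Dose–response modelling** — a statsmodels-style `DoseResponseModel` fits
  the four-parameter logistic v(d) = bottom + (top − bottom)/(1 + (d/IC50)^h)
  by bounded multi-start least squares; its `DoseResponseResults` carries the
  parameters, diagnostics and a `summary()`. Combination doses are chosen as
  the largest half-log grid dose keeping predicted inhibition below 50%.
* **Drug-synergy scoring** — Bliss Independence (expected combined inhibition
  Pt = Pa + Pb − Pa·Pb, index BI = Po/Pt, "obvious" synergy at BI > 1.3) and
  the Chou–Talalay combination index CI = DA/da + DB/db with log-linear
  interpolation to the IC50-equivalent combination dose.
* **Consensus hub genes** — ten node centralities (MCC, MNC, EPC,
  Betweenness, BottleNeck, Closeness, Degree, EcCentricity, Radiality,
  Stress) on a PPI network; each method's top 10% of nodes is intersected to
  give the hub set.
* **Target filter cascade** — CPM normalization, a Wilcoxon + BH differential
  test, tumor-specific gene calling (|FC| ≥ 2, adj. p < 0.05), pan-cancer
  exclusion, functional-class and drug-target annotation, the surface-target
  screen (|FC| ≥ 4, CPM ≥ 90), the single-cell percent-expressed filter
  (> 25% in ≥ 1 cell type) and pre/post-chemotherapy overlaps.
* **Alternative splicing** — event typing (ES, A3SS, A5SS, IR, MEE) from
  two-transcript comparisons, junction-normalized percent spliced in (PSI),
  the paired differential screen (|ΔPSI| > 10%, adj. p < 0.01) and the
  patient-heterogeneity screen (SD(PSI) > 0.15).
* **Synthetic data** — seeded generators for every input above (plates,
  combination screens, hub-planted networks, negative-binomial counts,
  binomial junction counts with GTF gene models), so every stage is testable
  end to end.

## Worked example

```python
import numpy as np
from sarcoscreen import simulate, screen, synergy

# a drug with true IC50 = 1 uM, measured at 8 doses in triplicate, 3% noise
truth = simulate.ScreenTruth("cediranib-like", ic50=1.0, hill=1.0)
series = simulate.gen_dose_response_series(
    truth, list(np.geomspace(0.01, 100, 8)), replicates=3, noise_cv=0.03, seed=1
)
fit = screen.DoseResponseModel.from_dataframe(series).fit()
print(fit.summary())

dose = screen.select_combination_dose(fit)      # sub-IC50 combination dose
pt = synergy.bliss_expected(0.4, 0.4)           # expected combined inhibition
bi = synergy.bliss_index(0.94, pt)
print(f"combination dose {dose:.3f} uM, Pt={pt:.2f}, BI={bi:.3f}",
      synergy.classify_interaction(bi))
```

prints (seed 1):

```
4PL dose-response fit
==================================
n observations                  24
converged                     True
top                         1.0084
bottom                      0.0001
ic50 (uM)                   0.9805
hill slope                  0.9996
residual SSE              0.003316
combination dose 0.316 uM, Pt=0.64, BI=1.469 ('synergistic', True)
```

The fit recovers the true IC50 (1 µM) to within 2% despite the noise; the
chosen combination dose (0.316 µM) is the largest half-log grid dose with
predicted inhibition below 50%; and an observed combined inhibition of 0.94
against the Bliss expectation 0.64 gives BI = 1.469 — above the 1.3 cutoff,
so the pair is flagged as obviously synergistic.

A console script mirrors the library:

```bash
sarcoscreen sim ppi --n-nodes 200 --n-hubs 8 --seed 7 --out ppi.tsv
sarcoscreen hubs --edges ppi.tsv --fraction 0.10 --seed 7
```

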