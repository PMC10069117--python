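# odc — optimized low-dose drug-combination discovery from phenotypic screens

`odc` implements a therapeutically guided multidrug-optimization workflow
for phenotypic viability screens, for researchers who need to find
selective, synergistic low-dose combinations from a panel of 7–11 drugs
without assaying the combinatorial space exhaustively.  It provides:

- **Screen designs** — a 50-condition orthogonal-array composite design for
  a seven-drug first round (a 32-run resolution-IV two-level fraction on
  coded levels {0, 2} stacked with the classical 18-run three-level
  orthogonal array on {0, 1, 2}; level 1 = IC20/2, level 2 = IC20), plus
  scaled-down composites for the 4–7 drug follow-up rounds.
- **The regression engine** — viability (% of untreated control) is fitted
  as a full second-order polynomial in orthogonally coded dose scores
  xᵢ ∈ {−1, 0, +1},

  V = β₀ + Σᵢ βᵢxᵢ + Σ_{i<j} βᵢⱼxᵢxⱼ + Σᵢ βᵢᵢxᵢ²,

  pruned by backward stepwise elimination under weak heredity.  Significant
  βᵢⱼ < 0 is a synergistic pair, βᵢⱼ > 0 antagonistic; drugs with a net
  antagonistic interaction burden (Benjamini–Hochberg-controlled) are
  eliminated between rounds.
- **Selectivity** — the therapeutic window TW = V(non-cancer) − V(cancer)
  in percentage points scores how much a combination spares the
  non-malignant model; the final round picks the four-drug candidate
  maximizing predicted TW (or minimizing predicted cancer viability when no
  non-cancer screen exists).
- **Adaptive-lasso ranking** — an independent penalized-regression route:
  ridge-pilot adaptive lasso over the same basis, prediction of all
  C(n,4)·2⁴ candidates (560 for 7 drugs, 5280 for 11), and a one-sided 95%
  computed confidence interval (CCI) that selects every candidate
  statistically undistinguishable from the best, summarized as a drug
  network (GraphML) and dose-level stacked bars.
- **Combination index** — Chou–Talalay CI = Σᵢ Dᵢ/Dxᵢ from median-effect
  monotherapy fits fa/(1−fa) = (D/Dm)^m; CI < 1 synergy, ≈ 1 additivity,
  > 1 antagonism.
- **A synthetic screen simulator** with planted synergies/antagonisms and a
  known optimal combination, so the whole pipeline is testable without
  laboratory data.

See `docs/methods.md` for the model details and assumptions.

## Worked example

Simulate a seven-drug two-model screen with two planted synergies and one
antagonism, then run the full three-round campaign:

```python
from odc import make_ground_truth, run_tgmo_simulated

truth = make_ground_truth(seed=11)           # planted optimum is recorded
print(truth.planted_odc.members)             # ('drug01', 'drug03', 'drug04', 'drug06')

report, best = run_tgmo_simulated(truth, seed=3)
print(best.members, best.levels)
# ('drug01', 'drug03', 'drug04', 'drug06') {'drug01': 2, 'drug03': 2, 'drug04': 2, 'drug06': 2}
print(round(best.pred_cancer_viability, 1),  # 33.8  -> predicted 66.2% inhibition
      round(best.pred_healthy_viability, 1), # 80.3  -> non-cancer model largely spared
      round(best.ptw, 1))                    # 46.5  -> therapeutic window, points
print(report["rounds"][0]["elimination"]["eliminated"])
# ['drug02', 'drug05']  -> the planted antagonistic pair fell in round 1
```

The campaign eliminated exactly the antagonistic pair after the first
50-condition screen, re-screened the five survivors, and the dose-optimizing
final round returned the planted optimal combination at full (IC20) doses:
predicted cancer viability 33.8% of control versus 80.3% in the non-cancer
model — a 46.5-point therapeutic window.  `report["odc"]["doses_uM"]`
decodes the selected levels to concentrations.

The same workflow runs from CSV/JSON files (`odc run --config cfg.json`), and
each stage is exposed on its own:

```bash
odc simulate --drugs 7 --synergies 2 --antagonisms 1 --noise-sd 5 --seed 11 --out-dir sim/
odc design   --panel sim/panel.json --search 1 --out design.csv --doses-out doses_uM.csv
odc fit      --design sim/design.csv --panel sim/panel.json --screen sim/screen_cancer.csv --out model.json
odc rank     --design sim/design.csv --panel sim/panel.json --screen sim/screen_cancer.csv \
             --healthy sim/screen_noncancer.csv --out ranking.csv --graph net.graphml --seed 7
odc ci       --fits fits.json --combo combo.json --fa 0.7 --out ci.json
```

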