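# odormix

Odor-intensity modelling and interaction analysis for binary odorant
mixtures.

## The problem

When two odorants are smelled together, the mixture's perceived intensity is
usually *not* the sum of the components' intensities: most binary mixtures
are antagonistic (the whole smells weaker than the parts), and the degree of
suppression depends on the composition.  Quantifying this matters for odor
pollution assessment, where regulated sources can meet per-compound emission
limits yet still smell strongly because of mixture effects — and where human
sensory panels, the reference measurement, are slow and expensive.

`odormix` implements a machine-learning route to this question for binary
mixtures of esters, aldehydes and aromatic hydrocarbons:

1. **Psychophysics.** For a single odorant, intensity on the 1-butanol odor
   intensity referencing scale (OIRS, levels 1–8) is linear in the log odor
   activity value, lnOAV = ln(C / C_thr):

       esters:     OI = 1.40 · lnOAV − 2.70
       aldehydes:  OI = 1.76 · lnOAV − 1.82
       aromatics:  OI = 1.07 · lnOAV

   A registry of nine odorants (three per family) carries the detection
   thresholds C_thr in mg/m³.

2. **Intensity model.** Per mixture pair, an RBF-kernel support vector
   regression maps the two component concentrations to the panel-measured
   mixture intensity OI_mix.  Protocol: 70/30 random split, hyperparameters
   C and γ grid-searched on a log₂ lattice under seeded 10-fold
   cross-validation (selection by mean CV MAE), accuracy reported as R² and
   MAE on both splits.

3. **Interaction analysis.** The additive expectation is
   OI_sum = OI_a + OI_b; the interaction degree is

       OI reduction       = OI_sum − OI_mix
       OI reduction ratio = (OI_sum − OI_mix) / OI_sum

   (positive ⇒ antagonism, negative ⇒ synergism).  The fitted model
   densifies composition space on a lnOAV grid, weak stimuli (OI < 2 OIRS)
   are excluded, and the results are rendered as a contour map over the
   lnOAV plane plus a scatter of reduction ratio against the mixing ratio
   x_a = lnOAV_a / (lnOAV_a + lnOAV_b).

4. **Synthetic panel.** Because real olfactometry panels are rarely
   deposited, a seeded generator emulates them: 20–35 samples per pair,
   intensities ≈ 2–7 OIRS, Gaussian panel noise (σ = 0.3 OIRS), and a
   ground-truth ratio-dependent antagonism ρ(x_a) = ρ_max · (4·x_a·(1−x_a))^p
   peaking at equal mixing — strong for esters/aldehydes (ρ_max = 0.35),
   weak for aromatics (0.15).  Every downstream stage is testable against
   this known truth.

## Worked example

```python
import odormix as om

cfg = om.GeneratorConfig.for_pair("EA", "BA", seed=42)   # ethyl/butyl acetate
dataset = om.generate_panel_dataset(cfg)                  # 30 panel samples
train, test = om.split_dataset(dataset, 0.7, seed=7)
model = om.fit_intensity_model(train, cv_folds=10, seed=11)
print(om.evaluate_model(model, train, test).to_dict())

surface = om.simulate_interaction_surface(model, dataset, resolution=50)
scatter = om.ratio_scatter(dataset, surface)
print(om.summarize_surface(scatter).to_dict())
```

prints

```
{'r2_train': 0.937, 'r2_test': 0.957, 'mae_train': 0.192, 'mae_test': 0.182,
 'n_train': 21, 'n_test': 9}
{'peak_ratio': 0.357, 'peak_x_a': 0.525,
 'intensity_ratio_correlation': 0.176, 'n_points': 1280}
```

The held-out MAE (0.182 OIRS) is well inside the ≈ 0.4 OIRS error level
accepted for human olfactory evaluation, so the model can stand in for the
panel when densifying composition space.  The analysis then recovers the
generator's ground truth: the strongest antagonism (reduction ratio 0.357 vs
the true ρ_max = 0.35) occurs near equal log-activity mixing
(x_a = 0.525 ≈ 0.5), and the interaction degree is essentially uncorrelated
with the mixture's intensity level (rank correlation 0.176).

The same workflow is scriptable from the shell:

```bash
odormix generate --pair EA,BA --seed 42 --out panel.csv
odormix fit --dataset panel.csv --split-seed 7 --cv-seed 11 --out model.joblib
odormix evaluate --model model.joblib --dataset panel.csv --split-seed 7 --out eval.json
odormix run --config examples/run.yaml          # full pipeline + figures
```

## Layout

- `src/odormix/psychophysics.py` — odorant registry, OI–lnOAV laws
- `src/odormix/synthetic_panel.py` — panel generator and its ground truth
- `src/odormix/intensity_model.py` — split / grid-searched SVR / metrics
- `src/odormix/interaction.py` — interaction statistics, surface, scatter
- `src/odormix/pipeline.py`, `cli.py`, `plotting.py` — config, I/O, figures
- `docs/methods.md` — modelling assumptions and design notes
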