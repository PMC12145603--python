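# osteomet

NMR-metabolomics marker discovery for mesenchymal stem-cell
osteodifferentiation.

Human adipose-derived mesenchymal stem cells (hAMSC) committed to the bone
lineage change their metabolism within days, but donor-to-donor variability
makes single-donor markers unreliable. `osteomet` implements the full
analysis chain used to find **donor-independent metabolic signatures** of
osteodifferentiation from ¹H NMR spectra of cell extracts (endometabolome)
and conditioned culture media (exometabolome), together with a
ground-truth-annotated cohort simulator so that every stage is testable
without instrument data. It is aimed at metabolomics analysts and method
developers working with longitudinal, donor-blocked cell-culture designs.

## What it computes

* **Spectral preprocessing** — chemical-shift referencing to TSP (δ 0.00),
  exclusion of solvent/supplement regions (water δ 4.5–5.2, TSP δ 0.0–0.6,
  methanol δ 3.3–3.4, ethanol δ 1.1–1.2 and 3.6–3.7; in media additionally
  β-glycerophosphate/glycerol δ 3.5–3.9 and 4.1–4.2, DMSO δ 2.7–2.8),
  recursive segment-wise peak alignment, and total-spectral-area
  normalization.
* **Media-exchange correction** — conditioned-media values are corrected
  recursively for repeated media exchanges and varying cell numbers:

  ```
  S_corr[i,j] = mean(S_corr[i-1,·]) + (S[i,j] − B̄[i−1]) / TA[i,j]
  ```

  where `B̄[i−1]` is the mean fresh-medium (blank) value of the batch applied
  at the previous exchange and `TA[i,j]` the replicate's total spectral
  area. Positive trajectories mean net secretion, negative net uptake.
* **Chemometrics** — PCA and two-class PLS-DA (PLS1 NIPALS, unit-variance or
  centered scaling) as scikit-learn-style estimators, with back-transformed
  loadings and Wold variable importance in projection,
  `VIP_k = sqrt(p · Σ_a SSY_a (w_ak/‖w_a‖)² / Σ_a SSY_a)`.
* **Monte Carlo cross-validation** — stratified 7-block random splits, one
  block held out, 500 iterations; reports Q² = 1 − PRESS/TSS, sensitivity,
  specificity and classification rate, with the latent-variable count chosen
  inside each training split.
* **Marker screening and selection** — percent variation
  `100·(mean_OI − mean_CTR)/mean_CTR` per metabolite, donor and day; exact
  Wilcoxon rank-sum p-values (full enumeration up to 12 observations, and a
  donor-stratified exact variant for pooling across donors); explicit,
  tunable donor-independence rules (sign consistency, significant days,
  magnitude floor); thresholded Spearman correlation maps.
* **Synthetic cohort generator** — 3 donors × (control vs osteoinduced) ×
  triplicates, cells sampled on days 0/1/4/7/14/21 and media on days
  1/4/7/11/14/18/21 with exchanges twice a week, ~50 metabolites rendered as
  Lorentzian multiplets with donor-specific confounders, planted
  9-endometabolite and 17-exometabolite osteogenic signatures, chemical-shift
  jitter, noise and the study's missing-replicate pattern.

## Worked example

```python
from osteomet import (build_default_library, process_cells, run_mccv,
                      screen_table, select_donor_independent)
from osteomet.simulate import CohortConfig, simulate_cohort
from osteomet.validate import MCCVConfig

lib = build_default_library()
cells, media, blanks, truth = simulate_cohort(lib, CohortConfig(seed=1))
print(f"simulated {len(cells)} cell spectra, {len(media)} media spectra")

endo = process_cells(cells, lib)              # reference/align/exclude/normalize/integrate
screen = screen_table(endo, mode="osteo")     # % variation + Wilcoxon per donor and pooled
signature = select_donor_independent(screen)
print("donor-independent signature:", ", ".join(sorted(signature)))

late = endo[endo["day"] >= 14]
res = run_mccv(late[signature].to_numpy(), late["arm"].to_numpy(),
               MCCVConfig(n_blocks=7, n_iterations=500, seed=2))
s = res.summary
print(f"MCCV (D14-D21): sens {s['sens_mean']:.2f}  spec {s['spec_mean']:.2f}  "
      f"CR {s['cr_mean']:.2f}  Q2 {s['q2_mean']:.2f}")
```

prints

```
simulated 105 cell spectra, 118 media spectra
donor-independent signature: ADP, Cho, Etn, MG, PCho, PCr, U3.48, UDP-GalNAc, UDP-GlcNAc
MCCV (D14-D21): sens 1.00  spec 1.00  CR 1.00  Q2 0.92
```

i.e. the selection recovers exactly the nine planted intracellular markers
(choline, ethanolamine, UDP-GlcNAc, UDP-GalNAc and the unassigned δ 3.48
singlet up; ADP, methylguanidine, phosphocholine and phosphocreatine down),
and a PLS-DA model on those nine integrals classifies control vs
osteoinduced samples from day 14 onward with 100% sensitivity, specificity
and accuracy and strong predictive power.

A command-line interface mirrors the library
(`osteomet simulate|preprocess|correct-media|integrate|screen|fit|mccv|correlate|report|run-all`);
`osteomet run-all --seed 1 --out runs/demo` writes tables, fitted models,
figures and a run manifest.

## Layout

```
src/osteomet/
  library.py       metabolite library: multiplets, effects, signatures
  simulate.py      cohort simulator (spectra or integral tables)
  preprocess.py    referencing, exclusion, alignment, normalization
  media.py         recursive media-exchange correction
  quantify.py      window integration, marker ratios
  chemometrics.py  PCA, PLS-DA (NIPALS), VIP, scalers
  validate.py      Monte Carlo cross-validation
  screen.py        Wilcoxon screening, selection rules, Spearman maps
  pipeline.py      end-to-end orchestration, manifests, figures
  cli.py           command-line interface
docs/methods.md    model, assumptions, parameter choices, limitations
```
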