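# transcoloc

Quantitative analysis of ion-channel transcript expression and physical
association in single cardiomyocytes, combining three experimental readouts
in one tested pipeline:

1. **Single-molecule FISH image analysis** — detection and sub-pixel
   Gaussian localization of diffraction-limited mRNA spots, calibration of
   the single-mRNA fluorescence intensity from the pooled intensity
   histogram, mRNA copy-number and cluster-size statistics, and
   distance-from-nucleus spatial profiles.
2. **Chance-corrected object-based colocalization** — one-to-one matching
   of spots between channels at pixel-distance criteria, compared per cell
   with the analytic number of associations expected under spatial
   randomness, for transcript pairs and for mRNA–mRNA–protein triples
   (cotranslational complexes), plus per-cell count correlation
   (Pearson R with an F test; Spearman ρ).
3. **Knockdown quantification** — RT-qPCR relative expression by
   2^−ΔΔCt with per-replicate log/mean-center/autoscale standardization and
   95% CIs, smFISH-based co-knockdown comparisons, and voltage-clamp
   analysis (drug-sensitive subtraction, steady-state/tail/peak
   measurement, Boltzmann activation and availability fits, conductance–
   voltage curves, and the 50–800 ms late-sodium-current integral).

A ground-truthed synthetic-data generator (`transcoloc.simulate`) produces
cells, spot fields, rendered images, Ct tables and current sweeps with
known answers, so every stage is testable without microscopy data.

## The chance model

Spot signals are treated as discs of common radius *r* (the mean fitted
FWHM/2). Two spots at centre distance *d* overlap by the lens area

```
I(d, r) = 2 r² cos⁻¹(d / 2r) − (d/2) √(4r² − d²)
```

and the number of associations expected by chance in a cell with N₁ and N₂
spots of each species in analyzed area A is

```
E_m = N₁ N₂ (2π r² − I) / A                (pairs)
E_p = N_p E_m (π r² − I) / A               (triples, N_p protein spots)
```

Observed per-cell matched counts are tested against E_m by a paired
two-tailed t test with Bonferroni correction over the criteria grid
(1–4 px; 2 px ≈ 50% overlap is the criterion used for triples and
knockdown comparisons). A classical encounter-area null (π d² / A) is
available behind `null="classical"` for sensitivity analysis.

Voltage dependence of channel gating is characterized by Boltzmann fits

```
I(V) = (V − V_rev) G_max / (1 + e^((V − V_half)/k))            (activation)
I(V) = (I_min − I_max) + I_max / (1 + e^((V − V_max)/k))       (availability)
```

## Worked example

```python
import transcoloc as tc

geo = tc.make_cell_geometry(seed=1, shape_px=(512, 512), nucleus_radius_um=8.0)
spots, truth = tc.simulate_spot_field(
    geo, {"hERG1a": (30, 160), "SCN5A": (30, 160)}, coloc_fraction=0.25,
    n_cells=41, count_correlation=0.75, seed=42,
)
herg = spots[spots["channel"] == "hERG1a"]
scn = spots[spots["channel"] == "SCN5A"]
res = tc.SpotAssociation(
    herg, scn, areas_nm2=geo.cytoplasm_area_nm2, r_nm=125.0,
    criteria_px=[1, 2, 3, 4],
).fit()
print(res.summary())

counts = tc.counts_wide(tc.count_mrna_per_cell(spots))
print(tc.correlate(counts["hERG1a"], counts["SCN5A"]).summary())
```

prints

```
Object-based association analysis (union null), r = 125.0 nm, pixel 106.3 nm
cells: 41
  1 px: observed 22.95 +/- 1.42, expected 0.42 +/- 0.04, t=16.21, p=3.49e-19 (Bonferroni 1.4e-18); associated: 25.1% of A, 25.9% of B
  2 px: observed 23.46 +/- 1.45, expected 0.54 +/- 0.05, t=16.30, p=2.91e-19 (Bonferroni 1.17e-18); associated: 25.7% of A, 26.5% of B
  3 px: observed 24.10 +/- 1.50, expected 0.56 +/- 0.05, t=16.20, p=3.58e-19 (Bonferroni 1.43e-18); associated: 26.4% of A, 27.2% of B
  4 px: observed 24.83 +/- 1.59, expected 0.56 +/- 0.05, t=15.71, p=1.04e-18 (Bonferroni 4.16e-18); associated: 27.2% of A, 28.0% of B

Per-cell count correlation, n = 41 cells
  Pearson  R = 0.5460  (R^2 = 0.2982), p = 0.000222 (F test)
  Spearman rho = 0.5586, p = 0.000147 (two-tailed)
```

The 25% planted colocalized fraction is recovered as ~25–26% of each
population associated at the 1-px criterion, far above the ~0.5 particles
per cell expected by chance, and the correlated per-cell counts give a
significant Pearson/Spearman correlation at the 41-cell scale. Each
`Model.fit()` returns a results object carrying the estimates, their
uncertainties and a `summary()`; `plot()` methods draw the standard
figures (observed-vs-expected bars, intensity-histogram fit, I–V fits,
radial profiles).

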