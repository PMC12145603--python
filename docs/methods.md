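# Methods

This note documents the models, statistical procedures and design choices
behind `osteomet`, in the order data flows through the pipeline.

## Study design emulated by the simulator

The synthetic cohort reproduces a longitudinal, donor-blocked cell-culture
experiment: three donors, each split into a proliferating control arm (CTR)
and an osteoinduced arm (OI); cell extracts sampled in triplicate on days
0, 1, 4, 7, 14 and 21; conditioned media sampled in triplicate on days 1,
4, 7, 11, 14, 18 and 21; media exchanged on days 0, 4, 7, 11, 14, 18 and 21
(sampling precedes exchange on shared days); fresh-medium (blank) replicates
per exchange batch. The default missing-replicate pattern mirrors the
emulated study (donor 1: CTR D0 cells n=2, OI D7 media n=0; donor 2: CTR
D7/D18 media n=2, OI D11 media n=2, OI D21 media n=1, OI D21 cells n=1).

## Spectral model

Each metabolite is a set of Lorentzian multiplets (ppm center, relative
area, FWHM in Hz at 500.13 MHz). Spectra are rendered on a default grid of
8192 points over −0.5…10.0 ppm — a deliberate scale-down of a real
32k-point acquisition that preserves line-shape and overlap phenomena at a
fraction of the cost. Rendering is **bin-integrated**: each grid cell
receives the exact integral of the line over the cell (arctan differences),
so the trapezoidal area of a rendered peak equals its closed-form area
within the grid range to better than 10⁻⁶ relative — quadrature accuracy is
a property of the renderer, not of grid density. Chemical shifts are
approximate literature values; a few crowded resonances (the choline head
groups Cho/PCho/GPC, the creatine/phosphocreatine region) are spaced
slightly wider than in real spectra so the default integration windows stay
resolvable without deconvolution.

Per-sample variability: a global chemical-shift offset (SD 0.003 ppm,
shared by all peaks including the TSP reference, hence removable by
referencing), per-metabolite shift jitter (SD 0.0015 ppm, removable by
alignment), multiplicative lognormal replicate variability (CV 8%, a
typical flask-to-flask biological scatter for cultured cells), additive
Gaussian spectral noise (SD 1 intensity unit, giving SNR of roughly 40–1000
across the library), and 1% lognormal batch variability of blank media.
These values are fixed properties of the simulated conditions, chosen once
as realistic for this assay class.

Intracellular effects are multiplicative time-course multipliers,
piecewise-linear between breakpoints; donor-specific multiplicative offsets
apply to confounder metabolites only (lactate, glycerol, GPC, creatine,
taurine, 2-HIC, acetate, acetone, glutamate, glycine, formate), which makes
full-spectrum PCA group by donor, as inter-donor variability does in
practice. Extracellular effects multiply the uptake/secretion *rate*;
footprints accumulate linearly between exchanges and reset at each
exchange. Because the corrected trajectory is a cumulative sum over
exchange intervals, a rate step at onset day 4 produces a trajectory-level
contrast that lags the instantaneous rate change; the library solves the
step factor from the sampling/exchange schedule so that the planted
magnitude is the **trajectory** contrast at day 21 (the quantity the screen
measures).

Planted signatures: nine intracellular markers (Cho, Etn, UDP-GlcNAc,
UDP-GalNAc, U3.48 up ≥ +110% planted, observed ≥ +80% after normalization
closure; ADP, MG, PCho, PCr down 40–60%) with onset day 4; seventeen
extracellular markers (reduced uptake of Gln, BCAA, 2-HIBA, Pyr, Glc;
increased secretion of 3-HBA, Orn, PyroGlu, Lac; reduced secretion of
3-HIBA, α-KG, Cit; donor-dependent patterns but donor-independent end
levels for Ala, Cho, His); and a 14-metabolite proliferation signature
applied to both arms. Proliferation magnitudes are calibrated so the
*observed* normalized variations reach the stated levels (>85% increases,
>55% ATP/ADP decreases): total-area normalization is compositional, so an
observed +85% requires a planted concentration change of roughly +125%.
U3.48 is simulated as a singlet of unknown identity at δ 3.48; no identity
is invented.

## Preprocessing

Order: TSP referencing → alignment → region exclusion → normalization.
Referencing shifts each spectrum by an integer number of grid steps so the
maximum inside ±0.05 ppm lands on 0.00 ppm (exact to one grid step;
intensity values are repositioned, never rescaled). Alignment is a
recursive binary-segmentation variant of segment-wise peak alignment: each
segment is shifted by the integer step count (bounded by `max_shift`,
default 0.02 ppm) maximizing *normalized* cross-correlation with the
reference (normalization prevents edge padding from buying spurious gains
on sloping baselines; ties break toward zero shift), then split and
re-aligned recursively down to `min_segment` (default 64 points). Segments
split at the reference's local minimum within the admissible middle band,
never at a fixed midpoint — seams through peaks would otherwise delete or
duplicate peak slices, which is catastrophic for the small blank-referenced
media increments downstream. Total integral is preserved to well under
0.5%. Exclusion removes grid points inside the configured regions (overlaps
merged); normalization divides by the sum of retained intensities, so
excluded solvent area never influences scaling.

## Media-exchange correction

The recursion `S_corr[i,j] = mean(S_corr[i−1,·]) + (S[i,j] − B̄[i−1])/TA[i,j]`
(day-0 mean ≡ 0) is applied per (donor, arm, variable) in day order, at
integral level in the pipeline and equally applicable at data-point level.
`B̄[i−1]` is read as the mean blank value of the fresh-medium batch applied
at the previous exchange, making each step the area-normalized change
relative to fresh medium accumulated since that exchange; this reading is a
documented interpretation, and the shift-invariance property (adding a
constant to all raw and blank values changes nothing) holds under it. TA is
computed after region exclusion, matching the normalization convention.

**Missing days.** When a day's replicates are all missing, skipping it (or
carrying the previous mean forward) silently drops that exchange interval's
footprint from the running sum and biases *every later value* of the series
— under the emulated missing pattern (donor 1 OI D7 media n=0) by about
−20%, enough to flip signs and create systematic false positives in
selection. The implementation instead imputes the missing day's mean
increment from the per-day footprint rates of the nearest measured
neighbors, weighted by exchange-interval spans, and warns. With a constant
secretion rate the imputation is exact.

## Chemometrics

PLS-DA is PLS1 NIPALS regression on a 0/1 dummy coding of the two classes
(classes in sorted label order), with centering or unit-variance scaling
fit on training data only, a deterministic sign convention (largest-|weight|
element positive), prediction at a 0.5 cutoff (exact ties to class 0), and
early stopping when no covariance remains. VIP uses the standard Wold
definition; mean squared VIP over variables is 1 by construction.
Back-transformed loadings multiply each loading by the variable's training
SD. PCA is an SVD of the scaled matrix with the same sign convention.
Zero-variance columns are dropped with a warning before UV scaling.

Monte Carlo cross-validation draws, per iteration, a stratified random
7-block partition (each class spread round-robin over blocks from a random
offset) and holds one random block out (≈1/7 test fraction). The
latent-variable count (1–3) is chosen inside each training split by inner
cross-validated Q², preventing optimistic bias; Q² per iteration is
1 − PRESS/TSS with TSS about the training-set class mean, so predicting the
training mean scores exactly 0. Both per-iteration means/SDs and pooled
quantities (confusion counts, pooled Q²) are reported. Whether the original
in-house procedure stratified, and how it fixed the component count, is not
documented; these are this package's explicit defaults.

## Screening and selection

Percent variation per (metabolite, donor, day) is
`100·(mean_OI − mean_CTR)/mean_CTR` (osteogenesis mode) or day-i vs day-0
within the control arm (proliferation mode). Groups with fewer than 3
replicates never carry p-values and are flagged `visual_only`. Two-group
p-values are exact two-sided Wilcoxon rank-sum by complete enumeration with
mid-ranks up to 12 total observations, normal approximation with tie
correction above. With triplicates the exact two-sided floor is p = 0.1, so
per-donor significance at α = 0.05 is unattainable — significance must be
pooled across donors. The pooled test is a **donor-stratified** rank-sum:
ranks are formed within each donor block and the OI rank sums added across
blocks, with the exact null obtained by convolving the per-block
enumerations (minimum two-sided p = 2/20³ = 0.00025 for three triplicate
blocks). A naive pooled rank-sum was rejected because donor-level offsets
interleave the pooled ranks and can mask a shift that is consistent within
every donor.

Donor-independence selection is rule-explicit (`SelectionRules`): percent
variation must carry the same sign in every donor at all assessed days (day
≥ 14 by default, when inter-donor agreement is established), be significant
on ≥ 2 assessed days (per donor when group sizes permit, else in the
stratified pooled screen), and reach a 20% pooled magnitude floor at the
final day — the floor operationalizes "visual spectral confirmation" and is
flagged as a proxy. No multiple-testing correction is applied by default,
matching raw p < 0.05 usage; a Benjamini–Hochberg option is available via
`statsmodels` if desired upstream of the rules.

Spearman maps use mid-rank ρ with exact permutation p-values for untied
samples of n ≤ 9 (cached null distributions) and the t approximation
otherwise; endo–exo maps pair compartments by (donor, day) group means,
because cell and media replicates are not paired one-to-one. Default
thresholds follow common practice here: |ρ| > 0.7 or 0.8 with p < 0.001.

## What the simulation does and does not show

Passing tests demonstrate that the pipeline recovers planted,
donor-consistent effects of the stated magnitudes under realistic noise,
donor confounding, exchange structure and missing data — and that it stays
silent on effect-free cohorts (≥95% empty selections over 100 nulls). The
simulator does not model J-coupling fine structure, phase or baseline
artifacts, water-suppression residuals, ¹³C satellites, or peak-shape
distortions; real-data import assumes phased, baseline-corrected spectra.

Two real limitations surfaced by the simulation are worth knowing:

* **Closure.** Total-area normalization is compositional; large planted
  changes shift the normalized values of unchanged metabolites by several
  percent (opposite sign). The selection magnitude floor absorbs this, but
  very small true effects (< ~15%) are not reliably separable from closure.
* **Tail contamination.** Window integration without deconvolution leaks
  Lorentzian tail area from large, condition-dependent neighbors into the
  windows of small nearby signals. In the default library the lactate
  quartet at δ 4.11 (strongly increased by osteoinduction) contaminates the
  only usable myo-inositol window (δ 4.06) by ~5–10% of its corrected
  footprint; combined with closure this approaches the 20% selection floor
  in a minority of simulated cohorts. Analyses of real spectra should treat
  windows downfield-adjacent to dominant variable peaks with the same
  suspicion.

## Numerical and degenerate-input conventions

Axes are stored ascending (NMR display order is applied only in plots).
Referencing errors on flat windows raise; nonpositive total areas raise;
zero or negative ratio denominators yield missing values, never infinities;
windows overlapping an exclusion region by more than half their width are
flagged missing. All stochastic stages consume a single integer seed
(`numpy.random.default_rng`); identical seeds reproduce identical arrays
and identical written bytes for all tables and manifests (figures
excepted).
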