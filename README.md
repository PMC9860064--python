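# cocultx

Growth- and death-curve analysis for long-term phototroph–heterotroph
co-cultures.

## The problem

When *Prochlorococcus* (a marine picocyanobacterium) is grown alone in
nitrogen-limited batch culture it blooms, peaks, and dies within weeks. Grown
together with a heterotrophic *Alteromonas* partner it can survive nitrogen
starvation for months. The information about *how* a culture dies is in the
shape of its bulk chlorophyll-fluorescence curve: ~140 days of near-daily
measurements covering a lag, an exponential rise to a peak, and a long
decline. This package quantifies those curves for cultures of five
*Prochlorococcus* strains crossed with five *Alteromonas* strains plus axenic
controls, and asks which partner controls the dynamics, whether the
interaction is mutually beneficial, and how mortality should be modelled.

It is organised as an analysis project: the library under `src/cocultx/`
holds every computation, the numbered drivers under `analysis/` narrate the
study over simulated data, and a `cocultx` CLI exposes the stages for use on
any data in the documented CSV formats.

## The models

**Growth.** ln *N*<sub>t</sub> = ln *N*<sub>0</sub> + μ(*t* − *L*): ordinary
least squares of log fluorescence on time over the detected exponential
window (accepted only at R² > 0.9) gives the growth rate μ (d⁻¹) and lag *L*
(days).

**Mortality.** Four laws are fitted to the peak-normalized decline
y(τ) = FL/FL<sub>max</sub>, τ = days since the peak:

| model          | y(τ)                                   | free parameters |
|----------------|----------------------------------------|-----------------|
| exponential    | e^(−aτ)                                | 1               |
| bi-exponential | f·e^(−a₁τ) + (1−f)·e^(−a₂τ)            | 3               |
| harmonic       | 1/(1 + aτ)                             | 1               |
| Weibull        | e^(−aτⁿ)                               | 2               |

Fits use bounded nonlinear least squares (dogbox) with a soft-L1 robust loss
(f_scale 0.1) and multi-start initialisation; models are compared by plain
RMSE and Gaussian BIC. The Weibull shape *n* separates accelerating death
(*n* > 1, damage accumulation) from decelerating death (*n* < 1, acclimation),
and t<sub>d</sub> = (ln 10<sup>d</sup>/a)^(1/n) is the time to fall by *d*
decades (td₂ = two decades).

**Carrying capacity.** Flow-cytometry counts convert to nitrogen biomass via
cellular quotas, biomass[μmol N/L] = X[cells/ml]·Q_N[fg/cell]·10⁻⁶/MW_N,
bounded by the 100 μM N supplied; interactions are called from the log2 fold
change of each population's biomass against its axenic control.

**Curve shape.** Curves aligned to their peak (day −10 to +80, daily bins,
interpolated, z-scored) feed PCA ordination, PERMANOVA (adonis pseudo-F on
Euclidean distances), and stratified 10-fold random-forest classification
with per-day feature importance.

A fully specified synthetic-data generator (`cocultx.synthetic_data`)
reproduces the study design with known ground truth, so every stage is
testable end to end.

## Worked example

```sh
python analysis/01_simulate.py      # 105 cultures, tidy CSVs under results/simulated/
python analysis/03_decline_models.py
```

prints (abridged):

```
fitted 4 models x 90 cultures
RMSE (mean +/- SD) by model and treatment:
  biexponential  axenic_pro: 0.023 +/- 0.014 (n=15)  coculture: 0.016 +/- 0.005 (n=75)
  exponential    axenic_pro: 0.023 +/- 0.014 (n=15)  coculture: 0.082 +/- 0.027 (n=75)
  harmonic       axenic_pro: 0.063 +/- 0.023 (n=15)  coculture: 0.029 +/- 0.011 (n=75)
  weibull        axenic_pro: 0.007 +/- 0.003 (n=15)  coculture: 0.012 +/- 0.007 (n=75)
Weibull shape n: axenic 1.48 +/- 0.33 vs co-culture 0.39 +/- 0.12 (t-test p = 3.9e-38)
td2: axenic 13.5 d vs co-culture 349 d
```

Axenic cultures die with accelerating kinetics (*n* > 1) and lose two decades
of signal in about two weeks; co-cultures decelerate (*n* < 1) and would take
nearly a year — the heterotroph extends phototroph survival more than
twenty-fold. `analysis/04_nitrogen_budget.py` then shows the day-60 co-culture
carrying capacity (~70 μmol N/L, ~3/4 of it in the heterotroph) and which
phototroph strains repay the favour (positive heterotroph log2FC for MED4,
MIT0604, NATL2A; none for MIT9312, MIT9313), and `analysis/05_curve_shape.py`
shows that curve shape is set by the phototroph strain (PERMANOVA
F(4,70) = 48.7, p = 0.001; random-forest accuracy 0.78 vs 0.15 for the
heterotroph) with the informative days in the decline phase.

The same stages run on real data through the CLI, e.g.
`cocultx fit-decline --curves curves.csv --metadata metadata.csv --seed 17
--out fits.csv` (formats documented in `cocultx/io_model.py`).

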