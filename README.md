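# lapsched

**Dosing-schedule optimization for lapatinib in glioblastoma (GBM).**

EGFR-mutant glioblastoma cell lines respond to the EGFR/HER2 inhibitor
lapatinib in vitro, yet continuous daily dosing has failed in the clinic —
partly because tolerable oral doses cannot push enough drug across the gut
and the blood-brain barrier. A natural question for trial design is whether
*pulsatile* schedules (fewer, higher-dose days per cycle, which patients
tolerate at much higher daily doses) could outperform continuous dosing.
`lapsched` is a modeling platform for answering that question in silico: it
links in vitro pharmacodynamics, clinical toxicity limits, and lapatinib
pharmacokinetics to ODE and reaction-diffusion models of tumor growth, and
compares treatment schedules by tumor burden and simulated patient
survival. It is aimed at mathematical-oncology and quantitative-pharmacology
researchers who want a reproducible, testable implementation of this
pipeline.

## The models

**In vitro pharmacodynamics.** Viable and dead cell counts $(Y_1, Y_2)$
follow a logistic birth-death system

$$\frac{dY_1}{dt} = b\,Y_1\Big(1-\frac{Y_1}{K}\Big) - d\,Y_1,\qquad
\frac{dY_2}{dt} = d\,Y_1 - c\,Y_2,$$

with carrying capacity $K$ (max untreated day-5 count) and dead-cell
clearance $c$ (0 in the selected model). Rates at lapatinib concentration
$L$ (nM) follow exponential dose-response laws
$b(L) = b_0 e^{b_1 L}$, $d(L) = d_0 e^{d_1 L}$, estimated by an exhaustive
grid search per concentration followed by nonlinear least squares across
concentrations. Growth arrest requires
$L^\* = \ln(b_0/d_0)/(d_1-b_1) \approx 2.2\times 10^3$ nM.

**Toxicity and schedules.** Three clinical maximum-tolerated-dose points —
(5 d/cycle, 3000 mg/d), (2 d, 5250 mg/d), (1 d, 7000 mg/d) — are fitted by
linear and exponential (log-scale OLS) curves and compared by Gaussian-ML
AIC; the exponential curve fills in the 3- and 4-day designs. Each
schedule's oral dose maps to a serum peak (logarithmic absorption) and then
to a tumor concentration, $y_{tumor}(\mathrm{nM}) = 0.61\, y_{serum}
(\mathrm{ng/mL}) \times 1000 / 943.5$.

**Pharmacokinetic signal.** Every treatment day contributes a pulse: linear
uptake to the tumor peak over 4 h, then exponential decay with a 24 h
half-life; pulses superpose additively across days.

**Tumor growth.** The ODE model drives the logistic system with
$b(L(t)), d(L(t))$. The in vivo model is a spherically symmetric
Fisher-KPP equation
$\partial_t c = D\nabla^2 c + \rho(L(t))\,c\,(1-c/\kappa)$ with
$\rho(L) = \rho_0\,[b(L)-d(L)]/[b(0)-d(0)]$, no-flux boundaries, a
detection threshold of 8000 cells/mm³ defining the imaging radius, and
death at a 30 mm fatal radius. Variants add a resistant subpopulation, a
blood-brain-barrier factor $Q$, and hypoxia-driven Go-or-Grow switching
between proliferative and migratory phenotypes coupled to an oxygen field.

**In silico trial.** 50 virtual patients (parameters sampled around the
fitted estimates; absorption ~ Beta(2.3, 1.5); optionally diffusion ~
truncated Gamma) are run through every schedule; survival is analyzed with
Kaplan-Meier curves, log-rank tests, and a volume-on-motility regression
with schedule interactions.

## Worked example

```python
from lapsched import datasets, invitro, ode, toxicity

lin, expo = toxicity.fit_toxicity_models(datasets.toxicity_points())
print(f"AIC linear {lin.aic:.2f} vs exponential {expo.aic:.3f}")

dr = datasets.dose_response_params()
print(f"stasis concentration {invitro.stasis_concentration(dr):.0f} nM")

print(ode.compare_schedules(datasets.mtd_schedules(), dr, n_cycles=20))
```

prints

```
AIC linear 49.48 vs exponential -5.712
stasis concentration 2219 nM
    schedule   final_viable  pct_reduction
0  schedule1  419076.788348      57.443128
1  schedule2  701663.745972      28.746676
2  schedule3  884625.589183      10.167065
3  schedule4  960337.452663       2.478593
4  schedule5  979987.466198       0.483152
5    control  984745.283685       0.000000
```

The exponential toxicity curve is decisively preferred (lower AIC). The
growth-arrest concentration, ~2219 nM, exceeds what any tolerated schedule
reaches in the tumor (1275–1590 nM), so no schedule shrinks the tumor; but
over twenty 5-day cycles continuous dosing (schedule 1) cuts the viable
population ~57% below the untreated control, while the best pulsatile
schedule manages ~29% — concentrating dose into fewer days loses more
ground during treatment holidays than the higher peaks gain.

The same comparison under the reaction-diffusion model, its variants, and
the simulated trial is available from the command line:

```bash
lapsched run --seed 1 --outdir results/   # full pipeline + manifest
lapsched simulate-pde                     # final radii per schedule
lapsched trial --n-patients 50           # survival records + log-rank
```

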