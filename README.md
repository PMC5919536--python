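# antird — anti-RhD titer kinetics in hyper-immunised plasma donors

Anti-RhD immunoglobulin, the prophylactic that prevents foetal rhesus
disease, is harvested from RhD-negative donors who are deliberately
re-exposed to RhD-positive red cells ("boostered") to keep their antibody
titer high. Boostering burdens donors, so blood banks need to know, per
donor, how fast the titer falls without boostering and how much one
booster raises it — and hence what titer plateau any boostering schedule
will sustain.

`antird` implements a four-parameter kinetic model of the log2 anti-RhD
titer and everything needed to work with it: the donor's titer declines
log-linearly at a personal rate D_i and each booster adds a logistically
saturating gain,

    T_i(t) = T_i(0) + D_i t + Σ_j  2B · env(t − x_ij; H) · sat(T_i(x_ij); L_i)

where `env(t; H) = 2(logistic(Ht) − ½)` is the time envelope of a
booster's effect, `sat(T0; L) = 1 − logistic(L·T0)` is the saturation of
the gain with the titer at boostering, B and H are population parameters,
and (D_i, L_i) are donor-level random effects from a bivariate normal.
The package provides:

- **`antird.model`** — the response equations, trajectory prediction with
  forward-sequential latent starting titers, peak-day solver, log2↔percent
  conversions;
- **`antird.cohort`** — a synthetic donor-cohort generator whose defaults
  are calibrated at import time to published population summaries
  (−0.55 log2/yr mean decline, booster gains +4.26/+0.73/+0.38/+0.20 at
  starting titers 3/9/11/13, 26-day response peak, measurement SD 0.62);
- **`antird.fitting`** — the staged estimation pipeline: random-effects
  decline fit on unboostered stretches, booster-timing and
  booster-magnitude NLS fits, the integral nonlinear mixed-effects fit
  with iterated latent starting titers (adaptive Gauss–Hermite over the
  saturation effect, exact integration of the decline effect), per-donor
  residual diagnostics, MAP fitting of out-of-sample donors and
  split-sample validation;
- **`antird.regimes`** — steady-state ("plateau") titers under fixed
  boostering frequencies and the standard summary table;
- **`antird.io`** / **`antird.cli`** — CSV dialects (day-resolved, and an
  anonymised timing-free dialect), result serialisation, and a thin
  command line (`antird simulate|fit|validate|regimes|report`).

It is aimed at transfusion-medicine and biostatistics researchers who
model longitudinal antibody data, and can be driven entirely from Python
(see `examples/`).

## Worked example

Booster response under the calibrated default population
(`examples/01_booster_response.py`):

```text
calibrated population: B=7.99 log2, H=0.170/day,
  mean decline -0.55 log2/yr, mean saturation speed 0.338/log2

asymptotic gain of one booster by titer at boostering:
  starting log2 titer  0: +7.99 log2  (+25389% absolute)
  starting log2 titer  3: +4.26 log2  (+1816% absolute)
  starting log2 titer  9: +0.73 log2  (+66% absolute)
  starting log2 titer 11: +0.38 log2  (+30% absolute)
  starting log2 titer 13: +0.20 log2  (+15% absolute)

boostered at the median titer (log2 11), the mean donor peaks 26 days later,
+0.37 log2 above the starting titer
```

A donor at the median titer (log2 11 ≈ absolute 2048) gains 0.38 log2 per
booster (to ≈2665, +30%), but a new donor at titer 3 gains 4.26 log2 —
the response saturates steeply with the starting titer.

Boostering regimes (`examples/05_boostering_regimes.py`):

```text
average donor, boostered once per year:
  trough log2 9.88 just before boostering, peak 10.37 at 24 days after,
  time-average 10.14
```

and the plateau means at 0.5 / 1 / 1.5 boosters per year come out as
8.26 / 10.14 / 11.29: because boostering is most effective at low titers,
tripling the frequency raises the sustained titer by only ~3 log2 units.

`examples/03_staged_fit.py` simulates a cohort, runs the four-stage fit
and prints recovered versus generating parameters;
`examples/04_new_donor_map.py` MAP-fits a donor outside the reference fit
from their record alone.

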