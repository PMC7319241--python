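# oeflab

Tools for studying how the strength of **organism–environment feedback**
(OEF) shapes the response of an ecosystem to a gradually changing
environment: does the state track the driver smoothly, bend nonlinearly,
or jump between alternative stable states and show hysteresis?

The package is aimed at community ecologists and theoreticians working on
regime shifts. It combines (i) a minimal dynamical model for sweeping
feedback strength against the rate of environmental change, (ii) the two
response statistics used to quantify such experiments, (iii) a fully
synthetic, seeded microcosm experiment emulating an aquatic
predator–prey–oxygen system under five gas-exchange treatments, and
(iv) time-series regime detection for replicated experiments.

## The model and the statistics

The minimal ecosystem model is the scalar ODE

    dY/dt = a − b·Y + r·f(Y),     f(Y) = Yᵖ / (Yᵖ + hᵖ)

with state *Y* (say, dissolved oxygen in a pond), environmental driver *a*,
decay rate *b*, self-replacement rate *r*, shift threshold *h*, and
feedback exponent *p*. With *b = r = h = 1*, the equilibrium curve folds —
alternative stable states appear — once *p* exceeds a critical value
p\* ≈ 3.717 (the root of the tangency condition max f′(Y) = 1, at
Yᵖ = (p−1)/(p+1)); on an integer grid of *p* the smallest bistable
exponent within driver range a ∈ [0, 1] is 4.

Driving *a* linearly from 0 to 1 and back (in 200 steps, fast, or 20 000
steps, slow) yields a driver–response path per parameter set. Two
statistics summarize it:

- **absolute nonlinearity** — the RMS difference between the fitted values
  of a straight line and of a penalized cubic regression spline (GCV-chosen
  smoothness), per forcing phase, on unstandardized data;
- **hysteresis** — the mean absolute difference between ascending-phase and
  descending-phase states paired at equal driver values.

The synthetic microcosm experiment emulates 250-ml jars holding a
bacteria–ciliate–predator community whose respiration draws down dissolved
oxygen while a temperature ramp (15 → 25 → 15 °C in 0.7 °C steps every
2 days, one-week plateau) forces the system; five gas-exchange treatments
(open, +200/+100/+50 ml air every 2 days, closed) set the feedback
strength. Replicates stochastically diverge into a persistent low-oxygen
regime or functional extinction with oxygen recovery; regime detection
uses dynamic time warping distances with Ward clustering and a logistic
likelihood-ratio test of the cluster–treatment association.

## Worked example

```python
from oeflab import (MinimalModelParams, DriverRamp, simulate, critical_p,
                    bistable_interval, path_from_trajectory, compute_metrics)

print("critical p:", round(critical_p(), 4))
print("bistable interval at p=8:",
      tuple(round(v, 4) for v in bistable_interval(MinimalModelParams(p=8))))

for steps in (200, 20_000):
    traj = simulate(MinimalModelParams(p=8), DriverRamp(total_steps=steps))
    m = compute_metrics(path_from_trajectory(traj, id=f"{steps}"))
    print(f"steps={steps:>6}: nonlinearity_up={m.nonlinearity_up:.4f} "
          f"hysteresis={m.hysteresis:.4f} n_pairs={m.n_pairs}")
```

prints

```
critical p: 3.7174
bistable interval at p=8: (0.3886, 0.66)
steps=   200: nonlinearity_up=0.2440 hysteresis=0.4089 n_pairs=99
steps= 20000: nonlinearity_up=0.2400 hysteresis=0.2595 n_pairs=9999
```

At strong feedback (p = 8) the driver crosses both folds, so hysteresis is
large at either rate, but the fast ramp adds transient lag ("apparent"
hysteresis): 0.409 against 0.259 state units. The bistable driver window
(0.389, 0.660) brackets the jumps in the simulated path.

The same pipeline runs from the shell:

```sh
oeflab generate --seed 42 --out experiment.csv
oeflab metrics  --in experiment.csv --variable total_biomass --out metrics.csv
oeflab analyze  --in experiment.csv --out results/
oeflab sweep    --p-min 0 --p-max 10 --p-step 0.5 --steps 200,20000 --out sweep.csv
```

`analyze` writes DTW distance matrices, k = 2 cluster labels per variable,
the combined A/B/C regime codes, and prints the likelihood-ratio deviance
of the cluster–treatment association.

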