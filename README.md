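# copemorph

Quantitative sizing of mesozooplankton (copepods) from flow-imaging particle
pictures. The package implements the full measurement chain a plankton
ecologist needs to turn silhouette images into biovolumes, size
distributions and growth rates:

1. **Morphometrics** — segment dark-on-light particle frames and compute,
   per particle: pixel area, the Area-Based Diameter
   `d_ABD = 2 √(A/π)` (diameter of the solid circle with the particle's
   area), the ABD biovolume `V_ABD = (π/6) d_ABD³`, minimum/maximum feret
   diameters, and the conventional manual biovolume
   `V = prosome length × width²`.
2. **Calibration** — per-morphotype OLS regression on the natural-log scale,
   `ln V_microscopy = a·ln V_ABD + b`, converting instrument biovolume to
   microscopy-equivalent biovolume; a reference coefficient set for the 7
   dominant copepod morphotypes ships with the package.
3. **Size distributions and sample recycling** — log-binned biovolume
   histograms, plus a simulation of the recycling procedure in which the
   same physical sample is passed through the imager repeatedly
   (per-individual Bernoulli capture per pass, multiplicative lognormal
   measurement noise) so the pooled empirical distribution converges to the
   truth.
4. **Artificial-cohort growth** — `g = ln(W_T/W_0)/T` from the mean carbon
   biomass of a cohort before and after incubation, with carbon obtained
   from biovolume through a user-supplied power law `W = c·V^k`. Any
   constant multiplicative bias in the biomass measurements cancels exactly
   in `g`.
5. **Synthetic silhouettes** — a first-class generator of copepod-like
   particle images (elliptical prosome, optional urosome, thin rectangular
   antennae) with analytic ground truth, so the whole chain is testable
   without an instrument. The generator reproduces the characteristic
   antenna bias: long antennae stretch the feret-based length reading by
   >20% while inflating `V_ABD` by <15% (adding relative area ε changes
   `V_ABD` by exactly `(1+ε)^1.5`).

Users: plankton ecologists running flow-imaging instruments who need
ground-truthed biovolumes and growth rates; method developers who need a
testbed with known truth.

## Worked example

```python
import math
from copemorph import (ShapeSpec, Antenna, generate_particle, segment,
                       measure, table1_defaults, apply_calibration)

# a calanoid copepodite, prosome 400 x 100 um, with two 240-um antennae
ants = (Antenna(240, 5, 35), Antenna(240, 5, -35))
spec = ShapeSpec("calanoid_copepodite", 400, 100, antennae=ants,
                 pixel_size=1.0, noise_sd=5, seed=2)
img, truth = generate_particle(spec)
rec = measure(segment(img, min_esd_um=None, max_esd_um=None)[0])
print(f"feret length {rec.feret_max_um:.1f} um (true prosome {truth.true_length})")
print(f"ABD diameter {rec.abd_diameter_um:.1f} um, V_ABD {rec.v_abd_um3:.3e} um^3")
model = table1_defaults()["calanoid_copepodite"]
print(f"calibrated biovolume {apply_calibration(rec.v_abd_um3, model):.3e} um^3")
```

prints

```
feret length 612.2 um (true prosome 400)
ABD diameter 207.2 um, V_ABD 4.661e+06 um^3
calibrated biovolume 2.603e+06 um^3
```

The feret-based length (612 µm) is stretched 53% past the true prosome by
the antennae, while the ABD diameter (207 µm vs 200 µm for the bare body)
barely moves — the reason `V_ABD` plus a per-taxon calibration is the
biovolume estimator of choice. The last line converts the instrument
biovolume to its microscopy-equivalent value with the shipped calanoid
coefficients (a=0.88, b=1.26, natural log).

A command-line pipeline wraps the same stages:

```sh
copemorph simulate --morphotype calanoid_nauplius -n 100 --seed 7 --out sim/
copemorph measure --images sim/ --no-size-gate --out meas/
copemorph distribution --particles meas/particles.csv --out dist/
copemorph growth --t0 meas/particles.csv --tt meas_tT/particles.csv \
    --incubation-days 2 --carbon-c 1e-7 --carbon-k 0.9 --out growth/
```

Every output directory carries a `run.json` provenance record and a config
hash stamped into the CSV headers.

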