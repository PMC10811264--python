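# omnineck

Omni-directional neck-muscle feedback control for occupant simulation of
evasive vehicle maneuvers — the controller chain, the spatial-tuning-pattern
load sharing, a desk-scale surrogate head–neck plant, metamodel-based gain
tuning, and objective bio-fidelity rating, as one reusable Python library
with a thin CLI.

## The problem

Car crashes are frequently preceded by an evasive maneuver (hard braking, a
lane change) during which an occupant's posture and muscle state change.
Active human body models simulate this by driving neck muscles with
feedback controllers that emulate the vestibulocollic reflex: a deviation
of the head from a reference posture produces a corrective muscle
activation.  This package implements the two controller formulations used
in that setting, for researchers who need the control, tuning and rating
machinery without a proprietary finite-element human body model:

* **translational controller** — the error is the angular deviation of the
  T1→head-centre-of-gravity link from its reference, sensed in a frame
  that follows T1 in yaw; the horizontal direction of head displacement
  selects the muscle load sharing;
* **rotational controller** — head orientation relative to a fixed
  reference frame is converted to the axis–angle form `(v, θ)`; the angle
  `θ` is the scalar error and the axis `v` selects the load sharing.

Both feed the same chain (delayed error → PID → saturation → spatial
tuning patterns → baseline → activation dynamics):

```
u(t) = Kp·e(t−τ) + Ki·∫ e(t−τ) dt + Kd·de(t−τ)/dt          (parallel PID)
drive_i = min(1, sat(u)·w_i(direction) + b_i)               (load sharing)
τ_e·Ṅe = drive − Ne;   τ_a·Ṅa = Ne − Na                    (activation dynamics)
```

with `Kp` in 1/rad, `Ki` in 1/(rad·ms), `Kd` in ms/rad.  The weights
`w_i` come from **spatial tuning patterns (STPs)**: per-muscle-group maps
of normalized EMG activity over a 26-direction grid (eight
flexion/extension–lateral-bending azimuths × three axial-rotation levels,
plus two pure axial rotations), merged from heterogeneous experimental
sources by priority (dynamic+MVIC > dynamic > isometric), mirrored from
right to left, and normalized per direction.

Gain tuning uses the sequential response surface method (SRSM) with domain
reduction: 7 D-optimally selected designs per iteration, a linear
metamodel, region panning and zooming, a 99 % activity constraint whose
response is penalized by saturation duration, and a curve-mapping
discrepancy between simulated and reference displacement histories as the
objective.  The Ziegler–Nichols step-response relation `Ki = Kp²/(4·Kd)`
derives the integral-gain ceiling from previously published controllers.

Rated outputs use a CORA-style score per channel (corridor containment +
shape/size/phase correlation, each in [0, 1]), composites weighted by the
reference peak magnitude, and an overall score averaging the translation
and rotation composites.

## Worked example

```bash
omnineck fixtures  --seed 7 --out runs
omnineck build-stp --sources runs/stp_sources.csv --out runs/stp.csv
omnineck simulate  --config braking.yaml --stp runs/stp.csv
omnineck rate      --sim braking/kinematics.csv --ref runs/corridor_braking.csv --out braking
```

with `braking.yaml`:

```yaml
maneuver: {kind: braking, peak: 11.0, duration: 2.5, settle: 0.25, loading: 2.25}
seed: 7
output_dir: braking
```

prints

```
channel scores:
  head_ry: 0.419 (poor)
  head_tx: 0.402 (poor)
  head_tz: 0.535 (poor)
translation composite 0.424, rotation composite 0.419, overall 0.421 (poor)
```

Each channel score is the CORA-style rating of one simulated head channel
against the synthetic volunteer-like corridor; the composites weight the
channels by the corridor peak magnitudes.  The untuned default gains rate
"poor" against corridors they were never tuned to — running `omnineck
tune` against the reference first and re-simulating with
`--gains tuned_gains.yaml` is the intended loop.

At the library level, the closed loop behaves physically:

```python
from omnineck.controller import ControllerConfig, ControllerGains
from omnineck.io_cli import StpFixtureSpec, generate_stp_fixture
from omnineck.plant import HeadNeckPlant, braking_pulse, simulate
from omnineck.stp import StpSet, combine_sources, default_registry, normalize_per_direction

records = generate_stp_fixture(StpFixtureSpec(seed=1))
stps = normalize_per_direction(
    StpSet.from_right_patterns(combine_sources(records, default_registry()))
)
plant = HeadNeckPlant()
pulse = braking_pulse(11.0, 2.5, settle=0.25, loading=2.25)
cfg = ControllerConfig(mode="translational", baseline_scale=0.05)
off = simulate(plant, cfg, ControllerGains(0, 0, 0), stps, pulse)
on = simulate(plant, cfg, ControllerGains(0.8, 1e-5, 250.0), stps, pulse)
print(off.head_translation[:, 0].max())   # 0.0607  m, passive forward excursion
print(on.head_translation[:, 0].max())    # 0.0249  m, controller active
print(on.activations.max())               # 0.37    peak muscle activation
```

In an 11 m/s² braking pulse the active controller roughly halves the
forward head excursion at sub-maximal muscle activity.

The surrogate plant is a single rigid head on a spring–damper neck with
point-to-point muscle elements (defaults: head mass 4.5 kg, human-scale
inertia, CoG 2 cm anterior of the atlanto-occipital joint, stiffnesses
documented in `HeadNeckPlant`).  It reproduces the qualitative physics the
controllers need — gravity bias, excursion under pulses, load-sharing
direction — and is *not* a finite-element human body model; all
closed-loop expectations against it are property-based.

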