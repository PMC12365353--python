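# peristalsim

A 1-D mathematical model of human oesophageal motility, built for
computational physiologists and motility researchers who want to study how
normal peristalsis — and each Chicago-classification motility disorder —
emerges from the interplay of the central command, the enteric nervous
system (ENS) and the smooth muscle.

## The model

The oesophagus is a line segment (oral → anal) carrying three fields: the
ENS activity *U*, its recovery variable *V*, and the muscle activation *W*.
The neural layer is a modified FitzHugh–Nagumo system, coupled **nonlocally**
through two box-shaped convolution kernels instead of a diffusion term:

```
∂U/∂t = −10 ( U (U − T_ENS A_ENS)(U − 2 A_ENS) + 0.5 V ) + (K_IN ∗ U) + S_CNS(x,t)
∂V/∂t = max(U, 0) − D_ENS(x) V
∂W/∂t = E_SM U − D_SM W + B_SM + (K_MN ∗ U) + W_PEP(x,t)
```

* `K_IN` — the **interneuron kernel**: amplitude `s_IN` on a box of radius
  `r_IN` shifted analward by `d_IN`.  The shift reflects the anatomical
  anal-side deviation of enteric interneuron projections and is what makes
  the contraction pulse travel one way: for `d_IN ≥ r_IN` no excitation can
  propagate oralward at all.
* `K_MN` — the **motoneuron kernel**: inhibitory amplitude `i_MN < 0` over
  `[0, r_MN)`, producing the dilatation band anal to the contraction (the
  "law of the intestine").
* `D_ENS(x)` is the spatial switch: `0.6` in the body makes each node
  **excitable** (one resting state); `100` in the distal sphincter segment
  makes it **bistable** (rest and tonically active states), so the lower
  oesophageal sphincter (LES) behaves as a toggle switch — contracted at
  rest, switched off by the swallow command, re-contracted by the arriving
  pulse.
* `S_CNS` is the swallow program: body/LES-wide inhibition at swallow onset
  (deglutitive inhibition) plus a delayed oral kick; `max(U, 0)` in the
  recovery source guarantees that releasing the inhibition never fires a
  rebound spike.
* `W_PEP` is an optional whole-body pressurization drive (pan-oesophageal
  pressurization in type II achalasia).

Integration is explicit Euler on a uniform grid (`dx = 0.1`, `dt = 0.01`,
nondimensional units throughout).  Muscle activity is rendered as clinical
high-resolution manometry (HRM): negative pressures are clipped and the
coordinate axis distal to the contractile deceleration point is rescaled so
the displayed pulse runs at half its model speed.

## A worked example

```
$ python examples/normal_swallow.py
normal single swallow
  pulse speed (body)   : 1.15 length/time
  IRP analogue         : 0.057 (relaxed)
  transmitted pulses   : 1
  peak contraction W   : 1.17
  classification       : normal
```

One swallow produces exactly one anally travelling contraction at speed
≈1.15 model-lengths per time unit; the integrated-relaxation-pressure
analogue (the minimum windowed LES mean of *W*) drops from the resting tone
≈1.7 to ≈0.06, i.e. the sphincter opens, and re-contracts with a small
overshoot once the pulse arrives.  The classifier, which sees only these
measurements, labels the run `normal`.

Other entry points, each a short narrative script under `examples/`:
phase-plane analysis (`phase_plane.py`), multiple rapid swallows
(`multiple_rapid_swallows.py`), the unidirectionality sweep
(`unidirectionality_sweep.py`), one disorder preset per Chicago label
(`disorder_catalogue.py`) and HRM/distension export (`hrm_export.py`).
The same functionality is exposed on the command line:

```
peristalsim list                  # all ~40 scenario presets
peristalsim run egjoo_icns --out out/
peristalsim phase --D 100 --T 0.3 --A 1
peristalsim sweep-din
peristalsim mrs --n 5 --interval 2
```

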