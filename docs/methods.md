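# Methods

## Model

One spatial dimension, `x ∈ [0, 10]` in nondimensional length units, oral →
anal; the lower oesophageal sphincter (LES) occupies `x ≥ 9`, and `x_cdp = 7`
marks the contractile deceleration point used only by the display transform.
Three fields evolve on the grid: enteric neural activity `U`, recovery `V`,
muscle activation `W`:

    dU/dt = −g ( U (U − T A)(U − 2A) + c V ) + (K_IN ∗ U) + S_CNS(x, t)
    dV/dt = max(U, 0) − D(x) V
    dW/dt = E U − D_SM W + B + (K_MN ∗ U) + W_PEP(x, t)

with fixed cubic gain `g = 10` and recovery coupling `c = 0.5`.  The
recovery variable *inhibits* the activity (the `+cV` inside the negated
bracket).  With the opposite sign the printed regime facts cannot hold: the
body at `D = 0.6` would acquire a second stable state and never repolarize,
and the sphincter's three-steady-state structure would not appear.  The
sign is kept as a single switchable constant (`RECOVERY_SIGN`) for
auditability.

The rectifier `max(U, 0)` in the recovery source removes post-inhibitory
rebound: during a purely negative stimulus `V` only decays, so releasing
the stimulus returns the node to rest without an excursion (verified as a
property test over stimulus amplitudes up to 30 and durations up to 3).

### Space-clamped structure

At a single node the equilibria are closed-form: `U* = 0` always, and
positive equilibria solve `(U − TA)(U − 2A) = −c/D` — a quadratic.  The
node is *bistable* iff that quadratic has two distinct positive roots,
i.e. `D > D* = 4c/(A(2 − T))²`.  With the canonical `T = 0.3`, `A = 1`:
`D* ≈ 0.692`; the body (`D = 0.6`) is excitable, the LES (`D = 100`)
bistable with equilibria `U* ≈ {0, 0.3029, 1.9971}` (stable, saddle,
stable).  A supra-threshold kick in the body produces an excursion peaking
near `2A` (measured 1.94 for a kick of 0.5).

### Nonlocal coupling

Both kernels are boxes.  The interneuron kernel has amplitude `s_IN` on
`[d_IN − r_IN, d_IN + r_IN)`; the motoneuron kernel has amplitude
`i_MN < 0` on `[0, r_MN)`.  Convolution is a Riemann sum with the `dx`
measure and zero padding outside the domain (nothing enters from pharynx or
stomach).  Kernels are sampled by **cell coverage**: each grid offset
represents a cell of width `dx` and carries the amplitude times its
fractional overlap with the box.  Interior weights equal the amplitude; the
two boundary cells carry partial weights.  This makes the discrete zeroth
and first moments exact and the dynamics second-order accurate in the
kernel sampling — with naive equal-weight sampling the effective kernel is
shifted by `dx/2` and the pulse speed changes by ~6–7% under grid halving,
versus ~2% with coverage weighting.  Coverage weighting preserves the exact
one-sidedness property: for `d_IN ≥ r_IN` every weighted offset is ≥ 0, so
a field supported anal of a node contributes exactly zero oral of it.

### Swallow program

Each swallow at onset `t0` applies `−i_amp` to the whole body and the LES
for 1 time unit (deglutitive inhibition) and `+s_amp = 1.5` to the oral-most
0.5 length units during `(t0+2, t0+2.5)`.  Two calibration facts fix these
numbers:

* Switching the bistable LES off requires the inhibition to exceed the
  saddle-node value `g·max(−cubic) ≈ 9.1` (at `T = 0.3`); `i_amp = 10.5`
  clears it with margin.  Lowering the LES threshold fraction *deepens* the
  on-state (the required inhibition grows towards ≈12 as `T → 0`), which is
  exactly why the "low LES T_ENS" preset produces relaxation failure.
* The kick delay equals the canonical 2-unit rapid-swallow interval, so
  during multiple rapid swallows the next swallow's body inhibition exactly
  covers the previous swallow's kick window and masks it; only the final,
  unmasked kick launches a pulse.  This masking, not pulse collision, is
  the mechanism behind the single transmitted pulse in the
  multiple-rapid-swallow protocol.

### Numerics

Explicit Euler, `dx = 0.1`, `dt = 0.01`, instability guard at |field| >
10³.  The analytic initial state (body at rest, LES at its local upper
equilibrium) ignores kernel contributions, which shift the true resting
state slightly (intra-LES excitation raises `U`; motoneuron inhibition
lowers anal-LES `W`).  `simulate` therefore relaxes the state for a
non-recorded 40-time-unit equilibration before `t = 0`; the recorded
zero-stimulus run is then stationary to 1e−6 over 10 units.  Halving both
`dx` and `dt` changes the measured normal pulse speed by ≈2%.

## Calibration

The canonical parameter set is a calibration, not a transcription:
`T_ENS = 0.3`, `A_ENS = 1` everywhere; `D_ENS` 0.6 (body) / 100 (LES);
`E_SM = D_SM = 1`, `B_SM = 0`; `s_IN = 1.0`, `r_IN = 0.5`, `d_IN = 0.5`;
`i_MN = −0.3`, `r_MN = 3`.  The kernel is deliberately short-range: with a
reach comparable to half the body length, propagation is all-or-nothing
ballistic (the whole body excites within one time unit and no localized
travelling pulse exists).  The chosen kernel yields a pulse of width ≈2.5
travelling at ≈1.2–1.5, crossing the body in ≈6 time units — the regime in
which rapid-swallow masking and the pressure-topography patterns are
meaningful.  `d_IN = r_IN` keeps the normal kernel exactly one-sided.

Near this calibration the propagation margins are thin and quantified:
transmission fails for body `T_ENS ≳ 0.315` (normal 0.3) or `s_IN ≲ 0.935`
(normal 1.0).  The stochastic "inefficient motility" protocols place the
per-swallow parameter mean just beyond these boundaries
(`T_ENS: +0.032 ± 0.012`, `s_IN: −0.08 ± 0.012`, one scalar draw per
swallow), so 80–100% of ten seeded swallows fail while the unshifted model
transmits reliably.

## Metrics and classification

Contraction pulses are tracked on `W` thresholded at half the normal-preset
peak; connected segments are linked across frames by largest interval
overlap.  Speed is the least-squares slope of the leading edge within
`x ∈ [2, 7]` (oral of the deceleration point, past the launch transient).
The IRP analogue is the minimum over 4 time units post-swallow of the LES
spatial mean of `W` (mirroring the 4-s clinical window), "relaxed" below
25% of resting tone.  A swallow is transmitted when one anal-direction
track runs from `x ≤ 1` to `x ≥ 8`; requiring birth in the oral half keeps
simultaneous whole-body pressurization from counting as peristalsis.
Premature means speed > 1.5× the normal reference; hypercontractile means
peak `W` > 1.5× or supra-threshold duration > 2× normal; the classifier is
a fixed first-match decision list over {impaired relaxation, transmitted,
premature, PEP, hypercontractile}.

Directionality after a point stimulus is judged on the neural field: a
direction counts as propagated when `U` exceeds 1.0 beyond 2 length units
from the stimulated patch — a verdict that remains well defined for
arbitrarily fast pulses (the muscle band lags `U` by its rise time and its
leading edge saturates at high speeds) and inherits the one-sided-kernel
invariant exactly.  The deviation sweep uses a stimulus of amplitude 3.0
and width 1.0 so ignition succeeds even when a one-sided kernel gives the
stimulated patch no recurrent excitation; the backward pulse disappears
from `d_IN = 1.5` (bound: 2.0, exact at `d_IN = r_IN = 2`).

## Speed surrogate

Taylor-expanding the convolution gives the local surrogate
`K∗U ≈ M0·U − M1·∂U/∂x + (M2/2)·∂²U/∂x²` with the box-kernel moments.  The
surrogate PDE (integrated explicitly with a step chosen below its
diffusive/advective stability limits) predicts the measured front speed to
3–7% in the wide-kernel regime (`r_IN = 2, d_IN = 2.5`), where the kernel
is broad relative to the front interface.  For the narrow calibrated normal
kernel the truncation overestimates the speed by roughly half again — the
front interface is as wide as the kernel and the parabolic diffusion term
leaks influence ahead of it — so the quantitative 20% agreement contract is
stated for the wide-kernel regime only.  Monotonicity of both predicted and
measured speeds in `s_IN`, `r_IN` and `d_IN` holds in both regimes.

## Disorder catalogue

Presets are documented multiples of the normal value (low = ×0.3, high =
×2) applied per region, with four deliberate exceptions: the premature
factors use ×1.6 (×2 impairs LES relaxation through the nonlocal coupling
and tips a spasm run into the type III achalasia pattern — the same
crossover the clinical taxonomy acknowledges); the hypercontractile
amplitude factor uses ×1.1 (the body crosses its bistability boundary at
`A ≈ 1.07·…1.15` and the contraction then never releases); the "high basal
LES drive" preset sets `B_SM = 2.0` absolutely (the normal basal drive is
zero, so a multiple is meaningless); and pan-oesophageal pressurization
uses amplitude 1.0 over `t ∈ (3, 8)`.

Three mechanisms cannot express their textbook pattern under this
calibration and carry their empirically verified labels plus a note in the
catalogue: high `d_IN` produces saltatory (spatially skipping) propagation
whose contraction band fragments, losing measurable transmission; lowering
body `T_ENS` accelerates the pulse but reaches the excitable/bistable
boundary (`T ≈ 0.174`) before the 1.5× premature criterion; raising
`A_ENS` is capped by the same bistability boundary before either
hypercontractile cutoff.  These are consequences of the short-range
calibrated kernel, not of the model structure.

## What the simulations do and do not show

All inputs are synthetic: the model reproduces the qualitative anatomy of
clinical pressure topography (one-way pulses, sphincter toggling,
deglutitive inhibition, the dilatation band, disorder patterns), in
dimensionless units with no physical calibration of cm, seconds or mmHg.
Passing tests demonstrate internal consistency and the claimed dynamical
mechanisms; they say nothing about fits to individual patient recordings,
intrabolus pressure, mechanical feedback from the muscle to the nerves, or
the skeletal-muscle upper oesophagus, none of which are modelled.
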