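"""Multiple rapid swallows: only the last stimulus becomes a pulse.

Five swallows arrive at 2-unit intervals.  Each swallow's body-wide
inhibition masks the previous swallow's oral kick, so the intermediate
stimuli launch nothing; only the final, unmasked kick produces a
travelling contraction, while the sphincter stays relaxed throughout —
the clinical multiple-rapid-swallows response.
"""

from peristalsim import default_spec, simulate
from peristalsim.metrics import default_threshold, les_relaxation_metric, transmitted_count
from peristalsim.scenarios import mrs_program

prog = mrs_program(n_swallows=5, interval=2.0)
spec = default_spec(program=prog, t_end=25.0)
result = simulate(spec, seed=0)
thr = default_threshold(spec)

print(f"swallow onsets : {[e.t0 for e in prog.events]}")
print(f"transmitted    : {transmitted_count(result, thr)}  (expected: 1, the last)")
for ev in prog.events:
    val, relaxed = les_relaxation_metric(result, ev.t0)
    print(f"  swallow t0={ev.t0:4.1f}: IRP analogue {val: .3f} "
          f"({'relaxed' if relaxed else 'impaired'})")
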