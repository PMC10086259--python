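"""Simulate one lateralized-ERP session and recover its transfer delay.

Builds a compact all-unilateral letter-matching session with a known
34 ms interhemispheric transfer time (IHTT), runs the full reduction
chain (filter, epoch, artifact control, average), extracts P1/N1 peak
latencies at the two occipital electrodes, and prints the recovered
indirect-minus-direct difference scores next to the injected truth.
"""

from ihtt.preprocess import preprocess_session
from ihtt.recovery import unilateral_task_config
from ihtt.scoring import score_session
from ihtt.simulate import SimulationParams, simulate_session
from ihtt.task import generate_schedule

cfg = unilateral_task_config(trials_per_block=40)
schedule = generate_schedule(cfg, seed=7)
params = SimulationParams(ihtt_ms=34.0, noise_rms_uv=5.0, accuracy_p=1.0,
                          seed=7)

recording, events, truth = simulate_session(params, schedule, task_config=cfg)
epochs, evokeds = preprocess_session(recording)
result = score_session(epochs, evokeds, events)

print(f"injected IHTT:        {truth.ihtt_ms:6.1f} ms")
print(f"recovered P1 IHTT:    {result.p1_ihtt_ms:6.1f} ms "
      f"(direct {result.direct_means['P1']:.1f}, "
      f"indirect {result.indirect_means['P1']:.1f})")
print(f"recovered N1 IHTT:    {result.n1_ihtt_ms:6.1f} ms "
      f"(direct {result.direct_means['N1']:.1f}, "
      f"indirect {result.indirect_means['N1']:.1f})")
print(f"residual noise (uV):  {result.qc['noise_rms']:6.2f}")
print(f"retained trials:      LVF {result.n_trials['LVF']}, "
      f"RVF {result.n_trials['RVF']}")
# The P1/N1 difference scores estimate the callosal transfer delay; with
# 5 uV noise and ~40 trials per field they land within a few ms of truth.
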