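"""End-to-end studies on synthetic cohorts.

These helpers run the full chain -- schedule, simulation, reduction,
scoring -- for a cohort with known ground truth, and summarize how well
the injected transfer delay is recovered and whether the manipulation
checks (direct vs indirect latency / response time) behave as expected.
They are the package's own validation instruments and power the worked
examples.

Study sizing: recovery runs use compact sessions (two 40-trial blocks
with letter pairs confined to the unilateral corner pairs, so each
visual-field cell holds about 40 trials) rather than the full 384-trial
task, which carries the same per-cell trial count into the analysis at a
fraction of the simulation cost.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .preprocess import RejectionThresholds, preprocess_session
from .scoring import compute_rt_difference, score_session
from .simulate import SimulationParams, simulate_behavior, simulate_session
from .stats import paired_t
from .task import TaskConfig, generate_schedule

__all__ = [
    "unilateral_task_config",
    "run_recovery_study",
    "rt_manipulation_check_rate",
]

#: Corner-pair weights that draw only the two unilateral pairs.
UNILATERAL_WEIGHTS = (0.5, 0.5, 0.0, 0.0, 0.0, 0.0)


def unilateral_task_config(
    n_blocks: int = 2, trials_per_block: int = 40
) -> TaskConfig:
    """A compact task whose trials are all unilateral (~half per field)."""
    return TaskConfig(
        n_blocks=n_blocks,
        trials_per_block=trials_per_block,
        n_practice=0,
        pair_weights=UNILATERAL_WEIGHTS,
    )


def run_recovery_study(
    n_participants: int = 40,
    ihtt_ms: float = 34.0,
    noise_rms_uv: float = 5.0,
    trials_per_cell: int = 40,
    between_sd_ihtt_ms: float = 0.0,
    seed: int = 0,
    thresholds: RejectionThresholds | None = None,
) -> pd.DataFrame:
    """Simulate and score ``n_participants`` single sessions.

    Each participant gets an IHTT of ``ihtt_ms`` (optionally jittered
    between participants, truncated at 1 ms), a compact all-unilateral
    schedule sized for ``trials_per_cell`` correct trials per visual
    field (accuracy is set to 1 so the cell counts are exact in
    expectation), and defaults otherwise. Returns one row per
    participant with true and recovered P1/N1 IHTT.
    """
    cfg = unilateral_task_config(trials_per_block=trials_per_cell)
    rng = np.random.default_rng(seed)
    rows = []
    for pid in range(n_participants):
        true_ihtt = ihtt_ms
        if between_sd_ihtt_ms > 0:
            true_ihtt = max(ihtt_ms + between_sd_ihtt_ms * rng.standard_normal(), 1.0)
        params = SimulationParams(
            ihtt_ms=float(true_ihtt),
            noise_rms_uv=noise_rms_uv,
            accuracy_p=1.0,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        schedule = generate_schedule(cfg, int(rng.integers(0, 2**31 - 1)))
        rec, events, truth = simulate_session(params, schedule, task_config=cfg)
        epochs, evokeds = preprocess_session(rec, thresholds)
        res = score_session(epochs, evokeds, events, participant=pid)
        rows.append({
            "participant": pid,
            "true_ihtt_ms": truth.ihtt_ms,
            "p1_ihtt_ms": res.p1_ihtt_ms,
            "n1_ihtt_ms": res.n1_ihtt_ms,
            "p1_direct_ms": res.direct_means.get("P1"),
            "p1_indirect_ms": res.indirect_means.get("P1"),
            "n1_direct_ms": res.direct_means.get("N1"),
            "n1_indirect_ms": res.indirect_means.get("N1"),
            "noise_rms": res.qc["noise_rms"],
        })
    return pd.DataFrame(rows)


def rt_manipulation_check_rate(
    n_participants: int = 20,
    n_replicates: int = 20,
    delta_ms: float = 4.0,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Rejection rate of the behavioral (RT) manipulation check.

    Each replicate simulates ``n_participants`` behavioral sessions on
    the full 384-trial task (responses only; no EEG), computes each
    participant's direct and indirect mean correct RT, and runs the
    paired t-test. With a small crossed-uncrossed delay and realistic
    ex-Gaussian RT noise this check is underpowered, so it should fail
    to reject most of the time.
    """
    cfg = TaskConfig()
    rng = np.random.default_rng(seed)
    rejections = 0
    last = None
    for _ in range(n_replicates):
        direct, indirect = [], []
        for _ in range(n_participants):
            params = SimulationParams(
                rt_crossed_uncrossed_delta_ms=delta_ms,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            schedule = generate_schedule(cfg, int(rng.integers(0, 2**31 - 1)))
            behavior = simulate_behavior(
                schedule, params, np.random.default_rng(params.seed)
            )
            rt = compute_rt_difference(behavior)
            direct.append(rt["pathway_means"]["direct"])
            indirect.append(rt["pathway_means"]["indirect"])
        last = paired_t(direct, indirect, label="RT direct vs indirect")
        if last.p < alpha:
            rejections += 1
    return {
        "reject_rate": rejections / n_replicates,
        "n_replicates": n_replicates,
        "last_result": last,
    }
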