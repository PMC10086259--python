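"""Synthetic lateralized-ERP sessions with known ground truth.

A session is a continuous 128-channel, 1 kHz recording in which every
unilateral trial evokes a P1 (positive) and N1 (negative) component over
the occipital cortex contralateral to the stimulated hemifield, and the
same components delayed by the interhemispheric transfer time (IHTT) and
attenuated over the ipsilateral cortex. On top of the evoked activity the
generator adds 1/f + white instrument noise, Poisson blink artifacts with
a frontal periocular topography, optionally misbehaving ("bad") channels,
and ex-Gaussian response times with a crossed-uncrossed (indirect minus
direct) offset. Everything is reproducible from a seed, and the injected
quantities are returned as ground truth for parameter-recovery tests.

Components are Gaussian bumps; ``component_width_ms`` is the full width
at half maximum. Scalp patterns are hemisphere-confined and sum to zero
across scalp channels, so average referencing leaves evoked peak
latencies untouched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from .montage import EVENT_COLUMNS, ChannelMontage, ContinuousRecording, load_montage
from .task import TaskConfig, TrialSpec, generate_schedule, label_rt_pathway
from .windows import EPOCH_START_MS, EPOCH_STOP_MS, SFREQ_HZ, epoch_times_ms

__all__ = [
    "SimulationParams",
    "GroundTruth",
    "SessionSpec",
    "erp_kernel",
    "component_patterns",
    "blink_pattern",
    "simulate_behavior",
    "simulate_session",
    "simulate_cohort",
]

_FWHM_TO_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass
class SimulationParams:
    """Ground-truth parameters of a simulated session.

    Latency/amplitude defaults follow typical direct-pathway P1/N1 values
    in lateralized letter-matching data (P1 near 95 ms, N1 near 165 ms)
    with a 34 ms transfer delay; response times are ex-Gaussian with a
    small crossed-uncrossed offset. ``trial_latency_jitter_ms`` and
    ``trial_amplitude_cv`` default to 0 (single-trial variability in real
    data is unknown; both are exposed for experimentation).
    """

    p1_latency_ms: float = 95.0
    n1_latency_ms: float = 165.0
    ihtt_ms: float = 34.0
    p1_amplitude_uv: float = 4.0
    n1_amplitude_uv: float = -6.0
    ipsilateral_gain: float = 0.8
    component_width_ms: float = 25.0  # FWHM
    noise_rms_uv: float = 5.0
    noise_spectrum: str = "mix"  # white | pink | mix
    pink_slope: float = 1.0
    blink_rate_hz: float = 0.1
    blink_amplitude_uv: float = 120.0
    blink_duration_ms: float = 300.0
    bad_channel_indices: tuple[int, ...] = ()
    bad_channel_rms_uv: float = 25.0
    rt_exgauss: dict = field(default_factory=lambda: {
        "mu_ms": 600.0, "sigma_ms": 60.0, "tau_ms": 100.0,
    })
    rt_crossed_uncrossed_delta_ms: float = 4.0
    accuracy_p: float = 0.9
    trial_latency_jitter_ms: float = 0.0
    trial_amplitude_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.component_width_ms <= 0:
            raise ValueError("component_width_ms must be > 0")
        if min(self.noise_rms_uv, self.blink_rate_hz, self.bad_channel_rms_uv) < 0:
            raise ValueError("rates and RMS levels must be >= 0")
        if not 0.0 <= self.accuracy_p <= 1.0:
            raise ValueError("accuracy_p must be in [0, 1]")
        if not (self.p1_amplitude_uv > 0 > self.n1_amplitude_uv):
            raise ValueError("require p1_amplitude_uv > 0 > n1_amplitude_uv")
        if self.noise_spectrum not in ("white", "pink", "mix"):
            raise ValueError(f"unknown noise_spectrum {self.noise_spectrum!r}")


@dataclass
class GroundTruth:
    """Injected quantities of one simulated session."""

    ihtt_ms: float
    delta_ms: float
    trial_latencies: pd.DataFrame  # per unilateral trial: contra/ipsi P1 & N1
    blink_times_s: np.ndarray
    bad_channels: tuple[int, ...]
    params: SimulationParams


# -- building blocks -------------------------------------------------------

def erp_kernel(
    component: str,
    latency_ms: float,
    amplitude_uv: float,
    width_ms: float,
    times_ms: np.ndarray | None = None,
) -> np.ndarray:
    """Gaussian ERP component over the epoch grid.

    The extremum sits exactly at ``latency_ms`` on the 1 kHz grid (the
    latency is snapped to the grid) with value ``amplitude_uv``;
    ``width_ms`` is the FWHM.
    """
    if width_ms <= 0:
        raise ValueError("width_ms must be > 0")
    if component == "P1":
        if amplitude_uv <= 0:
            raise ValueError("P1 amplitude must be positive")
    elif component == "N1":
        if amplitude_uv >= 0:
            raise ValueError("N1 amplitude must be negative")
    else:
        raise ValueError(f"unknown component {component!r}")
    if times_ms is None:
        times_ms = epoch_times_ms()
    if not (times_ms[0] <= latency_ms <= times_ms[-1]):
        raise ValueError(f"latency {latency_ms} ms outside the epoch window")
    step = times_ms[1] - times_ms[0]
    latency_ms = times_ms[0] + round((latency_ms - times_ms[0]) / step) * step
    sigma = width_ms / _FWHM_TO_SIGMA
    return amplitude_uv * np.exp(-0.5 * ((times_ms - latency_ms) / sigma) ** 2)


def component_patterns(
    montage: ChannelMontage, spread_rad: float = 0.45
) -> dict[str, np.ndarray]:
    """Occipital scalp patterns for the left and right hemisphere sources.

    Each pattern is a Gaussian (in great-circle distance) around the ROI
    electrode, confined to that hemisphere's scalp channels, shifted to
    sum to zero over scalp channels and scaled to 1 at the ROI electrode.
    The zero-sum makes average referencing exactly latency-preserving.
    """
    out = {}
    for side, roi_index in (("left", montage.left_occipital),
                            ("right", montage.right_occipital)):
        pat = np.zeros(montage.n_channels)
        roi_pos = montage.positions[montage.row(roi_index)]
        sign = -1.0 if side == "left" else 1.0
        support = [
            r for r in montage.scalp_rows
            if sign * montage.positions[r, 0] > 0
        ]
        d = np.arccos(np.clip(montage.positions[support] @ roi_pos, -1, 1))
        w = np.exp(-0.5 * (d / spread_rad) ** 2)
        w = w - w.mean()  # zero-sum over its support (hence over the scalp)
        pat[support] = w
        pat /= pat[montage.row(roi_index)]
        out[side] = pat
    return out


def blink_pattern(
    montage: ChannelMontage, spread_rad: float = 0.55, anterior_shift: float = 0.0
) -> np.ndarray:
    """Frontal rank-1 blink topography, maximal at the eye channels,
    normalized to peak 1."""
    eye_pos = montage.positions[montage.eye_rows].mean(axis=0)
    eye_pos = eye_pos + anterior_shift * np.array([0.0, 1.0, 0.0])
    eye_pos /= np.linalg.norm(eye_pos)
    d = np.arccos(np.clip(montage.positions @ eye_pos, -1, 1))
    pat = np.exp(-0.5 * (d / spread_rad) ** 2)
    return pat / pat.max()


def _noise(
    rng: np.random.Generator,
    n_channels: int,
    n_samples: int,
    rms_uv: float,
    spectrum: str,
    pink_slope: float,
) -> np.ndarray:
    if rms_uv == 0:
        return np.zeros((n_channels, n_samples), dtype=np.float32)
    from scipy import fft as sfft

    def white():
        return rng.standard_normal((n_channels, n_samples)).astype(np.float32)

    def pink():
        w = rng.standard_normal((n_channels, n_samples)).astype(np.float32)
        spec = sfft.rfft(w, axis=1)
        f = sfft.rfftfreq(n_samples, d=1.0 / SFREQ_HZ)
        gain = np.zeros_like(f, dtype=np.float32)
        gain[1:] = f[1:] ** np.float32(-pink_slope / 2.0)
        x = sfft.irfft(spec * gain, n=n_samples, axis=1)
        x /= x.std()  # unit RMS overall; per-channel spread is physiological
        return x

    if spectrum == "white":
        out = white()
    elif spectrum == "pink":
        out = pink()
    else:  # mix: equal power split
        out = (white() + pink()) / np.float32(math.sqrt(2.0))
    return out * np.float32(rms_uv)


def _exgauss(rng: np.random.Generator, n: int, mu: float, sigma: float, tau: float):
    return mu + sigma * rng.standard_normal(n) + rng.exponential(tau, size=n)


def simulate_behavior(
    schedule: list[TrialSpec], params: SimulationParams, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw responses and ex-Gaussian response times for a schedule.

    Unilateral trials whose visual-field x assigned-hand combination is
    *indirect* receive the crossed-uncrossed delay on top of the
    ex-Gaussian base; correctness is Bernoulli(``accuracy_p``).
    Returns a partial event table (no onsets).
    """
    ex = params.rt_exgauss
    rows = []
    for t in schedule:
        rt = float(_exgauss(rng, 1, ex["mu_ms"], ex["sigma_ms"], ex["tau_ms"])[0])
        vf = t.visual_field
        if vf in ("LVF", "RVF"):
            if label_rt_pathway(vf, t.assigned_hand) == "indirect":
                rt += params.rt_crossed_uncrossed_delta_ms
        rt = max(rt, 150.0)
        correct = bool(rng.random() < params.accuracy_p)
        truth = "match" if t.match else "nonmatch"
        other = "nonmatch" if t.match else "match"
        rows.append({
            "trial_id": t.trial_id,
            "block": t.block,
            "visual_field": vf,
            "match": t.match,
            "response_hand": t.assigned_hand,
            "response": truth if correct else other,
            "rt_ms": round(rt, 1),
            "correct": correct,
        })
    return pd.DataFrame(rows)


def _onsets(schedule, config: TaskConfig, rng) -> np.ndarray:
    lead_in_ms = 1000.0
    t = lead_in_ms
    onsets = []
    lo, hi = config.iti_range_ms
    for _ in schedule:
        t += config.fixation_ms
        onsets.append(t)
        t += config.stimulus_ms + rng.uniform(lo, hi)
    return np.asarray(onsets)


def simulate_session(
    params: SimulationParams,
    schedule: list[TrialSpec],
    montage: ChannelMontage | None = None,
    task_config: TaskConfig | None = None,
    seed: int | None = None,
) -> tuple[ContinuousRecording, pd.DataFrame, GroundTruth]:
    """Simulate one continuous recording plus behavior for a schedule.

    For each unilateral trial the contralateral occipital pattern carries
    the P1/N1 kernels at their nominal latencies and the ipsilateral
    pattern carries them delayed by ``ihtt_ms`` and scaled by
    ``ipsilateral_gain``. Bilateral trials evoke both hemispheres at the
    nominal latencies with no delay. Injected latencies are snapped to
    the 1 ms grid and recorded in the returned :class:`GroundTruth`.
    """
    if not schedule:
        raise ValueError("schedule must be non-empty")
    montage = montage or load_montage()
    task_config = task_config or TaskConfig()
    bad = tuple(int(i) for i in params.bad_channel_indices)
    for i in bad:
        if int(i) not in montage.indices:
            raise ValueError(f"bad channel {i} not in montage")
    rng = np.random.default_rng(params.seed if seed is None else seed)

    onsets_ms = _onsets(schedule, task_config, rng)
    dur_ms = onsets_ms[-1] + EPOCH_STOP_MS + 1000.0
    n_samples = int(math.ceil(dur_ms / 1000.0)) * int(SFREQ_HZ)
    n_ch = montage.n_channels

    data = _noise(rng, n_ch, n_samples, params.noise_rms_uv,
                  params.noise_spectrum, params.pink_slope)

    # evoked activity ------------------------------------------------------
    pats = component_patterns(montage)
    times = epoch_times_ms()
    e0 = int(EPOCH_START_MS)  # sample offset of epoch start relative to onset
    lat_rows = []
    for t, onset_ms in zip(schedule, onsets_ms):
        vf = t.visual_field
        onset = int(round(onset_ms))
        jit = params.trial_latency_jitter_ms
        amp = 1.0 + params.trial_amplitude_cv * rng.standard_normal()
        p1 = params.p1_latency_ms + (jit * rng.standard_normal() if jit else 0.0)
        n1 = params.n1_latency_ms + (jit * rng.standard_normal() if jit else 0.0)
        p1, n1 = round(p1), round(n1)
        if vf == "bilateral":
            wave = (erp_kernel("P1", p1, params.p1_amplitude_uv, params.component_width_ms, times)
                    + erp_kernel("N1", n1, params.n1_amplitude_uv, params.component_width_ms, times))
            contrib = np.outer(pats["left"] + pats["right"], amp * wave)
            sl = slice(onset + e0, onset + e0 + len(times))
            data[:, sl] += contrib.astype(np.float32)
            continue
        contra = "right" if vf == "LVF" else "left"
        ipsi = "left" if vf == "LVF" else "right"
        p1_i = round(p1 + params.ihtt_ms)
        n1_i = round(n1 + params.ihtt_ms)
        g = params.ipsilateral_gain
        wave_c = (erp_kernel("P1", p1, params.p1_amplitude_uv, params.component_width_ms, times)
                  + erp_kernel("N1", n1, params.n1_amplitude_uv, params.component_width_ms, times))
        wave_i = (erp_kernel("P1", p1_i, g * params.p1_amplitude_uv, params.component_width_ms, times)
                  + erp_kernel("N1", n1_i, g * params.n1_amplitude_uv, params.component_width_ms, times))
        contrib = np.outer(pats[contra], amp * wave_c) + np.outer(pats[ipsi], amp * wave_i)
        sl = slice(onset + e0, onset + e0 + len(times))
        data[:, sl] += contrib.astype(np.float32)
        lat_rows.append({
            "trial_id": t.trial_id, "visual_field": vf,
            "p1_contra_ms": p1, "n1_contra_ms": n1,
            "p1_ipsi_ms": p1_i, "n1_ipsi_ms": n1_i,
        })

    # blink artifacts ------------------------------------------------------
    duration_s = n_samples / SFREQ_HZ
    n_blinks = rng.poisson(params.blink_rate_hz * duration_s)
    blink_times = np.sort(rng.uniform(0, duration_s, size=n_blinks))
    if n_blinks:
        bpat = blink_pattern(montage) * params.blink_amplitude_uv
        blen = int(params.blink_duration_ms)
        course = np.hanning(blen).astype(np.float32)
        for bt in blink_times:
            s0 = int(bt * SFREQ_HZ)
            s1 = min(s0 + blen, n_samples)
            data[:, s0:s1] += np.outer(bpat, course[: s1 - s0]).astype(np.float32)

    # bad channels: large narrowband (8-12 Hz) oscillatory contamination
    if bad:
        sos = sps.butter(4, [8, 12], btype="bandpass", fs=SFREQ_HZ, output="sos")
        for i in bad:
            osc = sps.sosfilt(sos, rng.standard_normal(n_samples))
            osc *= params.bad_channel_rms_uv / osc.std()
            data[montage.row(i)] += osc.astype(np.float32)

    # behavior -------------------------------------------------------------
    behavior = simulate_behavior(schedule, params, rng)
    events = behavior.copy()
    events.insert(1, "onset_sample", [int(round(o)) for o in onsets_ms])
    events = events[EVENT_COLUMNS]

    rec = ContinuousRecording(
        data=data, sampling_rate_hz=SFREQ_HZ, montage=montage, events=events
    )
    truth = GroundTruth(
        ihtt_ms=float(params.ihtt_ms),
        delta_ms=float(params.rt_crossed_uncrossed_delta_ms),
        trial_latencies=pd.DataFrame(lat_rows),
        blink_times_s=blink_times,
        bad_channels=bad,
        params=params,
    )
    return rec, events, truth


# -- cohorts ---------------------------------------------------------------

DEFAULT_BETWEEN_SD = {
    "ihtt_ms": 8.0,
    "delta_ms": 3.0,
    "p1_latency_ms": 10.0,
    "n1_latency_ms": 10.0,
    "mu_ms": 60.0,
}


@dataclass
class SessionSpec:
    """One participant x session cell of a simulated cohort.

    ``params`` holds the concrete per-session ground truth;
    ``simulate()`` materializes the recording.
    """

    participant: int
    group: str  # "concussion" | "control"
    session: int  # 1 | 2
    params: SimulationParams
    seed: int

    def simulate(self, montage=None, task_config=None, schedule=None):
        sched_seed = self.seed ^ 0x5EED
        if schedule is None:
            schedule = generate_schedule(task_config or TaskConfig(), sched_seed)
        return simulate_session(self.params, schedule, montage=montage,
                                task_config=task_config, seed=self.seed)


def simulate_cohort(
    n_per_group: int,
    params: SimulationParams | None = None,
    group_effect_ihtt_ms: float = 0.0,
    group_effect_delta_ms: float = 0.0,
    test_retest_rho: float = 0.3,
    between_sd: dict | None = None,
    seed: int = 0,
) -> list[SessionSpec]:
    """Draw a two-group x two-session cohort of session specifications.

    Participant-level parameters are jittered with between-subject SDs
    (``between_sd``); the concussion group additionally receives
    ``group_effect_ihtt_ms`` / ``group_effect_delta_ms``. Session values
    share a participant-level component so that repeated measures
    correlate at ``test_retest_rho``. Only parameter sets are returned;
    EEG is materialized lazily via :meth:`SessionSpec.simulate`.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    if not -1.0 < test_retest_rho < 1.0:
        raise ValueError("|test_retest_rho| must be < 1")
    params = params or SimulationParams()
    sd = dict(DEFAULT_BETWEEN_SD)
    if between_sd:
        sd.update(between_sd)
    rng = np.random.default_rng(seed)
    a, b = math.sqrt(max(test_retest_rho, 0.0)), math.sqrt(1 - max(test_retest_rho, 0.0))

    def draw(mean, s):
        zp = rng.standard_normal()
        return [mean + s * (a * zp + b * rng.standard_normal()) for _ in (1, 2)]

    specs: list[SessionSpec] = []
    pid = 0
    for group in ("concussion", "control"):
        eff_i = group_effect_ihtt_ms if group == "concussion" else 0.0
        eff_d = group_effect_delta_ms if group == "concussion" else 0.0
        for _ in range(n_per_group):
            pid += 1
            ihtt = draw(params.ihtt_ms + eff_i, sd["ihtt_ms"])
            delta = draw(params.rt_crossed_uncrossed_delta_ms + eff_d, sd["delta_ms"])
            p1 = draw(params.p1_latency_ms, sd["p1_latency_ms"])
            n1 = draw(params.n1_latency_ms, sd["n1_latency_ms"])
            mu = draw(params.rt_exgauss["mu_ms"], sd["mu_ms"])
            for s in (1, 2):
                p1_s = float(np.clip(p1[s - 1], 60.0, 140.0))
                n1_s = float(np.clip(n1[s - 1], p1_s + 45.0, 230.0))
                p = replace(
                    params,
                    ihtt_ms=float(max(ihtt[s - 1], 1.0)),
                    rt_crossed_uncrossed_delta_ms=float(delta[s - 1]),
                    p1_latency_ms=p1_s,
                    n1_latency_ms=n1_s,
                    rt_exgauss={**params.rt_exgauss,
                                "mu_ms": float(max(mu[s - 1], 250.0))},
                )
                specs.append(SessionSpec(
                    participant=pid, group=group, session=s, params=p,
                    seed=int(rng.integers(0, 2**31 - 1)),
                ))
    return specs
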