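"""P1/N1 peak-latency extraction and interhemispheric transfer scores.

The IHTT of a component is the mean of the two indirect-pathway peak
latencies (stimulated field -> ipsilateral occipital electrode) minus the
mean of the two direct-pathway latencies (stimulated field ->
contralateral electrode). The behavioral analogue is the indirect minus
direct mean response time over correct unilateral trials. Participant
data are excluded for physiologically improbable negative ERP IHTT,
excess residual noise, insufficient trials per cell, or failed
performance validity (TOMM/RDS rule).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import EpochSet, EvokedWaveform, RejectionThresholds
from .task import label_erp_pathway, label_rt_pathway
from .windows import N1_WINDOW_MS, P1_WINDOW_MS, WINDOW_CLAMP_MS, WINDOW_STEP_MS

__all__ = [
    "PeakMeasurement",
    "IHTTResult",
    "ValidityScores",
    "detect_peak",
    "compute_erp_ihtt",
    "compute_rt_difference",
    "score_session",
    "participant_qc",
]

_DEFAULT_WINDOWS = {"P1": P1_WINDOW_MS, "N1": N1_WINDOW_MS}


@dataclass
class PeakMeasurement:
    """One component peak on one electrode for one visual field."""

    component: str
    electrode: int
    visual_field: str
    latency_ms: float
    amplitude_uv: float
    search_window_ms: tuple[float, float]
    window_adjusted: bool


@dataclass
class ValidityScores:
    """Performance-validity indicators.

    ``tomm_trial_scores`` are the administered TOMM recognition-trial
    scores in order (0-50 each; if the first is >= 45 later trials are
    typically not administered). ``rds`` is the Reliable Digit Span.
    """

    tomm_trial_scores: tuple[int, ...]
    rds: int
    brief_t_scores: dict = field(default_factory=dict)
    impact_total_symptom: float | None = None

    def __post_init__(self) -> None:
        if any(not 0 <= s <= 50 for s in self.tomm_trial_scores):
            raise ValueError("TOMM trial scores must be in [0, 50]")
        if self.rds < 0:
            raise ValueError("rds must be >= 0")


@dataclass
class IHTTResult:
    """Per participant x session transfer-time summary and QC flags."""

    participant: int | str
    session: int
    p1_ihtt_ms: float | None = None
    n1_ihtt_ms: float | None = None
    rt_diff_ms: float | None = None
    direct_means: dict = field(default_factory=dict)
    indirect_means: dict = field(default_factory=dict)
    accuracies: dict = field(default_factory=dict)
    n_trials: dict = field(default_factory=dict)
    qc: dict = field(default_factory=lambda: {
        "noise_rms": None,
        "validity_ok": True,
        "negative_ihtt": {},
        "usable": True,
        "reasons": [],
    })


def detect_peak(
    evoked: EvokedWaveform, component: str, electrode: int
) -> PeakMeasurement:
    """Locate the P1 (most positive) or N1 (most negative) peak.

    The extremum is searched on the 1 ms grid within the component's
    default window, ties broken by the earliest latency. If the extremum
    lands on a window boundary, the window is widened symmetrically in
    25 ms steps (clamped to [0, 350] ms) until the extremum is interior
    or the clamp is reached; any widening sets ``window_adjusted`` (the
    automated analogue of per-waveform visual inspection).
    """
    if not evoked.usable:
        raise ValueError("evoked waveform is not usable (too few trials)")
    if component not in _DEFAULT_WINDOWS:
        raise ValueError(f"unknown component {component!r}")
    row = evoked.montage.row(electrode)
    wave = evoked.data[row]
    times = evoked.times_ms
    lo, hi = _DEFAULT_WINDOWS[component]
    clamp_lo, clamp_hi = WINDOW_CLAMP_MS
    adjusted = False
    while True:
        mask = (times >= lo) & (times <= hi)
        seg = wave[mask]
        seg_t = times[mask]
        if np.ptp(seg) == 0:  # flat: tie broken to window start, no adjustment
            return PeakMeasurement(component, int(electrode), evoked.condition,
                                   float(seg_t[0]), float(seg[0]), (lo, hi), adjusted)
        k = int(np.argmax(seg) if component == "P1" else np.argmin(seg))
        can_widen = (k == 0 and lo > clamp_lo) or (
            k == len(seg) - 1 and hi < clamp_hi
        )
        if not can_widen:
            return PeakMeasurement(component, int(electrode), evoked.condition,
                                   float(seg_t[k]), float(seg[k]), (lo, hi), adjusted)
        lo = max(lo - WINDOW_STEP_MS, clamp_lo)
        hi = min(hi + WINDOW_STEP_MS, clamp_hi)
        adjusted = True


def compute_erp_ihtt(peaks: list[PeakMeasurement]) -> float:
    """IHTT of one component: mean(indirect) - mean(direct) latency.

    Expects the four cells of that component (2 visual fields x 2 ROI
    electrodes).
    """
    if len(peaks) != 4:
        raise ValueError(f"need the 4 field x electrode cells, got {len(peaks)}")
    comp = {p.component for p in peaks}
    if len(comp) != 1:
        raise ValueError(f"mixed components {comp}")
    by_path: dict[str, list[float]] = {"direct": [], "indirect": []}
    seen = set()
    for p in peaks:
        key = (p.visual_field, p.electrode)
        if key in seen:
            raise ValueError(f"duplicate cell {key}")
        seen.add(key)
        by_path[label_erp_pathway(p.visual_field, p.electrode)].append(p.latency_ms)
    if len(by_path["direct"]) != 2 or len(by_path["indirect"]) != 2:
        raise ValueError("need two direct and two indirect cells")
    return float(np.mean(by_path["indirect"]) - np.mean(by_path["direct"]))


def compute_rt_difference(events: pd.DataFrame) -> dict:
    """Indirect minus direct mean response time over correct unilateral
    trials, with per-pathway means, trial counts, and accuracies."""
    uni = events[(events["visual_field"].isin(["LVF", "RVF"]))
                 & (events["block"] > 0)].copy()
    if not len(uni):
        raise ValueError("no unilateral trials")
    uni["pathway"] = [
        label_rt_pathway(vf, hand)
        for vf, hand in zip(uni["visual_field"], uni["response_hand"])
    ]
    out: dict = {"pathway_means": {}, "pathway_accuracy": {}, "n_trials": {}}
    for path in ("direct", "indirect"):
        sub = uni[uni["pathway"] == path]
        corr = sub[sub["correct"].astype(bool)]
        if not len(corr):
            raise ValueError(f"no correct trials on the {path} pathway")
        out["pathway_means"][path] = float(corr["rt_ms"].mean())
        out["pathway_accuracy"][path] = float(sub["correct"].astype(bool).mean())
        out["n_trials"][path] = int(len(corr))
    out["rt_diff_ms"] = (
        out["pathway_means"]["indirect"] - out["pathway_means"]["direct"]
    )
    return out


def score_session(
    epochs: EpochSet,
    evokeds: dict[str, EvokedWaveform],
    events: pd.DataFrame,
    participant: int | str = 0,
    session: int = 1,
    thresholds: RejectionThresholds | None = None,
) -> IHTTResult:
    """Score one preprocessed session into an :class:`IHTTResult`."""
    thresholds = thresholds or RejectionThresholds()
    montage = epochs.montage
    res = IHTTResult(participant=participant, session=session)
    electrodes = (montage.left_occipital, montage.right_occipital)

    for comp in ("P1", "N1"):
        peaks = []
        ok = True
        for vf in ("LVF", "RVF"):
            ev = evokeds.get(vf)
            if ev is None or not ev.usable:
                ok = False
                break
            for el in electrodes:
                peaks.append(detect_peak(ev, comp, el))
        if not ok:
            res.qc["reasons"].append(f"{comp}: missing or unusable cell")
            continue
        setattr(res, comp.lower() + "_ihtt_ms", compute_erp_ihtt(peaks))
        for path, target in (("direct", res.direct_means),
                             ("indirect", res.indirect_means)):
            lats = [p.latency_ms for p in peaks
                    if label_erp_pathway(p.visual_field, p.electrode) == path]
            target[comp] = float(np.mean(lats))

    rt = compute_rt_difference(events)
    res.rt_diff_ms = rt["rt_diff_ms"]
    res.direct_means["RT"] = rt["pathway_means"]["direct"]
    res.indirect_means["RT"] = rt["pathway_means"]["indirect"]
    res.accuracies = rt["pathway_accuracy"]
    res.n_trials = {
        **{f"rt_{k}": v for k, v in rt["n_trials"].items()},
        **{vf: ev.n_trials for vf, ev in evokeds.items()},
    }
    noises = [ev.noise_rms for ev in evokeds.values() if np.isfinite(ev.noise_rms)]
    res.qc["noise_rms"] = float(np.mean(noises)) if noises else None
    return res


def participant_qc(
    result: IHTTResult,
    validity: ValidityScores | None = None,
    thresholds: RejectionThresholds | None = None,
) -> IHTTResult:
    """Apply the participant-level exclusion rules, updating ``result.qc``.

    Unusable if: (a) P1 or N1 IHTT is negative (physiologically
    improbable; flagged per component), (b) residual noise exceeds
    ``noise_rms_max``, (c) performance validity fails (all administered
    of the first two TOMM recognition trials < 45 AND RDS <= 6), or
    (d) any required cell is below ``min_trials_per_cell``. A negative
    RT difference alone never excludes.
    """
    thresholds = thresholds or RejectionThresholds()
    qc = result.qc
    qc["negative_ihtt"] = {}
    for comp in ("P1", "N1"):
        val = getattr(result, comp.lower() + "_ihtt_ms")
        if val is not None and val < 0:
            qc["negative_ihtt"][comp] = val
            qc["reasons"].append(f"negative {comp} IHTT ({val:.1f} ms)")
    noise = qc.get("noise_rms")
    noise_bad = noise is not None and noise > thresholds.noise_rms_max
    if noise_bad:
        qc["reasons"].append(f"noise_rms {noise:.1f} > {thresholds.noise_rms_max}")
    validity_ok = True
    if validity is not None:
        first_two = validity.tomm_trial_scores[:2]
        tomm_fail = len(first_two) > 0 and all(s < 45 for s in first_two)
        validity_ok = not (tomm_fail and validity.rds <= 6)
    qc["validity_ok"] = validity_ok
    if not validity_ok:
        qc["reasons"].append("performance validity invalid (TOMM+RDS)")
    low_cells = {
        k: v for k, v in result.n_trials.items()
        if v < thresholds.min_trials_per_cell
    }
    if low_cells:
        qc["reasons"].append(f"cells below trial floor: {low_cells}")
    qc["usable"] = not (
        bool(qc["negative_ihtt"]) or noise_bad or not validity_ok or bool(low_cells)
    )
    return result
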