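"""Data model and file I/O for recordings, events, and the 128-channel montage.

The montage is an approximate equidistant spherical layout of 128 scalp
electrodes (unit-sphere positions; x = right, y = anterior, z = superior).
Two posterior channels are designated as the occipital region-of-interest
for lateralized visual ERPs -- index 65 over the left hemisphere and index
90 over the right -- and four periocular channels record eye activity.
Continuous data are carried in EDF (16-bit, microvolts) with a tab-separated
sidecar table of trial events.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MontageFormatError",
    "ChannelMontage",
    "ContinuousRecording",
    "EVENT_COLUMNS",
    "load_montage",
    "nearest_neighbors",
    "read_events",
    "write_events",
    "validate_events",
    "read_recording",
    "write_recording",
]

#: Required columns of an event table, one row per trial.
EVENT_COLUMNS = [
    "trial_id",
    "onset_sample",
    "block",
    "visual_field",
    "match",
    "response_hand",
    "response",
    "rt_ms",
    "correct",
]

_VISUAL_FIELDS = {"LVF", "RVF", "bilateral"}


class MontageFormatError(ValueError):
    """Raised when a montage file violates the layout contract."""


@dataclass
class ChannelMontage:
    """128 scalp channels with unit-sphere positions and role tags.

    Parameters
    ----------
    labels : list of str
        Channel labels, in index order.
    indices : ndarray of int
        1-based channel indices, unique, in the same order as ``labels``.
    positions : ndarray, shape (n_channels, 3)
        Unit-norm electrode positions.
    reference_label : str
        Label of the (virtual) recording reference, ``"Cz"`` by default.
    eye_channel_indices : frozenset of int
        Periocular channels; excluded from scalp statistics and from
        neighbor queries.
    roi : dict
        ``{"left_occipital": 65, "right_occipital": 90}``.
    """

    labels: list[str]
    indices: np.ndarray
    positions: np.ndarray
    reference_label: str = "Cz"
    eye_channel_indices: frozenset = frozenset()
    roi: dict = field(default_factory=dict)
    name: str = "unnamed"

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        self.positions = np.asarray(self.positions, dtype=float)
        self.eye_channel_indices = frozenset(int(i) for i in self.eye_channel_indices)
        self._validate()
        self._row_of = {int(ix): r for r, ix in enumerate(self.indices)}

    def _validate(self) -> None:
        n = len(self.labels)
        if n != 128:
            raise MontageFormatError(f"expected exactly 128 channels, got {n}")
        if len(np.unique(self.indices)) != n:
            raise MontageFormatError("duplicate channel indices")
        norms = np.linalg.norm(self.positions, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise MontageFormatError("positions must have unit norm within 1e-6")
        for key in ("left_occipital", "right_occipital"):
            if key not in self.roi:
                raise MontageFormatError(f"roi missing {key!r}")
            if int(self.roi[key]) not in self.indices:
                raise MontageFormatError(f"roi channel {self.roi[key]} not in montage")
        if not self.eye_channel_indices:
            raise MontageFormatError("eye_channel_indices must be non-empty")
        if self.eye_channel_indices & set(int(v) for v in self.roi.values()):
            raise MontageFormatError("eye channels must be disjoint from the roi")

    # -- convenience -------------------------------------------------------
    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def row(self, index: int) -> int:
        """0-based data row for a 1-based channel index."""
        try:
            return self._row_of[int(index)]
        except KeyError:
            raise KeyError(f"channel index {index} not in montage") from None

    @property
    def scalp_rows(self) -> np.ndarray:
        """Rows of non-eye channels."""
        eye = self.eye_rows
        return np.array([r for r in range(self.n_channels) if r not in set(eye)])

    @property
    def eye_rows(self) -> np.ndarray:
        return np.array(sorted(self.row(i) for i in self.eye_channel_indices))

    @property
    def left_occipital(self) -> int:
        return int(self.roi["left_occipital"])

    @property
    def right_occipital(self) -> int:
        return int(self.roi["right_occipital"])


def load_montage(path: str | Path | None = None) -> ChannelMontage:
    """Load a montage from JSON; the bundled 128-channel layout by default.

    The bundled layout is a synthetic approximate-equidistant spherical
    lattice (only relative inter-electrode distances matter downstream).
    """
    if path is None:
        with resources.files("ihtt.data").joinpath("montage128.json").open() as f:
            doc = json.load(f)
    else:
        with open(path) as f:
            doc = json.load(f)
    try:
        chans = doc["channels"]
        labels = [c["label"] for c in chans]
        indices = np.array([int(c["index"]) for c in chans])
        positions = np.array([c["position"] for c in chans], dtype=float)
    except (KeyError, TypeError) as exc:
        raise MontageFormatError(f"malformed montage file: {exc}") from exc
    norms = np.linalg.norm(positions, axis=1)
    if np.any(norms <= 0):
        raise MontageFormatError("zero-length electrode position")
    positions = positions / norms[:, None]  # normalize on load
    return ChannelMontage(
        labels=labels,
        indices=indices,
        positions=positions,
        reference_label=doc.get("reference_label", "Cz"),
        eye_channel_indices=frozenset(doc.get("eye_channels", [])),
        roi={k: int(v) for k, v in doc.get("roi", {}).items()},
        name=doc.get("name", "unnamed"),
    )


def great_circle_distance(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Great-circle distance (radians) between unit vectors."""
    return np.arccos(np.clip(np.dot(p, np.atleast_2d(q).T).squeeze(), -1.0, 1.0))


def nearest_neighbors(
    montage: ChannelMontage,
    channel: int,
    k: int,
    exclude: set[int] | None = None,
) -> list[int]:
    """The ``k`` nearest scalp neighbors of ``channel``.

    Ordered by ascending great-circle distance, ties broken by ascending
    channel index. The query channel, eye channels, and any ``exclude``
    set are never returned.
    """
    exclude = set() if exclude is None else {int(i) for i in exclude}
    exclude |= {int(channel)} | set(montage.eye_channel_indices)
    qrow = montage.row(channel)
    cand = [int(ix) for ix in montage.indices if int(ix) not in exclude]
    if k >= montage.n_channels:
        raise ValueError(f"k={k} must be < {montage.n_channels}")
    if k > len(cand):
        raise ValueError(f"k={k} exceeds the {len(cand)} available channels")
    d = great_circle_distance(
        np.array([montage.positions[montage.row(i)] for i in cand]),
        montage.positions[qrow],
    )
    order = sorted(range(len(cand)), key=lambda j: (d[j], cand[j]))
    return [cand[j] for j in order[:k]]


@dataclass
class ContinuousRecording:
    """A continuous multichannel recording in microvolts.

    ``data`` is channels x samples in montage row order; ``events`` is a
    trial table with :data:`EVENT_COLUMNS`.
    """

    data: np.ndarray
    sampling_rate_hz: float
    montage: ChannelMontage
    events: pd.DataFrame
    acquisition_meta: dict = field(default_factory=lambda: {
        "hardware_bandpass_hz": [0.01, 100.0],
        "reference": "Cz",
    })

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)  # float32 or float64
        if not np.issubdtype(self.data.dtype, np.floating):
            self.data = self.data.astype(float)
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be > 0")
        if self.data.shape[0] != self.montage.n_channels:
            raise ValueError(
                f"data has {self.data.shape[0]} rows for a "
                f"{self.montage.n_channels}-channel montage"
            )
        if len(self.events):
            validate_events(self.events)
            last = int(self.events["onset_sample"].max())
            if last >= self.n_samples or int(self.events["onset_sample"].min()) < 0:
                raise ValueError("event onset beyond recording bounds")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


# -- events ----------------------------------------------------------------

def validate_events(events: pd.DataFrame) -> None:
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise ValueError(f"event table missing columns {missing}")
    if events["trial_id"].duplicated().any():
        raise ValueError("duplicate trial_id in event table")
    onsets = events["onset_sample"].to_numpy()
    if np.any(np.diff(onsets) <= 0):
        raise ValueError("onset_sample must be strictly increasing")
    bad_vf = set(events["visual_field"]) - _VISUAL_FIELDS
    if bad_vf:
        raise ValueError(f"unknown visual_field values {bad_vf}")
    responded = events["response"].isin(["match", "nonmatch"])
    expect = events.loc[responded, "response"] == events.loc[responded, "match"].map(
        {True: "match", False: "nonmatch"}
    )
    if not (events.loc[responded, "correct"].astype(bool) == expect).all():
        raise ValueError("correct flag inconsistent with response vs match status")


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    validate_events(events)
    events.to_csv(path, sep="\t", index=False)


def read_events(path: str | Path) -> pd.DataFrame:
    events = pd.read_csv(path, sep="\t")
    events["match"] = events["match"].astype(bool)
    events["correct"] = events["correct"].astype(bool)
    validate_events(events)
    return events


# -- EDF I/O ---------------------------------------------------------------
# Fixed symmetric physical range: with a 16-bit code space this yields an
# exact 0.1 uV quantization step (max round-trip error 0.05 uV).
_PHYS_MAX_UV = 3276.7


def _pad16(s: str, n: int) -> bytes:
    b = s.encode("ascii")[:n]
    return b + b" " * (n - len(b))


def _write_edf(
    data: np.ndarray, sfreq: int, labels: list[str], path: str | Path
) -> None:
    """Low-level EDF writer: channels x samples (uV), 1-second records."""
    n_ch, n_samp = data.shape
    n_rec = int(np.ceil(n_samp / sfreq))
    if n_rec * sfreq != n_samp:
        data = np.pad(data, ((0, 0), (0, n_rec * sfreq - n_samp)))

    clipped = np.clip(data, -_PHYS_MAX_UV, _PHYS_MAX_UV)
    if np.any(np.abs(data) > _PHYS_MAX_UV):
        warnings.warn("samples beyond +/-3276.7 uV were clipped on EDF write")
    # exact inverse of the EDF affine map [-32768, 32767] -> [-pm, +pm]
    slope = (2 * _PHYS_MAX_UV) / 65535.0
    offset = -_PHYS_MAX_UV - slope * (-32768)
    digital = np.clip(
        np.round((clipped - offset) / slope), -32768, 32767
    ).astype("<i2")

    hdr = b""
    hdr += _pad16("0", 8)
    hdr += _pad16("X X X X", 80)
    hdr += _pad16("Startdate 01-JAN-2000 X X X", 80)
    hdr += _pad16("01.01.00", 8)
    hdr += _pad16("00.00.00", 8)
    hdr += _pad16(str(256 * (n_ch + 1)), 8)
    hdr += _pad16("", 44)
    hdr += _pad16(str(n_rec), 8)
    hdr += _pad16("1", 8)
    hdr += _pad16(str(n_ch), 4)
    for lab in labels:
        hdr += _pad16(lab, 16)
    hdr += _pad16("AgAgCl electrode", 80) * n_ch
    hdr += _pad16("uV", 8) * n_ch
    hdr += _pad16(f"{-_PHYS_MAX_UV}", 8) * n_ch
    hdr += _pad16(f"{_PHYS_MAX_UV}", 8) * n_ch
    hdr += _pad16("-32768", 8) * n_ch
    hdr += _pad16("32767", 8) * n_ch
    hdr += _pad16("", 80) * n_ch
    hdr += _pad16(str(sfreq), 8) * n_ch
    hdr += _pad16("", 32) * n_ch

    with open(path, "wb") as f:
        f.write(hdr)
        for r in range(n_rec):
            f.write(digital[:, r * sfreq : (r + 1) * sfreq].tobytes())


def write_recording(
    rec: ContinuousRecording, edf_path: str | Path, events_path: str | Path | None = None
) -> None:
    """Write a recording as EDF plus an events TSV sidecar.

    Signals are stored as 16-bit integers over a fixed +/-3276.7 uV
    physical range (0.1 uV resolution). The recording is zero-padded to a
    whole number of 1-second data records.
    """
    sfreq = rec.sampling_rate_hz
    if abs(sfreq - round(sfreq)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    _write_edf(rec.data, int(round(sfreq)), rec.montage.labels, edf_path)
    if events_path is not None:
        write_events(rec.events, events_path)


def read_recording(
    edf_path: str | Path,
    events_path: str | Path | None = None,
    montage: ChannelMontage | None = None,
) -> ContinuousRecording:
    """Read an EDF recording and its events TSV into a ContinuousRecording.

    EDF channel labels must map one-to-one onto the montage labels; data
    are returned in microvolts in montage row order.
    """
    import mne

    montage = montage or load_montage()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(str(edf_path), preload=True, verbose="error")
    labels = list(raw.ch_names)
    missing = [lab for lab in montage.labels if lab not in labels]
    if missing:
        raise ValueError(f"EDF is missing montage channels: {missing[:8]}...")
    order = [labels.index(lab) for lab in montage.labels]
    data_uv = raw.get_data()[order] * 1e6  # mne returns volts

    if events_path is not None:
        events = read_events(events_path)
        if len(events) and int(events["onset_sample"].max()) >= data_uv.shape[1]:
            raise ValueError("event onset beyond recording end")
    else:
        events = pd.DataFrame(columns=EVENT_COLUMNS)
    return ContinuousRecording(
        data=data_uv,
        sampling_rate_hz=float(raw.info["sfreq"]),
        montage=montage,
        events=events,
    )
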