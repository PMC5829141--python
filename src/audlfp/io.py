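"""Epoched-LFP data model and file I/O.

The unit of analysis is an :class:`EpochSet`: a trial x sample voltage matrix
(microvolts) cut around a stimulus event, together with its sampling rate,
the time of sample 0 relative to the alignment event, and the recording
labels (brain region, consciousness condition, stimulus type, session id).

Continuous recordings come in as EDF (read through :mod:`mne`) or as a plain
two-column CSV (``time_s,voltage_uV``); event markers come in as a TSV
sidecar (``onset_s,label,pair_id``).  Epoch containers are single HDF5 files
with a versioned, documented layout (see :func:`save_epochs`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import h5py
import numpy as np
import pandas as pd
from scipy import signal as _sig

from .config import CONDITIONS, REGIONS, STIMULI

SCHEMA_VERSION = 1

#: Minimum epoch span (s, relative to the alignment event) required per
#: stimulus type: the paired-pulse analysis needs the control period through
#: the test response; the click-train analysis needs the full train plus
#: post-train window.
REQUIRED_SPAN = {"sound_pair": (-3.0, 0.7), "click_train": (-0.5, 1.0)}


@dataclass
class EpochSet:
    """Aligned trial x time voltage matrix with sampling metadata."""

    data: np.ndarray          # (n_trials, n_samples), microvolts
    fs: float                 # Hz
    t0: float                 # time of sample 0 relative to the event (s)
    region: str               # one of REGIONS
    condition: str            # one of CONDITIONS
    stimulus: str             # one of STIMULI
    session_id: str = ""
    #: when False, skip the per-paradigm minimum-span check (generic signal
    #: buffers for spectral analysis need not cover a full trial layout)
    validate_span: bool = True

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2 or self.data.shape[0] < 1:
            raise ValueError("data must be a (n_trials >= 1, n_samples) matrix")
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        for name, value, valid in (
            ("region", self.region, REGIONS),
            ("condition", self.condition, CONDITIONS),
            ("stimulus", self.stimulus, STIMULI),
        ):
            if value not in valid:
                raise ValueError(f"{name}={value!r}; valid values: {valid}")
        lo, hi = REQUIRED_SPAN[self.stimulus]
        tol = 1.5 / self.fs
        if self.validate_span and (self.t0 > lo + tol or self.t_end < hi - tol):
            raise ValueError(
                f"{self.stimulus} epochs must span [{lo}, {hi}] s around the event; "
                f"got [{self.t0:.4f}, {self.t_end:.4f}]"
            )

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def t_end(self) -> float:
        return self.t0 + (self.n_samples - 1) / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs

    def index_of(self, t: float) -> int:
        """Index of the sample nearest to time ``t`` (ties toward earlier)."""
        return _nearest_index(t - self.t0, self.fs)

    def __eq__(self, other) -> bool:  # bit-exact comparison, used in round trips
        if not isinstance(other, EpochSet):
            return NotImplemented
        return (
            np.array_equal(self.data, other.data)
            and self.data.dtype == other.data.dtype
            and self.fs == other.fs
            and self.t0 == other.t0
            and (self.region, self.condition, self.stimulus, self.session_id)
            == (other.region, other.condition, other.stimulus, other.session_id)
        )


@dataclass
class EventTable:
    """Stimulus event markers on the recording clock."""

    onset_s: np.ndarray       # strictly increasing event times (s)
    labels: list[str] = field(default_factory=list)
    pair_id: np.ndarray | None = None   # groups conditioning/test onsets

    def __post_init__(self) -> None:
        self.onset_s = np.asarray(self.onset_s, dtype=float)
        if self.onset_s.ndim != 1:
            raise ValueError("onset_s must be 1-D")
        if np.any(np.diff(self.onset_s) <= 0):
            raise ValueError("event onsets must be strictly increasing")
        if self.labels and len(self.labels) != len(self.onset_s):
            raise ValueError("labels and onset_s lengths differ")
        if self.pair_id is not None:
            self.pair_id = np.asarray(self.pair_id)
            if len(self.pair_id) != len(self.onset_s):
                raise ValueError("pair_id and onset_s lengths differ")

    def validate_pairs(self, fs: float, isi: float = 0.5) -> None:
        """Check every C onset has a T onset ``isi`` later (one-sample tol)."""
        if self.pair_id is None:
            return
        tol = 1.0 / fs
        for pid in np.unique(self.pair_id):
            sel = self.pair_id == pid
            lab = [l for l, s in zip(self.labels, sel) if s]
            t = self.onset_s[sel]
            if "C" in lab and "T" in lab:
                gap = t[lab.index("T")] - t[lab.index("C")]
                if abs(gap - isi) > tol:
                    raise ValueError(
                        f"pair {pid!r}: C→T interval {gap:.4f} s deviates from "
                        f"{isi} s by more than one sample"
                    )

    def select(self, label: str) -> np.ndarray:
        if not self.labels:
            return self.onset_s
        mask = np.array([l == label for l in self.labels])
        return self.onset_s[mask]


def read_events(path) -> EventTable:
    """Read an event sidecar TSV with columns onset_s, label, pair_id."""
    df = pd.read_csv(path, sep="\t")
    for col in ("onset_s", "label"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    pair = df["pair_id"].to_numpy() if "pair_id" in df.columns else None
    return EventTable(df["onset_s"].to_numpy(float), list(df["label"].astype(str)), pair)


def write_events(events: EventTable, path) -> None:
    df = pd.DataFrame({"onset_s": events.onset_s})
    df["label"] = events.labels if events.labels else ""
    if events.pair_id is not None:
        df["pair_id"] = events.pair_id
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# continuous recordings
# ---------------------------------------------------------------------------

def read_continuous(path, format: str | None = None) -> tuple[np.ndarray, float]:
    """Read a single-channel continuous recording.

    Returns ``(voltage_uV, fs)``.  ``format`` is ``"EDF"`` or ``"CSV"``;
    when omitted it is inferred from the file suffix.
    """
    path = str(path)
    if format is None:
        format = "EDF" if path.lower().endswith(".edf") else "CSV"
    format = format.upper()
    if format == "EDF":
        import mne

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        data = raw.get_data()[0] * 1e6  # mne loads volts; LFP convention is uV
        return np.asarray(data, dtype=float), float(raw.info["sfreq"])
    if format == "CSV":
        return _read_csv_trace(path)
    raise ValueError(f"unknown continuous format {format!r} (use EDF or CSV)")


def _read_csv_trace(path) -> tuple[np.ndarray, float]:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"{path}: could not parse CSV ({exc})") from exc
    for col in ("time_s", "voltage_uV"):
        if col not in df.columns:
            raise ValueError(
                f"{path}: expected header columns time_s,voltage_uV; got "
                f"{list(df.columns)}"
            )
    t = df["time_s"].to_numpy(float)
    v = df["voltage_uV"].to_numpy(float)
    if len(t) < 2:
        raise ValueError(f"{path}: need at least two samples")
    dt = np.diff(t)
    bad = np.nonzero(dt <= 0)[0]
    if bad.size:
        raise ValueError(
            f"{path}: time column not strictly increasing at data row {bad[0] + 2}"
        )
    step = float(np.median(dt))
    if np.any(np.abs(dt - step) > 0.01 * step):
        worst = int(np.argmax(np.abs(dt - step)))
        raise ValueError(
            f"{path}: non-uniform sampling (time step at data row {worst + 2} "
            f"deviates from the median {step:.6g} s by more than 1%)"
        )
    return v, 1.0 / step


def write_continuous_csv(path, trace: np.ndarray, fs: float, t_start: float = 0.0) -> None:
    """Write a trace in the package CSV dialect (header time_s,voltage_uV)."""
    t = t_start + np.arange(len(trace)) / fs
    # %.17g preserves float64 exactly -> bit-identical round trips
    pd.DataFrame({"time_s": t, "voltage_uV": np.asarray(trace)}).to_csv(
        path, index=False, float_format="%.17g")


def write_edf(path, trace: np.ndarray, fs: float, channel: str = "LFP") -> None:
    """Write a single-channel EDF file.

    Minimal EDF: ASCII header plus 1-s data records of little-endian int16
    samples, scaled to the trace's physical range.  Sufficient for round
    trips through any standard EDF reader; ``fs`` must be a whole number of
    samples per second.
    """
    trace = np.asarray(trace, dtype=float)
    spr = int(round(fs))
    if abs(spr - fs) > 1e-9 or spr <= 0:
        raise ValueError(f"EDF writer requires an integer sampling rate, got {fs}")
    n_rec = int(np.ceil(len(trace) / spr))
    padded = np.zeros(n_rec * spr)
    padded[: len(trace)] = trace
    pmin, pmax = float(padded.min()), float(padded.max())
    if pmax <= pmin:
        pmin, pmax = pmin - 1.0, pmax + 1.0
    dmin, dmax = -32768, 32767
    scaled = (padded - pmin) / (pmax - pmin) * (dmax - dmin) + dmin
    digital = np.clip(np.round(scaled), dmin, dmax).astype("<i2")

    def f(text: str, width: int) -> bytes:
        s = str(text)[:width]
        return s.ljust(width).encode("ascii")

    header = b"".join([
        f("0", 8), f("X X X X", 80), f("X X X X", 80),
        f("01.01.00", 8), f("00.00.00", 8), f(str(256 + 256), 8), f("", 44),
        f(str(n_rec), 8), f("1", 8), f("1", 4),
    ])
    sig = b"".join([
        f(channel, 16), f("synthetic", 80), f("uV", 8),
        f(f"{pmin:.6g}", 8), f(f"{pmax:.6g}", 8),
        f(str(dmin), 8), f(str(dmax), 8), f("", 80), f(str(spr), 8), f("", 32),
    ])
    with open(path, "wb") as fh:
        fh.write(header + sig)
        fh.write(digital.tobytes())


# ---------------------------------------------------------------------------
# filtering and epoching
# ---------------------------------------------------------------------------

def bandpass(trace: np.ndarray, fs: float, lo: float, hi: float, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth bandpass (forward-backward), same length out.

    The acquisition convention for these recordings is a 1-300 Hz band.
    """
    if not 0 < lo < hi:
        raise ValueError(f"need 0 < lo < hi, got lo={lo}, hi={hi}")
    if hi >= fs / 2:
        raise ValueError(f"hi={hi} Hz reaches the Nyquist frequency {fs / 2} Hz")
    sos = _sig.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return _sig.sosfiltfilt(sos, np.asarray(trace, dtype=float))


def bandpass_response(fs: float, lo: float, hi: float, freqs: np.ndarray,
                      order: int = 4) -> np.ndarray:
    """Analytic amplitude response of :func:`bandpass` at ``freqs`` (Hz)."""
    sos = _sig.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    _, h = _sig.sosfreqz(sos, worN=np.asarray(freqs), fs=fs)
    return np.abs(h) ** 2  # forward-backward filtering squares the response


def _nearest_index(t_rel: float, fs: float) -> int:
    # nearest sample; exact half-sample ties resolve toward the earlier sample
    return int(np.ceil(t_rel * fs - 0.5))


def epoch(trace: np.ndarray, fs: float, events: EventTable,
          span: tuple[float, float], align_label: str | None = None,
          **meta) -> EpochSet:
    """Cut ``span``-second epochs around each event with ``align_label``.

    Sample 0 of each trial is the sample nearest the event onset.  Events
    whose span falls outside the recording are skipped with a warning that
    reports how many were dropped.
    """
    trace = np.asarray(trace, dtype=float)
    t_min, t_max = span
    if not t_min < t_max:
        raise ValueError(f"invalid span {span}")
    onsets = events.select(align_label) if align_label else events.onset_s
    n_pre = _nearest_index(-t_min, fs)
    n_post = _nearest_index(t_max, fs)
    rows, skipped = [], 0
    for t_ev in onsets:
        idx = _nearest_index(t_ev, fs)
        start, stop = idx - n_pre, idx + n_post
        if start < 0 or stop > len(trace):
            skipped += 1
            continue
        rows.append(trace[start:stop])
    if skipped:
        warnings.warn(
            f"skipped {skipped} of {len(onsets)} events too close to the "
            f"recording edge", stacklevel=2)
    if not rows:
        raise ValueError("no event with the requested span inside the recording")
    return EpochSet(np.stack(rows), fs=fs, t0=-n_pre / fs, **meta)


# ---------------------------------------------------------------------------
# epoch container (HDF5)
# ---------------------------------------------------------------------------
# Layout (schema 1): root attrs schema_version, fs, t0, region, condition,
# stimulus, session_id; dataset /data holding the trial x sample matrix in
# its native dtype (bit-exact round trip).

def save_epochs(epochs: EpochSet, path) -> None:
    with h5py.File(path, "w") as fh:
        fh.attrs["schema_version"] = SCHEMA_VERSION
        fh.attrs["fs"] = epochs.fs
        fh.attrs["t0"] = epochs.t0
        for key in ("region", "condition", "stimulus", "session_id"):
            fh.attrs[key] = getattr(epochs, key)
        fh.create_dataset("data", data=epochs.data)


def load_epochs(path) -> EpochSet:
    with h5py.File(path, "r") as fh:
        version = int(fh.attrs.get("schema_version", -1))
        if version != SCHEMA_VERSION:
            raise ValueError(
                f"{path}: epoch container schema {version} is incompatible with "
                f"this reader (expected {SCHEMA_VERSION})"
            )
        return EpochSet(
            data=fh["data"][...],
            fs=float(fh.attrs["fs"]),
            t0=float(fh.attrs["t0"]),
            region=str(fh.attrs["region"]),
            condition=str(fh.attrs["condition"]),
            stimulus=str(fh.attrs["stimulus"]),
            session_id=str(fh.attrs["session_id"]),
        )
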