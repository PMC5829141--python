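"""Evoked-potential peak quantification and inhibitory gating (T/C) ratios.

The paired-pulse paradigm presents two identical noise bursts 500 ms apart
(conditioning C, then test T).  Per session the pipeline

1. averages the 120 trials into one waveform,
2. finds the region's characteristic negative and positive deflections as
   the largest local extrema of matching polarity inside predefined search
   windows (AC: N25/P40; HP/AMY/PFC: N35/P70), each amplitude measured
   relative to the waveform value at that stimulus's onset,
3. accepts a peak only if its per-trial amplitude differs from a 1-s
   pre-stimulus control period (3 s before C) in a sliding-window Welch
   t-test at the 0.01 level, and
4. reports T-amp / C-amp per peak label — the gating ratio, < 1 meaning the
   response to the repeated stimulus is suppressed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as _stats

from .config import RunConfig
from .io import EpochSet

#: Peak labels per region: the auditory cortex response is earlier and is
#: labelled by its ~25/40-ms latencies; downstream regions by ~35/70 ms.
REGION_LABELS = {"AC": ("N25", "P40"), "HP": ("N35", "P70"),
                 "AMY": ("N35", "P70"), "PFC": ("N35", "P70")}


@dataclass(frozen=True)
class PeakSpec:
    """One labelled deflection to search for."""

    label: str                      # e.g. "N25"
    polarity: str                   # "negative" | "positive"
    search_window: tuple[float, float]   # s relative to its stimulus onset
    applies_to_region: str

    def __post_init__(self):
        neg = self.label.startswith("N")
        if (self.polarity == "negative") != neg:
            raise ValueError(f"label {self.label} inconsistent with polarity "
                             f"{self.polarity}")
        lo, hi = self.search_window
        if not (0.0 < lo < hi < 0.5):
            raise ValueError(f"search window {self.search_window} must lie in (0, 0.5) s")


@dataclass
class PeakMeasurement:
    """One measured deflection for one stimulus role (C or T)."""

    label: str
    stimulus_role: str              # "C" | "T"
    latency: float                  # s from its stimulus onset
    amplitude: float                # signed uV relative to value at onset
    p_value: float
    significant: bool
    boundary: bool = False          # True if no interior local extremum existed


@dataclass
class IGResult:
    """Per-session gating summary: C-amp, T-amp and T/C per peak label."""

    region: str
    condition: str
    session_id: str
    peaks: dict[str, dict[str, PeakMeasurement]]   # label -> {"C": .., "T": ..}
    tc_ratio: dict[str, float]                     # label -> ratio (NaN if undefined)


def peak_specs_for_region(region: str, config: RunConfig) -> tuple[PeakSpec, PeakSpec]:
    labels = REGION_LABELS[region]
    windows = config.peak_windows[region]
    return (
        PeakSpec(labels[0], "negative", tuple(windows["negative"]), region),
        PeakSpec(labels[1], "positive", tuple(windows["positive"]), region),
    )


def average_erp(epochs: EpochSet) -> np.ndarray:
    """Pointwise trial mean; same time base as the EpochSet."""
    return epochs.data.mean(axis=0)


def detect_peak(times: np.ndarray, waveform: np.ndarray, spec: PeakSpec,
                stim_onset: float) -> tuple[float, float, bool]:
    """Locate one deflection in the averaged waveform.

    Among strict local extrema of the matching polarity inside the search
    window, the one with the largest \\|amplitude\\| (relative to the waveform
    value at ``stim_onset``) wins; equal depths resolve to the earliest
    latency.  If the window holds no interior local extremum the window's
    extremal sample is returned with ``boundary=True``.

    Returns ``(latency, amplitude, boundary)``.
    """
    times = np.asarray(times)
    waveform = np.asarray(waveform)
    lo, hi = spec.search_window
    sel = np.nonzero((times >= stim_onset + lo) & (times <= stim_onset + hi))[0]
    if sel.size == 0:
        raise ValueError(
            f"search window {spec.search_window} s after onset {stim_onset} s is "
            f"empty on this time base")
    base = waveform[int(np.argmin(np.abs(times - stim_onset)))]
    negative = spec.polarity == "negative"
    best = None
    for i in sel:
        if i == 0 or i == len(waveform) - 1:
            continue
        v, prev, nxt = waveform[i], waveform[i - 1], waveform[i + 1]
        is_ext = (v < prev and v < nxt) if negative else (v > prev and v > nxt)
        if not is_ext:
            continue
        amp = v - base
        # a deflection of this polarity must deviate from baseline in that
        # direction; noise ripples riding the opposite lobe are not candidates
        if (amp >= 0) if negative else (amp <= 0):
            continue
        if best is None or abs(amp) > abs(best[1]):
            best = (times[i] - stim_onset, amp)
    if best is not None:
        return best[0], best[1], False
    seg = waveform[sel]
    j = sel[int(np.argmin(seg) if negative else np.argmax(seg))]
    return float(times[j] - stim_onset), float(waveform[j] - base), True


def peak_significance(epochs: EpochSet, latency: float, stim_onset: float,
                      control_period: tuple[float, float],
                      halfwidth: float = 0.005, step: float = 0.010) -> float:
    """Sliding-window test of a peak against the pre-stimulus control period.

    Per trial, the response statistic is the mean voltage in a
    ``+/-halfwidth`` window centred ``latency`` after ``stim_onset``, minus
    the voltage at ``stim_onset``.  The null sample applies the identical
    statistic (same window, same baseline lag) at centres stepped every
    ``step`` seconds through the control period, pooled over trials.  A
    two-sided Welch t-test between the two samples gives the p-value.
    """
    fs = epochs.fs
    hw = int(round(halfwidth * fs))
    i_on = epochs.index_of(stim_onset)
    i_pk = epochs.index_of(stim_onset + latency)

    def stat(centers: np.ndarray) -> np.ndarray:
        # mean over the +/-hw window minus the sample `latency` earlier
        lag = i_pk - i_on
        cols = centers[None, :] + np.arange(-hw, hw + 1)[:, None]
        win = epochs.data[:, cols].mean(axis=1)          # (n_trials, n_centers)
        return win - epochs.data[:, centers - lag]

    resp = stat(np.array([i_pk]))[:, 0]
    t_lo, t_hi = control_period
    if t_lo < epochs.t0 + (i_pk - i_on) / fs or t_hi > epochs.t_end:
        raise ValueError("control period (plus baseline lag) must lie inside the epoch")
    c_first = epochs.index_of(t_lo) + hw
    c_last = epochs.index_of(t_hi) - hw
    centers = np.arange(c_first, c_last + 1, int(round(step * fs)))
    if len(centers) < 10:
        raise ValueError(
            f"only {len(centers)} null windows fit in the control period; need >= 10")
    null = stat(centers).ravel()
    v_r, v_n = resp.var(ddof=1) if len(resp) > 1 else 0.0, null.var(ddof=1)
    if v_r == 0.0 and v_n == 0.0:
        return 0.0 if resp.mean() != null.mean() else 1.0
    return float(_stats.ttest_ind(resp, null, equal_var=False).pvalue)


def compute_ig(epochs: EpochSet, config: RunConfig) -> IGResult:
    """Full inhibitory-gating quantification for one sound-pair session.

    Detects and tests both regional peaks for the C (onset 0 s) and T
    (onset ``config.t_onset_test`` s) responses; a T/C ratio is emitted per
    label only when both constituent peaks are significant and C-amp is
    nonzero (otherwise NaN, never a silent zero).
    """
    if epochs.stimulus != "sound_pair":
        raise ValueError(f"compute_ig needs sound_pair epochs, got {epochs.stimulus!r}")
    erp = average_erp(epochs)
    times = epochs.times
    # Peaks are located and measured on the +/-stat_halfwidth boxcar-mean of
    # the averaged waveform, i.e. the deflection is the window position with
    # the extremal mean -- the same local statistic the significance test
    # operates on.  The window mean shrinks C and T by the identical kernel-
    # shape factor, so T/C is unaffected, while the noise-extremum bias of
    # picking a raw peak sample largely averages out.
    hw = int(round(config.stat_halfwidth * epochs.fs))
    kern = np.ones(2 * hw + 1) / (2 * hw + 1)
    smoothed = np.convolve(erp, kern, mode="same")
    peaks: dict[str, dict[str, PeakMeasurement]] = {}
    tc: dict[str, float] = {}
    for spec in peak_specs_for_region(epochs.region, config):
        per_role: dict[str, PeakMeasurement] = {}
        for role, onset in (("C", 0.0), ("T", config.t_onset_test)):
            lat, amp, boundary = detect_peak(times, smoothed, spec, onset)
            p = peak_significance(epochs, lat, onset, config.control_period,
                                  config.stat_halfwidth, config.null_step)
            per_role[role] = PeakMeasurement(
                label=spec.label, stimulus_role=role, latency=lat, amplitude=amp,
                p_value=p, significant=bool(p < config.alpha_peak), boundary=boundary)
        peaks[spec.label] = per_role
        c, t = per_role["C"], per_role["T"]
        if c.significant and t.significant and c.amplitude != 0.0:
            tc[spec.label] = t.amplitude / c.amplitude
        else:
            tc[spec.label] = float("nan")
            warnings.warn(
                f"{epochs.session_id or 'session'}: {spec.label} T/C undefined "
                f"(C significant={c.significant}, T significant={t.significant})",
                stacklevel=2)
    return IGResult(region=epochs.region, condition=epochs.condition,
                    session_id=epochs.session_id, peaks=peaks, tc_ratio=tc)


def ig_result_rows(result: IGResult) -> list[dict]:
    """Flatten an IGResult into TSV-ready rows (one per peak label)."""
    rows = []
    for label, per_role in result.peaks.items():
        c, t = per_role["C"], per_role["T"]
        rows.append({
            "session_id": result.session_id, "region": result.region,
            "condition": result.condition, "label": label,
            "C_amp": c.amplitude, "T_amp": t.amplitude,
            "tc_ratio": result.tc_ratio[label],
            "p_C": c.p_value, "p_T": t.p_value,
        })
    return rows
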