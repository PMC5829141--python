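"""Synthetic LFP generator.

Emulates one recording session of the two auditory paradigms on which the
analysis pipeline operates:

* **click trains** — a 0.5-s, 40-Hz click train entrains a gamma oscillation
  (the auditory steady-state response, ASSR) whose amplitude and per-trial
  phase jitter are region- and condition-dependent;
* **sound pairs** — two identical 80-ms noise bursts 500 ms apart evoke a
  biphasic deflection (negative then positive Gaussian bump); the response
  to the second (test, T) burst is a gated copy of the first (conditioning,
  C), scaled by ``gateN``/``gateP`` per polarity.  The gate values are,
  by construction, the ground-truth T/C ratios that the gating pipeline
  should recover.

Background activity is 1/f (pink) noise, the canonical null model for LFP
baseline spectra.  Region x condition presets encode the published
representative values: ASSR strength ordered AC > HP > AMY > PFC (absent),
gating strength increasing from AC to PFC, anesthesia shrinking the ASSR
(amplitude x0.4, phase jitter x2) and the evoked amplitudes (x0.8) while
leaving the gate ratios essentially unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .config import CONDITIONS, REGIONS
from .io import EpochSet

#: Epoch spans (s around stimulus onset) emitted by the generators.
CLICK_SPAN = (-0.5, 1.0)
PAIR_SPAN = (-3.5, 1.1)

#: Inter-trial-interval ranges (s) used when emitting continuous recordings.
CLICK_ITI = (2.0, 4.0)
PAIR_ITI = (8.0, 10.0)


@dataclass
class AssrParams:
    """Click-train (ASSR) trial generator parameters."""

    f_stim: float = 40.0          # entrainment frequency (Hz)
    train_dur: float = 0.5        # click-train duration (s)
    amp: float = 20.0             # entrained oscillation amplitude (uV)
    phase_jitter_sd: float = 0.4  # per-trial phase jitter (rad)
    noise_amp: float = 20.0       # pink-noise standard deviation (uV)
    n_trials: int = 120
    fs: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amp < 0 or self.phase_jitter_sd < 0 or self.noise_amp < 0:
            raise ValueError("amp, phase_jitter_sd and noise_amp must be >= 0")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.fs <= 2 * self.f_stim:
            raise ValueError("fs must exceed twice the entrainment frequency")


@dataclass
class PairParams:
    """Sound-pair (inhibitory gating) trial generator parameters."""

    latN: float = 0.025           # negative-peak latency (s after onset)
    latP: float = 0.040           # positive-peak latency (s after onset)
    ampN: float = -40.0           # negative-peak amplitude (uV, signed)
    ampP: float = 30.0            # positive-peak amplitude (uV, signed)
    width: float = 0.012          # deflection half-width, Gaussian FWHM (s)
    gateN: float = 1.0            # T-response scaling, negative peak
    gateP: float = 1.0            # T-response scaling, positive peak
    isi: float = 0.5              # C -> T interval (s)
    noise_amp: float = 20.0       # pink-noise standard deviation (uV)
    n_trials: int = 120
    fs: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.gateN <= 1.5 and 0.0 <= self.gateP <= 1.5):
            raise ValueError("gate factors must lie in [0, 1.5]")
        if not 0.0 < self.latN < self.latP < self.isi:
            raise ValueError("latencies must satisfy 0 < latN < latP < isi")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")


@dataclass
class RegionPreset:
    """Generator parameters for one region x condition cell."""

    region: str
    condition: str
    pair: PairParams
    assr: AssrParams


def _preset(region, condition, latN, latP, gateN, gateP, assr_amp, jitter,
            evoked_scale=1.0) -> RegionPreset:
    return RegionPreset(
        region=region,
        condition=condition,
        pair=PairParams(latN=latN, latP=latP, ampN=-40.0 * evoked_scale,
                        ampP=30.0 * evoked_scale, gateN=gateN, gateP=gateP),
        assr=AssrParams(amp=assr_amp, phase_jitter_sd=jitter),
    )


# Published representative values per region x condition: peak latencies
# (AC: N25/P40; HP/AMY/PFC: negative 39/37/35 ms, positive 65/65/75 ms) and
# T/C ratios used as ground-truth gate factors.  ASSR amplitudes are nominal
# (uV) but ordered AC > HP > AMY > PFC = 0; anesthesia scales the ASSR
# amplitude x0.4, doubles the phase jitter, and scales evoked amplitudes x0.8.
PRESETS: dict[tuple[str, str], RegionPreset] = {
    ("AC", "conscious"):      _preset("AC", "conscious", 0.025, 0.040, 0.75, 0.90, 20.0, 0.4),
    ("AC", "anesthetized"):   _preset("AC", "anesthetized", 0.025, 0.040, 0.72, 0.92, 8.0, 0.8, 0.8),
    ("HP", "conscious"):      _preset("HP", "conscious", 0.039, 0.065, 0.61, 0.51, 10.0, 0.4),
    ("HP", "anesthetized"):   _preset("HP", "anesthetized", 0.039, 0.065, 0.58, 0.45, 4.0, 0.8, 0.8),
    ("AMY", "conscious"):     _preset("AMY", "conscious", 0.037, 0.065, 0.50, 0.35, 5.0, 0.4),
    ("AMY", "anesthetized"):  _preset("AMY", "anesthetized", 0.037, 0.065, 0.52, 0.30, 2.0, 0.8, 0.8),
    ("PFC", "conscious"):     _preset("PFC", "conscious", 0.035, 0.075, 0.25, 0.28, 0.0, 0.4),
    ("PFC", "anesthetized"):  _preset("PFC", "anesthetized", 0.035, 0.075, 0.21, 0.23, 0.0, 0.8, 0.8),
}

#: Ground-truth peak labels carried by each preset, for reporting.
PEAK_LABELS = {"AC": ("N25", "P40"), "HP": ("N35", "P70"),
               "AMY": ("N35", "P70"), "PFC": ("N35", "P70")}


def presets_table() -> pd.DataFrame:
    """The preset table as a DataFrame (also usable as a text override file)."""
    rows = []
    for (region, condition), p in PRESETS.items():
        rows.append({
            "region": region, "condition": condition,
            "latN": p.pair.latN, "latP": p.pair.latP,
            "ampN": p.pair.ampN, "ampP": p.pair.ampP, "width": p.pair.width,
            "gateN": p.pair.gateN, "gateP": p.pair.gateP,
            "pair_noise_amp": p.pair.noise_amp,
            "assr_amp": p.assr.amp, "phase_jitter_sd": p.assr.phase_jitter_sd,
            "assr_noise_amp": p.assr.noise_amp,
        })
    return pd.DataFrame(rows)


def presets_from_table(path) -> dict[tuple[str, str], RegionPreset]:
    """Load a preset override table (TSV with the columns of presets_table)."""
    df = pd.read_csv(path, sep="\t")
    out = {}
    for _, r in df.iterrows():
        key = (str(r["region"]), str(r["condition"]))
        out[key] = RegionPreset(
            region=key[0], condition=key[1],
            pair=PairParams(latN=r["latN"], latP=r["latP"], ampN=r["ampN"],
                            ampP=r["ampP"], width=r["width"], gateN=r["gateN"],
                            gateP=r["gateP"], noise_amp=r["pair_noise_amp"]),
            assr=AssrParams(amp=r["assr_amp"], phase_jitter_sd=r["phase_jitter_sd"],
                            noise_amp=r["assr_noise_amp"]),
        )
    return out


# ---------------------------------------------------------------------------
# noise and trial generators
# ---------------------------------------------------------------------------

def gen_pink_noise(n_samples: int, fs: float, scale: float,
                   seed=None, n_traces: int = 1) -> np.ndarray:
    """Zero-mean 1/f noise with standard deviation ``scale`` (uV).

    Spectral synthesis: white Gaussian Fourier coefficients shaped by
    f^(-1/2), inverse-transformed and deterministically normalized so that
    the *expected* per-trace variance equals ``scale**2`` (individual traces
    fluctuate naturally).  Returns shape ``(n_traces, n_samples)`` squeezed
    to 1-D when ``n_traces == 1``.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    if scale < 0:
        raise ValueError(f"noise scale must be >= 0, got {scale}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if scale == 0.0:
        out = np.zeros((n_traces, n_samples))
        return out[0] if n_traces == 1 else out
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** -0.5
    coef = rng.standard_normal((n_traces, len(freqs))) + 1j * rng.standard_normal(
        (n_traces, len(freqs)))
    spec = coef * shape
    if n_samples % 2 == 0:
        spec[:, -1] = spec[:, -1].real  # Nyquist bin must be real
    x = np.fft.irfft(spec, n=n_samples, axis=1)
    x *= scale / np.sqrt(_pink_expected_var(n_samples, shape))
    return x[0] if n_traces == 1 else x


def _pink_expected_var(n_samples: int, shape: np.ndarray) -> float:
    # x[m] = (1/n) [sum over interior bins of 2*Re(spec_k e^{i theta}) +
    # (+/-1)^m * spec_Nyq]; with unit-variance real/imag draws each interior
    # bin contributes 4*shape^2 to n^2*Var, the (real) Nyquist bin shape^2.
    weights = np.full(len(shape), 4.0)
    weights[0] = 0.0
    if n_samples % 2 == 0:
        weights[-1] = 1.0
    return float((shape**2 * weights).sum() / n_samples**2)


def _ramped_gate(t: np.ndarray, t_on: float, t_off: float, ramp: float = 0.010) -> np.ndarray:
    """On/off envelope with raised-cosine ramps of ``ramp`` seconds."""
    env = np.zeros_like(t)
    rise = (t >= t_on) & (t < t_on + ramp)
    env[rise] = 0.5 * (1 - np.cos(np.pi * (t[rise] - t_on) / ramp))
    env[(t >= t_on + ramp) & (t <= t_off - ramp)] = 1.0
    fall = (t > t_off - ramp) & (t <= t_off)
    env[fall] = 0.5 * (1 - np.cos(np.pi * (t_off - t[fall]) / ramp))
    return env


def gen_assr_epochs(p: AssrParams, region: str = "AC", condition: str = "conscious",
                    session_id: str = "") -> EpochSet:
    """Simulate click-train trials: pink noise + phase-jittered 40-Hz tone.

    Each trial adds ``amp * cos(2*pi*f_stim*t + phi_n)`` gated over
    ``[0, train_dur]`` (10-ms raised-cosine ramps) to an independent pink-
    noise background, with per-trial phase ``phi_n ~ N(0, phase_jitter_sd^2)``.
    """
    fs = p.fs
    n_pre = int(round(-CLICK_SPAN[0] * fs))
    n_post = int(round(CLICK_SPAN[1] * fs))
    n = n_pre + n_post
    t = (np.arange(n) - n_pre) / fs
    rng = np.random.default_rng(p.seed)
    data = gen_pink_noise(n, fs, p.noise_amp, rng, n_traces=p.n_trials)
    data = np.atleast_2d(data)
    phases = rng.normal(0.0, p.phase_jitter_sd, size=p.n_trials)
    env = _ramped_gate(t, 0.0, p.train_dur)
    osc = p.amp * np.cos(2 * np.pi * p.f_stim * t[None, :] + phases[:, None]) * env[None, :]
    return EpochSet(data + osc, fs=fs, t0=-n_pre / fs, region=region,
                    condition=condition, stimulus="click_train", session_id=session_id)


def pair_kernel(t: np.ndarray, p: PairParams) -> np.ndarray:
    """Noise-free biphasic evoked kernel for one stimulus at t = 0."""
    sigma = p.width / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    g = lambda tau: np.exp(-0.5 * (tau / sigma) ** 2)
    return p.ampN * g(t - p.latN) + p.ampP * g(t - p.latP)


def gen_pair_epochs(p: PairParams, region: str = "AC", condition: str = "conscious",
                    session_id: str = "") -> EpochSet:
    """Simulate sound-pair trials: pink noise + C kernel + gated T kernel."""
    fs = p.fs
    n_pre = int(round(-PAIR_SPAN[0] * fs))
    n_post = int(round(PAIR_SPAN[1] * fs))
    n = n_pre + n_post
    t = (np.arange(n) - n_pre) / fs
    sigma = p.width / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    g = lambda tau: np.exp(-0.5 * (tau / sigma) ** 2)
    kernel = pair_kernel(t, p)
    t_kernel = (p.ampN * p.gateN * g(t - p.isi - p.latN)
                + p.ampP * p.gateP * g(t - p.isi - p.latP))
    rng = np.random.default_rng(p.seed)
    data = np.atleast_2d(gen_pink_noise(n, fs, p.noise_amp, rng, n_traces=p.n_trials))
    return EpochSet(data + kernel[None, :] + t_kernel[None, :], fs=fs, t0=-n_pre / fs,
                    region=region, condition=condition, stimulus="sound_pair",
                    session_id=session_id)


def make_session(region: str, condition: str, seed: int,
                 presets: dict | None = None,
                 session_id: str | None = None) -> tuple[EpochSet, EpochSet]:
    """One recording session: a click-train EpochSet and a sound-pair EpochSet.

    Parameters are drawn from the region x condition preset; both sets carry
    matching labels and session id.  Deterministic in ``seed``.
    """
    presets = PRESETS if presets is None else presets
    key = (region, condition)
    if key not in presets:
        raise ValueError(
            f"no preset for {key}; valid regions {sorted({k[0] for k in presets})}, "
            f"conditions {sorted({k[1] for k in presets})}"
        )
    preset = presets[key]
    s_assr, s_pair = (int(s) & 0x7FFFFFFF for s in
                      np.random.SeedSequence(seed).generate_state(2))
    sid = session_id if session_id is not None else f"{region}-{condition}-s{seed}"
    clicks = gen_assr_epochs(replace(preset.assr, seed=s_assr), region=region,
                             condition=condition, session_id=sid)
    pairs = gen_pair_epochs(replace(preset.pair, seed=s_pair), region=region,
                            condition=condition, session_id=sid)
    return clicks, pairs


def emit_continuous(p: PairParams | AssrParams, n_events: int | None = None,
                    seed: int = 0) -> tuple[np.ndarray, "EventTable"]:
    """Render a session as one continuous trace plus an event table.

    Click trains use 2-4 s inter-train intervals; sound pairs use 8-10 s
    between pairs (with the fixed 0.5-s C->T interval inside each pair).
    Intended for exercising the continuous-file readers and the epoching
    path end to end.
    """
    from .io import EventTable

    rng = np.random.default_rng(seed)
    fs = p.fs
    is_pair = isinstance(p, PairParams)
    n_ev = n_events if n_events is not None else p.n_trials
    iti_lo, iti_hi = PAIR_ITI if is_pair else CLICK_ITI
    span = PAIR_SPAN if is_pair else CLICK_SPAN
    onsets = []
    t_cursor = -span[0] + 0.5
    for _ in range(n_ev):
        onsets.append(t_cursor)
        t_cursor += rng.uniform(iti_lo, iti_hi)
    total = t_cursor + span[1] + 0.5
    n = int(round(total * fs))
    t = np.arange(n) / fs
    trace = gen_pink_noise(n, fs, p.noise_amp, rng)
    labels, times, pair_ids = [], [], []
    for k, onset in enumerate(onsets):
        if is_pair:
            rel = t - onset
            trace += pair_kernel(rel, p) * (np.abs(rel) < 1.0)
            relT = rel - p.isi
            sigma = p.width / (2.0 * np.sqrt(2.0 * np.log(2.0)))
            g = lambda tau: np.exp(-0.5 * (tau / sigma) ** 2)
            trace += ((p.ampN * p.gateN * g(relT - p.latN)
                       + p.ampP * p.gateP * g(relT - p.latP)) * (np.abs(relT) < 1.0))
            times += [onset, onset + p.isi]
            labels += ["C", "T"]
            pair_ids += [k, k]
        else:
            rel = t - onset
            env = _ramped_gate(rel, 0.0, p.train_dur)
            phi = rng.normal(0.0, p.phase_jitter_sd)
            trace += p.amp * np.cos(2 * np.pi * p.f_stim * rel + phi) * env
            times.append(onset)
            labels.append("train")
            pair_ids.append(k)
    return trace, EventTable(np.asarray(times), labels, np.asarray(pair_ids))
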