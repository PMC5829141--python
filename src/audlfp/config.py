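"""Run configuration for the ASSR / inhibitory-gating pipeline.

All analysis constants live in a single flat :class:`RunConfig` so that a run
is fully described by one small text file: the wavelet grid, the 35–45 Hz /
50–550 ms ASSR summary box, the per-region peak search windows, the 1-s
pre-stimulus control period and the significance level used to accept evoked
peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

REGIONS = ("AC", "HP", "AMY", "PFC")
CONDITIONS = ("conscious", "anesthetized")
STIMULI = ("click_train", "sound_pair")

#: Peak search windows (s, relative to each stimulus onset).  The auditory
#: cortex shows an earlier biphasic response (N25/P40) than the downstream
#: regions (N35/P70); windows bracket the expected latencies with margin.
DEFAULT_PEAK_WINDOWS: dict[str, dict[str, tuple[float, float]]] = {
    "AC": {"negative": (0.010, 0.040), "positive": (0.025, 0.060)},
    "HP": {"negative": (0.025, 0.055), "positive": (0.050, 0.095)},
    "AMY": {"negative": (0.025, 0.055), "positive": (0.050, 0.095)},
    "PFC": {"negative": (0.025, 0.055), "positive": (0.050, 0.095)},
}


@dataclass
class RunConfig:
    """Analysis constants for one pipeline run.

    Parameters
    ----------
    fs : sampling rate used for simulation and epoching (Hz).
    freq_min, freq_max, freq_step : wavelet frequency grid (Hz).
    n_cycles : Morlet cycles (constant across frequencies).
    assr_band : frequency interval for the ASSR summary (Hz).
    assr_window : time interval for the ASSR summary (s after train onset).
    control_period : null interval for peak significance (s rel. to C onset).
    alpha_peak : significance level at which an evoked peak is accepted.
    stat_halfwidth : half-width of the peak-amplitude averaging window (s).
    null_step : stride of the sliding null windows in the control period (s).
    t_onset_test : onset of the test (T) stimulus relative to C (s).
    seed : base random seed for anything stochastic downstream.
    """

    fs: float = 1000.0
    freq_min: float = 1.0
    freq_max: float = 100.0
    freq_step: float = 1.0
    n_cycles: float = 7.0
    assr_band: tuple[float, float] = (35.0, 45.0)
    assr_window: tuple[float, float] = (0.05, 0.55)
    control_period: tuple[float, float] = (-3.0, -2.0)
    alpha_peak: float = 0.01
    stat_halfwidth: float = 0.005
    null_step: float = 0.010
    t_onset_test: float = 0.5
    seed: int = 0
    peak_windows: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {
            r: {p: w for p, w in d.items()} for r, d in DEFAULT_PEAK_WINDOWS.items()
        }
    )

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha_peak < 1.0:
            raise ValueError(f"alpha_peak must be in (0, 1), got {self.alpha_peak}")
        if not self.freq_min <= self.assr_band[0] < self.assr_band[1] <= self.freq_max:
            raise ValueError(
                f"assr_band {self.assr_band} outside frequency grid "
                f"[{self.freq_min}, {self.freq_max}]"
            )
        if self.control_period[1] > 0.0:
            raise ValueError("control_period must precede stimulus onset (t < 0)")
        if self.control_period[0] >= self.control_period[1]:
            raise ValueError("control_period must be a nonempty interval")

    @property
    def freq_grid(self) -> np.ndarray:
        n = int(round((self.freq_max - self.freq_min) / self.freq_step)) + 1
        return self.freq_min + self.freq_step * np.arange(n)

    # --- flat key/value text serialization -------------------------------

    def to_text(self) -> str:
        lines = []
        for key in (
            "fs", "freq_min", "freq_max", "freq_step", "n_cycles",
            "alpha_peak", "stat_halfwidth", "null_step", "t_onset_test", "seed",
        ):
            lines.append(f"{key} = {getattr(self, key)!r}")
        for key in ("assr_band", "assr_window", "control_period"):
            lo, hi = getattr(self, key)
            lines.append(f"{key} = {lo!r} {hi!r}")
        for region, d in self.peak_windows.items():
            for pol, (lo, hi) in d.items():
                lines.append(f"peak_window_{region}_{pol} = {lo!r} {hi!r}")
        return "\n".join(lines) + "\n"

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_text())

    @classmethod
    def from_text(cls, text: str) -> "RunConfig":
        cfg = cls()
        windows = {r: dict(d) for r, d in cfg.peak_windows.items()}
        scalars: dict[str, float | int] = {}
        for ln, raw in enumerate(text.splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"config line {ln}: expected 'key = value', got {raw!r}")
            key, val = (s.strip() for s in line.split("=", 1))
            parts = val.split()
            if key.startswith("peak_window_"):
                _, _, region, pol = key.split("_", 3)
                if region not in windows or pol not in ("negative", "positive"):
                    raise ValueError(f"config line {ln}: unknown peak window key {key!r}")
                windows[region][pol] = (float(parts[0]), float(parts[1]))
            elif key in ("assr_band", "assr_window", "control_period"):
                scalars[key] = (float(parts[0]), float(parts[1]))
            elif key == "seed":
                scalars[key] = int(parts[0])
            elif hasattr(cfg, key):
                scalars[key] = float(parts[0])
            else:
                raise ValueError(f"config line {ln}: unknown key {key!r}")
        return replace(cls(**scalars), peak_windows=windows)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_text(fh.read())
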