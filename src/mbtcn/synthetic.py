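"""Synthetic ECG beat and record generator.

Each beat is a sum of Gaussian waves — the classic P-QRS-T decomposition —
with per-class morphology templates that are qualitatively distinct:

* **N**: full P-QRS-T complex;
* **S** (supraventricular ectopic): diminished, early P wave (shortened
  pre-R interval), otherwise narrow QRS;
* **V** (ventricular ectopic): widened QRS, absent P, discordant (inverted) T;
* **F** (fusion): midpoint blend of the N and V templates;
* **Q** (unknown/paced): low-amplitude flattened complex.

Templates place the R apex at ``r_index`` (default sample 100 of 250 at
360 Hz) so the generator's geometry matches the segmentation window.
Realism knobs are additive white noise, slow-sinusoid baseline wander and
50 Hz powerline interference, plus small random jitter of wave amplitudes,
centers and widths.  Everything is driven by explicit seeds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .preprocess import AAMI_MAP, CLASSES, BeatMatrix, EcgRecord
from .io.wfdb import write_record

__all__ = [
    "Wave", "MorphologyTemplate", "GeneratorConfig", "TEMPLATES",
    "generate_beat", "generate_dataset", "generate_record", "add_noise",
    "largest_remainder_counts",
]


@dataclass(frozen=True)
class Wave:
    """One Gaussian component: amplitude (mV), center offset from R (samples),
    width (samples, Gaussian sigma)."""

    amplitude: float
    center: float
    width: float

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("wave width must be positive")


@dataclass(frozen=True)
class MorphologyTemplate:
    """Per-class set of Gaussian waves."""

    cls: str
    waves: tuple[Wave, ...]

    def render(self, length: int, r_index: int) -> np.ndarray:
        t = np.arange(length) - r_index
        out = np.zeros(length)
        for w in self.waves:
            out += w.amplitude * np.exp(-0.5 * ((t - w.center) / w.width) ** 2)
        return out


def _blend(a: MorphologyTemplate, b: MorphologyTemplate,
           cls: str) -> MorphologyTemplate:
    waves = tuple(Wave(w.amplitude * 0.5, w.center, w.width)
                  for w in a.waves + b.waves)
    return MorphologyTemplate(cls, waves)


_N = MorphologyTemplate("N", (
    Wave(0.15, -54, 10),    # P
    Wave(-0.10, -9, 3),     # Q
    Wave(1.20, 0, 5),       # R
    Wave(-0.25, 9, 4),      # S
    Wave(0.30, 80, 22),     # T
))
_S = MorphologyTemplate("S", (
    Wave(0.05, -34, 7),     # early, diminished ectopic P
    Wave(-0.08, -8, 3),
    Wave(1.10, 0, 5),
    Wave(-0.22, 8, 4),
    Wave(0.26, 72, 20),
))
_V = MorphologyTemplate("V", (
    Wave(1.00, 0, 14),      # broad R, no P
    Wave(-0.45, 26, 8),     # deep slurred S
    Wave(-0.35, 85, 24),    # discordant T
))
_Q = MorphologyTemplate("Q", (
    Wave(0.40, 0, 12),      # flattened low-amplitude complex
    Wave(-0.12, 24, 10),
    Wave(0.10, 82, 26),
))

#: Frozen per-class morphology templates (F is the N/V midpoint blend).
TEMPLATES: dict[str, MorphologyTemplate] = {
    "N": _N, "S": _S, "V": _V, "F": _blend(_N, _V, "F"), "Q": _Q,
}

#: AAMI class -> the annotation symbols it aggregates (inverse label map).
CLASS_SYMBOLS: dict[str, tuple[str, ...]] = {
    c: tuple(s for s, a in AAMI_MAP.items() if a == c) for c in CLASSES
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the generator.

    Default class proportions mirror the published MIT-BIH composition used
    throughout this package (N 68.5%, S 2.5%, V 6.5%, F 0.7%, remainder Q),
    so the balancing code paths face a realistic imbalance.
    """

    fs: float = 360.0
    beat_length: int = 250
    r_index: int = 100
    class_proportions: tuple[float, ...] = (0.685, 0.025, 0.065, 0.007, 0.218)
    white_sigma: float = 0.05          # mV
    baseline_amplitude: float = 0.10   # mV
    baseline_freq: float = 0.30        # Hz (< 0.5 Hz)
    powerline_amplitude: float = 0.05  # mV at 50 Hz
    powerline_freq: float = 50.0
    jitter_amplitude: float = 0.20     # relative sd of wave amplitudes
    jitter_center: float = 4.0         # samples sd of wave centers (P/T only)
    jitter_width: float = 0.20         # relative sd of wave widths
    fusion_spread: float = 0.15        # half-range of the F-beat N/V blend
    seed: int = 0

    def __post_init__(self):
        if len(self.class_proportions) != len(CLASSES):
            raise ValueError("need one proportion per AAMI class")
        if abs(sum(self.class_proportions) - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")

    def noiseless(self) -> "GeneratorConfig":
        return replace(self, white_sigma=0.0, baseline_amplitude=0.0,
                       powerline_amplitude=0.0, jitter_amplitude=0.0,
                       jitter_center=0.0, jitter_width=0.0)


def largest_remainder_counts(proportions: np.ndarray, total: int) -> np.ndarray:
    """Integer counts summing exactly to ``total``, proportional to weights."""
    proportions = np.asarray(proportions, dtype=np.float64)
    raw = proportions / proportions.sum() * total
    base = np.floor(raw).astype(int)
    short = total - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:short]] += 1
    return base


def _jittered_template(cls: str, cfg: GeneratorConfig,
                       rng: np.random.Generator) -> np.ndarray:
    t = np.arange(cfg.beat_length) - cfg.r_index
    out = np.zeros(cfg.beat_length)
    if cls == "F":
        # fusion beats vary in fusion degree: per-beat blend fraction of the
        # N and V morphologies (fixed midpoint when jitter is disabled)
        lam = 0.5
        if cfg.jitter_amplitude > 0 and cfg.fusion_spread > 0:
            lam = rng.uniform(0.5 - cfg.fusion_spread,
                              0.5 + cfg.fusion_spread)
        waves = tuple(Wave(w.amplitude * (1.0 - lam), w.center, w.width)
                      for w in TEMPLATES["N"].waves) + \
            tuple(Wave(w.amplitude * lam, w.center, w.width)
                  for w in TEMPLATES["V"].waves)
    else:
        waves = TEMPLATES[cls].waves
    for w in waves:
        amp = w.amplitude * (1.0 + cfg.jitter_amplitude * rng.standard_normal())
        # keep the R apex anchored: only off-center waves get center jitter
        center = w.center
        if abs(w.center) > 15 and cfg.jitter_center > 0:
            center = w.center + cfg.jitter_center * rng.standard_normal()
        width = w.width * (1.0 + cfg.jitter_width * rng.standard_normal())
        width = max(width, 0.5)
        out += amp * np.exp(-0.5 * ((t - center) / width) ** 2)
    return out


def add_noise(signal: np.ndarray, kind: str, level: float, seed: int = 0,
              fs: float = 360.0, freq: float | None = None) -> np.ndarray:
    """Additive contamination of the named kind at the given amplitude/sd."""
    signal = np.asarray(signal, dtype=np.float64)
    if level < 0:
        raise ValueError("noise level must be non-negative")
    if level == 0:
        return signal.copy()
    rng = np.random.default_rng(seed)
    t = np.arange(signal.size) / fs
    if kind == "white":
        return signal + level * rng.standard_normal(signal.size)
    if kind == "baseline":
        f = 0.3 if freq is None else freq
        return signal + level * np.sin(2 * np.pi * f * t
                                       + rng.uniform(0, 2 * np.pi))
    if kind == "powerline":
        f = 50.0 if freq is None else freq
        return signal + level * np.sin(2 * np.pi * f * t
                                       + rng.uniform(0, 2 * np.pi))
    raise ValueError(f"unknown noise kind {kind!r}")


def generate_beat(cls: str, cfg: GeneratorConfig = GeneratorConfig(),
                  seed: int = 0) -> np.ndarray:
    """One labelled beat: jittered class template plus configured noise."""
    if cls not in TEMPLATES:
        raise ValueError(f"unknown AAMI class {cls!r}")
    rng = np.random.default_rng(seed)
    beat = _jittered_template(cls, cfg, rng)
    t = np.arange(cfg.beat_length) / cfg.fs
    if cfg.baseline_amplitude > 0:
        beat = beat + cfg.baseline_amplitude * np.sin(
            2 * np.pi * cfg.baseline_freq * t + rng.uniform(0, 2 * np.pi))
    if cfg.powerline_amplitude > 0:
        beat = beat + cfg.powerline_amplitude * np.sin(
            2 * np.pi * cfg.powerline_freq * t + rng.uniform(0, 2 * np.pi))
    if cfg.white_sigma > 0:
        beat = beat + cfg.white_sigma * rng.standard_normal(cfg.beat_length)
    return beat


def generate_dataset(cfg: GeneratorConfig = GeneratorConfig(),
                     n: int = 10_000) -> BeatMatrix:
    """A labelled beat table with class counts proportional to the config.

    Counts follow largest-remainder rounding of the proportions, rows are
    shuffled, and the whole draw is reproducible from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    counts = largest_remainder_counts(np.array(cfg.class_proportions), n)
    beats = np.empty((n, cfg.beat_length))
    labels = np.empty(n, dtype="U1")
    row = 0
    for cls, count in zip(CLASSES, counts):
        for _ in range(count):
            beats[row] = generate_beat(cls, cfg,
                                       seed=int(rng.integers(2 ** 31)))
            labels[row] = cls
            row += 1
    perm = rng.permutation(n)
    return BeatMatrix(beats[perm], labels[perm],
                      synthetic_flags=np.ones(n, dtype=bool))


def generate_record(n_beats: int, cfg: GeneratorConfig = GeneratorConfig(),
                    rr_interval: float = 0.8,
                    write_dir=None, record_id: str = "synth") -> EcgRecord:
    """A continuous annotated record of ``n_beats`` concatenated beats.

    R-peaks are spaced ``rr_interval`` seconds apart; every annotation stores
    the true R index with a symbol drawn from the class's annotation-symbol
    pool.  If ``write_dir`` is given the record is also written as a WFDB
    header/signal/annotation triple.
    """
    if n_beats < 1:
        raise ValueError("need at least one beat")
    rng = np.random.default_rng(cfg.seed)
    rr = int(round(rr_interval * cfg.fs))
    if rr < cfg.beat_length:
        warnings.warn("RR interval shorter than the beat window; "
                      "adjacent windows will overlap")
    length = cfg.r_index + n_beats * rr + cfg.beat_length
    sig = np.zeros(length)
    annotations: list[tuple[int, str]] = []
    probs = np.asarray(cfg.class_proportions)
    for i in range(n_beats):
        cls = str(rng.choice(list(CLASSES), p=probs))
        r_pos = cfg.r_index + i * rr
        beat = _jittered_template(cls, cfg, rng)
        sig[r_pos - cfg.r_index: r_pos - cfg.r_index + cfg.beat_length] += beat
        symbol = str(rng.choice(CLASS_SYMBOLS[cls]))
        annotations.append((r_pos, symbol))
    base_seed = int(rng.integers(2 ** 31))
    sig = add_noise(sig, "baseline", cfg.baseline_amplitude, base_seed, cfg.fs,
                    cfg.baseline_freq)
    sig = add_noise(sig, "powerline", cfg.powerline_amplitude, base_seed + 1,
                    cfg.fs, cfg.powerline_freq)
    sig = add_noise(sig, "white", cfg.white_sigma, base_seed + 2, cfg.fs)
    record = EcgRecord(signal=sig, fs=cfg.fs, annotations=annotations,
                       record_id=record_id)
    if write_dir is not None:
        write_record(write_dir, record_id, sig, cfg.fs, annotations)
    return record
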