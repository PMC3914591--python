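"""Synthetic multi-class signal generator for end-to-end pipeline testing.

Each class is an AR(2) resonance — the simplest stationary process with a
tunable spectral peak, so windows of one class share a common covariance
structure — driven by unit-variance white noise, scaled by a per-class gain,
plus optional Poisson-placed raised-cosine spike transients (50 ms width) and
additive white measurement noise.  Class differences therefore live in
(i) the within-window correlation/spectral structure (peak frequency and
bandwidth) and (ii) the average window power (gain), the two axes the
windowed-PCA feature schemes are designed to pick up.

Two presets ship with the package: a "bonn-like" set of five short-segment
single-channel classes (two low-power normal-like, two interictal-like with
spikes, one high-power low-frequency ictal-like rhythm) and a "freiburg-like"
two-class set with matched power but distinct spectral peaks, where energy
alone cannot discriminate.  Presets are stored as YAML files and are fully
deterministic under their master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence, Union

import numpy as np
import yaml
from scipy.signal import lfilter

from .types import Signal

__all__ = [
    "ClassSpec",
    "DatasetSpec",
    "ar2_coefficients",
    "ar2_variance",
    "generate_signal",
    "generate_dataset",
    "load_preset",
    "bonn_like",
    "freiburg_like",
]

SPIKE_WIDTH_SECONDS = 0.05  # raised-cosine transient width, fixed
_BURN_IN = 2048             # samples discarded so the AR process is stationary


@dataclass
class ClassSpec:
    """Generative parameters of one signal class.

    ``center_frequency`` (Hz) and ``bandwidth`` (Hz) place the AR(2) spectral
    peak; ``amplitude_scale`` multiplies the resonance output;
    ``spike_rate`` (events/s) and ``spike_amplitude`` control transients;
    ``noise_sd`` is the standard deviation of additive white noise.
    """

    label: str
    center_frequency: float
    bandwidth: float
    amplitude_scale: float = 1.0
    spike_rate: float = 0.0
    spike_amplitude: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude_scale < 0:
            raise ValueError("amplitude_scale must be >= 0")
        if self.spike_rate < 0:
            raise ValueError("spike_rate must be >= 0")
        if self.bandwidth <= 0:
            raise ValueError("bandwidth must be > 0")


@dataclass
class DatasetSpec:
    """A full labelled dataset: classes × replicates, one master seed."""

    classes: list
    n_signals_per_class: int
    signal_length: int
    sample_rate: float
    seed: int = 0
    name: str = "custom"

    def __post_init__(self) -> None:
        if self.n_signals_per_class < 1:
            raise ValueError("n_signals_per_class must be >= 1")
        if self.signal_length < 1:
            raise ValueError("signal_length must be >= 1")


def ar2_coefficients(center_frequency: float, bandwidth: float,
                     sample_rate: float) -> tuple[float, float]:
    """AR(2) coefficients placing a resonance at ``center_frequency``.

    The complex pole pair sits at radius ``r = exp(-pi * bandwidth / fs)``
    and angle ``2*pi*f0/fs``, the standard resonator design:
    ``x[t] = a1*x[t-1] + a2*x[t-2] + e[t]`` with ``a1 = 2r cos(theta)``,
    ``a2 = -r^2``.
    """
    if not 0 < center_frequency < sample_rate / 2:
        raise ValueError(
            f"center_frequency must lie in (0, Nyquist={sample_rate / 2}), "
            f"got {center_frequency}"
        )
    r = np.exp(-np.pi * bandwidth / sample_rate)
    theta = 2 * np.pi * center_frequency / sample_rate
    return 2 * r * np.cos(theta), -r * r


def ar2_variance(center_frequency: float, bandwidth: float,
                 sample_rate: float) -> float:
    """Stationary variance of the unit-variance-driven AR(2) resonance.

    Closed form for ``x[t] = a1 x[t-1] + a2 x[t-2] + e[t]``, Var(e)=1:
    ``gamma0 = (1 - a2) / ((1 + a2) ((1 - a2)^2 - a1^2))``.
    """
    a1, a2 = ar2_coefficients(center_frequency, bandwidth, sample_rate)
    return (1 - a2) / ((1 + a2) * ((1 - a2) ** 2 - a1 ** 2))


def class_variance(spec: ClassSpec, sample_rate: float) -> float:
    """Analytic variance of the spike-free part of a class: AR(2) + noise."""
    g0 = ar2_variance(spec.center_frequency, spec.bandwidth, sample_rate)
    return spec.amplitude_scale ** 2 * g0 + spec.noise_sd ** 2


def _spike_template(sample_rate: float) -> np.ndarray:
    width = max(3, int(round(SPIKE_WIDTH_SECONDS * sample_rate)))
    return np.hanning(width)


SeedLike = Union[int, np.random.SeedSequence, np.random.Generator]


def generate_signal(spec: ClassSpec, n_samples: int, sample_rate: float,
                    seed: SeedLike) -> Signal:
    """Draw one signal of ``n_samples`` from a class specification.

    The same seed always yields a bit-identical sample sequence.  The AR(2)
    process is run through a burn-in so the returned stretch is stationary.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    a1, a2 = ar2_coefficients(spec.center_frequency, spec.bandwidth,
                              sample_rate)
    rng = np.random.default_rng(seed)
    drive = rng.standard_normal(n_samples + _BURN_IN)
    resonance = lfilter([1.0], [1.0, -a1, -a2], drive)[_BURN_IN:]
    x = spec.amplitude_scale * resonance
    if spec.noise_sd > 0:
        x = x + spec.noise_sd * rng.standard_normal(n_samples)
    if spec.spike_rate > 0 and spec.spike_amplitude != 0:
        template = _spike_template(sample_rate)
        duration = n_samples / sample_rate
        n_spikes = rng.poisson(spec.spike_rate * duration)
        width = template.size
        for _ in range(n_spikes):
            start = int(rng.integers(0, max(1, n_samples - width + 1)))
            sign = 1.0 if rng.random() < 0.5 else -1.0
            stop = min(start + width, n_samples)
            x[start:stop] += sign * spec.spike_amplitude * template[: stop - start]
    return Signal(samples=x, sample_rate=sample_rate, label=spec.label,
                  source_id=f"synthetic:{spec.label}")


def generate_dataset(spec: DatasetSpec) -> list[Signal]:
    """Generate ``n_signals_per_class`` signals per class, deterministically.

    The per-signal seed is ``SeedSequence([master_seed, class_index,
    replicate_index])`` — collision-free and fully determined by the master
    seed.
    """
    signals = []
    for ci, cls in enumerate(spec.classes):
        for ri in range(spec.n_signals_per_class):
            child = np.random.SeedSequence([int(spec.seed), ci, ri])
            sig = generate_signal(cls, spec.signal_length, spec.sample_rate,
                                  child)
            sig.source_id = f"{spec.name}:{cls.label}:{ri}"
            signals.append(sig)
    return signals


# ---------------------------------------------------------------------------
# presets

def _class_from_mapping(entry: dict, sample_rate: float) -> ClassSpec:
    entry = dict(entry)
    target_rms = entry.pop("target_rms", None)
    if target_rms is not None:
        # gain chosen so the AR(2) part has exactly this RMS
        g0 = ar2_variance(entry["center_frequency"], entry["bandwidth"],
                          sample_rate)
        entry["amplitude_scale"] = float(target_rms) / float(np.sqrt(g0))
    return ClassSpec(**entry)


def load_preset(name: str, seed: Optional[int] = None) -> DatasetSpec:
    """Load a shipped preset ('bonn_like' or 'freiburg_like') as a DatasetSpec.

    ``seed`` overrides the preset's default master seed.
    """
    path = resources.files("dpcawin.presets").joinpath(f"{name}.yaml")
    try:
        text = path.read_text()
    except FileNotFoundError:
        raise ValueError(f"unknown preset {name!r}") from None
    cfg = yaml.safe_load(text)
    classes = [_class_from_mapping(c, cfg["sample_rate"]) for c in cfg["classes"]]
    return DatasetSpec(
        classes=classes,
        n_signals_per_class=cfg["n_signals_per_class"],
        signal_length=cfg["signal_length"],
        sample_rate=cfg["sample_rate"],
        seed=cfg["seed"] if seed is None else seed,
        name=name,
    )


def bonn_like(seed: Optional[int] = None) -> DatasetSpec:
    """Five-class short-segment preset: normal / interictal / ictal-like."""
    return load_preset("bonn_like", seed)


def freiburg_like(seed: Optional[int] = None) -> DatasetSpec:
    """Two-class equal-power, distinct-spectrum preset."""
    return load_preset("freiburg_like", seed)
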