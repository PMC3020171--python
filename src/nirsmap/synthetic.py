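"""Synthetic multichannel NIRS generator with known ground truth.

No public recording accompanies the online mapping framework, so every test
and demo runs on simulated dHbO series that emulate the signal and noise
structure of real block-design NIRS at 1.81 Hz:

* a task response — amplitude x (stimulus boxcar convolved with the
  double-gamma response, peak-normalized) — on the designated active channels;
* sinusoidal physiological oscillations: cardiac (~1.1 Hz, deliberately above
  the Nyquist rate of the default protocol so realistic aliasing is
  exercised), respiratory (~0.3 Hz) and Mayer-wave (~0.1 Hz) components;
* very-low-frequency drift, modelled as a slow sinusoid (0.002 Hz) plus a
  random walk — the optode-shift/baseline-wander class of artifact, which in
  real recordings dwarfs the ~1 uM hemodynamic response (default amplitude
  5 uM);
* AR(1)-correlated measurement noise, the temporal-correlation surrogate for
  unmodelled physiology.

The generator is fully deterministic given its seed, and each channel's trace
is exactly the sum of the components it reports.  What the generator does NOT
emulate: motion-spike artifacts, nonlinear hemodynamics (balloon-type
models), spatially correlated noise across channels, and subject-specific
response-shape variability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .design import (FINGER_TAPPING_PROTOCOL, HRFParams, ProtocolSpec,
                     double_gamma_kernel, stimulus_vector)
from .mbll import HemoSeries, IntensitySeries, OpticalConstants, hemoglobin_to_od

__all__ = ["PhysioComponent", "DriftSpec", "SimSpec", "SimOutput", "simulate",
           "simulate_intensity", "DEFAULT_PHYSIO"]


@dataclass(frozen=True)
class PhysioComponent:
    """One sinusoidal physiological noise source."""

    frequency_hz: float
    amplitude_um: float
    phase_rad: float = 0.0


#: Default physiological noise inventory: cardiac, respiratory, Mayer wave.
DEFAULT_PHYSIO: tuple[PhysioComponent, ...] = (
    PhysioComponent(1.1, 0.10),
    PhysioComponent(0.3, 0.15),
    PhysioComponent(0.1, 0.25),
)


@dataclass(frozen=True)
class DriftSpec:
    """Very-low-frequency drift: slow sinusoid plus random walk.

    ``sine_phase_rad=None`` draws an independent phase per channel from the
    simulation RNG, so drift realizations differ across channels and seeds.
    """

    sine_frequency_hz: float = 0.002
    sine_amplitude_um: float = 5.0
    sine_phase_rad: float | None = None
    random_walk_sd_um: float = 0.01


@dataclass(frozen=True)
class SimSpec:
    """Full description of one simulated recording."""

    protocol: ProtocolSpec = FINGER_TAPPING_PROTOCOL
    n_channels: int = 24
    active_channels: tuple[int, ...] = (5,)  # 0-based; channel "ch6"
    amplitude_um: float = 1.0
    noise_sd_um: float = 0.5
    ar_rho: float = 0.0
    physio: tuple[PhysioComponent, ...] = ()
    drift: DriftSpec | None = None
    hrf: HRFParams = field(default_factory=HRFParams)
    hbr_coupling: float = -0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if any(not 0 <= c < self.n_channels for c in self.active_channels):
            raise ValueError("active_channels outside channel range")
        if self.amplitude_um < 0 or self.noise_sd_um < 0:
            raise ValueError("amplitudes must be non-negative")
        if not abs(self.ar_rho) < 1:
            raise ValueError("|ar_rho| must be < 1")

    @classmethod
    def realistic(cls, **overrides) -> "SimSpec":
        """Defaults with the physiological and drift noise sources enabled."""
        kw = dict(physio=DEFAULT_PHYSIO, drift=DriftSpec())
        kw.update(overrides)
        return cls(**kw)


@dataclass
class SimOutput:
    """Simulated recording plus its ground truth and component decomposition."""

    hemo: HemoSeries
    truth_beta1: np.ndarray          # per-channel true task coefficient (uM)
    truth_active: np.ndarray         # per-channel bool
    components: dict[str, np.ndarray]
    spec: SimSpec


def _task_regressor(spec: SimSpec) -> np.ndarray:
    stim = stimulus_vector(spec.protocol)
    kernel = double_gamma_kernel(spec.hrf, spec.protocol.sampling_rate_hz)
    task = np.convolve(stim, kernel)[: spec.protocol.n_samples]
    peak = np.max(np.abs(task))
    return task / peak if peak > 0 else task


def simulate(spec: SimSpec) -> SimOutput:
    """Generate the dHbO series described by ``spec``.

    Each component is offset to start at zero (the MBLL referencing step fixes
    the first sample of any real recording at zero), so the output is both a
    valid :class:`HemoSeries` and exactly the sum of the reported components.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.protocol.n_samples
    ch = spec.n_channels
    fs = spec.protocol.sampling_rate_hz
    t = np.arange(n) / fs

    truth_beta1 = np.zeros(ch)
    truth_beta1[list(spec.active_channels)] = spec.amplitude_um
    task = truth_beta1[None, :] * _task_regressor(spec)[:, None]

    physio = np.zeros((n, ch))
    for comp in spec.physio:
        wave = comp.amplitude_um * np.sin(
            2 * np.pi * comp.frequency_hz * t + comp.phase_rad
        )
        physio += (wave - wave[0])[:, None]

    drift = np.zeros((n, ch))
    if spec.drift is not None:
        d = spec.drift
        if d.sine_phase_rad is None:
            phases = rng.uniform(0.0, 2 * np.pi, ch)
        else:
            phases = np.full(ch, d.sine_phase_rad)
        sine = d.sine_amplitude_um * np.sin(
            2 * np.pi * d.sine_frequency_hz * t[:, None] + phases[None, :]
        )
        drift += sine - sine[0]
        if d.random_walk_sd_um > 0:
            walk = np.cumsum(rng.normal(0, d.random_walk_sd_um, (n, ch)), axis=0)
            drift += walk - walk[0]

    noise = np.zeros((n, ch))
    if spec.noise_sd_um > 0:
        innov = rng.normal(0.0, spec.noise_sd_um, (n, ch))
        if spec.ar_rho:
            # stationary AR(1) start, then recursion
            u = np.empty((n, ch))
            u[0] = rng.normal(0.0, spec.noise_sd_um / np.sqrt(1 - spec.ar_rho**2), ch)
            for k in range(1, n):
                u[k] = spec.ar_rho * u[k - 1] + innov[k]
            noise = u
        else:
            noise = innov
        noise = noise - noise[0]

    total = task + physio + drift + noise
    hemo = HemoSeries(
        delta_hbo=total,
        delta_hbr=spec.hbr_coupling * total,
        sampling_rate_hz=fs,
    )
    return SimOutput(
        hemo=hemo,
        truth_beta1=truth_beta1,
        truth_active=truth_beta1 > 0,
        components={"task": task, "physio": physio, "drift": drift,
                    "noise": noise},
        spec=spec,
    )


def simulate_intensity(
    spec: SimSpec,
    constants: OpticalConstants,
    baseline_intensity: float | Sequence[float] = 1.0,
) -> tuple[IntensitySeries, SimOutput]:
    """Simulate raw dual-wavelength intensities via the forward MBLL.

    The simulated (dHbO, dHbR) pair is mapped to dOD at both wavelengths and
    then to intensities I(k) = I(0) * 10^(-dOD(k)); feeding the result through
    the MBLL module recovers the concentrations exactly (up to rounding).
    """
    out = simulate(spec)
    od = hemoglobin_to_od(
        out.hemo.delta_hbo,
        out.hemo.delta_hbr,
        constants,
        out.hemo.sampling_rate_hz,
        out.hemo.channel_names,
    )
    i0 = np.broadcast_to(
        np.asarray(baseline_intensity, dtype=float), od.delta_od.shape[1:]
    )
    if np.any(i0 <= 0):
        raise ValueError("baseline_intensity must be positive")
    samples = i0[None] * 10.0 ** (-od.delta_od)
    raw = IntensitySeries(
        samples, constants.wavelengths, out.hemo.sampling_rate_hz,
        out.hemo.channel_names,
    )
    return raw, out
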