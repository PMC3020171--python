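"""Modified Beer-Lambert law (MBLL) conversion.

Continuous-wave NIRS instruments record back-scattered light intensity at two
wavelengths per channel.  Changes in optical density relative to a reference
time step are, under the MBLL, a linear combination of the oxy- (HbO) and
deoxy-hemoglobin (HbR) concentration changes::

    dOD(lambda) = (a_HbO(lambda) * dC_HbO + a_HbR(lambda) * dC_HbR) * L * DPF(lambda)

where ``a_*`` are extinction coefficients (uM^-1 mm^-1), ``L`` the
source-detector separation (mm) and ``DPF`` the differential path length
factor.  With two wavelengths this is a 2x2 linear system per channel and time
step, inverted here to recover the concentration changes in uM.

Optical density changes use the base-10 logarithm of the intensity ratio
(the standard MBLL convention): ``dOD(k) = -log10(I(k) / I(ref))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_EXTINCTION",
    "OpticalConstants",
    "IntensitySeries",
    "ODSeries",
    "HemoSeries",
    "intensity_to_od",
    "od_to_hemoglobin",
    "hemoglobin_to_od",
    "hemoglobin_channel_signal",
]

#: Extinction coefficients in uM^-1 mm^-1, keyed by wavelength (nm), as
#: (a_HbO, a_HbR).  Values from the standard Gratzer/Cope compilation of
#: hemoglobin spectra (originally cm^-1 M^-1, converted by 1e-7).
DEFAULT_EXTINCTION: Dict[float, Tuple[float, float]] = {
    760.0: (1.4866e-4, 3.8437e-4),
    830.0: (2.3215e-4, 1.7917e-4),
}


class MBLLConfigError(ValueError):
    """Raised for unusable optical constants (e.g. singular extinction matrix)."""


@dataclass(frozen=True)
class OpticalConstants:
    """Optical constants entering the MBLL.

    Parameters
    ----------
    distance_mm
        Source-detector separation ``L`` in mm.  No default is applied:
        it is geometry-dependent and must be supplied explicitly.
    wavelengths
        The two laser wavelengths in nm.
    ext_coeffs
        Mapping wavelength -> (a_HbO, a_HbR) in uM^-1 mm^-1.
    dpf
        Differential path length factor, either a scalar applied at both
        wavelengths or a mapping wavelength -> DPF.  Default 6.0, a common
        adult-head value.
    max_condition
        Upper bound on the condition number of the 2x2 extinction matrix.
    """

    distance_mm: float
    wavelengths: Tuple[float, float] = (760.0, 830.0)
    ext_coeffs: Dict[float, Tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_EXTINCTION)
    )
    dpf: object = 6.0
    max_condition: float = 1e6

    def __post_init__(self) -> None:
        if len(self.wavelengths) != 2:
            raise MBLLConfigError("exactly two wavelengths are required")
        if self.distance_mm <= 0:
            raise MBLLConfigError("distance_mm must be positive")
        for lam in self.wavelengths:
            if lam not in self.ext_coeffs:
                raise MBLLConfigError(f"no extinction coefficients for {lam} nm")
            if self.dpf_at(lam) <= 0:
                raise MBLLConfigError("DPF must be positive")
        m = self.extinction_matrix()
        cond = np.linalg.cond(m)
        if not np.isfinite(cond) or cond > self.max_condition:
            raise MBLLConfigError(
                f"extinction matrix is singular/ill-conditioned (cond={cond:.3g})"
            )

    def dpf_at(self, wavelength: float) -> float:
        if isinstance(self.dpf, dict):
            return float(self.dpf[wavelength])
        return float(self.dpf)

    def extinction_matrix(self) -> np.ndarray:
        """2x2 matrix [[a_HbO(l1), a_HbR(l1)], [a_HbO(l2), a_HbR(l2)]]."""
        return np.array([self.ext_coeffs[lam] for lam in self.wavelengths])

    def pathlength_factors(self) -> np.ndarray:
        """Per-wavelength effective path lengths L * DPF(lambda) in mm."""
        return np.array(
            [self.distance_mm * self.dpf_at(lam) for lam in self.wavelengths]
        )


@dataclass
class IntensitySeries:
    """Raw light intensity, shape (n_samples, n_channels, 2 wavelengths)."""

    samples: np.ndarray
    wavelengths: Tuple[float, float]
    sampling_rate_hz: float
    channel_names: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 3 or self.samples.shape[2] != 2:
            raise ValueError(
                "samples must have shape (n_samples, n_channels, 2 wavelengths)"
            )
        if self.channel_names is None:
            self.channel_names = [f"ch{i + 1}" for i in range(self.n_channels)]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        wavelengths: Tuple[float, float],
        sampling_rate_hz: float,
    ) -> "IntensitySeries":
        """Parse the ``ch<i>_w<lambda>`` column convention into a series."""
        chans: list[str] = []
        for col in df.columns:
            name, _, w = col.rpartition("_w")
            if not w:
                raise ValueError(f"column {col!r} does not match ch<i>_w<lambda>")
            if name not in chans:
                chans.append(name)
        data = np.empty((len(df), len(chans), 2))
        for ci, ch in enumerate(chans):
            for wi, lam in enumerate(wavelengths):
                col = f"{ch}_w{lam:g}"
                if col not in df.columns:
                    raise ValueError(f"missing column {col!r}")
                data[:, ci, wi] = df[col].to_numpy(dtype=float)
        return cls(data, tuple(wavelengths), sampling_rate_hz, chans)


@dataclass
class ODSeries:
    """Optical-density changes, shape (n_samples, n_channels, 2)."""

    delta_od: np.ndarray
    wavelengths: Tuple[float, float]
    sampling_rate_hz: float
    channel_names: Sequence[str] | None = None

    @property
    def n_samples(self) -> int:
        return self.delta_od.shape[0]

    @property
    def n_channels(self) -> int:
        return self.delta_od.shape[1]


@dataclass
class HemoSeries:
    """Hemoglobin concentration changes per channel, in uM.

    ``delta_hbo`` and ``delta_hbr`` have shape (n_samples, n_channels) and are
    zero at the reference sample by construction.
    """

    delta_hbo: np.ndarray
    delta_hbr: np.ndarray
    sampling_rate_hz: float
    channel_names: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.delta_hbo = np.asarray(self.delta_hbo, dtype=float)
        self.delta_hbr = np.asarray(self.delta_hbr, dtype=float)
        if self.delta_hbo.shape != self.delta_hbr.shape:
            raise ValueError("HbO and HbR arrays must share one shape")
        if self.channel_names is None:
            self.channel_names = [f"ch{i + 1}" for i in range(self.n_channels)]

    @property
    def n_samples(self) -> int:
        return self.delta_hbo.shape[0]

    @property
    def n_channels(self) -> int:
        return self.delta_hbo.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        cols = {}
        for i, ch in enumerate(self.channel_names):
            cols[f"{ch}_hbo"] = self.delta_hbo[:, i]
            cols[f"{ch}_hbr"] = self.delta_hbr[:, i]
        return pd.DataFrame(cols)


def intensity_to_od(raw: IntensitySeries, reference_index: int = 0) -> ODSeries:
    """Convert intensity to optical-density change relative to a reference step.

    ``dOD(k) = -log10(I(k) / I(reference))`` per channel and wavelength, so the
    reference step has dOD exactly zero.  Raises ``ValueError`` naming the
    offending channel / wavelength / step for non-positive intensities.
    """
    samples = raw.samples
    if not (0 <= reference_index < raw.n_samples):
        raise IndexError(f"reference_index {reference_index} out of range")
    bad = np.argwhere(~(samples > 0))
    if bad.size:
        k, c, w = bad[0]
        raise ValueError(
            f"non-positive intensity at step {k}, channel "
            f"{raw.channel_names[c]}, wavelength {raw.wavelengths[w]:g} nm"
        )
    ref = samples[reference_index]
    dod = -np.log10(samples / ref)
    dod[reference_index] = 0.0  # exact zero at the reference step
    return ODSeries(dod, raw.wavelengths, raw.sampling_rate_hz, raw.channel_names)


def od_to_hemoglobin(od: ODSeries, constants: OpticalConstants) -> HemoSeries:
    """Invert the MBLL: solve the per-sample 2x2 system for (dHbO, dHbR)."""
    if tuple(od.wavelengths) != tuple(constants.wavelengths):
        raise MBLLConfigError("wavelength mismatch between data and constants")
    # dOD_l = (E @ [dHbO, dHbR])_l * (L * DPF_l)  ->  scale rows, invert once
    m = constants.extinction_matrix() * constants.pathlength_factors()[:, None]
    minv = np.linalg.inv(m)
    conc = np.einsum("ij,kcj->kci", minv, od.delta_od)
    return HemoSeries(
        conc[:, :, 0], conc[:, :, 1], od.sampling_rate_hz, od.channel_names
    )


def hemoglobin_to_od(
    delta_hbo: np.ndarray,
    delta_hbr: np.ndarray,
    constants: OpticalConstants,
    sampling_rate_hz: float,
    channel_names: Sequence[str] | None = None,
) -> ODSeries:
    """Forward MBLL: map concentration changes (uM) to dOD at both wavelengths."""
    conc = np.stack([np.asarray(delta_hbo), np.asarray(delta_hbr)], axis=-1)
    m = constants.extinction_matrix() * constants.pathlength_factors()[:, None]
    dod = np.einsum("ij,kcj->kci", m, conc)
    return ODSeries(dod, constants.wavelengths, sampling_rate_hz, channel_names)


def hemoglobin_channel_signal(
    h: HemoSeries, channel: int | str, chromophore: str = "hbo"
) -> np.ndarray:
    """Select one channel's HbO (default) or HbR series for the estimator."""
    if isinstance(channel, str):
        try:
            idx = list(h.channel_names).index(channel)
        except ValueError:
            raise KeyError(f"unknown channel {channel!r}") from None
    else:
        idx = int(channel)
        if not (0 <= idx < h.n_channels):
            raise KeyError(f"channel index {channel} out of range")
    chromophore = chromophore.lower()
    if chromophore == "hbo":
        return h.delta_hbo[:, idx]
    if chromophore == "hbr":
        return h.delta_hbr[:, idx]
    raise ValueError(f"chromophore must be 'hbo' or 'hbr', got {chromophore!r}")
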