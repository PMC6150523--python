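"""Synthetic coelomic-fluid fluorescence spectra and Mp/Mn peak calling.

The M-fluorophore fingerprint is an excitation peak near 320 nm (recorded
260-360 nm) and an emission peak near 380 nm (recorded 340-480 nm).
M-positive scans are modeled as a Gaussian bump on a low flat baseline;
M-negative scans are baseline only.  Peak width and baseline/amplitude
levels are generator parameters of this package, not measured quantities.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np

Axis = Literal["excitation", "emission"]

#: recorded wavelength windows (nm), 1-nm grid
AXIS_RANGES: dict[str, tuple[int, int]] = {
    "emission": (340, 480),
    "excitation": (260, 360),
}
#: default peak centers of an M-positive scan (nm)
PEAK_CENTERS: dict[str, float] = {"emission": 380.0, "excitation": 320.0}
#: windows within which a detected peak counts as the M-fluorophore (nm)
PEAK_WINDOWS: dict[str, tuple[float, float]] = {
    "emission": (370.0, 380.0),
    "excitation": (314.0, 320.0),
}

PEAK_SD_NM = 15.0  # invented generator width
BASELINE_AU = 10.0
PEAK_AMPLITUDE_AU = 100.0
DEFAULT_PROMINENCE = 2.0


@dataclass(frozen=True)
class Spectrum:
    """One excitation or emission scan on a strictly increasing nm grid."""

    axis: Axis
    wavelengths_nm: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        it = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "intensities", it)
        if self.axis not in AXIS_RANGES:
            raise ValueError(f"axis must be 'excitation' or 'emission', got {self.axis!r}")
        if wl.ndim != 1 or wl.shape != it.shape:
            raise ValueError("wavelengths and intensities must be 1-D and equal length")
        if wl.size < 2 or not np.all(np.diff(wl) > 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if np.any(it < 0):
            raise ValueError("intensities must be nonnegative")

    def argmax_nm(self) -> float:
        """Wavelength of maximum intensity; ties break to the lower wavelength."""
        return float(self.wavelengths_nm[int(np.argmax(self.intensities))])

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("wavelength_nm,intensity\n")
            for wl, it in zip(self.wavelengths_nm, self.intensities):
                fh.write(f"{wl:g},{it:.6g}\n")

    @classmethod
    def from_csv(cls, path: str | Path, axis: Axis) -> "Spectrum":
        data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        return cls(axis=axis, wavelengths_nm=data[:, 0], intensities=data[:, 1])


def generate_spectrum(
    m_status: str,
    axis: Axis,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    peak_center: float | None = None,
) -> Spectrum:
    """Synthesize one scan for an Mp or Mn specimen.

    Mp scans carry a Gaussian peak (SD 15 nm, amplitude 100 a.u.) centered
    at 380 nm (emission) or 320 nm (excitation) on a 10 a.u. baseline; Mn
    scans are baseline only.  Additive Gaussian noise of ``noise_sd`` is
    applied and intensities are clipped at 0.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    if noise_sd > 0 and rng is None:
        raise ValueError("noisy generation requires a seeded rng")
    lo, hi = AXIS_RANGES[axis]
    wl = np.arange(lo, hi + 1, 1.0)
    intensities = np.full(wl.shape, BASELINE_AU)
    if m_status == "Mp":
        center = PEAK_CENTERS[axis] if peak_center is None else peak_center
        intensities = intensities + PEAK_AMPLITUDE_AU * np.exp(-0.5 * ((wl - center) / PEAK_SD_NM) ** 2)
    elif m_status != "Mn":
        raise ValueError(f"m_status must be 'Mp' or 'Mn', got {m_status!r}")
    if noise_sd > 0:
        intensities = intensities + rng.normal(0.0, noise_sd, size=wl.shape)
    return Spectrum(axis=axis, wavelengths_nm=wl, intensities=np.clip(intensities, 0.0, None))


def peak_prominence(s: Spectrum) -> float:
    """(peak - median baseline) / median baseline; 0 for a flat scan."""
    peak = float(np.max(s.intensities))
    baseline = float(np.median(s.intensities))
    if baseline <= 0:
        return float("inf") if peak > 0 else 0.0
    return (peak - baseline) / baseline


def classify_spectrum(
    em: Spectrum,
    ex: Spectrum,
    prominence_threshold: float = DEFAULT_PROMINENCE,
) -> tuple[str, dict[str, float]]:
    """Call Mp/Mn from an emission/excitation scan pair.

    Mp iff the emission argmax lies in 370-380 nm, the excitation argmax in
    314-320 nm, and both peaks exceed the prominence threshold over the
    median baseline.  Returns the call and the detected peak wavelengths.
    Grids extending outside the recorded windows are rejected.
    """
    for s in (em, ex):
        lo, hi = AXIS_RANGES[s.axis]
        if s.wavelengths_nm[0] < lo or s.wavelengths_nm[-1] > hi:
            raise ValueError(
                f"{s.axis} grid [{s.wavelengths_nm[0]:g}, {s.wavelengths_nm[-1]:g}] outside recorded window [{lo}, {hi}] nm"
            )
    if em.axis != "emission" or ex.axis != "excitation":
        raise ValueError("classify_spectrum requires (emission, excitation) in that order")
    peaks = {"emission_nm": em.argmax_nm(), "excitation_nm": ex.argmax_nm()}
    ok = True
    for s, key in ((em, "emission_nm"), (ex, "excitation_nm")):
        win = PEAK_WINDOWS[s.axis]
        if not (win[0] <= peaks[key] <= win[1]) or peak_prominence(s) <= prominence_threshold:
            ok = False
    return ("Mp" if ok else "Mn"), peaks
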