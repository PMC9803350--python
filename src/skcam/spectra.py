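"""Tryptophan emission-spectrum reduction.

SKp carries a single native tryptophan (W432) whose emission, excited at
265 nm and scanned in 1-nm steps from 315 to 400 nm, reports on the
residue's environment: a solvent-exposed Trp peaks near 348 nm, a buried
one shifts blue.  The reduction chain is: buffer-background subtraction,
replicate averaging with per-wavelength SEM, binomial smoothing, and peak
localization on the integer-nm grid; pairs of summaries are compared as a
peak shift (nm) and a percent amplitude change.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EmissionSpectrum",
    "SpectrumSummary",
    "subtract_buffer",
    "binomial_smooth",
    "average_with_sem",
    "peak_summary",
    "compare_spectra",
    "read_spectra_csv",
    "write_spectrum_csv",
]

EMISSION_WINDOW_NM = (315, 400)
EXCITATION_NM = 265


@dataclass(frozen=True)
class EmissionSpectrum:
    """Fluorescence emission scan on a uniform integer-nm grid."""

    wavelengths: np.ndarray  # nm
    intensities: np.ndarray  # arbitrary units
    excitation_nm: float = EXCITATION_NM
    filter_cuton_nm: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        it = np.asarray(self.intensities, dtype=float)
        if wl.ndim != 1 or wl.shape != it.shape or wl.size == 0:
            raise ValueError("wavelengths/intensities must be equal-length 1-D")
        steps = np.diff(wl)
        if wl.size > 1 and not np.allclose(steps, 1.0):
            raise ValueError("wavelength grid must be strictly increasing, 1-nm step")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "intensities", it)

    def same_grid(self, other: "EmissionSpectrum") -> bool:
        return self.wavelengths.shape == other.wavelengths.shape and np.array_equal(
            self.wavelengths, other.wavelengths
        )


@dataclass(frozen=True)
class SpectrumSummary:
    """Peak location/amplitude of a (smoothed) emission spectrum."""

    peak_wavelength: float | None  # nm; None when the spectrum is flat
    peak_amplitude: float | None
    boundary: bool = False  # peak sits on the scan edge
    label: str = ""


def subtract_buffer(sample: EmissionSpectrum, buffer: EmissionSpectrum) -> EmissionSpectrum:
    """Pointwise buffer-background subtraction.

    Negative differences are retained (with a warning), never clipped, so
    over-subtraction remains visible downstream.
    """
    if not sample.same_grid(buffer):
        raise ValueError("sample and buffer are on different wavelength grids")
    diff = sample.intensities - buffer.intensities
    if np.any(diff < 0):
        warnings.warn(
            "buffer subtraction produced negative intensities (retained)",
            RuntimeWarning,
            stacklevel=2,
        )
    return replace(sample, intensities=diff)


def binomial_smooth(s: EmissionSpectrum, passes: int = 1) -> EmissionSpectrum:
    """Repeated (1, 2, 1)/4 convolution with reflected ends.

    One pass of the binomial kernel; ``passes`` applications converge toward
    a Gaussian of variance passes/2 grid steps.  ``passes = 0`` is the
    identity.  Linear trends are preserved at interior points.
    """
    if passes < 0:
        raise ValueError("passes must be >= 0")
    y = s.intensities.copy()
    for _ in range(passes):
        if y.size < 3:
            break
        padded = np.pad(y, 1, mode="reflect")
        y = 0.25 * padded[:-2] + 0.5 * padded[1:-1] + 0.25 * padded[2:]
    return replace(s, intensities=y)


def average_with_sem(
    replicates: Sequence[EmissionSpectrum],
) -> tuple[EmissionSpectrum, np.ndarray | None]:
    """Pointwise mean spectrum and per-wavelength SEM across replicates.

    A single replicate yields SEM None (not zero) to distinguish
    "unknown" from "measured identical".
    """
    if not replicates:
        raise ValueError("need at least one replicate")
    first = replicates[0]
    for r in replicates[1:]:
        if not first.same_grid(r):
            raise ValueError("replicates are on different wavelength grids")
    stack = np.vstack([r.intensities for r in replicates])
    mean = replace(first, intensities=stack.mean(axis=0))
    if len(replicates) == 1:
        return mean, None
    sem = stack.std(axis=0, ddof=1) / np.sqrt(len(replicates))
    return mean, sem


def peak_summary(s: EmissionSpectrum, smoothing_passes: int = 0) -> SpectrumSummary:
    """Locate the emission peak on the integer-nm grid.

    The spectrum is binomially smoothed ``smoothing_passes`` times first.
    Ties resolve to the smallest wavelength; a maximum on the scan edge is
    flagged ``boundary``; an all-equal spectrum has no peak.
    """
    sm = binomial_smooth(s, smoothing_passes)
    y = sm.intensities
    if np.all(y == y[0]):
        return SpectrumSummary(None, None, boundary=False, label=s.label)
    idx = int(np.argmax(y))  # argmax takes the first (smallest-wavelength) tie
    boundary = idx == 0 or idx == y.size - 1
    return SpectrumSummary(
        peak_wavelength=float(sm.wavelengths[idx]),
        peak_amplitude=float(y[idx]),
        boundary=boundary,
        label=s.label,
    )


def compare_spectra(
    sample: SpectrumSummary, reference: SpectrumSummary
) -> tuple[float, float]:
    """Peak shift and amplitude change of a sample relative to a reference.

    Returns (delta_lambda in nm, amplitude change in percent), where the
    amplitude change is (A_sample / A_reference - 1) * 100 — a sample 3.3x
    the reference reads +230% ("230% greater").
    """
    if sample.peak_wavelength is None or reference.peak_wavelength is None:
        raise ValueError("both summaries must have a located peak")
    if reference.peak_amplitude == 0:
        raise ValueError("reference amplitude is zero")
    delta = sample.peak_wavelength - reference.peak_wavelength
    pct = (sample.peak_amplitude / reference.peak_amplitude - 1.0) * 100.0
    return delta, pct


def read_spectra_csv(path: str | Path, label: str = "") -> list[EmissionSpectrum]:
    """Read spectra from CSV (wavelength_nm, intensity[, replicate])."""
    df = pd.read_csv(path)
    if "replicate" not in df.columns:
        df = df.assign(replicate=0)
    out = []
    for rep, grp in df.groupby("replicate"):
        grp = grp.sort_values("wavelength_nm")
        out.append(
            EmissionSpectrum(
                wavelengths=grp["wavelength_nm"].to_numpy(dtype=float),
                intensities=grp["intensity"].to_numpy(dtype=float),
                label=label or f"replicate{rep}",
            )
        )
    return out


def write_spectrum_csv(
    spectra: Sequence[EmissionSpectrum], path: str | Path
) -> None:
    frames = []
    for rep, s in enumerate(spectra):
        frames.append(
            pd.DataFrame(
                {
                    "wavelength_nm": s.wavelengths,
                    "intensity": s.intensities,
                    "replicate": rep,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
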