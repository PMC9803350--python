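"""Synthetic-data generators with the statistical structure the analyses assume.

Every generator is a deterministic function of its parameters and a seed;
per-generator substreams are derived from the global seed by a stable hash
of the generator name, so e.g. a MALS simulation and a spectrum simulation
with the same seed draw independent noise.

The generators emulate the study conditions, not the raw instruments:

* :func:`simulate_mals_dataset` — weight-average molar masses along a
  cross-over gradient from the equilibrium forward model, with proportional
  (CV) noise per step and replicate, as light-scattering error scales with
  signal.  Default CV 2%.
* :func:`simulate_spectrum` — a unimodal, log-normal-in-wavelength Trp
  emission profile on the 315-400 nm integer grid (asymmetric red tail);
  only the peak position and amplitude are contract-bearing.
* :func:`simulate_patch_trace` — a piecewise-exponential patch current
  following the EGTA / Ca / non-WT application / washout / WT application
  protocol, with leak, optional linear drift, and additive Gaussian noise.
"""

from __future__ import annotations

import math
import zlib
from typing import Sequence

import numpy as np

from .binding import BindingModel, Composition
from .ephys import Epoch, PatchRecord
from .mals import Gradient, MALSDataset, predict_mw
from .spectra import EMISSION_WINDOW_NM, EmissionSpectrum

__all__ = [
    "substream",
    "simulate_mals_dataset",
    "simulate_spectrum",
    "simulate_patch_trace",
    "DEFAULT_EPOCH_SCHEDULE",
]

DEFAULT_NOISE_CV = 0.02


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent RNG substream for one generator, stable across runs."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(name.encode())])


def simulate_mals_dataset(
    model: BindingModel,
    gradient: Gradient,
    noise_cv: float = DEFAULT_NOISE_CV,
    n_replicates: int = 1,
    seed: int = 0,
) -> MALSDataset:
    """Cross-over M_w data from the forward model with proportional noise.

    Each observation is ``M_w * (1 + eps)`` with ``eps ~ N(0, noise_cv)``,
    independent per step and replicate.  ``noise_cv = 0`` reproduces the
    forward model exactly in every replicate.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    mw = predict_mw(model, gradient)
    rng = substream(seed, "mals")
    eps = rng.normal(0.0, noise_cv, size=(mw.size, n_replicates)) if noise_cv else 0.0
    observed = mw[:, None] * (1.0 + eps) if noise_cv else np.tile(mw[:, None], (1, n_replicates))
    sem = (
        observed.std(axis=1, ddof=1) / math.sqrt(n_replicates)
        if n_replicates > 1
        else None
    )
    return MALSDataset(
        gradient=gradient,
        measured_mw=observed,
        sem_mw=sem,
        condition_label=model.condition_label,
    )


def simulate_spectrum(
    peak_nm: float,
    width_nm: float = 25.0,
    amplitude: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    label: str = "",
) -> EmissionSpectrum:
    """Unimodal Trp-like emission spectrum on the 315-400 nm 1-nm grid.

    The noiseless profile is log-normal in wavelength,
    ``A * exp(-(ln(lambda / peak))^2 / (2 s^2))`` with ``s = width / peak``,
    whose mode sits exactly at ``peak_nm`` (an asymmetric red tail, like
    real Trp emission).  Additive Gaussian noise of SD ``noise_sd``.
    """
    lo, hi = EMISSION_WINDOW_NM
    if not lo <= peak_nm <= hi:
        raise ValueError(f"peak must lie in the {lo}-{hi} nm scan window")
    if width_nm <= 0 or amplitude < 0 or noise_sd < 0:
        raise ValueError("width_nm > 0, amplitude >= 0, noise_sd >= 0 required")
    wl = np.arange(lo, hi + 1, dtype=float)
    s = width_nm / peak_nm
    profile = amplitude * np.exp(-0.5 * (np.log(wl / peak_nm) / s) ** 2)
    if noise_sd:
        profile = profile + substream(seed, "spectrum").normal(0.0, noise_sd, wl.size)
    return EmissionSpectrum(wavelengths=wl, intensities=profile, label=label)


#: canonical protocol: leak estimation, basal Ca, non-WT application (R1),
#: washout, WT application (R2), final washout — (label, construct, n_samples)
DEFAULT_EPOCH_SCHEDULE: tuple[tuple[str, str | None, int], ...] = (
    ("EGTA", None, 40),
    ("Ca", None, 40),
    ("EGTA", None, 40),
    ("Ca", None, 40),
    ("CaM", "non-WT", 60),
    ("Ca", None, 40),
    ("CaM", "WT", 60),
    ("Ca", None, 20),
)


def simulate_patch_trace(
    leak: float = -0.05,
    basal_ca_current: float = -0.5,
    fractions: tuple[float, float, float] = (0.1, 0.85, 0.05),
    recovery_amplitude: float = -1.0,
    transition_tau: float = 5.0,
    drift_slope: float = 0.0,
    noise_sd: float = 0.0,
    epoch_schedule: Sequence[tuple[str, str | None, int]] = DEFAULT_EPOCH_SCHEDULE,
    sample_interval_s: float = 3.0,
    seed: int = 0,
) -> PatchRecord:
    """Synthetic inside-out patch current following the recovery protocol.

    ``fractions = (nonwt, wt, drift)`` must sum to 1 and set the steady
    current targets: with total recovery ``recovery_amplitude`` (nA, signed
    like the currents), the non-WT application ends ``nonwt`` of the way
    there, the washout drifts a further ``drift``, and the WT application
    completes it.  Epoch targets are approached exponentially with time
    constant ``transition_tau`` (s); ``drift_slope`` (nA/s) adds a global
    linear ramp; Gaussian noise of SD ``noise_sd`` (nA) is added per sample.
    """
    f_nonwt, f_wt, f_drift = fractions
    if not math.isclose(f_nonwt + f_wt + f_drift, 1.0, rel_tol=0, abs_tol=1e-9):
        raise ValueError("fractions (nonwt, wt, drift) must sum to 1")
    labels = [e[0] for e in epoch_schedule]
    cam_positions = [i for i, lab in enumerate(labels) if lab == "CaM"]
    if "EGTA" not in labels or labels.count("Ca") < 2 or len(cam_positions) < 2:
        raise ValueError(
            "schedule must contain EGTA, two Ca epochs, and two CaM applications"
        )
    r1_pos, r2_pos = cam_positions[0], cam_positions[-1]

    delta = recovery_amplitude
    targets: list[float] = []
    seen_r1 = seen_r2 = False
    for pos, (label, _, _) in enumerate(epoch_schedule):
        if label == "EGTA":
            targets.append(leak)
            continue
        if pos == r1_pos:
            seen_r1 = True
            level = basal_ca_current + f_nonwt * delta
        elif pos == r2_pos:
            seen_r2 = True
            level = basal_ca_current + delta
        elif not seen_r1:
            level = basal_ca_current
        elif seen_r1 and not seen_r2:
            level = basal_ca_current + (f_nonwt + f_drift) * delta
        else:
            level = basal_ca_current + delta
        targets.append(leak + level)

    currents = []
    prev = targets[0]
    for (label, _, n), target in zip(epoch_schedule, targets):
        t_local = np.arange(n) * sample_interval_s
        if transition_tau > 0:
            seg = target + (prev - target) * np.exp(-t_local / transition_tau)
        else:
            seg = np.full(n, target)
        currents.append(seg)
        prev = float(seg[-1])
    current = np.concatenate(currents)
    time = np.arange(current.size) * sample_interval_s

    if drift_slope:
        current = current + drift_slope * time
    if noise_sd:
        current = current + substream(seed, "patch").normal(0.0, noise_sd, current.size)

    epochs = []
    start = 0
    for label, construct, n in epoch_schedule:
        epochs.append(Epoch(label=label, construct=construct, start=start, stop=start + n))
        start += n
    return PatchRecord(time=time, current=current, epochs=tuple(epochs))
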