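"""Fractional-recovery analysis of inside-out patch currents.

SK2 currents are sampled as the mean of a 1-s step to -60 mV every 3 s
while the bath alternates between Ca2+-free (EGTA), 10 uM free Ca2+, and
Ca2+ plus an exogenous CaM construct.  The EGTA epochs estimate the leak
current; the protocol applies a non-WT CaM construct first (R1), washes it
out, then applies WT-CaM (R2).  The analysis partitions the total
recovered current into the portion due to the non-WT construct, the
washout drift, and the WT portion — three fractions that sum to 1 by
construction and are deliberately not clipped to [0, 1].
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Epoch",
    "PatchRecord",
    "RecoveryResult",
    "estimate_leak",
    "drift_correct",
    "fractional_recovery",
    "summarize_recovery",
    "paired_tests",
    "read_patch_csv",
    "write_patch_csv",
]

#: steady-state window: mean of the last k samples of an epoch (k*3 s)
DEFAULT_STEADY_SAMPLES = 5

EPOCH_LABELS = ("EGTA", "Ca", "CaM")


@dataclass(frozen=True)
class Epoch:
    """A contiguous solution epoch: [start, stop) sample indices."""

    label: str  # EGTA | Ca | CaM
    construct: str | None  # CaM construct name for application epochs
    start: int
    stop: int

    def __post_init__(self) -> None:
        if self.label not in EPOCH_LABELS:
            raise ValueError(f"unknown epoch label {self.label!r}")
        if self.stop <= self.start:
            raise ValueError("epoch must span at least one sample")


@dataclass(frozen=True)
class PatchRecord:
    """Current-vs-time series with ordered solution epochs."""

    time: np.ndarray  # s
    current: np.ndarray  # nA
    epochs: tuple[Epoch, ...]

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        i = np.asarray(self.current, dtype=float)
        if t.shape != i.shape or t.ndim != 1:
            raise ValueError("time/current must be equal-length 1-D")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "current", i)
        prev_stop = 0
        for e in self.epochs:
            if e.start < prev_stop:
                raise ValueError("epochs must be ordered and non-overlapping")
            if e.stop > t.size:
                raise ValueError("epoch extends past the record")
            prev_stop = e.stop

    def epochs_with(self, label: str) -> list[Epoch]:
        return [e for e in self.epochs if e.label == label]


def _steady(rec: PatchRecord, epoch: Epoch, k: int) -> float:
    """Steady-state current: mean of the last k samples of the epoch."""
    seg = rec.current[epoch.start : epoch.stop]
    return float(seg[-min(k, seg.size) :].mean())


def estimate_leak(rec: PatchRecord, k: int = DEFAULT_STEADY_SAMPLES) -> float:
    """Leak current from the nominally Ca2+-free (EGTA) epochs, nA.

    The mean of the last ``k`` samples of each EGTA epoch, averaged across
    epochs: with no Ca2+ the SK conductance is shut, so what remains is leak.
    """
    egta = rec.epochs_with("EGTA")
    if not egta:
        raise ValueError("record has no EGTA epoch; leak not estimable")
    return float(np.mean([_steady(rec, e, k) for e in egta]))


def drift_correct(
    rec: PatchRecord, epochs_to_fit: Sequence[Epoch]
) -> tuple[PatchRecord, float]:
    """Fit a line to the designated epochs and subtract it from the record.

    Ordinary least squares over the concatenated samples of
    ``epochs_to_fit``; the fitted line minus its value at the window start
    is subtracted from the whole record, so the current level at the start
    of the fit window is preserved.  Returns (corrected record, slope nA/s).
    """
    idx = np.concatenate(
        [np.arange(e.start, e.stop) for e in epochs_to_fit]
    ) if epochs_to_fit else np.array([], dtype=int)
    if idx.size < 2:
        raise ValueError("drift-fit window must span at least 2 samples")
    t = rec.time[idx]
    y = rec.current[idx]
    slope, intercept = np.polyfit(t, y, 1)
    t0 = rec.time[idx[0]]
    line = slope * (rec.time - t0)
    corrected = replace(rec, current=rec.current - line)
    return corrected, float(slope)


@dataclass(frozen=True)
class RecoveryResult:
    """Partition of total recovered current into non-WT / drift / WT parts.

    The three fractions sum to 1 identically; values outside [0, 1] occur
    when current drifts across solution changes and are reported unclipped.
    """

    leak_current: float
    basal_ca_current: float
    nonwt_construct: str | None
    steady_currents: Mapping[str, float]  # leak-subtracted I_pre/I_R1/I_post/I_final
    fraction_nonwt: float
    fraction_wt: float
    fraction_drift: float
    drift_slope: float | None = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "leak_nA": self.leak_current,
                "basal_ca_nA": self.basal_ca_current,
                "nonwt_construct": self.nonwt_construct,
                "steady_currents_nA": dict(self.steady_currents),
                "fraction_nonwt": self.fraction_nonwt,
                "fraction_wt": self.fraction_wt,
                "fraction_drift": self.fraction_drift,
                "drift_slope_nA_per_s": self.drift_slope,
            },
            indent=2,
        )


def _protocol_epochs(rec: PatchRecord) -> tuple[Epoch, Epoch, Epoch, Epoch]:
    """Locate (basal Ca, R1 application, washout Ca, R2 application)."""
    cam_epochs = rec.epochs_with("CaM")
    if len(cam_epochs) < 2:
        raise ValueError(
            "protocol needs two application epochs (non-WT then WT CaM)"
        )
    r1, r2 = cam_epochs[0], cam_epochs[-1]
    pre = [e for e in rec.epochs_with("Ca") if e.stop <= r1.start]
    if not pre:
        raise ValueError("no basal Ca epoch before the first application")
    wash = [
        e for e in rec.epochs_with("Ca") if e.start >= r1.stop and e.stop <= r2.start
    ]
    if not wash:
        raise ValueError("no washout Ca epoch between the applications")
    return pre[-1], r1, wash[-1], r2


def fractional_recovery(
    rec: PatchRecord, k: int = DEFAULT_STEADY_SAMPLES
) -> RecoveryResult:
    """Fraction of total recovered SK current due to each applied construct.

    With leak-subtracted steady currents I_pre (basal Ca), I_R1 (end of the
    non-WT application), I_post (washout Ca before WT), and I_final (end of
    the WT application), the total recovery is D = I_final - I_pre and

        fraction_nonwt = (I_R1 - I_pre) / D
        fraction_drift = (I_post - I_R1) / D
        fraction_wt    = (I_final - I_post) / D

    which sum to 1 identically.  D = 0 raises (fractions undefined).
    """
    leak = estimate_leak(rec, k)
    basal, r1, wash, r2 = _protocol_epochs(rec)
    i_pre = _steady(rec, basal, k) - leak
    i_r1 = _steady(rec, r1, k) - leak
    i_post = _steady(rec, wash, k) - leak
    i_final = _steady(rec, r2, k) - leak
    delta = i_final - i_pre
    if delta == 0:
        raise ValueError("zero total recovery: fractions undefined")
    return RecoveryResult(
        leak_current=leak,
        basal_ca_current=i_pre,
        nonwt_construct=r1.construct,
        steady_currents={
            "I_pre": i_pre,
            "I_R1": i_r1,
            "I_post": i_post,
            "I_final": i_final,
        },
        fraction_nonwt=(i_r1 - i_pre) / delta,
        fraction_wt=(i_final - i_post) / delta,
        fraction_drift=(i_post - i_r1) / delta,
    )


def summarize_recovery(
    groups: Mapping[str, Sequence[float]],
) -> pd.DataFrame:
    """Per-construct summary of fractional recoveries: n, median, mean, SD.

    Mirrors the published summary-table layout.  SD is the sample standard
    deviation (ddof=1); a single-record group reports SD 0.
    """
    rows = []
    for construct, values in groups.items():
        v = np.asarray(list(values), dtype=float)
        if v.size == 0:
            raise ValueError(f"empty group {construct!r}")
        sd = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
        rows.append(
            {
                "construct": construct,
                "n": int(v.size),
                "median": float(np.median(v)),
                "mean": float(v.mean()),
                "sd": sd,
            }
        )
    return pd.DataFrame(rows)


def paired_tests(
    groups: Mapping[str, Sequence[float]],
    alpha: float = 0.01,
    bonferroni: bool = False,
) -> pd.DataFrame:
    """Two-sided paired t-tests between every pair of groups.

    Vectors must be paired (equal length, same ordering of subjects).
    Significance is called at ``alpha`` on the raw p-values by default; the
    Bonferroni option divides alpha by the number of comparisons.
    """
    names = list(groups)
    rows = []
    pairs = [(a, b) for ai, a in enumerate(names) for b in names[ai + 1 :]]
    level = alpha / len(pairs) if (bonferroni and pairs) else alpha
    for a, b in pairs:
        va = np.asarray(list(groups[a]), dtype=float)
        vb = np.asarray(list(groups[b]), dtype=float)
        if va.size != vb.size:
            raise ValueError(f"groups {a!r} and {b!r} are not paired (length mismatch)")
        if va.size < 2:
            raise ValueError("paired t-test needs n >= 2")
        if np.array_equal(va, vb):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_rel(va, vb)
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "t": float(t),
                "p": float(p),
                "significant": bool(p < level),
            }
        )
    return pd.DataFrame(rows)


def write_patch_csv(rec: PatchRecord, path: str | Path) -> None:
    """CSV: time_s, current_nA, epoch_index, epoch_label, construct."""
    labels = np.array([""] * rec.time.size, dtype=object)
    constructs = np.array([""] * rec.time.size, dtype=object)
    epoch_idx = np.full(rec.time.size, -1)
    for n, e in enumerate(rec.epochs):
        labels[e.start : e.stop] = e.label
        constructs[e.start : e.stop] = e.construct or ""
        epoch_idx[e.start : e.stop] = n
    pd.DataFrame(
        {
            "time_s": rec.time,
            "current_nA": rec.current,
            "epoch_index": epoch_idx,
            "epoch_label": labels,
            "construct": constructs,
        }
    ).to_csv(path, index=False)


def read_patch_csv(path: str | Path) -> PatchRecord:
    df = pd.read_csv(path, keep_default_na=False)
    epochs = []
    for n, grp in df[df.epoch_index >= 0].groupby("epoch_index"):
        idx = grp.index.to_numpy()
        epochs.append(
            Epoch(
                label=str(grp["epoch_label"].iloc[0]),
                construct=str(grp["construct"].iloc[0]) or None,
                start=int(idx[0]),
                stop=int(idx[-1]) + 1,
            )
        )
    return PatchRecord(
        time=df["time_s"].to_numpy(dtype=float),
        current=df["current_nA"].to_numpy(dtype=float),
        epochs=tuple(sorted(epochs, key=lambda e: e.start)),
    )
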