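"""Sensor-level mismatch-negativity analysis.

Difference waveforms (deviant minus repeated tones), mean amplitude over the
a-priori 140-160 ms window, robust outlier exclusion (3 scaled median absolute
deviations at *both* sessions), a paired t-test for session change and an
ordinary regression of amplitude on a covariate such as baseline MMSE.

Statistics are computed from their textbook formulas (p-values via the t
distribution); an independent reference implementation (scipy) cross-checks
them in the test suite.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from .erpio import ERPDataset
from .errors import (
    DegenerateDataError, InvalidParameterError, StructuralError,
)

MAD_SCALE = 1.4826  # scaled MAD: consistent with the SD under normality
MMN_WINDOW = (140.0, 160.0)


@dataclass
class MMNRecord:
    """One subject/session's difference waveform and windowed amplitude."""

    subject: str
    session: str
    waveform: np.ndarray
    amplitude: float
    covariates: dict = field(default_factory=dict)


def mmn_waveform(deviant: np.ndarray, repeats) -> np.ndarray:
    """Deviant response minus the mean of the repeated-tone responses.

    ``repeats`` is a single array or a sequence of arrays (tones 2-11) sharing
    the deviant's time axis; arrays may be 1-D or (time x modes).
    """
    deviant = np.asarray(deviant, dtype=float)
    if isinstance(repeats, np.ndarray) or np.ndim(repeats[0]) == 0:
        repeats = [repeats]
    reps = [np.asarray(r, dtype=float) for r in repeats]
    for r in reps:
        if r.shape != deviant.shape:
            raise StructuralError(
                f"repeat shape {r.shape} does not match deviant {deviant.shape}"
            )
    return deviant - np.mean(reps, axis=0)


def window_mean(waveform: np.ndarray, times: np.ndarray,
                lo: float = MMN_WINDOW[0], hi: float = MMN_WINDOW[1]) -> float:
    """Mean amplitude over the inclusive [lo, hi] ms window."""
    waveform = np.asarray(waveform, dtype=float)
    times = np.asarray(times, dtype=float)
    if waveform.shape[0] != times.shape[0]:
        raise StructuralError("waveform and time axis lengths differ")
    if lo < times[0] or hi > times[-1] or hi < lo:
        raise InvalidParameterError(f"window [{lo}, {hi}] outside the epoch")
    sel = (times >= lo - 1e-9) & (times <= hi + 1e-9)
    if not np.any(sel):
        raise InvalidParameterError("window contains no samples")
    return float(np.mean(waveform[sel]))


def mad_outlier_mask(baseline: np.ndarray, followup: np.ndarray,
                     threshold: float = 3.0) -> np.ndarray:
    """Inclusion mask: exclude only subjects extreme at *both* sessions.

    A subject is an outlier at one session when its amplitude deviates more
    than ``threshold`` scaled MADs from the session median.  A zero MAD (all
    amplitudes identical) flags nothing and logs a warning.
    """
    baseline = np.asarray(baseline, dtype=float)
    followup = np.asarray(followup, dtype=float)
    if baseline.shape != followup.shape or baseline.ndim != 1:
        raise StructuralError("baseline and follow-up amplitudes must be 1-D and paired")
    if len(baseline) < 3:
        raise InvalidParameterError("need at least 3 subjects for outlier detection")

    def flags(x):
        med = np.median(x)
        mad = MAD_SCALE * np.median(np.abs(x - med))
        if mad == 0:
            warnings.warn("zero MAD: no outliers flagged for this session")
            return np.zeros(len(x), dtype=bool)
        return np.abs(x - med) > threshold * mad

    return ~(flags(baseline) & flags(followup))


class TTestResult(NamedTuple):
    t: float
    p: float
    dof: int
    cohen_d: float


def paired_t(a: np.ndarray, b: np.ndarray) -> TTestResult:
    """Paired t-test of a-b with Cohen's d = mean(diff)/sd(diff); two-sided p."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise StructuralError("paired samples must be equal-length 1-D, n >= 2")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        raise DegenerateDataError("zero-variance differences: t undefined")
    n = len(d)
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * t_dist.sf(abs(t), n - 1)
    return TTestResult(float(t), float(p), n - 1, float(d.mean() / sd))


class RegressionResult(NamedTuple):
    slope: float
    intercept: float
    r: float
    p: float


def amplitude_vs_covariate(amplitudes: np.ndarray, covariate: np.ndarray
                           ) -> RegressionResult:
    """OLS of amplitude on a covariate plus the Pearson correlation."""
    y = np.asarray(amplitudes, dtype=float)
    x = np.asarray(covariate, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise StructuralError("amplitudes and covariate must be matched 1-D arrays")
    if len(y) < 3:
        raise InvalidParameterError("need at least 3 observations")
    sx = x.std(ddof=0)
    if sx == 0:
        raise DegenerateDataError("constant covariate: regression degenerate")
    xc = x - x.mean()
    yc = y - y.mean()
    slope = float(xc @ yc / (xc @ xc))
    intercept = float(y.mean() - slope * x.mean())
    sy = y.std(ddof=0)
    r = float(xc @ yc / (len(y) * sx * sy)) if sy > 0 else 0.0
    n = len(y)
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r ** 2))
        p = float(2.0 * t_dist.sf(abs(t), n - 2))
    return RegressionResult(slope, intercept, r, p)


# -- cohort-level pipeline ----------------------------------------------

def difference_component(datasets: Sequence[ERPDataset],
                         deviant: str = "deviant", standard: str = "standard"
                         ) -> np.ndarray:
    """Leading spatial component of the cohort's difference waveforms.

    The per-mode difference waveforms of all subjects/sessions are stacked in
    time and their first right singular vector is returned, oriented so the
    grand-average amplitude over the canonical window is positive.  Collapsing
    the modes onto this component gives a single robust waveform per
    recording, the analogue of a combined-gradiometer MMN trace.
    """
    if not datasets:
        raise InvalidParameterError("no datasets given")
    diffs = [mmn_waveform(d.conditions[deviant], d.conditions[standard])
             for d in datasets]
    stacked = np.vstack(diffs)
    _, _, vt = np.linalg.svd(stacked, full_matrices=False)
    w = vt[0]
    grand = np.mean(diffs, axis=0) @ w
    if window_mean(grand, datasets[0].times) < 0:
        w = -w
    return w


def mmn_records(datasets: Sequence[ERPDataset], component: np.ndarray | None = None,
                window: tuple = MMN_WINDOW) -> list[MMNRecord]:
    """Collapse datasets onto the difference component and window the result."""
    if component is None:
        component = difference_component(datasets)
    out = []
    for d in datasets:
        wf = mmn_waveform(d.conditions["deviant"], d.conditions["standard"]) @ component
        out.append(MMNRecord(d.subject, d.session, wf,
                             window_mean(wf, d.times, *window),
                             covariates=dict(d.meta)))
    return out


def amplitude_table(records: Sequence[MMNRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"subject": r.subject, "session": r.session, "amplitude": r.amplitude,
          **r.covariates} for r in records]
    )
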