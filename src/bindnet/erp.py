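"""Condition-average ERPs, mean-amplitude extraction and electrode validation.

The P3 analysis window is 400-700 ms after S2 at electrode Cz; the choice of
electrode is validated by comparing, per electrode, the single-subject mean
amplitude against the average of all remaining electrodes with a paired
t-test, Bonferroni-corrected over electrodes (with 60 electrodes the
per-test threshold is 0.05/60, i.e. p = .0008).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import EpochSet

__all__ = [
    "ErpWaveform",
    "average_condition",
    "mean_amplitude",
    "amplitude_table",
    "validate_electrode",
]

P3_WINDOW_MS = (400.0, 700.0)
P3_ELECTRODE = "Cz"


@dataclass
class ErpWaveform:
    """Trial-average waveform (channels x samples) of one condition."""

    data: np.ndarray
    srate: float
    window_ms: tuple[float, float]
    condition: object
    n_trials: int

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")

    @property
    def times_ms(self) -> np.ndarray:
        return self.window_ms[0] + np.arange(self.data.shape[1]) / self.srate * 1000.0


def average_condition(epochs_by_condition: dict) -> dict:
    """Pointwise trial average per condition."""

    out = {}
    for cond, ep in epochs_by_condition.items():
        out[cond] = ErpWaveform(
            data=ep.data.mean(axis=2),
            srate=ep.srate,
            window_ms=ep.window_ms,
            condition=cond,
            n_trials=ep.n_trials,
        )
    return out


def mean_amplitude(erp: ErpWaveform, electrode: int | str,
                   window_ms: tuple[float, float] = P3_WINDOW_MS,
                   montage=None) -> float:
    """Mean amplitude over an analysis window (endpoints inclusive)."""

    if isinstance(electrode, str):
        if montage is None:
            raise ValueError("montage required to resolve an electrode name")
        electrode = montage.index(electrode)
    t = erp.times_ms
    m = (t >= window_ms[0]) & (t <= window_ms[1])
    if not m.any():
        raise ValueError(f"window {window_ms} outside waveform")
    return float(erp.data[electrode, m].mean())


def amplitude_table(erps_by_subject: dict,
                    window_ms: tuple[float, float] = P3_WINDOW_MS) -> pd.DataFrame:
    """subject x condition x electrode mean amplitudes as a tidy table.

    ``erps_by_subject`` maps subject id -> {condition -> ErpWaveform}.
    """

    rows = []
    for subject, erps in erps_by_subject.items():
        for cond, erp in erps.items():
            t = erp.times_ms
            m = (t >= window_ms[0]) & (t <= window_ms[1])
            amps = erp.data[:, m].mean(axis=1)
            for e, a in enumerate(amps):
                rows.append({"subject": subject, "condition": str(cond),
                             "electrode": e, "amplitude": float(a)})
    return pd.DataFrame(rows)


def validate_electrode(
    amplitudes: np.ndarray,
    polarity: str = "positive",
    alpha: float = 0.05,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Data-driven electrode validation.

    Parameters
    ----------
    amplitudes
        subjects x electrodes array of window-mean amplitudes (typically the
        grand mean across conditions).
    polarity
        'positive' retains electrodes whose amplitude significantly exceeds
        the mean of the others (P-type components), 'negative' the reverse.

    Returns
    -------
    selected
        Indices of retained electrodes.
    table
        Per-electrode t, uncorrected p and the Bonferroni threshold used.
    """

    a = np.asarray(amplitudes, float)
    if a.ndim != 2:
        raise ValueError("amplitudes must be subjects x electrodes")
    n_sub, n_el = a.shape
    if n_sub < 2:
        raise ValueError("electrode validation needs >= 2 subjects")
    if polarity not in ("positive", "negative"):
        raise ValueError("polarity must be 'positive' or 'negative'")

    total = a.sum(axis=1, keepdims=True)
    others = (total - a) / (n_el - 1)          # mean of the other electrodes
    diff = a - others
    t, p = sps.ttest_rel(a, others, axis=0)
    threshold = alpha / n_el
    sign_ok = diff.mean(axis=0) > 0 if polarity == "positive" else diff.mean(axis=0) < 0
    selected = np.flatnonzero((p < threshold) & sign_ok)
    table = pd.DataFrame({
        "electrode": np.arange(n_el),
        "t": t,
        "p": p,
        "mean_difference": diff.mean(axis=0),
        "selected": np.isin(np.arange(n_el), selected),
    })
    table.attrs["bonferroni_threshold"] = threshold
    return selected, table
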