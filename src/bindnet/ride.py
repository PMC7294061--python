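"""Residue iteration decomposition (RIDE) of single-trial epochs.

Single-trial ERPs are modelled as the superposition of three component
clusters: a stimulus-locked **S** cluster (latency fixed at stimulus onset),
a response-locked **R** cluster (latency given by each trial's reaction
time), and a central **C** cluster whose latency varies from trial to trial
and is estimated from the data.  Each cluster is estimated by subtracting
the current estimates of the other two from every trial, aligning the
residuals to the cluster's latency, and taking the pointwise median across
trials (an L1 estimate, robust to the other clusters' residual overlap)
inside a predefined time window.  C latencies are re-estimated from the
residuals by template matching, and the whole procedure is iterated until
the C waveform stabilizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import EpochSet

__all__ = ["RideConfig", "RideResult", "initialize", "estimate_component",
           "estimate_c_latency", "decompose", "reconstruct"]


@dataclass(frozen=True)
class RideConfig:
    """Windows are in ms, relative to S2 onset for S and C and to the
    response for R.  ``tol`` is the relative L2 change of the C waveform at
    which iteration stops."""

    window_s_ms: tuple[float, float] = (-200.0, 700.0)
    window_r_ms: tuple[float, float] = (-300.0, 300.0)
    window_c_ms: tuple[float, float] = (150.0, 800.0)
    c_search_ms: tuple[float, float] = (-200.0, 200.0)
    max_iter: int = 10
    tol: float = 1e-3
    taper_ms: float = 100.0
    latency_channels: tuple[int, ...] | None = None  # None: match on all channels

    def __post_init__(self) -> None:
        for name in ("window_s_ms", "window_r_ms", "window_c_ms"):
            a, b = getattr(self, name)
            if b <= a:
                raise ValueError(f"{name} is empty")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


@dataclass
class RideResult:
    """Decomposition output.  Component waveforms are full-epoch arrays
    (channels x samples); S and C live in the stimulus-locked frame, R in
    the response-locked frame (response at time 0)."""

    s_wave: np.ndarray
    c_wave: np.ndarray
    r_wave: np.ndarray
    c_latency_ms: np.ndarray
    r_latency_ms: np.ndarray
    srate: float
    window_ms: tuple[float, float]
    config: RideConfig
    n_iter: int = 0
    converged: bool = False
    trace: list = field(default_factory=list)


def _shift(x: np.ndarray, n: int) -> np.ndarray:
    """Shift along the last axis by n samples, zero-filling."""
    if n == 0:
        return x.copy()
    out = np.zeros_like(x)
    if n > 0:
        out[..., n:] = x[..., :-n]
    else:
        out[..., :n] = x[..., -n:]
    return out


def _window_mask(times_ms: np.ndarray, window: tuple[float, float],
                 taper_ms: float) -> np.ndarray:
    """1 inside the window with cosine ramps of ``taper_ms`` at the edges."""
    a, b = window
    m = np.zeros_like(times_ms)
    inside = (times_ms >= a) & (times_ms <= b)
    m[inside] = 1.0
    if taper_ms > 0:
        rise = (times_ms >= a) & (times_ms < a + taper_ms)
        m[rise] = 0.5 * (1 - np.cos(np.pi * (times_ms[rise] - a) / taper_ms))
        fall = (times_ms > b - taper_ms) & (times_ms <= b)
        m[fall] = 0.5 * (1 - np.cos(np.pi * (b - times_ms[fall]) / taper_ms))
    return m


def _check_window(times_ms: np.ndarray, window: tuple[float, float], name: str) -> None:
    if window[0] < times_ms[0] - 1e-9 or window[1] > times_ms[-1] + 1e-9:
        raise ValueError(f"{name} window {window} outside epoch "
                         f"({times_ms[0]:.0f}, {times_ms[-1]:.0f}) ms")


def estimate_component(
    data: np.ndarray,
    others: list[tuple[np.ndarray, np.ndarray]],
    target_shifts: np.ndarray,
    mask: np.ndarray,
) -> np.ndarray:
    """Median-based estimate of one component cluster.

    Parameters
    ----------
    data
        channels x samples x trials.
    others
        List of (waveform, per-trial shifts in samples) for the components to
        subtract; waveforms are in their own frame and are placed into each
        trial at the given shift.
    target_shifts
        Per-trial shift (samples) of the component being estimated; residuals
        are aligned by shifting each trial by the negative of this.
    mask
        Tapered window mask over samples, applied in the target frame.
    """

    n_ch, n_samples, n_trials = data.shape
    if n_trials == 0:
        raise ValueError("no trials")
    aligned = np.empty((n_ch, n_samples, n_trials))
    for t in range(n_trials):
        resid = data[:, :, t].copy()
        for wave, shifts in others:
            resid -= _shift(wave, int(shifts[t]))
        aligned[:, :, t] = _shift(resid, -int(target_shifts[t]))
    return np.median(aligned, axis=2) * mask[None, :]


def _template_bank(template: np.ndarray, lags: np.ndarray) -> np.ndarray:
    """Mean-centred template shifted to every candidate lag
    (lags x channels x samples)."""
    t = np.atleast_2d(template)
    t = t - t.mean(axis=1, keepdims=True)
    return np.stack([_shift(t, int(l)) for l in lags])


def estimate_c_latency(
    residual: np.ndarray,
    c_template: np.ndarray,
    lags: np.ndarray,
) -> int:
    """Lag (samples) maximizing the multichannel cross-correlation of a
    single-trial residual with the C template; ties break toward the smaller
    absolute lag.

    Both arguments are channels x samples (1-D inputs are treated as a
    single channel); the score at each lag sums the per-channel
    cross-correlations, i.e. a matched filter over the whole topography.
    """

    bank = _template_bank(np.atleast_2d(c_template), lags)
    scores = np.einsum("lcs,cs->l", bank, np.atleast_2d(residual))
    best = scores.max()
    cand = np.flatnonzero(scores >= best - 1e-12 * max(abs(best), 1.0))
    return int(lags[cand[np.argmin(np.abs(lags[cand]))]])


def initialize(epochs: EpochSet, rts_ms: np.ndarray | None = None,
               cfg: RideConfig | None = None) -> RideResult:
    """Starting point of the iteration: S latency 0 everywhere, R latency at
    each trial's RT, C latency 0 with a stimulus-locked median template."""

    cfg = cfg or RideConfig()
    if epochs.n_trials == 0:
        raise ValueError("no trials to decompose")
    if rts_ms is None:
        if not epochs.trials:
            raise ValueError("rts_ms required when epochs carry no metadata")
        rts_ms = np.array([t.rt_ms for t in epochs.trials])
    rts_ms = np.asarray(rts_ms, float)
    if rts_ms.size != epochs.n_trials:
        raise ValueError("one RT per trial required")
    times = epochs.times_ms
    for name, win in (("S", cfg.window_s_ms), ("C", cfg.window_c_ms)):
        _check_window(times, win, name)
    zeros = np.zeros(epochs.n_trials, int)
    mask_c = _window_mask(times, cfg.window_c_ms, cfg.taper_ms)
    c0 = estimate_component(epochs.data, [], zeros, mask_c)
    return RideResult(
        s_wave=np.zeros((epochs.n_channels, epochs.n_samples)),
        c_wave=c0,
        r_wave=np.zeros((epochs.n_channels, epochs.n_samples)),
        c_latency_ms=np.zeros(epochs.n_trials),
        r_latency_ms=rts_ms,
        srate=epochs.srate,
        window_ms=epochs.window_ms,
        config=cfg,
    )


def decompose(epochs: EpochSet, rts_ms: np.ndarray | None = None,
              cfg: RideConfig | None = None) -> RideResult:
    """Iterative S/C/R decomposition with per-trial C-latency estimation.

    Deterministic given its inputs.  If the C waveform has not stabilized
    after ``cfg.max_iter`` outer iterations the result is returned with
    ``converged=False``.
    """

    cfg = cfg or RideConfig()
    res = initialize(epochs, rts_ms, cfg)
    data = epochs.data
    times = epochs.times_ms
    srate = epochs.srate
    ms_per_sample = 1000.0 / srate

    mask_s = _window_mask(times, cfg.window_s_ms, cfg.taper_ms)
    # R window is relative to the response; in the response frame the
    # response sits at epoch time 0.
    _check_window(times, cfg.window_r_ms, "R")
    mask_r = _window_mask(times, cfg.window_r_ms, cfg.taper_ms)
    mask_c = _window_mask(times, cfg.window_c_ms, cfg.taper_ms)

    zeros = np.zeros(epochs.n_trials, int)
    rt_shifts = np.round(res.r_latency_ms / ms_per_sample).astype(int)
    c_shifts = np.zeros(epochs.n_trials, int)
    lag_lo = int(np.ceil(cfg.c_search_ms[0] / ms_per_sample))
    lag_hi = int(np.floor(cfg.c_search_ms[1] / ms_per_sample))
    lags = np.arange(lag_lo, lag_hi + 1)

    s_wave = res.s_wave
    r_wave = res.r_wave
    c_wave = res.c_wave
    trace: list[float] = []
    converged = False
    n_iter = 0
    for n_iter in range(1, cfg.max_iter + 1):
        s_wave = estimate_component(
            data, [(c_wave, c_shifts), (r_wave, rt_shifts)], zeros, mask_s)
        r_wave = estimate_component(
            data, [(s_wave, zeros), (c_wave, c_shifts)], rt_shifts, mask_r)
        c_new = estimate_component(
            data, [(s_wave, zeros), (r_wave, rt_shifts)], c_shifts, mask_c)

        # re-estimate per-trial C latencies by multichannel template matching
        chans = (list(cfg.latency_channels) if cfg.latency_channels is not None
                 else slice(None))
        bank = _template_bank(c_new[chans], lags)
        for t in range(epochs.n_trials):
            resid = data[:, :, t] - s_wave - _shift(r_wave, int(rt_shifts[t]))
            scores = np.einsum("lcs,cs->l", bank, resid[chans])
            best = scores.max()
            cand = np.flatnonzero(scores >= best - 1e-12 * max(abs(best), 1.0))
            c_shifts[t] = int(lags[cand[np.argmin(np.abs(lags[cand]))]])
        # the decomposition is invariant to a common shift of template and
        # latencies; re-centre to zero median so the origin cannot drift
        c_shifts -= int(np.round(np.median(c_shifts)))
        np.clip(c_shifts, lags[0], lags[-1], out=c_shifts)

        denom = np.linalg.norm(c_wave)
        change = np.linalg.norm(c_new - c_wave) / denom if denom > 0 else np.inf
        trace.append(float(change))
        c_wave = c_new
        if change <= cfg.tol:
            converged = True
            break

    res.s_wave, res.c_wave, res.r_wave = s_wave, c_wave, r_wave
    res.c_latency_ms = c_shifts * ms_per_sample
    res.n_iter = n_iter
    res.converged = converged
    res.trace = trace
    return res


def reconstruct(res: RideResult, trial: int) -> np.ndarray:
    """Sum of the three placed components for one trial (channels x samples)."""

    ms_per_sample = 1000.0 / res.srate
    c_shift = int(np.round(res.c_latency_ms[trial] / ms_per_sample))
    r_shift = int(np.round(res.r_latency_ms[trial] / ms_per_sample))
    return res.s_wave + _shift(res.c_wave, c_shift) + _shift(res.r_wave, r_shift)
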