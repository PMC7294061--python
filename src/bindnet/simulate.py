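"""Synthetic multichannel EEG for the S1-S2 binding paradigm.

Each simulated S2-locked epoch is a sum of

* an **S component** — stimulus-locked, fixed latency, posterior topography
  (early perceptual processing);
* a **C component** — a P3-like central positivity whose single-trial latency
  jitters around its nominal peak and whose amplitude carries the
  feature-overlap x response interaction (smallest for full-overlap/response
  repetition);
* an **R component** — locked to the trial's response time, lateral-central
  topography;
* 1/f background noise, independent across channels; and
* band-limited oscillations injected along the edges of a condition-specific
  coupling graph with a 90 degree phase lag between the two endpoint
  channels, so that the imaginary part of coherency — the connectivity
  statistic used downstream — is maximally sensitive to them.  The graph is a
  ring lattice, a Watts-Strogatz graph, or a fully rewired (random) graph
  depending on the condition, which is what makes the small-world character
  of the recovered network condition-dependent.

Everything injected is recorded in :class:`GroundTruth` so recovery can be
tested against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import EpochSet, Montage, TrialRecord, make_equidistant_montage
from . import network as _network

__all__ = ["EegSimParams", "GroundTruth", "generate_eeg", "component_topography"]


@dataclass(frozen=True)
class EegSimParams:
    """Tunable parameters of the epoch generator (times in ms, amplitudes in
    microvolt)."""

    srate: float = 256.0
    window_ms: tuple[float, float] = (-1000.0, 1000.0)

    # Gaussian component templates: peak time, width (SD), base amplitude
    s_peak_ms: float = 180.0
    s_width_ms: float = 50.0
    s_amp_uv: float = 6.0
    c_peak_ms: float = 550.0
    c_width_ms: float = 120.0
    c_amp_uv: float = 8.0
    r_peak_offset_ms: float = -40.0  # R peaks slightly before the keypress
    r_width_ms: float = 60.0
    r_amp_uv: float = 4.0

    c_amp_interaction: float = 0.3      # relative overlap x response modulation
    c_jitter_sd_ms: float = 50.0
    c_jitter_max_ms: float = 150.0      # truncation of the latency jitter

    noise_rms_uv: float = 10.0
    noise_exponent: float = 1.0         # 1/f^exponent power spectrum

    coupling_band_hz: tuple[float, float] = (4.0, 8.0)
    coupling_strength_uv: float = 6.0   # RMS of each injected edge oscillation
    coupling_k: int = 2                 # lattice neighbours per side
    topology_by_condition: dict = field(
        default_factory=lambda: {
            (0, "repeat"): "random",
            (3, "repeat"): "lattice",
            (0, "alternate"): "lattice",
            (3, "alternate"): "random",
        }
    )
    default_topology: str = "smallworld"
    smallworld_beta: float = 0.1


@dataclass
class GroundTruth:
    """Record of everything the generator injected."""

    c_latency_ms: np.ndarray            # per-trial C latency shift
    c_amp_factor: np.ndarray            # per-trial C amplitude scaling
    templates: dict                      # 'S','C','R' -> channels x samples
    coupling_topology: dict              # condition -> adjacency (n x n, 0/1)
    params: EegSimParams = None

    def __post_init__(self) -> None:
        for adj in self.coupling_topology.values():
            if not np.array_equal(adj, adj.T) or np.any(np.diag(adj) != 0):
                raise ValueError("coupling topology must be symmetric, zero diagonal")


def component_topography(montage: Montage, center_theta: float, center_phi: float,
                         width_deg: float = 45.0) -> np.ndarray:
    """Gaussian spatial weight over channels, by angular distance to a
    target direction on the scalp sphere."""

    pos = montage.positions()
    th, ph = np.radians(center_theta), np.radians(center_phi)
    target = np.array([np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)])
    ang = np.degrees(np.arccos(np.clip(pos @ target, -1.0, 1.0)))
    return np.exp(-0.5 * (ang / width_deg) ** 2)


def _gauss_bump(times_ms: np.ndarray, peak_ms: float, width_ms: float) -> np.ndarray:
    return np.exp(-0.5 * ((times_ms - peak_ms) / width_ms) ** 2)


def _one_over_f_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                      n_trials: int, srate: float, rms: float, exponent: float
                      ) -> np.ndarray:
    """Gaussian noise with a 1/f**exponent power spectrum, unit-free RMS."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / srate)
    scale = np.zeros_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    shape = (n_channels, freqs.size, n_trials)
    spec = (rng.standard_normal(shape) + 1j * rng.standard_normal(shape))
    spec *= scale[None, :, None]
    x = np.fft.irfft(spec, n=n_samples, axis=1)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd * rms


def _band_noise_pair(rng: np.random.Generator, n_samples: int, srate: float,
                     band: tuple[float, float], n_signals: int
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Band-limited Gaussian signals plus their 90-degree-lagged copies.

    Returns two (n_signals, n_samples) arrays; the second is the quadrature
    (Hilbert-shifted) version of the first, so a pair of channels receiving
    (x, x_quad) exhibits purely imaginary coherency in the band.
    """

    freqs = np.fft.rfftfreq(n_samples, d=1.0 / srate)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    if not np.any(in_band):
        raise ValueError(f"band {band} contains no FFT bins at n={n_samples}")
    spec = np.zeros((n_signals, freqs.size), dtype=complex)
    nb = int(in_band.sum())
    spec[:, in_band] = rng.standard_normal((n_signals, nb)) + 1j * rng.standard_normal(
        (n_signals, nb)
    )
    x = np.fft.irfft(spec, n=n_samples, axis=1)
    xq = np.fft.irfft(spec * -1j, n=n_samples, axis=1)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd, xq / sd


def _ring_lattice(n: int, k: int) -> np.ndarray:
    return _network.ws_generate(n, k, 0.0, rng=np.random.default_rng(0))


def _topology(regime: str, n: int, k: int, beta_sw: float,
              rng: np.random.Generator) -> np.ndarray:
    if regime == "lattice":
        return _ring_lattice(n, k)
    if regime == "random":
        return _network.ws_generate(n, k, 1.0, rng=rng)
    if regime == "smallworld":
        return _network.ws_generate(n, k, beta_sw, rng=rng)
    raise ValueError(f"unknown topology regime {regime!r}")


def generate_eeg(
    design: list[TrialRecord],
    montage: Montage | None = None,
    params: EegSimParams | None = None,
    seed: int = 0,
) -> tuple[EpochSet, GroundTruth]:
    """Simulate S2-locked epochs for a behavioral trial list.

    Trials must already carry reaction times (see
    :func:`bindnet.design.generate_behavior`); the R component is placed at
    each trial's RT.  Returns the epochs (potential units) and the injected
    ground truth.
    """

    montage = montage or make_equidistant_montage(60)
    params = params or EegSimParams()
    rng = np.random.default_rng(seed)
    n_ch = len(montage)
    n_samples = int(round((params.window_ms[1] - params.window_ms[0])
                          / 1000.0 * params.srate))
    times = params.window_ms[0] + np.arange(n_samples) / params.srate * 1000.0
    n_trials = len(design)
    if n_trials == 0:
        raise ValueError("empty design")
    rts = np.array([t.rt_ms for t in design])
    if np.any(~np.isfinite(rts)):
        raise ValueError("design trials must carry rt_ms (run generate_behavior)")

    # topographies
    topo_s = component_topography(montage, 75.0, 180.0, 40.0)
    topo_c = component_topography(montage, 0.0, 0.0, 45.0)
    topo_r = (component_topography(montage, 40.0, 90.0, 35.0)
              + component_topography(montage, 40.0, 270.0, 35.0))

    # per-trial C modulation: amplitude interaction + latency jitter
    overlap = np.array([t.overlap for t in design], float)
    sgn = np.array([1.0 if t.response_relation == "repeat" else -1.0 for t in design])
    z = (overlap - 1.5) / 1.5 * sgn
    c_amp_factor = 1.0 - params.c_amp_interaction * z
    c_lat = rng.normal(0.0, params.c_jitter_sd_ms, n_trials) if params.c_jitter_sd_ms > 0 \
        else np.zeros(n_trials)
    c_lat = np.clip(c_lat, -params.c_jitter_max_ms, params.c_jitter_max_ms)

    s_shape = _gauss_bump(times, params.s_peak_ms, params.s_width_ms)
    data = np.empty((n_ch, n_samples, n_trials))
    data[:] = (params.s_amp_uv * topo_s)[:, None, None] * s_shape[None, :, None]
    c_shapes = _gauss_bump(times[None, :], (params.c_peak_ms + c_lat)[:, None],
                           params.c_width_ms)        # trials x samples
    data += (params.c_amp_uv * topo_c)[:, None, None] * \
        (c_amp_factor[:, None] * c_shapes).T[None, :, :]
    r_shapes = _gauss_bump(times[None, :], (rts + params.r_peak_offset_ms)[:, None],
                           params.r_width_ms)
    data += (params.r_amp_uv * topo_r)[:, None, None] * r_shapes.T[None, :, :]

    if params.noise_rms_uv > 0:
        data += _one_over_f_noise(rng, n_ch, n_samples, n_trials, params.srate,
                                  params.noise_rms_uv, params.noise_exponent)

    # condition-dependent phase-lagged coupling
    topologies: dict = {}
    if params.coupling_strength_uv > 0 and n_ch >= 2 * params.coupling_k + 1:
        conditions = sorted({t.condition for t in design})
        for cond in conditions:
            regime = params.topology_by_condition.get(cond, params.default_topology)
            topologies[cond] = _topology(regime, n_ch, params.coupling_k,
                                         params.smallworld_beta, rng)
        for ti, trial in enumerate(design):
            adj = topologies[trial.condition]
            ii, jj = np.nonzero(np.triu(adj, 1))
            x, xq = _band_noise_pair(rng, n_samples, params.srate,
                                     params.coupling_band_hz, len(ii))
            amp = params.coupling_strength_uv
            np.add.at(data[:, :, ti], ii, amp * x)
            np.add.at(data[:, :, ti], jj, amp * xq)

    templates = {
        "S": (params.s_amp_uv * topo_s)[:, None] * s_shape[None, :],
        "C": (params.c_amp_uv * topo_c)[:, None]
        * _gauss_bump(times, params.c_peak_ms, params.c_width_ms)[None, :],
        # R template with the response at epoch time 0
        "R": (params.r_amp_uv * topo_r)[:, None]
        * _gauss_bump(times, params.r_peak_offset_ms, params.r_width_ms)[None, :],
    }
    epochs = EpochSet(data=data, srate=params.srate, window_ms=params.window_ms,
                      montage=montage, trials=list(design), units="potential")
    truth = GroundTruth(c_latency_ms=c_lat, c_amp_factor=c_amp_factor,
                        templates=templates, coupling_topology=topologies,
                        params=params)
    return epochs, truth
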