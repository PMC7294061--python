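"""Functional-connectivity networks and the small-world statistic omega.

The chain implemented here is: band-limited imaginary coherence between all
channel pairs -> percentile-thresholded binary adjacency -> clustering
coefficient C and characteristic path length L -> comparison against
Watts-Strogatz reference networks -> the small-world parameter

    omega = L_rand / L - C / C_latt

where ``rand`` refers to fully rewired (random) references and ``latt`` to
the ring lattice of the same size and mean degree.  omega is close to 0 for
small-world graphs, positive for random-like and negative for lattice-like
organization, and is bounded by [-1, 1] for Watts-Strogatz-type graphs.

The imaginary part of coherency is used (rather than its magnitude) because
it is blind to zero-lag coupling, the signature of volume conduction in
scalp EEG.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path

from .containers import EpochSet

__all__ = [
    "CoherenceMatrix",
    "NetworkMetrics",
    "band_imag_coherence",
    "threshold_adjacency",
    "clustering_coefficient",
    "path_length",
    "ws_generate",
    "reference_metrics",
    "small_world_omega",
    "omega_from_adjacency",
    "network_pipeline",
]


@dataclass
class CoherenceMatrix:
    """|Im(coherency)| averaged over a frequency band; symmetric, zero
    diagonal, entries in [0, 1]."""

    values: np.ndarray
    band_hz: tuple[float, float]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("coherence matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("coherence matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("coherence diagonal must be zero")
        if v.min() < -1e-12 or v.max() > 1 + 1e-9:
            raise ValueError("coherence entries must lie in [0, 1]")
        self.values = v


@dataclass
class NetworkMetrics:
    """Graph metrics of one adjacency matrix plus its Watts-Strogatz
    references.  ``omega`` is recomputable from the other fields."""

    c_real: float
    l_real: float
    c_rand: float
    l_rand: float
    c_latt: float
    k: int
    mean_degree: float
    omega: float
    n_disconnected_pairs: int = 0
    in_bounds: bool = True


def band_imag_coherence(
    epochs: EpochSet | np.ndarray,
    band_hz: tuple[float, float],
    srate: float | None = None,
    taper: str = "hann",
) -> CoherenceMatrix:
    """Trial-averaged imaginary coherence between all channel pairs.

    A single taper is applied to each full epoch, cross- and auto-spectra are
    averaged across trials, coherency is formed per frequency bin and
    |Im(coherency)| is averaged over the bins inside ``band_hz``.
    """

    if isinstance(epochs, EpochSet):
        data, srate = epochs.data, epochs.srate
    else:
        data = np.asarray(epochs, float)
        if srate is None:
            raise ValueError("srate required for raw arrays")
    if data.ndim != 3:
        raise ValueError("data must be channels x samples x trials")
    n_ch, n_samples, n_trials = data.shape
    if n_trials < 2:
        raise ValueError("need at least 2 trials for coherence estimation")
    if not 0 < band_hz[0] < band_hz[1] < srate / 2:
        raise ValueError(f"band {band_hz} outside (0, Nyquist)")

    if taper == "hann":
        win = np.hanning(n_samples)
    elif taper in (None, "boxcar"):
        win = np.ones(n_samples)
    else:
        raise ValueError(f"unknown taper {taper!r}")

    freqs = np.fft.rfftfreq(n_samples, d=1.0 / srate)
    in_band = (freqs >= band_hz[0]) & (freqs <= band_hz[1])
    if not np.any(in_band):
        raise ValueError(f"band {band_hz} contains no FFT bins")
    spec = np.fft.rfft(data * win[None, :, None], axis=1)[:, in_band, :]
    # cross-spectra averaged over trials: (ch, ch, bins)
    sxy = np.einsum("aft,bft->abf", spec, np.conj(spec)) / n_trials
    auto = np.real(np.einsum("aaf->af", sxy))
    denom = np.sqrt(auto[:, None, :] * auto[None, :, :])
    denom[denom == 0] = np.inf
    coherency = sxy / denom
    imcoh = np.abs(np.imag(coherency)).mean(axis=2)
    imcoh = 0.5 * (imcoh + imcoh.T)
    np.fill_diagonal(imcoh, 0.0)
    return CoherenceMatrix(values=np.clip(imcoh, 0.0, 1.0), band_hz=tuple(band_hz))


def threshold_adjacency(coh: CoherenceMatrix | np.ndarray, percentile: float) -> np.ndarray:
    """Binarize by keeping the strongest (100 - percentile)% of pairs.

    The edge quota is ``round(keep_fraction * n(n-1)/2)`` (round-half-even);
    ties at the cut are broken by lexicographic pair order so the result is
    deterministic.
    """

    values = coh.values if isinstance(coh, CoherenceMatrix) else np.asarray(coh, float)
    if not 0 < percentile < 100:
        raise ValueError("percentile must lie in (0, 100)")
    n = values.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    quota = int(np.round((100.0 - percentile) / 100.0 * iu.size))
    order = np.lexsort((ju, iu, -values[iu, ju]))  # strength desc, then (i, j)
    keep = order[:quota]
    adj = np.zeros((n, n), dtype=int)
    adj[iu[keep], ju[keep]] = 1
    return adj | adj.T


def _degrees(adj: np.ndarray) -> np.ndarray:
    return np.asarray(adj).sum(axis=1)


def clustering_coefficient(adj: np.ndarray) -> float:
    """Watts-Strogatz average local clustering coefficient.

    For each node, the fraction of its neighbour pairs that are themselves
    connected; nodes of degree < 2 contribute 0.
    """

    a = np.asarray(adj, dtype=float)
    deg = _degrees(a)
    triangles = np.diag(a @ a @ a) / 2.0
    possible = deg * (deg - 1) / 2.0
    local = np.zeros(a.shape[0])
    mask = possible > 0
    local[mask] = triangles[mask] / possible[mask]
    return float(local.mean())


def path_length(adj: np.ndarray, return_disconnected: bool = False):
    """Characteristic path length: mean shortest-path distance over connected
    ordered node pairs.  Disconnected pairs are excluded from the mean; their
    count is available via ``return_disconnected``."""

    a = np.asarray(adj, dtype=float)
    d = shortest_path(a, method="D", unweighted=True, directed=False)
    off = ~np.eye(a.shape[0], dtype=bool)
    finite = np.isfinite(d) & off
    n_disc = int(np.sum(off & ~finite))
    l_real = float(d[finite].mean()) if finite.any() else np.inf
    if return_disconnected:
        return l_real, n_disc
    return l_real


def ws_generate(n: int, k: int, beta: float,
                rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Watts-Strogatz graph as a binary adjacency matrix.

    Starts from a ring lattice where each node connects to its ``k`` nearest
    neighbours per side (mean degree 2k); each lattice edge is then rewired
    with probability ``beta`` to a uniformly chosen target that is neither
    the source nor an existing neighbour.  ``beta=0`` returns the lattice
    unchanged, ``beta=1`` rewires every edge.
    """

    if not 1 <= k < n / 2:
        raise ValueError("need 1 <= k < n/2")
    if not 0.0 <= beta <= 1.0:
        raise ValueError("beta must lie in [0, 1]")
    rng = np.random.default_rng(rng)
    adj = np.zeros((n, n), dtype=int)
    for offset in range(1, k + 1):
        for i in range(n):
            j = (i + offset) % n
            adj[i, j] = adj[j, i] = 1
    if beta > 0:
        for offset in range(1, k + 1):
            for i in range(n):
                j = (i + offset) % n
                if rng.random() >= beta or adj[i, j] == 0:
                    continue
                candidates = np.flatnonzero(adj[i] == 0)
                candidates = candidates[candidates != i]
                if candidates.size == 0:
                    continue
                new_j = int(rng.choice(candidates))
                adj[i, j] = adj[j, i] = 0
                adj[i, new_j] = adj[new_j, i] = 1
    return adj


def reference_metrics(adj: np.ndarray, n_realizations: int = 20,
                      rng: np.random.Generator | int | None = None
                      ) -> tuple[float, float, float]:
    """(L_rand, C_rand, C_latt) for Watts-Strogatz references matched in size
    and mean degree to ``adj``.

    ``k`` is ``round(mean degree / 2)``; random references are ``beta=1``
    models averaged over ``n_realizations``, the lattice reference is the
    deterministic ``beta=0`` ring.
    """

    rng = np.random.default_rng(rng)
    a = np.asarray(adj)
    n = a.shape[0]
    k = int(np.round(_degrees(a).mean() / 2.0))
    if k < 1:
        raise ValueError("graph too sparse: reference k < 1")
    c_latt = clustering_coefficient(ws_generate(n, k, 0.0))
    if c_latt == 0:
        raise ValueError(
            "lattice reference has zero clustering (k = 1): the thresholded "
            "graph is too sparse for omega; use a denser threshold or more "
            "channels")
    l_rand_acc, c_rand_acc = [], []
    for _ in range(n_realizations):
        r = ws_generate(n, k, 1.0, rng=rng)
        l_rand_acc.append(path_length(r))
        c_rand_acc.append(clustering_coefficient(r))
    return float(np.mean(l_rand_acc)), float(np.mean(c_rand_acc)), c_latt


def small_world_omega(c_real: float, l_real: float, c_latt: float,
                      l_rand: float) -> tuple[float, bool]:
    """omega = L_rand/L_real - C_real/C_latt; values outside [-1, 1] are
    flagged (``in_bounds=False``) but never clipped."""

    if l_real <= 0 or c_latt <= 0:
        raise ValueError("L_real and C_latt must be positive")
    omega = l_rand / l_real - c_real / c_latt
    in_bounds = bool(-1.0 <= omega <= 1.0)
    if not in_bounds:
        warnings.warn(f"omega={omega:.3f} outside [-1, 1]", stacklevel=2)
    return float(omega), in_bounds


def omega_from_adjacency(adj: np.ndarray, n_realizations: int = 20,
                         rng: np.random.Generator | int | None = None
                         ) -> NetworkMetrics:
    """Full metric set (C, L, references, omega) for one adjacency matrix."""

    a = np.asarray(adj)
    c_real = clustering_coefficient(a)
    l_real, n_disc = path_length(a, return_disconnected=True)
    l_rand, c_rand, c_latt = reference_metrics(a, n_realizations, rng)
    omega, in_bounds = small_world_omega(c_real, l_real, c_latt, l_rand)
    deg = _degrees(a).mean()
    return NetworkMetrics(
        c_real=c_real, l_real=l_real, c_rand=c_rand, l_rand=l_rand,
        c_latt=c_latt, k=int(np.round(deg / 2.0)), mean_degree=float(deg),
        omega=omega, n_disconnected_pairs=n_disc, in_bounds=in_bounds,
    )


def network_pipeline(
    epochs_by_condition: dict,
    bands: dict | None = None,
    percentiles: tuple[float, ...] = (85.0, 90.0),
    n_realizations: int = 20,
    seed: int = 0,
    subject: int | str = 0,
) -> pd.DataFrame:
    """Coherence -> adjacency -> metrics -> omega for every condition, band
    and threshold of one subject; returns a tidy table."""

    bands = bands or {"theta": (4.0, 8.0), "alpha": (8.0, 12.0)}
    rng = np.random.default_rng(seed)
    rows = []
    for cond, epochs in epochs_by_condition.items():
        for band_name, band in bands.items():
            coh = band_imag_coherence(epochs, band)
            for pct in percentiles:
                adj = threshold_adjacency(coh, pct)
                m = omega_from_adjacency(adj, n_realizations, rng)
                rows.append({
                    "subject": subject,
                    "condition": str(cond),
                    "band": band_name,
                    "percentile": pct,
                    "c_real": m.c_real, "l_real": m.l_real,
                    "c_rand": m.c_rand, "l_rand": m.l_rand,
                    "c_latt": m.c_latt, "k": m.k,
                    "mean_degree": m.mean_degree, "omega": m.omega,
                    "n_disconnected_pairs": m.n_disconnected_pairs,
                    "in_bounds": m.in_bounds,
                })
    return pd.DataFrame(rows)
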