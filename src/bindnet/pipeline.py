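"""End-to-end orchestration of the simulation study.

One :class:`RunConfig` fully determines a run: for every simulated subject
the paradigm, behavior and EEG are generated, preprocessed, decomposed and
reduced to the four dependent measures (accuracy, median RT, P3 amplitude,
RIDE C-cluster amplitude) plus the small-world omega per condition, band and
threshold; the group-level 2x2 repeated-measures statistics are computed at
the end.  All tables are written as TSV plus one JSON summary.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import design as _design
from . import erp as _erp
from . import network as _network
from . import preprocess as _pre
from . import ride as _ride
from . import simulate as _sim
from . import stats as _stats
from .containers import EpochSet, make_equidistant_montage, trials_to_frame

__all__ = ["RunConfig", "run_simulation_study", "run_on_data"]

logger = logging.getLogger("bindnet")


@dataclass
class RunConfig:
    """Serializable configuration of a full simulation study."""

    seed: int = 0
    n_subjects: int = 28
    n_repeats: int = 3
    n_channels: int = 60
    behavior: _design.BehaviorEffects = field(default_factory=_design.BehaviorEffects)
    sim: _sim.EegSimParams = field(default_factory=_sim.EegSimParams)
    preprocess: _pre.PreprocessConfig = field(default_factory=_pre.PreprocessConfig)
    ride: _ride.RideConfig = field(default_factory=_ride.RideConfig)
    bands: dict = field(default_factory=lambda: {"theta": (4.0, 8.0),
                                                 "alpha": (8.0, 12.0)})
    percentiles: tuple[float, ...] = (85.0, 90.0)
    n_reference_realizations: int = 20
    analysis_window_ms: tuple[float, float] = (400.0, 700.0)
    analysis_electrode: str = "Cz"
    run_ride: bool = True
    output_dir: str = "bindnet_out"

    def validate(self) -> None:
        for name, (lo, hi) in self.bands.items():
            if not 0 < lo < hi:
                raise ValueError(f"invalid band {name!r}: {(lo, hi)}")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")

    def to_json(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return dataclasses.asdict(o)
            if isinstance(o, tuple):
                return list(o)
            raise TypeError(type(o))

        d = dataclasses.asdict(self)
        d["sim"]["topology_by_condition"] = {
            f"{k[0]}:{k[1]}": v for k, v in d["sim"]["topology_by_condition"].items()
        }
        return json.dumps(d, default=enc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        if "sim" in d:
            topo = d["sim"].get("topology_by_condition")
            if topo is not None:
                d["sim"]["topology_by_condition"] = {
                    (int(k.split(":")[0]), k.split(":")[1]): v
                    for k, v in topo.items()
                }
            for key in ("window_ms", "coupling_band_hz"):
                if key in d["sim"]:
                    d["sim"][key] = tuple(d["sim"][key])
            d["sim"] = _sim.EegSimParams(**d["sim"])
        if "behavior" in d:
            d["behavior"] = _design.BehaviorEffects(**d["behavior"])
        if "preprocess" in d:
            for key in ("baseline_ms",):
                if key in d["preprocess"]:
                    d["preprocess"][key] = tuple(d["preprocess"][key])
            d["preprocess"] = _pre.PreprocessConfig(**d["preprocess"])
        if "ride" in d:
            for key in ("window_s_ms", "window_r_ms", "window_c_ms", "c_search_ms"):
                if key in d["ride"]:
                    d["ride"][key] = tuple(d["ride"][key])
            if d["ride"].get("latency_channels") is not None:
                d["ride"]["latency_channels"] = tuple(d["ride"]["latency_channels"])
            d["ride"] = _ride.RideConfig(**d["ride"])
        if "bands" in d:
            d["bands"] = {k: tuple(v) for k, v in d["bands"].items()}
        if "percentiles" in d:
            d["percentiles"] = tuple(d["percentiles"])
        if "analysis_window_ms" in d:
            d["analysis_window_ms"] = tuple(d["analysis_window_ms"])
        return cls(**d)


def _behavior_cells(trials) -> dict:
    """Accuracy (%) and median correct RT per (overlap, relation) cell."""
    df = trials_to_frame(trials)
    out = {}
    for (ov, rel), g in df.groupby(["overlap", "response_relation"]):
        rts = g.loc[g["correct"], "rt_ms"]
        out[(ov, rel)] = {
            "accuracy_pct": 100.0 * g["correct"].mean(),
            "median_rt_ms": float(rts.median()) if len(rts) else np.nan,
        }
    return out


def _cells_to_array(values: dict) -> np.ndarray:
    """(overlap in {0,3}) x (repeat, alternate) cell dict -> 2x2 array."""
    return np.array([
        [values[(0, "repeat")], values[(0, "alternate")]],
        [values[(3, "repeat")], values[(3, "alternate")]],
    ])


def analyze_subject(
    epochs: EpochSet,
    cfg: RunConfig,
    subject: int,
    network_seed: int,
) -> dict:
    """Preprocess one subject's epochs and extract all dependent measures."""

    conditions, mask = _pre.preprocess_epochs(epochs, cfg.preprocess, overlaps=(0, 3))
    electrode = epochs.montage.index(cfg.analysis_electrode)

    erps = _erp.average_condition(conditions)
    p3 = {cond: _erp.mean_amplitude(w, electrode, cfg.analysis_window_ms)
          for cond, w in erps.items()}

    c_amp = {}
    if cfg.run_ride:
        for cond, ep in conditions.items():
            res = _ride.decompose(ep, cfg=cfg.ride)
            t = ep.times_ms
            m = (t >= cfg.analysis_window_ms[0]) & (t <= cfg.analysis_window_ms[1])
            c_amp[cond] = float(res.c_wave[electrode, m].mean())

    net = _network.network_pipeline(
        conditions, bands=cfg.bands, percentiles=cfg.percentiles,
        n_realizations=cfg.n_reference_realizations, seed=network_seed,
        subject=subject)
    logger.info("subject %d: kept %d/%d trials", subject,
                int(mask.keep.sum()), mask.keep.size)
    return {"p3": p3, "c_amp": c_amp, "network": net,
            "n_kept": int(mask.keep.sum())}


def run_simulation_study(cfg: RunConfig, write: bool = True) -> dict:
    """Simulate and analyze a full cohort; returns the report bundle.

    The bundle contains the per-subject measure tables, the network table,
    the group ANOVA report and (when ``write``) the TSV/JSON files in
    ``cfg.output_dir``.
    """

    cfg.validate()
    master = np.random.default_rng(cfg.seed)
    sub_seeds = master.integers(0, 2 ** 31 - 1, size=(cfg.n_subjects, 3))
    montage = make_equidistant_montage(cfg.n_channels)

    behavior_rows, measure_rows, net_tables = [], [], []
    for s in range(cfg.n_subjects):
        g_seed, e_seed, n_seed = (int(x) for x in sub_seeds[s])
        trials = _design.generate_design(cfg.n_repeats, g_seed)
        trials = _design.generate_behavior(trials, cfg.behavior, g_seed + 1)
        epochs, _truth = _sim.generate_eeg(trials, montage, cfg.sim, e_seed)
        sub = analyze_subject(epochs, cfg, s, n_seed)

        beh = _behavior_cells(trials)
        for (ov, rel), vals in beh.items():
            behavior_rows.append({"subject": s, "overlap": ov, "response": rel,
                                  **vals})
        for cond, amp in sub["p3"].items():
            row = {"subject": s, "overlap": cond[0], "response": cond[1],
                   "p3_amplitude": amp}
            if sub["c_amp"]:
                row["c_cluster_amplitude"] = sub["c_amp"][cond]
            row["accuracy_pct"] = beh[cond]["accuracy_pct"]
            row["median_rt_ms"] = beh[cond]["median_rt_ms"]
            measure_rows.append(row)
        net_tables.append(sub["network"])

    behavior_df = pd.DataFrame(behavior_rows)
    measures_df = pd.DataFrame(measure_rows)
    network_df = pd.concat(net_tables, ignore_index=True)

    # group stats: subjects x (overlap 0, 3) x (repeat, alternate)
    def stack(col, frame, ov_col="overlap", rel_col="response"):
        out = np.empty((cfg.n_subjects, 2, 2))
        for i, ov in enumerate((0, 3)):
            for j, rel in enumerate(("repeat", "alternate")):
                sel = frame[(frame[ov_col] == ov) & (frame[rel_col] == rel)]
                out[:, i, j] = sel.sort_values("subject")[col].to_numpy()
        return out

    measures = {
        "accuracy": stack("accuracy_pct", measures_df),
        "rt": stack("median_rt_ms", measures_df),
        "p3": stack("p3_amplitude", measures_df),
    }
    if "c_cluster_amplitude" in measures_df:
        measures["c_cluster"] = stack("c_cluster_amplitude", measures_df)
    if "theta" in cfg.bands:
        pct = 90.0 if 90.0 in cfg.percentiles else cfg.percentiles[0]
        theta = network_df[(network_df["band"] == "theta")
                           & (network_df["percentile"] == pct)].copy()
        cond = theta["condition"].str.extract(r"\((\d+), '(\w+)'\)")
        theta["overlap"] = cond[0].astype(int)
        theta["response"] = cond[1]
        measures[f"omega_theta_{pct:.0f}"] = stack("omega", theta)

    if cfg.n_subjects >= 3:
        report = _stats.binding_effect_report(measures)
    else:
        import warnings

        warnings.warn("fewer than 3 subjects: group statistics skipped",
                      stacklevel=2)
        report = pd.DataFrame(columns=["measure", "interaction_F",
                                       "interaction_p"])
    bundle = {"behavior": behavior_df, "measures": measures_df,
              "network": network_df, "report": report, "config": cfg}

    if write:
        out = Path(cfg.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        behavior_df.to_csv(out / "behavior.tsv", sep="\t", index=False)
        measures_df.to_csv(out / "measures.tsv", sep="\t", index=False)
        network_df.to_csv(out / "network.tsv", sep="\t", index=False)
        report.to_csv(out / "anova_report.tsv", sep="\t", index=False)
        (out / "config.json").write_text(cfg.to_json())
        summary = {
            "n_subjects": cfg.n_subjects,
            "seed": cfg.seed,
            "interactions": {
                row["measure"]: {"F": row["interaction_F"],
                                 "p": row["interaction_p"],
                                 "partial_eta_sq": row["interaction_partial_eta_sq"]}
                for _, row in report.iterrows()
            },
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return bundle


def run_on_data(epoch_paths: list, cfg: RunConfig, write: bool = True) -> dict:
    """Run the analysis chain on user-supplied epoch containers (one file per
    subject), skipping generation."""

    cfg.validate()
    if not epoch_paths:
        raise ValueError("no epoch files given")
    master = np.random.default_rng(cfg.seed)
    seeds = master.integers(0, 2 ** 31 - 1, size=len(epoch_paths))
    rows, net_tables = [], []
    for s, path in enumerate(epoch_paths):
        epochs = EpochSet.load(path)
        sub = analyze_subject(epochs, cfg, s, int(seeds[s]))
        for cond, amp in sub["p3"].items():
            row = {"subject": s, "overlap": cond[0], "response": cond[1],
                   "p3_amplitude": amp}
            if sub["c_amp"]:
                row["c_cluster_amplitude"] = sub["c_amp"][cond]
            rows.append(row)
        net_tables.append(sub["network"])
    measures_df = pd.DataFrame(rows)
    network_df = pd.concat(net_tables, ignore_index=True)
    bundle = {"measures": measures_df, "network": network_df, "config": cfg}
    if write:
        out = Path(cfg.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        measures_df.to_csv(out / "measures.tsv", sep="\t", index=False)
        network_df.to_csv(out / "network.tsv", sep="\t", index=False)
    return bundle
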