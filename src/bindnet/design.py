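"""Factorial trial design and behavioral model of the S1-S2 binding task.

Each trial presents a first stimulus (S1) followed, after a short delay, by a
second stimulus (S2); both vary in orientation, location and color.  A first
response (R1) is cued independently of S1, the second response (R2) is chosen
by S2 orientation.  The design fully crosses the S2 features, the
repetition/alternation of each of the three features, and the
repetition/alternation of the response, yielding 2**7 = 128 cells.  The
feature-overlap level of a trial (0-3) is the number of repeated features.

Behavior follows the signature crossover of event-file binding ("partial
repetition costs"): feature overlap improves accuracy and speeds responses
when the response repeats, and hurts both when the response alternates.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .containers import _FEATURE_LEVELS, _FEATURE_NAMES, TrialRecord

__all__ = ["BehaviorEffects", "generate_design", "generate_behavior"]

_N_CELLS = 2 ** 7  # S2 features (3 binary) x feature repetitions (3) x response relation


def _other_level(feature: str, level: str) -> str:
    a, b = _FEATURE_LEVELS[feature]
    return b if level == a else a


def generate_design(n_repeats: int, seed: int) -> list[TrialRecord]:
    """Build the full factorial trial list, shuffled.

    Parameters
    ----------
    n_repeats
        Number of repetitions of each of the 128 factorial cells; the
        canonical session uses ``n_repeats=3`` (384 trials).
    seed
        Seed for the shuffle order.

    Returns
    -------
    list of TrialRecord with ``rt_ms``/``correct`` not yet filled in
    (see :func:`generate_behavior`).
    """

    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    cells = itertools.product(
        _FEATURE_LEVELS["orientation"],
        _FEATURE_LEVELS["location"],
        _FEATURE_LEVELS["color"],
        (True, False),  # orientation repeated?
        (True, False),  # location repeated?
        (True, False),  # color repeated?
        ("repeat", "alternate"),
    )
    protos = []
    for s2_ori, s2_loc, s2_col, rep_ori, rep_loc, rep_col, relation in cells:
        s2 = (s2_ori, s2_loc, s2_col)
        reps = (rep_ori, rep_loc, rep_col)
        s1 = tuple(
            lvl if rep else _other_level(name, lvl)
            for name, lvl, rep in zip(_FEATURE_NAMES, s2, reps)
        )
        # R2 is determined by S2 orientation (left key = horizontal line);
        # R1 follows from R2 and the response-relation factor.
        r2 = "left" if s2_ori == "horiz" else "right"
        r1 = r2 if relation == "repeat" else ("left" if r2 == "right" else "right")
        protos.append((s1, s2, sum(reps), relation, r1, r2))

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(protos) * n_repeats)
    trials = []
    for new_idx, flat in enumerate(order):
        s1, s2, overlap, relation, r1, r2 = protos[flat % _N_CELLS]
        trials.append(
            TrialRecord(
                index=new_idx,
                s1_features=s1,
                s2_features=s2,
                overlap=overlap,
                response_relation=relation,
                r1_side=r1,
                r2_side=r2,
            )
        )
    return trials


@dataclass(frozen=True)
class BehaviorEffects:
    """Parameters of the behavioral generator.

    ``interaction_acc`` is the logit-scale slope of the overlap x response
    crossover (positive: overlap helps repeats, hurts alternations);
    ``interaction_rt_ms`` the mirrored RT effect in ms at full overlap.
    """

    base_acc: float = 0.93
    base_rt_ms: float = 450.0
    interaction_acc: float = 0.5
    interaction_rt_ms: float = 20.0
    sd_rt_ms: float = 100.0

    def __post_init__(self) -> None:
        if not 0.0 < self.base_acc < 1.0:
            raise ValueError("base_acc must lie in (0, 1)")
        if self.sd_rt_ms <= 0:
            raise ValueError("sd_rt_ms must be positive")
        if self.base_rt_ms <= 0:
            raise ValueError("base_rt_ms must be positive")


def _overlap_score(overlap: np.ndarray) -> np.ndarray:
    """Centred overlap covariate in [-1, 1] (0 -> -1, 3 -> +1)."""
    return (np.asarray(overlap, float) - 1.5) / 1.5


def generate_behavior(
    design: list[TrialRecord],
    effects: BehaviorEffects | None = None,
    seed: int = 0,
    rt_bounds_ms: tuple[float, float] = (150.0, 2000.0),
) -> list[TrialRecord]:
    """Fill accuracy and reaction times into a trial list.

    Accuracy is Bernoulli with a logistic model whose only systematic term is
    the overlap x response interaction; RT is Gaussian with the mirrored
    interaction (partial repetition costs slow responses) and is clipped to
    ``rt_bounds_ms`` (responses later than the S2 response deadline cannot
    occur).
    """

    effects = effects or BehaviorEffects()
    rng = np.random.default_rng(seed)
    overlap = np.array([t.overlap for t in design])
    sign = np.array([1.0 if t.response_relation == "repeat" else -1.0 for t in design])
    z = _overlap_score(overlap) * sign

    logit0 = np.log(effects.base_acc / (1.0 - effects.base_acc))
    p_correct = 1.0 / (1.0 + np.exp(-(logit0 + effects.interaction_acc * z)))
    correct = rng.random(len(design)) < p_correct

    rt = (
        effects.base_rt_ms
        - effects.interaction_rt_ms * z
        + rng.normal(0.0, effects.sd_rt_ms, len(design))
    )
    rt = np.clip(rt, *rt_bounds_ms)

    out = []
    for t, c, r in zip(design, correct, rt):
        out.append(
            TrialRecord(
                index=t.index,
                s1_features=t.s1_features,
                s2_features=t.s2_features,
                overlap=t.overlap,
                response_relation=t.response_relation,
                r1_side=t.r1_side,
                r2_side=t.r2_side,
                rt_ms=float(r),
                correct=bool(c),
            )
        )
    return out
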