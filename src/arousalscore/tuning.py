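"""Seeded Bayesian hyperparameter search: TPE sampling, successive halving.

A compact tree-structured Parzen estimator. After a random start-up phase,
observed trials are split at the gamma-quantile of the objective into "good"
and "bad" sets; each parameter is sampled by drawing candidates from a
Gaussian mixture over the good values and keeping the candidate with the
best good/bad density ratio. Objectives are evaluated incrementally (e.g.
one CV fold at a time); a trial is pruned when its running mean falls below
the median of earlier trials at the same rung, which keeps roughly the top
half alive at every rung (successive halving).

Search-space grammar (per parameter)::

    {"type": "int",         "low": 2,    "high": 64}
    {"type": "float",       "low": 0.01, "high": 0.3, "log": True}
    {"type": "categorical", "choices": ["a", "b"]}
"""
from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class Trial:
    number: int
    params: dict
    fold_values: list[float] = field(default_factory=list)
    value: float | None = None   # mean objective; None while pruned/unfinished
    pruned: bool = False


def _transform(spec: dict, v: float) -> float:
    return math.log(v) if spec.get("log") else float(v)


def _inverse(spec: dict, t: float) -> float:
    v = math.exp(t) if spec.get("log") else t
    lo, hi = spec["low"], spec["high"]
    v = min(max(v, lo), hi)
    if spec["type"] == "int":
        v = int(round(v))
    return v


def _sample_random(space: dict, rng: np.random.Generator) -> dict:
    params = {}
    for name, spec in space.items():
        if spec["type"] == "categorical":
            params[name] = spec["choices"][rng.integers(len(spec["choices"]))]
        else:
            lo, hi = _transform(spec, spec["low"]), _transform(spec, spec["high"])
            params[name] = _inverse(spec, float(rng.uniform(lo, hi)))
    return params


def _mixture_logpdf(x: float, centers: np.ndarray, bw: float) -> float:
    if len(centers) == 0:
        return 0.0
    z = (x - centers) / bw
    log_terms = -0.5 * z ** 2 - math.log(bw * math.sqrt(2 * math.pi))
    m = np.max(log_terms)
    return float(m + np.log(np.mean(np.exp(log_terms - m))))


def _sample_tpe(
    space: dict,
    good: list[Trial],
    bad: list[Trial],
    rng: np.random.Generator,
    n_candidates: int,
) -> dict:
    params = {}
    for name, spec in space.items():
        if spec["type"] == "categorical":
            choices = spec["choices"]
            counts = np.array(
                [1.0 + sum(t.params[name] == c for t in good) for c in choices]
            )
            params[name] = choices[rng.choice(len(choices), p=counts / counts.sum())]
            continue
        lo, hi = _transform(spec, spec["low"]), _transform(spec, spec["high"])
        span = max(hi - lo, 1e-12)
        g = np.array([_transform(spec, t.params[name]) for t in good])
        b = np.array([_transform(spec, t.params[name]) for t in bad])
        bw_g = max(span / math.sqrt(len(g) + 1), 1e-3 * span)
        bw_b = max(span / math.sqrt(len(b) + 1), 1e-3 * span)
        best_t, best_score = None, -np.inf
        for _ in range(n_candidates):
            center = g[rng.integers(len(g))] if len(g) else (lo + hi) / 2
            cand = float(np.clip(center + bw_g * rng.standard_normal(), lo, hi))
            score = _mixture_logpdf(cand, g, bw_g) - _mixture_logpdf(cand, b, bw_b)
            if score > best_score:
                best_t, best_score = cand, score
        params[name] = _inverse(spec, best_t)
    return params


def tune(
    evaluate_fold,
    n_folds: int,
    space: dict,
    n_trials: int,
    seed: int,
    n_startup: int = 8,
    gamma: float = 0.25,
    n_candidates: int = 24,
    min_rung_population: int = 4,
) -> tuple[dict, float, list[Trial]]:
    """Maximize the mean of ``evaluate_fold(params, fold)`` over folds.

    Returns ``(best_params, best_value, history)``. With ``n_trials`` 0 the
    search is skipped and an empty parameter set (estimator defaults) is
    returned with a warning. Fully deterministic for a fixed seed.
    """
    if n_trials < 1:
        warnings.warn("n_trials=0: skipping search, using estimator defaults")
        return {}, float("nan"), []
    rng = np.random.default_rng(seed)
    history: list[Trial] = []
    for number in range(n_trials):
        complete = [t for t in history if t.value is not None]
        if len(complete) < n_startup or not space:
            params = _sample_random(space, rng)
        else:
            ordered = sorted(complete, key=lambda t: -t.value)
            n_good = max(1, math.ceil(gamma * len(ordered)))
            params = _sample_tpe(space, ordered[:n_good], ordered[n_good:], rng, n_candidates)
        trial = Trial(number=number, params=params)
        for f in range(n_folds):
            trial.fold_values.append(float(evaluate_fold(params, f)))
            if f < n_folds - 1:
                rung = [
                    float(np.mean(t.fold_values[: f + 1]))
                    for t in history
                    if len(t.fold_values) > f
                ]
                if len(rung) >= min_rung_population and np.mean(
                    trial.fold_values
                ) < np.median(rung):
                    trial.pruned = True
                    logger.debug("trial %d pruned at fold %d", number, f)
                    break
        if not trial.pruned:
            trial.value = float(np.mean(trial.fold_values))
        history.append(trial)
    complete = [t for t in history if t.value is not None]
    if not complete:  # pragma: no cover - pruning never removes the first trial
        raise RuntimeError("no trial ran to completion")
    best = max(complete, key=lambda t: (t.value, -t.number))
    return best.params, best.value, history
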