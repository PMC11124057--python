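"""A compact tree-structured Parzen estimator (TPE) sampler.

Sequential model-based minimisation: after a random startup phase the
observed trials are split into a "good" fraction (lowest objective
values, fraction ``gamma``) and the rest.  For every parameter a Parzen
(kernel-density) estimate l(x) is built over the good values and g(x)
over the bad ones; candidates are drawn from l and the one maximising
l(x)/g(x) is proposed.  Parameters are treated independently
(univariate TPE), which is the standard default for small search
spaces.  All draws come from a seeded generator, so identical seeds
reproduce identical trial sequences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Any, Sequence

import numpy as np


@dataclass(frozen=True)
class Real:
    name: str
    low: float
    high: float
    log: bool = False

    def transform(self, v: float) -> float:
        return math.log(v) if self.log else v

    def inverse(self, t: float) -> float:
        v = math.exp(t) if self.log else t
        return min(max(v, self.low), self.high)

    @property
    def t_bounds(self) -> tuple[float, float]:
        return (self.transform(self.low), self.transform(self.high))


@dataclass(frozen=True)
class Integer:
    name: str
    low: int
    high: int

    def transform(self, v: int) -> float:
        return float(v)

    def inverse(self, t: float) -> int:
        return int(min(max(round(t), self.low), self.high))

    @property
    def t_bounds(self) -> tuple[float, float]:
        return (float(self.low), float(self.high))


@dataclass(frozen=True)
class Categorical:
    name: str
    choices: tuple[Any, ...]


Param = Real | Integer | Categorical
SearchSpace = Sequence[Param]


@dataclass
class Trial:
    number: int
    params: dict[str, Any]
    value: float


def _parzen_pdf(x: np.ndarray, data: np.ndarray, bw: float) -> np.ndarray:
    """Mean of Gaussian kernels centred on ``data``."""
    z = (x[:, None] - data[None, :]) / bw
    return np.exp(-0.5 * z * z).mean(axis=1) / (bw * math.sqrt(2 * math.pi))


class TPESampler:
    def __init__(
        self,
        space: SearchSpace,
        seed: int = 0,
        n_startup: int = 10,
        gamma: float = 0.25,
        n_candidates: int = 24,
    ):
        names = [p.name for p in space]
        if len(set(names)) != len(names):
            raise ValueError("duplicate parameter names in search space")
        self.space = list(space)
        self.rng = np.random.default_rng(seed)
        self.n_startup = n_startup
        self.gamma = gamma
        self.n_candidates = n_candidates

    # -- random sampling -------------------------------------------------
    def _random_value(self, p: Param) -> Any:
        if isinstance(p, Categorical):
            return p.choices[self.rng.integers(len(p.choices))]
        lo, hi = p.t_bounds
        return p.inverse(self.rng.uniform(lo, hi))

    def _random_params(self) -> dict[str, Any]:
        return {p.name: self._random_value(p) for p in self.space}

    # -- TPE proposal ----------------------------------------------------
    def _split(self, trials: list[Trial]) -> tuple[list[Trial], list[Trial]]:
        finite = [t for t in trials if math.isfinite(t.value)]
        ordered = sorted(finite, key=lambda t: t.value)
        n_good = max(1, math.ceil(self.gamma * len(ordered)))
        return ordered[:n_good], ordered[n_good:]

    def _propose_numeric(
        self, p: Real | Integer, good: np.ndarray, bad: np.ndarray
    ) -> Any:
        lo, hi = p.t_bounds
        span = hi - lo
        if span <= 0:
            return p.inverse(lo)

        def bandwidth(data: np.ndarray) -> float:
            if data.size < 2:
                return max(span / 5.0, 1e-12)
            bw = data.std() * data.size ** (-1 / 5)
            return max(bw, span / 20.0, 1e-12)

        bw_g = bandwidth(good)
        centres = self.rng.choice(good, size=self.n_candidates)
        cands = centres + self.rng.normal(0.0, bw_g, size=self.n_candidates)
        cands = np.clip(cands, lo, hi)
        l_pdf = _parzen_pdf(cands, good, bw_g) + 1e-12
        if bad.size:
            g_pdf = _parzen_pdf(cands, bad, bandwidth(bad)) + 1e-12
        else:
            g_pdf = np.full(cands.shape, 1.0 / span)
        best = cands[int(np.argmax(l_pdf / g_pdf))]
        return p.inverse(best)

    def _propose_categorical(
        self, p: Categorical, good: list[Any], bad: list[Any]
    ) -> Any:
        k = len(p.choices)
        counts_g = np.array([good.count(c) for c in p.choices], dtype=float)
        counts_b = np.array([bad.count(c) for c in p.choices], dtype=float)
        l_prob = (counts_g + 1.0) / (counts_g.sum() + k)
        g_prob = (counts_b + 1.0) / (counts_b.sum() + k)
        ratio = l_prob / g_prob
        # sample proportionally to the ratio to keep exploration alive
        prob = ratio / ratio.sum()
        return p.choices[self.rng.choice(k, p=prob)]

    def suggest(self, trials: list[Trial]) -> dict[str, Any]:
        if len(trials) < self.n_startup:
            return self._random_params()
        good, bad = self._split(trials)
        if not good:
            return self._random_params()
        params: dict[str, Any] = {}
        for p in self.space:
            if isinstance(p, Categorical):
                params[p.name] = self._propose_categorical(
                    p,
                    [t.params[p.name] for t in good],
                    [t.params[p.name] for t in bad],
                )
            else:
                gv = np.array([p.transform(t.params[p.name]) for t in good])
                bv = np.array([p.transform(t.params[p.name]) for t in bad])
                params[p.name] = self._propose_numeric(p, gv, bv)
        return params


def minimize(
    objective,
    space: SearchSpace,
    n_trials: int,
    seed: int = 0,
    **sampler_kwargs,
) -> list[Trial]:
    """Run ``n_trials`` of TPE minimisation; returns the trial history.

    Failed trials (objective raising) are recorded with value +inf.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    sampler = TPESampler(space, seed=seed, **sampler_kwargs)
    trials: list[Trial] = []
    errors: list[tuple[int, Exception]] = []
    for i in range(n_trials):
        params = sampler.suggest(trials)
        try:
            value = float(objective(params))
        except Exception as exc:  # recorded, trial marked failed
            errors.append((i, exc))
            value = math.inf
        trials.append(Trial(i, params, value))
    if all(not math.isfinite(t.value) for t in trials):
        detail = "; ".join(f"trial {i}: {e!r}" for i, e in errors[:5])
        raise RuntimeError(f"all {n_trials} trials failed ({detail})")
    return trials
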