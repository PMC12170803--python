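"""Tree-structured Parzen estimator (TPE) sampling and median pruning.

TPE is a Bayesian-optimization strategy: past trials are split into a
"good" fraction (top ``gamma`` by objective value) and the rest, each
parameter's observations are turned into Parzen density estimates l(x)
(good) and g(x) (bad), and the next value is the candidate maximizing the
ratio l(x)/g(x). Conditional parameters — sampled only when a parent
parameter takes an allowed value — are supported, matching how gradient
boosting search spaces nest (e.g. sampling method parameters under the
chosen booster).

The median pruner cancels a running trial whose partial objective at a
given step falls below the median of completed trials' partial objectives
at the same step.

Everything is seeded; identical (space, history, seed) yields identical
suggestions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np


@dataclass(frozen=True)
class Uniform:
    low: float
    high: float
    condition: Optional[tuple] = None  # (parent_name, allowed values)

    def __post_init__(self):
        if not (math.isfinite(self.low) and math.isfinite(self.high)):
            raise ValueError("bounds must be finite")
        if self.low >= self.high:
            raise ValueError("low must be < high")

    def transform(self, x):
        return float(x)

    def inverse(self, t):
        return float(np.clip(t, self.low, self.high))

    def bounds_t(self):
        return self.low, self.high

    def random(self, rng):
        return float(rng.uniform(self.low, self.high))


@dataclass(frozen=True)
class LogUniform(Uniform):
    def __post_init__(self):
        super().__post_init__()
        if self.low <= 0:
            raise ValueError("log-uniform bounds must be positive")

    def transform(self, x):
        return math.log(x)

    def inverse(self, t):
        return float(np.clip(math.exp(t), self.low, self.high))

    def bounds_t(self):
        return math.log(self.low), math.log(self.high)

    def random(self, rng):
        return float(
            math.exp(rng.uniform(math.log(self.low), math.log(self.high)))
        )


@dataclass(frozen=True)
class IntUniform(Uniform):
    def inverse(self, t):
        return int(np.clip(round(t), self.low, self.high))

    def random(self, rng):
        return int(rng.integers(int(self.low), int(self.high) + 1))


@dataclass(frozen=True)
class Categorical:
    choices: tuple
    condition: Optional[tuple] = None

    def __post_init__(self):
        if not self.choices:
            raise ValueError("need at least one choice")

    def random(self, rng):
        return self.choices[int(rng.integers(len(self.choices)))]


def validate_space(space: dict):
    """Conditional parameters must reference parameters defined earlier."""
    seen = set()
    for name, dist in space.items():
        cond = getattr(dist, "condition", None)
        if cond is not None and cond[0] not in seen:
            raise ValueError(
                f"parameter {name!r} conditions on undefined parent {cond[0]!r}"
            )
        seen.add(name)


class TPESampler:
    """Univariate TPE over a (possibly conditional) search space."""

    def __init__(
        self,
        space: dict,
        seed: int = 0,
        n_startup: int = 10,
        gamma: float = 0.25,
        n_candidates: int = 24,
    ):
        validate_space(space)
        self.space = space
        self.rng = np.random.default_rng(seed)
        self.n_startup = n_startup
        self.gamma = gamma
        self.n_candidates = n_candidates

    def _active(self, name, dist, params) -> bool:
        cond = getattr(dist, "condition", None)
        if cond is None:
            return True
        parent, allowed = cond
        return parent in params and params[parent] in allowed

    def _random_params(self) -> dict:
        params = {}
        for name, dist in self.space.items():
            if self._active(name, dist, params):
                params[name] = dist.random(self.rng)
        return params

    @staticmethod
    def _split(history: Sequence[tuple], gamma: float) -> tuple:
        ordered = sorted(history, key=lambda h: -h[1])
        n_good = max(1, math.ceil(gamma * len(ordered)))
        return ordered[:n_good], ordered[n_good:]

    def _parzen_logpdf(self, dist, obs_t, lo, hi, x_t):
        if len(obs_t) == 0:
            return -math.log(hi - lo)  # uniform prior
        sigma = max((hi - lo) / max(math.sqrt(len(obs_t)), 1.0), 1e-12)
        # mixture of Gaussians at observations plus a flat prior component
        comps = [
            -0.5 * ((x_t - mu) / sigma) ** 2
            - math.log(sigma * math.sqrt(2 * math.pi))
            for mu in obs_t
        ]
        comps.append(-math.log(hi - lo))
        m = max(comps)
        return m + math.log(sum(math.exp(c - m) for c in comps) / len(comps))

    def _suggest_numeric(self, dist, good_vals, bad_vals):
        lo, hi = dist.bounds_t()
        good_t = [dist.transform(v) for v in good_vals]
        bad_t = [dist.transform(v) for v in bad_vals]
        sigma = max((hi - lo) / max(math.sqrt(max(len(good_t), 1)), 1.0), 1e-12)
        cands = []
        for _ in range(self.n_candidates):
            if good_t and self.rng.random() > 1.0 / (len(good_t) + 1):
                mu = good_t[int(self.rng.integers(len(good_t)))]
                t = float(np.clip(self.rng.normal(mu, sigma), lo, hi))
            else:
                t = float(self.rng.uniform(lo, hi))
            cands.append(t)
        scores = [
            self._parzen_logpdf(dist, good_t, lo, hi, t)
            - self._parzen_logpdf(dist, bad_t, lo, hi, t)
            for t in cands
        ]
        return dist.inverse(cands[int(np.argmax(scores))])

    def _suggest_categorical(self, dist, good_vals, bad_vals):
        def probs(vals):
            counts = np.ones(len(dist.choices))  # add-one prior
            for v in vals:
                counts[dist.choices.index(v)] += 1
            return counts / counts.sum()

        pg, pb = probs(good_vals), probs(bad_vals)
        ratio = pg / pb
        idx = self.rng.choice(len(dist.choices), size=self.n_candidates, p=pg)
        best = idx[int(np.argmax(ratio[idx]))]
        return dist.choices[int(best)]

    def suggest(self, history: Sequence[tuple]) -> dict:
        """Next parameter set given ``history`` of (params, value) pairs."""
        usable = [(p, v) for p, v in history if v is not None]
        if len(usable) < self.n_startup:
            return self._random_params()
        good, bad = self._split(usable, self.gamma)
        params = {}
        for name, dist in self.space.items():
            if not self._active(name, dist, params):
                continue
            good_vals = [p[name] for p, _ in good if name in p]
            bad_vals = [p[name] for p, _ in bad if name in p]
            if isinstance(dist, Categorical):
                params[name] = self._suggest_categorical(dist, good_vals, bad_vals)
            else:
                params[name] = self._suggest_numeric(dist, good_vals, bad_vals)
        return params


@dataclass
class MedianPruner:
    """Prune a trial whose running mean falls below the running median.

    ``n_warmup_trials`` completed trials are required before any pruning;
    comparisons happen per step (fold index) against the partial means the
    completed trials reported at that same step.
    """

    n_warmup_trials: int = 5
    completed_steps: list = field(default_factory=list)  # per-trial list of partial means

    def report_completed(self, partial_means: Sequence[float]):
        self.completed_steps.append(list(partial_means))

    def should_prune(self, step: int, running_mean: float) -> bool:
        at_step = [
            t[step] for t in self.completed_steps if len(t) > step
        ]
        if len(at_step) < self.n_warmup_trials:
            return False
        return running_mean < float(np.median(at_step))
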