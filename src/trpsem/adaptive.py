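"""Adaptive trial-placement procedures.

Two algorithms drive the simulated sessions:

* a Bayesian adaptive (QUEST-style) procedure for the motion task: a grid
  posterior over the log10-ms duration threshold, updated by the likelihood
  of each binary response under an assumed 2AFC psychometric family, with
  posterior-mean placement and estimation, targeting 82% correct and
  starting at 80 ms;
* a weighted up-down staircase for the auditory timing tasks: asymmetric
  steps (e.g. +9 ms after an incorrect, -3 ms after a correct response,
  switching to +6/-2 from the seventh trial) whose equilibrium percent
  correct is step_up / (step_up + step_down) = 75%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["QuestConfig", "Quest", "Staircase", "interleave_series",
           "weibull_2afc", "logistic_2afc"]


# ---------------------------------------------------------------------------
# psychometric families (2AFC, parameterized by the level of target_p)
# ---------------------------------------------------------------------------

def weibull_2afc(x, threshold, slope, chance, lapse, target_p):
    """P(correct) for a Weibull on log10 duration, anchored so that
    P(threshold) = target_p."""
    span = 1.0 - lapse - chance
    frac = (target_p - chance) / span
    shift = np.log10(-np.log1p(-frac))  # 10**(slope*(x-T)) offset
    return chance + span * (1.0 - np.exp(-(10.0 ** (slope * (np.asarray(x) - threshold) + shift))))


def logistic_2afc(x, threshold, slope, chance, lapse, target_p):
    """Logistic alternative on the same scale, same anchoring."""
    span = 1.0 - lapse - chance
    frac = (target_p - chance) / span
    bias = np.log(frac / (1.0 - frac))
    k = slope * np.log(10.0)
    return chance + span / (1.0 + np.exp(-(k * (np.asarray(x) - threshold) + bias)))


_FAMILIES = {"weibull": weibull_2afc, "logistic": logistic_2afc}


# ---------------------------------------------------------------------------
# QUEST
# ---------------------------------------------------------------------------

@dataclass
class QuestConfig:
    """Assumptions of the Bayesian adaptive procedure.

    The threshold grid spans 2-500 ms on the log10 scale at 0.01 steps;
    the prior is uniform; placement and estimation use the posterior mean.
    """
    grid_lo: float = float(np.log10(2.0))
    grid_hi: float = float(np.log10(500.0))
    grid_step: float = 0.01
    target_p: float = 0.82
    assumed_slope: float = 3.5
    assumed_lapse: float = 0.01
    chance: float = 0.5
    initial_log_duration: float = float(np.log10(80.0))
    family: str = "weibull"

    def __post_init__(self):
        if not (self.chance < self.target_p < 1.0 - self.assumed_lapse):
            raise ValueError("target_p must lie strictly between chance and 1-lapse")
        if self.grid_hi <= self.grid_lo or self.grid_step <= 0:
            raise ValueError("grid must be strictly increasing")


class Quest:
    """Grid-posterior Bayesian threshold tracker."""

    def __init__(self, config: QuestConfig | None = None):
        self.config = config or QuestConfig()
        c = self.config
        self.grid = np.arange(c.grid_lo, c.grid_hi + c.grid_step / 2, c.grid_step)
        self.log_posterior = np.zeros_like(self.grid)  # uniform prior
        self.trial_count = 0
        self.degenerate = False
        self._psych = _FAMILIES[c.family]

    # -- posterior -------------------------------------------------------
    @property
    def posterior(self) -> np.ndarray:
        w = np.exp(self.log_posterior - self.log_posterior.max())
        return w / w.sum()

    def _p_correct(self, level):
        c = self.config
        return self._psych(level, self.grid, c.assumed_slope, c.chance,
                           c.assumed_lapse, c.target_p)

    # -- interface -------------------------------------------------------
    def next_level(self) -> float:
        """Stimulus level for the next trial (log10 ms)."""
        if self.trial_count == 0:
            return float(np.clip(self.config.initial_log_duration,
                                 self.grid[0], self.grid[-1]))
        post = self.posterior
        if post.argmax() in (0, self.grid.size - 1) and post.max() > 0.5:
            self.degenerate = True
        return float(np.clip(post @ self.grid, self.grid[0], self.grid[-1]))

    def update(self, level: float, correct: bool) -> None:
        if not np.isfinite(level):
            raise ValueError("level must be finite")
        p = np.clip(self._p_correct(level), 1e-12, 1 - 1e-12)
        self.log_posterior += np.log(p if correct else 1.0 - p)
        self.log_posterior -= self.log_posterior.max()
        self.trial_count += 1

    def estimate(self) -> float:
        """Posterior-mean threshold estimate (log10 ms)."""
        if self.trial_count == 0:
            raise RuntimeError("estimate requested before any update")
        return float(self.posterior @ self.grid)

    def run(self, respond, n_trials: int) -> float:
        """Convenience driver: ``respond(level) -> bool``; returns estimate."""
        for _ in range(n_trials):
            level = self.next_level()
            self.update(level, respond(level))
        return self.estimate()


# ---------------------------------------------------------------------------
# weighted up-down staircase
# ---------------------------------------------------------------------------

@dataclass
class Staircase:
    """Weighted up-down tracker on a millisecond difference.

    ``steps`` is a sequence of (step_up, step_down) phases;
    ``phase_switch`` gives the 1-based trial index at which each later phase
    begins (default: second phase from trial 7).  The level is clamped at
    ``floor``.  Equilibrium percent correct is step_up/(step_up+step_down).
    """
    initial_level: float
    steps: tuple = ((9.0, 3.0), (6.0, 2.0))
    phase_switch: tuple = (7,)
    floor: float = 1.0
    ceiling: float = float("inf")
    series_length: int = 32

    level: float = field(init=False)
    history: list = field(init=False, default_factory=list)

    def __post_init__(self):
        for up, down in self.steps:
            if up <= 0 or down <= 0:
                raise ValueError("step sizes must be positive")
        if len(self.phase_switch) != len(self.steps) - 1:
            raise ValueError("need one switch index per extra phase")
        self.level = max(float(self.initial_level), self.floor)

    @property
    def trial_index(self) -> int:
        """1-based index of the next trial to run."""
        return len(self.history) + 1

    @property
    def complete(self) -> bool:
        return len(self.history) >= self.series_length

    def current_steps(self, trial_index: int) -> tuple:
        phase = sum(trial_index >= sw for sw in self.phase_switch)
        return self.steps[phase]

    def record(self, correct: bool) -> float:
        """Record the response to the current trial; return the next level."""
        if self.complete:
            raise RuntimeError("series already complete")
        t = self.trial_index
        self.history.append((self.level, bool(correct)))
        up, down = self.current_steps(t)
        nxt = self.level - down if correct else self.level + up
        self.level = min(max(nxt, self.floor), self.ceiling)
        return self.level

    def threshold(self, last: int = 20) -> float:
        """Mean presented level over the last ``last`` trials of the series."""
        if not self.complete:
            raise RuntimeError(
                f"series incomplete ({len(self.history)}/{self.series_length} trials)")
        levels = [lv for lv, _ in self.history[-last:]]
        return float(np.mean(levels))

    @property
    def equilibrium_p(self) -> float:
        up, down = self.steps[-1]
        return up / (up + down)


def interleave_series(len_a: int, len_b: int, rng) -> list[dict]:
    """Randomized balanced schedule for two interleaved series.

    Returns one dict per trial with the series label, the within-series
    trial index (order preserved) and a counterbalanced standard-first
    flag (half of each series' trials, shuffled).
    """
    if len_a != len_b:
        raise ValueError("series must have equal lengths to interleave")
    if len_a % 2:
        raise ValueError("odd series length cannot balance standard order")
    order = np.array(["A"] * len_a + ["B"] * len_b)
    rng.shuffle(order)
    schedule, counters = [], {"A": 0, "B": 0}
    first = {}
    for s in "AB":
        flags = np.array([True] * (len_a // 2) + [False] * (len_a // 2))
        rng.shuffle(flags)
        first[s] = flags
    for s in order:
        i = counters[s]
        schedule.append({"series": s, "series_trial": i + 1,
                         "standard_first": bool(first[s][i])})
        counters[s] += 1
    return schedule
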