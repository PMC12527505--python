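"""Apple Gathering Task design: offer grid, trial schedule, calibration, exertion omission.

The AGT presents a fixed factorial grid of offers — a reward (number of
apples) for a required grip force (a proportion of the participant's
maximum voluntary contraction, MVC).  Each reward/effort combination is
repeated a fixed number of times in a randomised order; with the default
4 x 4 grid and 5 repetitions a session comprises 80 offers.  To mitigate
fatigue, the exertion phase is omitted on a quarter of accepted offers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "DesignError",
    "CalibrationError",
    "DesignGrid",
    "TrialSchedule",
    "CalibrationProtocol",
    "TrialRecord",
    "build_schedule",
    "compute_mvc",
    "assign_exertion_omission",
]


class DesignError(ValueError):
    """Invalid task-design configuration."""


class CalibrationError(ValueError):
    """Invalid or insufficient calibration data."""


@dataclass(frozen=True)
class DesignGrid:
    """Factorial offer grid.

    Parameters
    ----------
    reward_levels:
        Apple counts on offer, strictly increasing.
    effort_levels:
        Required force as proportions of MVC, strictly increasing, in (0, 1].
    repetitions:
        Number of times each reward x effort cell appears.
    """

    reward_levels: tuple = (3, 6, 9, 12)
    effort_levels: tuple = (0.20, 0.40, 0.60, 0.80)
    repetitions: int = 5

    def __post_init__(self):
        object.__setattr__(self, "reward_levels", tuple(self.reward_levels))
        object.__setattr__(self, "effort_levels", tuple(self.effort_levels))
        if not self.reward_levels or not self.effort_levels:
            raise DesignError("reward and effort level lists must be non-empty")
        if any(r <= 0 for r in self.reward_levels):
            raise DesignError("reward levels must be positive")
        if any(not (0 < e <= 1) for e in self.effort_levels):
            raise DesignError("effort levels must lie in (0, 1]")
        if list(self.reward_levels) != sorted(set(self.reward_levels)):
            raise DesignError("reward levels must be strictly increasing")
        if list(self.effort_levels) != sorted(set(self.effort_levels)):
            raise DesignError("effort levels must be strictly increasing")
        if self.repetitions < 1:
            raise DesignError("repetitions must be >= 1")

    @property
    def n_trials(self) -> int:
        return len(self.reward_levels) * len(self.effort_levels) * self.repetitions

    @property
    def cells(self) -> list:
        """All (reward, effort) combinations in grid order."""
        return [(r, e) for r in self.reward_levels for e in self.effort_levels]


@dataclass(frozen=True)
class TrialSchedule:
    """Ordered sequence of offers for one session.

    ``trials`` is a list of ``(trial_index, reward_apples, effort_prop)``
    with contiguous indices starting at 0.
    """

    trials: tuple
    seed: Optional[int] = None

    def __len__(self) -> int:
        return len(self.trials)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            list(self.trials), columns=["trial_index", "reward_apples", "effort_prop"]
        )


@dataclass(frozen=True)
class CalibrationProtocol:
    """MVC calibration: ``n_squeezes`` maximal squeezes; the peak force over
    the final ``mvc_window`` squeezes defines the MVC."""

    n_squeezes: int = 6
    mvc_window: int = 3
    practice_levels: tuple = (0.20, 0.40, 0.60, 0.80)

    def __post_init__(self):
        if self.mvc_window > self.n_squeezes:
            raise CalibrationError("mvc_window cannot exceed n_squeezes")
        if self.mvc_window < 1 or self.n_squeezes < 1:
            raise CalibrationError("window and squeeze counts must be positive")


@dataclass
class TrialRecord:
    """One offer and its outcome.

    ``success`` is None for refused offers and for accepted offers on which
    the exertion phase was omitted.
    """

    trial_index: int
    reward_apples: float
    effort_prop: float
    accepted: bool
    exertion_omitted: bool = False
    success: Optional[bool] = None


def build_schedule(grid: DesignGrid, seed: int) -> TrialSchedule:
    """Full-factorial crossing x repetitions, uniformly permuted by ``seed``."""
    pairs = [(r, e) for r in grid.reward_levels for e in grid.effort_levels
             for _ in range(grid.repetitions)]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pairs))
    trials = tuple(
        (i, float(pairs[j][0]), float(pairs[j][1])) for i, j in enumerate(order)
    )
    return TrialSchedule(trials=trials, seed=seed)


def compute_mvc(calibration_forces: Sequence[float],
                protocol: CalibrationProtocol = CalibrationProtocol()) -> float:
    """Peak force over the final ``mvc_window`` calibration squeezes."""
    forces = list(calibration_forces)
    if len(forces) != protocol.n_squeezes:
        raise CalibrationError(
            f"expected {protocol.n_squeezes} calibration forces, got {len(forces)}"
        )
    window = forces[-protocol.mvc_window:]
    return float(max(window))


def assign_exertion_omission(accepted_trial_indices: Sequence[int],
                             fraction: float = 0.25) -> set:
    """Deterministically flag ``floor(fraction * n_accepted)`` accepted trials
    for exertion omission, taking every k-th accepted trial (k = round(1/fraction)).

    The deterministic every-k-th rule makes the omitted proportion exact and
    reproducible; flagged trials carry no exertion outcome.
    """
    if not (0 <= fraction <= 1):
        raise DesignError("fraction must lie in [0, 1]")
    accepted = list(accepted_trial_indices)
    n = len(accepted)
    n_flag = math.floor(fraction * n)
    if n_flag == 0:
        return set()
    k = max(1, round(1.0 / fraction))
    flagged = accepted[k - 1 :: k][:n_flag]
    # if the stride undershoots (fraction not of the form 1/k), top up from the end
    if len(flagged) < n_flag:
        extra = [i for i in reversed(accepted) if i not in flagged]
        flagged += extra[: n_flag - len(flagged)]
    return set(flagged)
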