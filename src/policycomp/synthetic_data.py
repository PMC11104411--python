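"""Set-size task designs and two-cohort synthetic behavioral datasets.

The emulated experiment: each subject completes 13 blocks; a block has a
*set size* between 2 and 6 distinct stimuli (never repeated across blocks),
each mapped deterministically to one of 3 rewarded actions.  A stimulus is
presented 9-15 times within its block under a performance criterion: once a
stimulus has at least 9 presentations and at least 4 of its last 5 responses
were correct, it is retired; otherwise it retires at 15 presentations.
Presentation order is a shuffled round-robin over the still-active stimuli,
which keeps per-stimulus counts near-balanced while the criterion runs.

Two cohorts are generated: a control-like group (36 subjects) and a
patient-like group (49 subjects) whose generating parameters differ in the
directions reported for schizophrenia — lower inverse temperature and higher
actor learning rate — with identical critic and marginal learning-rate
distributions.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "TaskConfig",
    "Block",
    "TaskDesign",
    "BlockScheduler",
    "SubjectData",
    "CohortSpec",
    "TrialSchemaError",
    "DEFAULT_SET_SIZES",
    "generate_task",
    "default_cohort_specs",
    "default_generating_ranges",
    "draw_params",
    "simulate_cohorts",
    "design_from_trials",
    "write_trials",
    "read_trials",
]

#: 13 blocks covering every set size 2-6 (3x sizes 2-4, 2x sizes 5-6)
DEFAULT_SET_SIZES: tuple[int, ...] = (2, 2, 2, 3, 3, 3, 4, 4, 4, 5, 5, 6, 6)

TRIAL_COLUMNS = [
    "subject_id",
    "group",
    "block",
    "set_size",
    "trial_in_block",
    "stimulus_id",
    "action",
    "reward",
]


class TrialSchemaError(ValueError):
    """A trial-log file violates the CSV dialect."""


@dataclass(frozen=True)
class TaskConfig:
    """Design parameters of the set-size task."""

    set_sizes: tuple[int, ...] = DEFAULT_SET_SIZES
    n_actions: int = 3
    min_presentations: int = 9
    max_presentations: int = 15
    criterion_window: int = 5
    criterion_correct: int = 4

    def __post_init__(self) -> None:
        if any(n < 2 or n > 6 for n in self.set_sizes):
            raise ValueError("set sizes must lie in [2, 6]")
        if self.min_presentations > self.max_presentations:
            raise ValueError("min_presentations must not exceed max_presentations")

    @property
    def n_blocks(self) -> int:
        return len(self.set_sizes)


@dataclass(frozen=True)
class Block:
    set_size: int
    stimulus_ids: np.ndarray  # globally unique ids, length set_size
    correct_actions: np.ndarray  # rewarded action per stimulus


@dataclass(frozen=True)
class TaskDesign:
    config: TaskConfig
    blocks: tuple[Block, ...]


@dataclass
class SubjectData:
    """Ordered trial records for one subject (13 blocks) with group label."""

    subject_id: str
    group: str
    trials: pd.DataFrame

    def to_arrays(self):
        """Flatten into per-trial arrays for the likelihood kernel.

        Returns (state, action, reward, block_ptr, n_states) where ``state``
        is the within-block stimulus index, assigned by order of first
        appearance, and ``block_ptr`` delimits blocks.
        """
        df = self.trials
        state = np.empty(len(df), dtype=np.int64)
        action = df["action"].to_numpy(dtype=np.int64)
        reward = df["reward"].to_numpy(dtype=np.float64)
        block_ptr = [0]
        n_states = []
        pos = 0
        for _, sub in df.groupby("block", sort=True):
            stim = sub["stimulus_id"].to_numpy()
            _, first_idx = np.unique(stim, return_index=True)
            order = stim[np.sort(first_idx)]
            mapping = {s: i for i, s in enumerate(order)}
            state[pos : pos + len(sub)] = [mapping[s] for s in stim]
            pos += len(sub)
            block_ptr.append(pos)
            n_states.append(len(mapping))
        return (
            state,
            action,
            reward,
            np.asarray(block_ptr, dtype=np.int64),
            np.asarray(n_states, dtype=np.int64),
        )


def generate_task(cfg: TaskConfig = TaskConfig(), seed: int = 0) -> TaskDesign:
    """Random task realization: shuffled block order, fresh stimulus ids,
    random stimulus-to-correct-action map."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(cfg.set_sizes))
    blocks = []
    next_id = 0
    for b in order:
        n = cfg.set_sizes[b]
        ids = np.arange(next_id, next_id + n)
        next_id += n
        correct = rng.integers(0, cfg.n_actions, size=n)
        blocks.append(Block(set_size=n, stimulus_ids=ids, correct_actions=correct))
    return TaskDesign(config=cfg, blocks=tuple(blocks))


class BlockScheduler:
    """Online presentation scheduler for one block.

    Presents still-active stimuli in shuffled round-robin passes; after each
    response, :meth:`record` applies the retirement rule (>= min
    presentations and the 4-of-last-5 criterion, or the hard cap).
    """

    def __init__(self, n_stimuli: int, cfg: TaskConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.rng = rng
        self.active = set(range(n_stimuli))
        self.counts = np.zeros(n_stimuli, dtype=int)
        self.history = [deque(maxlen=cfg.criterion_window) for _ in range(n_stimuli)]
        self._queue: list[int] = []

    def next_stimulus(self) -> int | None:
        while True:
            if not self._queue:
                if not self.active:
                    return None
                self._queue = list(self.rng.permutation(sorted(self.active)))
            s = self._queue.pop(0)
            if s in self.active:
                return int(s)

    def record(self, stimulus: int, correct: bool) -> None:
        self.counts[stimulus] += 1
        self.history[stimulus].append(bool(correct))
        c = self.counts[stimulus]
        met = (
            c >= self.cfg.min_presentations
            and sum(self.history[stimulus]) >= self.cfg.criterion_correct
        )
        if met or c >= self.cfg.max_presentations:
            self.active.discard(stimulus)


@dataclass(frozen=True)
class CohortSpec:
    """Group label, size, and generating parameter ranges (uniform draws)."""

    group: str
    n_subjects: int
    param_ranges: dict
    model: str = "fixed"

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")


# Generating ranges.  Patient-like subjects draw a lower inverse temperature
# and a higher actor learning rate than control-like subjects; the marginal
# learning rate is concentrated near zero in both groups.
_HC_RANGES = {
    "beta": (3.0, 8.0),
    "alpha_theta": (0.05, 0.3),
    "alpha_V": (0.1, 0.6),
    "alpha_P": (0.0, 0.05),
}
_SZ_RANGES = {
    "beta": (1.5, 5.0),
    "alpha_theta": (0.15, 0.5),
    "alpha_V": (0.1, 0.6),
    "alpha_P": (0.0, 0.05),
}
# Pooled ranges used for recovery studies, plus adaptive-variant parameters.
_POOLED_RANGES = {
    "beta": (1.5, 8.0),
    "beta0": (1.5, 8.0),
    "C": (0.2, 1.0),
    # alpha_beta drawn high enough that within-block beta adaptation is
    # behaviorally expressed (small values make the variants mimic fixed-beta)
    "alpha_beta": (0.5, 1.0),
    "alpha_theta": (0.05, 0.5),
    "alpha_V": (0.1, 0.6),
    "alpha_P": (0.0, 0.05),
}


def default_cohort_specs(
    n_hc: int = 36, n_sz: int = 49, model: str = "fixed"
) -> list[CohortSpec]:
    """Control-like (HC) and patient-like (SZ) cohorts at study sizes."""
    return [
        CohortSpec("HC", n_hc, dict(_HC_RANGES), model),
        CohortSpec("SZ", n_sz, dict(_SZ_RANGES), model),
    ]


def default_generating_ranges(model: str) -> dict:
    """Pooled generating ranges for a model's free parameters."""
    from .agents import FREE_PARAMS

    return {name: _POOLED_RANGES[name] for name in FREE_PARAMS[model]}


def draw_params(spec: CohortSpec, rng: np.random.Generator):
    """Draw ``spec.n_subjects`` AgentParams from the spec's uniform ranges."""
    from .agents import FREE_PARAMS, AgentParams

    needed = FREE_PARAMS[spec.model]
    ranges = dict(default_generating_ranges(spec.model))
    ranges.update(spec.param_ranges)
    out = []
    for _ in range(spec.n_subjects):
        kwargs = {name: float(rng.uniform(*ranges[name])) for name in needed}
        out.append(AgentParams(model=spec.model, **kwargs))
    return out


def simulate_cohorts(
    specs: list[CohortSpec],
    cfg: TaskConfig = TaskConfig(),
    seed: int = 0,
) -> tuple[list[SubjectData], pd.DataFrame]:
    """Simulate every subject of every cohort on a fresh task realization.

    Returns the subject list and a ground-truth parameter table (one row per
    subject) for recovery studies.
    """
    from .agents import simulate

    if not specs:
        raise ValueError("no cohort specs given")
    rng = np.random.default_rng(seed)
    subjects: list[SubjectData] = []
    truth_rows = []
    idx = 0
    for spec in specs:
        params_list = draw_params(spec, rng)
        for params in params_list:
            sid = f"{spec.group}{idx:03d}"
            task_seed = int(rng.integers(0, 2**31 - 1))
            sim_seed = int(rng.integers(0, 2**31 - 1))
            task = generate_task(cfg, seed=task_seed)
            subjects.append(
                simulate(params, task, seed=sim_seed, subject_id=sid, group=spec.group)
            )
            row = {"subject_id": sid, "group": spec.group, "model": spec.model}
            row.update(params.free_values())
            truth_rows.append(row)
            idx += 1
    return subjects, pd.DataFrame(truth_rows)


def design_from_trials(data: SubjectData, rng: np.random.Generator) -> TaskDesign:
    """Reconstruct a subject's task design from their trial log.

    Stimuli, block order and set sizes are read off directly; each
    stimulus's correct action is taken from any rewarded trial.  A stimulus
    never answered correctly (possible for chance-level responders) gets a
    random assignment.  Used to re-simulate a fitted model on the same
    stimuli the subject saw.
    """
    blocks = []
    for _, sub in data.trials.groupby("block", sort=True):
        stim = sub["stimulus_id"].drop_duplicates().to_numpy()
        correct = []
        for s in stim:
            rewarded = sub[(sub["stimulus_id"] == s) & (sub["reward"] == 1)]
            if len(rewarded):
                correct.append(int(rewarded["action"].iloc[0]))
            else:
                correct.append(int(rng.integers(0, 3)))
        blocks.append(
            Block(int(sub["set_size"].iloc[0]), stim, np.asarray(correct))
        )
    return TaskDesign(config=TaskConfig(), blocks=tuple(blocks))


def write_trials(subjects: list[SubjectData], path) -> None:
    """Write subjects to the trial-log CSV dialect."""
    frames = [s.trials[TRIAL_COLUMNS] for s in subjects]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_trials(path) -> list[SubjectData]:
    """Read and validate a trial-log CSV, returning one SubjectData per
    subject in file order."""
    df = pd.read_csv(path)
    if list(df.columns) != TRIAL_COLUMNS:
        raise TrialSchemaError(
            f"expected columns {TRIAL_COLUMNS}, found {list(df.columns)}"
        )
    bad = df.index[~df["action"].isin([0, 1, 2])]
    if len(bad):
        raise TrialSchemaError(f"action outside {{0,1,2}} at row {int(bad[0]) + 2}")
    bad = df.index[~df["reward"].isin([0, 1])]
    if len(bad):
        raise TrialSchemaError(f"reward outside {{0,1}} at row {int(bad[0]) + 2}")
    bad = df.index[(df["set_size"] < 2) | (df["set_size"] > 6)]
    if len(bad):
        raise TrialSchemaError(f"set_size outside [2,6] at row {int(bad[0]) + 2}")
    subjects = []
    for sid in df["subject_id"].unique():
        sub = df[df["subject_id"] == sid].reset_index(drop=True)
        for _, blk in sub.groupby("block", sort=True):
            t = blk["trial_in_block"].to_numpy()
            if not np.array_equal(t, np.arange(len(t))):
                raise TrialSchemaError(
                    f"non-contiguous trial_in_block for subject {sid}, "
                    f"block {int(blk['block'].iloc[0])}"
                )
        group = str(sub["group"].iloc[0])
        subjects.append(SubjectData(subject_id=str(sid), group=group, trials=sub))
    return subjects
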