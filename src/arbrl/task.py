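"""Probabilistic reversal-learning task environments and agent simulation.

Emulates the monkey paradigm: 80-trial blocks in which one of two options is
rewarded with probability 0.8, 0.7 or 0.6 (the other with the complement) and
the contingency reverses, unsignalled, on a uniformly random trial between 30
and 50.  In the What-only task reward always attaches to stimulus identity;
in the What/Where task each block is randomly a What block (stimulus-based)
or a Where block (side-based).  Stimulus-to-side assignment is randomized per
trial and independent of the reward process.

Agents are any model of the family in :mod:`arbrl.models`; lesion-mimicking
cohorts shift the group means of the arbitration parameters (low initial
weight omega_0 for amygdala-like agents, low baseline ratio rho for
VS-like agents).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .params import DEFAULT_BOUNDS, ModelParams

__all__ = [
    "BlockSpec",
    "TrialRecord",
    "SessionData",
    "CohortSpec",
    "GROUP_PARAM_DISTS",
    "make_block_spec",
    "sample_reward",
    "simulate_raw",
    "simulate_session",
    "p_better_matrix",
    "generate_cohort",
    "session_arrays",
    "blocks_env_arrays",
]

SIDE_CODE = {"L": 0, "R": 1}
STIM_CODE = {"A": 0, "B": 1}
SIDE_NAME = ("L", "R")
STIM_NAME = ("A", "B")

SCHEDULES = (0.8, 0.7, 0.6)
REVERSAL_RANGE = (30, 50)  # inclusive
N_TRIALS_DEFAULT = 80


@dataclass(frozen=True)
class BlockSpec:
    """Environment of one block: task variant, contingency dimension,
    reward schedule, reversal trial, and which option starts better."""

    task: str  # "what_only" | "what_where"
    block_type: str  # "what" | "where"
    p_better: float
    reversal_trial: int
    better_id: str  # "A"/"B" for what blocks, "L"/"R" for where blocks
    n_trials: int = N_TRIALS_DEFAULT

    def __post_init__(self):
        if self.task not in ("what_only", "what_where"):
            raise ValueError(f"invalid task {self.task!r}")
        if self.block_type not in ("what", "where"):
            raise ValueError(f"invalid block_type {self.block_type!r}")
        if self.task == "what_only" and self.block_type != "what":
            raise ValueError("what_only task implies what blocks")
        if not 1 <= self.reversal_trial <= self.n_trials:
            raise ValueError("reversal_trial outside the block")
        valid_ids = STIM_NAME if self.block_type == "what" else SIDE_NAME
        if self.better_id not in valid_ids:
            raise ValueError(
                f"better_id {self.better_id!r} invalid for {self.block_type} block"
            )

    @property
    def better_code(self) -> int:
        table = STIM_CODE if self.block_type == "what" else SIDE_CODE
        return table[self.better_id]


@dataclass(frozen=True)
class TrialRecord:
    """One completed trial."""

    trial: int  # 1-based within block
    stimA_side: str  # side stimulus A appeared on
    choice_side: str
    choice_stim: str
    reward: int

    def __post_init__(self):
        expected = STIM_NAME[SIDE_CODE[self.choice_side] ^ SIDE_CODE[self.stimA_side]]
        if self.choice_stim != expected:
            raise ValueError(
                f"trial {self.trial}: choice_stim {self.choice_stim!r} inconsistent "
                f"with choice_side={self.choice_side} stimA_side={self.stimA_side}"
            )
        if self.reward not in (0, 1):
            raise ValueError(f"trial {self.trial}: reward must be 0/1")


@dataclass
class SessionData:
    """Ordered blocks of one experimental session."""

    subject_id: str
    session_id: str
    blocks: list[tuple[BlockSpec, list[TrialRecord]]] = field(default_factory=list)

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @property
    def n_trials(self) -> int:
        return sum(len(trials) for _, trials in self.blocks)


#: per-group parameter distributions (mean, spread) for cohort generation.
#: omega_0 group means follow the fitted What/Where values (control
#: 0.374 +- 0.058, amygdala 0.179 +- 0.053); the VS-like group lowers the
#: baseline ratio rho instead.  Remaining means sit at the canonical
#: simulation values (alpha_+ = alpha_- = 0.5, zeta = 0.3, alpha_omega = 0.2,
#: zeta_omega = 0.05, beta_0 = 0).
GROUP_PARAM_DISTS: dict[str, dict[str, tuple[float, float]]] = {
    "control": {
        "alpha_pos": (0.5, 0.1),
        "alpha_neg": (0.5, 0.1),
        "zeta": (0.3, 0.1),
        "beta1": (8.0, 2.0),
        "beta0": (0.0, 0.2),
        "omega0": (0.374, 0.058),
        "alpha_omega": (0.2, 0.05),
        "zeta_omega": (0.05, 0.02),
        "rho": (0.5, 0.05),
    },
}
GROUP_PARAM_DISTS["amygdala"] = dict(
    GROUP_PARAM_DISTS["control"], omega0=(0.179, 0.053)
)
GROUP_PARAM_DISTS["vs"] = dict(GROUP_PARAM_DISTS["control"], rho=(0.4, 0.05))


@dataclass
class CohortSpec:
    """Recipe for a synthetic cohort of agents playing the task."""

    group: str = "control"
    n_subjects: int = 4
    n_sessions: int = 10
    blocks_per_session: int = 20  # ~20 blocks per session in the experiment
    task: str = "what_where"
    model_id: str = "dynamic_omega_rho"
    param_dists: dict[str, tuple[float, float]] | None = None

    def dists(self) -> dict[str, tuple[float, float]]:
        if self.param_dists is not None:
            return self.param_dists
        if self.group not in GROUP_PARAM_DISTS:
            raise ValueError(f"unknown group {self.group!r}")
        return GROUP_PARAM_DISTS[self.group]


def make_block_spec(task: str, rng: np.random.Generator, n_trials: int = N_TRIALS_DEFAULT) -> BlockSpec:
    """Draw one block environment: schedule uniform over 80/20, 70/30, 60/40;
    reversal trial uniform over the inclusive range 30..50; for the
    What/Where task the block type is a fair draw between what and where."""
    if task == "what_only":
        block_type = "what"
    elif task == "what_where":
        block_type = "what" if rng.random() < 0.5 else "where"
    else:
        raise ValueError(f"invalid task {task!r}")
    p_better = SCHEDULES[rng.integers(len(SCHEDULES))]
    reversal = int(rng.integers(REVERSAL_RANGE[0], REVERSAL_RANGE[1] + 1))
    names = STIM_NAME if block_type == "what" else SIDE_NAME
    better = names[rng.integers(2)]
    return BlockSpec(task, block_type, p_better, reversal, better, n_trials)


def sample_reward(
    spec: BlockSpec, trial: int, choice_side: str, choice_stim: str, rng: np.random.Generator
) -> int:
    """Bernoulli reward for a choice on ``trial`` (1-based).  The initially
    better option flips at and after the reversal trial; the relevant choice
    dimension is the stimulus for what blocks and the side for where blocks."""
    if not 1 <= trial <= spec.n_trials:
        raise ValueError(f"trial {trial} outside 1..{spec.n_trials}")
    better = spec.better_code
    if trial >= spec.reversal_trial:
        better = 1 - better
    if spec.block_type == "what":
        chosen = STIM_CODE[choice_stim]
    else:
        chosen = SIDE_CODE[choice_side]
    p = spec.p_better if chosen == better else 1.0 - spec.p_better
    return int(rng.random() < p)


def blocks_env_arrays(specs: Iterable[BlockSpec]):
    """Pack block environments into the kernel's flat arrays."""
    specs = list(specs)
    block_dim = np.array([0 if s.block_type == "what" else 1 for s in specs], dtype=np.int64)
    better = np.array([s.better_code for s in specs], dtype=np.int64)
    p_better = np.array([s.p_better for s in specs], dtype=np.float64)
    rev = np.array([s.reversal_trial for s in specs], dtype=np.int64)
    n_trials = np.array([s.n_trials for s in specs], dtype=np.int64)
    return block_dim, better, p_better, rev, n_trials


def _draw_sides(specs: list[BlockSpec], rng: np.random.Generator, balanced: bool) -> np.ndarray:
    T = max(s.n_trials for s in specs)
    sides = np.zeros((len(specs), T), dtype=np.int64)
    for b, s in enumerate(specs):
        n = s.n_trials
        if balanced:
            half = n // 2
            v = np.concatenate([np.zeros(half, dtype=np.int64), np.ones(n - half, dtype=np.int64)])
            sides[b, :n] = rng.permutation(v)
        else:
            sides[b, :n] = rng.integers(0, 2, n)
    return sides


def simulate_raw(
    model_id: str,
    params: ModelParams,
    blocks: Iterable[BlockSpec],
    rng: np.random.Generator,
    v_init: float = 0.5,
    balanced_sides: bool = False,
    record: bool = True,
) -> dict:
    """Vectorized generative simulation returning flat kernel arrays.

    Runs the generative loop of the named model over a batch of blocks: per
    trial, assign stimulus sides, compute the softmax choice probability
    from the current latent state, draw the choice and the reward, and
    update values (and the arbitration weight for dynamic models).  State
    re-initializes at every block start.  Pure function of
    ``(model_id, params, blocks, rng state)``.

    Returns a dict of ``(B, T)`` arrays (``stimA_side``, ``choice_side``,
    ``choice_stim``, ``reward``), the ``(B, T, N_REC)`` latent-record array
    ``rec``, and the environment arrays.  Large batch sizes are cheap; this
    is the engine behind :func:`simulate_session` and the grid experiments.
    """
    from ._kernel import N_REC, run_blocks
    from .params import model_codes

    specs = list(blocks)
    params.validate(model_id, DEFAULT_BOUNDS)
    code, rel = model_codes(model_id)
    theta = params.to_theta(model_id)
    block_dim, better, p_b, rev, n_trials = blocks_env_arrays(specs)
    B, T = len(specs), int(n_trials.max()) if specs else 0
    stimA = _draw_sides(specs, rng, balanced_sides) if specs else np.zeros((0, 0), dtype=np.int64)
    u = rng.random((B, T, 2))
    cside = np.zeros((B, T), dtype=np.int64)
    cstim = np.zeros((B, T), dtype=np.int64)
    rew = np.zeros((B, T), dtype=np.int64)
    rec = np.zeros((B, T, N_REC) if record else (1, 1, N_REC), dtype=np.float64)
    nll_out = np.zeros(B, dtype=np.float64)
    if B:
        run_blocks(
            True, code, rel, theta, v_init,
            block_dim, better, p_b, rev, n_trials,
            stimA, cside, cstim, rew, u, record, rec, nll_out,
        )
    return {
        "specs": specs,
        "block_dim": block_dim,
        "better": better,
        "p_better": p_b,
        "reversal": rev,
        "n_trials": n_trials,
        "stimA_side": stimA,
        "choice_side": cside,
        "choice_stim": cstim,
        "reward": rew,
        "rec": rec,
    }


def p_better_matrix(raw: dict) -> np.ndarray:
    """Per-trial indicator of choosing the currently better option, from a
    :func:`simulate_raw` result.  Shape ``(B, T)``."""
    B, T = raw["choice_side"].shape
    trial = np.arange(1, T + 1)[None, :]
    cur_better = np.where(
        trial >= raw["reversal"][:, None],
        1 - raw["better"][:, None],
        raw["better"][:, None],
    )
    rel_choice = np.where(
        raw["block_dim"][:, None] == 0, raw["choice_stim"], raw["choice_side"]
    )
    return (rel_choice == cur_better).astype(float)


def simulate_session(
    model_id: str,
    params: ModelParams,
    blocks: Iterable[BlockSpec],
    rng: np.random.Generator,
    subject_id: str = "sim",
    session_id: str = "s1",
    v_init: float = 0.5,
    balanced_sides: bool = False,
):
    """Simulate one agent playing the given blocks.

    Object-level wrapper over :func:`simulate_raw`; returns
    ``(SessionData, list[LatentTrajectory])``.
    """
    from . import models

    raw = simulate_raw(model_id, params, blocks, rng, v_init, balanced_sides)
    specs = raw["specs"]
    stimA, cside = raw["stimA_side"], raw["choice_side"]
    cstim, rew, rec = raw["choice_stim"], raw["reward"], raw["rec"]
    session = SessionData(subject_id, session_id)
    trajs = []
    for b, s in enumerate(specs):
        trials = [
            TrialRecord(
                trial=t + 1,
                stimA_side=SIDE_NAME[stimA[b, t]],
                choice_side=SIDE_NAME[cside[b, t]],
                choice_stim=STIM_NAME[cstim[b, t]],
                reward=int(rew[b, t]),
            )
            for t in range(s.n_trials)
        ]
        session.blocks.append((s, trials))
        trajs.append(models.LatentTrajectory.from_rec(rec[b], s.n_trials))
    return session, trajs


def session_arrays(session: SessionData):
    """Unpack observed session data into the kernel's flat arrays."""
    specs = [spec for spec, _ in session.blocks]
    block_dim, better, p_b, rev, n_trials = blocks_env_arrays(specs)
    B = len(specs)
    T = int(n_trials.max()) if B else 0
    stimA = np.zeros((B, T), dtype=np.int64)
    cside = np.zeros((B, T), dtype=np.int64)
    cstim = np.zeros((B, T), dtype=np.int64)
    rew = np.zeros((B, T), dtype=np.int64)
    for b, (spec, trials) in enumerate(session.blocks):
        if len(trials) != spec.n_trials:
            raise ValueError(
                f"block {b}: {len(trials)} records, expected {spec.n_trials}"
            )
        for t, trec in enumerate(trials):
            stimA[b, t] = SIDE_CODE[trec.stimA_side]
            cside[b, t] = SIDE_CODE[trec.choice_side]
            cstim[b, t] = STIM_CODE[trec.choice_stim]
            rew[b, t] = trec.reward
    return block_dim, better, p_b, rev, n_trials, stimA, cside, cstim, rew


def _sample_params(
    model_id: str,
    dists: dict[str, tuple[float, float]],
    rng: np.random.Generator,
    fixed: dict[str, float] | None = None,
) -> ModelParams:
    """Truncated-normal draw of each free parameter within its bounds."""
    from .params import FREE_PARAMS

    kw: dict[str, float] = {}
    for name in FREE_PARAMS[model_id]:
        if fixed and name in fixed:
            kw[name] = fixed[name]
            continue
        mean, sd = dists[name]
        lo, hi = DEFAULT_BOUNDS[name]
        if not lo <= mean <= hi:
            raise ValueError(f"distribution mean for {name} outside bounds")
        for _ in range(1000):
            val = rng.normal(mean, sd)
            if lo <= val <= hi:
                kw[name] = float(val)
                break
        else:
            raise ValueError(f"could not sample {name} within bounds")
    return ModelParams(**kw)


def generate_cohort(spec: CohortSpec, rng: np.random.Generator):
    """Simulate a whole cohort and return ``(data, truth)``.

    ``data`` maps subject id to a list of :class:`SessionData`; ``truth`` is a
    pandas DataFrame of the generating parameters, one row per
    (subject, session), with rho held constant within subject (it is a
    per-animal baseline, estimated once per monkey).
    """
    import pandas as pd

    dists = spec.dists()
    data: dict[str, list[SessionData]] = {}
    rows = []
    for i in range(spec.n_subjects):
        subj = f"{spec.group}_{i+1:02d}"
        subj_rng = np.random.default_rng(rng.integers(2**31))
        rho = None
        if "rho" in dists and "rho" in _free(spec.model_id):
            lo, hi = DEFAULT_BOUNDS["rho"]
            mean, sd = dists["rho"]
            while True:
                rho = float(subj_rng.normal(mean, sd))
                if lo <= rho <= hi:
                    break
        sessions = []
        for j in range(spec.n_sessions):
            fixed = {"rho": rho} if rho is not None else None
            params = _sample_params(spec.model_id, dists, subj_rng, fixed)
            blocks = [
                make_block_spec(spec.task, subj_rng)
                for _ in range(spec.blocks_per_session)
            ]
            sess, _ = simulate_session(
                spec.model_id, params, blocks, subj_rng,
                subject_id=subj, session_id=f"s{j+1:02d}",
            )
            sessions.append(sess)
            row = {"subject": subj, "session": sess.session_id, "group": spec.group,
                   "model_id": spec.model_id}
            row.update({k: getattr(params, k) for k in _free(spec.model_id)})
            rows.append(row)
        data[subj] = sessions
    truth = pd.DataFrame(rows)
    return data, truth


def _free(model_id: str):
    from .params import FREE_PARAMS

    return FREE_PARAMS[model_id]
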