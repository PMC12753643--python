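"""Trial-table CSV round-tripping and YAML run configuration.

Schema (UTF-8, header required), one row per trial::

    subject,session,block,trial,task,block_type,p_better,reversal_trial,
    stimA_side,choice_side,choice_stim,reward

Enum codes: sides L/R, stimuli A/B, block_type what/where, task
what_only/what_where, reward 0/1.  ``choice_stim`` is redundant with
(choice_side, stimA_side) and is validated on read; inconsistent rows are
rejected with their row number.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .task import BlockSpec, CohortSpec, SessionData, TrialRecord

__all__ = ["COLUMNS", "write_trials", "read_trials", "load_cohort_spec"]

COLUMNS = [
    "subject", "session", "block", "trial", "task", "block_type",
    "p_better", "reversal_trial", "stimA_side", "choice_side",
    "choice_stim", "reward",
]


def _iter_sessions(data):
    if isinstance(data, dict):
        for sessions in data.values():
            yield from sessions
    elif isinstance(data, SessionData):
        yield data
    else:
        yield from data


def write_trials(data, path) -> None:
    """Write sessions (list, dict keyed by subject, or a single session)."""
    rows = []
    for sess in _iter_sessions(data):
        for b, (spec, trials) in enumerate(sess.blocks):
            for t in trials:
                rows.append(
                    (
                        sess.subject_id, sess.session_id, b, t.trial,
                        spec.task, spec.block_type, spec.p_better,
                        spec.reversal_trial, t.stimA_side, t.choice_side,
                        t.choice_stim, t.reward,
                    )
                )
    pd.DataFrame(rows, columns=COLUMNS).to_csv(path, index=False)


def read_trials(path) -> list[SessionData]:
    """Read and validate a trial table; returns sessions in file order."""
    df = pd.read_csv(path, dtype={"subject": str, "session": str})
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    sessions: list[SessionData] = []
    index: dict[tuple, SessionData] = {}
    for (subj, sess_id, block), grp in df.groupby(
        ["subject", "session", "block"], sort=False
    ):
        first = grp.iloc[0]
        rownum = int(grp.index[0]) + 2  # header + 1-based
        try:
            spec = BlockSpec(
                task=str(first["task"]),
                block_type=str(first["block_type"]),
                p_better=float(first["p_better"]),
                reversal_trial=int(first["reversal_trial"]),
                better_id=_infer_better_placeholder(first),
                n_trials=len(grp),
            )
        except ValueError as e:
            raise ValueError(f"row {rownum}: {e}") from e
        trials = []
        for i, (_, row) in enumerate(grp.iterrows()):
            rownum = int(row.name) + 2
            try:
                trials.append(
                    TrialRecord(
                        trial=int(row["trial"]),
                        stimA_side=str(row["stimA_side"]),
                        choice_side=str(row["choice_side"]),
                        choice_stim=str(row["choice_stim"]),
                        reward=int(row["reward"]),
                    )
                )
            except ValueError as e:
                raise ValueError(f"row {rownum}: {e}") from e
            if trials[-1].trial != i + 1:
                raise ValueError(
                    f"row {rownum}: trial index {trials[-1].trial}, expected {i + 1}"
                )
        key = (subj, sess_id)
        if key not in index:
            index[key] = SessionData(subj, sess_id)
            sessions.append(index[key])
        index[key].blocks.append((spec, trials))
    return sessions


def _infer_better_placeholder(row) -> str:
    # better_id is not part of the observable trial record (it is implied by
    # the reward draws); the schema stores the environment minus the better
    # option, so a valid placeholder is used when reading observed data.
    return "A" if str(row["block_type"]) == "what" else "L"


def load_cohort_spec(path) -> CohortSpec:
    """Load a :class:`CohortSpec` from a YAML mapping mirroring its fields."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    dists = cfg.pop("param_dists", None)
    if dists is not None:
        dists = {k: (float(v[0]), float(v[1])) for k, v in dists.items()}
    return CohortSpec(param_dists=dists, **cfg)
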