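"""Entropy of reward-dependent strategy (ERDS) and strategy-dominance labels.

ERDS is the conditional Shannon entropy, in bits, of the per-trial
stay/switch decision given the previous trial's reward outcome:

    ERDS = H(str | rew)
         = -sum_{s, r} P(s, r) * log2( P(s, r) / P(r) )

computed on a named choice dimension: the *stimulus* dimension compares the
chosen stimulus identity across consecutive trials, the *action* dimension
compares the chosen side.  ERDS is 0 for a deterministic feedback-driven
strategy (e.g. perfect win-stay/lose-switch) and 1 bit when staying is
independent of reward with P(stay) = 0.5; lower ERDS on a dimension means
more consistent reward-driven behavior on that dimension.  Probabilities
are empirical frequencies with the 0*log(0) = 0 convention (no smoothing).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .task import SessionData, TrialRecord

__all__ = [
    "StayRewardSeries",
    "stay_reward_series",
    "erds",
    "erds_from_counts",
    "erds_wsls_form",
    "stay_reward_counts",
    "sliding_dominance",
    "erds_matrix",
    "erds_by_block",
]


@dataclass
class StayRewardSeries:
    """Per-trial stay flags and previous-reward flags for one block.

    ``valid`` masks out the first trial (no previous trial to compare to);
    flags never compare across block boundaries."""

    dimension: str  # "stimulus" | "action"
    stay: np.ndarray  # 1 = repeated previous choice on this dimension
    prev_reward: np.ndarray  # reward on the previous trial
    valid: np.ndarray


def stay_reward_series(trials: list[TrialRecord], dimension: str) -> StayRewardSeries:
    """Build the stay/previous-reward series for one block of trials."""
    if len(trials) < 2:
        raise ValueError("need at least 2 trials")
    if dimension == "stimulus":
        choices = [t.choice_stim for t in trials]
    elif dimension == "action":
        choices = [t.choice_side for t in trials]
    else:
        raise ValueError(f"unknown dimension {dimension!r}")
    n = len(trials)
    stay = np.zeros(n, dtype=np.int64)
    prev_rew = np.zeros(n, dtype=np.int64)
    valid = np.zeros(n, dtype=bool)
    for i in range(1, n):
        stay[i] = int(choices[i] == choices[i - 1])
        prev_rew[i] = trials[i - 1].reward
        valid[i] = True
    return StayRewardSeries(dimension, stay, prev_rew, valid)


def stay_reward_counts(series: StayRewardSeries) -> np.ndarray:
    """2x2 joint counts, indexed ``counts[stay, prev_reward]``."""
    counts = np.zeros((2, 2), dtype=np.int64)
    for s, r in zip(series.stay[series.valid], series.prev_reward[series.valid]):
        counts[s, r] += 1
    return counts


def erds_from_counts(counts: np.ndarray) -> float:
    """Conditional entropy H(str|rew) in bits from a 2x2 count table."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("no valid trials")
    p_joint = counts / total
    p_rew = p_joint.sum(axis=0)  # P(rew)
    h = 0.0
    for s in (0, 1):
        for r in (0, 1):
            pj = p_joint[s, r]
            if pj > 0:
                h -= pj * np.log2(pj / p_rew[r])
    return float(h)


def erds_wsls_form(counts: np.ndarray) -> float:
    """ERDS via the win-stay / lose-switch decomposition.

    With WinStay = P(stay|win) and LoseSwitch = P(switch|lose):

        ERDS = -{ P(stay,win) log2(WinStay) + P(switch,win) log2(1-WinStay)
                + P(stay,lose) log2(1-LoseSwitch)
                + P(switch,lose) log2(LoseSwitch) }

    Algebraically identical to :func:`erds_from_counts`; kept as a second,
    independently coded route for verification.
    """
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("no valid trials")
    p = counts / total
    n_win = counts[:, 1].sum()
    n_lose = counts[:, 0].sum()
    win_stay = counts[1, 1] / n_win if n_win else 0.0
    lose_switch = counts[0, 0] / n_lose if n_lose else 0.0

    def term(prob, cond):
        return prob * np.log2(cond) if prob > 0 else 0.0

    h = -(
        term(p[1, 1], win_stay)
        + term(p[0, 1], 1.0 - win_stay)
        + term(p[1, 0], 1.0 - lose_switch)
        + term(p[0, 0], lose_switch)
    )
    return float(h)


def erds(series: StayRewardSeries) -> float:
    """ERDS in bits for one stay/reward series."""
    return erds_from_counts(stay_reward_counts(series))


def sliding_dominance(
    trials_by_block: list[list[TrialRecord]],
    window: int = 10,
) -> pd.DataFrame:
    """Trial-level strategy-dominance labels from a trailing window.

    For each trial whose trailing window of ``window`` stay/reward pairs
    lies entirely within the block, computes ERDS on both dimensions over
    that window and labels the trial ``stim_dominant`` (ERDS_stim <
    ERDS_action), ``action_dominant`` (the reverse), or ``tie`` (equal —
    flagged so downstream analyses can drop them).  Trials with an
    incomplete window are labeled ``unlabeled``.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    rows = []
    for b, trials in enumerate(trials_by_block):
        ser_s = stay_reward_series(trials, "stimulus")
        ser_a = stay_reward_series(trials, "action")
        for t in range(len(trials)):
            # trailing window covers stay flags of trials t-window+2 .. t+1
            # (1-based); complete iff the earliest flag is trial 2's
            lo = t - window + 1
            if lo < 1:
                rows.append((b, t + 1, np.nan, np.nan, "unlabeled"))
                continue
            sl = slice(lo, t + 1)
            e_s = erds_from_counts(_window_counts(ser_s, sl))
            e_a = erds_from_counts(_window_counts(ser_a, sl))
            if e_s < e_a:
                label = "stim_dominant"
            elif e_a < e_s:
                label = "action_dominant"
            else:
                label = "tie"
            rows.append((b, t + 1, e_s, e_a, label))
    return pd.DataFrame(
        rows, columns=["block", "trial", "erds_stim", "erds_action", "label"]
    )


def _window_counts(series: StayRewardSeries, sl: slice) -> np.ndarray:
    counts = np.zeros((2, 2), dtype=np.int64)
    for s, r in zip(series.stay[sl], series.prev_reward[sl]):
        counts[s, r] += 1
    return counts


def erds_matrix(choices: np.ndarray, rewards: np.ndarray) -> np.ndarray:
    """Vectorized per-block ERDS from ``(B, T)`` choice-code and reward
    arrays (used by the simulation experiments; one value per block)."""
    stay = (choices[:, 1:] == choices[:, :-1]).astype(np.int64)
    prev = rewards[:, :-1]
    n = stay.shape[1]
    c11 = ((stay == 1) & (prev == 1)).sum(axis=1)  # stay, win
    c01 = ((stay == 0) & (prev == 1)).sum(axis=1)  # switch, win
    c10 = ((stay == 1) & (prev == 0)).sum(axis=1)  # stay, lose
    c00 = ((stay == 0) & (prev == 0)).sum(axis=1)  # switch, lose
    out = np.zeros(choices.shape[0])
    p_win = (c11 + c01) / n
    p_lose = 1.0 - p_win
    for cj, pr in ((c11, p_win), (c01, p_win), (c10, p_lose), (c00, p_lose)):
        pj = cj / n
        with np.errstate(divide="ignore", invalid="ignore"):
            term = pj * np.log2(pj / pr)
        out -= np.where(pj > 0, term, 0.0)
    return out


def erds_by_block(cohort) -> pd.DataFrame:
    """Per-block ERDS table over a cohort.

    ``cohort`` is a mapping of subject id to a list of :class:`SessionData`
    (or a bare list of sessions).  One row per block with ERDS on both
    dimensions and their difference ``delta_erds = erds_stim - erds_action``
    (negative values indicate a more stimulus-driven block).
    """
    if isinstance(cohort, dict):
        items = [(subj, s) for subj, sessions in cohort.items() for s in sessions]
    else:
        items = [(s.subject_id, s) for s in cohort]
    rows = []
    for subj, sess in items:
        for b, (spec, trials) in enumerate(sess.blocks):
            e_s = erds(stay_reward_series(trials, "stimulus"))
            e_a = erds(stay_reward_series(trials, "action"))
            rows.append(
                {
                    "subject": subj,
                    "session": sess.session_id,
                    "block": b,
                    "block_type": spec.block_type,
                    "p_better": spec.p_better,
                    "erds_stim": e_s,
                    "erds_action": e_a,
                    "delta_erds": e_s - e_a,
                }
            )
    return pd.DataFrame(rows)
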