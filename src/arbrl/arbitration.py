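"""Downstream analysis of arbitration trajectories.

The effective arbitration weight Omega(t) summarizes the stimulus system's
net share of choice sensitivity.  Its per-trial changes define *effective
arbitration rates*, one per direction:

    psi_plus(t)  = [dOmega(t)]+ / (1 - Omega(t))   (toward the stimulus system)
    psi_minus(t) = [dOmega(t)]- / (0 - Omega(t))   (toward the action system)

where []+ / []- select positive / negative changes, so at most one rate is
nonzero on a trial and both lie in [0, 1] for trajectories generated by the
arbitration dynamics.  Delta-psi — the post-reversal difference of their
means — measures whether arbitration is biased toward the stimulus-based
(positive) or action-based (negative) system after the contingency reversal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .task import BlockSpec

__all__ = [
    "ArbitrationRates",
    "AlignedTrajectory",
    "effective_rates",
    "reconstruct_omega",
    "delta_psi_post_reversal",
    "align_and_smooth",
    "permutation_test_groups",
]


@dataclass
class ArbitrationRates:
    """Per-trial effective arbitration rates for one block.

    ``psi_plus[t]`` / ``psi_minus[t]`` describe the change from trial t+1 to
    trial t+2 (1-based), so the arrays have length ``len(omega) - 1``."""

    psi_plus: np.ndarray
    psi_minus: np.ndarray
    omega: np.ndarray  # the input trajectory, kept for reconstruction


def effective_rates(omega_eff: np.ndarray) -> ArbitrationRates:
    """Effective arbitration rates from a per-trial Omega trajectory.

    Guards at the corners: psi_plus is 0 where Omega(t) = 1 (no headroom —
    a positive change is impossible there) and psi_minus is 0 where
    Omega(t) = 0, symmetrically.
    """
    om = np.asarray(omega_eff, dtype=float)
    if om.ndim != 1 or om.size < 2:
        raise ValueError("need a 1-D trajectory of length >= 2")
    if np.any((om < 0) | (om > 1)):
        raise ValueError("Omega must lie in [0, 1]")
    d = np.diff(om)
    cur = om[:-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        psi_p = np.where((d > 0) & (cur < 1.0), d / (1.0 - cur), 0.0)
        psi_m = np.where((d < 0) & (cur > 0.0), d / (0.0 - cur), 0.0)
    return ArbitrationRates(psi_p, psi_m, om.copy())


def reconstruct_omega(omega0: float, psi_plus: np.ndarray, psi_minus: np.ndarray) -> np.ndarray:
    """Invert :func:`effective_rates`: rebuild the Omega trajectory from its
    starting value and the per-trial rates."""
    n = len(psi_plus)
    out = np.empty(n + 1)
    out[0] = omega0
    for t in range(n):
        if psi_plus[t] > 0:
            out[t + 1] = out[t] + psi_plus[t] * (1.0 - out[t])
        elif psi_minus[t] > 0:
            out[t + 1] = out[t] + psi_minus[t] * (0.0 - out[t])
        else:
            out[t + 1] = out[t]
    return out


def delta_psi_post_reversal(omega_eff: np.ndarray, spec: BlockSpec) -> float:
    """Delta-psi = mean(psi_plus) - mean(psi_minus) over post-reversal trials.

    Post-reversal means trials at or after the block's reversal trial; the
    pre-reversal portion is excluded to avoid confounds with the initial
    bias omega_0.
    """
    rates = effective_rates(omega_eff)
    if not 1 <= spec.reversal_trial <= len(rates.omega):
        raise ValueError("reversal trial outside the trajectory")
    # psi index t (0-based) describes the step out of trial t+1 (1-based)
    sel = slice(spec.reversal_trial - 1, None)
    return float(rates.psi_plus[sel].mean() - rates.psi_minus[sel].mean())


@dataclass
class AlignedTrajectory:
    """Across-block average of a per-trial quantity on the 3 x n_anchor grid
    (block start, reversal, block end), with a phase label per bin."""

    mean: np.ndarray
    sem: np.ndarray
    phase: np.ndarray  # "acquisition" for the start-anchored segment, else "reversal"
    per_block: np.ndarray  # (n_blocks, 3 * n_anchor), NaN where unavailable


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered NaN-aware moving average with shrinking edge windows."""
    n = len(x)
    out = np.full(n, np.nan)
    half = window // 2
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        seg = x[lo:hi]
        good = ~np.isnan(seg)
        if good.any():
            out[i] = seg[good].mean()
    return out


def align_and_smooth(
    series_by_block: list[np.ndarray],
    reversal_trials: list[int],
    n_anchor: int = 20,
    smooth_window: int = 5,
) -> AlignedTrajectory:
    """Align per-trial series across blocks with random reversal positions.

    Each block contributes three ``n_anchor``-trial segments: forward from
    the block start, forward from the reversal trial, and backward from the
    block end, concatenated in that order.  Segments are averaged across
    blocks (NaN where a block is too short) and smoothed with a moving
    average applied within each segment only, so no value leaks across the
    acquisition/reversal boundary.
    """
    blocks = []
    for series, rev in zip(series_by_block, reversal_trials):
        x = np.asarray(series, dtype=float)
        n = len(x)
        row = np.full(3 * n_anchor, np.nan)
        m = min(n_anchor, n)
        row[:m] = x[:m]
        post = x[rev - 1 :]
        m = min(n_anchor, len(post))
        row[n_anchor : n_anchor + m] = post[:m]
        m = min(n_anchor, n)
        row[3 * n_anchor - m :] = x[n - m :]
        blocks.append(row)
    per_block = np.vstack(blocks)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins stay NaN
        mean = np.nanmean(per_block, axis=0)
        counts = (~np.isnan(per_block)).sum(axis=0)
        sd = np.nanstd(per_block, axis=0, ddof=1)
        sem = np.where(counts > 1, sd / np.sqrt(np.maximum(counts, 1)), np.nan)
    if smooth_window and smooth_window > 1:
        for s in range(3):
            seg = slice(s * n_anchor, (s + 1) * n_anchor)
            mean[seg] = _moving_average(mean[seg], smooth_window)
            sem[seg] = _moving_average(sem[seg], smooth_window)
    phase = np.array(
        ["acquisition"] * n_anchor + ["reversal"] * (2 * n_anchor), dtype=object
    )
    return AlignedTrajectory(mean, sem, phase, per_block)


def permutation_test_groups(
    values,
    groups,
    n_perm: int = 10_000,
    rng: np.random.Generator | None = None,
) -> float:
    """Two-sided permutation test of a difference in group means.

    Shuffles the group assignment ``n_perm`` times; the p-value is the
    proportion of shuffles (the observed labeling included, so p is never
    0) whose absolute mean difference is at least the observed one.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    names = np.unique(groups)
    if len(names) != 2:
        raise ValueError("exactly two groups required")
    mask = groups == names[0]
    if mask.all() or not mask.any():
        raise ValueError("each group needs at least one value")

    n0 = int(mask.sum())
    n = len(values)
    obs = abs(values[mask].mean() - values[~mask].mean())
    # vectorized shuffles: first n0 of a random permutation form group 0
    pick = rng.random((n_perm, n)).argsort(axis=1)[:, :n0]
    sums = values[pick].sum(axis=1)
    total = values.sum()
    stats = sums / n0 - (total - sums) / (n - n0)
    count = 1 + int(np.sum(np.abs(stats) >= obs - 1e-12))  # identity included
    return count / (n_perm + 1)
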