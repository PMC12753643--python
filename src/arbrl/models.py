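"""Per-trial dynamics and likelihood of the dual-system model family.

Model family
------------
``stim_only`` / ``action_only``
    Single-system reinforcement learners over stimulus identities (A/B) or
    actions (left/right): chosen value moves toward the 0/1 reward with
    separate learning rates for rewarded (alpha_pos) and unrewarded
    (alpha_neg) trials, the unchosen value decays by (1 - zeta).
``static_omega``
    Both systems learn in parallel; choice uses the weighted overall values
    OV_i = omega * V_stim(i) + (1 - omega) * V_action(i) with a fixed weight.
``dynamic_omega_{vcho, absrpe, absdv, sumv}``
    The weight omega is updated each trial toward the system whose
    reliability signal is currently larger, with arbitration rate
    alpha_omega and passive decay zeta_omega back toward the initial weight
    omega0.  The four variants differ only in the reliability signal.
``dynamic_omega_rho``
    Adds a per-subject constant rho scaling the baseline strength of the
    stimulus system relative to the action system:
    OV_i = rho * omega * V_stim(i) + (1 - rho) * (1 - omega) * V_action(i).
    The effective weight Omega = rho*omega / (rho*omega + (1-rho)(1-omega))
    summarizes the net stimulus-system share of choice sensitivity.

Choice is a logistic function of the overall-value difference:
P(right) = 1 / (1 + exp(-(beta1 * (OV_right - OV_left) + beta0))).

Conventions (fixed; see docs/methods.md): values initialize at ``v_init``
(default 0.5) and the full state resets at each block start; reliability
signals and RPEs use the pre-update values of the current trial, which makes
the identity ``delta V_cho = RPE_action - RPE_stim`` exact on every trial;
likelihoods are natural-log with per-trial probabilities floored at 1e-10.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernel
from ._kernel import N_REC, run_blocks
from .params import DEFAULT_BOUNDS, ModelParams, model_codes
from .task import SessionData, session_arrays

__all__ = [
    "LatentState",
    "LatentTrajectory",
    "init_state",
    "overall_values",
    "choice_prob",
    "choice_logit_terms",
    "update_values",
    "relative_reliability",
    "update_omega",
    "effective_omega",
    "session_negloglik",
]


@dataclass
class LatentState:
    """Latent values of both systems plus the arbitration weight."""

    v_stimA: float
    v_stimB: float
    v_left: float
    v_right: float
    omega: float


@dataclass
class LatentTrajectory:
    """Per-trial model internals for one block."""

    ov_left: np.ndarray
    ov_right: np.ndarray
    p_right: np.ndarray
    drel: np.ndarray
    omega: np.ndarray
    omega_eff: np.ndarray
    rpe_stim: np.ndarray
    rpe_action: np.ndarray
    dv_cho: np.ndarray
    v_stimA: np.ndarray
    v_stimB: np.ndarray
    v_left: np.ndarray
    v_right: np.ndarray

    @classmethod
    def from_rec(cls, rec: np.ndarray, n: int) -> "LatentTrajectory":
        k = _kernel
        return cls(
            ov_left=rec[:n, k.R_OVL].copy(),
            ov_right=rec[:n, k.R_OVR].copy(),
            p_right=rec[:n, k.R_PRIGHT].copy(),
            drel=rec[:n, k.R_DREL].copy(),
            omega=rec[:n, k.R_OMEGA].copy(),
            omega_eff=rec[:n, k.R_OMEGA_EFF].copy(),
            rpe_stim=rec[:n, k.R_RPE_STIM].copy(),
            rpe_action=rec[:n, k.R_RPE_ACT].copy(),
            dv_cho=rec[:n, k.R_DVCHO].copy(),
            v_stimA=rec[:n, k.R_VA].copy(),
            v_stimB=rec[:n, k.R_VB].copy(),
            v_left=rec[:n, k.R_VL].copy(),
            v_right=rec[:n, k.R_VR].copy(),
        )

    def to_dict(self) -> dict:
        return {k: v.tolist() for k, v in self.__dict__.items()}


def init_state(model_id: str, params: ModelParams, v_init: float = 0.5) -> LatentState:
    """Block-onset state: all four values at ``v_init``; omega at the static
    weight (static model), omega0 (dynamic models), or the degenerate 1/0
    for the single-system models."""
    code, _ = model_codes(model_id)
    theta = params.to_theta(model_id)
    return LatentState(v_init, v_init, v_init, v_init, float(theta[5]))


def overall_values(
    state: LatentState, stimA_side: str, params: ModelParams, model_id: str
) -> tuple[float, float]:
    """Overall values (OV_left, OV_right) combining the two systems.

    The stimulus value contributing to a side follows where stimulus A is
    displayed on this trial.  Single-system models pass through the relevant
    system's values unchanged."""
    code, _ = model_codes(model_id)
    if stimA_side == "L":
        vs_l, vs_r = state.v_stimA, state.v_stimB
    else:
        vs_l, vs_r = state.v_stimB, state.v_stimA
    if code == 0:
        return vs_l, vs_r
    if code == 1:
        return state.v_left, state.v_right
    w = state.omega
    if code == 4:
        rho = params.rho if params.rho is not None else 0.5
        ws, wa = rho * w, (1.0 - rho) * (1.0 - w)
    else:
        ws, wa = w, 1.0 - w
    return ws * vs_l + wa * state.v_left, ws * vs_r + wa * state.v_right


def choice_prob(ov_left, ov_right, beta1: float, beta0: float):
    """P(choose right): logistic of beta1*(OV_right - OV_left) + beta0."""
    z = beta1 * (np.asarray(ov_right) - np.asarray(ov_left)) + beta0
    return 1.0 / (1.0 + np.exp(-z))


def choice_logit_terms(
    state: LatentState, stimA_side: str, params: ModelParams, model_id: str
) -> dict:
    """Decompose the choice logit into per-system sensitivity terms.

    Returns the stimulus-system term beta1*ws*dV_stim, the action-system term
    beta1*wa*dV_action, the bias beta0, and their sum ``logit`` — which
    equals the direct softmax logit on the same state exactly.
    """
    code, _ = model_codes(model_id)
    if stimA_side == "L":
        dv_stim = state.v_stimB - state.v_stimA  # right minus left
    else:
        dv_stim = state.v_stimA - state.v_stimB
    dv_action = state.v_right - state.v_left
    w = state.omega
    if code == 0:
        ws, wa = 1.0, 0.0
    elif code == 1:
        ws, wa = 0.0, 1.0
    elif code == 4:
        rho = params.rho if params.rho is not None else 0.5
        ws, wa = rho * w, (1.0 - rho) * (1.0 - w)
    else:
        ws, wa = w, 1.0 - w
    stim_term = params.beta1 * ws * dv_stim
    action_term = params.beta1 * wa * dv_action
    return {
        "stim_term": stim_term,
        "action_term": action_term,
        "beta0": params.beta0,
        "logit": stim_term + action_term + params.beta0,
    }


def update_values(
    state: LatentState,
    choice_side: str,
    choice_stim: str,
    stimA_side: str,
    reward: int,
    params: ModelParams,
) -> LatentState:
    """Rescorla-Wagner update of both systems in parallel.

    The chosen value moves toward the reward by alpha_pos (rewarded) or
    alpha_neg (unrewarded); the unchosen value decays by (1 - zeta)."""
    if reward not in (0, 1):
        raise ValueError("reward must be 0 or 1")
    lr = params.alpha_pos if reward == 1 else params.alpha_neg
    vA, vB = state.v_stimA, state.v_stimB
    vL, vR = state.v_left, state.v_right
    if choice_stim == "A":
        vA, vB = vA + lr * (reward - vA), (1.0 - params.zeta) * vB
    else:
        vB, vA = vB + lr * (reward - vB), (1.0 - params.zeta) * vA
    if choice_side == "L":
        vL, vR = vL + lr * (reward - vL), (1.0 - params.zeta) * vR
    else:
        vR, vL = vR + lr * (reward - vR), (1.0 - params.zeta) * vL
    return LatentState(vA, vB, vL, vR, state.omega)


def relative_reliability(
    state: LatentState,
    choice_side: str,
    choice_stim: str,
    reward: int,
    reliability_kind: str = "v_cho",
) -> float:
    """Relative reliability of the stimulus over the action system.

    Evaluated on the values held during the trial (pre-update), positive
    when the stimulus-based system is the more reliable one:

    - ``v_cho``:   V_cho,stim - V_cho,action  (equals RPE_action - RPE_stim)
    - ``abs_rpe``: |RPE_action| - |RPE_stim|
    - ``abs_dv``:  |V_stimA - V_stimB| - |V_left - V_right|
    - ``sum_v``:   (V_stimA + V_stimB) - (V_left + V_right)
    """
    vc_stim = state.v_stimA if choice_stim == "A" else state.v_stimB
    vc_act = state.v_left if choice_side == "L" else state.v_right
    if reliability_kind == "v_cho":
        return vc_stim - vc_act
    if reliability_kind == "abs_rpe":
        return abs(reward - vc_act) - abs(reward - vc_stim)
    if reliability_kind == "abs_dv":
        return abs(state.v_stimA - state.v_stimB) - abs(state.v_left - state.v_right)
    if reliability_kind == "sum_v":
        return (state.v_stimA + state.v_stimB) - (state.v_left + state.v_right)
    raise ValueError(f"unknown reliability_kind {reliability_kind!r}")


def update_omega(omega: float, delta_rel: float, params: ModelParams) -> float:
    """One arbitration step: positive reliability difference moves omega
    toward 1 at rate alpha_omega * delta_rel, negative toward 0, and the
    passive decay zeta_omega * (omega0 - omega) always applies.  The result
    is clipped to [0, 1] (the printed update can overshoot marginally at
    extreme parameter corners)."""
    a_w = params.alpha_omega
    z_w = params.zeta_omega
    w0 = params.omega0
    if delta_rel > 0:
        out = omega + a_w * delta_rel * (1.0 - omega) + z_w * (w0 - omega)
    elif delta_rel < 0:
        out = omega + a_w * abs(delta_rel) * (0.0 - omega) + z_w * (w0 - omega)
    else:
        out = omega + z_w * (w0 - omega)
    return min(1.0, max(0.0, out))


def effective_omega(omega, rho):
    """Effective arbitration weight Omega = rho*w / (rho*w + (1-rho)(1-w)).

    Reduces to omega at rho = 0.5 and to rho at omega = 0.5; at the
    degenerate corner (denominator 0) it returns omega's corner value, the
    continuous extension along rho = 0.5."""
    omega = np.asarray(omega, dtype=float)
    rho = np.asarray(rho, dtype=float)
    num = rho * omega
    den = num + (1.0 - rho) * (1.0 - omega)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, num / np.where(den > 0, den, 1.0), omega)
    return out if out.ndim else float(out)


def session_negloglik(
    model_id: str,
    params: ModelParams,
    session: SessionData,
    v_init: float = 0.5,
    return_trajectories: bool = True,
):
    """Negative log-likelihood (natural log) of the observed choices.

    State resets at every block start.  Returns ``(nll, trajectories)`` with
    one :class:`LatentTrajectory` per block, or ``(nll, None)`` when
    trajectories are not requested (fast path used by the optimizer).
    """
    params.validate(model_id, DEFAULT_BOUNDS)
    code, rel = model_codes(model_id)
    theta = params.to_theta(model_id)
    arrays = session_arrays(session)
    block_dim, better, p_b, rev, n_trials, stimA, cside, cstim, rew = arrays
    B = len(n_trials)
    T = int(n_trials.max()) if B else 0
    u = np.zeros((B, T, 2))
    rec = np.zeros((B, T, N_REC) if return_trajectories else (1, 1, N_REC))
    nll_out = np.zeros(B)
    total = run_blocks(
        False, code, rel, theta, v_init,
        block_dim, better, p_b, rev, n_trials,
        stimA, cside, cstim, rew, u, return_trajectories, rec, nll_out,
    )
    trajs = None
    if return_trajectories:
        trajs = [
            LatentTrajectory.from_rec(rec[b], int(n_trials[b])) for b in range(B)
        ]
    return float(total), trajs


def negloglik_arrays(model_code, rel_code, theta, arrays, v_init=0.5, nll_out=None):
    """Fast path on pre-unpacked :func:`arbrl.task.session_arrays` output.

    Used by the optimizer so the per-evaluation cost is one kernel call.
    Returns ``(total_nll, per_block_nll)``.
    """
    block_dim, better, p_b, rev, n_trials, stimA, cside, cstim, rew = arrays
    B = len(n_trials)
    T = int(n_trials.max()) if B else 0
    if nll_out is None:
        nll_out = np.zeros(B)
    total = run_blocks(
        False, model_code, rel_code, theta, v_init,
        block_dim, better, p_b, rev, n_trials,
        stimA, cside, cstim, rew, _EMPTY_U, False, _EMPTY_REC, nll_out,
    )
    return float(total), nll_out


_EMPTY_U = np.zeros((1, 1, 2))
_EMPTY_REC = np.zeros((1, 1, N_REC))
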