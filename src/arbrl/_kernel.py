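"""Numba-compiled inner loops shared by likelihood evaluation and simulation.

One kernel runs a batch of blocks either in *evaluation* mode (observed
choices and rewards are read, per-trial choice log-likelihoods accumulated)
or in *simulation* mode (choices and rewards are drawn from pre-supplied
uniform variates and written back).  Keeping a single code path guarantees
the generative model and the likelihood are the same model.

Per-trial order of operations (fixed convention, see docs/methods.md):

1. overall values from the current state and today's stimulus-side layout
2. softmax probability of choosing right
3. choice and reward (read or drawn)
4. reliability difference and the two RPEs from the *pre-update* values
5. value update (separate gain/loss learning rates; unchosen value decays)
6. arbitration-weight update (dynamic models only)

Sides are coded L=0 / R=1 and stimuli A=0 / B=1 everywhere in this module;
``choice_stim = choice_side XOR stimA_side``.
"""

import numpy as np
from numba import njit

# record-array channel indices (axis 2 of ``rec``)
R_OVL, R_OVR, R_PRIGHT, R_DREL, R_OMEGA, R_OMEGA_EFF = 0, 1, 2, 3, 4, 5
R_RPE_STIM, R_RPE_ACT, R_DVCHO = 6, 7, 8
R_VA, R_VB, R_VL, R_VR = 9, 10, 11, 12
N_REC = 13

P_FLOOR = 1e-10  # per-trial likelihood floor keeping -LL finite


@njit(cache=True)
def _omega_eff(omega, rho):
    num = rho * omega
    den = num + (1.0 - rho) * (1.0 - omega)
    if den <= 0.0:
        # degenerate corner; continuous along rho = 0.5
        return omega
    return num / den


@njit(cache=True)
def run_blocks(
    sim,          # bool: simulate (write choices) vs evaluate (read them)
    model_code,   # 0 stim, 1 action, 2 static, 3 dynamic, 4 dynamic-rho
    rel_code,     # 0 v_cho, 1 abs_rpe, 2 abs_dv, 3 sum_v
    theta,        # (9,) packed parameters, see params.py
    v_init,       # initial value of all four value estimates
    block_dim,    # (B,) 0 = what (stimulus dimension), 1 = where (action)
    better_id,    # (B,) initially better stimulus/side, 0/1
    p_better,     # (B,) reward probability of the better option
    rev_trial,    # (B,) 1-based reversal trial
    n_trials,     # (B,) trials per block
    stimA_side,   # (B,T) side of stimulus A per trial (always an input)
    choice_side,  # (B,T) in/out
    choice_stim,  # (B,T) in/out
    reward,       # (B,T) in/out
    u,            # (B,T,2) uniforms for choice and reward draws (sim mode)
    record,       # bool: fill ``rec``
    rec,          # (B,T,N_REC) latent-trajectory records
    nll_out,      # (B,) per-block negative log-likelihood
):
    a_pos, a_neg, zeta = theta[0], theta[1], theta[2]
    beta1, beta0 = theta[3], theta[4]
    w_init, a_w, z_w, rho = theta[5], theta[6], theta[7], theta[8]
    B = n_trials.shape[0]
    total = 0.0
    for b in range(B):
        vA = v_init
        vB = v_init
        vL = v_init
        vR = v_init
        omega = w_init
        nll = 0.0
        for t in range(n_trials[b]):
            sA = stimA_side[b, t]
            vs_left = vA if sA == 0 else vB
            vs_right = vB if sA == 0 else vA
            # system weights in the overall-value combination
            if model_code == 0:
                ws, wa = 1.0, 0.0
            elif model_code == 1:
                ws, wa = 0.0, 1.0
            elif model_code == 4:
                ws = rho * omega
                wa = (1.0 - rho) * (1.0 - omega)
            else:
                ws = omega
                wa = 1.0 - omega
            ovl = ws * vs_left + wa * vL
            ovr = ws * vs_right + wa * vR
            p_right = 1.0 / (1.0 + np.exp(-(beta1 * (ovr - ovl) + beta0)))

            if sim:
                cs = 1 if u[b, t, 0] < p_right else 0
                cstim = cs ^ sA
                choice_side[b, t] = cs
                choice_stim[b, t] = cstim
                # reward from the block's schedule on its relevant dimension
                cur_better = better_id[b]
                if t + 1 >= rev_trial[b]:
                    cur_better = 1 - cur_better
                rel_choice = cstim if block_dim[b] == 0 else cs
                p_rew = p_better[b] if rel_choice == cur_better else 1.0 - p_better[b]
                r = 1 if u[b, t, 1] < p_rew else 0
                reward[b, t] = r
            else:
                cs = choice_side[b, t]
                cstim = choice_stim[b, t]
                r = reward[b, t]
                p_obs = p_right if cs == 1 else 1.0 - p_right
                if p_obs < P_FLOOR:
                    p_obs = P_FLOOR
                elif p_obs > 1.0 - P_FLOOR:
                    p_obs = 1.0 - P_FLOOR
                nll -= np.log(p_obs)

            # reliability signals from pre-update values
            vc_stim = vA if cstim == 0 else vB
            vc_act = vL if cs == 0 else vR
            rpe_stim = r - vc_stim
            rpe_act = r - vc_act
            dv_cho = vc_stim - vc_act
            if rel_code == 0:
                drel = dv_cho
            elif rel_code == 1:
                drel = abs(rpe_act) - abs(rpe_stim)
            elif rel_code == 2:
                drel = abs(vA - vB) - abs(vL - vR)
            else:
                drel = (vA + vB) - (vL + vR)

            if record:
                rec[b, t, R_OVL] = ovl
                rec[b, t, R_OVR] = ovr
                rec[b, t, R_PRIGHT] = p_right
                rec[b, t, R_DREL] = drel
                rec[b, t, R_OMEGA] = omega
                rec[b, t, R_OMEGA_EFF] = (
                    _omega_eff(omega, rho) if model_code == 4 else omega
                )
                rec[b, t, R_RPE_STIM] = rpe_stim
                rec[b, t, R_RPE_ACT] = rpe_act
                rec[b, t, R_DVCHO] = dv_cho
                rec[b, t, R_VA] = vA
                rec[b, t, R_VB] = vB
                rec[b, t, R_VL] = vL
                rec[b, t, R_VR] = vR

            # value update: chosen moves toward reward, unchosen decays
            lr = a_pos if r == 1 else a_neg
            if cstim == 0:
                vA = vA + lr * (r - vA)
                vB = (1.0 - zeta) * vB
            else:
                vB = vB + lr * (r - vB)
                vA = (1.0 - zeta) * vA
            if cs == 0:
                vL = vL + lr * (r - vL)
                vR = (1.0 - zeta) * vR
            else:
                vR = vR + lr * (r - vR)
                vL = (1.0 - zeta) * vL

            # arbitration-weight update (dynamic models)
            if model_code >= 3:
                if drel > 0.0:
                    omega = omega + a_w * drel * (1.0 - omega) + z_w * (w_init - omega)
                elif drel < 0.0:
                    omega = omega + a_w * abs(drel) * (0.0 - omega) + z_w * (w_init - omega)
                else:
                    omega = omega + z_w * (w_init - omega)
                if omega < 0.0:
                    omega = 0.0
                elif omega > 1.0:
                    omega = 1.0
        nll_out[b] = nll
        total += nll
    return total
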