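"""Maximum-likelihood fitting, model comparison, and cross-validation.

One parameter set is fitted per session by bounded local optimization
(L-BFGS-B) from many uniform-random starting points; the subject-level
baseline ratio rho uses the two-stage procedure: fit the whole subject's
data jointly, keep only rho, then refit each session with rho pinned.
Goodness of fit is summarized by AIC and McFadden's pseudo-R^2 against the
chance model (-LL of 80 * ln 2 per 80-trial block), and out-of-sample
performance by repeated k-fold cross-validation over blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .models import negloglik_arrays
from .params import (
    DEFAULT_BOUNDS,
    FREE_PARAMS,
    START_RANGES,
    ModelParams,
    model_codes,
    n_free_params,
)
from .task import SessionData, session_arrays

__all__ = [
    "FitResult",
    "CrossvalResult",
    "fit_session",
    "fit_blocks",
    "fit_rho_subject",
    "crossval",
    "mcfadden_r2",
    "aic",
    "model_selection_table",
]

_THETA_INDEX = {
    "alpha_pos": 0,
    "alpha_neg": 1,
    "zeta": 2,
    "beta1": 3,
    "beta0": 4,
    "omega": 5,
    "omega0": 5,
    "alpha_omega": 6,
    "zeta_omega": 7,
    "rho": 8,
}

FTOL = 1e-9


@dataclass
class FitResult:
    """Per-session maximum-likelihood estimate."""

    model_id: str
    params: ModelParams
    neg_loglik: float
    aic: float
    mcfadden_r2: float
    n_trials: int
    n_blocks: int
    n_starts: int
    converged: bool
    best_start: int
    fixed: dict = field(default_factory=dict)


@dataclass
class CrossvalResult:
    """Repeated k-fold cross-validation over a subject's blocks."""

    model_id: str
    table: pd.DataFrame  # columns: repeat, fold, block, neg_loglik, n_trials
    mean_block_negloglik: float
    mean_mcfadden_r2: float
    k: int
    repeats: int


def _theta_template(model_id: str) -> np.ndarray:
    code, _ = model_codes(model_id)
    theta = np.zeros(9)
    theta[8] = 0.5  # rho neutral unless free/fixed
    if code == 0:
        theta[5] = 1.0
    elif code == 1:
        theta[5] = 0.0
    return theta


def _merge_arrays(sessions: list[SessionData]):
    """Concatenate all blocks of several sessions into one block batch.

    Valid because the latent state resets at every block boundary, so the
    joint likelihood factorizes over blocks."""
    parts = [session_arrays(s) for s in sessions if s.n_blocks]
    if not parts:
        raise ValueError("no blocks to fit")
    T = max(a[4].max() for a in parts)

    def pad(x):
        if x.ndim == 1:
            return x
        out = np.zeros((x.shape[0], T), dtype=x.dtype)
        out[:, : x.shape[1]] = x
        return out

    return tuple(
        np.concatenate([pad(p[i]) for p in parts], axis=0) for i in range(9)
    )


def _subset_arrays(arrays, idx):
    idx = np.asarray(idx)
    return tuple(a[idx] for a in arrays)


def fit_blocks(
    arrays,
    model_id: str,
    bounds: dict | None = None,
    n_starts: int = 100,
    rng: np.random.Generator | None = None,
    fixed: dict | None = None,
    v_init: float = 0.5,
):
    """Fit one parameter set to a batch of blocks (kernel-array form).

    Returns ``(params, nll, converged, best_start)``.  ``fixed`` pins named
    parameters at given values (they are then not free and not counted by
    the AIC penalty applied in :func:`fit_session`).
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    bounds = bounds or DEFAULT_BOUNDS
    fixed = fixed or {}
    code, rel = model_codes(model_id)
    free = [p for p in FREE_PARAMS[model_id] if p not in fixed]
    template = _theta_template(model_id)
    for name, val in fixed.items():
        template[_THETA_INDEX[name]] = val
    idx = np.array([_THETA_INDEX[p] for p in free])
    box = [bounds[p] for p in free]
    n_blocks = len(arrays[4])
    nll_buf = np.zeros(n_blocks)
    theta = template.copy()

    def objective(x):
        theta[idx] = x
        total, _ = negloglik_arrays(code, rel, theta, arrays, v_init, nll_buf)
        return total

    if not free:  # fully pinned model: nothing to optimize
        total, _ = negloglik_arrays(code, rel, template, arrays, v_init, nll_buf)
        params = ModelParams.from_free_values(
            model_id, [fixed[p] for p in FREE_PARAMS[model_id]]
        )
        return params, float(total), True, 0

    best = None
    best_start = -1
    any_converged = False
    for start in range(n_starts):
        x0 = np.array([rng.uniform(*START_RANGES[p]) for p in free])
        res = minimize(
            objective, x0, method="L-BFGS-B", bounds=box,
            options={"ftol": FTOL, "maxiter": 500},
        )
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best, best_start = res, start
    values = dict(zip(free, best.x))
    values.update(fixed)
    params = ModelParams.from_free_values(
        model_id, [values[p] for p in FREE_PARAMS[model_id]]
    )
    return params, float(best.fun), any_converged, best_start


def fit_session(
    session: SessionData,
    model_id: str,
    bounds: dict | None = None,
    n_starts: int = 100,
    rng: np.random.Generator | None = None,
    fixed: dict | None = None,
    v_init: float = 0.5,
) -> FitResult:
    """Maximum-likelihood fit of one model to one session.

    Runs ``n_starts`` bounded local searches from uniform-random initial
    points and keeps the lowest negative log-likelihood.  ``fixed`` pins
    parameters (used by the stage-2 rho refits); pinned parameters do not
    count toward the AIC penalty.
    """
    if session.n_blocks == 0:
        raise ValueError("empty session")
    arrays = session_arrays(session)
    params, nll, converged, best_start = fit_blocks(
        arrays, model_id, bounds, n_starts, rng, fixed, v_init
    )
    k = n_free_params(model_id) - len(fixed or {})
    n_blocks = session.n_blocks
    _, per_block = negloglik_arrays(
        *model_codes(model_id), params.to_theta(model_id), arrays, v_init
    )
    return FitResult(
        model_id=model_id,
        params=params,
        neg_loglik=nll,
        aic=2 * k + 2 * nll,
        mcfadden_r2=mcfadden_r2(per_block),
        n_trials=session.n_trials,
        n_blocks=n_blocks,
        n_starts=n_starts,
        converged=converged,
        best_start=best_start,
        fixed=dict(fixed or {}),
    )


def fit_rho_subject(
    sessions: list[SessionData],
    rng: np.random.Generator | None = None,
    n_starts: int = 100,
    bounds: dict | None = None,
    v_init: float = 0.5,
):
    """Two-stage subject-level fit of the dynamic omega-rho model.

    Stage 1 fits one parameter set to all of the subject's sessions jointly
    and keeps only rho (a per-animal baseline assumed constant across
    sessions).  Stage 2 refits each session separately with rho pinned to
    the stage-1 value.  Returns ``(rho, [FitResult per session])``.
    """
    if not sessions:
        raise ValueError("need at least one session")
    rng = rng if rng is not None else np.random.default_rng(0)
    arrays = _merge_arrays(sessions)
    joint_params, _, _, _ = fit_blocks(
        arrays, "dynamic_omega_rho", bounds, n_starts, rng, None, v_init
    )
    rho = float(joint_params.rho)
    fits = [
        fit_session(
            s, "dynamic_omega_rho", bounds, n_starts, rng,
            fixed={"rho": rho}, v_init=v_init,
        )
        for s in sessions
    ]
    return rho, fits


def crossval(
    sessions: list[SessionData] | SessionData,
    model_id: str,
    k: int = 5,
    repeats: int = 50,
    n_starts: int = 20,
    rng: np.random.Generator | None = None,
    bounds: dict | None = None,
    fixed: dict | None = None,
    v_init: float = 0.5,
) -> CrossvalResult:
    """Repeated k-fold cross-validation over a subject's blocks.

    Per repeat, blocks are randomly partitioned into k near-equal folds;
    one parameter set is fitted to the k-1 training folds and scored on
    each held-out block.  The headline number is the mean held-out negative
    log-likelihood per block across all tested blocks and repeats.
    """
    if isinstance(sessions, SessionData):
        sessions = [sessions]
    rng = rng if rng is not None else np.random.default_rng(0)
    arrays = _merge_arrays(sessions)
    n_blocks = len(arrays[4])
    if n_blocks < k:
        raise ValueError(f"{n_blocks} blocks < {k} folds")
    code, rel = model_codes(model_id)
    rows = []
    for rep in range(repeats):
        perm = rng.permutation(n_blocks)
        folds = np.array_split(perm, k)
        for f, test_idx in enumerate(folds):
            train_idx = np.setdiff1d(perm, test_idx)
            params, _, _, _ = fit_blocks(
                _subset_arrays(arrays, train_idx), model_id,
                bounds, n_starts, rng, fixed, v_init,
            )
            theta = params.to_theta(model_id)
            _, per_block = negloglik_arrays(
                code, rel, theta, _subset_arrays(arrays, test_idx), v_init
            )
            for b, nll_b in zip(test_idx, per_block):
                rows.append(
                    (rep, f, int(b), float(nll_b), int(arrays[4][b]))
                )
    table = pd.DataFrame(
        rows, columns=["repeat", "fold", "block", "neg_loglik", "n_trials"]
    )
    mean_nll = float(table["neg_loglik"].mean())
    r2 = mcfadden_r2(table["neg_loglik"].to_numpy())
    return CrossvalResult(model_id, table, mean_nll, r2, k, repeats)


def mcfadden_r2(block_negloglik, n_trials_per_block: int = 80) -> float:
    """McFadden pseudo-R^2 against the chance model.

    ``1 - sum(LL_model) / (n_blocks * n_trials_per_block * ln 0.5)``; the
    log base cancels in the ratio.  0 for a chance-level model, 1 for
    perfect prediction.
    """
    nll = np.asarray(block_negloglik, dtype=float)
    denom = nll.size * n_trials_per_block * np.log(2.0)
    return float(1.0 - nll.sum() / denom)


def aic(fit: FitResult) -> float:
    """AIC = 2k + 2 * (-LL) with k the number of free parameters."""
    return fit.aic


def model_selection_table(fits_per_session: dict[str, list[FitResult]]) -> pd.DataFrame:
    """Best model per session by AIC (ties go to fewer free parameters).

    ``fits_per_session`` maps a session key to that session's fits under
    the candidate models.
    """
    rows = []
    for key, fits in fits_per_session.items():
        ranked = sorted(
            fits, key=lambda f: (f.aic, n_free_params(f.model_id) - len(f.fixed))
        )
        best = ranked[0]
        row = {"session": key, "best_model": best.model_id, "aic": best.aic}
        row.update({f"aic_{f.model_id}": f.aic for f in fits})
        rows.append(row)
    return pd.DataFrame(rows)
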