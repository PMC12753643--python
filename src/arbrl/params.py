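"""Model registry, parameter container, bounds, and theta-vector packing.

The model family shares a single flat parameter vector (``theta``) layout so
that the numba kernels can stay monomorphic::

    theta = [alpha_pos, alpha_neg, zeta, beta1, beta0,
             omega_init, alpha_omega, zeta_omega, rho]

``omega_init`` holds the static weight (Static-omega model) or the initial
weight omega_0 (dynamic models); it is forced to 1 / 0 for the two
single-system models.  ``rho`` is 0.5 for every model except Dynamic
omega-rho.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
import json

__all__ = [
    "ModelParams",
    "MODEL_IDS",
    "FREE_PARAMS",
    "DEFAULT_BOUNDS",
    "START_RANGES",
    "n_free_params",
    "model_codes",
    "RELIABILITY_KINDS",
]

MODEL_IDS = (
    "stim_only",
    "action_only",
    "static_omega",
    "dynamic_omega_vcho",
    "dynamic_omega_absrpe",
    "dynamic_omega_absdv",
    "dynamic_omega_sumv",
    "dynamic_omega_rho",
)

RELIABILITY_KINDS = ("v_cho", "abs_rpe", "abs_dv", "sum_v")

_BASE = ("alpha_pos", "alpha_neg", "zeta", "beta1", "beta0")
_DYN = _BASE + ("omega0", "alpha_omega", "zeta_omega")

#: free parameters per model, in theta order
FREE_PARAMS: dict[str, tuple[str, ...]] = {
    "stim_only": _BASE,
    "action_only": _BASE,
    "static_omega": _BASE + ("omega",),
    "dynamic_omega_vcho": _DYN,
    "dynamic_omega_absrpe": _DYN,
    "dynamic_omega_absdv": _DYN,
    "dynamic_omega_sumv": _DYN,
    "dynamic_omega_rho": _DYN + ("rho",),
}

#: repo-default box constraints, overridable per fit
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "alpha_pos": (0.0, 1.0),
    "alpha_neg": (0.0, 1.0),
    "zeta": (0.0, 1.0),
    "beta1": (0.0, 100.0),
    "beta0": (-5.0, 5.0),
    "omega": (0.0, 1.0),
    "omega0": (0.0, 1.0),
    "alpha_omega": (0.0, 1.0),
    "zeta_omega": (0.0, 1.0),
    "rho": (0.0, 1.0),
}

#: ranges that random optimizer starts are drawn from.  Identical to the
#: bounds except beta1: uniform starts over [0, 100] put almost all mass in
#: the saturated-softmax plateau, so starts are drawn from [0, 20] while the
#: bound itself stays [0, 100].
START_RANGES: dict[str, tuple[float, float]] = dict(
    DEFAULT_BOUNDS, beta1=(0.0, 20.0)
)

# kernel codes
_MODEL_CODE = {
    "stim_only": 0,
    "action_only": 1,
    "static_omega": 2,
    "dynamic_omega_vcho": 3,
    "dynamic_omega_absrpe": 3,
    "dynamic_omega_absdv": 3,
    "dynamic_omega_sumv": 3,
    "dynamic_omega_rho": 4,
}
_REL_CODE = {"v_cho": 0, "abs_rpe": 1, "abs_dv": 2, "sum_v": 3}
_MODEL_REL = {
    "dynamic_omega_vcho": "v_cho",
    "dynamic_omega_absrpe": "abs_rpe",
    "dynamic_omega_absdv": "abs_dv",
    "dynamic_omega_sumv": "sum_v",
    "dynamic_omega_rho": "v_cho",
}


def model_codes(model_id: str) -> tuple[int, int]:
    """Return ``(model_code, reliability_code)`` for the numba kernels."""
    if model_id not in MODEL_IDS:
        raise ValueError(f"unknown model_id {model_id!r}")
    rel = _MODEL_REL.get(model_id, "v_cho")
    return _MODEL_CODE[model_id], _REL_CODE[rel]


def n_free_params(model_id: str) -> int:
    """Number of free parameters k used in the AIC penalty."""
    return len(FREE_PARAMS[model_id])


@dataclass
class ModelParams:
    """All parameters of the model family; unused fields stay ``None``.

    alpha_pos / alpha_neg : learning rates on rewarded / unrewarded trials
    zeta                  : decay (forgetting) rate of the unchosen value
    beta1                 : inverse temperature (choice sensitivity)
    beta0                 : side bias, positive toward the right option
    omega                 : static stimulus-system weight (Static-omega only)
    omega0                : initial arbitration weight (dynamic models)
    alpha_omega           : arbitration rate
    zeta_omega            : passive decay of omega back toward omega0
    rho                   : per-subject baseline stimulus:action signal ratio
    """

    alpha_pos: float = 0.5
    alpha_neg: float = 0.5
    zeta: float = 0.0
    beta1: float = 5.0
    beta0: float = 0.0
    omega: float | None = None
    omega0: float | None = None
    alpha_omega: float | None = None
    zeta_omega: float | None = None
    rho: float | None = None
    reliability_kind: str = "v_cho"

    def validate(self, model_id: str, bounds: dict | None = None) -> None:
        bounds = bounds or DEFAULT_BOUNDS
        for name in FREE_PARAMS[model_id]:
            val = getattr(self, name)
            if val is None:
                raise ValueError(f"{model_id} requires parameter {name}")
            lo, hi = bounds[name]
            if not (lo <= val <= hi):
                raise ValueError(f"{name}={val} outside bounds [{lo}, {hi}]")

    def to_theta(self, model_id: str) -> "np.ndarray":
        """Pack into the 9-element kernel vector (see module docstring)."""
        import numpy as np

        code, _ = model_codes(model_id)
        if code == 0:
            w_init = 1.0
        elif code == 1:
            w_init = 0.0
        elif code == 2:
            w_init = float(self.omega)
        else:
            w_init = float(self.omega0)
        rho = 0.5 if (code != 4 or self.rho is None) else float(self.rho)
        a_w = float(self.alpha_omega) if code >= 3 else 0.0
        z_w = float(self.zeta_omega) if code >= 3 else 0.0
        return np.array(
            [
                self.alpha_pos,
                self.alpha_neg,
                self.zeta,
                self.beta1,
                self.beta0,
                w_init,
                a_w,
                z_w,
                rho,
            ],
            dtype=np.float64,
        )

    @classmethod
    def from_free_values(cls, model_id: str, values) -> "ModelParams":
        """Build from a vector ordered like ``FREE_PARAMS[model_id]``."""
        kw = dict(zip(FREE_PARAMS[model_id], (float(v) for v in values)))
        p = cls(**kw)
        p.reliability_kind = _MODEL_REL.get(model_id, "v_cho")
        return p

    def free_values(self, model_id: str) -> list[float]:
        return [float(getattr(self, name)) for name in FREE_PARAMS[model_id]]

    def to_json(self) -> str:
        d = {k: v for k, v in asdict(self).items() if v is not None}
        return json.dumps(d)

    @classmethod
    def from_json(cls, s: str) -> "ModelParams":
        return cls(**json.loads(s))
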