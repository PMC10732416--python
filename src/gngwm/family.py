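"""The eight nested model variants and condition-dependent parameter lookup.

The baseline model has six free parameters: learning rate eps, reward and
punishment sensitivities rho_rew / rho_pun, go bias b, Pavlovian bias pi,
and irreducible noise xi.  The seven nested extensions give one or more of
{pi, eps, xi} a free-standing second copy (the *_wm* variant) that governs
behavior only in the working-memory load condition; rho and b are always
shared across conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

from .task import GNG, TASKS, WMGNG

BASE_PARAMS = ("eps", "rho_rew", "rho_pun", "b", "pi", "xi")

# model_id -> (split_pi, split_eps, split_xi)
_SPLITS = {
    1: (False, False, False),
    2: (True, False, False),
    3: (False, True, False),
    4: (False, False, True),
    5: (True, True, False),
    6: (True, False, True),
    7: (False, True, True),
    8: (True, True, True),
}


@dataclass(frozen=True)
class ModelSpec:
    """Which of pi, eps, xi get a separate WM-load copy."""

    model_id: int
    split_pi: bool
    split_eps: bool
    split_xi: bool

    @property
    def n_params(self) -> int:
        return 6 + self.split_pi + self.split_eps + self.split_xi

    @property
    def split_names(self) -> tuple[str, ...]:
        names = []
        if self.split_pi:
            names.append("pi")
        if self.split_eps:
            names.append("eps")
        if self.split_xi:
            names.append("xi")
        return tuple(names)


def build_model_spec(model_id: int) -> ModelSpec:
    """Model spec for ids 1-8 (1 = baseline, 8 = full model)."""
    if model_id not in _SPLITS:
        raise ValueError(f"model_id must be in 1..8, got {model_id!r}")
    return ModelSpec(model_id, *_SPLITS[model_id])


def active_params(spec: ModelSpec) -> tuple[str, ...]:
    """Free-parameter names of a model, base six first then WM variants."""
    extras = []
    if spec.split_pi:
        extras.append("pi_wm")
    if spec.split_eps:
        extras.append("eps_wm")
    if spec.split_xi:
        extras.append("xi_wm")
    return BASE_PARAMS + tuple(extras)


def resolve_params(spec: ModelSpec, params, task: str):
    """Effective (eps, rho_rew, rho_pun, b, pi, xi) governing one task.

    For GNG the base parameters apply; for WMGNG each split parameter is
    replaced by its ``_wm`` variant.  Raises if a required ``_wm`` value is
    missing from ``params``.
    """
    if task not in TASKS:
        raise ValueError(f"unknown task: {task!r}")
    eps, pi, xi = params.eps, params.pi, params.xi
    if task == WMGNG:
        if spec.split_eps:
            eps = _require(params, "eps_wm", spec)
        if spec.split_pi:
            pi = _require(params, "pi_wm", spec)
        if spec.split_xi:
            xi = _require(params, "xi_wm", spec)
    return eps, params.rho_rew, params.rho_pun, params.b, pi, xi


def _require(params, name: str, spec: ModelSpec) -> float:
    value = getattr(params, name, None)
    if value is None:
        raise ValueError(
            f"model {spec.model_id} splits {name.removesuffix('_wm')} "
            f"but params has no {name}"
        )
    return value


def effective_theta(spec: ModelSpec, params) -> list[float]:
    """Kernel parameter vector: condition-resolved values in fixed order.

    Layout: [eps_gng, eps_wm, rho_rew, rho_pun, b, pi_gng, pi_wm,
    xi_gng, xi_wm] where the WM slots repeat the base value when the model
    does not split that parameter.
    """
    eps0, rr, rp, b, pi0, xi0 = resolve_params(spec, params, GNG)
    eps1, _, _, _, pi1, xi1 = resolve_params(spec, params, WMGNG)
    return [eps0, eps1, rr, rp, b, pi0, pi1, xi0, xi1]
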