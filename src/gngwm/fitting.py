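"""Hierarchical Bayesian estimation of the go/no-go model family.

Every free parameter is sampled on an unconstrained scale and mapped to its
native range afterwards: probit (standard-normal CDF) for the
[0, 1]-bounded learning rates and irreducible noise, exponential for the
strictly positive outcome sensitivities, identity for the go and Pavlovian
biases.  Subjects are exchangeable draws from group-level normal
distributions on the unconstrained scale; sampling uses the non-centered
("Matt trick") parameterization

    u_subject = mu + sigma * raw,    raw ~ Normal(0, 1)

which decorrelates the group mean and standard deviation from the
subject-level deviations.

Priors (weakly informative, overridable through :class:`MCMCConfig`):
group means ~ Normal(0, 1); group SDs ~ half-Normal with scale 1 for
location-type parameters (b, pi, log-rho) and 0.2 for probit-scale
parameters (eps, xi), whose unconstrained axis is much more compressed.

The posterior is sampled with an adaptive Metropolis-within-Gibbs scheme:
each iteration sweeps every coordinate block (each group mean, each group
SD on the log scale, and each subject-level raw column, the latter proposed
for all subjects at once and accepted subject-by-subject, which is valid
because subjects are conditionally independent given the group
hyperparameters).  Gaussian proposal scales adapt toward a 0.44 acceptance
rate during warm-up only, so the retained draws come from a fixed kernel.

Group-level mixing is boosted by an ancillarity-sufficiency interweaving
step: after each non-centered sweep, every (mu, sigma) pair is re-drawn in
the centered parameterization conditional on the current subject-level
values (a conjugate Gibbs draw for the mean, a short Metropolis update on
log sigma), after which the raw deviations are recomputed.  Because the
subject-level unconstrained values are held fixed, this step costs no
likelihood evaluations.  Convergence is monitored with rank-normalized
split R-hat across independent chains.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from . import _kernel
from .family import ModelSpec, active_params
from .model import SubjectParams, encode_trials

__all__ = [
    "MCMCConfig",
    "FitResult",
    "transform_to_constrained",
    "transform_to_unconstrained",
    "fit_hierarchical",
    "rhat",
    "summarize_posterior",
]

_PROBIT_PARAMS = frozenset({"eps", "xi", "eps_wm", "xi_wm"})
_LOG_PARAMS = frozenset({"rho_rew", "rho_pun"})
_IDENTITY_PARAMS = frozenset({"b", "pi", "pi_wm"})
_ALL_PARAMS = _PROBIT_PARAMS | _LOG_PARAMS | _IDENTITY_PARAMS

# theta columns (see gngwm._kernel) written by each parameter, given a spec
def _theta_columns(name: str, spec: ModelSpec) -> tuple[int, ...]:
    table = {
        "eps": (0,) if spec.split_eps else (0, 1),
        "eps_wm": (1,),
        "rho_rew": (2,),
        "rho_pun": (3,),
        "b": (4,),
        "pi": (5,) if spec.split_pi else (5, 6),
        "pi_wm": (6,),
        "xi": (7,) if spec.split_xi else (7, 8),
        "xi_wm": (8,),
    }
    return table[name]


def transform_to_constrained(name: str, u):
    """Map an unconstrained value to the parameter's native scale."""
    if name in _PROBIT_PARAMS:
        return ndtr(u)
    if name in _LOG_PARAMS:
        return np.exp(u)
    if name in _IDENTITY_PARAMS:
        return u
    raise ValueError(f"unknown parameter name: {name!r}")


def transform_to_unconstrained(name: str, x):
    """Inverse of :func:`transform_to_constrained`."""
    if name in _PROBIT_PARAMS:
        return ndtri(x)
    if name in _LOG_PARAMS:
        return np.log(x)
    if name in _IDENTITY_PARAMS:
        return x
    raise ValueError(f"unknown parameter name: {name!r}")


def prior_sigma_scale(name: str) -> float:
    """Half-normal prior scale for the group SD of a parameter."""
    return 0.2 if name in _PROBIT_PARAMS else 1.0


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler configuration.

    Defaults mirror the study protocol: four independent chains of 4000
    iterations each, the first 2000 discarded as warm-up.  Desk-scale
    experiments (recovery studies, tests) pass reduced values.
    """

    chains: int = 4
    iters: int = 4000
    warmup: int = 2000
    sweeps_per_iter: int = 2
    adapt_every: int = 25
    init_retries: int = 20
    prior_mu_sd: float = 1.0
    prior_sigma_scales: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.chains < 1:
            raise ValueError("need at least one chain")
        if not 0 < self.warmup < self.iters:
            raise ValueError("require 0 < warmup < iters")

    def sigma_scale(self, name: str) -> float:
        if self.prior_sigma_scales and name in self.prior_sigma_scales:
            return float(self.prior_sigma_scales[name])
        return prior_sigma_scale(name)


class _PackedCohort:
    """Trial table flattened to kernel arrays, one pointer per subject."""

    def __init__(self, trials: pd.DataFrame):
        if "subject_id" not in trials.columns:
            raise ValueError("trial table must carry subject_id")
        self.subject_ids: list = []
        chunks = {k: [] for k in ("cue", "wm", "reset", "action", "outcome")}
        ptr = [0]
        for sid, grp in trials.groupby("subject_id", sort=True):
            enc = encode_trials(grp)
            self.subject_ids.append(sid)
            for k in chunks:
                chunks[k].append(enc[k])
            ptr.append(ptr[-1] + len(grp))
        self.ptr = np.array(ptr, dtype=np.int64)
        self.arrays = {k: np.concatenate(v) for k, v in chunks.items()}
        self.n_subjects = len(self.subject_ids)

    def loglik(self, thetas: np.ndarray, out: np.ndarray) -> np.ndarray:
        a = self.arrays
        _kernel.cohort_loglik(self.ptr, a["cue"], a["wm"], a["reset"],
                              a["action"], a["outcome"], thetas, out)
        return out


@dataclass
class FitResult:
    """Posterior draws and diagnostics from one hierarchical fit.

    Group-level draws are stored on the unconstrained sampling scale
    (``mu``, ``sigma`` with shape (chain, draw, param)); subject-level
    deviations in ``raw`` (chain, draw, subject, param).
    ``pointwise_loglik`` holds each subject's total choice log-likelihood
    at every retained draw (chain, draw, subject) — the pointwise input to
    PSIS-LOO with subjects as the exchangeable unit.
    """

    spec: ModelSpec
    param_names: tuple[str, ...]
    subject_ids: list
    mu: np.ndarray
    sigma: np.ndarray
    raw: np.ndarray
    pointwise_loglik: np.ndarray
    rhat: dict[str, float]
    accept_rates: dict[str, float]
    config: dict

    @property
    def n_draws(self) -> int:
        return self.mu.shape[0] * self.mu.shape[1]

    @property
    def max_rhat(self) -> float:
        return max(self.rhat.values())

    def subject_unconstrained(self) -> np.ndarray:
        """Subject-level values mu + sigma * raw, shape (chain, draw, S, K)."""
        return self.mu[:, :, None, :] + self.sigma[:, :, None, :] * self.raw

    def subject_constrained(self) -> np.ndarray:
        u = self.subject_unconstrained()
        out = np.empty_like(u)
        for k, name in enumerate(self.param_names):
            out[..., k] = transform_to_constrained(name, u[..., k])
        return out

    def group_constrained(self, name: str) -> np.ndarray:
        """Pooled draws of the transformed group mean for one parameter."""
        k = self.param_names.index(name)
        return np.asarray(
            transform_to_constrained(name, self.mu[:, :, k].ravel())
        )

    def posterior_median_params(self) -> pd.DataFrame:
        """Per-subject posterior-median parameters on the constrained scale."""
        c = self.subject_constrained()  # (C, D, S, K)
        med = np.median(c.reshape(-1, *c.shape[2:]), axis=0)
        return pd.DataFrame(med, index=pd.Index(self.subject_ids,
                                                name="subject_id"),
                            columns=list(self.param_names))

    def median_subject_params(self) -> dict[object, SubjectParams]:
        table = self.posterior_median_params()
        return {
            sid: SubjectParams(**row.to_dict())
            for sid, row in table.iterrows()
        }

    def pointwise_matrix(self) -> np.ndarray:
        """Pointwise log-likelihood as a (draws, subjects) matrix."""
        c, d, s = self.pointwise_loglik.shape
        return self.pointwise_loglik.reshape(c * d, s)

    def draws_long(self) -> pd.DataFrame:
        """Group-level draws in long format (chain, iteration, parameter, value)."""
        rows = []
        chains, draws, k = self.mu.shape
        for kind, arr in (("mu", self.mu), ("sigma", self.sigma)):
            for j, name in enumerate(self.param_names):
                for c in range(chains):
                    rows.append(pd.DataFrame({
                        "chain": c + 1,
                        "iteration": np.arange(1, draws + 1),
                        "parameter": f"{kind}_{name}",
                        "value": arr[c, :, j],
                    }))
        return pd.concat(rows, ignore_index=True)


def rhat(chains, method: str = "rank") -> float:
    """Split-chain potential scale reduction for one scalar parameter.

    ``chains`` is (n_chains, n_draws).  Uses the rank-normalized split
    variant by default (``method="rank"``); ``method="split"`` gives the
    classic split-chain statistic.  Identical constant chains return 1.0
    with a warning (the statistic is undefined there).
    """
    import arviz as az

    x = np.asarray(chains, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need >= 2 chains of draws")
    if x.shape[1] < 4:
        raise ValueError("need >= 4 draws per chain")
    if np.ptp(x) == 0.0:
        warnings.warn("constant chains: R-hat undefined, returning 1.0")
        return 1.0
    return float(az.rhat(x, method=method))


def _init_state(rng, n_subjects: int, n_params: int):
    mu = rng.normal(0.0, 0.3, size=n_params)
    sigma = np.abs(rng.normal(0.0, 0.25, size=n_params)) + 0.05
    raw = rng.normal(0.0, 0.5, size=(n_subjects, n_params))
    return mu, np.log(sigma), raw


def _run_chain(packed: _PackedCohort, spec: ModelSpec,
               names: Sequence[str], cfg: MCMCConfig, rng):
    """One adaptive Metropolis-within-Gibbs chain; returns retained draws."""
    S, K = packed.n_subjects, len(names)
    theta_cols = [_theta_columns(n, spec) for n in names]
    sig_scales = np.array([cfg.sigma_scale(n) for n in names])
    keep = cfg.iters - cfg.warmup

    def constrain(k, u):
        # extreme proposals may overflow exp(); the resulting non-finite
        # likelihood is rejected by the MH step, so silence the warning
        with np.errstate(over="ignore"):
            return transform_to_constrained(names[k], u)

    def build_theta(cvals):
        theta = np.empty((S, 9))
        for k, cols in enumerate(theta_cols):
            for c in cols:
                theta[:, c] = cvals[:, k]
        return theta

    # initialization with retry on non-finite likelihood
    for _attempt in range(cfg.init_retries):
        mu, ls, raw = _init_state(rng, S, K)
        sigma = np.exp(ls)
        uvals = mu[None, :] + sigma[None, :] * raw
        cvals = np.column_stack([constrain(k, uvals[:, k]) for k in range(K)])
        theta = build_theta(cvals)
        subj_ll = packed.loglik(theta, np.empty(S))
        if np.all(np.isfinite(subj_ll)):
            break
    else:
        raise RuntimeError(
            f"no finite starting point after {cfg.init_retries} retries; "
            f"last per-subject log-likelihoods: {subj_ll}"
        )

    # adaptive Gaussian proposal scales, shared across subjects per column
    step_mu = np.full(K, 0.15)
    step_ls = np.full(K, 0.2)
    step_raw = np.full(K, 0.6)
    step_asis = np.full(K, 0.4)
    acc_mu = np.zeros(K)
    acc_ls = np.zeros(K)
    acc_raw = np.zeros(K)
    acc_asis = np.zeros(K)

    out_mu = np.empty((keep, K))
    out_sigma = np.empty((keep, K))
    out_raw = np.empty((keep, S, K))
    out_ll = np.empty((keep, S))

    ll_buf = np.empty(S)

    def sweep():
        """One full pass over every coordinate block, mutating state."""
        nonlocal subj_ll
        # --- group means ---
        for k in range(K):
            prop = mu[k] + rng.normal(0.0, step_mu[k])
            u_new = prop + sigma[k] * raw[:, k]
            c_new = constrain(k, u_new)
            theta_prop = theta.copy()
            for c in theta_cols[k]:
                theta_prop[:, c] = c_new
            ll_new = packed.loglik(theta_prop, ll_buf)
            dprior = -0.5 * (prop**2 - mu[k] ** 2) / cfg.prior_mu_sd**2
            if np.log(rng.random()) < ll_new.sum() - subj_ll.sum() + dprior:
                mu[k] = prop
                cvals[:, k] = c_new
                theta[:, :] = theta_prop
                subj_ll = ll_new.copy()
                acc_mu[k] += 1
        # --- group SDs (log scale; half-normal prior + Jacobian) ---
        for k in range(K):
            prop = ls[k] + rng.normal(0.0, step_ls[k])
            s_new = np.exp(prop)
            u_new = mu[k] + s_new * raw[:, k]
            c_new = constrain(k, u_new)
            theta_prop = theta.copy()
            for c in theta_cols[k]:
                theta_prop[:, c] = c_new
            ll_new = packed.loglik(theta_prop, ll_buf)
            dprior = (-0.5 * (s_new**2 - sigma[k] ** 2) / sig_scales[k] ** 2
                      + (prop - ls[k]))
            if np.log(rng.random()) < ll_new.sum() - subj_ll.sum() + dprior:
                ls[k] = prop
                sigma[k] = s_new
                cvals[:, k] = c_new
                theta[:, :] = theta_prop
                subj_ll = ll_new.copy()
                acc_ls[k] += 1
        # --- subject deviations, one parameter column at a time, all
        # subjects proposed jointly and accepted independently (valid:
        # subjects are conditionally independent given the group) ---
        for k in range(K):
            prop = raw[:, k] + rng.normal(0.0, step_raw[k], size=S)
            u_new = mu[k] + sigma[k] * prop
            c_new = constrain(k, u_new)
            theta_prop = theta.copy()
            for c in theta_cols[k]:
                theta_prop[:, c] = c_new
            ll_new = packed.loglik(theta_prop, ll_buf)
            dprior = -0.5 * (prop**2 - raw[:, k] ** 2)
            accept = np.log(rng.random(S)) < (ll_new - subj_ll) + dprior
            if np.any(accept):
                raw[accept, k] = prop[accept]
                cvals[accept, k] = c_new[accept]
                for c in theta_cols[k]:
                    theta[accept, c] = c_new[accept]
                subj_ll[accept] = ll_new[accept]
            acc_raw[k] += accept.mean()
        # --- interweaving: centered re-draw of (mu, sigma) with the
        # subject-level unconstrained values held fixed; costs no
        # likelihood evaluations ---
        for k in range(K):
            u = mu[k] + sigma[k] * raw[:, k]
            prec = S / sigma[k] ** 2 + 1.0 / cfg.prior_mu_sd**2
            mean = (u.sum() / sigma[k] ** 2) / prec
            mu[k] = mean + rng.normal() / np.sqrt(prec)
            ssq = np.sum((u - mu[k]) ** 2)
            tau2 = sig_scales[k] ** 2

            def logp(l):
                v = np.exp(2.0 * l)
                return -S * l - ssq / (2.0 * v) - v / (2.0 * tau2) + l

            cur = logp(ls[k])
            for _ in range(2):
                prop = ls[k] + rng.normal(0.0, step_asis[k])
                new = logp(prop)
                if np.log(rng.random()) < new - cur:
                    ls[k] = prop
                    cur = new
                    acc_asis[k] += 0.5
            sigma[k] = np.exp(ls[k])
            raw[:, k] = (u - mu[k]) / sigma[k]

    n_sub = cfg.sweeps_per_iter
    batch = 0
    for it in range(cfg.iters):
        for _ in range(n_sub):
            sweep()
        # --- warm-up adaptation toward 0.44 acceptance ---
        if it < cfg.warmup and (it + 1) % cfg.adapt_every == 0:
            batch += 1
            delta = min(0.25, batch ** -0.5)
            denom = cfg.adapt_every * n_sub
            for step, acc in ((step_mu, acc_mu), (step_ls, acc_ls),
                              (step_raw, acc_raw), (step_asis, acc_asis)):
                rate = acc / denom
                step *= np.exp(np.where(rate > 0.44, delta, -delta))
                acc[:] = 0.0
        if it == cfg.warmup - 1:
            acc_mu[:] = acc_ls[:] = acc_raw[:] = acc_asis[:] = 0.0

        if it >= cfg.warmup:
            j = it - cfg.warmup
            out_mu[j] = mu
            out_sigma[j] = sigma
            out_raw[j] = raw
            out_ll[j] = subj_ll

    denom = (cfg.iters - cfg.warmup) * n_sub
    tot_acc = {
        "mu": float(acc_mu.mean() / denom),
        "sigma": float(acc_ls.mean() / denom),
        "raw": float(acc_raw.mean() / denom),
    }
    return out_mu, out_sigma, out_raw, out_ll, tot_acc


def fit_hierarchical(
    trials: pd.DataFrame,
    spec: ModelSpec,
    mcmc: MCMCConfig | None = None,
    seed: int | None = None,
) -> FitResult:
    """Fit one model to a multi-subject trial table.

    Returns posterior draws for all group- and subject-level parameters,
    per-subject pointwise log-likelihood at every retained draw, and
    rank-normalized split R-hat for every group mean, group SD, and
    subject-level unconstrained parameter.
    """
    cfg = mcmc or MCMCConfig()
    packed = _PackedCohort(trials)
    if packed.n_subjects < 2:
        warnings.warn("single-subject fit: group SDs are weakly identified")
    names = active_params(spec)
    K = len(names)

    chain_seeds = np.random.SeedSequence(seed).spawn(cfg.chains)
    mus, sigmas, raws, lls, accs = [], [], [], [], []
    for ss in chain_seeds:
        m, s, r, ll, acc = _run_chain(packed, spec, names, cfg,
                                      np.random.default_rng(ss))
        mus.append(m)
        sigmas.append(s)
        raws.append(r)
        lls.append(ll)
        accs.append(acc)

    mu = np.stack(mus)          # (C, D, K)
    sigma = np.stack(sigmas)
    raw = np.stack(raws)        # (C, D, S, K)
    pointwise = np.stack(lls)   # (C, D, S)

    diagnostics: dict[str, float] = {}
    if cfg.chains >= 2:
        for k, name in enumerate(names):
            diagnostics[f"mu_{name}"] = rhat(mu[:, :, k])
            diagnostics[f"sigma_{name}"] = rhat(sigma[:, :, k])
        subj_u = mu[:, :, None, :] + sigma[:, :, None, :] * raw
        for i, sid in enumerate(packed.subject_ids):
            for k, name in enumerate(names):
                diagnostics[f"{name}[{sid}]"] = rhat(subj_u[:, :, i, k])

    accept = {key: float(np.mean([a[key] for a in accs])) for key in accs[0]}
    return FitResult(
        spec=spec,
        param_names=names,
        subject_ids=packed.subject_ids,
        mu=mu,
        sigma=sigma,
        raw=raw,
        pointwise_loglik=pointwise,
        rhat=diagnostics,
        accept_rates=accept,
        config={
            "chains": cfg.chains,
            "iters": cfg.iters,
            "warmup": cfg.warmup,
            "seed": seed,
            "prior_mu_sd": cfg.prior_mu_sd,
            "prior_sigma_scales": {n: cfg.sigma_scale(n) for n in names},
            "rhat_method": "rank-normalized split",
        },
    )


@dataclass(frozen=True)
class PosteriorSummary:
    """Group-level medians/HDIs plus HDI-overlap flags for split pairs."""

    table: pd.DataFrame
    hdi_overlap: dict[str, bool] = field(default_factory=dict)


def summarize_posterior(fit: FitResult, prob: float = 0.95) -> PosteriorSummary:
    """Median and highest-density interval of each group-level parameter.

    Computed from pooled post-warm-up draws of the transformed group mean.
    For each condition-split parameter the summary also reports whether the
    base and ``_wm`` HDIs overlap — the credible-difference criterion (no
    overlap = credible difference).
    """
    import arviz as az

    if not 0.0 < prob < 1.0:
        raise ValueError("prob must lie in (0, 1)")
    rows = []
    intervals = {}
    for name in fit.param_names:
        draws = fit.group_constrained(name)
        lo, hi = az.hdi(draws, hdi_prob=prob)
        intervals[name] = (float(lo), float(hi))
        rows.append({
            "param": name,
            "median": float(np.median(draws)),
            "hdi_low": float(lo),
            "hdi_high": float(hi),
        })
    overlap = {}
    for base in ("pi", "eps", "xi"):
        wm = f"{base}_wm"
        if wm in intervals:
            (alo, ahi), (blo, bhi) = intervals[base], intervals[wm]
            overlap[base] = not (ahi < blo or bhi < alo)
    return PosteriorSummary(pd.DataFrame(rows), overlap)
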