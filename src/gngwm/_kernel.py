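"""Numba-compiled trial-replay kernels.

These are the hot path of hierarchical fitting: replaying a subject's trial
sequence under candidate parameters and accumulating the choice
log-likelihood.  The scientific definitions live in :mod:`gngwm.model`;
the kernels implement the identical recursion over flat arrays.

Encoding conventions (see :func:`gngwm.model.encode_trials`):
  cue     int 0..3 (cue-type index into gngwm.task.CUE_TYPES)
  wm      1 for WMGNG trials, 0 for GNG
  reset   1 on the first trial of each task run (latent state starts fresh)
  action  1 = go, 0 = nogo
  outcome -1, 0, +1

theta layout (per subject, condition-resolved; see
:func:`gngwm.family.effective_theta`):
  [eps_gng, eps_wm, rho_rew, rho_pun, b, pi_gng, pi_wm, xi_gng, xi_wm]
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def replay_subject(cue, wm, reset, action, outcome, theta, ll, w_go, w_nogo, p_go):
    """Replay one subject's observed trials, filling per-trial outputs.

    ``ll[t]`` is log P(observed action at t); ``w_go``/``w_nogo`` the
    action weights entering the decision rule; ``p_go`` the go
    probability after the irreducible-noise squash.  Returns the total
    log-likelihood.
    """
    Q = np.zeros((4, 2))
    V = np.zeros(4)
    total = 0.0
    for t in range(cue.shape[0]):
        if reset[t] == 1:
            Q[:, :] = 0.0
            V[:] = 0.0
        c = cue[t]
        if wm[t] == 1:
            eps, pi, xi = theta[1], theta[6], theta[8]
        else:
            eps, pi, xi = theta[0], theta[5], theta[7]
        b = theta[4]
        wg = Q[c, 1] + b + pi * V[c]
        wn = Q[c, 0]
        d = wg - wn
        # numerically stable logistic
        if d >= 0.0:
            sm = 1.0 / (1.0 + np.exp(-d))
        else:
            e = np.exp(d)
            sm = e / (1.0 + e)
        pg = sm * (1.0 - xi) + 0.5 * xi
        w_go[t] = wg
        w_nogo[t] = wn
        p_go[t] = pg
        p = pg if action[t] == 1 else 1.0 - pg
        ll[t] = np.log(p)
        total += ll[t]
        r = outcome[t]
        rho = theta[2] if r > 0 else theta[3]
        delta_target = rho * r
        Q[c, action[t]] += eps * (delta_target - Q[c, action[t]])
        V[c] += eps * (delta_target - V[c])
    return total


@njit(cache=True)
def subject_loglik(cue, wm, reset, action, outcome, theta):
    """Total choice log-likelihood of one subject's trials."""
    Q = np.zeros((4, 2))
    V = np.zeros(4)
    total = 0.0
    for t in range(cue.shape[0]):
        if reset[t] == 1:
            Q[:, :] = 0.0
            V[:] = 0.0
        c = cue[t]
        if wm[t] == 1:
            eps, pi, xi = theta[1], theta[6], theta[8]
        else:
            eps, pi, xi = theta[0], theta[5], theta[7]
        wg = Q[c, 1] + theta[4] + pi * V[c]
        wn = Q[c, 0]
        d = wg - wn
        if d >= 0.0:
            sm = 1.0 / (1.0 + np.exp(-d))
        else:
            e = np.exp(d)
            sm = e / (1.0 + e)
        pg = sm * (1.0 - xi) + 0.5 * xi
        p = pg if action[t] == 1 else 1.0 - pg
        total += np.log(p)
        r = outcome[t]
        rho = theta[2] if r > 0 else theta[3]
        delta_target = rho * r
        Q[c, action[t]] += eps * (delta_target - Q[c, action[t]])
        V[c] += eps * (delta_target - V[c])
    return total


@njit(cache=True)
def cohort_loglik(ptr, cue, wm, reset, action, outcome, thetas, out):
    """Per-subject total log-likelihood over a packed cohort.

    ``ptr`` holds subject trial offsets (len n_subjects + 1); ``thetas``
    is (n_subjects, 9).  Results go into ``out``.
    """
    for i in range(ptr.shape[0] - 1):
        lo, hi = ptr[i], ptr[i + 1]
        out[i] = subject_loglik(
            cue[lo:hi], wm[lo:hi], reset[lo:hi], action[lo:hi],
            outcome[lo:hi], thetas[i],
        )
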