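"""Independent scalar re-implementation of the trial-replay likelihood.

Deliberately written with plain Python dictionaries and math functions,
sharing no code with the package's array/JIT implementation, so it can
serve as an oracle for the likelihood recursion.
"""

import math


def oracle_replay(params, trials, splits):
    """Per-trial log P(observed action) plus latent trajectories.

    ``params``: dict with eps, rho_rew, rho_pun, b, pi, xi and optional
    *_wm entries.  ``trials``: iterable of dicts with keys task, cue_type,
    action, outcome, ordered with task runs contiguous.  ``splits``:
    (split_pi, split_eps, split_xi).

    Returns (logliks, q_values, v_values) where the trajectories record
    every Q and V value encountered (for boundedness checks).
    """
    split_pi, split_eps, split_xi = splits
    logliks, q_seen, v_seen = [], [], []
    prev_task = None
    Q = {}
    V = {}
    for tr in trials:
        if tr["task"] != prev_task:
            Q = {}
            V = {}
            prev_task = tr["task"]
        wm = tr["task"] == "WMGNG"
        eps = params["eps_wm"] if (wm and split_eps) else params["eps"]
        pi = params["pi_wm"] if (wm and split_pi) else params["pi"]
        xi = params["xi_wm"] if (wm and split_xi) else params["xi"]
        cue = tr["cue_type"]
        q_go = Q.get((cue, "go"), 0.0)
        q_nogo = Q.get((cue, "nogo"), 0.0)
        v = V.get(cue, 0.0)
        w_go = q_go + params["b"] + pi * v
        w_nogo = q_nogo
        p_go = (1.0 / (1.0 + math.exp(-(w_go - w_nogo)))) * (1.0 - xi) + xi / 2.0
        p = p_go if tr["action"] == "go" else 1.0 - p_go
        logliks.append(math.log(p))
        r = tr["outcome"]
        rho = params["rho_rew"] if r > 0 else params["rho_pun"]
        Q[(cue, tr["action"])] = (
            Q.get((cue, tr["action"]), 0.0)
            + eps * (rho * r - Q.get((cue, tr["action"]), 0.0))
        )
        V[cue] = v + eps * (rho * r - v)
        q_seen.append(Q[(cue, tr["action"])])
        v_seen.append(V[cue])
    return logliks, q_seen, v_seen


def random_params(rng, split=True):
    """Random parameter dict covering the full model's ranges."""
    p = {
        "eps": rng.uniform(0.02, 0.9),
        "rho_rew": rng.uniform(0.2, 8.0),
        "rho_pun": rng.uniform(0.2, 8.0),
        "b": rng.normal(0.0, 1.0),
        "pi": rng.normal(0.0, 2.0),
        "xi": rng.uniform(0.0, 0.9),
    }
    if split:
        p.update({
            "eps_wm": rng.uniform(0.02, 0.9),
            "pi_wm": rng.normal(0.0, 2.0),
            "xi_wm": rng.uniform(0.0, 0.9),
        })
    return p
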