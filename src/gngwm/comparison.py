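"""Model comparison by PSIS-LOO leave-one-out cross-validation.

The pointwise unit is the subject (each entry of the log-likelihood matrix
is one subject's total choice log-likelihood at one posterior draw), so
LOO approximates leave-one-subject-out prediction — the natural
exchangeable unit in a hierarchical model.  LOOIC is reported on the
deviance scale (-2 x elpd); lower is better.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fitting import FitResult

#: Pareto shape threshold above which an importance ratio is flagged.
PARETO_K_THRESHOLD = 0.7


@dataclass(frozen=True)
class LooResult:
    looic: float
    se: float
    elpd: float
    pointwise_elpd: np.ndarray
    pareto_k: np.ndarray
    unreliable: bool

    @property
    def n_units(self) -> int:
        return self.pointwise_elpd.shape[0]


def looic(pointwise_loglik: np.ndarray) -> LooResult:
    """LOOIC with standard error from a (draws, units) log-likelihood matrix.

    Uses Pareto-smoothed importance sampling; units with Pareto k above
    0.7 mark the estimate as unreliable (flagged, never suppressed).  A
    matrix with no across-draw variation degenerates to the in-sample
    log-likelihood exactly.
    """
    import arviz as az

    mat = np.asarray(pointwise_loglik, dtype=float)
    if mat.ndim != 2:
        raise ValueError("pointwise log-likelihood must be (draws, units)")
    if not np.all(np.isfinite(mat)):
        raise ValueError("pointwise log-likelihood contains non-finite values")
    n_draws, n_units = mat.shape
    if n_draws < 100:
        raise ValueError(f"need >= 100 draws for PSIS-LOO, got {n_draws}")

    if np.allclose(mat.var(axis=0), 0.0):
        # degenerate posterior: importance weights are uniform and LOO
        # reduces to the in-sample log-likelihood
        elpd_i = mat[0].copy()
        k = np.zeros(n_units)
    else:
        idata = az.from_dict(
            log_likelihood={"subject": mat[None, :, :]}
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            # draws are pooled across chains, so the relative efficiency
            # of the importance ratios is taken as 1
            res = az.loo(idata, pointwise=True, reff=1.0)
        elpd_i = np.asarray(res.loo_i.values, dtype=float)
        k = np.asarray(res.pareto_k.values, dtype=float)

    elpd = float(elpd_i.sum())
    se = 2.0 * float(np.sqrt(n_units * np.var(elpd_i)))
    unreliable = bool(np.any(k > PARETO_K_THRESHOLD))
    if unreliable:
        warnings.warn(
            f"{int(np.sum(k > PARETO_K_THRESHOLD))} of {n_units} units have "
            f"Pareto k > {PARETO_K_THRESHOLD}; LOOIC may be unreliable"
        )
    return LooResult(
        looic=-2.0 * elpd,
        se=se,
        elpd=elpd,
        pointwise_elpd=elpd_i,
        pareto_k=k,
        unreliable=unreliable,
    )


def compare_models(fits: dict[int, FitResult]) -> pd.DataFrame:
    """LOOIC ranking across fitted models on the same subjects.

    Returns one row per model sorted by ascending LOOIC with the
    difference from the best model (``delta_looic``; the winner has 0).
    Ties are broken by smaller parameter count, then model id.
    """
    if not fits:
        raise ValueError("no fits to compare")
    subject_sets = {tuple(f.subject_ids) for f in fits.values()}
    if len(subject_sets) != 1:
        raise ValueError("fits cover different subject sets")

    rows = []
    for model_id, fit in fits.items():
        res = looic(fit.pointwise_matrix())
        rows.append({
            "model_id": model_id,
            "n_params": fit.spec.n_params,
            "looic": res.looic,
            "se": res.se,
            "unreliable": res.unreliable,
        })
    table = pd.DataFrame(rows).sort_values(
        ["looic", "n_params", "model_id"], kind="stable"
    ).reset_index(drop=True)
    table["delta_looic"] = table["looic"] - table["looic"].iloc[0]
    return table
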