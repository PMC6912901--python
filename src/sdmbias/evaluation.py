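"""Parameter-recovery, map-correlation and AUC metrics."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.metrics import roc_auc_score

from .grid import Grid
from .sdm import BackgroundSet, SDMResults
from .species import SexParams

__all__ = ["parameter_bias", "spearman_map_correlation", "cv_auc"]


def parameter_bias(fit: SDMResults, truth: SexParams) -> pd.Series:
    """Signed coefficient bias, estimate - truth, per covariate."""
    est = fit.coefficients
    missing = set(truth.slopes) ^ set(est.index)
    if missing:
        raise ValueError(f"coefficient names do not match: {sorted(missing)}")
    return pd.Series({k: float(est[k]) - v for k, v in truth.slopes.items()})


def spearman_map_correlation(predicted: Grid, truth: Grid) -> float:
    """Spearman rank correlation between two aligned maps (average-rank ties),
    computed over the jointly non-missing cells; NaN for constant maps."""
    if not predicted.same_geometry(truth):
        raise ValueError("maps are not aligned")
    a = predicted.values.ravel()
    b = truth.values.ravel()
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3:
        raise ValueError("need at least 3 jointly non-missing cells")
    if np.ptp(a[ok]) == 0 or np.ptp(b[ok]) == 0:
        warnings.warn("constant map: Spearman correlation undefined")
        return float("nan")
    rho, _ = spearmanr(a[ok], b[ok])
    return float(rho)


def cv_auc(
    presences: pd.DataFrame,
    eval_background: BackgroundSet,
    fit: SDMResults,
    distance: Grid | None = None,
    k: int = 10,
    seed: int = 0,
) -> tuple[float, float]:
    """K-fold cross-validated presence-vs-background ranking AUC.

    The fitted model scores presence records against an evaluation
    background drawn independently of the fitting background. Folds are
    stratified over presences and background; the return value is the mean
    and the between-fold variance of the fold AUCs. Folds lacking either
    class are skipped with a warning.
    """
    if k < 2:
        raise ValueError("need k >= 2 folds")
    scores_p = fit.score_points(presences["x"].to_numpy(), presences["y"].to_numpy(),
                                distance=distance)
    scores_b = fit.score_points(eval_background.points[:, 0], eval_background.points[:, 1],
                                distance=distance)
    rng = np.random.default_rng(seed)
    folds_p = rng.permuted(np.arange(len(scores_p)) % k)
    folds_b = rng.permuted(np.arange(len(scores_b)) % k)
    aucs = []
    for fold in range(k):
        sp = scores_p[folds_p == fold]
        sb = scores_b[folds_b == fold]
        if len(sp) == 0 or len(sb) == 0:
            warnings.warn(f"fold {fold} has no presences or background; skipped")
            continue
        y = np.concatenate([np.ones(len(sp)), np.zeros(len(sb))])
        s = np.concatenate([sp, sb])
        aucs.append(roc_auc_score(y, s))
    if not aucs:
        raise ValueError("no usable folds")
    return float(np.mean(aucs)), float(np.var(aucs, ddof=1)) if len(aucs) > 1 else 0.0
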