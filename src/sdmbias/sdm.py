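"""Presence-only SDM fitting (Maxent-equivalent weighted logistic regression).

The model contrasts presence records against background points with an
infinitely weighted logistic regression (IWLR): presences get weight 1,
background points a large weight W, and as W grows the slope estimates
converge to the maximum-likelihood fit of the inhomogeneous Poisson point
process that Maxent estimates. Only linear features are used — the
generating process is log-linear — with an optional distance-to-trajectory
covariate implementing the distance bias correction.

Background strategies
---------------------
* uniform: points uniform over the landscape (no bias correction);
* targeted: points along the survey trajectories with offsets drawn from
  the detection distance density, so the fitting contrast carries the same
  spatial bias as the observation process and the bias cancels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .grid import CovariateStack, Grid
from .survey import DetectionModel, SurveyDesign

__all__ = [
    "BackgroundSet",
    "uniform_background",
    "targeted_background",
    "PresenceOnlySDM",
    "SDMResults",
]

#: Distance covariate is entered as d / DISTANCE_SCALE for conditioning;
#: beta_d is reported back on the per-metre scale.
DISTANCE_SCALE = 100.0


@dataclass(frozen=True)
class BackgroundSet:
    """Background (pseudo-absence) point set used as the model contrast."""

    points: np.ndarray  # (n, 2)
    method: str  # uniform | targeted
    seed: int | None = None

    @property
    def n(self) -> int:
        return len(self.points)


def uniform_background(grid: Grid, n: int = 10_000, seed: int = 0) -> BackgroundSet:
    """``n`` uniform background points over the non-missing cells."""
    from .survey import random_points

    design = random_points(grid, n=n, seed=seed)
    return BackgroundSet(points=design.points, method="uniform", seed=seed)


def targeted_background(
    design: SurveyDesign,
    model: DetectionModel,
    n: int = 10_000,
    seed: int = 0,
    extent: tuple[float, float, float, float] | None = None,
) -> BackgroundSet:
    """Background points along the survey trajectories with distance offsets
    drawn from the detection density g, replicating the observation bias.

    Each point takes a position uniform by length along the trajectory
    collection, an offset distance from g, and a side chosen uniformly;
    points falling outside ``extent`` (when given) are re-drawn.
    """
    if not design.trajectories:
        raise ValueError("targeted background requires a trajectory design")
    if n < 1:
        raise ValueError("n must be >= 1")
    lengths = np.array([t.length for t in design.trajectories])
    if lengths.sum() == 0:
        raise ValueError("degenerate (zero-length) trajectories")
    starts = np.vstack([t.segments[0] for t in design.trajectories])
    ends = np.vstack([t.segments[1] for t in design.trajectories])
    seg_vec = ends - starts
    seg_len = np.hypot(seg_vec[:, 0], seg_vec[:, 1])
    keep = seg_len > 0
    starts, seg_vec, seg_len = starts[keep], seg_vec[keep], seg_len[keep]
    cum = np.cumsum(seg_len)
    rng = np.random.default_rng(seed)
    pts = np.empty((0, 2))
    while len(pts) < n:
        m = 2 * (n - len(pts)) + 8
        pos = rng.uniform(0, cum[-1], size=m)
        idx = np.searchsorted(cum, pos)
        frac = (pos - (cum[idx] - seg_len[idx])) / seg_len[idx]
        base = starts[idx] + frac[:, None] * seg_vec[idx]
        unit = seg_vec[idx] / seg_len[idx, None]
        normal = np.column_stack([-unit[:, 1], unit[:, 0]])
        offset = model.sample(m, rng)
        side = rng.choice([-1.0, 1.0], size=m)
        cand = base + (side * offset)[:, None] * normal
        if extent is not None:
            xmin, ymin, xmax, ymax = extent
            ok = (cand[:, 0] >= xmin) & (cand[:, 0] <= xmax) & (cand[:, 1] >= ymin) & (cand[:, 1] <= ymax)
            cand = cand[ok]
        pts = np.vstack([pts, cand])
    return BackgroundSet(points=pts[:n], method="targeted", seed=seed)


# ---------------------------------------------------------------------------
# Model / Results


class PresenceOnlySDM:
    """Maxent-equivalent presence-only SDM.

    Parameters
    ----------
    presences : DataFrame with columns x, y (sex ignored here)
        Presence-only records; duplicate rows are distinct observations.
    background : BackgroundSet
    stack : CovariateStack
        Standardized covariates providing the linear features.
    distance : Grid, optional
        Distance-to-trajectories raster; when given, d/100 enters as an
        additional linear predictor (the distance bias correction) and the
        fit carries a ``distance_coefficient``.
    background_weight : float
        Logistic case weight W on background points (IWLR weight).
    """

    def __init__(
        self,
        presences: pd.DataFrame,
        background: BackgroundSet,
        stack: CovariateStack,
        distance: Grid | None = None,
        background_weight: float = 10_000.0,
    ) -> None:
        if len(presences) < 5:
            raise ValueError("need at least 5 presence records")
        if not stack.standardized:
            raise ValueError("covariates must be standardized")
        self.presences = presences.reset_index(drop=True)
        self.background = background
        self.stack = stack
        self.distance = distance
        self.background_weight = float(background_weight)
        self.covariate_names = list(stack.names)
        self.correction = "none" if distance is None else "distance"
        if background.method == "targeted":
            self.correction = "targeted" if distance is None else "targeted+distance"

        px, py = presences["x"].to_numpy(float), presences["y"].to_numpy(float)
        bx, by = background.points[:, 0], background.points[:, 1]
        X_pres = stack.values_at(px, py)
        X_back = stack.values_at(bx, by)
        if distance is not None:
            X_pres = np.column_stack([X_pres, distance.value_at(px, py) / DISTANCE_SCALE])
            X_back = np.column_stack([X_back, distance.value_at(bx, by) / DISTANCE_SCALE])
        X = np.vstack([X_pres, X_back])
        keep = np.all(np.isfinite(X), axis=1)
        self._X = sm.add_constant(X[keep], prepend=True, has_constant="add")
        self._y = np.concatenate([np.ones(len(X_pres)), np.zeros(len(X_back))])[keep]
        self._w = np.where(self._y == 1, 1.0, self.background_weight)
        n_params = self._X.shape[1]
        if int(self._y.sum()) < n_params:
            raise ValueError(
                f"fewer presences ({int(self._y.sum())}) than coefficients ({n_params})"
            )

    @property
    def exog_names(self) -> list[str]:
        names = ["intercept"] + self.covariate_names
        if self.distance is not None:
            names.append("distance")
        return names

    def fit(self, ridge: float = 0.0, maxiter: int = 200) -> "SDMResults":
        """Maximise the weighted-logistic likelihood.

        ``ridge`` adds an optional small L2 penalty as a separation rescue;
        the default is unpenalised.
        """
        glm = sm.GLM(self._y, self._X, family=sm.families.Binomial(), freq_weights=self._w)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if ridge > 0:
                res = glm.fit_regularized(alpha=ridge, L1_wt=0.0, maxiter=maxiter)
            else:
                res = glm.fit(maxiter=maxiter)
        params = np.asarray(res.params, dtype=float)
        if not np.all(np.isfinite(params)):
            raise RuntimeError(
                "weighted-logistic fit failed to converge (possible complete "
                "separation); consider ridge > 0"
            )
        return SDMResults(self, res)


class SDMResults:
    """Fitted presence-only SDM: coefficients, uncertainties, diagnostics."""

    def __init__(self, model: PresenceOnlySDM, glm_results) -> None:
        self.model = model
        self._res = glm_results
        names = model.exog_names
        params = pd.Series(np.asarray(glm_results.params, dtype=float), index=names)
        self.intercept = float(params["intercept"])
        self.coefficients = params[model.covariate_names]
        #: beta_d on the per-metre scale (present iff a distance grid was supplied)
        self.distance_coefficient = (
            float(params["distance"]) / DISTANCE_SCALE if model.distance is not None else None
        )
        try:
            self.bse = pd.Series(np.asarray(glm_results.bse, dtype=float), index=names)
        except (AttributeError, NotImplementedError):  # regularized fits
            self.bse = pd.Series(np.nan, index=names)
        self.llf = float(getattr(glm_results, "llf", np.nan))
        self.n_presence = int(model._y.sum())
        self.n_background = int((model._y == 0).sum())
        self.correction = model.correction

    def linear_predictor(self, stack: CovariateStack | None = None,
                         distance: Grid | None = None,
                         zero_distance: bool = False) -> np.ndarray:
        """Per-cell linear predictor sum_i x_i beta_i (+ beta_d d), no intercept."""
        stack = stack or self.model.stack
        missing = set(self.model.covariate_names) - set(stack.names)
        if missing:
            raise ValueError(f"stack lacks fitted covariates: {sorted(missing)}")
        eta = np.zeros_like(stack.reference.values)
        for name in self.model.covariate_names:
            eta = eta + stack[name].values * self.coefficients[name]
        if self.distance_coefficient is not None and not zero_distance:
            dgrid = distance if distance is not None else self.model.distance
            eta = eta + dgrid.values * self.distance_coefficient
        return eta

    def predict_relative_abundance(self, stack: CovariateStack | None = None,
                                   zero_distance: bool = True) -> Grid:
        """Relative abundance map mu_j (the Maxent 'raw' output).

        mu_j = exp(eta_j) / sum_j exp(eta_j) over non-missing cells, summing
        to 1; with ``zero_distance`` (the default, used for bias-corrected
        abundance) the distance term contributes exp(0).
        """
        from dataclasses import replace

        stack = stack or self.model.stack
        eta = self.linear_predictor(stack, zero_distance=zero_distance)
        raw = np.exp(eta - np.nanmax(eta))
        total = np.nansum(raw)
        return replace(stack.reference, values=raw / total)

    def score_points(self, x: np.ndarray, y: np.ndarray,
                     distance: Grid | None = None) -> np.ndarray:
        """Linear-predictor scores at point locations (for AUC ranking)."""
        X = self.model.stack.values_at(np.asarray(x, float), np.asarray(y, float),
                                       self.model.covariate_names)
        eta = X @ self.coefficients.to_numpy()
        if self.distance_coefficient is not None:
            dgrid = distance if distance is not None else self.model.distance
            eta = eta + dgrid.value_at(np.asarray(x, float), np.asarray(y, float)) * self.distance_coefficient
        return eta

    def summary(self) -> str:
        lines = [
            "Presence-only SDM (weighted logistic / point-process fit)",
            f"  correction: {self.correction}   presences: {self.n_presence}"
            f"   background: {self.n_background} ({self.model.background.method})",
            f"  log-likelihood: {self.llf:.2f}",
            f"  {'term':<12}{'coef':>10}{'std err':>10}",
            f"  {'intercept':<12}{self.intercept:>10.4f}{self.bse['intercept']:>10.4f}",
        ]
        for name in self.model.covariate_names:
            lines.append(f"  {name:<12}{self.coefficients[name]:>10.4f}{self.bse[name]:>10.4f}")
        if self.distance_coefficient is not None:
            lines.append(
                f"  {'distance':<12}{self.distance_coefficient:>10.6f}"
                f"{self.bse['distance'] / DISTANCE_SCALE:>10.6f}  (per m)"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        d = {
            "correction": self.correction,
            "intercept": self.intercept,
            "coefficients": {k: float(v) for k, v in self.coefficients.items()},
            "n_presence": self.n_presence,
            "n_background": self.n_background,
            "normalization_constants": {
                k: list(map(float, v))
                for k, v in self.model.stack.normalization_constants.items()
            },
        }
        if self.distance_coefficient is not None:
            d["distance_coefficient_per_m"] = self.distance_coefficient
        return d
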