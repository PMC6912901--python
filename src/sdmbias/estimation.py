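"""Detection surfaces, expected-total-sign and sex-ratio estimation.

Given a fitted SDM's relative abundance map mu_j (summing to 1) and a
per-cell detection probability p_obs,j, the expected total number of signs
that complete, detection-free sampling would have recorded is

    N_tot = N_obs / sum_j mu_j * p_obs,j

which reduces to N_obs when p is 1 everywhere. The sex ratio (proportion of
females) is then N_tot,f / (N_tot,f + N_tot,m); computed instead from raw
observation counts it is N_obs,f / (N_obs,f + N_obs,m).

Detection surfaces come in three flavours matching the bias-correction
route: the distance density g(d_j)/g(0) (uncorrected and targeted models),
exp(beta_d * d_j) from the distance-covariate model, and a binary sampled-
cell indicator for the random point design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .grid import Grid
from .sdm import SDMResults
from .survey import DetectionModel, SurveyDesign, sampled_cell_mask

__all__ = [
    "SexRatioEstimate",
    "detection_grid",
    "estimate_total_signs",
    "sign_density",
    "sex_ratio_from_observations",
    "sex_ratio_from_models",
]


@dataclass(frozen=True)
class SexRatioEstimate:
    """Proportion of females with the per-sex quantities it was built from."""

    ratio: float
    method: str  # observations | model-none | model-targeted | model-distance
    n_obs_female: int
    n_obs_male: int
    n_tot_female: float | None = None
    n_tot_male: float | None = None


def detection_grid(
    method: str,
    distance: Grid | None = None,
    fit: SDMResults | None = None,
    model: DetectionModel | None = None,
    design: SurveyDesign | None = None,
    grid: Grid | None = None,
) -> Grid:
    """Per-cell detection probability surface p_obs,j in [0, 1].

    methods
    -------
    distance-model : p_j = exp(beta_d * d_j), capped at 1 (needs ``fit``
        with a distance coefficient and the ``distance`` grid)
    detection-density : p_j = g(d_j)/g(0) (needs ``model`` and ``distance``)
    sampled-cells : 1 in cells holding >= 1 sample point, else 0 (needs a
        point ``design`` and the reference ``grid``)
    """
    if method == "distance-model":
        if fit is None or fit.distance_coefficient is None:
            raise ValueError("distance-model needs a fit with a distance coefficient")
        if distance is None:
            raise ValueError("distance-model needs the distance grid")
        beta_d = fit.distance_coefficient
        if beta_d > 0:
            warnings.warn(
                f"beta_d = {beta_d:.3g} > 0: detection increasing with distance "
                "suggests a fitting problem; capping p at 1"
            )
        p = np.minimum(np.exp(beta_d * distance.values), 1.0)
        return replace(distance, values=p)
    if method == "detection-density":
        if model is None or distance is None:
            raise ValueError("detection-density needs a detection model and distance grid")
        return replace(distance, values=model.detection(distance.values))
    if method == "sampled-cells":
        if design is None or grid is None:
            raise ValueError("sampled-cells needs a point design and a reference grid")
        return replace(grid, values=sampled_cell_mask(grid, design).astype(float))
    raise ValueError(f"unknown detection-grid method {method!r}")


def estimate_total_signs(n_obs: float, mu: Grid, p_obs: Grid) -> float:
    """Expected total signs under complete sampling, N_obs / sum_j mu_j p_j."""
    if not mu.same_geometry(p_obs):
        raise ValueError("mu and p_obs grids are not aligned")
    total_mu = np.nansum(mu.values)
    if abs(total_mu - 1.0) > 1e-6:
        raise ValueError(f"relative abundances must sum to 1 (got {total_mu})")
    detectable = np.nansum(mu.values * p_obs.values)
    if detectable <= 0:
        raise ValueError("sum of mu_j * p_obs,j is zero: no detectable mass")
    return float(n_obs) / float(detectable)


def sign_density(mu: Grid, n_tot: float, cell_area_ha: float | None = None) -> Grid:
    """Sign density map lambda_j = mu_j * N_tot / a_j, in signs per ha."""
    if n_tot < 0:
        raise ValueError("n_tot must be non-negative")
    a = cell_area_ha if cell_area_ha is not None else mu.cell_area_ha
    if a <= 0:
        raise ValueError("cell area must be positive")
    return replace(mu, values=mu.values * n_tot / a)


def sex_ratio_from_observations(records: pd.DataFrame) -> SexRatioEstimate:
    """Proportion of females among raw presence records."""
    if len(records) == 0:
        raise ValueError("no presence records")
    sexes = records["sex"].astype(str)
    n_f = int((sexes == "female").sum())
    n_m = int((sexes == "male").sum())
    if n_f + n_m == 0:
        raise ValueError("records carry no female/male labels")
    return SexRatioEstimate(ratio=n_f / (n_f + n_m), method="observations",
                            n_obs_female=n_f, n_obs_male=n_m)


def sex_ratio_from_models(
    n_obs_f: float,
    n_obs_m: float,
    mu_f: Grid,
    mu_m: Grid,
    p_obs_f: Grid,
    p_obs_m: Grid,
    method: str = "model",
) -> SexRatioEstimate:
    """Sex ratio from model-based expected totals under complete sampling."""
    n_tot_f = estimate_total_signs(n_obs_f, mu_f, p_obs_f)
    n_tot_m = estimate_total_signs(n_obs_m, mu_m, p_obs_m)
    return SexRatioEstimate(
        ratio=n_tot_f / (n_tot_f + n_tot_m),
        method=method,
        n_obs_female=int(n_obs_f),
        n_obs_male=int(n_obs_m),
        n_tot_female=n_tot_f,
        n_tot_male=n_tot_m,
    )
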