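"""Sex-specific virtual species intensity surfaces.

Each sex follows an inhomogeneous Poisson point process on the raster:
ln lambda(s) = beta0 + sum_i x_i(s) * beta_i, with standardized covariates
x_i. Sign counts per cell are independent Poisson(lambda_j) draws. The male
intercept can be calibrated in closed form so the expected sex ratio
(female share of total intensity) equals a prescribed target exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import yaml

from .grid import CovariateStack, Grid

__all__ = [
    "SexParams",
    "compute_intensity",
    "calibrate_male_intercept",
    "realize_counts",
    "default_params",
]


@dataclass(frozen=True)
class SexParams:
    """Per-sex log-linear intensity coefficients (intercept beta0, slopes beta_i)."""

    sex: str
    intercept: float
    slopes: dict[str, float]

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {"sex": self.sex, "intercept": float(self.intercept),
                 "slopes": {k: float(v) for k, v in self.slopes.items()}},
                fh,
            )

    @classmethod
    def from_yaml(cls, path) -> "SexParams":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(sex=d["sex"], intercept=float(d["intercept"]),
                   slopes={k: float(v) for k, v in d["slopes"].items()})


#: Default virtual-species parameterization: sexes prefer contrasting
#: habitat (females dense/heterogeneous cover, males open canopy). The male
#: intercept shown here applies to the original study landscape; use
#: :func:`calibrate_male_intercept` on any other landscape to hold the
#: expected sex ratio at target.
_DEFAULTS = {
    "female": SexParams("female", -4.0, {"slope": -0.9, "canopy": -0.8, "simpson": 1.0}),
    "male": SexParams("male", -3.55, {"slope": -0.2, "canopy": 0.9, "simpson": -0.9}),
}


def default_params(sex: str) -> SexParams:
    """Named default parameter sets ('female', 'male')."""
    try:
        return _DEFAULTS[sex]
    except KeyError:
        raise KeyError(f"no default parameters for sex {sex!r}") from None


def _linear_predictor(stack: CovariateStack, slopes: dict[str, float]) -> np.ndarray:
    unknown = set(slopes) - set(stack.names)
    if unknown:
        raise ValueError(f"slopes reference unknown covariates: {sorted(unknown)}")
    eta = np.zeros_like(stack.reference.values)
    for name, beta in slopes.items():
        eta = eta + stack[name].values * beta
    return eta


def compute_intensity(stack: CovariateStack, params: SexParams) -> Grid:
    """Intensity lambda(s) = exp(beta0 + sum_i x_i(s) beta_i) per cell.

    Requires a standardized stack; missing covariate cells yield missing
    intensity.
    """
    if not stack.standardized:
        raise ValueError("covariate stack must be standardized before computing intensity")
    eta = params.intercept + _linear_predictor(stack, params.slopes)
    ref = stack.reference
    return replace(ref, values=np.exp(eta))


def calibrate_male_intercept(
    stack: CovariateStack,
    female: SexParams,
    male_slopes: dict[str, float],
    target_ratio: float = 0.5,
) -> SexParams:
    """Closed-form male intercept giving an exact expected sex ratio.

    With the female share defined as r = sum(lambda_f) / (sum(lambda_f) +
    sum(lambda_m)), the male intercept is

        beta0_m = ln sum_s lambda_f(s) - ln sum_s exp(sum_i x_i(s) beta_i,m)
                  + ln((1 - r) / r)

    so that sum(lambda_m) = sum(lambda_f) * (1 - r)/r exactly.
    """
    if not (0.0 < target_ratio < 1.0):
        raise ValueError("target_ratio must lie in (0, 1)")
    lam_f = compute_intensity(stack, female).values
    total_f = np.nansum(lam_f)
    if not np.isfinite(total_f) or total_f <= 0:
        raise ValueError("female intensity sums to zero (empty or all-missing landscape)")
    eta_m = _linear_predictor(stack, male_slopes)
    log_total_m_base = np.log(np.nansum(np.exp(eta_m)))
    if not np.isfinite(log_total_m_base):
        raise ValueError("male base intensity sums to zero (empty or all-missing landscape)")
    intercept = (
        float(np.log(total_f)) - float(log_total_m_base)
        + float(np.log((1.0 - target_ratio) / target_ratio))
    )
    return SexParams("male", intercept, dict(male_slopes))


def realize_counts(intensity: Grid, seed: int) -> Grid:
    """Independent Poisson(lambda_j) sign counts per cell, reproducible under seed.

    Missing intensity yields zero counts (no habitat, no signs).
    """
    lam = intensity.values
    finite = np.isfinite(lam)
    if np.any(lam[finite] < 0):
        raise ValueError("intensity must be non-negative")
    if np.any(np.isinf(lam)):
        raise ValueError("intensity must be finite")
    rng = np.random.default_rng(seed)
    counts = np.zeros_like(lam)
    counts[finite] = rng.poisson(lam[finite])
    return replace(intensity, values=counts)
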