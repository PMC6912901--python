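"""Survey designs, distance-to-trajectory rasters, detection, and thinning.

Three designs are supported: uniform random points, systematic parallel
transects, and subjective (opportunistic) trajectories. For trajectory
designs, sign observation follows a monotone distance-decay detection
function p(d) = g(d)/g(0) built from a distance density g (cubic
log-density spline fitted to empirical sign-to-track distances, or an
exponential / half-normal parametric form). Simulated sign counts are
thinned cell-wise with Binomial(count_j, p_obs,j) draws and converted to
presence-only records (one row per observed sign, at the cell center).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

from .grid import Grid
from .landscape import Trajectory

__all__ = [
    "SurveyDesign",
    "DetectionModel",
    "systematic_transects",
    "random_points",
    "distance_to_trajectories",
    "fit_detection_model",
    "detection_probability",
    "thin_to_presences",
]


@dataclass(frozen=True)
class SurveyDesign:
    """Where sampling effort falls: a point set (random design) or a
    trajectory collection (systematic / subjective designs)."""

    kind: str  # random | systematic | subjective
    points: np.ndarray | None = None  # (n, 2), random kind only
    trajectories: list[Trajectory] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind == "random":
            if self.points is None or self.trajectories:
                raise ValueError("random design needs points and no trajectories")
        elif self.kind in ("systematic", "subjective"):
            if not self.trajectories or self.points is not None:
                raise ValueError(f"{self.kind} design needs trajectories and no points")
        else:
            raise ValueError(f"unknown design kind {self.kind!r}")

    @property
    def total_length(self) -> float:
        return float(sum(t.length for t in self.trajectories))


def systematic_transects(
    extent: tuple[float, float, float, float],
    spacing: float = 400.0,
    orientation: float = 90.0,
    seed: int | None = None,
    offset: float | None = None,
) -> SurveyDesign:
    """Parallel transects spanning the extent at a fixed spacing.

    ``orientation`` is the transect bearing in degrees (90 = north-south);
    the first-line offset across the transect direction is drawn uniformly
    in [0, spacing) under ``seed`` unless given explicitly. Lines are
    clipped to the extent. Defaults mirror a 400 m transect grid.
    """
    from shapely.geometry import LineString, box

    if spacing <= 0:
        raise ValueError("spacing must be positive")
    xmin, ymin, xmax, ymax = extent
    width = min(xmax - xmin, ymax - ymin)
    if spacing > max(xmax - xmin, ymax - ymin):
        warnings.warn("spacing exceeds the extent; a single transect is produced")
    theta = np.deg2rad(orientation)
    u = np.array([np.cos(theta), np.sin(theta)])  # along-transect
    nvec = np.array([-u[1], u[0]])  # across-transect
    corners = np.array([(xmin, ymin), (xmin, ymax), (xmax, ymin), (xmax, ymax)])
    proj = corners @ nvec
    pmin, pmax = proj.min(), proj.max()
    if offset is None:
        rng = np.random.default_rng(seed)
        offset = float(rng.uniform(0, spacing))
    clip = box(xmin, ymin, xmax, ymax)
    half = np.hypot(xmax - xmin, ymax - ymin)
    mid = corners.mean(axis=0)
    trajectories = []
    p = pmin + offset
    while p < pmax:
        center = mid + (p - mid @ nvec) * nvec
        line = LineString([center - half * u, center + half * u]).intersection(clip)
        if not line.is_empty and line.length > 0:
            trajectories.append(Trajectory(np.asarray(line.coords)))
        p += spacing
    if not trajectories:
        raise ValueError(f"no transects fall within the extent (width {width})")
    return SurveyDesign(kind="systematic", trajectories=trajectories)


def random_points(grid: Grid, n: int = 2_000, seed: int = 0) -> SurveyDesign:
    """``n`` i.i.d. uniform sample points over the non-missing cells."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not np.isfinite(grid.values).any():
        raise ValueError("grid has no non-missing cells")
    rng = np.random.default_rng(seed)
    xmin, ymin, xmax, ymax = grid.extent
    pts = np.empty((0, 2))
    while len(pts) < n:
        cand = rng.uniform([xmin, ymin], [xmax, ymax], size=(2 * (n - len(pts)) + 8, 2))
        row, col = grid.index_of(cand[:, 0], cand[:, 1])
        cand = cand[np.isfinite(grid.values[row, col])]
        pts = np.vstack([pts, cand])
    return SurveyDesign(kind="random", points=pts[:n])


def _min_segment_distance(px: np.ndarray, py: np.ndarray, design: SurveyDesign) -> np.ndarray:
    """Minimum Euclidean point-to-segment distance, vectorised and chunked."""
    starts = np.vstack([t.segments[0] for t in design.trajectories])
    ends = np.vstack([t.segments[1] for t in design.trajectories])
    seg = ends - starts
    seg_len2 = np.einsum("ij,ij->i", seg, seg)
    seg_len2 = np.where(seg_len2 == 0, 1.0, seg_len2)
    pts = np.column_stack([px, py])
    out = np.full(len(pts), np.inf)
    chunk = max(1, int(4e6 // max(1, len(starts))))
    for lo in range(0, len(pts), chunk):
        p = pts[lo : lo + chunk]
        d = p[:, None, :] - starts[None, :, :]
        t = np.clip(np.einsum("pij,ij->pi", d, seg) / seg_len2, 0.0, 1.0)
        closest = starts[None, :, :] + t[..., None] * seg[None, :, :]
        dist = np.sqrt(np.sum((p[:, None, :] - closest) ** 2, axis=-1))
        out[lo : lo + chunk] = dist.min(axis=1)
    return out


def distance_to_trajectories(grid: Grid, design: SurveyDesign) -> Grid:
    """Per-cell minimum distance (m) from cell center to any trajectory."""
    if not design.trajectories:
        raise ValueError("distance to trajectories is undefined for a point design")
    px, py = grid.cell_centers()
    dist = _min_segment_distance(px, py, design)
    return replace(grid, values=dist.reshape(grid.n_rows, grid.n_cols))


# ---------------------------------------------------------------------------
# Detection


@dataclass(frozen=True)
class DetectionModel:
    """Distance density g(d) on [0, truncation] and the induced detection
    probability p(d) = g(d)/g(0), with p(0) = 1 and p = 0 beyond truncation.
    """

    form: str  # empirical-spline | exponential | half-normal | point-mass
    truncation: float = 300.0
    params: dict = field(default_factory=dict)
    _grid_d: np.ndarray | None = None  # spline form: dense d grid
    _grid_g: np.ndarray | None = None  # spline form: density on the grid

    @classmethod
    def exponential(cls, rate: float, truncation: float = 300.0) -> "DetectionModel":
        return cls("exponential", truncation, {"rate": float(rate)})

    @classmethod
    def half_normal(cls, sigma: float, truncation: float = 300.0) -> "DetectionModel":
        return cls("half-normal", truncation, {"sigma": float(sigma)})

    @classmethod
    def point_mass(cls) -> "DetectionModel":
        """Degenerate density concentrated on the trajectory itself."""
        return cls("point-mass", 0.0, {})

    def density(self, d) -> np.ndarray:
        """g(d), unnormalised beyond a multiplicative constant."""
        d = np.asarray(d, dtype=float)
        if self.form == "exponential":
            g = self.params["rate"] * np.exp(-self.params["rate"] * d)
        elif self.form == "half-normal":
            s = self.params["sigma"]
            g = np.exp(-0.5 * (d / s) ** 2)
        elif self.form == "empirical-spline":
            g = np.interp(d, self._grid_d, self._grid_g)
        elif self.form == "point-mass":
            return np.where(d == 0, np.inf, 0.0)
        else:  # pragma: no cover
            raise ValueError(f"unknown detection form {self.form!r}")
        return np.where(d <= self.truncation, g, 0.0)

    def detection(self, d) -> np.ndarray:
        """p(d) = g(d)/g(0), clipped to [0, 1], 0 beyond truncation."""
        d = np.asarray(d, dtype=float)
        if np.any(d < 0):
            raise ValueError("distances must be non-negative")
        if self.form == "point-mass":
            return np.where(d == 0, 1.0, 0.0)
        g0 = float(self.density(0.0))
        if g0 <= 0:
            raise ValueError("detection model has zero density at distance 0")
        return np.clip(self.density(d) / g0, 0.0, 1.0)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` distances from g on [0, truncation] (inverse CDF)."""
        if self.form == "point-mass":
            return np.zeros(n)
        d = np.linspace(0, self.truncation, 4096)
        g = self.density(d)
        cdf = np.cumsum((g[1:] + g[:-1]) / 2 * np.diff(d))
        cdf = np.concatenate([[0.0], cdf])
        cdf /= cdf[-1]
        return np.interp(rng.uniform(size=n), cdf, d)


def detection_probability(model: DetectionModel, d) -> np.ndarray:
    """Detection probability p(d) in [0, 1]; rejects negative distances."""
    return model.detection(d)


def fit_detection_model(distances, form: str = "empirical-spline",
                        truncation: float = 300.0) -> DetectionModel:
    """Fit a distance density to empirical sign-to-trajectory distances.

    Parametric forms use the closed-form MLE (exponential: rate = 1/mean;
    half-normal: sigma^2 = mean(d^2)). The empirical-spline form fits a
    cubic B-spline to the log-density via a Poisson regression on binned
    counts, emulating a logspline density estimate.
    """
    if truncation <= 0:
        raise ValueError("truncation must be positive")
    d = np.asarray(distances, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    n_beyond = int(np.sum(d > truncation))
    if n_beyond:
        warnings.warn(f"dropping {n_beyond} distances beyond the {truncation} m truncation")
        d = d[d <= truncation]
    if d.size == 0:
        raise ValueError("no distances within truncation")
    if form == "exponential":
        mean = d.mean()
        if mean == 0:
            raise ValueError("all distances are zero; exponential MLE undefined")
        return DetectionModel.exponential(1.0 / mean, truncation)
    if form == "half-normal":
        ms = np.mean(d**2)
        if ms == 0:
            raise ValueError("all distances are zero; half-normal MLE undefined")
        return DetectionModel.half_normal(np.sqrt(ms), truncation)
    if form != "empirical-spline":
        raise ValueError(f"unknown detection form {form!r}")
    if d.size < 20:
        raise ValueError("empirical-spline form needs >= 20 distances")
    if np.ptp(d) == 0:
        raise ValueError("all distances identical; spline density undefined")

    import statsmodels.api as sm

    n_bins = 20
    counts, edges = np.histogram(d, bins=n_bins, range=(0.0, truncation))
    mids = (edges[:-1] + edges[1:]) / 2
    # cubic B-spline basis, modest flexibility (4 interior-free columns)
    k = 3
    inner = np.quantile(d, [1 / 3, 2 / 3])
    knots = np.concatenate([[0.0] * (k + 1), inner, [truncation] * (k + 1)])
    design = BSpline.design_matrix(mids, knots, k).toarray()
    fit = sm.GLM(counts, design, family=sm.families.Poisson()).fit()
    grid_d = np.linspace(0.0, truncation, 512)
    basis = BSpline.design_matrix(np.clip(grid_d, 0, truncation), knots, k).toarray()
    g = np.exp(basis @ fit.params)
    g /= np.trapezoid(g, grid_d)
    return DetectionModel("empirical-spline", truncation, {"n": int(d.size)},
                          _grid_d=grid_d, _grid_g=g)


# ---------------------------------------------------------------------------
# Thinning to presence-only records


def sampled_cell_mask(grid: Grid, design: SurveyDesign) -> np.ndarray:
    """Boolean mask of cells containing at least one random sample point."""
    if design.points is None:
        raise ValueError("sampled-cell mask requires a point design")
    mask = np.zeros(grid.values.shape, dtype=bool)
    row, col = grid.index_of(design.points[:, 0], design.points[:, 1])
    mask[row, col] = True
    return mask


def thin_to_presences(
    counts: Grid,
    design: SurveyDesign,
    model: DetectionModel | None = None,
    seed: int = 0,
    sex: str = "unknown",
    distance: Grid | None = None,
) -> pd.DataFrame:
    """Thin simulated sign counts into presence-only records.

    Each cell's observed count is Binomial(count_j, p_obs,j): for trajectory
    designs p_obs,j = p(d_j) from the detection model; for the random design
    p_obs,j is 1 in sampled cells and 0 elsewhere. Cells with zero observed
    signs are dropped; each observed sign becomes one (x, y, sex) row at the
    cell center (duplicates retained).
    """
    c = counts.values
    if np.any(np.isfinite(c) & ((c < 0) | (c != np.round(c)))):
        raise ValueError("counts must be non-negative integers")
    if design.kind == "random":
        p = sampled_cell_mask(counts, design).astype(float)
    else:
        if model is None:
            raise ValueError("trajectory designs require a detection model")
        if distance is None:
            distance = distance_to_trajectories(counts, design)
        elif not counts.same_geometry(distance):
            raise ValueError("distance grid geometry does not match the count grid")
        p = model.detection(distance.values)
    rng = np.random.default_rng(seed)
    n = np.where(np.isfinite(c), c, 0).astype(int)
    observed = rng.binomial(n, p)
    rows, cols = np.nonzero(observed)
    reps = observed[rows, cols]
    x0, y0 = counts.origin
    xs = np.repeat(x0 + (cols + 0.5) * counts.cell_size, reps)
    ys = np.repeat(y0 + (rows + 0.5) * counts.cell_size, reps)
    return pd.DataFrame({"x": xs, "y": ys, "sex": sex})
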