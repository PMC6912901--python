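"""Synthetic landscapes and observer trajectories.

The covariate generator emulates LiDAR-derived terrain/vegetation rasters:
spatially autocorrelated Gaussian random fields (circulant-embedding FFT
simulation with an exponential correlogram) that are standardized and then
linearly mixed so that the realized pairwise Pearson correlations between
layers equal a prescribed low-correlation target exactly.

The subjective-trajectory generator emulates opportunistic GNSS survey
tracks: a correlated random walk whose step-direction choice up-weights
cells with higher values of a habitat-preference grid, producing survey
effort concentrated in preferred habitat.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass

import numpy as np

from .grid import CovariateStack, Grid, standardize

__all__ = [
    "Trajectory",
    "generate_covariates",
    "generate_subjective_trajectory",
    "default_landscape",
    "read_trajectories",
    "write_trajectories",
]


@dataclass(frozen=True)
class Trajectory:
    """An ordered polyline of survey-track vertices, coordinates in metres."""

    vertices: np.ndarray  # shape (n, 2)

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[0] < 2 or v.shape[1] != 2:
            raise ValueError("a trajectory needs >= 2 (x, y) vertices")
        object.__setattr__(self, "vertices", v)

    @property
    def length(self) -> float:
        """Total polyline length in metres."""
        return float(np.sum(np.hypot(*np.diff(self.vertices, axis=0).T)))

    @property
    def segments(self) -> tuple[np.ndarray, np.ndarray]:
        """(start, end) arrays of shape (n_segments, 2)."""
        return self.vertices[:-1], self.vertices[1:]


# ---------------------------------------------------------------------------
# Gaussian random fields


def _grf_exponential(n_rows: int, n_cols: int, spatial_range: float, rng: np.random.Generator) -> np.ndarray:
    """One stationary Gaussian field with correlogram exp(-h/range).

    Circulant embedding on a 2x padded torus; tiny negative embedding
    eigenvalues (discretisation artefacts) are clipped to zero.
    """
    if spatial_range <= 0:
        return rng.standard_normal((n_rows, n_cols))
    m, n = 2 * n_rows, 2 * n_cols
    dr = np.minimum(np.arange(m), m - np.arange(m))
    dc = np.minimum(np.arange(n), n - np.arange(n))
    dist = np.hypot(dr[:, None], dc[None, :])
    cov = np.exp(-dist / spatial_range)
    lam = np.fft.fft2(cov).real
    lam = np.clip(lam, 0.0, None)
    noise = rng.standard_normal((m, n)) + 1j * rng.standard_normal((m, n))
    field = np.fft.fft2(np.sqrt(lam / (m * n)) * noise)
    return field.real[:n_rows, :n_cols]


def generate_covariates(
    n_rows: int,
    n_cols: int,
    n_layers: int = 3,
    spatial_range: float = 300.0,
    target_correlation: np.ndarray | None = None,
    seed: int = 0,
    cell_size: float = 25.0,
    names: list[str] | None = None,
) -> CovariateStack:
    """Generate standardized, cross-correlated covariate rasters.

    Parameters
    ----------
    spatial_range : float
        Range (metres) of the exponential correlogram governing within-layer
        spatial autocorrelation; 0 gives i.i.d. cells.
    target_correlation : (n_layers, n_layers) array, optional
        Desired pairwise Pearson correlation between layers (symmetric
        positive-definite, unit diagonal). Identity if omitted. The layers
        are empirically whitened and re-mixed with the Cholesky factor of
        this matrix, so realized correlations match the target exactly.
    names : list of str, optional
        Layer names; defaults to slope, canopy, simpson (then x4, x5, ...).

    Returns
    -------
    CovariateStack
        Standardized stack (each layer mean 0, sd 1).
    """
    if n_layers < 1:
        raise ValueError("n_layers must be >= 1")
    if spatial_range < 0:
        raise ValueError("spatial_range must be >= 0")
    if target_correlation is None:
        target_correlation = np.eye(n_layers)
    target = np.asarray(target_correlation, dtype=float)
    if target.shape != (n_layers, n_layers):
        raise ValueError("target_correlation must be n_layers x n_layers")
    if not np.allclose(target, target.T) or not np.allclose(np.diag(target), 1.0):
        raise ValueError("target_correlation must be symmetric with unit diagonal")
    try:
        chol = np.linalg.cholesky(target)
    except np.linalg.LinAlgError as err:
        raise ValueError(
            "target_correlation is not positive-definite "
            f"(eigenvalues {np.linalg.eigvalsh(target)})"
        ) from err

    rng = np.random.default_rng(seed)
    fields = np.stack(
        [_grf_exponential(n_rows, n_cols, spatial_range / cell_size, rng) for _ in range(n_layers)],
        axis=-1,
    )
    flat = fields.reshape(-1, n_layers)
    flat = (flat - flat.mean(axis=0)) / flat.std(axis=0)
    # empirical whitening, then mixing: realized correlation == target exactly
    emp_chol = np.linalg.cholesky(np.cov(flat.T, bias=True).reshape(n_layers, n_layers))
    mixed = flat @ np.linalg.inv(emp_chol).T @ chol.T

    default_names = ["slope", "canopy", "simpson"] + [f"x{i + 1}" for i in range(3, n_layers)]
    names = names or default_names[:n_layers]
    grids = {
        name: Grid(mixed[:, i].reshape(n_rows, n_cols), cell_size=cell_size)
        for i, name in enumerate(names)
    }
    stack = CovariateStack(grids)
    return standardize(stack)


def default_landscape(seed: int = 0) -> CovariateStack:
    """The default experimental landscape: 145x145 cells of 25 m (~13 km²),
    three layers (slope, canopy, simpson) with low pairwise correlation
    (0.18, 0.12, 0.21) matching LiDAR-derived terrain variables."""
    target = np.array(
        [
            [1.0, 0.21, 0.18],  # slope/canopy, slope/simpson
            [0.21, 1.0, 0.12],  # canopy/simpson
            [0.18, 0.12, 1.0],
        ]
    )
    return generate_covariates(145, 145, 3, spatial_range=300.0, target_correlation=target, seed=seed)


# ---------------------------------------------------------------------------
# Subjective trajectories


def generate_subjective_trajectory(
    preference: Grid,
    total_length: float = 31_200.0,
    step: float = 25.0,
    bias_strength: float = 5.0,
    seed: int = 0,
    n_candidates: int = 24,
    persistence: float = 1.0,
) -> list[Trajectory]:
    """Simulate an opportunistic survey track as a biased correlated random walk.

    At each step, ``n_candidates`` headings are scored by
    ``persistence * cos(turn) + bias_strength * z`` where z is the
    preference value (standardized over the grid) at the candidate endpoint;
    a heading is sampled from the softmax of the scores. ``bias_strength 0``
    with ``persistence 0`` is a uniform random walk; the default total
    length of 31.2 km mirrors a realistic cumulative survey effort.

    Returns a one-element list (a trajectory collection) whose realized
    length is within one step of ``total_length``.
    """
    if not (total_length > step > 0):
        raise ValueError("need total_length > step > 0")
    xmin, ymin, xmax, ymax = preference.extent
    if step > min(xmax - xmin, ymax - ymin):
        raise ValueError("step larger than the landscape extent")
    pref = preference.values
    finite = np.isfinite(pref)
    if not finite.any():
        raise ValueError("preference grid has no finite cells")
    mu, sd = np.nanmean(pref), np.nanstd(pref)
    z = (pref - mu) / (sd if sd > 0 else 1.0)
    z = np.where(np.isfinite(z), z, -np.inf)  # missing habitat is never entered

    rng = np.random.default_rng(seed)
    n_steps = int(round(total_length / step))
    pos = np.array(
        [rng.uniform(xmin + step, xmax - step), rng.uniform(ymin + step, ymax - step)]
    )
    heading = rng.uniform(0, 2 * np.pi)
    angles = np.linspace(-np.pi, np.pi, n_candidates, endpoint=False)
    verts = [pos.copy()]
    for _ in range(n_steps):
        cand_dir = heading + angles
        cx = pos[0] + step * np.cos(cand_dir)
        cy = pos[1] + step * np.sin(cand_dir)
        ok = (cx > xmin) & (cx < xmax) & (cy > ymin) & (cy < ymax)
        if not ok.any():  # cornered: jump back toward the interior
            heading += np.pi
            continue
        row = np.clip(((cy - ymin) // preference.cell_size).astype(int), 0, preference.n_rows - 1)
        col = np.clip(((cx - xmin) // preference.cell_size).astype(int), 0, preference.n_cols - 1)
        score = persistence * np.cos(angles) + bias_strength * z[row, col]
        score = np.where(ok, score, -np.inf)
        score -= score.max()
        prob = np.exp(score)
        prob /= prob.sum()
        k = rng.choice(n_candidates, p=prob)
        heading = cand_dir[k]
        pos = np.array([cx[k], cy[k]])
        verts.append(pos.copy())
    return [Trajectory(np.array(verts))]


# ---------------------------------------------------------------------------
# Trajectory I/O (GeoJSON LineString features, or vertex CSV)


def write_trajectories(trajectories: list[Trajectory], path, fmt: str | None = None) -> None:
    """Write trajectories as GeoJSON (one LineString feature each) or CSV
    (columns trajectory_id, vertex_index, x, y). Format inferred from the
    file suffix when ``fmt`` is omitted."""
    fmt = fmt or ("csv" if str(path).endswith(".csv") else "geojson")
    if fmt == "geojson":
        features = [
            {
                "type": "Feature",
                "properties": {"trajectory_id": i},
                "geometry": {"type": "LineString", "coordinates": t.vertices.tolist()},
            }
            for i, t in enumerate(trajectories)
        ]
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": features}, fh)
    elif fmt == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["trajectory_id", "vertex_index", "x", "y"])
            for i, t in enumerate(trajectories):
                for j, (x, y) in enumerate(t.vertices):
                    writer.writerow([i, j, repr(float(x)), repr(float(y))])
    else:
        raise ValueError(f"unknown trajectory format {fmt!r}")


def read_trajectories(path, fmt: str | None = None) -> list[Trajectory]:
    """Read trajectories written by :func:`write_trajectories`."""
    fmt = fmt or ("csv" if str(path).endswith(".csv") else "geojson")
    if fmt == "geojson":
        with open(path) as fh:
            data = json.load(fh)
        if data.get("type") != "FeatureCollection":
            raise ValueError(f"{path}: not a GeoJSON FeatureCollection")
        out = []
        for i, feat in enumerate(data.get("features", [])):
            geom = feat.get("geometry", {})
            if geom.get("type") != "LineString":
                raise ValueError(f"{path}: feature {i} is not a LineString")
            out.append(Trajectory(np.asarray(geom["coordinates"], dtype=float)))
        return out
    if fmt == "csv":
        rows: dict[int, list[tuple[int, float, float]]] = {}
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            for lineno, rec in enumerate(reader, start=2):
                try:
                    tid = int(rec["trajectory_id"])
                    rows.setdefault(tid, []).append(
                        (int(rec["vertex_index"]), float(rec["x"]), float(rec["y"]))
                    )
                except (KeyError, TypeError, ValueError) as err:
                    raise ValueError(f"{path}: malformed row at line {lineno}") from err
        out = []
        for tid in sorted(rows):
            pts = sorted(rows[tid])
            out.append(Trajectory(np.array([(x, y) for _, x, y in pts])))
        return out
    raise ValueError(f"unknown trajectory format {fmt!r}")
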