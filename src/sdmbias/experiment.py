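"""Replicated virtual-species experiment driver.

One experiment run wires the whole pipeline together: a synthetic
landscape, sex-specific intensity surfaces with the male intercept
calibrated to the target sex ratio, fixed survey designs (uniform random
points, systematic transects, a habitat-biased subjective trajectory),
fixed background point sets, and then ``n_replicates`` independent
realizations of sign counts, detection thinning, SDM fits per correction
and per model (female, male, generic), parameter biases, Spearman map
correlations, cross-validated AUCs and sex-ratio estimates.

Survey designs and background locations are held fixed across replicates
within a scenario; only the species realization and thinning are
re-randomized. All randomness derives from one master seed.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimation import (
    detection_grid,
    sex_ratio_from_models,
    sex_ratio_from_observations,
)
from .evaluation import cv_auc, parameter_bias, spearman_map_correlation
from .grid import CovariateStack
from .landscape import generate_covariates, generate_subjective_trajectory
from .sdm import PresenceOnlySDM, targeted_background, uniform_background
from .species import (
    SexParams,
    calibrate_male_intercept,
    compute_intensity,
    default_params,
    realize_counts,
)
from .survey import (
    DetectionModel,
    SurveyDesign,
    distance_to_trajectories,
    random_points,
    systematic_transects,
    thin_to_presences,
)

__all__ = ["ExperimentConfig", "ExperimentResult", "run_experiment"]

_DEFAULT_CORRELATION = (
    (1.0, 0.21, 0.18),
    (0.21, 1.0, 0.12),
    (0.18, 0.12, 1.0),
)


@dataclass
class ExperimentConfig:
    """Study conditions for one replicated experiment."""

    n_rows: int = 145
    n_cols: int = 145
    cell_size: float = 25.0
    spatial_range: float = 300.0
    target_correlation: tuple = _DEFAULT_CORRELATION
    female: SexParams | None = None  # defaults to the shipped female params
    male_slopes: dict | None = None  # defaults to the shipped male slopes
    target_ratio: float = 0.5
    designs: tuple = ("random", "systematic", "subjective")
    corrections: tuple = ("none", "targeted", "distance")
    n_replicates: int = 100
    n_random_points: int = 2_000
    transect_spacing: float = 400.0
    subjective_length: float = 31_200.0
    subjective_bias_strength: float = 2.0
    subjective_persistence: float = 2.0
    walk_step: float = 25.0
    detection_sigma: float = 10.0  # half-normal scale of true detectability, m
    detection_truncation: float = 300.0
    n_background: int = 10_000
    include_generic: bool = True
    compute_auc: bool = True
    auc_folds: int = 10

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.female is None:
            self.female = default_params("female")
        if self.male_slopes is None:
            self.male_slopes = dict(default_params("male").slopes)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "female" in raw and isinstance(raw["female"], dict):
            raw["female"] = SexParams("female", raw["female"]["intercept"],
                                      dict(raw["female"]["slopes"]))
        for key in ("designs", "corrections", "target_correlation"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(tuple(v) if isinstance(v, list) else v for v in raw[key])
        return cls(**raw)


@dataclass
class ExperimentResult:
    """Long-format result tables plus study-level metadata."""

    fits: pd.DataFrame  # one row per replicate x design x correction x model
    ratios: pd.DataFrame  # one row per replicate x design x ratio method
    true_ratio: float  # expected female share of total intensity
    stack: CovariateStack = field(repr=False)
    female: SexParams = field(repr=False)
    male: SexParams = field(repr=False)

    def summary_params(self, model: str = "female") -> pd.DataFrame:
        """Mean and sd of coefficient estimates per design x correction."""
        sub = self.fits[self.fits["model"] == model]
        cols = [c for c in sub.columns if c.startswith("est_")]
        return sub.groupby(["design", "correction"])[cols].agg(["mean", "std"])

    def summary_spearman(self) -> pd.DataFrame:
        """Mean and sd of Spearman map correlations per scenario/comparison."""
        rows = []
        for comp in ("rho_female", "rho_male"):
            sub = self.fits.dropna(subset=[comp])
            g = sub.groupby(["design", "correction", "model"])[comp].agg(["mean", "std"])
            g["comparison"] = comp.removeprefix("rho_")
            rows.append(g.reset_index())
        return pd.concat(rows, ignore_index=True)

    def summary_ratios(self) -> pd.DataFrame:
        """Median and quartiles of the sex-ratio estimates per scenario."""
        return (
            self.ratios.groupby(["design", "method"])["ratio"]
            .agg(median="median", q25=lambda s: s.quantile(0.25), q75=lambda s: s.quantile(0.75))
            .reset_index()
        )

    def write(self, directory) -> None:
        import os

        os.makedirs(directory, exist_ok=True)
        self.fits.to_csv(os.path.join(directory, "results.csv"), index=False)
        self.ratios.to_csv(os.path.join(directory, "ratios.csv"), index=False)
        self.summary_params().to_csv(os.path.join(directory, "summary_params.csv"))
        self.summary_spearman().to_csv(os.path.join(directory, "summary_spearman.csv"), index=False)
        self.summary_ratios().to_csv(os.path.join(directory, "summary_ratios.csv"), index=False)


def _seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


def run_experiment(config: ExperimentConfig, seed: int = 0, progress: bool = False) -> ExperimentResult:
    """Run the full replicated study under one master seed."""
    master = np.random.SeedSequence(seed)
    s_land, s_design, s_background, s_reps, s_auc = master.spawn(5)

    stack = generate_covariates(
        config.n_rows, config.n_cols, 3,
        spatial_range=config.spatial_range,
        target_correlation=np.asarray(config.target_correlation, dtype=float),
        seed=_seed(s_land), cell_size=config.cell_size,
    )
    ref = stack.reference
    female = config.female
    male = calibrate_male_intercept(stack, female, config.male_slopes, config.target_ratio)
    lam = {"female": compute_intensity(stack, female), "male": compute_intensity(stack, male)}
    truth = {"female": female, "male": male}
    detection = DetectionModel.half_normal(config.detection_sigma, config.detection_truncation)

    # --- fixed survey designs -------------------------------------------------
    d_design = dict(zip(("random", "systematic", "subjective"), s_design.spawn(3)))
    designs = {}
    if "random" in config.designs:
        designs["random"] = random_points(ref, config.n_random_points, seed=_seed(d_design["random"]))
    if "systematic" in config.designs:
        designs["systematic"] = systematic_transects(ref.extent, config.transect_spacing,
                                                     seed=_seed(d_design["systematic"]))
    if "subjective" in config.designs:
        # observers preferentially walk male-preferred habitat (preference =
        # male log-intensity): the scenario in which sampling effort is
        # spatially biased toward one sex
        from dataclasses import replace as _replace

        pref = _replace(lam["male"], values=np.log(lam["male"].values))
        walk = generate_subjective_trajectory(
            pref, total_length=config.subjective_length, step=config.walk_step,
            bias_strength=config.subjective_bias_strength,
            persistence=config.subjective_persistence,
            seed=_seed(d_design["subjective"]),
        )
        designs["subjective"] = SurveyDesign(kind="subjective", trajectories=walk)

    distances = {
        name: distance_to_trajectories(ref, des)
        for name, des in designs.items()
        if des.trajectories
    }

    # --- fixed background sets (shared across replicates, per scenario) ------
    backgrounds: dict[tuple[str, str], object] = {}
    eval_backgrounds: dict[str, object] = {}
    bg_children = iter(s_background.spawn(4 * len(designs) + 4))
    for name, des in designs.items():
        uni = uniform_background(ref, config.n_background, seed=_seed(next(bg_children)))
        backgrounds[(name, "none")] = uni
        backgrounds[(name, "distance")] = uni
        if des.trajectories:
            backgrounds[(name, "targeted")] = targeted_background(
                des, detection, config.n_background, seed=_seed(next(bg_children)),
                extent=ref.extent,
            )
            eval_backgrounds[name] = targeted_background(
                des, detection, config.n_background, seed=_seed(next(bg_children)),
                extent=ref.extent,
            )
        else:
            eval_backgrounds[name] = uniform_background(ref, config.n_background,
                                                        seed=_seed(next(bg_children)))

    models = ["female", "male"] + (["generic"] if config.include_generic else [])
    fit_rows: list[dict] = []
    ratio_rows: list[dict] = []
    rep_seeds = s_reps.spawn(config.n_replicates)
    auc_seed = _seed(s_auc)

    for rep in range(config.n_replicates):
        t0 = time.perf_counter()
        rs = rep_seeds[rep].spawn(4)
        counts = {
            "female": realize_counts(lam["female"], _seed(rs[0])),
            "male": realize_counts(lam["male"], _seed(rs[1])),
        }
        total_f = float(np.nansum(counts["female"].values))
        total_m = float(np.nansum(counts["male"].values))
        ratio_rows.append({"replicate": rep, "design": "(all simulated)", "method": "truth",
                           "ratio": total_f / (total_f + total_m),
                           "n_obs_female": total_f, "n_obs_male": total_m,
                           "n_tot_female": np.nan, "n_tot_male": np.nan})

        thin_children = iter(rs[2].spawn(2 * len(designs)))
        for dname, des in designs.items():
            records = {
                sex: thin_to_presences(
                    counts[sex], des,
                    model=detection if des.trajectories else None,
                    seed=_seed(next(thin_children)), sex=sex,
                    distance=distances.get(dname),
                )
                for sex in ("female", "male")
            }
            records["generic"] = pd.concat([records["female"], records["male"]],
                                           ignore_index=True)
            try:
                obs = sex_ratio_from_observations(records["generic"])
                ratio_rows.append({"replicate": rep, "design": dname, "method": "observations",
                                   "ratio": obs.ratio, "n_obs_female": obs.n_obs_female,
                                   "n_obs_male": obs.n_obs_male,
                                   "n_tot_female": np.nan, "n_tot_male": np.nan})
            except ValueError as err:
                ratio_rows.append({"replicate": rep, "design": dname, "method": "observations",
                                   "ratio": np.nan, "error": str(err)})

            corrections = config.corrections if des.trajectories else ("none",)
            for corr in corrections:
                fits = {}
                for mdl in models:
                    row = {"replicate": rep, "design": dname, "correction": corr, "model": mdl}
                    try:
                        m = PresenceOnlySDM(
                            records[mdl], backgrounds[(dname, corr)], stack,
                            distance=distances.get(dname) if corr == "distance" else None,
                        )
                        res = m.fit()
                        fits[mdl] = res
                        row["n_obs"] = len(records[mdl])
                        for name, val in res.coefficients.items():
                            row[f"est_{name}"] = float(val)
                        if res.distance_coefficient is not None:
                            row["beta_d"] = res.distance_coefficient
                        if mdl in truth:
                            for name, b in parameter_bias(res, truth[mdl]).items():
                                row[f"bias_{name}"] = float(b)
                        mu = res.predict_relative_abundance(zero_distance=True)
                        with warnings.catch_warnings():
                            warnings.simplefilter("ignore")
                            if mdl in ("female", "generic"):
                                row["rho_female"] = spearman_map_correlation(mu, lam["female"])
                            if mdl in ("male", "generic"):
                                row["rho_male"] = spearman_map_correlation(mu, lam["male"])
                        if config.compute_auc:
                            with warnings.catch_warnings():
                                warnings.simplefilter("ignore")
                                auc_mean, auc_var = cv_auc(
                                    records[mdl], eval_backgrounds[dname], res,
                                    distance=distances.get(dname), k=config.auc_folds,
                                    seed=auc_seed,
                                )
                            row["auc_mean"], row["auc_var"] = auc_mean, auc_var
                    except (ValueError, RuntimeError) as err:
                        row["error"] = str(err)
                    fit_rows.append(row)

                # model-based sex ratio for this design x correction
                rrow = {"replicate": rep, "design": dname, "method": f"model-{corr}"}
                try:
                    if "female" not in fits or "male" not in fits:
                        raise ValueError("missing per-sex fit")
                    p_obs = {}
                    for sex in ("female", "male"):
                        if des.kind == "random":
                            p_obs[sex] = detection_grid("sampled-cells", design=des, grid=ref)
                        elif corr == "distance":
                            with warnings.catch_warnings():
                                warnings.simplefilter("ignore")
                                p_obs[sex] = detection_grid(
                                    "distance-model", distance=distances[dname], fit=fits[sex]
                                )
                        else:  # none and targeted use the detection density
                            p_obs[sex] = detection_grid(
                                "detection-density", distance=distances[dname], model=detection
                            )
                    est = sex_ratio_from_models(
                        len(records["female"]), len(records["male"]),
                        fits["female"].predict_relative_abundance(zero_distance=True),
                        fits["male"].predict_relative_abundance(zero_distance=True),
                        p_obs["female"], p_obs["male"], method=f"model-{corr}",
                    )
                    rrow.update({"ratio": est.ratio, "n_obs_female": est.n_obs_female,
                                 "n_obs_male": est.n_obs_male,
                                 "n_tot_female": est.n_tot_female,
                                 "n_tot_male": est.n_tot_male})
                except (ValueError, RuntimeError) as err:
                    rrow.update({"ratio": np.nan, "error": str(err)})
                ratio_rows.append(rrow)
        if progress:
            print(f"replicate {rep + 1}/{config.n_replicates} "
                  f"({time.perf_counter() - t0:.2f} s)", flush=True)

    return ExperimentResult(
        fits=pd.DataFrame(fit_rows),
        ratios=pd.DataFrame(ratio_rows),
        true_ratio=config.target_ratio,
        stack=stack,
        female=female,
        male=male,
    )
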