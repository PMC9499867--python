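"""Seeded synthetic cohort generator with known ground truth.

The generator emulates the statistical structure of a middle-aged,
cognitively unimpaired research cohort enriched for amyloid pathology:

* a latent amyloid burden on the Centiloid axis, drawn from a right-skewed
  mixture — a majority component centred near 0 CL and a pathological
  minority with a gamma tail extending well past 30 CL; membership in the
  pathological component is more likely with age and APOE-e4 carriership;
* CSF Abeta42/40 as a monotone-decreasing sigmoid of latent burden with
  multiplicative lognormal noise, calibrated at generation time so the
  realized amyloid-positive fraction matches the configured target;
* each plasma biomarker as a monotone sigmoid of latent burden (in log10
  space) times lognormal noise and age/sex effects, with staggered
  midpoints so the markers become abnormal in a known order;
* observed PET Centiloids as latent burden plus measurement noise, with a
  configurable availability fraction;
* a 3-year follow-up with burden-dependent Centiloid accumulation and
  cognitive decline coupled to baseline p-tau231 in amyloid-positive
  participants (configurable interaction strength).

A single master seed expands into fixed, named child streams so that
adding or removing one biomarker never perturbs the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.optimize import brentq

from . import config as cfg
from . import schema

LN10 = np.log(10.0)

# fixed child-stream registry: order is part of the generator's contract
_STREAMS = {
    "demographics": 0,
    "latent": 1,
    "csf": 2,
    "pet": 3,
    "followup": 4,
    "plasma_ptau181": 10,
    "plasma_ptau217": 11,
    "plasma_ptau231": 12,
    "plasma_gfap": 13,
    "plasma_nfl": 14,
    "plasma_ab4240": 15,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],)))


def _sigma_log10(cv: float) -> float:
    """log10-scale SD of multiplicative lognormal noise with the given CV."""
    return np.sqrt(np.log1p(cv * cv)) / LN10


@dataclass(frozen=True)
class TrajectorySpec:
    """Ground-truth sigmoid trajectory of one biomarker vs latent Centiloids.

    In log10 space the noiseless curve is::

        log10(level) = log10(baseline)
                       + log10(fold_change) * expit((CL - midpoint) / width)

    so ``baseline`` is the healthy asymptote, ``baseline * fold_change``
    the pathological asymptote and ``midpoint`` the Centiloid value of
    half-maximal change.  ``cv`` is the residual coefficient of variation
    of the multiplicative noise; ``age_coef``/``sex_coef`` are additive
    log10 effects (per year of age / for female sex).
    """

    name: str
    baseline: float
    midpoint: float
    width: float
    fold_change: float
    cv: float
    age_coef: float = 0.0
    sex_coef: float = 0.0

    def log10_curve(self, cl) -> np.ndarray:
        cl = np.asarray(cl, dtype=float)
        return (np.log10(self.baseline)
                + np.log10(self.fold_change) * expit((cl - self.midpoint) / self.width))

    def validate(self, direction: int) -> None:
        if not np.isfinite(self.midpoint):
            raise ValueError(f"{self.name}: midpoint must be finite")
        if self.width <= 0 or self.baseline <= 0 or self.cv < 0:
            raise ValueError(f"{self.name}: width/baseline must be > 0, cv >= 0")
        if direction > 0 and self.fold_change < 1:
            raise ValueError(f"{self.name}: increasing marker needs fold_change >= 1")
        if direction < 0 and self.fold_change > 1:
            raise ValueError(f"{self.name}: decreasing marker needs fold_change <= 1")


def default_trajectories() -> dict[str, TrajectorySpec]:
    """Staggered defaults: p-tau231 earliest, then p-tau217, then GFAP;
    p-tau181, NfL and Abeta42/40 never reach the 2-SD threshold."""
    return {
        "plasma_ptau231": TrajectorySpec("plasma_ptau231", 8.0, 21.0, 10.0, 2.5, 0.25,
                                         age_coef=0.004, sex_coef=-0.01),
        "plasma_ptau217": TrajectorySpec("plasma_ptau217", 0.30, 33.0, 12.0, 2.8, 0.28,
                                         age_coef=0.004, sex_coef=-0.01),
        "plasma_gfap": TrajectorySpec("plasma_gfap", 130.0, 40.0, 10.0, 1.9, 0.25,
                                      age_coef=0.008, sex_coef=0.04),
        "plasma_ptau181": TrajectorySpec("plasma_ptau181", 10.0, 45.0, 12.0, 1.5, 0.30,
                                         age_coef=0.005, sex_coef=0.0),
        "plasma_nfl": TrajectorySpec("plasma_nfl", 12.0, 70.0, 15.0, 1.3, 0.35,
                                     age_coef=0.010, sex_coef=-0.02),
        "plasma_ab4240": TrajectorySpec("plasma_ab4240", 0.092, 28.0, 10.0, 0.87, 0.08,
                                        age_coef=-0.0005, sex_coef=0.0),
    }


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort; defaults emulate the study cohort
    (n=397, age 61.1 +/- 4.67 years, ~34% amyloid-positive by CSF)."""

    n: int = 397
    seed: int = 0
    prop_abeta_pos: float = 0.34
    age_mean: float = 61.1
    age_sd: float = 4.67
    age_min: float = 48.0
    age_max: float = 75.0
    female_fraction: float = 0.61
    apoe_e4_prevalence: float = 0.50
    education_mean: float = 13.5
    education_sd: float = 3.5

    # latent amyloid burden (Centiloid axis)
    path_fraction: float = 0.36
    path_logit_age: float = 0.10      # per year, on path-membership logit
    path_logit_apoe: float = 1.6      # carrier effect on path-membership logit
    normal_cl_mean: float = -1.0
    normal_cl_sd: float = 5.5
    path_gamma_shape: float = 0.51
    path_gamma_scale: float = 35.9

    # CSF Abeta42/40: decreasing sigmoid of latent CL, midpoint calibrated
    csf_ratio_high: float = 0.118
    csf_ratio_low: float = 0.046
    csf_ratio_width: float = 3.5
    csf_ratio_cv: float = 0.12

    # CSF M-p-tau181
    csf_tau_baseline: float = 15.5
    csf_tau_midpoint: float = 32.0
    csf_tau_width: float = 12.0
    csf_tau_fold: float = 2.2
    csf_tau_cv: float = 0.24
    csf_tau_age_coef: float = 0.004

    # observed PET
    pet_fraction: float = 339 / 397
    pet_noise_sd: float = 2.0

    trajectories: dict[str, TrajectorySpec] = field(default_factory=default_trajectories)

    # follow-up
    followup_cog_fraction: float = 214 / 397
    followup_pet_fraction: float = 145 / 397
    cog_interval_mean: float = 3.26
    cog_interval_sd: float = 0.31
    pet_interval_mean: float = 3.37
    pet_interval_sd: float = 0.44
    #: PACC-z decline per year per SD of log p-tau231 in amyloid-positives
    interaction_strength: float = 0.10
    base_decline: float = 0.03
    slope_noise: float = 0.12
    subtest_noise: float = 0.25
    cl_rate_base: float = 0.25
    cl_rate_max: float = 2.5
    cl_rate_midpoint: float = 15.0
    cl_rate_width: float = 8.0
    cl_rate_noise: float = 0.35

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        """Load a config from a plain-text key: value (YAML) file.

        Biomarker trajectories appear under ``trajectories`` as mappings of
        column name to TrajectorySpec fields; unspecified biomarkers keep
        their defaults.
        """
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        traj_raw = raw.pop("trajectories", {})
        cfg_obj = cls(**raw)
        for name, fields in traj_raw.items():
            base = cfg_obj.trajectories.get(name)
            if base is None:
                cfg_obj.trajectories[name] = TrajectorySpec(name=name, **fields)
            else:
                cfg_obj.trajectories[name] = replace(base, **fields)
        cfg_obj.validate()
        return cfg_obj

    def validate(self) -> None:
        if self.n < 10:
            raise ValueError("n must be >= 10")
        for name in ("prop_abeta_pos", "female_fraction", "apoe_e4_prevalence",
                     "path_fraction", "pet_fraction",
                     "followup_cog_fraction", "followup_pet_fraction"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        for name in ("age_sd", "normal_cl_sd", "csf_ratio_width", "csf_tau_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for col, spec in self.trajectories.items():
            spec.validate(schema.biomarker_info(col).direction)


_SUBTEST_NORMS = {  # healthy mean, SD, log-free age slope (points/year)
    "fcsrt": (30.0, 5.0, -0.15),
    "lm_delayed": (12.0, 4.0, -0.10),
    "coding": (60.0, 12.0, -0.55),
    "fluency": (22.0, 6.0, -0.12),
}


def _csf_ratio_curve(cl, midpoint, config: CohortConfig) -> np.ndarray:
    lo, hi = config.csf_ratio_low, config.csf_ratio_high
    return lo + (hi - lo) * expit(-(np.asarray(cl, float) - midpoint)
                                  / config.csf_ratio_width)


def _calibrate_csf_midpoint(cl_latent: np.ndarray, noise: np.ndarray,
                            config: CohortConfig) -> float:
    """Choose the ratio-sigmoid midpoint so the realized amyloid-positive
    fraction matches ``prop_abeta_pos`` as closely as n allows."""
    target = config.prop_abeta_pos

    def frac_pos(mid):
        return np.mean(_csf_ratio_curve(cl_latent, mid, config) * noise
                       < cfg.CSF_AB4240_POSITIVITY)

    lo, hi = -60.0, 60.0
    # fraction positive decreases as the midpoint moves right
    if frac_pos(lo) < target or frac_pos(hi) > target:
        raise ValueError("cannot calibrate CSF curve to prop_abeta_pos")
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if frac_pos(mid) > target:
            lo = mid
        else:
            hi = mid
    # pick the bracket end closest to the target
    return lo if abs(frac_pos(lo) - target) <= abs(frac_pos(hi) - target) else hi


def _latent_burden(config: CohortConfig, age: np.ndarray, apoe: np.ndarray,
                   rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Latent Centiloids and pathological-component membership."""
    n = age.size
    z = (config.path_logit_age * (age - config.age_mean)
         + config.path_logit_apoe * apoe)
    # intercept solved so the mean membership probability hits path_fraction
    b0 = brentq(lambda b: expit(b + z).mean() - config.path_fraction, -20, 20)
    is_path = rng.random(n) < expit(b0 + z)
    cl = rng.normal(config.normal_cl_mean, config.normal_cl_sd, n)
    n_path = int(is_path.sum())
    cl[is_path] = rng.gamma(config.path_gamma_shape, config.path_gamma_scale, n_path)
    return cl, is_path


def generate_cohort(config: CohortConfig | None = None,
                    include_latent: bool = False) -> pd.DataFrame:
    """Generate one baseline cohort table (deterministic given the seed).

    With ``include_latent`` the ground-truth ``latent_cl`` column is
    appended (needed by :func:`generate_followup`; drop it before writing
    a schema-exact CSV).
    """
    config = config or CohortConfig()
    config.validate()
    n = config.n

    demo = _rng(config.seed, "demographics")
    age = np.clip(demo.normal(config.age_mean, config.age_sd, n),
                  config.age_min, config.age_max)
    sex = (demo.random(n) < config.female_fraction).astype(int)
    apoe = (demo.random(n) < config.apoe_e4_prevalence).astype(int)
    education = np.clip(demo.normal(config.education_mean, config.education_sd, n),
                        6.0, 22.0)

    lat = _rng(config.seed, "latent")
    cl_latent, _ = _latent_burden(config, age, apoe, lat)

    csf = _rng(config.seed, "csf")
    ratio_noise = np.exp(csf.normal(0.0, np.sqrt(np.log1p(config.csf_ratio_cv ** 2)), n))
    mid = _calibrate_csf_midpoint(cl_latent, ratio_noise, config)
    csf_ab4240 = _csf_ratio_curve(cl_latent, mid, config) * ratio_noise

    tau_log = (np.log10(config.csf_tau_baseline)
               + np.log10(config.csf_tau_fold)
               * expit((cl_latent - config.csf_tau_midpoint) / config.csf_tau_width)
               + config.csf_tau_age_coef * (age - config.age_mean)
               + csf.normal(0.0, _sigma_log10(config.csf_tau_cv), n))
    csf_mptau181 = 10.0 ** tau_log

    pet = _rng(config.seed, "pet")
    centiloids = cl_latent + pet.normal(0.0, config.pet_noise_sd, n)
    n_pet = int(round(config.pet_fraction * n))
    missing_pet = np.ones(n, dtype=bool)
    missing_pet[pet.choice(n, size=n_pet, replace=False)] = False
    centiloids[missing_pet] = np.nan

    data = {
        schema.ID: [f"SYN{i:04d}" for i in range(n)],
        schema.AGE: age,
        schema.SEX: sex,
        schema.APOE: apoe,
        schema.EDUCATION: education,
        schema.CSF_AB4240: csf_ab4240,
        schema.CSF_MPTAU181: csf_mptau181,
        schema.CENTILOIDS: centiloids,
    }
    for col in schema.PLASMA_COLUMNS:
        spec = config.trajectories[col]
        rng_b = _rng(config.seed, col)
        logv = (spec.log10_curve(cl_latent)
                + spec.age_coef * (age - config.age_mean)
                + spec.sex_coef * sex
                + rng_b.normal(0.0, _sigma_log10(spec.cv), n))
        data[col] = 10.0 ** logv
    df = pd.DataFrame(data)
    if include_latent:
        df["latent_cl"] = cl_latent
    df.attrs["csf_ratio_midpoint"] = mid
    return df


def generate_followup(cohort: pd.DataFrame,
                      config: CohortConfig | None = None) -> pd.DataFrame:
    """Follow-up table: visit-2 Centiloids and two-visit cognitive subtests.

    ``cohort`` must come from :func:`generate_cohort` with
    ``include_latent=True`` (burden-dependent accumulation needs the latent
    column).  Cognitive decline couples to baseline log p-tau231 in
    amyloid-positive participants with slope ``interaction_strength``
    (PACC-z per year per SD of log p-tau231).
    """
    config = config or CohortConfig()
    config.validate()
    if "latent_cl" not in cohort.columns:
        raise ValueError("cohort must carry latent_cl "
                         "(generate_cohort(include_latent=True))")
    n = len(cohort)
    ids = cohort[schema.ID].to_numpy()
    if len(np.unique(ids)) != n:
        raise ValueError("cohort ids are not unique")
    rng = _rng(config.seed, "followup")

    cl_latent = cohort["latent_cl"].to_numpy(float)
    age = cohort[schema.AGE].to_numpy(float)
    edu = cohort[schema.EDUCATION].to_numpy(float)
    abeta_pos = (cohort[schema.CSF_AB4240].to_numpy(float)
                 < cfg.CSF_AB4240_POSITIVITY)

    base_date = (np.datetime64("2018-01-01")
                 + rng.integers(0, 365, n).astype("timedelta64[D]"))

    # cognitive subsample
    n_cog = int(round(config.followup_cog_fraction * n))
    cog_mask = np.zeros(n, dtype=bool)
    cog_mask[rng.choice(n, size=n_cog, replace=False)] = True
    cog_interval = np.maximum(
        rng.normal(config.cog_interval_mean, config.cog_interval_sd, n), 0.5)

    logpt = np.log10(cohort["plasma_ptau231"].to_numpy(float))
    zpt = (logpt - logpt.mean()) / logpt.std(ddof=1)
    slope_z = (-(config.base_decline
                 + config.interaction_strength * zpt * abeta_pos)
               + rng.normal(0.0, config.slope_noise, n))

    ability = rng.normal(0.0, 1.0, n)  # shared cognitive ability factor
    out = {schema.ID: ids}
    for name in schema.SUBTESTS:
        mean, sd, age_slope = _SUBTEST_NORMS[name]
        true1 = (mean + age_slope * (age - config.age_mean)
                 + 0.35 * sd * (edu - config.education_mean) / config.education_sd
                 + sd * (0.6 * ability + 0.4 * rng.normal(0.0, 1.0, n)))
        obs1 = true1 + sd * config.subtest_noise * rng.normal(0.0, 1.0, n)
        true2 = true1 + sd * slope_z * cog_interval
        obs2 = true2 + sd * config.subtest_noise * rng.normal(0.0, 1.0, n)
        out[schema.subtest_col(name, 1)] = np.where(cog_mask, obs1, np.nan)
        out[schema.subtest_col(name, 2)] = np.where(cog_mask, obs2, np.nan)

    cog_v2 = base_date + np.round(cog_interval * 365.25).astype("timedelta64[D]")
    out[schema.COG_DATE_V1] = np.where(cog_mask, base_date.astype(str), None)
    out[schema.COG_DATE_V2] = np.where(cog_mask, cog_v2.astype(str), None)

    # PET subsample
    n_pet = int(round(config.followup_pet_fraction * n))
    has_pet = np.isfinite(cohort[schema.CENTILOIDS].to_numpy(float))
    pet_candidates = np.flatnonzero(has_pet)
    n_pet = min(n_pet, pet_candidates.size)
    pet_mask = np.zeros(n, dtype=bool)
    pet_mask[rng.choice(pet_candidates, size=n_pet, replace=False)] = True
    pet_interval = np.maximum(
        rng.normal(config.pet_interval_mean, config.pet_interval_sd, n), 0.5)
    rate = (config.cl_rate_base
            + config.cl_rate_max
            * expit((cl_latent - config.cl_rate_midpoint) / config.cl_rate_width)
            + rng.normal(0.0, config.cl_rate_noise, n))
    cl2 = (cl_latent + rate * pet_interval
           + rng.normal(0.0, config.pet_noise_sd, n))
    pet_v2 = base_date + np.round(pet_interval * 365.25).astype("timedelta64[D]")
    out[schema.CL_V2] = np.where(pet_mask, cl2, np.nan)
    out[schema.PET_DATE_V1] = np.where(pet_mask, base_date.astype(str), None)
    out[schema.PET_DATE_V2] = np.where(pet_mask, pet_v2.astype(str), None)
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# ground truth

_GT_SEED = 987_654_321  # internal seed for the large-sample reference stats
_GT_N = 120_000


def reference_stats(config: CohortConfig, biomarker: str) -> tuple[float, float]:
    """Large-sample mean/SD of the biomarker (log10 scale for concentrations)
    in the reference stratum (CSF Abeta42/40 > 0.1) implied by the config.

    Age/sex effects are omitted: the pipeline removes them by
    residualization before standardizing, so the reference spread here is
    curve-plus-noise only.  Deterministic (internal fixed seed), so this is
    an analytic quantity up to negligible Monte-Carlo error.
    """
    spec = config.trajectories[biomarker]
    info = schema.biomarker_info(biomarker)
    big = replace(config, n=_GT_N, seed=_GT_SEED)
    rng = np.random.default_rng(np.random.SeedSequence(_GT_SEED, spawn_key=(99,)))

    z = np.zeros(_GT_N)  # age/apoe structure irrelevant for the ref spread
    b0 = logit(big.path_fraction)
    is_path = rng.random(_GT_N) < expit(b0 + z)
    cl = rng.normal(big.normal_cl_mean, big.normal_cl_sd, _GT_N)
    cl[is_path] = rng.gamma(big.path_gamma_shape, big.path_gamma_scale,
                            int(is_path.sum()))
    noise = np.exp(rng.normal(0.0, np.sqrt(np.log1p(big.csf_ratio_cv ** 2)), _GT_N))
    mid = _calibrate_csf_midpoint(cl, noise, big)
    ratio = _csf_ratio_curve(cl, mid, big) * noise
    ref = ratio > cfg.REFERENCE_AB4240

    vals = spec.log10_curve(cl[ref]) + rng.normal(
        0.0, _sigma_log10(spec.cv), int(ref.sum()))
    if not info.log10:  # ratios are standardized on the raw scale
        vals = 10.0 ** vals
    return float(vals.mean()), float(vals.std(ddof=1))


def ground_truth_crossing(config: CohortConfig, threshold_z: float,
                          biomarker: str,
                          cl_range: tuple[float, float] = (-30.0, 200.0),
                          ) -> float | None:
    """Centiloid value where the noiseless, pathology-oriented z-trajectory
    of ``biomarker`` crosses ``threshold_z``; None if it never does.

    The noiseless curve is standardized with :func:`reference_stats` and
    oriented so that movement in the pathological direction is positive;
    the crossing is found by bisection on the (monotone) sigmoid.
    """
    spec = config.trajectories[biomarker]
    info = schema.biomarker_info(biomarker)
    mean_ref, sd_ref = reference_stats(config, biomarker)

    def z_of(cl):
        vals = spec.log10_curve(cl)
        if not info.log10:
            vals = 10.0 ** vals
        return info.direction * (vals - mean_ref) / sd_ref

    lo, hi = cl_range
    if threshold_z == 0:
        # degenerate threshold: where the curve meets the reference mean
        if z_of(lo) >= 0:
            return float(lo)
        if z_of(hi) < 0:
            return None
        return float(brentq(lambda c: z_of(c), lo, hi))
    if z_of(hi) < threshold_z:
        return None
    if z_of(lo) >= threshold_z:
        return float(lo)
    return float(brentq(lambda c: z_of(c) - threshold_z, lo, hi))
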