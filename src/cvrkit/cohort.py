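"""Synthetic longitudinal regional-volume cohorts with known ground truth.

The generator emulates the structure of a multi-visit observational ageing
cohort: each subject contributes 2-10 visits over up to ~15 years, and every
atlas region follows a subject-specific linear trajectory on the log-volume
scale,

    log V_ri(t) = mu0_r + ba_r (age_i - 75) + bs_r sex_i + b0_ri
                  + (slope_r + dDX_r DX_i + dAB_r AB_i + dAPOE_r APOE4_i
                     + b1_ri) t
                  + s_iv + eps_riv

with correlated random intercept/slope (b0, b1), a per-visit scan-scale
offset s_iv shared by all regions of a visit (it cancels in region/region
ratios but not in region/ICV, since ICV is measured once per subject), and
i.i.d. region-level measurement noise eps. Amyloid positivity (AB),
cognitive impairment (DX) and APOE4 accelerate atrophy region-specifically;
ventricles expand.

All parameters are ground truth available to tests, and ``expected_slope``
returns the implied annual log-slope of any composite value ratio.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .atlas import DEFAULT_ATLAS, RegionAtlas

#: Regions with pronounced disease-accelerated atrophy (limbic/subcortical
#: structures classically implicated in Alzheimer's disease).
AD_SIGNATURE = (
    "hippocampus",
    "entorhinal",
    "amygdala",
    "accumbens_area",
    "thalamus",
    "ventraldc",
    "parahippocampal",
)

#: CSF spaces that expand with atrophy.
VENTRICULAR = ("lateral_ventricle", "inf_lat_vent")

# Typical bilateral volumes (mm^3) for a handful of notable structures; the
# remaining regions fall back to a generic cortical-parcel volume. Only the
# relative magnitudes matter (every biomarker is a ratio).
_TYPICAL_VOLUMES = {
    "lateral_ventricle": 30_000.0,
    "inf_lat_vent": 1_500.0,
    "hippocampus": 7_500.0,
    "amygdala": 3_200.0,
    "thalamus": 13_000.0,
    "caudate": 7_000.0,
    "putamen": 9_500.0,
    "pallidum": 3_500.0,
    "accumbens_area": 1_100.0,
    "ventraldc": 7_500.0,
    "brainstem": 21_000.0,
    "choroid_plexus": 1_600.0,
    "cerebellum_cortex": 100_000.0,
    "cc_anterior": 900.0,
    "cc_mid_anterior": 450.0,
    "cc_central": 450.0,
    "cc_mid_posterior": 450.0,
    "cc_posterior": 950.0,
    "entorhinal": 3_600.0,
    "frontalpole": 800.0,
    "temporalpole": 2_400.0,
    "transversetemporal": 1_500.0,
}
_GENERIC_VOLUME = 9_000.0


@dataclass(frozen=True)
class RegionParams:
    """Ground-truth generative parameters for one region (log-volume scale).

    ``mu0`` is the mean log-volume at age 75; ``beta_age`` (per year of
    baseline age) and ``beta_sex`` (sex coded +1 female / -1 male) act on
    the intercept. ``slope`` is the base annual log-slope, modified
    additively by ``d_dx``, ``d_ab`` and ``d_apoe4`` for subjects with the
    corresponding flag. ``sd_b0``/``sd_b1``/``corr`` parameterise the
    correlated random intercept/slope and ``sigma_e`` the residual sd.
    """

    mu0: float
    beta_age: float = -0.003
    beta_sex: float = -0.04
    slope: float = -0.002
    d_dx: float = -0.001
    d_ab: float = -0.001
    d_apoe4: float = -0.0005
    sd_b0: float = 0.10
    sd_b1: float = 0.004
    corr: float = -0.2
    sigma_e: float = 0.04

    def __post_init__(self) -> None:
        for name in ("sd_b0", "sd_b1", "sigma_e"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not -1.0 <= self.corr <= 1.0:
            raise ValueError(f"corr must be in [-1, 1], got {self.corr}")

    def slope_for(self, dx: int, ab: int, apoe4: int) -> float:
        return (
            self.slope + self.d_dx * dx + self.d_ab * ab + self.d_apoe4 * apoe4
        )


def default_region_params(
    atlas: RegionAtlas = DEFAULT_ATLAS,
    *,
    sd_b0: float = 0.10,
    sd_b1: float = 0.004,
    corr: float = -0.2,
    sigma_e: float = 0.04,
) -> dict[str, RegionParams]:
    """Default per-region ground truth for the given atlas.

    Ventricles expand (+2.5%/yr base, faster when AB+/CI); the limbic and
    subcortical disease-signature set atrophies at -0.6%/yr base with AB,
    DX and APOE4 increments; remaining regions show mild ageing atrophy.
    """
    var = dict(sd_b0=sd_b0, sd_b1=sd_b1, corr=corr, sigma_e=sigma_e)
    params: dict[str, RegionParams] = {}
    for name in atlas.region_names:
        mu0 = float(np.log(_TYPICAL_VOLUMES.get(name, _GENERIC_VOLUME)))
        if name in VENTRICULAR:
            params[name] = RegionParams(
                mu0=mu0, beta_age=0.012, beta_sex=-0.08,
                slope=0.025, d_dx=0.010, d_ab=0.012, d_apoe4=0.004, **var,
            )
        elif name == "choroid_plexus":
            params[name] = RegionParams(
                mu0=mu0, beta_age=0.006, slope=0.008,
                d_dx=0.002, d_ab=0.002, d_apoe4=0.001, **var,
            )
        elif name in AD_SIGNATURE:
            params[name] = RegionParams(
                mu0=mu0, slope=-0.006,
                d_dx=-0.004, d_ab=-0.006, d_apoe4=-0.002, **var,
            )
        else:
            params[name] = RegionParams(mu0=mu0, **var)
    return params


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for a synthetic cohort.

    Defaults emulate a large multi-visit ageing cohort: ~1400 subjects,
    2-10 visits at roughly 0.9-year intervals, age 74 (sd 7) at baseline,
    amyloid positivity coupled to cognitive status.
    """

    n_subjects: int = 1400
    seed: int = 0
    # visit schedule: n_visits = 2 + Binomial(visit_extra_n, visit_extra_p),
    # intervals ~ Uniform(interval_mean +- interval_jitter) years
    visit_extra_n: int = 8
    visit_extra_p: float = 0.3
    interval_mean: float = 0.9
    interval_jitter: float = 0.45
    # covariates
    p_female: float = 0.45
    p_apoe4: float = 0.45
    p_dx: float = 0.60
    p_ab_given_dx: float = 0.70
    p_ab_given_cu: float = 0.35
    age_mean: float = 74.0
    age_sd: float = 7.0
    education_mean: float = 16.0
    education_sd: float = 2.7
    # shared per-visit multiplicative scan-scale noise (log sd)
    sd_visit_scale: float = 0.02
    # ICV: log-normal, constant within subject
    icv_meanlog: float = float(np.log(1.5e6))
    icv_sdlog: float = 0.10
    icv_beta_sex: float = -0.06
    # whole-brain aggregate column (baseline biomarker only, not a candidate)
    whole_brain: RegionParams = field(
        default_factory=lambda: RegionParams(
            mu0=float(np.log(1.05e6)), slope=-0.003,
            d_dx=-0.002, d_ab=-0.002, d_apoe4=-0.001,
            sd_b0=0.06, sd_b1=0.003, corr=-0.2, sigma_e=0.04,
        )
    )
    region_params: dict[str, RegionParams] | None = None

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError(f"n_subjects must be >= 2, got {self.n_subjects}")
        for name in (
            "p_female", "p_apoe4", "p_dx", "p_ab_given_dx", "p_ab_given_cu",
            "visit_extra_p",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in (
            "age_sd", "education_sd", "sd_visit_scale", "icv_sdlog",
            "interval_jitter",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.interval_mean <= 0:
            raise ValueError(f"interval_mean must be > 0, got {self.interval_mean}")
        if self.visit_extra_n < 0:
            raise ValueError(f"visit_extra_n must be >= 0, got {self.visit_extra_n}")

    def params_for(self, atlas: RegionAtlas) -> dict[str, RegionParams]:
        params = self.region_params
        if params is None:
            return default_region_params(atlas)
        missing = set(atlas.region_names) - set(params)
        if missing:
            raise ValueError(f"region_params missing regions: {sorted(missing)}")
        return {r: params[r] for r in atlas.region_names}

    # -- (de)serialisation --------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        if d.get("whole_brain") is not None and not isinstance(
            d["whole_brain"], RegionParams
        ):
            d["whole_brain"] = RegionParams(**d["whole_brain"])
        if d.get("region_params") is not None:
            d["region_params"] = {
                k: v if isinstance(v, RegionParams) else RegionParams(**v)
                for k, v in d["region_params"].items()
            }
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "CohortConfig":
        """Load a config from a YAML or JSON file."""
        with open(path) as fh:
            text = fh.read()
        data = yaml.safe_load(text)  # YAML is a superset of JSON
        return cls.from_dict(data)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


COVARIATE_COLUMNS = ("age_bl", "sex", "DX", "AB", "APOE4", "education")


def generate_cohort(
    config: CohortConfig, atlas: RegionAtlas = DEFAULT_ATLAS
) -> pd.DataFrame:
    """Generate a long-format volume table (one row per subject-visit).

    Columns: ``subject_id``, ``visit_time`` (years from the subject's first
    visit), the covariates (``age_bl``, ``sex`` +1 female / -1 male, ``DX``,
    ``AB``, ``APOE4`` 0/1 flags, ``education`` years), one column per atlas
    region, plus ``whole_brain`` and the ICV column. Deterministic for a
    given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    m = config.n_subjects
    params = config.params_for(atlas)

    # subject-level covariates
    sex = np.where(rng.random(m) < config.p_female, 1, -1)
    apoe4 = (rng.random(m) < config.p_apoe4).astype(int)
    dx = (rng.random(m) < config.p_dx).astype(int)
    p_ab = np.where(dx == 1, config.p_ab_given_dx, config.p_ab_given_cu)
    ab = (rng.random(m) < p_ab).astype(int)
    age = rng.normal(config.age_mean, config.age_sd, m)
    edu = np.clip(np.round(rng.normal(config.education_mean, config.education_sd, m)), 6, 24)
    icv = np.exp(
        rng.normal(config.icv_meanlog, config.icv_sdlog, m)
        + config.icv_beta_sex * sex
    )

    # visit schedule
    n_visits = 2 + rng.binomial(config.visit_extra_n, config.visit_extra_p, m)
    lo = max(config.interval_mean - config.interval_jitter, 1e-3)
    hi = config.interval_mean + config.interval_jitter
    sid = np.repeat(np.arange(m), n_visits)
    intervals = rng.uniform(lo, hi, n_visits.sum())
    t = np.empty(n_visits.sum())
    pos = 0
    for i, k in enumerate(n_visits):
        t[pos] = 0.0
        t[pos + 1 : pos + k] = np.cumsum(intervals[pos + 1 : pos + k])
        pos += k
    n_rows = len(t)

    visit_scale = rng.normal(0.0, config.sd_visit_scale, n_rows)

    data = {
        "subject_id": np.array([f"S{i:05d}" for i in range(m)])[sid],
        "visit_time": t,
        "age_bl": age[sid],
        "sex": sex[sid],
        "DX": dx[sid],
        "AB": ab[sid],
        "APOE4": apoe4[sid],
        "education": edu[sid],
    }

    region_names = list(atlas.region_names) + ["whole_brain"]
    all_params = dict(params)
    all_params["whole_brain"] = config.whole_brain
    for name in region_names:
        p = all_params[name]
        cov = np.array(
            [
                [p.sd_b0**2, p.corr * p.sd_b0 * p.sd_b1],
                [p.corr * p.sd_b0 * p.sd_b1, p.sd_b1**2],
            ]
        )
        L = _chol_psd(cov)
        b = rng.standard_normal((m, 2)) @ L.T
        slope = (
            p.slope + p.d_dx * dx + p.d_ab * ab + p.d_apoe4 * apoe4 + b[:, 1]
        )
        intercept = (
            p.mu0 + p.beta_age * (age - 75.0) + p.beta_sex * sex + b[:, 0]
        )
        eps = rng.normal(0.0, p.sigma_e, n_rows) if p.sigma_e > 0 else 0.0
        logv = intercept[sid] + slope[sid] * t + visit_scale + eps
        if name == "whole_brain":
            # scan-scale noise hits the aggregate like any other measurement
            data[name] = np.exp(logv)
        else:
            data[name] = np.exp(logv)

    data[atlas.icv_name] = icv[sid]
    table = pd.DataFrame(data)
    table.attrs["seed"] = config.seed
    return table


def _chol_psd(cov: np.ndarray) -> np.ndarray:
    """Cholesky factor tolerating zero variances / |corr| = 1."""
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(cov)
        w = np.clip(w, 0.0, None)
        return v @ np.diag(np.sqrt(w))


def expected_slope(
    config: CohortConfig,
    numerator,
    denominator=None,
    profile: dict | None = None,
    atlas: RegionAtlas = DEFAULT_ATLAS,
) -> float:
    """First-order (delta-method) annual log-slope of a composite ratio.

    ``numerator`` may be a CVRSpec (then ``denominator`` is taken from it)
    or an iterable of region names alongside ``denominator``. Returns the
    slope of ``log(mean(num volumes) / mean(den volumes))`` at baseline
    for a subject with the given covariate ``profile`` (keys ``dx``, ``ab``,
    ``apoe4``, ``age_bl``, ``sex``; defaults 0/0/0/75/+1). The weights are
    the regions' expected baseline volumes, so the result is exact whenever
    all members of a composite share identical parameters.
    """
    if denominator is None:
        if not hasattr(numerator, "denominator"):
            raise TypeError(
                "provide a CVRSpec or both numerator and denominator"
            )
        numerator, denominator = numerator.numerator, numerator.denominator
    prof = {"dx": 0, "ab": 0, "apoe4": 0, "age_bl": 75.0, "sex": 1}
    if profile:
        prof.update(profile)
    params = config.params_for(atlas)

    def side(regions) -> float:
        regions = list(regions)
        if not regions:
            raise ValueError("composite must contain at least one region")
        unknown = [r for r in regions if r not in params]
        if unknown:
            raise KeyError(f"unknown regions: {unknown}")
        w = np.array(
            [
                np.exp(
                    params[r].mu0
                    + params[r].beta_age * (prof["age_bl"] - 75.0)
                    + params[r].beta_sex * prof["sex"]
                )
                for r in regions
            ]
        )
        s = np.array(
            [
                params[r].slope_for(prof["dx"], prof["ab"], prof["apoe4"])
                for r in regions
            ]
        )
        return float(np.sum(w * s) / np.sum(w))

    return side(numerator) - side(denominator)


def write_cohort(table: pd.DataFrame, path) -> None:
    """Write a volume table as CSV with a metadata comment header."""
    meta = {"seed": table.attrs.get("seed"), "n_rows": len(table)}
    with open(path, "w") as fh:
        fh.write(f"# cvrkit cohort {json.dumps(meta)}\n")
        table.to_csv(fh, index=False)


def read_cohort(path) -> pd.DataFrame:
    """Read a volume table written by :func:`write_cohort` (or plain CSV)."""
    seed = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            try:
                seed = json.loads(first.split("cohort", 1)[1]).get("seed")
            except (json.JSONDecodeError, IndexError):
                pass
            table = pd.read_csv(fh)
        else:
            fh.seek(0)
            table = pd.read_csv(fh)
    if seed is not None:
        table.attrs["seed"] = seed
    return table
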