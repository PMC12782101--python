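"""Clinical-trial design metrics computed from a fitted trajectory model.

Four metrics compare biomarkers:

* **Sample size estimate (SSE)** — per-arm n for a two-arm trial measured
  at baseline and a final visit at ``length_years``, powered to detect a
  ``pct_change`` fractional reduction of the annual slope:

      n = ceil( 2 (z_{1-a/2} + z_{power})^2 sigma_slope^2 / Delta^2 ),
      Delta = pct_change * |beta_time|,
      sigma_slope^2 = var(b1) + sigma_e^2 / sum_j (t_j - tbar)^2,

  with sum_j (t_j - tbar)^2 = T^2/2 for visits at 0 and T. This is the
  classical slope-difference formula for longitudinal designs; it is
  validated here by Monte-Carlo power simulation rather than against any
  particular reference implementation.
* **Percentage error** — 100 (e^{sd(residuals)} - 1): residual sd mapped
  from the log scale back to a native-scale percentage.
* **Group separation** — the Wald t-statistic of the ABxtime or DXxtime
  fixed effect.
* **Detectable effect** — the inversion of the SSE formula: the fractional
  slope change detectable at a given per-arm n.

Confidence intervals use the model-based parametric bootstrap
(percentile, 2.5/97.5) or, for the SSE, delta-method propagation of the
uncertainty in (beta_time, var(b1), sigma_e^2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .lmm import fit_lmm_core, varcomp_covariance
from .model import AtrophyLMM, AtrophyLMMResults


@dataclass(frozen=True)
class TrialDesign:
    """Two-timepoint trial configuration (baseline and final visit)."""

    length_years: float = 1.5
    power: float = 0.80
    alpha: float = 0.05
    pct_change: float = 0.20

    def __post_init__(self) -> None:
        if not 0 < self.power < 1:
            raise ValueError(f"power must be in (0, 1), got {self.power}")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.pct_change <= 0:
            raise ValueError(f"pct_change must be > 0, got {self.pct_change}")
        if self.length_years <= 0:
            raise ValueError(f"length_years must be > 0, got {self.length_years}")

    @property
    def visit_times(self) -> tuple[float, float]:
        return (0.0, self.length_years)

    @property
    def time_ss(self) -> float:
        """sum_j (t_j - tbar)^2 for the two visits: T^2/2."""
        return self.length_years**2 / 2.0

    @property
    def z_total(self) -> float:
        return float(
            stats.norm.ppf(1 - self.alpha / 2) + stats.norm.ppf(self.power)
        )


#: 78-week (1.5-year) design used for cognitively impaired trials and
#: all-data fits; 234-week (4.5-year) design for preclinical (CU) trials.
DESIGN_CI = TrialDesign(length_years=1.5)
DESIGN_CU = TrialDesign(length_years=4.5)


def slope_variance(fit: AtrophyLMMResults, design: TrialDesign) -> float:
    """Variance of a per-subject slope estimate under the trial design."""
    return float(fit.var_slope_re + fit.sigma_e**2 / design.time_ss)


def sample_size_estimate(
    fit: AtrophyLMMResults, design: TrialDesign = DESIGN_CI,
    ceiling: bool = True,
) -> float:
    """Per-arm sample size; ``ceiling=False`` returns the raw value."""
    if not fit.converged:
        raise RuntimeError("sample_size_estimate requires a converged fit")
    beta_t = float(fit.params["time"])
    if beta_t == 0.0:
        raise ValueError("sample size is undefined for a zero time slope")
    var_slope = slope_variance(fit, design)
    if var_slope <= 0:
        warnings.warn("zero total slope variance; returning n = 1", stacklevel=2)
        return 1.0
    delta = design.pct_change * abs(beta_t)
    n = 2.0 * design.z_total**2 * var_slope / delta**2
    return float(np.ceil(n)) if ceiling else float(n)


def percentage_error(fit: AtrophyLMMResults, empirical: bool = False) -> float:
    """100 (e^{sd(residuals)} - 1), residual variability on the log scale
    mapped back to a native-scale percentage.

    By default the model's (REML) residual-sd estimate sigma_e is used: it
    estimates the same quantity as the sd of the residual vector but
    without the shrinkage that predicted random effects induce in
    conditional residuals, so it is consistent for the generative residual
    sd. ``empirical=True`` uses the sd of the conditional residual vector
    instead.
    """
    resid = np.asarray(fit.resid)
    if resid.size == 0:
        raise ValueError("fit has no residuals")
    sd = float(np.std(resid, ddof=1)) if empirical else float(fit.sigma_e)
    return float(100.0 * np.expm1(sd))


def group_separation(fit: AtrophyLMMResults, which: str = "AB") -> float:
    """Wald t of the ABxtime or DXxtime slope term."""
    term = {"AB": "time:AB", "DX": "time:DX"}.get(which.upper())
    if term is None:
        raise ValueError(f"which must be 'AB' or 'DX', got {which!r}")
    if term not in fit.params.index:
        raise ValueError(f"{term} is not part of the fitted variant")
    return float(fit.tvalues[term])


def detectable_effect(
    fit: AtrophyLMMResults, n_per_arm: float, design: TrialDesign = DESIGN_CI,
) -> float:
    """Percent slope change detectable at ``n_per_arm`` (SSE inversion)."""
    if not fit.converged:
        raise RuntimeError("detectable_effect requires a converged fit")
    beta_t = float(fit.params["time"])
    if beta_t == 0.0:
        raise ValueError("detectable effect is undefined for a zero time slope")
    if n_per_arm < 1:
        raise ValueError(f"n_per_arm must be >= 1, got {n_per_arm}")
    var_slope = slope_variance(fit, design)
    pct = design.z_total * np.sqrt(2.0 * var_slope / n_per_arm) / abs(beta_t)
    return float(100.0 * pct)


def simulate_trial_power(
    fit: AtrophyLMMResults,
    design: TrialDesign = DESIGN_CI,
    n_per_arm: int | None = None,
    n_trials: int = 10_000,
    seed=None,
    chunk: int = 500,
) -> float:
    """Monte-Carlo power of a two-arm, two-timepoint trial at ``n_per_arm``.

    Subjects' change scores over the trial follow the fitted components:
    slope ~ N(beta_time, var(b1)) (treated arm: slope reduced by
    ``pct_change``), plus independent residuals at each of the two visits.
    Each simulated trial is analysed with a pooled two-sample t-test on
    per-subject change scores at the design's alpha. This validates the
    closed-form sample-size estimate: run at n = SSE and the rejection
    rate should match the design power.
    """
    if n_per_arm is None:
        n_per_arm = int(sample_size_estimate(fit, design))
    n_per_arm = int(n_per_arm)
    rng = np.random.default_rng(seed)
    T = design.length_years
    beta_t = float(fit.params["time"])
    sd_slope = np.sqrt(max(fit.var_slope_re, 0.0))
    sd_change_noise = np.sqrt(2.0) * fit.sigma_e  # eps at both visits
    delta = (1.0 - design.pct_change) * beta_t
    tcrit = stats.t.ppf(1.0 - design.alpha / 2.0, df=2 * n_per_arm - 2)

    rejected = 0
    done = 0
    while done < n_trials:
        k = min(chunk, n_trials - done)
        ctrl = (
            rng.normal(beta_t, sd_slope, (k, n_per_arm)) * T
            + rng.normal(0.0, sd_change_noise, (k, n_per_arm))
        )
        trt = (
            rng.normal(delta, sd_slope, (k, n_per_arm)) * T
            + rng.normal(0.0, sd_change_noise, (k, n_per_arm))
        )
        diff = ctrl.mean(axis=1) - trt.mean(axis=1)
        sp2 = 0.5 * (ctrl.var(axis=1, ddof=1) + trt.var(axis=1, ddof=1))
        tstat = diff / np.sqrt(2.0 * sp2 / n_per_arm)
        rejected += int(np.sum(np.abs(tstat) > tcrit))
        done += k
    return rejected / n_trials


# -- uncertainty ------------------------------------------------------------


@dataclass(frozen=True)
class BootstrapCI:
    point: float
    ci_low: float
    ci_high: float
    n_boot: int
    n_failed: int

    @property
    def reliable(self) -> bool:
        return self.n_failed <= 0.1 * self.n_boot

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.point, self.ci_low, self.ci_high)


def bootstrap_ci(
    series: pd.DataFrame,
    metric_fn,
    n_boot: int = 1000,
    seed=None,
    include_dx: bool = True,
    include_ab: bool = True,
) -> BootstrapCI:
    """Parametric-bootstrap percentile CI for any fit-level metric.

    Refits the model to ``n_boot`` datasets simulated from the original
    fit and takes the 2.5th/97.5th percentiles of ``metric_fn(fit)``. More
    than 10% failed replicates marks the interval unreliable
    (``reliable`` property).
    """
    model = AtrophyLMM(series, include_dx=include_dx, include_ab=include_ab)
    fit = model.fit()
    if not fit.converged:
        raise RuntimeError("bootstrap requires a converged fit on the original data")
    point = float(metric_fn(fit))
    rng = np.random.default_rng(seed)

    # the simulated datasets share the original design, so only the
    # response is redrawn and each refit warm-starts at the original
    # variance-parameter optimum
    X, Z, groups, tc = model.exog, model.exog_re, model.groups, model.tc
    _, gidx = np.unique(groups, return_inverse=True)
    m = gidx.max() + 1
    L = np.linalg.cholesky(fit.core.cov_re + 1e-300 * np.eye(2))
    mean = X @ fit.core.beta
    values = []
    n_failed = 0
    for _ in range(n_boot):
        b = rng.standard_normal((m, 2)) @ L.T
        y = mean + b[gidx, 0] + b[gidx, 1] * tc + rng.normal(
            0.0, fit.sigma_e, len(tc)
        )
        try:
            core = fit_lmm_core(y, X, Z, groups, reml=True,
                                start=fit.core.theta)
            if not core.converged:
                raise RuntimeError
            values.append(float(metric_fn(AtrophyLMMResults(model, core))))
        except Exception:
            n_failed += 1
    if n_failed > 0.1 * n_boot:
        warnings.warn(
            f"bootstrap: {n_failed}/{n_boot} replicates failed; CI unreliable",
            stacklevel=2,
        )
    if not values:
        return BootstrapCI(point, np.nan, np.nan, n_boot, n_failed)
    lo, hi = np.percentile(values, [2.5, 97.5])
    return BootstrapCI(point, float(lo), float(hi), n_boot, n_failed)


def sse_confint(
    fit: AtrophyLMMResults, design: TrialDesign = DESIGN_CI,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Delta-method CI for the per-arm SSE.

    Propagates the curvature-based uncertainty of (var(b1), sigma_e^2) and
    the GLS variance of beta_time through log(SSE), treating mean and
    variance parameters as asymptotically independent.
    """
    beta_t = float(fit.params["time"])
    se_beta_t = float(fit.bse["time"])
    var_b1 = fit.var_slope_re
    s2 = fit.sigma_e**2
    k = 1.0 / design.time_ss
    g = var_b1 + s2 * k  # slope variance under the design

    cov = varcomp_covariance(fit.core)  # over (th0, th1, th2, log s2)
    # var_b1 = exp(2 th1 + log s2); d var_b1/d th1 = 2 var_b1, /d log s2 = var_b1
    # s2 k: d/d log s2 = s2 k
    grad = np.array([0.0, 2.0 * var_b1, 0.0, var_b1 + s2 * k])
    var_g = float(grad @ cov @ grad)
    var_log = var_g / g**2 + 4.0 * (se_beta_t / beta_t) ** 2 if g > 0 else np.inf
    sse = sample_size_estimate(fit, design, ceiling=False)
    z = stats.norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(max(var_log, 0.0))
    return float(sse * np.exp(-half)), float(sse * np.exp(half))


@dataclass
class MetricReport:
    """The four evaluation metrics for one biomarker and target group."""

    biomarker: str
    target_group: str
    sse: float
    sse_ci: tuple[float, float] | None = None
    error_pct: float | None = None
    error_ci: tuple[float, float] | None = None
    t_ab: float | None = None
    t_ab_ci: tuple[float, float] | None = None
    t_dx: float | None = None
    t_dx_ci: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.sse is not None and self.sse < 1:
            raise ValueError("sse_per_arm must be >= 1")
        if self.error_pct is not None and self.error_pct < 0:
            raise ValueError("error_pct must be >= 0")
        for point, ci in (
            (self.sse, self.sse_ci), (self.error_pct, self.error_ci),
            (self.t_ab, self.t_ab_ci), (self.t_dx, self.t_dx_ci),
        ):
            if ci is not None and point is not None:
                if not ci[0] <= point <= ci[1]:
                    raise ValueError(
                        f"point {point} outside its CI {ci}"
                    )

    def to_row(self) -> dict:
        def fmt(point, ci):
            if point is None:
                return None
            if ci is None:
                return f"{point:.4g}"
            return f"{point:.4g} ({ci[0]:.4g}, {ci[1]:.4g})"

        return {
            "biomarker": self.biomarker,
            "target_group": self.target_group,
            "sse": fmt(self.sse, self.sse_ci),
            "error_pct": fmt(self.error_pct, self.error_ci),
            "t_ab": fmt(self.t_ab, self.t_ab_ci),
            "t_dx": fmt(self.t_dx, self.t_dx_ci),
        }

    def to_dict(self) -> dict:
        return {
            "biomarker": self.biomarker,
            "target_group": self.target_group,
            "sse": self.sse, "sse_ci": self.sse_ci,
            "error_pct": self.error_pct, "error_ci": self.error_ci,
            "t_ab": self.t_ab, "t_ab_ci": self.t_ab_ci,
            "t_dx": self.t_dx, "t_dx_ci": self.t_dx_ci,
        }
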