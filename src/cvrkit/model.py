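"""Mixed-effects model of log-biomarker trajectories.

The model fitted to every biomarker series is

    log(value) = b0 + beta_0 + beta_1 age_bl + beta_2 sex
                 + t_c (beta_3 + b1 + beta_4 DX + beta_5 AB + beta_6 APOE4)
                 + eps

where t_c is the visit time centred at each subject's mean visit time
(time-shift invariance), (b0, b1) are correlated subject-level random
intercept/slope, and sex is coded +1 female / -1 male. When the model is
fitted inside a single target group (e.g. amyloid-positive cognitively
impaired subjects) the DX and AB slope terms are dropped because those
covariates are constant there.

``AtrophyLMM`` is the model class; ``AtrophyLMM(series).fit()`` returns an
``AtrophyLMMResults`` carrying estimates, standard errors, Wald
t-statistics, the random-effects covariance, conditional residuals and a
``simulate`` method used by the parametric bootstrap. REML is used for
reported estimates; likelihood-ratio tests refit by ML.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .lmm import LMMCoreFit, fit_lmm_core

REQUIRED_COLUMNS = ("subject_id", "visit_time", "value")


def _centred_time(df: pd.DataFrame) -> np.ndarray:
    return (
        df["visit_time"] - df.groupby("subject_id")["visit_time"].transform("mean")
    ).to_numpy(dtype=float)


def _design(
    df: pd.DataFrame,
    tc: np.ndarray,
    include_dx: bool,
    include_ab: bool,
    extra_terms: tuple[str, ...] = (),
    include_apoe4: bool = True,
) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(df)), df["age_bl"].to_numpy(float),
            df["sex"].to_numpy(float), tc]
    names = ["intercept", "age_bl", "sex", "time"]
    if include_dx:
        cols.append(tc * df["DX"].to_numpy(float))
        names.append("time:DX")
    if include_ab:
        cols.append(tc * df["AB"].to_numpy(float))
        names.append("time:AB")
    if include_apoe4:
        cols.append(tc * df["APOE4"].to_numpy(float))
        names.append("time:APOE4")
    for term in extra_terms:
        if term.endswith(":time"):
            base = term[: -len(":time")]
            cols.append(tc * df[base].to_numpy(float))
        else:
            cols.append(df[term].to_numpy(float))
        names.append(term)
    return np.column_stack(cols), names


class AtrophyLMM:
    """Linear mixed model for one biomarker series.

    Parameters
    ----------
    series
        Long-format frame with columns ``subject_id``, ``visit_time``,
        ``value`` (> 0) and the covariates ``age_bl``, ``sex``, ``DX``,
        ``AB``, ``APOE4``.
    include_dx, include_ab
        Whether the DXxtime / ABxtime slope terms enter the fixed effects.
        Both are dropped when fitting within a fixed target group.
    extra_terms
        Additional fixed-effect terms, either a column name (intercept
        effect) or ``"column:time"`` (slope effect); used by the
        likelihood-ratio covariate screen.
    min_subjects
        Minimum number of subjects with >= 2 visits (safety rail).
    """

    def __init__(
        self,
        series: pd.DataFrame,
        include_dx: bool = True,
        include_ab: bool = True,
        extra_terms: tuple[str, ...] = (),
        min_subjects: int = 10,
        include_apoe4: bool = True,
    ) -> None:
        for col in REQUIRED_COLUMNS:
            if col not in series.columns:
                raise KeyError(f"series is missing column {col!r}")
        vals = series["value"].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)) or np.any(vals <= 0):
            raise ValueError("all biomarker values must be finite and > 0")
        visits = series.groupby("subject_id")["visit_time"].count()
        if int((visits >= 2).sum()) < min_subjects:
            raise ValueError(
                f"need >= {min_subjects} subjects with >= 2 visits, "
                f"got {int((visits >= 2).sum())}"
            )
        if include_ab and series["AB"].nunique() < 2:
            raise ValueError("include_ab requires both AB levels in the data")
        if include_dx and series["DX"].nunique() < 2:
            raise ValueError("include_dx requires both DX levels in the data")

        self.series = series.reset_index(drop=True)
        self.include_dx = include_dx
        self.include_ab = include_ab
        self.include_apoe4 = include_apoe4
        self.extra_terms = tuple(extra_terms)
        self.endog = np.log(self.series["value"].to_numpy(dtype=float))
        self.tc = _centred_time(self.series)
        self.exog, self.param_names = _design(
            self.series, self.tc, include_dx, include_ab, self.extra_terms,
            include_apoe4,
        )
        self.exog_re = np.column_stack([np.ones(len(self.series)), self.tc])
        self.groups = self.series["subject_id"].to_numpy()

    @classmethod
    def from_volume_table(
        cls, table: pd.DataFrame, spec, **kwargs
    ) -> "AtrophyLMM":
        """Convenience: build the model directly from a volume table and a
        :class:`~cvrkit.biomarkers.CVRSpec`."""
        from .biomarkers import compute_cvr

        return cls(compute_cvr(table, spec), **kwargs)

    def fit(self, reml: bool = True, start=None) -> "AtrophyLMMResults":
        core = fit_lmm_core(
            self.endog, self.exog, self.exog_re, self.groups,
            reml=reml, start=start,
        )
        return AtrophyLMMResults(model=self, core=core)


@dataclass
class AtrophyLMMResults:
    """Fitted log-biomarker mixed model."""

    model: AtrophyLMM
    core: LMMCoreFit
    params: pd.Series = field(init=False)
    bse: pd.Series = field(init=False)
    tvalues: pd.Series = field(init=False)

    def __post_init__(self) -> None:
        names = self.model.param_names
        self.params = pd.Series(self.core.beta, index=names)
        se = np.sqrt(np.clip(np.diag(self.core.cov_beta), 0.0, None))
        self.bse = pd.Series(se, index=names)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, self.core.beta / se, np.nan)
        self.tvalues = pd.Series(t, index=names)

    # -- contract fields ----------------------------------------------------

    @property
    def cov_re(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.core.cov_re, index=["intercept", "time"],
            columns=["intercept", "time"],
        )

    @property
    def sigma_e(self) -> float:
        return self.core.sigma_e

    @property
    def resid(self) -> np.ndarray:
        """Conditional residuals (log scale), one per observation."""
        return self.core.resid

    @property
    def pearson_resid(self) -> np.ndarray:
        return self.core.resid / max(self.core.sigma_e, 1e-300)

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.core.fitted

    @property
    def llf(self) -> float:
        return self.core.llf

    @property
    def converged(self) -> bool:
        return self.core.converged

    @property
    def singular(self) -> bool:
        return self.core.singular

    @property
    def n_obs(self) -> int:
        return self.core.n_obs

    @property
    def n_subjects(self) -> int:
        return self.core.n_groups

    @property
    def var_slope_re(self) -> float:
        """Variance of the random slope b1 (per year^2)."""
        return float(self.core.cov_re[1, 1])

    # -- reporting ----------------------------------------------------------

    def summary(self) -> str:
        lines = [
            "Log-biomarker linear mixed model "
            f"({'REML' if self.core.reml else 'ML'})",
            f"  observations: {self.n_obs}   subjects: {self.n_subjects}   "
            f"converged: {self.converged}",
            "",
            f"  {'term':<16}{'coef':>12}{'std err':>12}{'t':>10}",
        ]
        for name in self.params.index:
            lines.append(
                f"  {name:<16}{self.params[name]:>12.6f}"
                f"{self.bse[name]:>12.6f}{self.tvalues[name]:>10.3f}"
            )
        g = self.core.cov_re
        corr = g[0, 1] / np.sqrt(g[0, 0] * g[1, 1]) if g[0, 0] * g[1, 1] > 0 else np.nan
        lines += [
            "",
            f"  random effects sd: intercept {np.sqrt(g[0, 0]):.5f}  "
            f"slope {np.sqrt(g[1, 1]):.5f}  corr {corr:.3f}",
            f"  residual sd: {self.sigma_e:.5f}   log-likelihood: {self.llf:.2f}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "params": {k: float(v) for k, v in self.params.items()},
            "bse": {k: float(v) for k, v in self.bse.items()},
            "tvalues": {k: float(v) for k, v in self.tvalues.items()},
            "cov_re": self.core.cov_re.tolist(),
            "sigma_e": float(self.sigma_e),
            "llf": float(self.llf),
            "converged": bool(self.converged),
            "n_obs": int(self.n_obs),
            "n_subjects": int(self.n_subjects),
        }

    # -- simulation ---------------------------------------------------------

    def simulate(
        self, design: pd.DataFrame | None = None, seed=None,
        rng: np.random.Generator | None = None,
    ) -> pd.DataFrame:
        """Parametric simulation from the fitted model.

        New random effects are drawn from the fitted covariance and new
        residuals from the fitted sigma_e on the given design (default: the
        model's own rows); values are exponentiated back to biomarker scale.
        """
        if not self.converged:
            raise RuntimeError("cannot simulate from a non-converged fit")
        if rng is None:
            rng = np.random.default_rng(seed)
        if design is None:
            df = self.model.series.copy()
            tc = self.model.tc
            X = self.model.exog
        else:
            df = design.reset_index(drop=True).copy()
            tc = _centred_time(df)
            X, names = _design(
                df, tc, self.model.include_dx, self.model.include_ab,
                self.model.extra_terms, self.model.include_apoe4,
            )
            if names != self.model.param_names:  # pragma: no cover
                raise ValueError("design is incompatible with the fitted variant")
        cov = self.core.cov_re
        w = np.linalg.eigvalsh(cov)
        if w.min() < -1e-12 * max(w.max(), 1.0):
            raise ValueError("random-effects covariance is not PSD")
        subjects, gidx = np.unique(df["subject_id"].to_numpy(), return_inverse=True)
        covp = cov - w.min() * np.eye(2) if w.min() < 0 else cov
        L = np.linalg.cholesky(covp + 1e-300 * np.eye(2))
        b = rng.standard_normal((len(subjects), 2)) @ L.T
        eps = (
            rng.normal(0.0, self.sigma_e, len(df)) if self.sigma_e > 0
            else np.zeros(len(df))
        )
        logv = X @ self.core.beta + b[gidx, 0] + b[gidx, 1] * tc + eps
        out = df.copy()
        out["value"] = np.exp(logv)
        return out


def fit_lmm(
    series: pd.DataFrame, include_dx: bool = True, include_ab: bool = True,
    reml: bool = True, **kwargs,
) -> AtrophyLMMResults:
    """Fit the standard log-biomarker mixed model to a series."""
    return AtrophyLMM(
        series, include_dx=include_dx, include_ab=include_ab, **kwargs
    ).fit(reml=reml)


def simulate_from_fit(
    fit: AtrophyLMMResults, design: pd.DataFrame | None = None, seed=None,
) -> pd.DataFrame:
    return fit.simulate(design=design, seed=seed)


def lrt_covariate(
    series: pd.DataFrame, candidate_term: str,
    include_dx: bool = True, include_ab: bool = True,
) -> tuple[float, int, float]:
    """Likelihood-ratio screen for one extra fixed-effect term.

    Fits the base model and the model with ``candidate_term`` (a column
    name, or ``"column:time"`` for a slope effect) by ML on identical rows
    and returns (chi2, df, p). A term that adds no independent column
    (rank-deficient augmentation) is rejected.
    """
    if candidate_term in ("APOE4:time", "time:APOE4"):
        base_model = AtrophyLMM(series, include_dx=include_dx,
                                include_ab=include_ab, include_apoe4=False)
        full_model = AtrophyLMM(series, include_dx=include_dx,
                                include_ab=include_ab)
    else:
        base_model = AtrophyLMM(series, include_dx=include_dx,
                                include_ab=include_ab)
        full_model = AtrophyLMM(
            series, include_dx=include_dx, include_ab=include_ab,
            extra_terms=(candidate_term,),
        )
    rank_base = np.linalg.matrix_rank(base_model.exog)
    rank_full = np.linalg.matrix_rank(full_model.exog)
    if rank_full != rank_base + 1:
        raise ValueError(
            f"candidate term {candidate_term!r} adds no independent column "
            "(non-nested or redundant comparison)"
        )
    llf0 = base_model.fit(reml=False).llf
    llf1 = full_model.fit(reml=False).llf
    chi2 = max(2.0 * (llf1 - llf0), 0.0)
    df = 1
    p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p
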