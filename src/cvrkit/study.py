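"""Split-half discovery/evaluation study orchestration.

The full study mirrors a biomarker-discovery protocol on observational
cohort data: subjects are split 50/50 within strata of cognitive status x
amyloid status x sex x APOE4 x baseline-age quartile; the GA discovers a
composite value ratio on each half (per target group); every discovered CVR
and every traditional biomarker is then evaluated strictly on the opposite
half (out-of-fold) with sample-size estimates for three populations,
percentage error and both group separations; metric columns are min-max
normalised for a heatmap. A Pearson-residual trimming analysis probes the
robustness of the fixed effects to extreme trajectories.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .atlas import RegionAtlas
from .biomarkers import CVRSpec, compute_cvr, standard_biomarkers
from .ga import GAConfig, multistart
from .model import AtrophyLMM, AtrophyLMMResults
from .trial import (
    DESIGN_CI,
    DESIGN_CU,
    bootstrap_ci,
    group_separation,
    percentage_error,
    sample_size_estimate,
    sse_confint,
)

# -- stratified split -------------------------------------------------------


@dataclass
class SplitResult:
    """Subject-level 50/50 assignment with balance diagnostics."""

    assignments: pd.Series            # subject_id -> 1 or 2
    stratum_counts: pd.DataFrame      # per stratum, counts in each subset
    balance: dict[str, float]         # covariate -> balance p-value

    def subset(self, table: pd.DataFrame, which: int) -> pd.DataFrame:
        ids = self.assignments.index[self.assignments == which]
        return table[table["subject_id"].isin(ids)].reset_index(drop=True)


def stratified_split(table: pd.DataFrame, seed: int = 0) -> SplitResult:
    """Split subjects 50/50 within DX x AB x sex x APOE4 x age-quartile strata.

    Within each stratum subjects are shuffled and assigned alternately, so
    stratum counts differ by at most one; singleton strata are randomised.
    Balance p-values (rank-sum for continuous, chi-squared for categorical)
    are computed on baseline covariates.
    """
    if len(table) == 0:
        raise ValueError("cannot split an empty table")
    subj = (
        table.sort_values("visit_time")
        .groupby("subject_id", as_index=False)
        .first()[["subject_id", "age_bl", "sex", "DX", "AB", "APOE4", "education"]]
    )
    rng = np.random.default_rng(seed)
    age_q = pd.qcut(subj["age_bl"], 4, labels=False, duplicates="drop")
    # constant age collapses every quartile bin; one stratum level then
    age_q = pd.Series(age_q).fillna(0).astype(int)
    strata = subj.assign(age_q=age_q).groupby(
        ["DX", "AB", "sex", "APOE4", "age_q"], sort=True
    )
    assign = pd.Series(0, index=subj["subject_id"].to_numpy(), dtype=int)
    rows = []
    for key, grp in strata:
        ids = grp["subject_id"].to_numpy()
        rng.shuffle(ids)
        first = int(rng.integers(1, 3))  # random parity for odd strata
        labels = np.where(np.arange(len(ids)) % 2 == 0, first, 3 - first)
        assign.loc[ids] = labels
        rows.append(
            {"stratum": key, "n1": int((labels == 1).sum()),
             "n2": int((labels == 2).sum())}
        )
    counts = pd.DataFrame(rows)

    merged = subj.set_index("subject_id").assign(subset=assign)
    g1 = merged[merged["subset"] == 1]
    g2 = merged[merged["subset"] == 2]
    balance: dict[str, float] = {}
    for col in ("age_bl", "education"):
        balance[col] = float(sps.ranksums(g1[col], g2[col]).pvalue)
    for col in ("sex", "APOE4", "DX", "AB"):
        tab = pd.crosstab(merged["subset"], merged[col])
        if tab.shape == (2, 2) and (tab.values > 0).all():
            balance[col] = float(sps.chi2_contingency(tab.values)[1])
        else:
            balance[col] = np.nan
    return SplitResult(assignments=assign, stratum_counts=counts, balance=balance)


# -- metric evaluation ------------------------------------------------------

METRICS = ("sse_all", "sse_ci", "sse_cu", "error_pct", "t_ab", "t_dx")
#: metric -> True when lower is better
LOWER_BETTER = {
    "sse_all": True, "sse_ci": True, "sse_cu": True, "error_pct": True,
    "t_ab": False, "t_dx": False,
}


def evaluate_biomarker(
    series: pd.DataFrame,
    name: str,
    n_boot: int = 0,
    seed=None,
) -> dict:
    """All six evaluation metrics for one biomarker series.

    SSE is reported for three populations: all data under the 18-month
    design, amyloid-positive CI under 18 months, amyloid-positive CU under
    54 months. Error and group separations come from the all-data fit.
    Group cells whose population is absent are set to None. ``n_boot`` > 0
    adds percentile-bootstrap CIs for error and separations; SSE CIs use
    the delta method.
    """
    out: dict = {"biomarker": name}
    try:
        full = AtrophyLMM(series, include_dx=True, include_ab=True).fit()
        out["sse_all"] = sample_size_estimate(full, DESIGN_CI)
        out["sse_all_ci"] = sse_confint(full, DESIGN_CI)
        out["error_pct"] = percentage_error(full)
        out["t_ab"] = group_separation(full, "AB")
        out["t_dx"] = group_separation(full, "DX")
    except (ValueError, RuntimeError) as exc:
        warnings.warn(f"{name}: all-data fit unavailable ({exc})", stacklevel=2)
        for key in ("sse_all", "sse_all_ci", "error_pct", "t_ab", "t_dx"):
            out[key] = None

    for key, dx_val, design in (
        ("sse_ci", 1, DESIGN_CI), ("sse_cu", 0, DESIGN_CU),
    ):
        sub = series[(series["AB"] == 1) & (series["DX"] == dx_val)]
        try:
            fit = AtrophyLMM(sub, include_dx=False, include_ab=False).fit()
            out[key] = sample_size_estimate(fit, design)
            out[key + "_ci"] = sse_confint(fit, design)
        except (ValueError, RuntimeError) as exc:
            warnings.warn(f"{name}: {key} unavailable ({exc})", stacklevel=2)
            out[key] = None
            out[key + "_ci"] = None

    if n_boot > 0 and out.get("error_pct") is not None:
        rng = np.random.default_rng(seed)
        for key, fn in (
            ("error_pct", percentage_error),
            ("t_ab", lambda f: group_separation(f, "AB")),
            ("t_dx", lambda f: group_separation(f, "DX")),
        ):
            ci = bootstrap_ci(
                series, fn, n_boot=n_boot,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            out[key + "_ci"] = (ci.ci_low, ci.ci_high)
    return out


def normalize_scores(metrics: pd.DataFrame) -> pd.DataFrame:
    """Orientation-aware min-max normalisation per metric column.

    1 = best, 0 = worst within each column; lower is better for SSE and
    error, higher for the t-statistics. Constant columns map to 0.5 with a
    warning.
    """
    if len(metrics) < 2:
        raise ValueError("need at least two biomarkers to normalise")
    out = pd.DataFrame(index=metrics.index, columns=metrics.columns, dtype=float)
    for col in metrics.columns:
        x = metrics[col].astype(float)
        lo, hi = np.nanmin(x), np.nanmax(x)
        if not np.isfinite(hi - lo) or hi == lo:
            warnings.warn(f"metric {col!r} is constant; scores set to 0.5",
                          stacklevel=2)
            out[col] = 0.5
            continue
        score = (x - lo) / (hi - lo)
        if LOWER_BETTER.get(col, True):
            score = 1.0 - score
        out[col] = score
    return out


# -- sensitivity trimming ---------------------------------------------------


@dataclass
class TrimResult:
    """Refit after excluding subjects with extreme Pearson residuals."""

    refit: AtrophyLMMResults
    shifts: pd.Series                 # |delta beta| / SE_original
    n_excluded_subjects: int
    excluded_subjects: tuple
    level_lost: bool = False


def sensitivity_trim(
    series: pd.DataFrame,
    include_dx: bool = True,
    include_ab: bool = True,
    threshold: float = 3.0,
) -> TrimResult:
    """Exclude subjects with any |Pearson residual| > threshold and refit.

    Reports each fixed effect's shift in units of its original standard
    error. If trimming removes an entire covariate level the refit is
    flagged (``level_lost``).
    """
    model = AtrophyLMM(series, include_dx=include_dx, include_ab=include_ab)
    fit = model.fit()
    if not fit.converged:
        raise RuntimeError("sensitivity_trim requires a converged original fit")
    pearson = np.abs(fit.pearson_resid)
    flagged = pd.Series(pearson, index=model.series["subject_id"]).groupby(
        level=0
    ).max()
    bad = tuple(flagged.index[flagged > threshold])
    if not bad:
        return TrimResult(fit, pd.Series(0.0, index=fit.params.index), 0, ())
    kept = series[~series["subject_id"].isin(bad)]

    level_lost = (include_dx and kept["DX"].nunique() < 2) or (
        include_ab and kept["AB"].nunique() < 2
    )
    if level_lost:
        warnings.warn(
            "trimming removed a covariate level; keeping the original fit",
            stacklevel=2,
        )
        return TrimResult(fit, pd.Series(0.0, index=fit.params.index),
                          len(bad), bad, level_lost=True)
    refit = AtrophyLMM(kept, include_dx=include_dx, include_ab=include_ab).fit()
    with np.errstate(divide="ignore", invalid="ignore"):
        shifts = (refit.params - fit.params).abs() / fit.bse
    return TrimResult(refit, shifts, len(bad), bad, level_lost=False)


# -- full study -------------------------------------------------------------


@dataclass
class StudyReport:
    """Out-of-fold evaluation of discovered CVRs against baselines."""

    metrics: pd.DataFrame             # one row per (subset, biomarker)
    specs: dict                       # (discovery_subset, target) -> CVRSpec
    split: SplitResult
    seed: int
    sensitivity: dict = field(default_factory=dict)

    def metric_table(self, subset: int) -> pd.DataFrame:
        sub = self.metrics[self.metrics["eval_subset"] == subset]
        return sub.set_index("biomarker")[list(METRICS)]

    def heatmap_scores(self, subset: int) -> pd.DataFrame:
        return normalize_scores(self.metric_table(subset))

    def assert_out_of_fold(self) -> None:
        """Audit: no CVR may be evaluated on its own discovery subset."""
        cvr = self.metrics.dropna(subset=["discovery_subset"])
        same = cvr[cvr["discovery_subset"] == cvr["eval_subset"]]
        if len(same):
            raise AssertionError(
                f"in-fold evaluation rows present: {same['biomarker'].tolist()}"
            )


def run_study(
    table: pd.DataFrame,
    atlas: RegionAtlas,
    ga_config: GAConfig,
    seed: int = 0,
    n_boot: int = 1000,
    run_sensitivity: bool = False,
    targets: tuple[str, ...] = ("CI", "CU"),
) -> StudyReport:
    """Full split-half study: discover per subset and target group,
    evaluate everything out-of-fold.

    A master seed derives the split seed, the GA seeds (one per subset x
    target) and the bootstrap seeds through a fixed counter, so the whole
    study is reproducible from one integer. ``n_boot`` is the bootstrap
    replicate count for the error/separation CIs (default 1000; pass a
    smaller test profile, or 0 to skip them, for desk-scale runs).
    """
    master = np.random.default_rng(seed)
    split_seed = int(master.integers(0, 2**31 - 1))
    ga_seeds = {
        (s, tgt): int(master.integers(0, 2**31 - 1))
        for s in (1, 2) for tgt in targets
    }
    boot_seeds = {s: int(master.integers(0, 2**31 - 1)) for s in (1, 2)}

    split = stratified_split(table, seed=split_seed)
    halves = {1: split.subset(table, 1), 2: split.subset(table, 2)}

    specs: dict = {}
    for s in (1, 2):
        for tgt in targets:
            cfg = dataclasses.replace(ga_config, target_group=tgt)
            best = multistart(halves[s], atlas, cfg, seed=ga_seeds[(s, tgt)])
            specs[(s, tgt)] = best.spec

    rows = []
    sensitivity: dict = {}
    for eval_subset in (1, 2):
        other = 3 - eval_subset
        eval_table = halves[eval_subset]
        rng = np.random.default_rng(boot_seeds[eval_subset])
        candidates: list[tuple[str, pd.DataFrame, int | None]] = []
        for tgt in targets:
            spec = specs.get((other, tgt))
            if spec is not None:
                candidates.append(
                    (f"CVR_{tgt}", compute_cvr(eval_table, spec), other)
                )
        for name, series in standard_biomarkers(eval_table).items():
            candidates.append((name, series, None))

        for name, series, disc in candidates:
            row = evaluate_biomarker(
                series, name, n_boot=n_boot,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            row["eval_subset"] = eval_subset
            row["discovery_subset"] = disc
            rows.append(row)
            if run_sensitivity and disc is not None:
                sensitivity[(eval_subset, name)] = sensitivity_trim(series)

    report = StudyReport(
        metrics=pd.DataFrame(rows), specs=specs, split=split, seed=seed,
        sensitivity=sensitivity,
    )
    report.assert_out_of_fold()
    return report
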