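"""Selection inference on mother-offspring and mother-oocyte data.

Implements the transmission regression, the normality-gated mean-shift test,
follicle-stage shift summaries, maternal-age and litter-size associations,
the tissue-stability coefficient of variation, and culture-day copy-number
summaries.

Test policy throughout: Shapiro-Wilk at alpha = 0.05 gates between the
parametric test (t-test) and its rank-based fallback (Wilcoxon signed-rank
for one sample, Mann-Whitney U for two samples).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import log_shifts, shift_ratios
from .errors import DegenerateInputError, InsufficientDataError
from .records import STAGES, OocyteRecord, TransmissionPair

__all__ = [
    "RegressionFit",
    "MeanShiftTest",
    "StageShiftSummary",
    "TissueStability",
    "fit_transmission_regression",
    "mean_shift_test",
    "stage_shift_summary",
    "age_effect",
    "litter_size_association",
    "tissue_cv",
    "copy_dynamics_summary",
    "holm_adjust",
]

_SHAPIRO_ALPHA = 0.05


def _pair_frame(pairs: Iterable[TransmissionPair]) -> pd.DataFrame:
    rows = [{
        "mother_id": p.mother_id, "pup_id": p.pup_id,
        "generation": p.generation, "mother_h": p.mother_h, "pup_h": p.pup_h,
        "maternal_age_months": p.maternal_age_months,
        "litter_id": p.litter_id, "litter_size": p.litter_size,
    } for p in pairs]
    return pd.DataFrame(rows)


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Holm step-down adjustment (never decreases a p-value)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="holm")[1]


def _gated_two_sample(a: np.ndarray, b: np.ndarray) -> tuple[float, str]:
    """Two-sample comparison with the Shapiro-Wilk normality gate."""
    normal = True
    for arr in (a, b):
        if np.ptp(arr) == 0:
            normal = False
            break
        if stats.shapiro(arr).pvalue < _SHAPIRO_ALPHA:
            normal = False
            break
    if normal:
        return float(stats.ttest_ind(a, b).pvalue), "t-test"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue), \
        "mann-whitney"


# ---------------------------------------------------------------------------
# Transmission regression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegressionFit:
    slope: float
    intercept: float | None
    p_value: float
    r_squared: float
    n: int
    through_origin: bool
    slope_stderr: float = float("nan")

    def slope_ci95(self) -> tuple[float, float]:
        dof = self.n - (1 if self.through_origin else 2)
        t = stats.t.ppf(0.975, dof)
        return (self.slope - t * self.slope_stderr,
                self.slope + t * self.slope_stderr)


def fit_transmission_regression(
    pairs: Iterable[TransmissionPair],
    through_origin: bool = False,
) -> RegressionFit:
    """Least-squares fit of pup heteroplasmy on mother heteroplasmy.

    A slope below 1 (the unbiased-transmission line) indicates a reduction of
    the variant in offspring.  The default fit includes an intercept;
    ``through_origin=True`` forces the line through (0, 0).
    """
    df = _pair_frame(pairs)
    if len(df) < 3:
        raise InsufficientDataError("regression needs at least 3 pairs")
    x = df["mother_h"].to_numpy(dtype=float)
    y = df["pup_h"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise DegenerateInputError("all maternal heteroplasmies identical; "
                                   "design matrix is singular")
    n = x.size
    if through_origin:
        sxx = float(np.sum(x * x))
        slope = float(np.sum(x * y)) / sxx
        resid = y - slope * x
        dof = n - 1
        sigma2 = float(np.sum(resid ** 2)) / dof
        se = np.sqrt(sigma2 / sxx)
        tstat = slope / se if se > 0 else np.inf
        p = 2.0 * stats.t.sf(abs(tstat), dof)
        ss_tot = float(np.sum(y * y))  # uncentred for through-origin R^2
        r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 1.0
        return RegressionFit(slope=slope, intercept=None, p_value=float(p),
                             r_squared=r2, n=n, through_origin=True,
                             slope_stderr=float(se))
    res = stats.linregress(x, y)
    return RegressionFit(slope=float(res.slope), intercept=float(res.intercept),
                         p_value=float(res.pvalue),
                         r_squared=float(res.rvalue ** 2), n=n,
                         through_origin=False,
                         slope_stderr=float(res.stderr))


# ---------------------------------------------------------------------------
# Mean log-shift test (normality gated)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MeanShiftTest:
    mean_log_shift: float
    ci95: tuple[float, float]
    p_value: float
    test_used: str
    n: int
    n_excluded: int = 0


def mean_shift_test(pairs: Iterable[TransmissionPair],
                    boundary_policy: str = "exclude") -> MeanShiftTest:
    """Test whether the mean log shift differs from 0 (unbiased transmission).

    Log shifts are computed per pair (boundary records handled by
    ``boundary_policy``).  Shapiro-Wilk gates between a one-sample t-test and
    a Wilcoxon signed-rank test against 0; the gate's choice is reported.
    """
    df = _pair_frame(pairs)
    usable = df[(df.mother_h > 0) & (df.mother_h < 1)]
    shifts, n_excl = log_shifts(usable["pup_h"].to_numpy(),
                                usable["mother_h"].to_numpy(),
                                policy=boundary_policy)
    n_excl += len(df) - len(usable)
    if shifts.size < 3:
        raise InsufficientDataError(
            f"mean_shift_test needs >= 3 usable pairs, got {shifts.size}")
    mean = float(shifts.mean())
    if np.ptp(shifts) == 0:
        # degenerate: identical shifts for every pair
        return MeanShiftTest(mean_log_shift=mean, ci95=(mean, mean),
                             p_value=1.0 if mean == 0 else 0.0,
                             test_used="zero-variance", n=shifts.size,
                             n_excluded=n_excl)
    sem = stats.sem(shifts)
    t = stats.t.ppf(0.975, shifts.size - 1)
    ci = (mean - t * sem, mean + t * sem)
    if stats.shapiro(shifts).pvalue >= _SHAPIRO_ALPHA:
        p = float(stats.ttest_1samp(shifts, 0.0).pvalue)
        used = "t-test"
    else:
        p = float(stats.wilcoxon(shifts).pvalue)
        used = "wilcoxon"
    return MeanShiftTest(mean_log_shift=mean, ci95=ci, p_value=p,
                         test_used=used, n=shifts.size, n_excluded=n_excl)


# ---------------------------------------------------------------------------
# Follicle-stage shift summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StageShiftSummary:
    stage: str
    n: int
    mean_ratio: float
    median_ratio: float
    ci95: tuple[float, float]
    pairwise_p: dict = field(default_factory=dict)


def stage_shift_summary(
    records: Iterable[OocyteRecord | TransmissionPair],
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> list[StageShiftSummary]:
    """Per-stage mean shift ratio with bootstrap CI and stage-pair tests.

    Mother-pup pairs may be mixed in; they are treated as the ``offspring``
    reference level.  Consecutive present stages are compared with
    Mann-Whitney U; raw and Holm-adjusted p-values are attached to the later
    stage of each pair.
    """
    by_stage: dict[str, list[float]] = {}
    for rec in records:
        if isinstance(rec, TransmissionPair):
            stage, h, h0 = "offspring", rec.pup_h, rec.mother_h
        else:
            stage = rec.stage if rec.stage is not None else f"day{rec.day}"
            h, h0 = rec.h, rec.mother_h
        if not (0.0 < h0 < 1.0):
            warnings.warn(f"record with boundary mother_h={h0} skipped",
                          stacklevel=2)
            continue
        by_stage.setdefault(stage, []).append(
            float(shift_ratios([h], [h0])[0]))

    known = [s for s in STAGES if s in by_stage]
    extra = sorted(s for s in by_stage if s not in STAGES)
    ordered = known + extra
    rng = np.random.default_rng(seed)

    summaries: list[StageShiftSummary] = []
    for stage in ordered:
        vals = np.asarray(by_stage[stage])
        mean = float(vals.mean())
        if vals.size > 1:
            boots = rng.choice(vals, size=(n_bootstrap, vals.size),
                               replace=True).mean(axis=1)
            ci = (float(np.quantile(boots, 0.025)),
                  float(np.quantile(boots, 0.975)))
            ci = (min(ci[0], mean), max(ci[1], mean))
        else:
            ci = (mean, mean)
        summaries.append(StageShiftSummary(
            stage=stage, n=vals.size, mean_ratio=mean,
            median_ratio=float(np.median(vals)), ci95=ci))

    raw_ps, keys = [], []
    for prev, cur in zip(ordered, ordered[1:]):
        a, b = np.asarray(by_stage[prev]), np.asarray(by_stage[cur])
        if np.ptp(np.concatenate([a, b])) == 0:
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        raw_ps.append(p)
        keys.append((prev, cur))
    adj = holm_adjust(raw_ps)
    pmap = {k: {"raw": raw, "holm": float(h)}
            for k, raw, h in zip(keys, raw_ps, adj)}
    out = []
    for s in summaries:
        pairwise = {f"{a}-vs-{b}": v for (a, b), v in pmap.items()
                    if b == s.stage or a == s.stage}
        out.append(StageShiftSummary(
            stage=s.stage, n=s.n, mean_ratio=s.mean_ratio,
            median_ratio=s.median_ratio, ci95=s.ci95, pairwise_p=pairwise))
    return out


# ---------------------------------------------------------------------------
# Maternal age and litter size
# ---------------------------------------------------------------------------

def age_effect(pairs: Iterable[TransmissionPair],
               per_delivery: bool = True) -> dict:
    """Association between maternal age and the per-delivery mean shift ratio.

    Shifts are aggregated per delivery (litter) following the figure-level
    convention; ``per_delivery=False`` correlates at pup level instead.
    Returns Pearson (primary) and Spearman statistics.
    """
    df = _pair_frame(pairs)
    df = df.dropna(subset=["maternal_age_months", "litter_id"])
    if df.empty:
        raise InsufficientDataError("no pairs with age and litter covariates")
    df = df[(df.mother_h > 0) & (df.mother_h < 1) & (df.pup_h < 1)]
    df = df.assign(ratio=shift_ratios(df["pup_h"].to_numpy(),
                                      df["mother_h"].to_numpy()))
    if per_delivery:
        agg = df.groupby("litter_id").agg(
            ratio=("ratio", "mean"),
            age=("maternal_age_months", "first")).reset_index()
    else:
        agg = df.rename(columns={"maternal_age_months": "age"})
    if agg["age"].nunique() < 2:
        raise DegenerateInputError("need at least two distinct maternal ages")
    pear = stats.pearsonr(agg["age"], agg["ratio"])
    spear = stats.spearmanr(agg["age"], agg["ratio"])
    return {
        "per_delivery_means": agg,
        "correlation": float(pear.statistic),
        "p_value": float(pear.pvalue),
        "spearman_rho": float(spear.statistic),
        "spearman_p": float(spear.pvalue),
        "n": int(len(agg)),
    }


def litter_size_association(pairs: Iterable[TransmissionPair],
                            first_litter_only: bool = False) -> dict:
    """Correlation of litter size with maternal heteroplasmy, one record per
    delivery; optionally restricted to each mother's first delivery."""
    df = _pair_frame(pairs)
    df = df.dropna(subset=["litter_id", "litter_size"])
    if df.empty:
        raise InsufficientDataError("no pairs with litter covariates")
    per = df.groupby("litter_id").agg(
        mother_id=("mother_id", "first"),
        mother_h=("mother_h", "first"),
        litter_size=("litter_size", "first"),
        age=("maternal_age_months", "first")).reset_index()
    if first_litter_only:
        per = per.sort_values(["mother_id", "age", "litter_id"])
        per = per.groupby("mother_id", as_index=False).first()
    if per["litter_size"].nunique() < 2 or per["mother_h"].nunique() < 2:
        raise DegenerateInputError(
            "constant litter size or maternal heteroplasmy; "
            "correlation undefined")
    res = stats.pearsonr(per["mother_h"], per["litter_size"])
    return {
        "correlation": float(res.statistic),
        "p_value": float(res.pvalue),
        "n_deliveries": int(len(per)),
    }


# ---------------------------------------------------------------------------
# Tissue stability
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TissueStability:
    per_mouse_cv: dict[str, float]  # percent
    grand_mean_cv: float  # percent


def tissue_cv(measurements: pd.DataFrame) -> TissueStability:
    """Coefficient of variation of heteroplasmy across tissues, per mouse.

    ``measurements`` needs columns ``mouse_id``, ``tissue`` and ``h``.  The
    per-mouse CV is the sample standard deviation divided by the mean across
    its tissues, in percent; the grand mean averages the per-mouse CVs.
    Scale-invariant per mouse.  Mice with mean 0 are excluded with a warning.
    """
    per: dict[str, float] = {}
    for mouse, grp in measurements.groupby("mouse_id"):
        h = grp["h"].to_numpy(dtype=float)
        if h.size < 2:
            warnings.warn(f"mouse {mouse}: fewer than 2 tissues, skipped",
                          stacklevel=2)
            continue
        m = h.mean()
        if m == 0:
            warnings.warn(f"mouse {mouse}: mean heteroplasmy 0, CV undefined",
                          stacklevel=2)
            continue
        per[str(mouse)] = float(np.std(h, ddof=1) / m * 100.0)
    if not per:
        raise InsufficientDataError("no mouse with >= 2 tissues and mean > 0")
    return TissueStability(per_mouse_cv=per,
                           grand_mean_cv=float(np.mean(list(per.values()))))


# ---------------------------------------------------------------------------
# Copy-number time-course summaries
# ---------------------------------------------------------------------------

def copy_dynamics_summary(records: Iterable[OocyteRecord]) -> dict:
    """Per-day per-group copy-number summaries and the day-7 comparison.

    Emits mean +/- SEM of wild-type, mutant and total copies plus
    median/min/max of heteroplasmy per (group, day).  If both groups are
    present on day 7, total copies are compared with the normality-gated
    two-sample policy; otherwise the comparison is skipped with a warning.
    """
    rows = []
    for r in records:
        if r.day is None or r.wt_copies is None or r.mut_copies is None:
            continue
        rows.append({"group": r.group, "day": r.day, "wt": r.wt_copies,
                     "mut": r.mut_copies, "total": r.wt_copies + r.mut_copies,
                     "h": r.h})
    if not rows:
        raise InsufficientDataError("no records with culture day and copies")
    df = pd.DataFrame(rows)
    if df["day"].nunique() < 2:
        raise InsufficientDataError("need records spanning >= 2 culture days")

    def sem(x):
        return float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else 0.0

    table = df.groupby(["group", "day"]).agg(
        n=("h", "size"),
        wt_mean=("wt", "mean"), wt_sem=("wt", sem),
        mut_mean=("mut", "mean"), mut_sem=("mut", sem),
        total_mean=("total", "mean"), total_sem=("total", sem),
        h_median=("h", "median"), h_min=("h", "min"), h_max=("h", "max"),
    ).reset_index()

    day7 = df[df.day == 7]
    comparison = None
    groups = sorted(day7["group"].unique())
    if len(groups) >= 2:
        a = day7[day7.group == groups[0]]["total"].to_numpy()
        b = day7[day7.group == groups[1]]["total"].to_numpy()
        p, used = _gated_two_sample(a, b)
        comparison = {"groups": groups[:2], "p_value": p, "test_used": used,
                      "means": [float(a.mean()), float(b.mean())]}
    else:
        warnings.warn("day-7 comparison skipped: fewer than two groups present",
                      stacklevel=2)
    return {"per_day": table, "day7_comparison": comparison}
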