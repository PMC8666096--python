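"""Sandwich-immunoassay processing: calibration, duplicate QC, censoring,
and nonparametric group comparison.

A plate run is reduced to per-subject concentrations in four steps:

1. **Calibration** — a four-parameter logistic (4PL) is fitted to the
   standard curve (serial dilutions spanning 40 down to 0.055 ng/mL):
   ``signal = d + (a - d) / (1 + (conc / c)**b)`` with lower/upper
   asymptotes, inflection ``c`` and slope ``b``.  Unknown signals are
   back-calculated through the closed-form inverse.
2. **Duplicate QC** — each sample is assayed in duplicate; duplicates whose
   back-calculated concentrations have CV% strictly above 20% are flagged
   for repeat, otherwise the mean is taken.
3. **Censoring** — concentrations below the lower limit of quantification
   (LLOQ, 0.039 ng/mL) but above the limit of detection (LOD, 0.012 ng/mL)
   are recorded as LLOQ/2; values at or below the LOD are recorded as LOD/2
   by default (configurable to exclusion).
4. **Comparison** — groups are summarised by median and 25-75% IQR and
   compared with the two-sided Wilcoxon rank-sum (Mann-Whitney) test, exact
   when the pooled sample is small and tie-free, asymptotic with tie
   correction otherwise.  Spearman rank correlation covers associations with
   covariates, and a sensitivity filter drops samples whose pre-freeze
   processing time reached 4 days or more.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "CalibrationCurve",
    "AssayMeasurement",
    "GroupComparison",
    "four_pl",
    "fit_calibration",
    "back_calculate",
    "qc_duplicates",
    "censor_impute",
    "process_plate",
    "compare_groups",
    "spearman_assoc",
    "sensitivity_filter",
    "to_long_format",
]

DEFAULT_LLOQ = 0.039  # ng/mL
DEFAULT_LOD = 0.012   # ng/mL


def four_pl(conc, lower: float, upper: float, inflection: float, slope: float):
    """4PL response: lower/upper asymptotes, inflection (EC50), Hill slope."""
    conc = np.asarray(conc, dtype=float)
    return upper + (lower - upper) / (1.0 + (conc / inflection) ** slope)


@dataclass
class CalibrationCurve:
    lower: float       # signal as conc -> 0
    upper: float       # signal as conc -> inf
    inflection: float  # ng/mL at half-maximal signal
    slope: float
    standards: dict[float, float] = field(default_factory=dict)
    lloq: float = DEFAULT_LLOQ
    lod: float = DEFAULT_LOD

    def __post_init__(self) -> None:
        if not self.lod < self.lloq:
            raise ValueError(f"LOD {self.lod} must be below LLOQ {self.lloq}")

    def signal(self, conc):
        return four_pl(conc, self.lower, self.upper, self.inflection, self.slope)


def fit_calibration(
    standard_table: pd.DataFrame,
    lloq: float = DEFAULT_LLOQ,
    lod: float = DEFAULT_LOD,
) -> CalibrationCurve:
    """Least-squares 4PL fit to a standards table.

    ``standard_table`` needs a ``concentration`` column (ng/mL) and either a
    ``signal`` column or duplicate columns ``signal_1``/``signal_2`` that are
    averaged.  At least five distinct standards are required and the mean
    signals must be monotone in concentration.
    """
    df = standard_table.copy()
    if "signal" not in df.columns:
        df["signal"] = df[["signal_1", "signal_2"]].mean(axis=1)
    means = (
        df.groupby("concentration")["signal"].mean().sort_index()
    )
    if len(means) < 5:
        raise ValueError(f"need >= 5 standard points, got {len(means)}")
    conc = means.index.to_numpy(dtype=float)
    sig = means.to_numpy(dtype=float)
    # gross non-monotonicity (a corrupted standard) is a hard error; small
    # adjacent inversions from duplicate noise on the flat ends are not
    rho = stats.spearmanr(conc, sig).statistic
    if abs(rho) < 0.9:
        raise ValueError(
            f"standard signals are not monotone in concentration (rank "
            f"correlation {rho:.2f})"
        )
    increasing = sig[-1] > sig[0]
    lo0 = float(sig.min()) if increasing else float(sig.max())
    hi0 = float(sig.max()) if increasing else float(sig.min())
    p0 = [lo0, hi0, float(np.median(conc)), 1.0]
    params, _ = optimize.curve_fit(four_pl, conc, sig, p0=p0, maxfev=20000)
    curve = CalibrationCurve(
        lower=float(params[0]),
        upper=float(params[1]),
        inflection=float(params[2]),
        slope=float(params[3]),
        standards=dict(zip(conc, sig)),
        lloq=lloq,
        lod=lod,
    )
    grid = np.geomspace(conc.min(), conc.max(), 50)
    fitted = curve.signal(grid)
    d = np.diff(fitted)
    if not (np.all(d > 0) or np.all(d < 0)):
        raise ValueError("fitted calibration curve is not monotone over the "
                         "standard range")
    return curve


def back_calculate(signal: float, curve: CalibrationCurve) -> float | None:
    """Closed-form inverse of the 4PL; None when the signal sits at or
    outside the asymptotes (not invertible -> censored downstream)."""
    lo, hi = sorted((curve.lower, curve.upper))
    if not lo < signal < hi:
        return None
    ratio = (curve.lower - curve.upper) / (signal - curve.upper) - 1.0
    if ratio <= 0:
        return None
    return float(curve.inflection * ratio ** (1.0 / curve.slope))


def qc_duplicates(
    concentrations: tuple[float, float], cv_threshold: float = 20.0
) -> tuple[float, float, bool]:
    """(mean, CV%, repeat_required) for a duplicate pair of back-calculated
    concentrations.  CV% = 100 * sd / mean (sample sd, ddof=1); the repeat
    flag trips strictly above the threshold."""
    a, b = concentrations
    mean = (a + b) / 2.0
    if mean <= 0:
        raise ValueError(f"non-positive duplicate mean {mean}")
    cv = 100.0 * float(np.std([a, b], ddof=1)) / mean
    return mean, cv, cv > cv_threshold


@dataclass
class AssayMeasurement:
    subject_id: str
    group: str
    visit_month: str
    duplicate_signals: tuple[float, float]
    processing_days: int | None = None
    concentration: float | None = None
    cv_percent: float | None = None
    censor_state: str = "quantified"   # quantified | between_lod_lloq | below_lod
    repeat_required: bool = False


def censor_impute(
    concentration: float | None,
    lloq: float = DEFAULT_LLOQ,
    lod: float = DEFAULT_LOD,
    below_lod_policy: str = "half_lod",
) -> tuple[float | None, str]:
    """Apply the assay's reporting limits.

    >= LLOQ: unchanged, 'quantified'.  Between LOD and LLOQ: recorded as
    LLOQ/2, 'between_lod_lloq'.  At or below LOD (including signals that did
    not invert): LOD/2 with 'below_lod' under the default policy, or dropped
    (None) under ``below_lod_policy='exclude'``.
    """
    if lod >= lloq:
        raise ValueError(f"LOD {lod} must be below LLOQ {lloq}")
    if concentration is not None and concentration < 0:
        raise ValueError(f"negative concentration {concentration}")
    if concentration is None or concentration <= lod:
        if below_lod_policy == "exclude":
            return None, "below_lod"
        return lod / 2.0, "below_lod"
    if concentration < lloq:
        return lloq / 2.0, "between_lod_lloq"
    return concentration, "quantified"


def process_plate(
    plate: pd.DataFrame,
    curve: CalibrationCurve,
    cv_threshold: float = 20.0,
    below_lod_policy: str = "half_lod",
) -> list[AssayMeasurement]:
    """Back-calculate, QC and censor every subject-visit row of a plate.

    ``plate`` columns: subject_id, group, visit_month, dup_signal_1,
    dup_signal_2 and optionally processing_days.
    """
    out: list[AssayMeasurement] = []
    for row in plate.itertuples(index=False):
        sig = (float(row.dup_signal_1), float(row.dup_signal_2))
        m = AssayMeasurement(
            subject_id=str(row.subject_id),
            group=str(row.group),
            visit_month=str(row.visit_month),
            duplicate_signals=sig,
            processing_days=(
                int(row.processing_days)
                if "processing_days" in plate.columns
                and not pd.isna(row.processing_days)
                else None
            ),
        )
        concs = [back_calculate(s, curve) for s in sig]
        if all(c is not None for c in concs):
            mean, cv, repeat = qc_duplicates((concs[0], concs[1]), cv_threshold)
            m.cv_percent = cv
            m.repeat_required = repeat
            m.concentration, m.censor_state = censor_impute(
                mean, curve.lloq, curve.lod, below_lod_policy
            )
        else:
            # at least one signal outside the invertible range: censor low
            m.concentration, m.censor_state = censor_impute(
                None, curve.lloq, curve.lod, below_lod_policy
            )
        out.append(m)
    return out


@dataclass
class GroupComparison:
    n_a: int
    n_b: int
    median_a: float
    median_b: float
    iqr_a: tuple[float, float]
    iqr_b: tuple[float, float]
    statistic: float
    p_value: float


def compare_groups(values_a, values_b, exact_max_n: int = 30) -> GroupComparison:
    """Median/IQR summary plus two-sided Wilcoxon rank-sum test.

    The exact null distribution is used when the pooled sample has at most
    ``exact_max_n`` observations and no ties; otherwise the tie-corrected
    normal approximation.  IQR bounds are linear-interpolation quantiles.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (pooled.size <= exact_max_n and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return GroupComparison(
        n_a=int(a.size),
        n_b=int(b.size),
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
        iqr_a=(float(np.percentile(a, 25)), float(np.percentile(a, 75))),
        iqr_b=(float(np.percentile(b, 25)), float(np.percentile(b, 75))),
        statistic=float(res.statistic),
        p_value=float(min(1.0, res.pvalue)),
    )


def spearman_assoc(x, y) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties) with its
    t-approximation p-value.  Constant input is undefined -> (nan, nan)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired vectors with n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return math.nan, math.nan
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def sensitivity_filter(
    measurements: list[AssayMeasurement], max_days: int = 4
) -> list[AssayMeasurement]:
    """Withhold samples processed over ``max_days`` days or more; samples
    with unknown processing time are retained (with a warning upstream)."""
    return [
        m
        for m in measurements
        if m.processing_days is None or m.processing_days < max_days
    ]


def to_long_format(measurements: list[AssayMeasurement]) -> pd.DataFrame:
    """Tidy long table (one row per subject-visit) for external longitudinal
    modelling, e.g. a multi-level mixed-effects regression."""
    return pd.DataFrame(
        [
            {
                "subject_id": m.subject_id,
                "group": m.group,
                "visit_month": m.visit_month,
                "concentration": m.concentration,
                "censor_state": m.censor_state,
                "cv_percent": m.cv_percent,
                "repeat_required": m.repeat_required,
                "processing_days": m.processing_days,
            }
            for m in measurements
        ]
    )
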