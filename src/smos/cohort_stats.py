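"""Inferential layer: normative z-tests, operative contrast, correlations.

A patient cohort's SMoS is compared against the population reference values
one stratum at a time with two-tailed one-sample z-tests: the population
mean is treated as a known constant, so the test statistic and confidence
interval use only the sample standard error,

    z = (x̄ − μ₀) / (s/√n),    CI = (x̄ − μ₀) ± z_{1−α/2} · s/√n.

The operative-vs-non-operative severity contrast is a two-tailed independent
two-sample z-test with the unpooled (Welch-style) standard error and normal
quantiles. Association between SMoS and patient-reported disability (ODI,
NDI, VAS) uses Pearson's product-moment correlation with pairwise deletion,
and the Shapiro–Wilk test serves as a normality diagnostic attached to the
report — it never gates computation.

No multiple-testing correction is applied across strata by default;
optional Bonferroni-adjusted p-values can be added to the report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
from scipy import stats

from .errors import (
    EmptyStratumError,
    InsufficientDataError,
    InsufficientPairsError,
    UndefinedCorrelationError,
    UnsupportedSampleSizeError,
)
from .norms import AGE_BANDS, TOTAL_BAND, NormsTable, classify_age_band

if TYPE_CHECKING:  # pragma: no cover
    from .cohort_io import CohortRecord

DEFAULT_ALPHA = 0.05
SMALL_N_THRESHOLD = 10  # strata smaller than this get a small-n flag


@dataclass(frozen=True)
class StratumSummary:
    """Sample size, mean, SD (n−1 denominator) and SE of one stratum's SMoS."""

    n: int
    mean: float
    sd: float | None
    se: float | None
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class ZTestResult:
    """Two-tailed z-test outcome: difference, symmetric CI, z, p."""

    mean_difference: float
    ci_low: float
    ci_high: float
    z: float
    p: float
    alpha: float
    flags: tuple[str, ...] = ()

    @property
    def significant(self) -> bool:
        return self.p < self.alpha


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation with its r², two-sided p and pair count."""

    r: float
    r_squared: float
    p: float
    n: int


@dataclass(frozen=True)
class StratumComparison:
    """One row of the stratified normative comparison."""

    label: str
    age_band: str  # band label or "total"
    sex: str  # male | female | combined
    summary: StratumSummary | None = None
    test: ZTestResult | None = None
    reference_mean: float | None = None
    skipped: bool = False
    skip_reason: str | None = None
    p_bonferroni: float | None = None


def summarize_scores(values: Sequence[float]) -> StratumSummary:
    """Summary statistics of raw SMoS values (n, mean, sample SD, SE)."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise EmptyStratumError("cannot summarize an empty stratum")
    n = int(arr.size)
    mean = float(arr.mean())
    if n == 1:
        return StratumSummary(n=n, mean=mean, sd=None, se=None, flags=("sd-undefined",))
    sd = float(arr.std(ddof=1))
    return StratumSummary(n=n, mean=mean, sd=sd, se=sd / math.sqrt(n))


def summarize_stratum(records: Iterable["CohortRecord"]) -> StratumSummary:
    """Summary of SMoS totals over records that have a computed score."""
    scores = [r.smos.total for r in records if r.smos is not None]
    if not scores:
        raise EmptyStratumError("no records with a computed SMoS in stratum")
    return summarize_scores(scores)


def _two_sided_p(z: float) -> float:
    return float(2.0 * stats.norm.sf(abs(z)))


def _z_result(diff: float, se: float, alpha: float, flags: tuple[str, ...]) -> ZTestResult:
    if se == 0.0:
        # degenerate stratum (all scores identical): the test is decided by
        # the sign of the difference alone
        z = 0.0 if diff == 0.0 else math.copysign(math.inf, diff)
        p = 1.0 if diff == 0.0 else 0.0
        return ZTestResult(
            mean_difference=diff, ci_low=diff, ci_high=diff,
            z=z, p=p, alpha=alpha, flags=flags + ("zero-variance",),
        )
    z = diff / se
    crit = float(stats.norm.ppf(1.0 - alpha / 2.0))
    half = crit * se
    return ZTestResult(
        mean_difference=diff,
        ci_low=diff - half,
        ci_high=diff + half,
        z=z,
        p=_two_sided_p(z),
        alpha=alpha,
        flags=flags,
    )


def one_sample_z(
    summary: StratumSummary, reference_mean: float, alpha: float = DEFAULT_ALPHA
) -> ZTestResult:
    """Two-tailed one-sample z-test of a stratum mean against a reference mean.

    The reference (population) mean is a known constant, so the standard
    error is the sample SE alone. Strata with n < 10 are flagged small-n.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if not 0.0 <= reference_mean <= 100.0:
        raise ValueError(f"reference_mean outside [0, 100]: {reference_mean}")
    if summary.n < 2 or summary.se is None:
        raise InsufficientDataError(f"one-sample z-test needs n >= 2, got n = {summary.n}")
    flags = ("small-n",) if summary.n < SMALL_N_THRESHOLD else ()
    return _z_result(summary.mean - reference_mean, summary.se, alpha, flags)


def two_sample_z(
    g1: StratumSummary, g2: StratumSummary, alpha: float = DEFAULT_ALPHA
) -> ZTestResult:
    """Two-tailed independent two-sample z-test (unpooled SE), g1 − g2."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    for g in (g1, g2):
        if g.n < 2 or g.sd is None:
            raise InsufficientDataError(f"two-sample z-test needs n >= 2 in each group, got {g.n}")
    flags = ("small-n",) if min(g1.n, g2.n) < SMALL_N_THRESHOLD else ()
    se_diff = math.sqrt(g1.sd**2 / g1.n + g2.sd**2 / g2.n)
    return _z_result(g1.mean - g2.mean, se_diff, alpha, flags)


def _strata_layout() -> list[tuple[str, str]]:
    """(age_band, sex) pairs in report order: totals first, then each band."""
    layout = [(TOTAL_BAND, "combined"), (TOTAL_BAND, "male"), (TOTAL_BAND, "female")]
    for band in AGE_BANDS:
        layout += [(band.label, "combined"), (band.label, "male"), (band.label, "female")]
    return layout


def _stratum_members(
    records: Sequence["CohortRecord"], band_label: str, sex: str
) -> list["CohortRecord"]:
    out = []
    for r in records:
        if r.smos is None:
            continue
        if sex != "combined" and r.sex != sex:
            continue
        if band_label != TOTAL_BAND:
            band = classify_age_band(r.age)
            if band is None or band.label != band_label:
                continue
        out.append(r)
    return out


def stratified_comparison(
    records: Sequence["CohortRecord"],
    norms: NormsTable,
    alpha: float = DEFAULT_ALPHA,
    *,
    bonferroni: bool = False,
) -> list[StratumComparison]:
    """Normative comparison of every stratum, in the standard report order.

    One row per (age band x sex) stratum: total/male/female overall, then
    each age band with its combined/male/female sub-rows. Strata with no
    patients, no matching norm, or n < 2 appear with a skip flag and reason —
    they are never silently dropped. With ``bonferroni=True`` an adjusted
    p-value (p x number of tested strata, capped at 1) is attached.
    """
    rows: list[StratumComparison] = []
    for band_label, sex in _strata_layout():
        label = f"{band_label}/{sex}"
        members = _stratum_members(records, band_label, sex)
        if (band_label, sex) not in norms:
            rows.append(
                StratumComparison(label, band_label, sex, skipped=True, skip_reason="no norm")
            )
            continue
        if not members:
            rows.append(
                StratumComparison(label, band_label, sex, skipped=True, skip_reason="no patients")
            )
            continue
        summary = summarize_stratum(members)
        entry = norms.get(band_label, sex)
        if summary.n < 2:
            rows.append(
                StratumComparison(
                    label, band_label, sex,
                    summary=summary, reference_mean=entry.smos_mean,
                    skipped=True, skip_reason="n < 2",
                )
            )
            continue
        test = one_sample_z(summary, entry.smos_mean, alpha)
        rows.append(
            StratumComparison(
                label, band_label, sex,
                summary=summary, test=test, reference_mean=entry.smos_mean,
            )
        )
    if bonferroni:
        m = sum(1 for r in rows if r.test is not None)
        rows = [
            r if r.test is None
            else StratumComparison(
                r.label, r.age_band, r.sex, r.summary, r.test, r.reference_mean,
                r.skipped, r.skip_reason, p_bonferroni=min(1.0, r.test.p * m),
            )
            for r in rows
        ]
    return rows


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson product-moment correlation with pairwise deletion.

    Pairs where either value is missing (None/NaN) are dropped; at least 3
    complete pairs are required. Zero variance in either variable makes r
    undefined and raises rather than returning NaN.
    """
    xs = np.array([np.nan if v is None else float(v) for v in x], dtype=float)
    ys = np.array([np.nan if v is None else float(v) for v in y], dtype=float)
    if xs.shape != ys.shape:
        raise ValueError("x and y must have the same length")
    keep = ~(np.isnan(xs) | np.isnan(ys))
    xs, ys = xs[keep], ys[keep]
    n = int(xs.size)
    if n < 3:
        raise InsufficientPairsError(f"need >= 3 complete pairs, got {n}")
    if np.ptp(xs) == 0.0 or np.ptp(ys) == 0.0:
        raise UndefinedCorrelationError("zero variance in x or y; correlation undefined")
    res = stats.pearsonr(xs, ys)
    r = float(res.statistic)
    return CorrelationResult(r=r, r_squared=r * r, p=float(res.pvalue), n=n)


def normality_check(values: Sequence[float]) -> tuple[float, float]:
    """Shapiro–Wilk statistic and p for 3 <= n <= 5000 observations.

    A diagnostic only: callers attach the result to the analysis report and
    proceed regardless of the outcome.
    """
    arr = np.asarray(list(values), dtype=float)
    n = int(arr.size)
    if not 3 <= n <= 5000:
        raise UnsupportedSampleSizeError(f"Shapiro–Wilk supported for 3 <= n <= 5000, got {n}")
    if np.ptp(arr) == 0.0:
        raise UndefinedCorrelationError("constant sample; normality test undefined")
    stat, p = stats.shapiro(arr)
    return float(stat), float(p)


# ---------------------------------------------------------------------------
# Full-cohort analysis report
# ---------------------------------------------------------------------------

DISABILITY_SCORES = ("odi", "ndi", "vas")


@dataclass
class AnalysisReport:
    """Machine-readable result of the full analysis pipeline."""

    config: dict
    strata: list[StratumComparison]
    operative_contrast: ZTestResult | None
    operative_summary: StratumSummary | None
    nonoperative_summary: StratumSummary | None
    correlations: dict[str, CorrelationResult | str]
    normality: tuple[float, float] | str
    warnings: list[str] = field(default_factory=list)


def analyze_cohort(
    records: Sequence["CohortRecord"],
    norms: NormsTable,
    alpha: float = DEFAULT_ALPHA,
    *,
    bonferroni: bool = False,
    config: dict | None = None,
) -> AnalysisReport:
    """Run the full inferential pipeline on a scored cohort.

    Stratified normative z-tests, the operative two-sample contrast, Pearson
    correlations of SMoS with each disability score (pairwise deletion), and
    a Shapiro–Wilk normality diagnostic. Sub-analyses that cannot run (too
    few patients, constant scores, ...) are recorded as messages in their
    slot and in ``warnings`` instead of aborting the report.
    """
    notes: list[str] = []
    scored = [r for r in records if r.smos is not None]
    if not scored:
        raise EmptyStratumError("no records with a computed SMoS")
    unscored = len(records) - len(scored)
    if unscored:
        notes.append(f"{unscored} record(s) without a computed SMoS excluded from analysis")

    strata = stratified_comparison(scored, norms, alpha, bonferroni=bonferroni)
    for row in strata:
        if row.skipped:
            notes.append(f"stratum {row.label} skipped: {row.skip_reason}")
        elif row.test is not None and "small-n" in row.test.flags:
            notes.append(f"stratum {row.label} has n < {SMALL_N_THRESHOLD}")

    op = [r for r in scored if r.operative]
    nonop = [r for r in scored if not r.operative]
    op_sum = nonop_sum = contrast = None
    if len(op) >= 2 and len(nonop) >= 2:
        op_sum = summarize_stratum(op)
        nonop_sum = summarize_stratum(nonop)
        contrast = two_sample_z(op_sum, nonop_sum, alpha)
    else:
        notes.append(
            f"operative contrast skipped: group sizes {len(op)} operative / "
            f"{len(nonop)} non-operative (need >= 2 each)"
        )

    correlations: dict[str, CorrelationResult | str] = {}
    for score_name in DISABILITY_SCORES:
        totals = [r.smos.total for r in scored]
        other = [getattr(r, score_name) for r in scored]
        try:
            correlations[score_name] = pearson_correlation(totals, other)
        except (InsufficientPairsError, UndefinedCorrelationError) as exc:
            correlations[score_name] = str(exc)
            notes.append(f"correlation SMoS~{score_name.upper()} unavailable: {exc}")

    try:
        normality: tuple[float, float] | str = normality_check([r.smos.total for r in scored])
    except (UnsupportedSampleSizeError, UndefinedCorrelationError) as exc:
        normality = str(exc)
        notes.append(f"normality check unavailable: {exc}")

    cfg = {"alpha": alpha, "bonferroni": bonferroni}
    if config:
        cfg.update(config)
    return AnalysisReport(
        config=cfg,
        strata=strata,
        operative_contrast=contrast,
        operative_summary=op_sum,
        nonoperative_summary=nonop_sum,
        correlations=correlations,
        normality=normality,
        warnings=notes,
    )
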