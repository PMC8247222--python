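"""Cohort CSV ingestion, per-record scoring, and report output.

The cohort file is a UTF-8 CSV with header::

    patient_id,age,sex,walking_speed_mps,walk_distance_m,walk_time_s,
    daily_step_count,odi,ndi,vas,operative

``patient_id``, ``age`` and ``sex`` are required; walking speed comes either
directly (``walking_speed_mps``) or from a timed walk
(``walk_distance_m`` + ``walk_time_s``). Rows failing validation are
returned as row-level issues — never silently dropped — and every parseable
row becomes a :class:`CohortRecord` with its SMoS computed whenever both
gait metrics resolve.

Reports are written as machine-readable JSON (full precision, stable key
order) or a plain-text stratified table (scores at 1 decimal place, r at 3,
p at 3 or "< .001").
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from . import scoring
from .cohort_stats import AnalysisReport, CorrelationResult, StratumSummary, ZTestResult
from .errors import CohortSchemaError, MissingMetricError, SmosWarning
from .scoring import GaitMeasurement, SMoSResult, TimedWalk

COHORT_COLUMNS = (
    "patient_id",
    "age",
    "sex",
    "walking_speed_mps",
    "walk_distance_m",
    "walk_time_s",
    "daily_step_count",
    "odi",
    "ndi",
    "vas",
    "operative",
)
REQUIRED_COLUMNS = ("patient_id", "age", "sex", "daily_step_count")

_SEX_ALIASES = {"m": "male", "male": "male", "f": "female", "female": "female"}
_OPERATIVE_TRUE = {"1", "true", "yes"}
_OPERATIVE_FALSE = {"0", "false", "no"}

#: Valid ranges for the patient-reported disability scores.
SCORE_RANGES = {"odi": (0.0, 100.0), "ndi": (0.0, 100.0), "vas": (0.0, 10.0)}

MINIMUM_AGE = 18.0  # younger patients are excluded from analysis


@dataclass(frozen=True)
class CohortRecord:
    """One patient: demographics, gait metrics, disability scores, SMoS."""

    patient_id: str
    age: float
    sex: str  # male | female | other
    walking_speed: float | None = None  # m/s
    daily_step_count: float | None = None  # steps/day
    odi: float | None = None  # 0-100
    ndi: float | None = None  # 0-100
    vas: float | None = None  # 0-10
    operative: bool = False
    smos: SMoSResult | None = None
    notes: tuple[str, ...] = ()


@dataclass(frozen=True)
class RowIssue:
    """A cohort row that failed validation, with its reason(s)."""

    row: int  # 1-based file line number (header is line 1)
    patient_id: str | None
    reason: str


def _parse_float(raw: str, name: str, problems: list[str]) -> float | None:
    raw = raw.strip()
    if raw == "":
        return None
    try:
        value = float(raw)
    except ValueError:
        problems.append(f"{name} is not numeric: {raw!r}")
        return None
    if not math.isfinite(value):
        problems.append(f"{name} is not finite: {raw!r}")
        return None
    return value


def _resolve_speed(
    direct: float | None,
    dist: float | None,
    dur: float | None,
    problems: list[str],
    notes: list[str],
) -> float | None:
    has_walk = dist is not None or dur is not None
    if direct is not None:
        if direct < 0:
            problems.append(f"walking_speed_mps must be non-negative, got {direct}")
            return None
        if has_walk:
            notes.append("both direct walking speed and timed walk given; direct speed used")
        return direct
    if dist is None and dur is None:
        return None
    if dist is None or dur is None:
        problems.append("timed walk needs both walk_distance_m and walk_time_s")
        return None
    try:
        walk = TimedWalk(distance_m=dist, duration_s=dur)
    except Exception as exc:
        problems.append(str(exc))
        return None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", SmosWarning)
        return scoring.walking_speed_from_timed_walk(walk)


def read_cohort(path) -> tuple[list[CohortRecord], list[RowIssue]]:
    """Read and validate a cohort CSV.

    Returns ``(records, issues)`` with one entry per input row between them
    (rows_in == records_out + issues_out). Sex is normalised from
    {M, F, male, female} case-insensitively; anything else becomes "other"
    (scored normally, skipped in sex-specific normative comparison). An
    absent ``operative`` column marks every record non-operative with a
    warning.
    """
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise CohortSchemaError(f"could not parse cohort file {path}: {exc}") from exc

    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CohortSchemaError(f"cohort file missing required columns: {missing}")
    has_direct = "walking_speed_mps" in df.columns
    has_walk = {"walk_distance_m", "walk_time_s"} <= set(df.columns)
    if not has_direct and not has_walk:
        raise CohortSchemaError(
            "cohort file needs walking_speed_mps or walk_distance_m + walk_time_s"
        )
    if "operative" not in df.columns:
        warnings.warn(
            "no 'operative' column: all records treated as non-operative",
            SmosWarning,
            stacklevel=2,
        )

    def cell(row, name: str) -> str:
        return str(row[name]) if name in df.columns else ""

    records: list[CohortRecord] = []
    issues: list[RowIssue] = []
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        problems: list[str] = []
        notes: list[str] = []

        pid = cell(row, "patient_id").strip()
        if not pid:
            problems.append("patient_id is empty")

        age = _parse_float(cell(row, "age"), "age", problems)
        if age is None and not any("age" in p for p in problems):
            problems.append("age is missing")
        elif age is not None and age < MINIMUM_AGE:
            problems.append(f"age {age:g} below minimum {MINIMUM_AGE:g}")

        raw_sex = cell(row, "sex").strip().lower()
        sex = _SEX_ALIASES.get(raw_sex)
        if sex is None:
            sex = "other"
            notes.append(f"unrecognised sex {raw_sex!r}; normative comparison will be skipped")

        speed = _resolve_speed(
            _parse_float(cell(row, "walking_speed_mps"), "walking_speed_mps", problems),
            _parse_float(cell(row, "walk_distance_m"), "walk_distance_m", problems),
            _parse_float(cell(row, "walk_time_s"), "walk_time_s", problems),
            problems,
            notes,
        )

        dsc = _parse_float(cell(row, "daily_step_count"), "daily_step_count", problems)
        if dsc is not None and dsc < 0:
            problems.append(f"daily_step_count must be non-negative, got {dsc:g}")
            dsc = None

        disability: dict[str, float | None] = {}
        for name, (lo, hi) in SCORE_RANGES.items():
            value = _parse_float(cell(row, name), name, problems)
            if value is not None and not lo <= value <= hi:
                problems.append(f"{name} out of range [{lo:g},{hi:g}]: {value:g}")
                value = None
            disability[name] = value

        raw_op = cell(row, "operative").strip().lower()
        if raw_op in _OPERATIVE_TRUE:
            operative = True
        elif raw_op in _OPERATIVE_FALSE or raw_op == "":
            operative = False
        else:
            problems.append(f"operative flag not understood: {raw_op!r}")
            operative = False

        if problems:
            issues.append(RowIssue(row=line, patient_id=pid or None, reason="; ".join(problems)))
            continue

        smos = None
        if speed is not None and dsc is not None:
            try:
                smos = scoring.compute_smos(
                    GaitMeasurement(walking_speed=speed, daily_step_count=dsc)
                )
            except MissingMetricError:  # pragma: no cover - guarded above
                smos = None
        else:
            absent = "walking speed" if speed is None else "daily step count"
            notes.append(f"SMoS not computed: {absent} missing")

        records.append(
            CohortRecord(
                patient_id=pid,
                age=age,
                sex=sex,
                walking_speed=speed,
                daily_step_count=dsc,
                odi=disability["odi"],
                ndi=disability["ndi"],
                vas=disability["vas"],
                operative=operative,
                smos=smos,
                notes=tuple(notes),
            )
        )
    return records, issues


def _fmt_float(value: float | None) -> str:
    if value is None:
        return ""
    return repr(float(value))


def write_cohort(records: Sequence[CohortRecord], path) -> None:
    """Write records back to the cohort CSV schema (full float precision).

    Walking speed is always written to ``walking_speed_mps`` (derived speeds
    included), so records -> CSV -> records round-trips losslessly.
    """
    rows = []
    for r in records:
        rows.append(
            {
                "patient_id": r.patient_id,
                "age": _fmt_float(r.age),
                "sex": r.sex,
                "walking_speed_mps": _fmt_float(r.walking_speed),
                "walk_distance_m": "",
                "walk_time_s": "",
                "daily_step_count": _fmt_float(r.daily_step_count),
                "odi": _fmt_float(r.odi),
                "ndi": _fmt_float(r.ndi),
                "vas": _fmt_float(r.vas),
                "operative": "1" if r.operative else "0",
            }
        )
    pd.DataFrame(rows, columns=list(COHORT_COLUMNS)).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Report rendering
# ---------------------------------------------------------------------------


def format_p(p: float) -> str:
    """Render a p-value: "< .001" below 0.001, else 3 decimal places."""
    return "< .001" if p < 0.001 else f"{p:.3f}"


def format_score(x: float) -> str:
    return f"{x:.1f}"


def format_r(r: float) -> str:
    return f"{r:.3f}"


def _summary_dict(s: StratumSummary | None) -> dict | None:
    if s is None:
        return None
    return {"n": s.n, "mean": s.mean, "sd": s.sd, "se": s.se, "flags": list(s.flags)}


def _ztest_dict(t: ZTestResult | None) -> dict | None:
    if t is None:
        return None
    return {
        "mean_difference": t.mean_difference,
        "ci_low": t.ci_low,
        "ci_high": t.ci_high,
        "z": t.z if math.isfinite(t.z) else None,  # zero-variance stratum
        "p": t.p,
        "alpha": t.alpha,
        "significant": t.significant,
        "flags": list(t.flags),
    }


def report_to_dict(report: AnalysisReport) -> dict:
    """Machine-readable (JSON-serialisable) form of an analysis report."""
    strata = []
    for row in report.strata:
        d = {
            "stratum": row.label,
            "age_band": row.age_band,
            "sex": row.sex,
            "skipped": row.skipped,
            "skip_reason": row.skip_reason,
            "reference_mean": row.reference_mean,
            "summary": _summary_dict(row.summary),
            "test": _ztest_dict(row.test),
        }
        if row.p_bonferroni is not None:
            d["p_bonferroni"] = row.p_bonferroni
        strata.append(d)

    correlations = {}
    for name, res in report.correlations.items():
        if isinstance(res, CorrelationResult):
            correlations[name] = {
                "r": res.r,
                "r_squared": res.r_squared,
                "p": res.p,
                "n": res.n,
            }
        else:
            correlations[name] = {"error": res}

    if isinstance(report.normality, str):
        normality: dict = {"error": report.normality}
    else:
        normality = {"statistic": report.normality[0], "p": report.normality[1]}

    return {
        "config": report.config,
        "strata": strata,
        "operative_contrast": {
            "operative": _summary_dict(report.operative_summary),
            "non_operative": _summary_dict(report.nonoperative_summary),
            "test": _ztest_dict(report.operative_contrast),
        },
        "correlations": correlations,
        "normality": normality,
        "warnings": list(report.warnings),
    }


def render_text(report: AnalysisReport) -> str:
    """Plain-text stratified table in the style of a normative-comparison report."""
    lines: list[str] = []
    alpha = report.config.get("alpha")
    lines.append(f"SMoS normative comparison (alpha = {alpha})")
    lines.append("=" * 78)
    header = (
        f"{'Stratum':<16}{'n':>5}  {'Mean (SE)':<14}{'Ref':>6}  "
        f"{'Diff (95% CI)':<26}{'P':>8}"
    )
    lines.append(header)
    lines.append("-" * 78)
    for row in report.strata:
        if row.skipped or row.test is None or row.summary is None:
            lines.append(f"{row.label:<16}{'--':>5}  skipped: {row.skip_reason}")
            continue
        s, t = row.summary, row.test
        mean_se = f"{format_score(s.mean)} ({s.se:.2f})"
        ci = (
            f"{format_score(t.mean_difference)} "
            f"({format_score(t.ci_low)} to {format_score(t.ci_high)})"
        )
        p_txt = format_p(t.p)
        if row.p_bonferroni is not None:
            p_txt += f" [adj {format_p(row.p_bonferroni)}]"
        lines.append(
            f"{row.label:<16}{s.n:>5}  {mean_se:<14}{format_score(row.reference_mean):>6}  "
            f"{ci:<26}{p_txt:>8}"
        )
    lines.append("")

    lines.append("Operative vs non-operative contrast")
    lines.append("-" * 36)
    if report.operative_contrast is None:
        lines.append("  skipped (insufficient group sizes)")
    else:
        op, nonop, t = (
            report.operative_summary,
            report.nonoperative_summary,
            report.operative_contrast,
        )
        lines.append(f"  operative:     n={op.n:<4} mean {format_score(op.mean)} (SD {op.sd:.2f})")
        lines.append(
            f"  non-operative: n={nonop.n:<4} mean {format_score(nonop.mean)} (SD {nonop.sd:.2f})"
        )
        lines.append(
            f"  difference {format_score(t.mean_difference)} "
            f"(95% CI {format_score(t.ci_low)} to {format_score(t.ci_high)}), "
            f"p {format_p(t.p)}"
        )
    lines.append("")

    lines.append("Correlation of SMoS with disability scores")
    lines.append("-" * 43)
    for name, res in report.correlations.items():
        if isinstance(res, CorrelationResult):
            lines.append(
                f"  {name.upper():<4} r {format_r(res.r)} "
                f"(r^2 {format_r(res.r_squared)}, p {format_p(res.p)}, n {res.n})"
            )
        else:
            lines.append(f"  {name.upper():<4} unavailable: {res}")
    lines.append("")

    if isinstance(report.normality, str):
        lines.append(f"Normality (Shapiro-Wilk): unavailable: {report.normality}")
    else:
        stat, p = report.normality
        lines.append(f"Normality (Shapiro-Wilk): W {stat:.3f}, p {format_p(p)}")

    if report.warnings:
        lines.append("")
        lines.append("Warnings:")
        for note in report.warnings:
            lines.append(f"  - {note}")
    lines.append("")
    return "\n".join(lines)


def write_report(report: AnalysisReport, path, format: str = "json") -> None:
    """Write an analysis report; byte-deterministic for a given report."""
    if format == "json":
        payload = json.dumps(report_to_dict(report), indent=2, allow_nan=False)
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(payload + "\n")
    elif format == "text":
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(render_text(report))
    else:
        raise ValueError(f"unknown report format {format!r} (expected 'json' or 'text')")
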