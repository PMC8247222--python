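"""Synthetic patient cohorts with controlled SMoS structure.

The generator emulates the statistical shape of a spine-clinic cohort so the
whole pipeline is testable without patient data:

* per (age band x sex) stratum, latent SMoS totals are drawn from a normal
  distribution truncated to [0, 100] (rejection sampling; the spec is
  rejected as infeasible when less than half the normal mass survives
  truncation, to avoid silently distorting the distribution);
* an operative subgroup (Bernoulli flag) receives a mean shift on the latent
  scale, applied before truncation;
* each total is split into walking-speed and step-count component points
  uniformly over the feasible interval [max(0, S−50), min(50, S)] — the
  maximally non-informative choice, since the joint WS/DSC distribution is
  not constrained — and the scoring formulas are inverted on their sub-cap
  branches to emit raw metrics (speed = points·1.35/50, steps =
  points·10000/50), so re-scoring reproduces the latent points;
* disability scores (ODI, NDI on 0–100; VAS on 0–10) are tied to the latent
  SMoS through a Gaussian copula with configurable target Pearson r and
  marginal means.

Everything is reproducible from the spec's integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from datetime import date, timedelta

import numpy as np
import yaml
from scipy import stats

from .cohort_io import CohortRecord
from .errors import CohortSpecError
from .norms import AGE_BANDS
from .scoring import COMPONENT_MAX, DSC_CAP_STEPS, WS_CAP_MPS, SMoSResult, StepTimeseries

SCORE_LO, SCORE_HI = 0.0, 100.0
#: Minimum surviving normal mass after truncation to [0, 100].
MIN_ACCEPTANCE = 0.5
#: Sampling range for the open-ended 70+ band.
OPEN_BAND_UPPER_AGE = 89

_BAND_RANGES = {b.label: (b.lower, b.upper if b.upper is not None else OPEN_BAND_UPPER_AGE)
                for b in AGE_BANDS}

#: Defaults reflecting the spine-clinic study conditions: 38/182 operative,
#: operative group 11.9 points lower, SMoS~ODI r −0.570, ~VAS −0.561,
#: ~NDI −0.037, mean ODI 40, NDI 26, VAS 7.
STUDY_OPERATIVE_FRACTION = 38 / 182
STUDY_OPERATIVE_SHIFT = -11.9
STUDY_CORRELATIONS = {"odi": -0.570, "vas": -0.561, "ndi": -0.037}
STUDY_SCORE_MEANS = {"odi": 40.0, "ndi": 26.0, "vas": 7.0}


@dataclass(frozen=True)
class StratumSpec:
    """Target SMoS distribution for one (age band x sex) stratum."""

    age_band: str
    sex: str
    n: int
    smos_mean: float
    smos_sd: float

    def __post_init__(self) -> None:
        if self.age_band not in _BAND_RANGES:
            raise CohortSpecError(
                f"age_band must be one of {sorted(_BAND_RANGES)}, got {self.age_band!r}"
            )
        if self.sex not in ("male", "female"):
            raise CohortSpecError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.n < 0:
            raise CohortSpecError(f"n must be >= 0, got {self.n}")
        if not SCORE_LO <= self.smos_mean <= SCORE_HI:
            raise CohortSpecError(f"smos_mean outside [0, 100]: {self.smos_mean}")
        if not self.smos_sd > 0:
            raise CohortSpecError(f"smos_sd must be > 0, got {self.smos_sd}")


@dataclass(frozen=True)
class CohortSpec:
    """Full cohort recipe: strata, operative effect, disability correlations."""

    strata: tuple[StratumSpec, ...]
    operative_fraction: float = STUDY_OPERATIVE_FRACTION
    operative_shift: float = STUDY_OPERATIVE_SHIFT
    corr_odi: float = STUDY_CORRELATIONS["odi"]
    corr_vas: float = STUDY_CORRELATIONS["vas"]
    corr_ndi: float = STUDY_CORRELATIONS["ndi"]
    odi_mean: float = STUDY_SCORE_MEANS["odi"]
    ndi_mean: float = STUDY_SCORE_MEANS["ndi"]
    vas_mean: float = STUDY_SCORE_MEANS["vas"]
    seed: int = 0
    #: With True the operative shift is split as +shift·(1−f) / −shift·f so
    #: each stratum's marginal mean stays at smos_mean while the
    #: operative − non-operative gap equals the shift (used when stratum
    #: means describe a cohort that already contains operative patients).
    center_operative_shift: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "strata", tuple(self.strata))
        if not 0.0 <= self.operative_fraction <= 1.0:
            raise CohortSpecError(f"operative_fraction outside [0, 1]: {self.operative_fraction}")
        for name in ("corr_odi", "corr_vas", "corr_ndi"):
            r = getattr(self, name)
            if not abs(r) < 1.0:
                raise CohortSpecError(f"|{name}| must be < 1, got {r}")


def _truncation_mass(mean: float, sd: float) -> float:
    a = (SCORE_LO - mean) / sd
    b = (SCORE_HI - mean) / sd
    return float(stats.norm.cdf(b) - stats.norm.cdf(a))


def truncated_normal_moments(mean: float, sd: float) -> tuple[float, float]:
    """Analytic mean and SD of N(mean, sd) truncated to the score range."""
    a = (SCORE_LO - mean) / sd
    b = (SCORE_HI - mean) / sd
    dist = stats.truncnorm(a, b, loc=mean, scale=sd)
    return float(dist.mean()), float(dist.std())


def _sample_truncated(rng: np.random.Generator, means: np.ndarray, sd: float) -> np.ndarray:
    """Rejection-sample N(mean_i, sd) restricted to [0, 100], elementwise."""
    out = rng.normal(means, sd)
    bad = (out < SCORE_LO) | (out > SCORE_HI)
    while bad.any():
        out[bad] = rng.normal(means[bad], sd)
        bad = (out < SCORE_LO) | (out > SCORE_HI)
    return out


def _phi_map_attenuation(c: float) -> float:
    """Pearson attenuation of the copula mapping ``z ↦ Φ(z + c)``.

    For standard-normal z, cov(z, Φ(z+c)) = φ(c/√2)/√2 and
    E[Φ(z+c)²] = Φ₂(c/√2, c/√2; ρ=1/2), so the correlation between the
    latent normal and the mapped score has the closed form below (= √(3/π)
    ≈ 0.977 at c = 0, the classic normal-to-uniform factor).
    """
    u = c / math.sqrt(2.0)
    m = float(stats.norm.cdf(u))
    second = float(
        stats.multivariate_normal(mean=[0.0, 0.0], cov=[[1.0, 0.5], [0.5, 1.0]]).cdf([u, u])
    )
    var = second - m * m
    cov = float(stats.norm.pdf(u)) / math.sqrt(2.0)
    return cov / math.sqrt(var)


def _copula_scores(
    rng: np.random.Generator,
    z_smos: np.ndarray,
    r: float,
    scale: float,
    target_mean: float,
) -> np.ndarray:
    """Disability scores tied to the latent SMoS via a Gaussian copula.

    ``z_d = ρ·z_smos + sqrt(1−ρ²)·ε`` with the score
    ``scale · Φ(z_d + c)``; the offset c places the marginal mean at
    ``target_mean`` (c = √2·Φ⁻¹(target/scale)) and the latent ρ is the
    target Pearson r divided by the mapping's analytic attenuation factor,
    so the delivered SMoS-score correlation equals the target.
    """
    if not 0.0 < target_mean < scale:
        raise CohortSpecError(f"target score mean {target_mean} outside (0, {scale})")
    c = math.sqrt(2.0) * float(stats.norm.ppf(target_mean / scale))
    rho = r / _phi_map_attenuation(c)
    if not abs(rho) < 1.0:
        raise CohortSpecError(
            f"target correlation {r} is unreachable through the bounded-score mapping"
        )
    eps = rng.normal(size=z_smos.size)
    z_d = rho * z_smos + math.sqrt(1.0 - rho * rho) * eps
    return np.round(scale * stats.norm.cdf(z_d + c), 1)


def generate_cohort(spec: CohortSpec) -> list[CohortRecord]:
    """Generate a scored cohort from a :class:`CohortSpec`, reproducibly.

    Raises :class:`CohortSpecError` when any stratum's truncation to
    [0, 100] would discard more than half the normal mass.
    """
    rng = np.random.default_rng(spec.seed)
    f = spec.operative_fraction

    # Feasibility first, for every latent mean the sampler may use.
    for st in spec.strata:
        if spec.center_operative_shift:
            shifts = (spec.operative_shift * (1.0 - f), -spec.operative_shift * f)
        else:
            shifts = (spec.operative_shift, 0.0)
        for delta in shifts:
            if _truncation_mass(st.smos_mean + delta, st.smos_sd) < MIN_ACCEPTANCE:
                raise CohortSpecError(
                    f"stratum ({st.age_band}, {st.sex}): less than "
                    f"{MIN_ACCEPTANCE:.0%} of N({st.smos_mean + delta:g}, "
                    f"{st.smos_sd:g}) lies in [0, 100]"
                )

    total_n = sum(st.n for st in spec.strata)
    if total_n == 0:
        return []

    # Pass 1: latent totals, components and demographics per stratum.
    drawn: list[dict] = []
    for st in spec.strata:
        if st.n == 0:
            continue
        operative = rng.random(st.n) < f
        if spec.center_operative_shift:
            delta = spec.operative_shift * (operative.astype(float) - f)
        else:
            delta = spec.operative_shift * operative.astype(float)
        totals = _sample_truncated(rng, st.smos_mean + delta, st.smos_sd)

        lo = np.maximum(0.0, totals - COMPONENT_MAX)
        hi = np.minimum(COMPONENT_MAX, totals)
        ws_points = np.clip(lo + rng.random(st.n) * (hi - lo), 0.0, COMPONENT_MAX)
        dsc_points = np.clip(totals - ws_points, 0.0, COMPONENT_MAX)

        lo_age, hi_age = _BAND_RANGES[st.age_band]
        ages = rng.integers(lo_age, hi_age + 1, size=st.n)
        drawn.append(
            {
                "stratum": st,
                "operative": operative,
                "totals": totals,
                "ws_points": ws_points,
                "dsc_points": dsc_points,
                "ages": ages,
            }
        )

    # Pass 2: one pooled SMoS axis for the copula, standardised by the
    # realised (post-truncation) cohort moments — disability tracks absolute
    # mobility, not stratum-relative mobility.
    all_totals = np.concatenate([d["totals"] for d in drawn])
    pooled_mean = float(all_totals.mean())
    pooled_sd = float(all_totals.std())
    if pooled_sd == 0.0:
        pooled_sd = 1.0  # degenerate cohort: scores become pure noise

    records: list[CohortRecord] = []
    counter = 0
    for d in drawn:
        st = d["stratum"]
        z_smos = (d["totals"] - pooled_mean) / pooled_sd
        odi = _copula_scores(rng, z_smos, spec.corr_odi, 100.0, spec.odi_mean)
        ndi = _copula_scores(rng, z_smos, spec.corr_ndi, 100.0, spec.ndi_mean)
        vas = _copula_scores(rng, z_smos, spec.corr_vas, 10.0, spec.vas_mean)
        speeds = d["ws_points"] * WS_CAP_MPS / COMPONENT_MAX
        steps = d["dsc_points"] * DSC_CAP_STEPS / COMPONENT_MAX
        for i in range(st.n):
            counter += 1
            ws_i, dsc_i = float(d["ws_points"][i]), float(d["dsc_points"][i])
            records.append(
                CohortRecord(
                    patient_id=f"SYN{counter:05d}",
                    age=float(d["ages"][i]),
                    sex=st.sex,
                    walking_speed=float(speeds[i]),
                    daily_step_count=float(steps[i]),
                    odi=float(odi[i]),
                    ndi=float(ndi[i]),
                    vas=float(vas[i]),
                    operative=bool(d["operative"][i]),
                    smos=SMoSResult(ws_points=ws_i, dsc_points=dsc_i, total=ws_i + dsc_i),
                )
            )
    return records


def generate_step_timeseries(
    mean_steps: float,
    dispersion: float,
    days: int,
    seed: int,
    *,
    end_date: date = date(2020, 6, 30),
) -> StepTimeseries:
    """Dated daily step totals: normal(mean, dispersion) truncated at zero,
    rounded to whole steps, on consecutive calendar days ending ``end_date``."""
    if mean_steps < 0:
        raise ValueError(f"mean_steps must be >= 0, got {mean_steps}")
    if dispersion < 0:
        raise ValueError(f"dispersion must be >= 0, got {dispersion}")
    if days < 1:
        raise ValueError(f"days must be >= 1, got {days}")
    rng = np.random.default_rng(seed)
    if dispersion == 0:
        values = np.full(days, round(mean_steps), dtype=float)
    else:
        values = rng.normal(mean_steps, dispersion, size=days)
        bad = values < 0
        while bad.any():
            values[bad] = rng.normal(mean_steps, dispersion, size=int(bad.sum()))
            bad = values < 0
        values = np.round(values)
    start = end_date - timedelta(days=days - 1)
    entries = tuple((start + timedelta(days=i), float(values[i])) for i in range(days))
    return StepTimeseries(entries=entries)


def study_emulation_spec(seed: int = 0) -> CohortSpec:
    """A :class:`CohortSpec` emulating the published spine-clinic cohort.

    Stratum means and SE-implied SDs (sd = se·√n) come from the bundled
    per-band x sex sample summaries; the operative fraction, operative
    shift, disability correlations and marginal score means come from the
    published results. The operative shift is centred so stratum marginal
    means stay at their published values.
    """
    from .norms import load_study_cohort_summaries

    df = load_study_cohort_summaries()
    band_rows = df[(df["age_band"] != "total") & (df["sex"] != "combined")]
    strata = tuple(
        StratumSpec(
            age_band=row["age_band"],
            sex=row["sex"],
            n=int(row["n"]),
            smos_mean=float(row["mean"]),
            smos_sd=float(row["se"]) * math.sqrt(int(row["n"])),
        )
        for _, row in band_rows.iterrows()
    )
    return CohortSpec(strata=strata, seed=seed, center_operative_shift=True)


def load_cohort_spec(path) -> CohortSpec:
    """Read a :class:`CohortSpec` from a YAML (or JSON) file."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "strata" not in raw:
        raise CohortSpecError(f"{path}: spec file must be a mapping with a 'strata' list")
    try:
        strata = tuple(StratumSpec(**entry) for entry in raw.pop("strata"))
        return CohortSpec(strata=strata, **raw)
    except TypeError as exc:
        raise CohortSpecError(f"{path}: {exc}") from exc


def with_seed(spec: CohortSpec, seed: int) -> CohortSpec:
    """The same spec with a different seed."""
    return replace(spec, seed=seed)
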