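"""Age/sex-stratified population reference values for the SMoS.

A normative table gives, for each age band x sex stratum, the expected
population SMoS mean and its dispersion, derived from large population
studies of walking speed and daily step count. A bundled default table ships
as package data; users may load a replacement CSV with the same schema
(``age_band,sex,smos_mean,smos_sd,source``).

The dispersion column is stored verbatim and is never used inferentially:
all z-test arithmetic in :mod:`smos.cohort_stats` uses the sample standard
error, treating the population mean as a known constant.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .errors import NormLookupError, NormsFileError

VALID_SEXES = ("male", "female", "combined")
TOTAL_BAND = "total"


@dataclass(frozen=True, order=True)
class AgeBand:
    """A closed integer age range; ``upper is None`` means open-ended (70+)."""

    lower: int
    upper: int | None

    @property
    def label(self) -> str:
        return f"{self.lower}+" if self.upper is None else f"{self.lower}-{self.upper}"

    def contains(self, age: float) -> bool:
        if age < self.lower:
            return False
        return self.upper is None or age <= self.upper


#: The normative age bands, in order. Band edges are closed integer ranges.
AGE_BANDS: tuple[AgeBand, ...] = (
    AgeBand(30, 39),
    AgeBand(40, 49),
    AgeBand(50, 59),
    AgeBand(60, 69),
    AgeBand(70, None),
)

VALID_BAND_LABELS = (TOTAL_BAND,) + tuple(b.label for b in AGE_BANDS)


@dataclass(frozen=True)
class NormEntry:
    """Population SMoS mean and dispersion for one stratum."""

    age_band: str  # a band label or "total"
    sex: str  # male | female | combined
    smos_mean: float
    smos_sd: float
    source: str = ""


class NormsTable:
    """Validated collection of :class:`NormEntry`, keyed by (age_band, sex)."""

    def __init__(self, entries: list[NormEntry]):
        self._by_key: dict[tuple[str, str], NormEntry] = {}
        for e in entries:
            key = (e.age_band, e.sex)
            if key in self._by_key:
                raise NormsFileError(f"duplicate stratum {key}")
            self._by_key[key] = e
        self.entries: tuple[NormEntry, ...] = tuple(entries)

    def __len__(self) -> int:
        return len(self.entries)

    def get(self, age_band: str, sex: str) -> NormEntry:
        try:
            return self._by_key[(age_band, sex)]
        except KeyError:
            raise NormLookupError(f"no normative entry for stratum ({age_band}, {sex})") from None

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self._by_key


def _bundled(name: str):
    return resources.files("smos").joinpath("data", name)


def load_reference_norms(path=None) -> NormsTable:
    """Load a norms CSV; with no path, the bundled default (18 strata).

    Raises :class:`NormsFileError` (with the offending row number) for
    missing columns, out-of-range values, unknown strata or duplicates.
    """
    source = _bundled("reference_norms.csv") if path is None else path
    with (source.open("rb") if path is None else open(source, "rb")) as fh:
        try:
            df = pd.read_csv(fh)
        except Exception as exc:  # malformed CSV
            raise NormsFileError(f"could not parse norms file: {exc}") from exc
    required = {"age_band", "sex", "smos_mean", "smos_sd"}
    missing = required - set(df.columns)
    if missing:
        raise NormsFileError(f"norms file missing columns: {sorted(missing)}")
    if "source" not in df.columns:
        df["source"] = ""

    entries: list[NormEntry] = []
    for idx, row in df.iterrows():
        rownum = idx + 2  # 1-based, after header
        band = str(row["age_band"]).strip()
        sex = str(row["sex"]).strip().lower()
        if band not in VALID_BAND_LABELS:
            raise NormsFileError(f"row {rownum}: unknown age_band {band!r}")
        if sex not in VALID_SEXES:
            raise NormsFileError(f"row {rownum}: unknown sex {sex!r}")
        try:
            mean = float(row["smos_mean"])
            sd = float(row["smos_sd"])
        except (TypeError, ValueError) as exc:
            raise NormsFileError(f"row {rownum}: non-numeric mean/sd") from exc
        if not 0.0 <= mean <= 100.0:
            raise NormsFileError(f"row {rownum}: smos_mean {mean} outside [0, 100]")
        if not sd > 0.0:
            raise NormsFileError(f"row {rownum}: smos_sd must be > 0, got {sd}")
        entries.append(NormEntry(band, sex, mean, sd, str(row["source"])))
    try:
        return NormsTable(entries)
    except NormsFileError as exc:
        raise NormsFileError(f"{exc} in {getattr(source, 'name', source)}") from None


def classify_age_band(age: float) -> AgeBand | None:
    """Map an age in years to its normative band; ``None`` below the
    youngest band (under 30), which is a valid no-band outcome, not an error."""
    if age < 0:
        raise ValueError(f"age must be non-negative, got {age}")
    for band in AGE_BANDS:
        if band.contains(age):
            return band
    return None


def lookup_norm(age: float, sex: str, norms: NormsTable) -> NormEntry:
    """The normative entry for a patient's age band and sex.

    Raises :class:`NormLookupError` for under-30 ages or strata absent from
    the table; a miss is reported, never silently substituted.
    """
    band = classify_age_band(age)
    if band is None:
        raise NormLookupError(f"age {age} is below the youngest normative band (30)")
    return norms.get(band.label, sex)


def load_study_cohort_summaries() -> pd.DataFrame:
    """Published spine-clinic cohort stratum summaries bundled as package data.

    One row per stratum with the sample ``mean``, ``se`` and ``n``, plus the
    published difference column (``printed_difference``, ``printed_ci_low``,
    ``printed_ci_high``, ``printed_p``) for validation against the bundled
    norms.
    """
    with _bundled("spine_cohort_summaries.csv").open("rb") as fh:
        return pd.read_csv(fh, dtype={"printed_p": str})


#: Published operative / non-operative SMoS group summaries (mean, sd, n)
#: from the same spine-clinic cohort, for the two-sample severity contrast.
STUDY_NONOPERATIVE_GROUP = {"mean": 62.1, "sd": 22.97, "n": 144}
STUDY_OPERATIVE_GROUP = {"mean": 50.2, "sd": 21.25, "n": 38}
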