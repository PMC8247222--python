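import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import smos

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=200,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def norms():
    """The bundled population reference table."""
    return smos.load_reference_norms()


@pytest.fixture(scope="session")
def study_summaries():
    """The bundled spine-cohort stratum summaries."""
    return smos.load_study_cohort_summaries()


@pytest.fixture
def rng():
    return np.random.default_rng(20210701)


@pytest.fixture
def cohort_csv(tmp_path):
    """Write a cohort CSV from a list of row dicts; returns the path."""

    def _write(rows, columns=smos.cohort_io.COHORT_COLUMNS):
        lines = [",".join(columns)]
        for row in rows:
            lines.append(",".join(str(row.get(c, "")) for c in columns))
        path = tmp_path / "cohort.csv"
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
        return path

    return _write
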