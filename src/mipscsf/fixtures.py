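"""Packaged cohort tables: normalized phase and CSF volumetry, 8 animals x 9 time points."""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources

import pandas as pd

__all__ = ["FixtureBundle", "load_fixture_tables", "PUBLISHED_STATISTICS"]

#: Statistics published alongside the cohort tables, used only for
#: side-by-side display against values this package computes.
PUBLISHED_STATISTICS = {
    "multiple_R": 0.824,
    "R_squared": 0.680,
    "adj_R_squared": 0.573,
    "se_estimate": 0.33882,
    "F": 6.369,
    "regression_p": 0.033,
    "partial_r_mips_csf": 0.792,
    "partial_r_mips_blood": 0.748,
    "derivative_correlation_R": 0.751,
}

# sha256 of the packaged TSVs; a mismatch means the fixtures were altered.
_CHECKSUMS = {
    "table1_mips.tsv": "53b685c52fcf92c2cffd55b48ceb422f7c3f56fe128e64f11fe79b5a52059c2e",
    "table2_csf.tsv": "7c11cf35e6a058dbd75838c7cee1d150598344064d81c45d76b501605a76daec",
}


@dataclass(frozen=True)
class FixtureBundle:
    """The two cohort tables on identical time/blood axes.

    ``table1`` holds normalized phase-shift block means (dimensionless,
    ~100 scale); ``table2`` holds CSF volumes in ml.  Columns:
    ``time_min, blood_ml, rabbit_1 .. rabbit_8``.
    """

    table1: pd.DataFrame
    table2: pd.DataFrame

    def __post_init__(self) -> None:
        axes1 = self.table1[["time_min", "blood_ml"]]
        axes2 = self.table2[["time_min", "blood_ml"]]
        if not axes1.equals(axes2):
            raise ValueError("fixture tables have mismatched time/blood axes")


def _read_checked(name: str) -> pd.DataFrame:
    raw = resources.files("mipscsf.data").joinpath(name).read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _CHECKSUMS[name]:
        raise RuntimeError(
            f"packaged fixture {name} failed its checksum "
            f"(got {digest[:12]}..., expected {_CHECKSUMS[name][:12]}...)"
        )
    from io import BytesIO

    return pd.read_csv(BytesIO(raw), sep="\t")


def load_fixture_tables() -> FixtureBundle:
    """Load and checksum-verify the packaged cohort tables."""
    return FixtureBundle(
        table1=_read_checked("table1_mips.tsv"),
        table2=_read_checked("table2_csf.tsv"),
    )
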