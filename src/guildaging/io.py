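"""Readers, writers and validation for the tabular artifacts of the pipeline.

The canonical on-disk dialect is plain TSV.  OTU tables are written with OTUs
as rows and a ``#OTU ID`` sentinel as the first header cell (the common
QIIME-style dense layout); orientation is auto-detected on read, so a table
stored samples-by-OTUs round-trips to the same in-memory object.  All floats
are written with 10 significant digits so that re-runs are byte-identical.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

OTU_SENTINEL = "#OTU ID"
FLOAT_FORMAT = "%.10g"

#: sex labels accepted in metadata
SEXES = ("male", "female")
#: event codes for the prospective follow-up
EVENTS = ("none", "t2dm", "death")

#: disease indicator columns expected in a full metadata table
DISEASE_COLUMNS = (
    "t2dm", "obesity", "gout", "fattydis", "hypertension", "stroke",
    "heartdis", "underweight", "cancer", "renal_failure", "pd",
)

#: lifestyle behaviour columns (baseline and most recent survey)
LIFESTYLE_COLUMNS = tuple(
    f"{behaviour}_{wave}"
    for behaviour in ("exercise", "smoking", "drinking", "healthy_diet")
    for wave in ("baseline", "recent")
)

#: minimal covariate set every SampleFrame must provide
REQUIRED_METADATA_COLUMNS = (
    "age_years", "sex", "bmi", "energy_kcal", "education",
) + LIFESTYLE_COLUMNS + DISEASE_COLUMNS + ("followup_months", "event")


class ValidationError(ValueError):
    """Raised when an input table violates its contract."""


class ConvergenceError(RuntimeError):
    """Raised when an iterative fit fails to converge."""


@dataclass
class OtuTable:
    """A samples x OTUs nonnegative integer count matrix with optional taxonomy.

    ``counts`` is indexed by sample id with OTU ids as columns. ``taxonomy``
    maps a subset of the OTU ids to 7-rank semicolon lineages.
    """

    counts: pd.DataFrame
    taxonomy: dict[str, str] | None = field(default=None)

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            dup = c.index[c.index.duplicated()][0]
            raise ValidationError(f"duplicated sample id: {dup!r}")
        if c.columns.has_duplicates:
            dup = c.columns[c.columns.duplicated()][0]
            raise ValidationError(f"duplicated OTU id: {dup!r}")
        arr = c.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("counts must be numeric")
        if np.any(arr < 0):
            i, j = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative count at sample {c.index[i]!r}, OTU {c.columns[j]!r}"
            )
        if not np.issubdtype(arr.dtype, np.integer):
            if np.any(arr != np.floor(arr)):
                i, j = np.argwhere(arr != np.floor(arr))[0]
                raise ValidationError(
                    f"non-integer count at sample {c.index[i]!r}, "
                    f"OTU {c.columns[j]!r}"
                )
            self.counts = c.astype(np.int64)
        if self.taxonomy is not None:
            unknown = set(self.taxonomy) - set(c.columns)
            if unknown:
                warnings.warn(
                    f"taxonomy for {len(unknown)} unknown OTUs dropped "
                    f"(e.g. {sorted(unknown)[0]!r})",
                    stacklevel=2,
                )
                self.taxonomy = {
                    k: v for k, v in self.taxonomy.items() if k not in unknown
                }

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_otus(self) -> int:
        return self.counts.shape[1]

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample closure to relative abundances (rows sum to 1)."""
        totals = self.counts.sum(axis=1)
        if (totals == 0).any():
            bad = totals.index[totals == 0][0]
            raise ValidationError(f"sample {bad!r} has zero total count")
        return self.counts.div(totals, axis=0)

    def equals(self, other: "OtuTable") -> bool:
        return self.counts.equals(other.counts) and (
            (self.taxonomy or {}) == (other.taxonomy or {})
        )


def read_otu_table(path, taxonomy_path=None) -> OtuTable:
    """Read a dense TSV OTU table, auto-detecting orientation.

    A first header cell equal to ``#OTU ID`` marks an OTUs-as-rows layout;
    anything else is taken as samples-as-rows.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.index.name == OTU_SENTINEL:
        df = df.T  # back to samples x OTUs
        df.index.name = "sample_id"
    taxonomy = read_taxonomy(taxonomy_path) if taxonomy_path is not None else None
    return OtuTable(df, taxonomy)


def write_otu_table(t: OtuTable, path) -> None:
    out = t.counts.T
    out.index.name = OTU_SENTINEL
    out.to_csv(path, sep="\t")


def read_taxonomy(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValidationError("taxonomy TSV needs at least two columns")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_taxonomy(taxonomy: dict[str, str], path) -> None:
    pd.DataFrame(
        {"otu_id": list(taxonomy), "lineage": list(taxonomy.values())}
    ).to_csv(path, sep="\t", index=False)


def read_metadata(path, age_range=(0.0, 130.0)) -> pd.DataFrame:
    m = pd.read_csv(path, sep="\t", index_col=0)
    m.index = m.index.astype(str)
    return validate_metadata(m, age_range=age_range)


def write_metadata(m: pd.DataFrame, path) -> None:
    m.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def validate_metadata(m: pd.DataFrame, age_range=(0.0, 130.0)) -> pd.DataFrame:
    """Validate a SampleFrame: required columns, sex/event domains, ranges."""
    missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in m.columns]
    if missing:
        raise ValidationError(f"metadata missing required columns: {missing}")
    if m.index.has_duplicates:
        dup = m.index[m.index.duplicated()][0]
        raise ValidationError(f"duplicated sample id in metadata: {dup!r}")
    bad_sex = set(m["sex"].unique()) - set(SEXES)
    if bad_sex:
        raise ValidationError(f"unknown sex labels: {sorted(bad_sex)}")
    bad_event = set(m["event"].unique()) - set(EVENTS)
    if bad_event:
        raise ValidationError(f"unknown event codes: {sorted(bad_event)}")
    lo, hi = age_range
    ages = m["age_years"].to_numpy(dtype=float)
    if np.any((ages < lo) | (ages > hi)):
        raise ValidationError(f"age_years outside declared range [{lo}, {hi}]")
    if np.any(m["followup_months"].to_numpy(dtype=float) < 0):
        raise ValidationError("negative followup_months")
    for col in LIFESTYLE_COLUMNS + DISEASE_COLUMNS:
        m[col] = m[col].astype(bool)
    return m


def filter_prevalence(t: OtuTable, min_prevalence: float) -> OtuTable:
    """Keep OTUs with a nonzero count in at least ``ceil(f * n_samples)`` samples.

    A count of zero is absence; prevalence counts strictly positive entries.
    """
    if not 0 < min_prevalence <= 1:
        raise ValidationError("min_prevalence must be in (0, 1]")
    n_needed = math.ceil(min_prevalence * t.n_samples)
    present = (t.counts > 0).sum(axis=0)
    keep = present.index[present >= n_needed]
    if len(keep) == 0:
        raise ValidationError(
            f"no OTU present in >= {n_needed} of {t.n_samples} samples"
        )
    taxonomy = (
        {k: v for k, v in t.taxonomy.items() if k in set(keep)}
        if t.taxonomy
        else None
    )
    return OtuTable(t.counts[keep].copy(), taxonomy)


def harmonize(t: OtuTable, m: pd.DataFrame) -> tuple[OtuTable, pd.DataFrame]:
    """Restrict counts and metadata to their shared samples, sorted by id."""
    shared = sorted(set(t.sample_ids) & set(m.index))
    if not shared:
        raise ValidationError("no shared sample ids between counts and metadata")
    return OtuTable(t.counts.loc[shared].copy(), t.taxonomy), m.loc[shared].copy()


def write_matrix(df: pd.DataFrame, path) -> None:
    """Write a square or rectangular real matrix as TSV, 10 significant digits."""
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def read_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df
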