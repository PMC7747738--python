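"""Cohort data model, phenotype derivation and file I/O.

The central container is :class:`Cohort`, a thin wrapper around a pandas
DataFrame of individuals with family id, person id, sex, age and one or more
strictly positive phenotype columns (e.g. leptin and soluble leptin receptor
concentrations in ng/ml).  Phenotype values are pulled out of a cohort as
:class:`PhenotypeVector` objects, which carry the transform applied to them
(identity or natural log) so downstream estimators can report what scale they
operated on.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("qherit")

#: canonical non-phenotype columns every cohort must carry
ID_COLUMNS = ("family_id", "person_id", "sex", "age")

#: minimum eligible age in years
MIN_AGE = 16.0

#: accepted spellings for each sex code (case-insensitive)
DEFAULT_SEX_ALIASES: Mapping[str, str] = {
    "f": "F", "female": "F", "m": "M", "male": "M",
}


@dataclass
class Cohort:
    """A table of individuals grouped into sibships.

    Parameters
    ----------
    data
        One row per person.  Must contain the columns in :data:`ID_COLUMNS`
        plus at least one phenotype column.  ``person_id`` values are unique;
        ``sex`` is coded ``"F"``/``"M"``; ``age`` is in years and >= 16.
    exclusions
        Per-reason counts of rows dropped while building the cohort.
    """

    data: pd.DataFrame
    exclusions: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in ID_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"cohort is missing required columns: {missing}")
        if self.data["person_id"].duplicated().any():
            dups = self.data.loc[self.data["person_id"].duplicated(), "person_id"]
            raise ValueError(f"duplicate person_id values: {sorted(set(dups))[:5]}")

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def phenotype_names(self) -> list[str]:
        return [c for c in self.data.columns if c not in ID_COLUMNS]

    def phenotype(self, name: str, transform: str = "identity") -> "PhenotypeVector":
        """Extract a phenotype column as a :class:`PhenotypeVector`."""
        if name not in self.data.columns:
            raise KeyError(f"phenotype column {name!r} not in cohort")
        pv = PhenotypeVector(
            person_id=self.data["person_id"].to_numpy(),
            values=self.data[name].to_numpy(dtype=float),
            name=name,
        )
        return apply_transform(pv, transform) if transform != "identity" else pv

    def subset(self, mask: np.ndarray) -> "Cohort":
        return Cohort(self.data.loc[mask].reset_index(drop=True), dict(self.exclusions))


@dataclass
class PhenotypeVector:
    """Person-aligned phenotype values with provenance.

    ``values`` is aligned to ``person_id``; missing entries are NaN and are
    excluded listwise by downstream analyses of this phenotype only.
    """

    person_id: np.ndarray
    values: np.ndarray
    name: str
    transform_tag: str = "identity"
    model: object | None = None  # audit trail, e.g. an AdjustmentModel

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.person_id) != len(self.values):
            raise ValueError("person_id and values must be aligned")

    def __len__(self) -> int:
        return len(self.values)


def read_cohort(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    sex_aliases: Mapping[str, str] | None = None,
) -> Cohort:
    """Read a delimited cohort file, dropping and counting invalid rows.

    Parameters
    ----------
    path
        CSV/TSV file with a header row (delimiter sniffed).
    column_map
        Maps canonical names (``family_id``, ``person_id``, ``sex``, ``age``,
        phenotype names) to the column names used in the file.  Unmapped
        canonical names are assumed to appear verbatim.
    sex_aliases
        Extra spellings for the sex codes, e.g. ``{"0": "M", "1": "F"}``.

    Rows with missing family id, sex or age, age below 16, unrecognisable sex
    codes, or a non-positive phenotype value are dropped; the counts are
    recorded in ``Cohort.exclusions`` and logged.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    if column_map:
        missing = [src for src in column_map.values() if src not in df.columns]
        if missing:
            raise ValueError(f"mapped columns not found in {path}: {missing}")
        df = df.rename(columns={src: dst for dst, src in column_map.items()})
    missing = [c for c in ID_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"required columns missing from {path}: {missing}")
    if df["person_id"].duplicated().any():
        dups = df.loc[df["person_id"].duplicated(), "person_id"]
        raise ValueError(f"duplicate person_id in {path}: {sorted(set(dups))[:5]}")

    aliases = dict(DEFAULT_SEX_ALIASES)
    if sex_aliases:
        aliases.update({str(k).lower(): v for k, v in sex_aliases.items()})

    exclusions: dict[str, int] = {}

    def drop(mask: pd.Series, reason: str) -> pd.DataFrame:
        n = int(mask.sum())
        if n:
            exclusions[reason] = exclusions.get(reason, 0) + n
        return df.loc[~mask]

    df = drop(df["family_id"].isna(), "missing_family_id")
    df = drop(df["age"].isna(), "missing_age")
    df = drop(pd.to_numeric(df["age"], errors="coerce") < MIN_AGE, "under_age")
    sex = df["sex"].astype(str).str.strip().str.lower().map(aliases)
    df = df.assign(sex=sex.to_numpy())
    df = drop(df["sex"].isna(), "missing_or_unrecognised_sex")

    pheno_cols = [c for c in df.columns if c not in ID_COLUMNS]
    if not pheno_cols:
        raise ValueError(f"no phenotype columns found in {path}")
    for c in pheno_cols:
        vals = pd.to_numeric(df[c], errors="coerce")
        df = df.assign(**{c: vals.to_numpy()})
        df = drop(vals.notna() & (vals <= 0), f"non_positive_{c}")

    for reason, n in exclusions.items():
        logger.info("read_cohort: dropped %d row(s): %s", n, reason)
    return Cohort(df.reset_index(drop=True), exclusions)


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write the cohort in canonical column order (ids first, then phenotypes)."""
    cols = list(ID_COLUMNS) + cohort.phenotype_names
    cohort.data[cols].to_csv(path, index=False)


def write_run_log(cohort: Cohort, path: str | Path) -> None:
    """Dump the exclusion counts as a JSON run log."""
    Path(path).write_text(json.dumps({"n": cohort.n, "exclusions": cohort.exclusions},
                                     indent=2))


def compute_fli(leptin, receptor):
    """Free leptin index: per-person ratio of leptin to soluble receptor.

    Both arguments are concentrations in the same units (ng/ml); the result is
    dimensionless.  Computed per person, never as a ratio of means.  Where the
    receptor concentration is not strictly positive the ratio is undefined and
    NaN is returned (the record drops out of FLI analyses listwise).
    """
    lep = np.asarray(leptin, dtype=float)
    rec = np.asarray(receptor, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(rec > 0, lep / rec, np.nan)
    n_bad = int(np.sum(~(rec > 0) & ~np.isnan(rec)))
    if n_bad:
        logger.info("compute_fli: %d record(s) with non-positive receptor excluded", n_bad)
    if out.ndim == 0:
        return float(out)
    return out


def add_fli(cohort: Cohort, leptin: str = "leptin", receptor: str = "leptin_receptor",
            name: str = "fli") -> Cohort:
    """Return a cohort with a free-leptin-index column appended."""
    df = cohort.data.copy()
    df[name] = compute_fli(df[leptin].to_numpy(), df[receptor].to_numpy())
    return Cohort(df, dict(cohort.exclusions))


def apply_transform(values: PhenotypeVector, kind: str) -> PhenotypeVector:
    """Transform a phenotype vector element-wise.

    ``kind="log"`` applies the natural logarithm and requires every
    non-missing value to be strictly positive; offenders are reported by
    person id.  The transform tag is recorded so results can state the scale.
    """
    if kind == "identity":
        return replace(values, transform_tag="identity")
    if kind != "log":
        raise ValueError(f"unknown transform {kind!r}")
    v = values.values
    bad = ~np.isnan(v) & (v <= 0)
    if bad.any():
        ids = list(np.asarray(values.person_id)[bad][:10])
        raise ValueError(f"log transform requires positive values; offending person_id: {ids}")
    return replace(values, values=np.log(v), transform_tag="log")
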