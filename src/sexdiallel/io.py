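"""Reading, validation and summarisation of diallel phenotype tables.

The unit of data is one fitness assay of a single F1 individual: its dam
strain, sire strain, sex, replicate block, and fitness measured as the
count of F2 offspring it produced.  A full n-strain diallel has n**2
families keyed by the *ordered* (dam, sire) pair; the diagonal families
(dam == sire) are the inbred parental selfs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

SEX_F = "F"
SEX_M = "M"
SEXES = (SEX_F, SEX_M)

#: numeric sex codes used by raw data tables: 1 = female, 2 = male
_SEX_CODE = {1: SEX_F, 2: SEX_M, "1": SEX_F, "2": SEX_M,
             "F": SEX_F, "M": SEX_M, "f": SEX_F, "m": SEX_M}

REQUIRED_COLUMNS = ("fitness", "sex", "sire", "dam", "block")


class DiallelFormatError(ValueError):
    """Raised when an input table cannot be interpreted as diallel data."""


@dataclass(frozen=True)
class DiallelRecord:
    """One fitness assay: dam and sire strain (dense 1-based ids), sex
    ('F' or 'M'), replicate block label, and a non-negative integer
    fitness (count of F2 offspring)."""

    dam: int
    sire: int
    sex: str
    block: object
    fitness: int

    @property
    def is_self(self) -> bool:
        return self.dam == self.sire


class DiallelDataset:
    """Individual-level assay records for a full diallel.

    Internally a pandas DataFrame with columns ``dam, sire, sex, block,
    fitness``; dam/sire hold dense 1..n_strains ids.  ``strain_labels``
    maps dense id -> original strain label (dense id = position + 1).
    """

    def __init__(self, df: pd.DataFrame, n_strains: int,
                 strain_labels: Sequence[object] | None = None,
                 parse_errors: Sequence[str] = ()):
        if len(df) == 0:
            raise DiallelFormatError("no records")
        if n_strains < 2:
            raise DiallelFormatError("a diallel needs at least 2 strains")
        df = df.reset_index(drop=True)
        for col in REQUIRED_COLUMNS:
            if col not in df.columns:
                raise DiallelFormatError(f"missing column {col!r}")
        present = set(df["dam"]) | set(df["sire"])
        missing_strains = set(range(1, n_strains + 1)) - present
        if missing_strains:
            raise DiallelFormatError(
                f"strains never observed in any record: {sorted(missing_strains)}")
        self.df = df[list(REQUIRED_COLUMNS)].copy()
        self.n_strains = int(n_strains)
        self.strain_labels = (list(strain_labels) if strain_labels is not None
                              else list(range(1, n_strains + 1)))
        self.parse_errors = list(parse_errors)

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        return (isinstance(other, DiallelDataset)
                and self.n_strains == other.n_strains
                and self.df.reset_index(drop=True).equals(
                    other.df.reset_index(drop=True)))

    @property
    def records(self) -> list[DiallelRecord]:
        return [DiallelRecord(int(r.dam), int(r.sire), str(r.sex), r.block,
                              int(r.fitness))
                for r in self.df.itertuples(index=False)]

    def family_keys(self) -> set[tuple[int, int]]:
        """Ordered (dam, sire) pairs present in the data."""
        return set(map(tuple, self.df[["dam", "sire"]].drop_duplicates()
                       .itertuples(index=False)))

    def subset_sex(self, sex: str) -> "DiallelDataset":
        if sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}")
        return DiallelDataset(self.df[self.df["sex"] == sex],
                              self.n_strains, self.strain_labels)

    def to_csv(self, path) -> None:
        out = self.df.copy()
        out["sex"] = out["sex"].map({SEX_F: 1, SEX_M: 2})
        # write original strain labels so a round trip is label-faithful
        out["dam"] = [self.strain_labels[i - 1] for i in out["dam"]]
        out["sire"] = [self.strain_labels[i - 1] for i in out["sire"]]
        out[list(REQUIRED_COLUMNS)].to_csv(path, index=False)


@dataclass
class ValidationReport:
    """Summary counts and structural problems of a parsed dataset."""

    n_records: int
    counts_by_sex: dict
    counts_by_block: dict
    counts_by_family: pd.DataFrame  # columns dam, sire, sex, n
    missing_families: list          # outcross (dam, sire) absent entirely
    missing_selfs: list             # self families absent
    malformed_rows: list = field(default_factory=list)

    @property
    def n_missing_outcross(self) -> int:
        return len(self.missing_families)

    @property
    def n_missing_selfs(self) -> int:
        return len(self.missing_selfs)


@dataclass
class FamilyMeanMatrix:
    """n x n matrix of family means z̄[dam, sire] for one sex.

    ``mask`` is True where the family is absent for that sex (no value).
    Indexing is 0-based internally; ``mean_of`` takes 1-based strain ids.
    """

    values: np.ndarray
    mask: np.ndarray
    sex: str

    def mean_of(self, dam: int, sire: int) -> float:
        if self.mask[dam - 1, sire - 1]:
            raise KeyError(f"family ({dam},{sire}) has no {self.sex} records")
        return float(self.values[dam - 1, sire - 1])

    @property
    def n_strains(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        """Rows = dam, columns = sire; missing families as NaN."""
        vals = np.where(self.mask, np.nan, self.values)
        idx = range(1, self.n_strains + 1)
        return pd.DataFrame(vals, index=idx, columns=idx)


def _normalise_columns(df: pd.DataFrame) -> pd.DataFrame:
    df = df.rename(columns={c: str(c).strip().lower() for c in df.columns})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise DiallelFormatError(f"missing required column(s): {missing}")
    return df


def read_diallel_table(path, fmt: str | None = None,
                       sheet: str = "Raw data") -> DiallelDataset:
    """Read a diallel phenotype table from CSV or an xlsx sheet.

    Columns ``fitness, sex, sire, dam, block`` are required
    (case-insensitive).  Sex codes 1/2 are mapped to F/M.  Strain ids are
    remapped to a dense 1..n index; the original labels are kept on the
    returned dataset.  Malformed rows (non-integer strain id, negative or
    non-integer fitness, unknown sex code) are dropped and listed in
    ``dataset.parse_errors``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = "xlsx" if path.suffix.lower() in (".xlsx", ".xls") else "csv"
    if fmt == "xlsx":
        df = pd.read_excel(path, sheet_name=sheet)
    elif fmt == "csv":
        df = pd.read_csv(path)
    else:
        raise DiallelFormatError(f"unknown format {fmt!r}")
    if len(df) == 0:
        raise DiallelFormatError("no records")
    df = _normalise_columns(df)

    errors: list[str] = []
    rows = []
    for i, row in enumerate(df.itertuples(index=False)):
        problems = []
        sex = _SEX_CODE.get(getattr(row, "sex"), None)
        if sex is None:
            problems.append(f"unknown sex code {getattr(row, 'sex')!r}")
        dam, sire = getattr(row, "dam"), getattr(row, "sire")
        try:
            dam_i, sire_i = int(dam), int(sire)
            if dam_i != float(dam) or sire_i != float(sire):
                raise ValueError
        except (TypeError, ValueError):
            problems.append(f"non-integer strain id dam={dam!r} sire={sire!r}")
            dam_i = sire_i = None
        fit = getattr(row, "fitness")
        try:
            fit_f = float(fit)
            if not np.isfinite(fit_f) or fit_f < 0 or round(fit_f) != fit_f:
                raise ValueError
            fit_i = int(round(fit_f))
        except (TypeError, ValueError):
            problems.append(f"invalid fitness {fit!r}")
            fit_i = None
        if problems:
            errors.append(f"row {i}: " + "; ".join(problems))
        else:
            rows.append((dam_i, sire_i, sex, getattr(row, "block"), fit_i))
    if not rows:
        raise DiallelFormatError("no records")

    clean = pd.DataFrame(rows, columns=["dam", "sire", "sex", "block",
                                        "fitness"])
    labels = sorted(set(clean["dam"]) | set(clean["sire"]))
    remap = {lab: i + 1 for i, lab in enumerate(labels)}
    clean["dam"] = clean["dam"].map(remap)
    clean["sire"] = clean["sire"].map(remap)
    return DiallelDataset(clean, n_strains=len(labels), strain_labels=labels,
                          parse_errors=errors)


def validate_dataset(ds: DiallelDataset) -> ValidationReport:
    """Report per-sex/block/family counts and missing families.

    Purely descriptive; never mutates or fails on incomplete designs.
    """
    df = ds.df
    fam = (df.groupby(["dam", "sire", "sex"], sort=True)
             .size().rename("n").reset_index())
    present = ds.family_keys()
    missing_out, missing_self = [], []
    for i in range(1, ds.n_strains + 1):
        for j in range(1, ds.n_strains + 1):
            if (i, j) not in present:
                (missing_self if i == j else missing_out).append((i, j))
    return ValidationReport(
        n_records=len(df),
        counts_by_sex=df["sex"].value_counts().to_dict(),
        counts_by_block=df["block"].value_counts().to_dict(),
        counts_by_family=fam,
        missing_families=missing_out,
        missing_selfs=missing_self,
        malformed_rows=list(ds.parse_errors),
    )


def family_mean_table(values: Iterable[float], ds: DiallelDataset,
                      sex: str) -> FamilyMeanMatrix:
    """Tabulate family means of ``values`` for one sex.

    ``values`` must align 1:1 with ``ds`` records.  Replicates are pooled
    across blocks (unweighted arithmetic mean); block effects are assumed
    to have been removed upstream when that matters.  Families with no
    records of the requested sex are masked.
    """
    vals = np.asarray(list(values), dtype=float)
    if len(vals) != len(ds):
        raise ValueError(
            f"values length {len(vals)} != number of records {len(ds)}")
    if sex not in SEXES:
        raise ValueError(f"sex must be one of {SEXES}")
    n = ds.n_strains
    total = np.zeros((n, n))
    count = np.zeros((n, n), dtype=int)
    sel = ds.df["sex"].to_numpy() == sex
    dams = ds.df["dam"].to_numpy()[sel] - 1
    sires = ds.df["sire"].to_numpy()[sel] - 1
    np.add.at(total, (dams, sires), vals[sel])
    np.add.at(count, (dams, sires), 1)
    mask = count == 0
    with np.errstate(invalid="ignore"):
        means = np.where(mask, 0.0, total / np.maximum(count, 1))
    return FamilyMeanMatrix(values=means, mask=mask, sex=sex)
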