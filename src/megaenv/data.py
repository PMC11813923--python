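"""In-memory containers and CSV I/O for multi-environment trial phenotypes.

The canonical on-disk format is a long-format CSV with one row per plot:

    trial_id,location,year,row,col,genotype_id,rep_class,DTF,DTM,...

``rep_class`` is ``single`` (unreplicated entry), ``check`` (duplicated) or
``standard`` (six-fold replicated cultivar).  Row/column indices are
1-based.  Missing trait cells are empty and preserved as missing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError
from .traits import TraitRegistry

REP_CLASSES = ("single", "check", "standard")

#: Columns that identify and locate a plot, in on-disk order.
META_COLUMNS = ("trial_id", "location", "year", "row", "col",
                "genotype_id", "rep_class")


@dataclass(frozen=True)
class PlotRecord:
    """A single field plot: where it is, what grows on it, what was measured."""

    trial_id: str
    location: str
    year: int
    row: int
    col: int
    genotype_id: str
    rep_class: str
    trait_values: dict[str, float]

    def __post_init__(self) -> None:
        if self.rep_class not in REP_CLASSES:
            raise FormatError(f"unknown rep_class {self.rep_class!r}")
        for trait, value in self.trait_values.items():
            if value is not None and not np.isfinite(value):
                raise FormatError(
                    f"non-finite value for {trait} at "
                    f"({self.trial_id}, {self.row}, {self.col})")


@dataclass
class METDataset:
    """A multi-environment trial dataset: one row per plot, plus trait metadata.

    Internally a :class:`pandas.DataFrame` with the meta columns followed by
    one column per trait.  ``(trial_id, row, col)`` is unique.
    """

    frame: pd.DataFrame
    registry: TraitRegistry = field(default_factory=TraitRegistry)

    def __post_init__(self) -> None:
        missing = [c for c in META_COLUMNS if c not in self.frame.columns]
        if missing:
            raise FormatError(f"dataset missing columns: {missing}")
        key = self.frame[["trial_id", "row", "col"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0]
            raise FormatError(
                f"duplicate plot key ({dup.trial_id}, {dup.row}, {dup.col})")
        self.frame = self.frame.reset_index(drop=True)

    # -- accessors ---------------------------------------------------------
    @property
    def trait_columns(self) -> list[str]:
        return [c for c in self.frame.columns if c not in META_COLUMNS]

    @property
    def trials(self) -> list[str]:
        return list(dict.fromkeys(self.frame["trial_id"]))

    @property
    def genotypes(self) -> list[str]:
        return sorted(self.frame["genotype_id"].unique())

    def trial_meta(self) -> pd.DataFrame:
        """Location/year per trial, one row per trial."""
        return (self.frame[["trial_id", "location", "year"]]
                .drop_duplicates("trial_id").reset_index(drop=True))

    def subset_trials(self, trial_ids) -> "METDataset":
        keep = self.frame["trial_id"].isin(list(trial_ids))
        return METDataset(self.frame[keep].copy(), self.registry)

    def records(self) -> list[PlotRecord]:
        out = []
        for row in self.frame.itertuples(index=False):
            values = {t: getattr(row, t) for t in self.trait_columns
                      if pd.notna(getattr(row, t))}
            out.append(PlotRecord(row.trial_id, row.location, int(row.year),
                                  int(row.row), int(row.col),
                                  row.genotype_id, row.rep_class, values))
        return out

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other) -> bool:
        if not isinstance(other, METDataset):
            return NotImplemented
        try:
            pd.testing.assert_frame_equal(self.frame, other.frame,
                                          check_like=True)
        except AssertionError:
            return False
        return True


def write_met_csv(dataset: METDataset, path) -> None:
    """Write a dataset to the long-format phenotype CSV."""
    cols = list(META_COLUMNS) + dataset.trait_columns
    dataset.frame.to_csv(path, index=False, columns=cols)


def read_met_csv(path, registry: TraitRegistry | None = None) -> METDataset:
    """Read a long-format phenotype CSV.

    Unknown trait columns are carried through with a warning; a duplicated
    ``(trial_id, row, col)`` key is a :class:`FormatError`.
    """
    registry = registry or TraitRegistry()
    frame = pd.read_csv(path, dtype={"trial_id": str, "location": str,
                                     "genotype_id": str, "rep_class": str})
    missing = [c for c in META_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    unknown = [c for c in frame.columns
               if c not in META_COLUMNS and c not in registry]
    if unknown:
        warnings.warn(f"{path}: unknown trait columns carried through: "
                      f"{unknown}", stacklevel=2)
    frame["row"] = frame["row"].astype(int)
    frame["col"] = frame["col"].astype(int)
    frame["year"] = frame["year"].astype(int)
    return METDataset(frame, registry)
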