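"""Categorical data tables with an explicit missingness mask.

The table is the universal data currency of the package: rows are samples,
columns are categorical variables with declared level sets.  Values are stored
as integer level codes; a boolean mask marks cells that are *missing* (hidden
from any learner).  When a table was produced by amputation the true code is
retained underneath the mask so that imputation accuracy can be evaluated
against ground truth; learners must only ever consume :meth:`observed_codes`
or :meth:`to_frame`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CategoricalTable", "read_csv", "write_csv"]

#: sentinel for "missing / no ground truth available" in code matrices
MISSING_CODE = -1


@dataclass
class CategoricalTable:
    """n_rows x n_cols table of category levels with a missingness mask.

    Parameters
    ----------
    columns : list of str
        Variable names, in column order.
    levels : dict
        Map variable name -> ordered list of category labels.
    codes : ndarray of int, shape (n_rows, n_cols)
        Integer level codes.  Cells under the mask may hold the pre-amputation
        ground-truth code (privileged; see :meth:`ground_truth_codes`) or
        ``-1`` when no ground truth exists (externally loaded data).
    mask : ndarray of bool, shape (n_rows, n_cols)
        ``True`` marks a missing cell.
    """

    columns: list[str]
    levels: dict[str, list[str]]
    codes: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int64)
        if self.codes.ndim != 2 or self.codes.shape[1] != len(self.columns):
            raise ValueError("codes must be 2-D with one column per variable")
        if self.mask is None:
            self.mask = np.zeros(self.codes.shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.codes.shape:
            raise ValueError("mask and codes must have identical shape")
        for j, name in enumerate(self.columns):
            k = len(self.levels[name])
            col = self.codes[:, j]
            obs = col[~self.mask[:, j]]
            if obs.size and (obs.min() < 0 or obs.max() >= k):
                raise ValueError(
                    f"observed codes of {name!r} outside its level set (k={k})"
                )

    # -- basic geometry ----------------------------------------------------
    @property
    def n_rows(self) -> int:
        return self.codes.shape[0]

    @property
    def n_cols(self) -> int:
        return self.codes.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.codes.shape

    @property
    def level_counts(self) -> np.ndarray:
        return np.array([len(self.levels[c]) for c in self.columns])

    @property
    def is_complete(self) -> bool:
        return not self.mask.any()

    # -- views --------------------------------------------------------------
    def observed_codes(self) -> np.ndarray:
        """Codes with masked cells replaced by -1 (what learners may see)."""
        out = self.codes.copy()
        out[self.mask] = MISSING_CODE
        return out

    def ground_truth_codes(self) -> np.ndarray:
        """Privileged accessor: codes including values hidden by the mask.

        Intended for the evaluation layer only (Hamming distance against the
        pre-amputation truth).  Raises if any masked cell has no ground truth.
        """
        if (self.codes[self.mask] == MISSING_CODE).any():
            raise ValueError("no ground truth recorded under the mask")
        return self.codes.copy()

    def complete_row_mask(self) -> np.ndarray:
        return ~self.mask.any(axis=1)

    @property
    def n_complete_rows(self) -> int:
        return int(self.complete_row_mask().sum())

    def complete_cases(self) -> "CategoricalTable":
        """Listwise deletion: rows with any missing cell are dropped."""
        keep = self.complete_row_mask()
        return CategoricalTable(
            list(self.columns),
            {c: list(self.levels[c]) for c in self.columns},
            self.codes[keep].copy(),
            self.mask[keep].copy(),
        )

    # -- derivation ---------------------------------------------------------
    def with_mask(self, mask: np.ndarray) -> "CategoricalTable":
        """New table with the given mask; underlying codes kept as truth."""
        return CategoricalTable(
            list(self.columns),
            {c: list(self.levels[c]) for c in self.columns},
            self.codes.copy(),
            np.asarray(mask, dtype=bool).copy(),
        )

    def filled(self, codes: np.ndarray) -> "CategoricalTable":
        """Completed copy: masked cells take values from ``codes``.

        Observed cells are required to agree with the input, so imputation can
        never alter data that was actually seen.
        """
        codes = np.asarray(codes, dtype=np.int64)
        if codes.shape != self.shape:
            raise ValueError("shape mismatch")
        obs = ~self.mask
        if not np.array_equal(codes[obs], self.codes[obs]):
            raise ValueError("completion disagrees with observed cells")
        return CategoricalTable(
            list(self.columns),
            {c: list(self.levels[c]) for c in self.columns},
            codes.copy(),
            np.zeros(self.shape, dtype=bool),
        )

    def copy(self) -> "CategoricalTable":
        return self.with_mask(self.mask)

    # -- pandas / CSV interop ----------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Observed view as a DataFrame of labels, NaN where missing."""
        data = {}
        for j, name in enumerate(self.columns):
            labels = np.array(self.levels[name], dtype=object)
            col = np.where(
                self.mask[:, j], None, labels[np.clip(self.codes[:, j], 0, None)]
            )
            data[name] = col
        return pd.DataFrame(data)

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, levels: dict[str, list[str]] | None = None
    ) -> "CategoricalTable":
        """Build from a DataFrame; NaN / None / "" cells become missing.

        Level sets default to the sorted observed labels of each column.
        """
        columns = [str(c) for c in df.columns]
        str_vals = df.astype("string")
        mask = (
            df.isna().to_numpy()
            | (str_vals == "").fillna(False).to_numpy(dtype=bool)
            | (str_vals == "NA").fillna(False).to_numpy(dtype=bool)
        )
        if levels is None:
            levels = {}
            for c in columns:
                obs = df.loc[~pd.isna(df[c]), c].astype(str)
                obs = obs[(obs != "") & (obs != "NA")]
                levels[c] = sorted(obs.unique())
        codes = np.full(df.shape, MISSING_CODE, dtype=np.int64)
        for j, c in enumerate(columns):
            lookup = {lab: i for i, lab in enumerate(levels[c])}
            col = df[c].astype(str).to_numpy()
            for i in range(df.shape[0]):
                if not mask[i, j]:
                    try:
                        codes[i, j] = lookup[col[i]]
                    except KeyError:
                        raise ValueError(
                            f"value {col[i]!r} not in levels of {c!r}"
                        ) from None
        return cls(columns, levels, codes, mask)


def write_csv(table: CategoricalTable, path) -> None:
    """Write the observed view as CSV; missing cells become empty fields."""
    table.to_frame().to_csv(path, index=False, na_rep="")


def read_csv(path, levels: dict[str, list[str]] | None = None) -> CategoricalTable:
    """Read a CSV written by :func:`write_csv`; empty fields or "NA" missing."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df = df.replace({"": None, "NA": None})
    return CategoricalTable.from_frame(df, levels=levels)
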