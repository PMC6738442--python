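"""Core data containers shared across the pipeline.

A phenotype table is a subjects x variables real matrix with explicit
missing entries (NaN) plus per-variable metadata: the modality *block* the
variable came from (e.g. a segmentation tool for imaging measures, or a
questionnaire battery for the rest), the *subdomain* used for post-hoc
aggregation, and a *polarity* flag (+1 when larger values indicate a
favourable quality, -1 when lower is better, e.g. reaction times or error
counts).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PhenotypeTable",
    "ConfoundSet",
    "CONFOUND_NAMES",
]

#: The four nuisance regressors removed from every variable before analysis.
CONFOUND_NAMES = ("age", "abs_motion", "rel_motion", "head_size")

MANIFEST_COLUMNS = ("variable", "block", "subdomain", "polarity")


@dataclass
class PhenotypeTable:
    """Subjects x variables matrix with a per-variable manifest.

    Parameters
    ----------
    values : pandas.DataFrame
        Numeric matrix indexed by subject ID, one column per variable.
        Missing entries are NaN.
    manifest : pandas.DataFrame
        One row per variable with columns ``variable``, ``block``,
        ``subdomain`` and ``polarity`` (+1 or -1), in column order of
        ``values``.
    """

    values: pd.DataFrame
    manifest: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate subject IDs: {dups[:5]}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate variable names: {dups[:5]}")
        missing_cols = set(MANIFEST_COLUMNS) - set(self.manifest.columns)
        if missing_cols:
            raise ValueError(f"manifest missing columns: {sorted(missing_cols)}")
        if len(self.manifest) != self.values.shape[1]:
            raise ValueError(
                f"manifest has {len(self.manifest)} rows for "
                f"{self.values.shape[1]} variables"
            )
        if list(self.manifest["variable"]) != list(self.values.columns):
            raise ValueError("manifest variable order does not match columns")
        if not set(np.unique(self.manifest["polarity"])) <= {-1, 1}:
            raise ValueError("polarity must be +1 or -1")

    # -- conveniences ----------------------------------------------------
    @property
    def subject_ids(self) -> pd.Index:
        return self.values.index

    @property
    def variables(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def polarity(self) -> np.ndarray:
        return self.manifest["polarity"].to_numpy()

    def matrix(self) -> np.ndarray:
        # always a copy: callers mutate freely without aliasing the table
        return self.values.to_numpy(dtype=float, copy=True)

    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    def is_complete(self) -> bool:
        return self.n_missing() == 0

    def copy(self) -> "PhenotypeTable":
        return PhenotypeTable(self.values.copy(), self.manifest.copy())

    def with_values(self, values: np.ndarray) -> "PhenotypeTable":
        """Same subjects/manifest, new value matrix."""
        df = pd.DataFrame(
            np.asarray(values, dtype=float),
            index=self.values.index,
            columns=self.values.columns,
        )
        return PhenotypeTable(df, self.manifest.copy())

    def select_subjects(self, ids) -> "PhenotypeTable":
        return PhenotypeTable(self.values.loc[ids].copy(), self.manifest.copy())

    def select_blocks(self, blocks) -> "PhenotypeTable":
        keep = self.manifest["block"].isin(list(blocks)).to_numpy()
        return PhenotypeTable(
            self.values.loc[:, self.values.columns[keep]].copy(),
            self.manifest.loc[keep].reset_index(drop=True),
        )


@dataclass
class ConfoundSet:
    """The four nuisance regressors: age, absolute and relative motion
    during scanning, and head size (a scaling factor)."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(CONFOUND_NAMES):
            raise ValueError(
                f"confound columns must be {CONFOUND_NAMES}, "
                f"got {list(self.values.columns)}"
            )
        if self.values.isna().any().any():
            raise ValueError("confounds must not contain missing values")

    @property
    def subject_ids(self) -> pd.Index:
        return self.values.index

    def matrix(self) -> np.ndarray:
        # always a copy: callers mutate freely without aliasing the table
        return self.values.to_numpy(dtype=float, copy=True)

    def aligned_to(self, table: PhenotypeTable) -> "ConfoundSet":
        if not self.values.index.equals(table.subject_ids):
            if set(self.values.index) != set(table.subject_ids):
                raise ValueError("confound subjects do not match table subjects")
            return ConfoundSet(self.values.loc[table.subject_ids].copy())
        return self
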