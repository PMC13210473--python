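"""Feature-by-sample abundance container shared by every analysis layer.

An :class:`OmicsMatrix` wraps a :class:`pandas.DataFrame` of intensities
(protein / PTM-site layers) or TPM (RNA layer) together with the sample
group design (sample -> condition).  Missing measurements are ``NaN``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

VALID_LAYERS = ("rna", "protein", "phospho", "acetyl")


class InputError(ValueError):
    """Raised when an input table or matrix violates the documented dialect."""


@dataclass
class OmicsMatrix:
    """Feature x sample abundance matrix with a group design.

    Parameters
    ----------
    values
        DataFrame indexed by feature id with one column per sample id.
        ``NaN`` encodes a missing measurement.
    layer
        One of ``rna``, ``protein``, ``phospho``, ``acetyl``.
    design
        Series mapping every sample id to its condition label.
    """

    values: pd.DataFrame
    layer: str
    design: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        if self.layer not in VALID_LAYERS:
            raise InputError(f"unknown layer {self.layer!r}; expected one of {VALID_LAYERS}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise InputError(f"duplicate feature ids: {dups[:5]}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise InputError(f"duplicate sample ids: {dups[:5]}")
        if self.values.shape[1] == 0:
            raise InputError("matrix has zero samples")
        missing = [s for s in self.values.columns if s not in self.design.index]
        if missing:
            raise InputError(f"samples absent from group design: {missing}")
        self.design = self.design.loc[self.values.columns]

    # -- convenience ------------------------------------------------------

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for c in self.design:
            if c not in seen:
                seen.append(c)
        return seen

    def samples_of(self, condition: str) -> list[str]:
        cols = [s for s in self.values.columns if self.design[s] == condition]
        if not cols:
            raise InputError(f"condition {condition!r} has no samples")
        return cols

    def condition_means(self, skipna: bool = True) -> pd.DataFrame:
        """Per-feature mean abundance for each condition (columns in design order)."""
        out = {}
        for cond in self.conditions:
            out[cond] = self.values[self.samples_of(cond)].mean(axis=1, skipna=skipna)
        return pd.DataFrame(out)

    def with_values(self, values: pd.DataFrame) -> "OmicsMatrix":
        return replace(self, values=values)

    def mask_missing(self) -> pd.DataFrame:
        """Boolean mask, True where a measurement is present."""
        return self.values.notna()

    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())


def read_matrix(path, layer: str, design: pd.Series) -> OmicsMatrix:
    """Read a tab-delimited feature x sample matrix (empty cell = missing)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise InputError(f"duplicate feature id {dup!r} in {path}")
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            if len(bad):
                raise InputError(
                    f"non-numeric cell {bad.iloc[0]!r} for feature {bad.index[0]!r} in {path}"
                )
            df[col] = pd.to_numeric(df[col], errors="coerce")
    return OmicsMatrix(values=df.astype(float), layer=layer, design=design)


def write_matrix(matrix: OmicsMatrix, path) -> None:
    """Write a matrix in the tab-delimited dialect; NaN becomes an empty cell."""
    matrix.values.to_csv(path, sep="\t", index_label="feature_id", na_rep="")


def read_design(path) -> pd.Series:
    """Read samples.tsv (sample_id, condition, replicate) into sample -> condition."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "condition"):
        if col not in df.columns:
            raise InputError(f"samples table missing required column {col!r}")
    if df["sample_id"].duplicated().any():
        raise InputError("duplicate sample_id in samples table")
    return pd.Series(df["condition"].values, index=df["sample_id"].values, name="condition")
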