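"""Channel-matrix containers and their TSV dialect.

A quantification matrix is proteins (rows) by channels (columns), where a
channel is one reporter channel of one multiplexed batch, addressed by the
key ``"<batch>:<channel>"``.  Missing measurements are NA (empty cell in
the TSV dialect) and are distinct from literal 0, which denotes a measured
absence.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

DESIGN_COLUMNS = [
    "batch",
    "channel",
    "sample_id",
    "cell_line",
    "dimension",
    "replicate",
    "is_reference",
    "pool",
]


def channel_key(batch, channel) -> str:
    return f"{batch}:{channel}"


def design_keys(design: pd.DataFrame) -> pd.Series:
    return design["batch"].astype(str) + ":" + design["channel"].astype(str)


@dataclass
class QuantMatrix:
    """Reporter-intensity table plus per-channel sample metadata.

    Parameters
    ----------
    values
        Nonnegative (or NA) floats, indexed by protein accession, one
        column per channel key.
    design
        One row per channel with columns :data:`DESIGN_COLUMNS`; the
        channel keys derived from ``batch``/``channel`` must equal the
        value columns.
    """

    values: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        self.values.index.name = "accession"
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate accessions: {dups[:5]}")
        keys = list(design_keys(self.design))
        if list(self.values.columns) != keys:
            missing = set(keys) ^ set(self.values.columns)
            raise ValueError(f"value columns and design channels disagree: {sorted(missing)[:5]}")

    # -- channel accessors ------------------------------------------------

    @property
    def accessions(self) -> pd.Index:
        return self.values.index

    @property
    def channel_keys(self) -> list[str]:
        return list(self.values.columns)

    @property
    def batches(self) -> list:
        return sorted(self.design["batch"].unique().tolist())

    @property
    def sample_keys(self) -> list[str]:
        d = self.design
        return list(design_keys(d)[~d["is_reference"]])

    @property
    def reference_keys(self) -> list[str]:
        d = self.design
        return list(design_keys(d)[d["is_reference"]])

    def batch_keys(self, batch) -> list[str]:
        d = self.design
        return list(design_keys(d)[d["batch"] == batch])

    def batch_reference_keys(self, batch) -> list[str]:
        d = self.design
        return list(design_keys(d)[(d["batch"] == batch) & d["is_reference"]])

    def with_values(self, values: pd.DataFrame) -> "QuantMatrix":
        return replace(self, values=values)

    # -- IO ---------------------------------------------------------------

    def to_tsv(self, path) -> None:
        write_matrix_tsv(self.values, path)

    @classmethod
    def from_tsv(cls, values_path, design_path) -> "QuantMatrix":
        design = read_design_tsv(design_path)
        values = read_matrix_tsv(values_path)
        values = values.reindex(columns=list(design_keys(design)))
        return cls(values=values, design=design)


@dataclass
class LogMatrix(QuantMatrix):
    """Log2-scale channel matrix with a processing-stage tag."""

    stage: str = "raw-log2"

    STAGES = ("raw-log2", "reference-scaled", "centered")

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.stage not in self.STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")

    def to_tsv(self, path) -> None:
        write_matrix_tsv(self.values, path, header_lines=[f"#stage={self.stage}"])

    @classmethod
    def from_tsv(cls, values_path, design_path) -> "LogMatrix":
        design = read_design_tsv(design_path)
        stage = "raw-log2"
        with open(values_path) as fh:
            first = fh.readline()
        if first.startswith("#stage="):
            stage = first.strip().split("=", 1)[1]
        values = read_matrix_tsv(values_path)
        values = values.reindex(columns=list(design_keys(design)))
        return cls(values=values, design=design, stage=stage)


# ---------------------------------------------------------------------------
# TSV helpers.  Empty cell == NA; literal 0 == measured zero.


def write_matrix_tsv(values: pd.DataFrame, path, header_lines: list[str] | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(line + "\n")
        values.to_csv(fh, sep="\t", index_label="accession", na_rep="")


def read_matrix_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", index_col="accession")
    return df.astype(float)


def write_design_tsv(design: pd.DataFrame, path) -> None:
    design.to_csv(path, sep="\t", index=False)


def read_design_tsv(path) -> pd.DataFrame:
    design = pd.read_csv(path, sep="\t")
    design["is_reference"] = design["is_reference"].astype(bool)
    for col in ("cell_line", "dimension"):
        design[col] = design[col].fillna("").astype(str)
    return design
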