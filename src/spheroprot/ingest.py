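"""Inclusion/exclusion rules applied before normalization.

Three gates, in the order the pipeline applies them:

1. optional peptide-level aggregation (unique peptides with mean reporter
   S/N strictly above a floor, summed per protein);
2. contaminant removal (any protein group containing a listed accession);
3. batch-support filtering (a protein must have at least one nonzero,
   non-missing value in every batch; NA-across-a-whole-batch is treated
   as a technical failure, literal zeros as biological absence and kept).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from spheroprot.quant import QuantMatrix, design_keys

GROUP_SEPARATOR = ";"


class EmptyResultError(ValueError):
    pass


def read_contaminant_list(path) -> set[str]:
    text = Path(path).read_text()
    return {line.strip() for line in text.splitlines() if line.strip()}


def read_peptide_table(path) -> pd.DataFrame:
    """Peptide TSV: peptide_id, accession, is_unique, then channel columns."""
    df = pd.read_csv(path, sep="\t")
    df["is_unique"] = df["is_unique"].astype(bool)
    return df


def aggregate_peptides(
    peptides: pd.DataFrame, design: pd.DataFrame, sn_min: float = 3.0
) -> QuantMatrix:
    """Sum retained unique peptides' reporter S/N into protein rows.

    A peptide is retained iff ``is_unique`` and its mean S/N over all
    channels is strictly greater than ``sn_min``.  Proteins with no
    retained peptide are absent from the result.

    Raises
    ------
    EmptyResultError
        If no peptide survives the S/N filter.
    """
    keys = list(design_keys(design))
    missing = [k for k in keys if k not in peptides.columns]
    if missing:
        raise ValueError(f"peptide table lacks channel columns: {missing[:5]}")

    sn = peptides[keys].astype(float)
    mean_sn = sn.mean(axis=1, skipna=True)
    keep = peptides["is_unique"].to_numpy() & (mean_sn.to_numpy() > sn_min)
    retained = peptides.loc[keep]
    if retained.empty:
        raise EmptyResultError(f"no peptides survive the S/N > {sn_min} filter")

    grouped = retained.groupby("accession")[keys].sum(min_count=1)
    grouped.index.name = "accession"
    return QuantMatrix(values=grouped, design=design.copy())


def remove_contaminants(
    q: QuantMatrix, contaminants: set[str] | list[str]
) -> tuple[QuantMatrix, list[str]]:
    """Drop every protein group containing at least one listed accession.

    Group membership is read from the row accession split on ``;``.
    Returns the filtered matrix and the removed accessions.
    """
    contaminants = set(contaminants)
    if not contaminants:
        return q.with_values(q.values.copy()), []

    def is_contaminated(group: str) -> bool:
        return any(a in contaminants for a in str(group).split(GROUP_SEPARATOR))

    mask = np.array([is_contaminated(a) for a in q.accessions])
    removed = list(q.accessions[mask])
    return q.with_values(q.values.loc[~mask]), removed


def filter_master_proteins(q: QuantMatrix) -> QuantMatrix:
    """Keep proteins with >=1 nonzero, non-missing value in every batch.

    Proteins missing (NA) across an entire batch are excluded; rows that
    merely contain zeros are retained.
    """
    keep = np.ones(len(q.accessions), dtype=bool)
    for b in q.batches:
        block = q.values[q.batch_keys(b)]
        has_support = ((block.notna() & (block != 0)).sum(axis=1) > 0).to_numpy()
        keep &= has_support
    return q.with_values(q.values.loc[keep])
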