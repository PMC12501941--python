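"""Multiplexed study design: sample-to-(batch, channel) assignment.

Biological samples (cell line x dimension x replicate) are randomly spread
over a number of multiplexed batches; every batch additionally carries the
same set of pooled reference channels used downstream to bridge batches.
Each reference pool is built from a fixed subset ("pooling set") of the
biological samples; samples are partitioned into as many pooling sets as
there are reference channels per batch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from spheroprot.quant import DESIGN_COLUMNS, design_keys, read_design_tsv, write_design_tsv

#: Reporter channel labels for an 18-plex reagent set.
PLEX18_CHANNELS = [
    "126", "127N", "127C", "128N", "128C", "129N", "129C", "130N", "130C",
    "131N", "131C", "132N", "132C", "133N", "133C", "134N", "134C", "135N",
]

DIMENSIONS = ("2D", "3D")


class BatchCapacityError(ValueError):
    """Raised when a batch would need more channels than the plex offers."""


@dataclass(frozen=True)
class StudyDesign:
    """Channel map for one multi-batch experiment.

    ``table`` has one row per channel (columns :data:`~spheroprot.quant.DESIGN_COLUMNS`).
    Reference channels have ``is_reference=True``, ``sample_id="ref<pool>"``
    and ``pool`` = the pooling-set id they represent; biological samples
    carry in ``pool`` the pooling set they contribute to.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        samples = t[~t["is_reference"]]
        if samples["sample_id"].duplicated().any():
            raise ValueError("a biological sample occupies more than one channel")
        per_batch_refs = t[t["is_reference"]].groupby("batch").size()
        if per_batch_refs.nunique() > 1:
            raise ValueError("batches carry unequal reference-channel counts")

    @property
    def batches(self) -> list:
        return sorted(self.table["batch"].unique().tolist())

    @property
    def cell_lines(self) -> list:
        t = self.table
        return sorted(t.loc[~t["is_reference"], "cell_line"].unique().tolist())

    @property
    def n_references_per_batch(self) -> int:
        t = self.table
        return int(t[t["is_reference"]].groupby("batch").size().iloc[0])

    @property
    def sample_table(self) -> pd.DataFrame:
        return self.table[~self.table["is_reference"]].reset_index(drop=True)

    def keys(self) -> pd.Series:
        return design_keys(self.table)

    def pooling_sets(self) -> dict[int, list[str]]:
        """Pooling-set id -> sample_ids contributing to that reference pool."""
        s = self.sample_table
        return {int(p): g["sample_id"].tolist() for p, g in s.groupby("pool")}

    def to_tsv(self, path) -> None:
        write_design_tsv(self.table, path)

    @classmethod
    def from_tsv(cls, path) -> "StudyDesign":
        return cls(read_design_tsv(path))


def generate_design(
    cell_lines=("PEO1", "PEO4", "UWB1.289", "UWB1.289+BRCA1"),
    replicates: int = 3,
    n_batches: int = 4,
    references_per_batch: int = 3,
    seed: int = 0,
    plex: int = 18,
) -> StudyDesign:
    """Randomly assign samples to batches and channels, seed-reproducibly.

    Samples are shuffled and dealt into batches as evenly as possible;
    every batch receives all ``references_per_batch`` reference channels.
    Channel order within each batch is randomized.

    Raises
    ------
    BatchCapacityError
        If any batch would need more channels than ``plex``.
    """
    if replicates < 1 or n_batches < 1 or references_per_batch < 1:
        raise ValueError("counts must be positive")
    rng = np.random.default_rng(seed)

    sample_ids = [
        (line, dim, rep)
        for line in cell_lines
        for dim in DIMENSIONS
        for rep in range(1, replicates + 1)
    ]
    n_samples = len(sample_ids)

    # even split: first (n_samples % n_batches) batches get one extra
    base, extra = divmod(n_samples, n_batches)
    counts = [base + (1 if b < extra else 0) for b in range(n_batches)]
    for b, c in enumerate(counts, start=1):
        if c + references_per_batch > plex:
            raise BatchCapacityError(
                f"batch {b} needs {c + references_per_batch} channels "
                f"but the plex capacity is {plex}"
            )

    order = rng.permutation(n_samples)
    pools = _partition_pools(n_samples, references_per_batch, rng)

    rows = []
    cursor = 0
    channels = PLEX18_CHANNELS[:plex] if plex <= 18 else [f"ch{i:02d}" for i in range(1, plex + 1)]
    for b in range(1, n_batches + 1):
        take = order[cursor : cursor + counts[b - 1]]
        cursor += counts[b - 1]
        batch_entries = []
        for idx in take:
            line, dim, rep = sample_ids[idx]
            batch_entries.append(
                dict(
                    batch=b,
                    sample_id=f"{line}_{dim}_r{rep}",
                    cell_line=line,
                    dimension=dim,
                    replicate=rep,
                    is_reference=False,
                    pool=int(pools[idx]),
                )
            )
        for r in range(1, references_per_batch + 1):
            batch_entries.append(
                dict(
                    batch=b,
                    sample_id=f"ref{r}",
                    cell_line="",
                    dimension="",
                    replicate=0,
                    is_reference=True,
                    pool=r,
                )
            )
        chan_order = rng.permutation(len(batch_entries))
        for slot, entry_idx in enumerate(chan_order):
            batch_entries[entry_idx]["channel"] = channels[slot]
        batch_entries.sort(key=lambda e: channels.index(e["channel"]))
        rows.extend(batch_entries)

    table = pd.DataFrame(rows)[DESIGN_COLUMNS]
    return StudyDesign(table)


def _partition_pools(n_samples: int, n_pools: int, rng: np.random.Generator) -> np.ndarray:
    """Random near-even partition of samples into pooling sets 1..n_pools."""
    assignment = np.array([1 + i % n_pools for i in range(n_samples)])
    rng.shuffle(assignment)
    return assignment
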