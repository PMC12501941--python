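"""Cross-cell-line direction classes and membrane-annotation ratios.

A protein passing the volcano filter in *every* cell line is classed by
sign unanimity: ``common_up`` / ``common_down`` when the fold-change sign
agrees everywhere, ``discordant`` otherwise.  Proteins significant in at
least one but not all lines are ``not_common``.  Class counts over the
all-lines intersection always satisfy

    |common_up| + |common_down| + |discordant| = |intersection|.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

CLASSES = ("common_up", "common_down", "discordant", "not_common")


def classify_concordance(
    sig: dict[str, dict[str, set[str]]], cell_lines: list[str] | None = None
) -> pd.DataFrame:
    """Classify every protein significant in >=1 line.

    ``sig`` maps cell line -> ``{"up": set, "down": set}`` (the volcano
    output at one threshold setting).  Returns a table indexed by
    accession with per-line ``sig_<line>`` / ``sign_<line>`` columns and a
    ``concordance_class`` column.
    """
    lines = list(cell_lines) if cell_lines is not None else sorted(sig)
    universe = sorted(set().union(*(s["up"] | s["down"] for s in sig.values())))
    rows = []
    for acc in universe:
        signs = {}
        for line in lines:
            if acc in sig[line]["up"]:
                signs[line] = 1
            elif acc in sig[line]["down"]:
                signs[line] = -1
            else:
                signs[line] = 0
        in_all = all(signs[line] != 0 for line in lines)
        if not in_all:
            klass = "not_common"
        elif all(signs[line] == 1 for line in lines):
            klass = "common_up"
        elif all(signs[line] == -1 for line in lines):
            klass = "common_down"
        else:
            klass = "discordant"
        row = {"accession": acc, "concordance_class": klass}
        for line in lines:
            row[f"sig_{line}"] = int(signs[line] != 0)
            row[f"sign_{line}"] = signs[line]
        rows.append(row)
    out = pd.DataFrame(
        rows, columns=["accession", "concordance_class"]
        + [c for line in lines for c in (f"sig_{line}", f"sign_{line}")],
    ).set_index("accession")
    return out


def concordance_counts(records: pd.DataFrame) -> dict[str, int]:
    counts = {k: 0 for k in CLASSES}
    counts.update(records["concordance_class"].value_counts().to_dict())
    return counts


@dataclass
class MembraneRatioRow:
    """One line (or intersection) of the membrane-annotation ratio table."""

    label: str
    n_total: int
    n_membrane: int
    n_membrane_up: int
    n_membrane_down: int

    @property
    def ratio_pct(self) -> float:
        if self.n_total == 0:
            return float("nan")
        return 100.0 * self.n_membrane / self.n_total


def membrane_baseline_pct(annotated: set[str], universe: set[str]) -> float:
    """Percentage of annotated proteins in the identified-protein universe."""
    if not universe:
        raise ValueError("empty universe")
    return 100.0 * len(set(annotated) & set(universe)) / len(universe)


def membrane_ratio(
    sig: dict[str, dict[str, set[str]]],
    annotated: set[str],
    universe: set[str],
    intersections: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Annotated-protein counts and percentages per differential set.

    One row per cell line plus one per requested intersection (mapping
    label -> list of lines).  For an intersection, the total is every
    protein significant in all member lines (any signs) while the
    annotated up/down counts use the unidirectional subsets, so
    ``n_membrane = n_membrane_up + n_membrane_down`` holds throughout.
    """
    annotated = set(annotated) & set(universe)
    rows: list[MembraneRatioRow] = []

    for line in sorted(sig):
        up, down = sig[line]["up"], sig[line]["down"]
        total = up | down
        rows.append(
            MembraneRatioRow(
                label=line,
                n_total=len(total),
                n_membrane=len(annotated & total),
                n_membrane_up=len(annotated & up),
                n_membrane_down=len(annotated & down),
            )
        )

    for label, lines in (intersections or {}).items():
        ups = [sig[l]["up"] for l in lines]
        downs = [sig[l]["down"] for l in lines]
        alls = [u | d for u, d in zip(ups, downs)]
        inter_any = set.intersection(*alls)
        inter_up = set.intersection(*ups)
        inter_down = set.intersection(*downs)
        rows.append(
            MembraneRatioRow(
                label=label,
                n_total=len(inter_any),
                n_membrane=len(annotated & (inter_up | inter_down)),
                n_membrane_up=len(annotated & inter_up),
                n_membrane_down=len(annotated & inter_down),
            )
        )

    empty = [r.label for r in rows if r.n_total == 0]
    if empty:
        warnings.warn(f"empty differential sets, ratio undefined: {empty}")

    frame = pd.DataFrame(
        [
            {
                "label": r.label,
                "n_total": r.n_total,
                "n_membrane": r.n_membrane,
                "n_membrane_up": r.n_membrane_up,
                "n_membrane_down": r.n_membrane_down,
                "ratio_pct": r.ratio_pct,
            }
            for r in rows
        ]
    ).set_index("label")
    return frame


def read_annotation_tsv(path) -> set[str]:
    """Two-column TSV (accession, source); returns the annotated accessions."""
    df = pd.read_csv(path, sep="\t", header=None, names=["accession", "source"], comment="#")
    return set(df["accession"].astype(str))


def write_annotation_tsv(accessions: set[str], path, source: str = "annotation") -> None:
    with open(path, "w") as fh:
        for acc in sorted(accessions):
            fh.write(f"{acc}\t{source}\n")
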