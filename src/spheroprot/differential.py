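"""Row-wise one-way ANOVA, fold changes, and threshold selections.

The F statistic is computed from explicit between/within sums of squares
(classical equal-variance ANOVA) rather than delegated, so degenerate rows
can be handled per the pipeline's conventions:

- zero within-group variance with unequal group means -> p is the smallest
  positive float, flagged;
- all values identical -> F = 0, p = 1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from spheroprot.quant import LogMatrix, design_keys

P_SMALLEST = np.nextafter(0.0, 1.0)


@dataclass(frozen=True)
class GroupSpec:
    """Channel-to-group mapping plus the per-cell-line 3D-vs-2D pairs."""

    groups: dict[str, list[str]]  # group label -> channel keys
    comparisons: dict[str, tuple[str, str]]  # cell line -> (3D group, 2D group)

    def __post_init__(self) -> None:
        if len(self.groups) < 2:
            raise ValueError("need at least two groups")
        small = [g for g, keys in self.groups.items() if len(keys) < 2]
        if small:
            raise ValueError(f"groups need >=2 members for variance estimation: {small}")

    @classmethod
    def from_design(cls, design: pd.DataFrame) -> "GroupSpec":
        """One group per (cell line, dimension); references excluded."""
        d = design[~design["is_reference"]]
        keys = design_keys(d)
        groups: dict[str, list[str]] = {}
        for (line, dim), sub in d.groupby(["cell_line", "dimension"]):
            groups[f"{line}|{dim}"] = list(keys.loc[sub.index])
        comparisons = {}
        for line in sorted(d["cell_line"].unique()):
            g3, g2 = f"{line}|3D", f"{line}|2D"
            if g3 in groups and g2 in groups:
                comparisons[line] = (g3, g2)
        return cls(groups=groups, comparisons=comparisons)


def oneway_anova(*groups) -> tuple[float, float]:
    """Classical one-way ANOVA on >=2 groups of observations.

    Returns ``(F, p)`` with the conventions documented in the module
    docstring for degenerate rows.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    arrays = [a[np.isfinite(a)] for a in arrays]
    if len(arrays) < 2 or any(len(a) < 2 for a in arrays):
        raise ValueError("need >=2 groups with >=2 finite values each")
    ns = np.array([len(a) for a in arrays])
    means = np.array([a.mean() for a in arrays])
    grand = np.concatenate(arrays).mean()
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(sum(np.sum((a - m) ** 2) for a, m in zip(arrays, means)))
    df_between = len(arrays) - 1
    df_within = int(ns.sum()) - len(arrays)
    if df_within < 1:
        raise ValueError("no residual degrees of freedom")
    if ss_within == 0.0:
        if ss_between == 0.0:
            return 0.0, 1.0
        return math.inf, P_SMALLEST
    F = (ss_between / df_between) / (ss_within / df_within)
    p = float(stats.f.sf(F, df_between, df_within))
    return F, max(p, P_SMALLEST)


def rowwise_anova(values: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized one-way ANOVA over matrix rows (NaN-aware).

    ``labels`` assigns each column to a group; returns per-row ``(F, p)``.
    """
    values = np.asarray(values, dtype=float)
    uniq = pd.unique(labels)
    finite = np.isfinite(values)
    x = np.where(finite, values, 0.0)

    ns, sums, ss_within = [], [], 0.0
    group_cols = [labels == g for g in uniq]
    for cols in group_cols:
        ns.append(finite[:, cols].sum(axis=1))
        sums.append(x[:, cols].sum(axis=1))
    ns = np.stack(ns, axis=1).astype(float)
    sums = np.stack(sums, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        means = sums / ns

    # two-pass residual sum keeps ss_within exactly 0 for constant groups
    ss_within = np.zeros(len(values))
    for j, cols in enumerate(group_cols):
        resid = np.where(finite[:, cols], x[:, cols] - means[:, j][:, None], 0.0)
        ss_within += (resid**2).sum(axis=1)

    n_tot = ns.sum(axis=1)
    grand = sums.sum(axis=1) / n_tot
    ss_between = np.nansum(ns * (means - grand[:, None]) ** 2, axis=1)

    k_eff = (ns > 0).sum(axis=1)
    df_between = k_eff - 1
    df_within = n_tot - k_eff
    F = np.full(len(values), np.nan)
    p = np.full(len(values), np.nan)
    ok = (df_between >= 1) & (df_within >= 1)

    degenerate = ok & (ss_within == 0.0)
    flat = degenerate & (ss_between <= 1e-300)
    spiked = degenerate & ~flat
    F[flat], p[flat] = 0.0, 1.0
    F[spiked], p[spiked] = np.inf, P_SMALLEST

    reg = ok & ~degenerate
    F[reg] = (ss_between[reg] / df_between[reg]) / (ss_within[reg] / df_within[reg])
    p[reg] = np.maximum(stats.f.sf(F[reg], df_between[reg], df_within[reg]), P_SMALLEST)
    return F, p


def compute_differential(m: LogMatrix, spec: GroupSpec | None = None) -> pd.DataFrame:
    """Per-protein global ANOVA plus per-cell-line lfc and pairwise p.

    Columns: ``anova_F``, ``anova_p`` (all groups), then ``lfc_<line>``
    (mean log2 over 3D replicates minus mean over 2D; positive = up in 3D)
    and ``p_<line>`` (two-group ANOVA on that line's samples).
    """
    spec = spec or GroupSpec.from_design(m.design)
    used_keys = [k for keys in spec.groups.values() for k in keys]
    labels = np.concatenate([[g] * len(keys) for g, keys in spec.groups.items()])
    data = m.values[used_keys].to_numpy()

    F, p = rowwise_anova(data, labels)
    out = pd.DataFrame({"anova_F": F, "anova_p": p}, index=m.accessions)

    for line, (g3, g2) in spec.comparisons.items():
        m3 = m.values[spec.groups[g3]].mean(axis=1, skipna=True)
        m2 = m.values[spec.groups[g2]].mean(axis=1, skipna=True)
        if m3.isna().all() or m2.isna().all():
            warnings.warn(f"cell line {line}: a dimension group is entirely missing")
        out[f"lfc_{line}"] = m3 - m2
        pair_labels = np.array([g3] * len(spec.groups[g3]) + [g2] * len(spec.groups[g2]))
        pair_data = m.values[spec.groups[g3] + spec.groups[g2]].to_numpy()
        _, pp = rowwise_anova(pair_data, pair_labels)
        out[f"p_{line}"] = pp
    return out


def cell_lines_of(table: pd.DataFrame) -> list[str]:
    return [c[len("lfc_") :] for c in table.columns if c.startswith("lfc_")]


def volcano_filter(
    table: pd.DataFrame, p_thresh: float = 0.01, lfc_thresh: float = 1.0
) -> dict[str, dict[str, set[str]]]:
    """Per-cell-line up/down significant sets at strict thresholds.

    A protein is significant for a line iff its pairwise ``p < p_thresh``
    and ``|lfc| > lfc_thresh`` (both strict, as stated).
    """
    if p_thresh <= 0 or lfc_thresh < 0:
        raise ValueError("thresholds must be positive")
    out: dict[str, dict[str, set[str]]] = {}
    for line in cell_lines_of(table):
        p = table[f"p_{line}"]
        lfc = table[f"lfc_{line}"]
        sig = (p < p_thresh) & (lfc.abs() > lfc_thresh)
        out[line] = {
            "up": set(table.index[sig & (lfc > 0)]),
            "down": set(table.index[sig & (lfc < 0)]),
        }
    return out


def add_significance_flags(
    table: pd.DataFrame,
    p_strict: float = 0.01,
    p_relaxed: float = 0.05,
    lfc_min: float = 1.0,
) -> pd.DataFrame:
    """Append 0/1 flag columns recomputable from the stored p and lfc."""
    out = table.copy()
    for line in cell_lines_of(table):
        p = table[f"p_{line}"]
        a = table[f"lfc_{line}"].abs()
        out[f"sig_strict_{line}"] = ((p < p_strict) & (a > lfc_min)).astype(int)
        out[f"sig_relaxed_{line}"] = ((p < p_relaxed) & (a > lfc_min)).astype(int)
    return out


@dataclass
class HeatmapSelection:
    accessions: list[str]
    sd: pd.Series
    sd_cutoff: float
    p_max: float


def heatmap_select(
    table: pd.DataFrame,
    m: LogMatrix,
    p_max: float = 0.01,
    top_frac: float = 0.3,
) -> HeatmapSelection:
    """Significant-and-variable selection for the expression heatmap.

    Restricts to global ``anova_p < p_max`` and keeps the top ``top_frac``
    fraction (ceiling) by per-protein standard deviation of the centered
    log2 values over sample channels; ties at the cutoff are all kept.
    """
    if not 0 < top_frac <= 1:
        raise ValueError("top_frac must be in (0, 1]")
    sig = table.index[table["anova_p"] < p_max]
    if len(sig) == 0:
        return HeatmapSelection([], pd.Series(dtype=float), math.nan, p_max)
    sd = m.values.loc[sig, m.sample_keys].std(axis=1, skipna=True)
    n_keep = math.ceil(top_frac * len(sd))
    cutoff = float(np.sort(sd.to_numpy())[::-1][n_keep - 1])
    selected = sd.index[sd >= cutoff]
    return HeatmapSelection(list(selected), sd, cutoff, p_max)
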