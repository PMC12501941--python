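"""Ground-truth-labeled synthetic reporter-intensity datasets.

Generative model (log2 scale, chosen so that per-batch reference scaling
removes the batch term exactly):

    signal[i, s] = baseline[i] + line_offset[i, line(s)]
                   + effect[i, line(s)] * 1{dim(s) == 3D}
                   + batch_offset[i, batch(s)] + noise

Linear intensities are ``2**signal``.  Each reference pool equals the mean
*linear* base abundance of the samples in its pooling set; measured
reference channels carry the batch offset (and measurement noise) of the
batch they are run in, which is what makes them usable for cross-batch
bridging.  Zeros are injected only into biological sample channels.
Contaminant rows are nonzero only in 3D sample channels (matrix-embedded
cultures are the only contamination source).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from spheroprot.design import DIMENSIONS, StudyDesign
from spheroprot.quant import QuantMatrix

CONTAMINANT_PREFIX = "CONT_MOUSE_"


@dataclass(frozen=True)
class SyntheticParams:
    """Knobs of the generative model.

    ``frac_de`` of the ``n_proteins`` human proteins get a true 3D-vs-2D
    shift of ``effect_log2`` (log2 units); ``frac_common`` of those share
    one sign across all cell lines, the rest draw independent per-line
    signs.  ``n_contaminants`` extra rows are spiked only into 3D sample
    channels.
    """

    n_proteins: int = 6000
    frac_de: float = 0.1
    effect_log2: float = 2.0
    frac_common: float = 0.9
    common_sign: int | None = None
    cellline_effect_sd: float = 0.5
    batch_effect_sd: float = 0.3
    noise_sd: float = 0.15
    zero_rate: float = 0.004
    n_contaminants: int = 0
    baseline_log2_mean: float = 7.0
    baseline_log2_sd: float = 1.5
    contaminant_log2_mean: float = 5.0
    contaminant_log2_sd: float = 1.0
    de_from_baseline_tails: bool = False
    tail_margin_log2: float = 1.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be positive")
        for name in ("frac_de", "frac_common"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("cellline_effect_sd", "batch_effect_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.zero_rate <= 0.05:
            raise ValueError(f"zero_rate must be in [0, 0.05], got {self.zero_rate}")
        if self.common_sign not in (None, -1, 1):
            raise ValueError("common_sign must be None, -1 or +1")
        if self.n_contaminants < 0:
            raise ValueError("n_contaminants must be >= 0")
        if self.de_from_baseline_tails and self.frac_common != 1.0:
            raise ValueError(
                "tail-placed differential proteins require frac_common=1 "
                "(mixed per-line signs cannot stay clear of the median)"
            )


@dataclass
class GroundTruth:
    """Per-protein truth labels and true log2 condition means.

    ``table`` is indexed by accession with columns ``is_de``,
    ``is_contaminant``, ``baseline_log2``, ``common`` and one ``sign_<line>``
    column per cell line (0 when not differential).  ``means`` holds the
    true log2 mean per ``<line>|<dim>`` condition (NA where the protein is
    absent, i.e. contaminants in 2D).
    """

    table: pd.DataFrame
    means: pd.DataFrame
    cell_lines: list[str]
    effect_log2: float

    @property
    def de_accessions(self) -> pd.Index:
        return self.table.index[self.table["is_de"]]

    @property
    def contaminant_accessions(self) -> pd.Index:
        return self.table.index[self.table["is_contaminant"]]

    def expected_lfc(self, cell_line: str) -> pd.Series:
        """True 3D-minus-2D log2 fold change per protein for one line."""
        sign = self.table[f"sign_{cell_line}"]
        return sign.astype(float) * self.effect_log2

    def to_tsv(self, path) -> None:
        merged = self.table.join(self.means)
        merged.insert(0, "effect_log2", self.effect_log2)
        merged.to_csv(path, sep="\t", index_label="accession", na_rep="")

    @classmethod
    def from_tsv(cls, path) -> "GroundTruth":
        merged = pd.read_csv(path, sep="\t", index_col="accession")
        effect = float(merged.pop("effect_log2").iloc[0])
        mean_cols = [c for c in merged.columns if "|" in c]
        lines = sorted({c.split("|")[0] for c in mean_cols})
        table = merged.drop(columns=mean_cols)
        table["is_de"] = table["is_de"].astype(bool)
        table["is_contaminant"] = table["is_contaminant"].astype(bool)
        table["common"] = table["common"].astype(bool)
        return cls(table=table, means=merged[mean_cols], cell_lines=lines, effect_log2=effect)


def _rng_for(params: SyntheticParams, stream: int) -> np.random.Generator:
    # one root seed, disjoint deterministic streams per stage
    return np.random.default_rng([params.seed, stream])


def generate_truth(params: SyntheticParams, design: StudyDesign) -> GroundTruth:
    """Draw baselines, pick differential proteins, assign per-line signs.

    Exactly ``round(n_proteins * frac_de)`` proteins are differential; of
    those, ``round(frac_common * n_de)`` share one sign across all lines.
    With ``de_from_baseline_tails`` the up-shifted proteins are drawn from
    baselines above the median and the down-shifted from below it (by at
    least ``tail_margin_log2``), which keeps every channel's median
    composed of non-differential proteins.
    """
    rng = _rng_for(params, 0)
    lines = design.cell_lines
    n = params.n_proteins

    accessions = [f"HP{i:05d}" for i in range(1, n + 1)]
    baseline = rng.normal(params.baseline_log2_mean, params.baseline_log2_sd, size=n)

    n_de = round(n * params.frac_de)
    n_common = round(n_de * params.frac_common)

    signs = np.zeros((n, len(lines)), dtype=int)
    common = np.zeros(n, dtype=bool)

    if params.de_from_baseline_tails:
        de_idx, de_signs = _tail_placed_de(params, baseline, n_de, rng)
        for j, idx in enumerate(de_idx):
            signs[idx, :] = de_signs[j]
        common[de_idx] = True
    else:
        de_idx = rng.choice(n, size=n_de, replace=False)
        common_idx = de_idx[:n_common]
        indep_idx = de_idx[n_common:]
        for idx in common_idx:
            s = params.common_sign if params.common_sign is not None else int(rng.choice([-1, 1]))
            signs[idx, :] = s
        for idx in indep_idx:
            signs[idx, :] = rng.choice([-1, 1], size=len(lines))
        common[common_idx] = True

    is_de = np.zeros(n, dtype=bool)
    is_de[de_idx] = True

    line_offsets = rng.normal(0.0, params.cellline_effect_sd, size=(n, len(lines)))

    table = pd.DataFrame(
        {
            "is_de": is_de,
            "is_contaminant": False,
            "common": common,
            "baseline_log2": baseline,
        },
        index=pd.Index(accessions, name="accession"),
    )
    for j, line in enumerate(lines):
        table[f"sign_{line}"] = signs[:, j]

    means = {}
    for j, line in enumerate(lines):
        base = baseline + line_offsets[:, j]
        means[f"{line}|2D"] = base
        means[f"{line}|3D"] = base + signs[:, j] * params.effect_log2
    means = pd.DataFrame(means, index=table.index)

    if params.n_contaminants:
        cont_acc = [f"{CONTAMINANT_PREFIX}C{i:04d}" for i in range(1, params.n_contaminants + 1)]
        cont_base = rng.normal(
            params.contaminant_log2_mean, params.contaminant_log2_sd, size=params.n_contaminants
        )
        cont_table = pd.DataFrame(
            {
                "is_de": False,
                "is_contaminant": True,
                "common": False,
                "baseline_log2": cont_base,
            },
            index=pd.Index(cont_acc, name="accession"),
        )
        for line in lines:
            cont_table[f"sign_{line}"] = 0
        cont_means = pd.DataFrame(np.nan, index=cont_table.index, columns=means.columns)
        for line in lines:
            cont_means[f"{line}|3D"] = cont_base
        table = pd.concat([table, cont_table])
        means = pd.concat([means, cont_means])

    return GroundTruth(table=table, means=means, cell_lines=list(lines), effect_log2=params.effect_log2)


def _tail_placed_de(
    params: SyntheticParams, baseline: np.ndarray, n_de: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    med = np.median(baseline)
    de_signs = (
        np.full(n_de, params.common_sign, dtype=int)
        if params.common_sign is not None
        else rng.choice([-1, 1], size=n_de)
    )
    n_up = int(np.sum(de_signs == 1))
    n_down = n_de - n_up
    hi = np.flatnonzero(baseline > med + params.tail_margin_log2)
    lo = np.flatnonzero(baseline < med - params.tail_margin_log2)
    if len(hi) < n_up or len(lo) < n_down:
        raise ValueError(
            f"not enough tail candidates for tail-placed differential proteins "
            f"(need {n_up} up / {n_down} down, have {len(hi)} / {len(lo)})"
        )
    up_idx = rng.choice(hi, size=n_up, replace=False)
    down_idx = rng.choice(lo, size=n_down, replace=False)
    de_idx = np.empty(n_de, dtype=int)
    de_idx[de_signs == 1] = up_idx
    de_idx[de_signs == -1] = down_idx
    return de_idx, de_signs


def generate_quant(params: SyntheticParams, design: StudyDesign, truth: GroundTruth) -> QuantMatrix:
    """Realize a reporter-intensity matrix from the design and the truth.

    Returns a proteins x channels matrix of nonnegative linear values.
    Reference channels never receive injected zeros.
    """
    rng = _rng_for(params, 1)
    dtab = design.table
    batches = design.batches
    batch_pos = {b: j for j, b in enumerate(batches)}
    n_rows = len(truth.table)
    n_chan = len(dtab)

    acc = truth.table.index
    is_cont = truth.table["is_contaminant"].to_numpy()

    beta = rng.normal(0.0, params.batch_effect_sd, size=(n_rows, len(batches)))
    eps = rng.normal(0.0, params.noise_sd, size=(n_rows, n_chan))

    # linear base pool per (protein, pooling set); contaminants contribute 0
    pools = design.pooling_sets()
    sample_tab = design.sample_table.set_index("sample_id")
    pool_linear = {}
    for pool_id, sample_ids in pools.items():
        cols = []
        for sid in sample_ids:
            line = sample_tab.loc[sid, "cell_line"]
            dim = sample_tab.loc[sid, "dimension"]
            m = truth.means[f"{line}|{dim}"].to_numpy(dtype=float)
            lin = np.where(np.isnan(m), 0.0, np.exp2(np.where(np.isnan(m), 0.0, m)))
            cols.append(lin)
        pool_linear[pool_id] = np.mean(cols, axis=0)

    values = np.zeros((n_rows, n_chan))
    sample_chan_mask = np.zeros(n_chan, dtype=bool)
    for c, row in enumerate(dtab.itertuples(index=False)):
        bpos = batch_pos[row.batch]
        if row.is_reference:
            p = pool_linear[int(row.pool)]
            with np.errstate(divide="ignore"):
                logp = np.where(p > 0, np.log2(np.where(p > 0, p, 1.0)), -np.inf)
            sig = logp + beta[:, bpos] + eps[:, c]
            values[:, c] = np.where(np.isfinite(sig), np.exp2(np.where(np.isfinite(sig), sig, 0.0)), 0.0)
        else:
            sample_chan_mask[c] = True
            m = truth.means[f"{row.cell_line}|{row.dimension}"].to_numpy(dtype=float)
            sig = m + beta[:, bpos] + eps[:, c]
            vals = np.where(np.isnan(sig), 0.0, np.exp2(np.where(np.isnan(sig), 0.0, sig)))
            values[:, c] = vals

    # contaminant rows exist only where matrix-embedded material was measured
    if is_cont.any():
        is_3d_sample = (~dtab["is_reference"] & (dtab["dimension"] == "3D")).to_numpy()
        values[np.ix_(is_cont, ~is_3d_sample)] = 0.0

    if params.zero_rate > 0:
        zero_mask = rng.random((n_rows, n_chan)) < params.zero_rate
        zero_mask[:, ~sample_chan_mask] = False
        values[zero_mask] = 0.0

    cols = list(design.keys())
    frame = pd.DataFrame(values, index=acc, columns=cols)
    return QuantMatrix(values=frame, design=dtab.copy())


def write_contaminant_list(truth: GroundTruth, path) -> None:
    Path(path).write_text("".join(a + "\n" for a in truth.contaminant_accessions))
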