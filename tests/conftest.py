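import numpy as np
import pandas as pd
import pytest

from spheroprot.design import generate_design
from spheroprot.quant import DESIGN_COLUMNS, LogMatrix, QuantMatrix
from spheroprot.simulate import SyntheticParams, generate_quant, generate_truth


@pytest.fixture(scope="session")
def design4x4():
    """4 lines x 2 dims x 3 reps over 4 batches, 3 references per batch."""
    return generate_design(seed=11)


@pytest.fixture(scope="session")
def small_design():
    return generate_design(
        cell_lines=("A", "B"), replicates=2, n_batches=2, references_per_batch=2, seed=3
    )


@pytest.fixture(scope="session")
def noisefree_dataset(design4x4):
    """Noise-free synthetic data with batch effects and tail-placed effects."""
    params = SyntheticParams(
        n_proteins=800,
        frac_de=0.1,
        frac_common=1.0,
        effect_log2=1.5,
        cellline_effect_sd=0.0,
        batch_effect_sd=0.3,
        noise_sd=0.0,
        zero_rate=0.0,
        de_from_baseline_tails=True,
        seed=11,
    )
    truth = generate_truth(params, design4x4)
    quant = generate_quant(params, design4x4, truth)
    return params, truth, quant


@pytest.fixture(scope="session")
def noisy_dataset(design4x4):
    params = SyntheticParams(
        n_proteins=600,
        frac_de=0.1,
        frac_common=0.9,
        effect_log2=2.0,
        cellline_effect_sd=0.5,
        batch_effect_sd=0.3,
        noise_sd=0.2,
        zero_rate=0.004,
        n_contaminants=12,
        seed=7,
    )
    truth = generate_truth(params, design4x4)
    quant = generate_quant(params, design4x4, truth)
    return params, truth, quant


def make_matrix(values, design_rows, log=False, stage="centered"):
    """Build a (Log)QuantMatrix from a 2D array and (batch, channel, ...) rows."""
    design = pd.DataFrame(design_rows, columns=DESIGN_COLUMNS)
    keys = design["batch"].astype(str) + ":" + design["channel"].astype(str)
    n = np.asarray(values).shape[0]
    frame = pd.DataFrame(
        np.asarray(values, dtype=float),
        index=[f"P{i:03d}" for i in range(1, n + 1)],
        columns=list(keys),
    )
    if log:
        return LogMatrix(values=frame, design=design, stage=stage)
    return QuantMatrix(values=frame, design=design)


def simple_rows(n_samples_per_batch=2, n_refs=1, n_batches=1, dims=None):
    """Design rows for hand-built matrices: samples then refs per batch."""
    rows = []
    for b in range(1, n_batches + 1):
        for i in range(n_samples_per_batch):
            dim = dims[i] if dims else "2D"
            rows.append(
                dict(
                    batch=b,
                    channel=f"c{i+1}",
                    sample_id=f"S{b}_{i+1}",
                    cell_line="A",
                    dimension=dim,
                    replicate=i + 1,
                    is_reference=False,
                    pool=1,
                )
            )
        for r in range(1, n_refs + 1):
            rows.append(
                dict(
                    batch=b,
                    channel=f"r{r}",
                    sample_id=f"ref{r}",
                    cell_line="",
                    dimension="",
                    replicate=0,
                    is_reference=True,
                    pool=r,
                )
            )
    return rows
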