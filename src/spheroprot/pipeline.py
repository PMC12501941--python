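"""End-to-end orchestration: simulate/ingest -> normalize -> differential
-> concordance/membrane -> enrichment -> dose-response.

Every stage writes plain TSV into the output directory and records a
SHA-256 of each artifact in the run manifest, so that re-running with an
identical configuration and inputs reproduces identical hashes for the
deterministic stages (all of them — every random draw flows from the one
root seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from spheroprot import __version__
from spheroprot import concordance as conc
from spheroprot import differential as diff
from spheroprot import dose_response as dr
from spheroprot import enrichment as enr
from spheroprot import ingest as ing
from spheroprot import normalize as norm
from spheroprot.design import StudyDesign, generate_design
from spheroprot.quant import QuantMatrix
from spheroprot.simulate import SyntheticParams, generate_quant, generate_truth, write_contaminant_list


@dataclass
class Thresholds:
    p_strict: float = 0.01
    p_relaxed: float = 0.05
    lfc_min: float = 1.0
    sd_top_frac: float = 0.3
    zero_floor: float = 0.1
    peptide_sn_min: float = 3.0

    def __post_init__(self) -> None:
        for name in ("p_strict", "p_relaxed", "lfc_min", "zero_floor", "peptide_sn_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.sd_top_frac < 1:
            raise ValueError("sd_top_frac must be in (0, 1)")


@dataclass
class SyntheticConfig:
    cell_lines: list[str] = field(
        default_factory=lambda: ["PEO1", "PEO4", "UWB1.289", "UWB1.289+BRCA1"]
    )
    replicates: int = 3
    n_batches: int = 4
    references_per_batch: int = 3
    params: dict = field(default_factory=dict)  # SyntheticParams overrides


@dataclass
class PipelineConfig:
    """Single-file configuration holding every analysis constant."""

    seed: int = 0
    thresholds: Thresholds = field(default_factory=Thresholds)
    synthetic: SyntheticConfig | None = field(default_factory=SyntheticConfig)
    quant: str | None = None
    design: str | None = None
    contaminants: str | None = None
    annotations: str | None = None
    gene_sets: str | None = None
    plates: str | None = None
    remove_contaminants: bool = True
    run_enrichment: bool = True
    gsea_B: int = 1000

    def to_yaml(self, path) -> None:
        data = asdict(self)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        if "thresholds" in data and data["thresholds"] is not None:
            data["thresholds"] = Thresholds(**data["thresholds"])
        if data.get("synthetic") is not None:
            data["synthetic"] = SyntheticConfig(**data["synthetic"])
        return cls(**data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class PipelineError(RuntimeError):
    def __init__(self, stage: str, manifest: dict, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.manifest = manifest
        self.cause = cause


def run_all(config: PipelineConfig, outdir) -> dict:
    """Execute every configured stage; returns the run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "started": datetime.now(timezone.utc).isoformat(),
        "stages": [],
        "counts": {},
    }

    def record(stage: str, outputs: dict[str, Path]) -> None:
        manifest["stages"].append(
            {"stage": stage, "outputs": {name: _sha256(p) for name, p in outputs.items()}}
        )

    state: dict = {}
    try:
        _stage_inputs(config, outdir, manifest, state, record)
        _stage_ingest(config, outdir, manifest, state, record)
        _stage_normalize(config, outdir, manifest, state, record)
        _stage_differential(config, outdir, manifest, state, record)
        _stage_concordance(config, outdir, manifest, state, record)
        _stage_membrane(config, outdir, manifest, state, record)
        if config.run_enrichment and config.gene_sets:
            _stage_enrichment(config, outdir, manifest, state, record)
        if config.plates:
            _stage_dose_response(config, outdir, manifest, state, record)
    except Exception as exc:  # record completed stages, then abort
        manifest["failed_stage"] = getattr(exc, "stage", "unknown")
        _write_manifest(manifest, outdir)
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(manifest["failed_stage"], manifest, exc) from exc

    manifest["finished"] = datetime.now(timezone.utc).isoformat()
    _write_manifest(manifest, outdir)
    return manifest


def _write_manifest(manifest: dict, outdir: Path) -> None:
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def _wrap(stage):
    def deco(fn):
        def inner(config, outdir, manifest, state, record):
            try:
                fn(config, outdir, manifest, state, record)
            except Exception as exc:
                raise PipelineError(stage, manifest, exc) from exc

        return inner

    return deco


@_wrap("inputs")
def _stage_inputs(config, outdir, manifest, state, record):
    if config.quant and config.design:
        q = QuantMatrix.from_tsv(config.quant, config.design)
        state["quant"] = q
        state["design"] = StudyDesign(q.design)
        state["contaminant_list"] = (
            ing.read_contaminant_list(config.contaminants) if config.contaminants else set()
        )
        record("inputs", {})
        return
    if config.synthetic is None:
        raise ValueError("no quant/design paths and synthetic generation disabled")
    sc = config.synthetic
    design = generate_design(
        cell_lines=sc.cell_lines,
        replicates=sc.replicates,
        n_batches=sc.n_batches,
        references_per_batch=sc.references_per_batch,
        seed=config.seed,
    )
    params = SyntheticParams(**{"seed": config.seed, **sc.params})
    truth = generate_truth(params, design)
    q = generate_quant(params, design, truth)
    design_path = outdir / "design.tsv"
    quant_path = outdir / "quant.tsv"
    truth_path = outdir / "truth.tsv"
    cont_path = outdir / "contaminants.txt"
    design.to_tsv(design_path)
    q.to_tsv(quant_path)
    truth.to_tsv(truth_path)
    write_contaminant_list(truth, cont_path)
    state.update(
        quant=q,
        design=design,
        truth=truth,
        contaminant_list=set(truth.contaminant_accessions),
    )
    record(
        "inputs",
        {"design": design_path, "quant": quant_path, "truth": truth_path, "contaminants": cont_path},
    )


@_wrap("ingest")
def _stage_ingest(config, outdir, manifest, state, record):
    q = state["quant"]
    n_raw = len(q.accessions)
    removed: list[str] = []
    if config.remove_contaminants and state.get("contaminant_list"):
        q, removed = ing.remove_contaminants(q, state["contaminant_list"])
    q = ing.filter_master_proteins(q)
    state["filtered"] = q
    path = outdir / "filtered.tsv"
    q.to_tsv(path)
    manifest["counts"].update(
        proteins_raw=n_raw,
        contaminants_removed=len(removed),
        proteins_retained=len(q.accessions),
    )
    record("ingest", {"filtered": path})


@_wrap("normalize")
def _stage_normalize(config, outdir, manifest, state, record):
    m = norm.normalize_pipeline(state["filtered"], floor=config.thresholds.zero_floor)
    state["norm"] = m
    path = outdir / "normalized.tsv"
    m.to_tsv(path)
    outputs = {"normalized": path}
    try:
        pca = norm.run_pca(m, k=2)
        pca_path = outdir / "pca_scores.tsv"
        pca.scores.to_csv(pca_path, sep="\t")
        outputs["pca"] = pca_path
    except ValueError:
        pass
    corr_path = outdir / "sample_correlation.tsv"
    norm.sample_correlation(m).to_csv(corr_path, sep="\t")
    outputs["correlation"] = corr_path
    record("normalize", outputs)


@_wrap("differential")
def _stage_differential(config, outdir, manifest, state, record):
    t = config.thresholds
    table = diff.compute_differential(state["norm"])
    table = diff.add_significance_flags(table, t.p_strict, t.p_relaxed, t.lfc_min)
    state["diff"] = table
    path = outdir / "differential.tsv"
    table.to_csv(path, sep="\t", na_rep="")
    for line in diff.cell_lines_of(table):
        manifest["counts"][f"differential_strict_{line}"] = int(table[f"sig_strict_{line}"].sum())
        manifest["counts"][f"differential_relaxed_{line}"] = int(table[f"sig_relaxed_{line}"].sum())
    record("differential", {"differential": path})


@_wrap("concordance")
def _stage_concordance(config, outdir, manifest, state, record):
    t = config.thresholds
    sig = diff.volcano_filter(state["diff"], t.p_strict, t.lfc_min)
    records = conc.classify_concordance(sig)
    state["sig_strict"] = sig
    state["concordance"] = records
    path = outdir / "concordance.tsv"
    records.to_csv(path, sep="\t")
    counts = conc.concordance_counts(records)
    manifest["counts"].update({f"class_{k}": v for k, v in counts.items()})
    record("concordance", {"concordance": path})


@_wrap("membrane")
def _stage_membrane(config, outdir, manifest, state, record):
    if not config.annotations:
        return
    t = config.thresholds
    annotated = conc.read_annotation_tsv(config.annotations)
    sig = diff.volcano_filter(state["diff"], t.p_relaxed, t.lfc_min)
    universe = set(state["norm"].accessions)
    lines = sorted(sig)
    table = conc.membrane_ratio(sig, annotated, universe, intersections={"all": lines})
    state["membrane"] = table
    path = outdir / "membrane_ratio.tsv"
    table.to_csv(path, sep="\t")
    manifest["counts"]["membrane_baseline_pct"] = conc.membrane_baseline_pct(annotated, universe)
    record("membrane", {"membrane": path})


@_wrap("enrichment")
def _stage_enrichment(config, outdir, manifest, state, record):
    collection = enr.read_gmt(config.gene_sets)
    universe = set(state["norm"].accessions)
    records = state["concordance"]
    common = set(
        records.index[records["concordance_class"].isin(["common_up", "common_down"])]
    )
    outputs = {}
    if common:
        ora = enr.ora_collection(common, collection, universe)
        ora_path = outdir / "ora.tsv"
        ora.to_csv(ora_path, sep="\t")
        outputs["ora"] = ora_path
    table = state["diff"]
    for line in diff.cell_lines_of(table):
        ranking = table[f"lfc_{line}"].dropna()
        res = enr.gsea_collection(
            ranking, collection, B=config.gsea_B, seed=config.seed, weight_exponent=1.0
        )
        path = outdir / f"gsea_{line}.tsv"
        res.to_csv(path, sep="\t")
        outputs[f"gsea_{line}"] = path
    record("enrichment", outputs)


@_wrap("dose_response")
def _stage_dose_response(config, outdir, manifest, state, record):
    readings = dr.read_plate_csv(config.plates)
    fits = dr.fit_plate(readings, seed=config.seed)
    state["fits"] = fits
    path = outdir / "dose_response.tsv"
    fits.to_csv(path, sep="\t", na_rep="")
    record("dose_response", {"fits": path})


def report_counts(manifest: dict) -> pd.DataFrame:
    """Paper-style summary: quantified, per-line differential, classes."""
    counts = manifest.get("counts", {})
    rows = [{"quantity": k, "count": v} for k, v in counts.items()]
    return pd.DataFrame(rows)
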