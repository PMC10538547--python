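"""End-to-end orchestration: simulate -> collapse/digest/assign ->
quantify -> nonadditive -> solubility -> bias.

Each stage reads its inputs from and writes its outputs into one run
directory, so any stage can be re-run in isolation; a manifest with
SHA-256 checksums of every output underwrites byte-level reproducibility
claims. All randomness flows from the single seed in the configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, io
from .bias import classify_bias, count_subgenome_peptides, intersect_bias_nonadditive
from .nonadditive import classify_and_summarize, mpv_contrast
from .orthoproteome import (
    assign_peptides,
    build_collapsed_proteome,
    digest,
    filter_cross_matches,
    records_to_frame,
)
from .quantify import filter_features, impute_missing, median_normalize, top3_quantify
from .simulate import SimulationParams, generate_proteomes, simulate_intensities
from .solubility import analyze_solubility

logger = logging.getLogger(__name__)

PARENT_GENOTYPES = {"parent1": "parent1", "parent2": "parent2"}


@dataclass
class RunConfig:
    """Pipeline configuration: simulation parameters, stage options, and
    the classification thresholds (defaults: |log2FC| 0.5, p 0.05,
    solubility score 0.5, bias fraction 0.75)."""

    simulation: SimulationParams = field(default_factory=SimulationParams)
    digest_min_len: int = 6
    digest_max_len: int = 50
    digest_max_missed: int = 2
    filter_min_runs: int = 3
    impute_method: str = "aft"
    top_n: int = 3
    lfc_threshold: float = 0.5
    p_threshold: float = 0.05
    score_threshold: float = 0.5
    bias_threshold: float = 0.75

    def validate(self) -> None:
        self.simulation.validate()
        for name in ("lfc_threshold", "p_threshold", "score_threshold",
                     "bias_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationParams.from_dict(raw.pop("simulation", {}) or {})
        cfg = cls(simulation=sim, **raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        raw = {k: v for k, v in self.__dict__.items() if k != "simulation"}
        raw["simulation"] = self.simulation.to_dict()
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def stage_simulate(cfg: RunConfig, outdir: Path) -> list[Path]:
    params = cfg.simulation
    sequences, catalog, truth = generate_proteomes(params)
    p1 = {k: v for k, v in sequences.items() if catalog.parent_label(k) == "parent1"}
    p2 = {k: v for k, v in sequences.items() if catalog.parent_label(k) == "parent2"}
    io.write_fasta(p1, outdir / "parent1.fasta")
    io.write_fasta(p2, outdir / "parent2.fasta")
    catalog.to_tsv(outdir / "orthogroups.tsv")
    io.write_tsv(truth, outdir / "truth.tsv")
    return [outdir / n for n in
            ("parent1.fasta", "parent2.fasta", "orthogroups.tsv", "truth.tsv")]


def stage_assign(cfg: RunConfig, outdir: Path) -> list[Path]:
    catalog = io.read_catalog(outdir / "orthogroups.tsv")
    sequences = {
        **io.read_fasta(outdir / "parent1.fasta"),
        **io.read_fasta(outdir / "parent2.fasta"),
    }
    proteome = build_collapsed_proteome(catalog, sequences)
    io.write_collapsed_fasta(proteome, outdir / "collapsed.fasta")
    peptides = sorted(
        {
            p.sequence
            for entry in proteome.values()
            for p in digest(
                entry.sequence,
                max_missed=cfg.digest_max_missed,
                min_len=cfg.digest_min_len,
                max_len=cfg.digest_max_len,
            )
        }
    )
    records = assign_peptides(peptides, proteome, catalog)
    io.write_tsv(records_to_frame(records), outdir / "peptide_records.tsv")

    truth = pd.read_csv(outdir / "truth.tsv", sep="\t")
    design, features = simulate_intensities(cfg.simulation, catalog, truth, records)
    io.write_tsv(design, outdir / "design.tsv")
    io.write_tsv(features, outdir / "features.tsv")
    return [outdir / n for n in
            ("collapsed.fasta", "peptide_records.tsv", "design.tsv", "features.tsv")]


def stage_quantify(cfg: RunConfig, outdir: Path) -> list[Path]:
    features = io.read_features(outdir / "features.tsv")
    design = io.read_design(outdir / "design.tsv")
    filtered = filter_features(features, min_runs=cfg.filter_min_runs)
    normalized = median_normalize(filtered)
    imputed = impute_missing(
        normalized, design, method=cfg.impute_method,
        genotype_subgenome=PARENT_GENOTYPES,
    )
    io.write_tsv(imputed, outdir / "features_processed.tsv")
    matrices = top3_quantify(imputed, design, top_n=cfg.top_n)
    paths = [outdir / "features_processed.tsv"]
    for fraction, matrix in matrices.items():
        path = outdir / f"abundance_{fraction}.tsv"
        io.write_matrix(matrix, path)
        paths.append(path)
    return paths


def _hybrid_genotypes(design: pd.DataFrame) -> list[str]:
    return [g for g in dict.fromkeys(design["genotype"]) if g not in PARENT_GENOTYPES]


def stage_nonadditive(cfg: RunConfig, outdir: Path) -> list[Path]:
    design = io.read_design(outdir / "design.tsv")
    soluble = io.read_matrix(outdir / "abundance_soluble.tsv")
    results = pd.concat(
        [
            mpv_contrast(soluble, design, hyb, ("parent1", "parent2"))
            for hyb in _hybrid_genotypes(design)
        ],
        ignore_index=True,
    )
    classified, up, down, overlap = classify_and_summarize(
        results, cfg.lfc_threshold, cfg.p_threshold
    )
    io.write_tsv(classified, outdir / "nonadditive.tsv")
    io.write_tsv(overlap, outdir / "nonadditive_overlap.tsv")
    return [outdir / "nonadditive.tsv", outdir / "nonadditive_overlap.tsv"]


def stage_solubility(cfg: RunConfig, outdir: Path) -> list[Path]:
    design = io.read_design(outdir / "design.tsv")
    matrices = {
        "soluble": io.read_matrix(outdir / "abundance_soluble.tsv"),
        "insoluble": io.read_matrix(outdir / "abundance_insoluble.tsv"),
    }
    results = pd.concat(
        [
            analyze_solubility(
                matrices, design, hyb, ("parent1", "parent2"),
                cfg.score_threshold, cfg.p_threshold,
            )
            for hyb in _hybrid_genotypes(design)
        ],
        ignore_index=True,
    )
    io.write_tsv(results, outdir / "solubility.tsv")
    return [outdir / "solubility.tsv"]


def stage_bias(cfg: RunConfig, outdir: Path) -> list[Path]:
    design = io.read_design(outdir / "design.tsv")
    features = io.read_features(outdir / "features.tsv")
    rec_frame = pd.read_csv(outdir / "peptide_records.tsv", sep="\t")
    # reconstruct the minimal record view needed for the cross-match filter
    from .orthoproteome import PeptideRecord

    records = [
        PeptideRecord(
            sequence=row["peptide"],
            missed_cleavages=int(row["missed_cleavages"]),
            hits=(
                [(row["orthogroup_id"], "", 0)]
                if isinstance(row["orthogroup_id"], str) and row["orthogroup_id"]
                else []
            ),
            unique_to_orthogroup=bool(row["unique_to_orthogroup"]),
            subgenome_specific=row["subgenome_specific"],
        )
        for _, row in rec_frame.iterrows()
    ]
    kept, discarded = filter_cross_matches(
        records, features, design, PARENT_GENOTYPES
    )
    # whole-cell runs are QC-only; bias is counted over the analysis
    # fractions, where intensity-dependent censoring carries the dose signal
    frac_runs = set(
        design.loc[design["fraction"].isin(("soluble", "insoluble")), "run_id"]
    )
    counts = count_subgenome_peptides(
        features[features["run_id"].isin(frac_runs)],
        design,
        kept,
        _hybrid_genotypes(design),
    )
    per_sample, pooled = classify_bias(counts, threshold=cfg.bias_threshold)
    io.write_tsv(per_sample, outdir / "bias_per_sample.tsv")
    io.write_tsv(pooled, outdir / "bias_pooled.tsv")
    classified = pd.read_csv(outdir / "nonadditive.tsv", sep="\t")
    summary = intersect_bias_nonadditive(pooled, classified)
    io.write_tsv(summary, outdir / "bias_nonadditive_overlap.tsv")
    return [
        outdir / "bias_per_sample.tsv",
        outdir / "bias_pooled.tsv",
        outdir / "bias_nonadditive_overlap.tsv",
    ]


STAGES = [
    ("simulate", stage_simulate),
    ("assign", stage_assign),
    ("quantify", stage_quantify),
    ("nonadditive", stage_nonadditive),
    ("solubility", stage_solubility),
    ("bias", stage_bias),
]


def run_pipeline(cfg: RunConfig, outdir) -> dict:
    """Run every stage in order; returns (and writes) the run manifest."""
    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(outdir / "config.yaml")
    manifest: dict = {
        "version": __version__,
        "seed": cfg.simulation.seed,
        "stages": [],
        "outputs": {},
    }
    for name, fn in STAGES:
        logger.info("stage %s", name)
        try:
            paths = fn(cfg, outdir)
        except Exception as exc:  # pragma: no cover - error path
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        manifest["stages"].append(name)
        for p in paths:
            manifest["outputs"][p.name] = _sha256(p)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
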