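"""End-to-end orchestration: fixture generation, stage running, manifest.

A single YAML configuration drives the stages: annotation feature
extraction, enrichment calling, motif-frequency characterization,
UTR-length comparison and qPCR validation. Every stochastic step draws
from the mandatory config seed; rerunning a config reproduces every output
byte-for-byte, which the run manifest (parameter echo + SHA-256 checksums
of inputs and outputs) makes checkable.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from . import __version__
from .annotation import (
    complete_transcripts,
    extract_features,
    feature_length_table,
    read_gtf,
)
from .characterization import (
    MotifEnrichment,
    MotifSpec,
    UtrLengthComparison,
    motif_profiles,
)
from .enrichment import RipEnrichment
from .qpcr import QpcrValidation
from . import simulate as sim


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception | str):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


class PipelinePaths(BaseModel):
    gtf: Path
    fasta: Path
    counts: Path
    qpcr: Path | None = None
    outdir: Path = Path("results")


class PipelineParams(BaseModel):
    seed: int
    fold_cutoff: float = 2.0
    alpha: float = 0.05
    pseudocount: float = Field(0.5, gt=0)
    motif_forward: str = "CTCCTCCTCCTCC"
    motif_reverse: str = "GAGGAGGAGGAGG"
    strict_rc: bool = False
    overlap_mode: str = "overlapping"
    normalization: str = "transcript_length"
    n_sets: int = Field(100, ge=1)
    n_high: int = 50
    n_low: int = 50
    top_bottom_k: int = 10
    utr_test: str = "rank_sum"
    min_input_expression: float = 1.0

    @field_validator("overlap_mode")
    @classmethod
    def _overlap(cls, v):
        if v not in ("overlapping", "non-overlapping"):
            raise ValueError(f"unknown overlap_mode {v!r}")
        return v

    @field_validator("normalization")
    @classmethod
    def _norm(cls, v):
        if v not in ("transcript_length", "feature_length"):
            raise ValueError(f"unknown normalization {v!r}")
        return v

    @field_validator("utr_test")
    @classmethod
    def _utr(cls, v):
        if v not in ("rank_sum", "signed_rank"):
            raise ValueError(f"unknown utr_test {v!r}")
        return v


class PipelineConfig(BaseModel):
    paths: PipelinePaths
    params: PipelineParams

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        cfg = cls.model_validate(raw)
        base = Path(path).parent
        for name in ("gtf", "fasta", "counts", "qpcr", "outdir"):
            p = getattr(cfg.paths, name)
            if p is not None and not p.is_absolute():
                setattr(cfg.paths, name, base / p)
        return cfg

    def motif_spec(self) -> MotifSpec:
        return MotifSpec(
            forward=self.params.motif_forward,
            reverse=self.params.motif_reverse,
            overlap_mode=self.params.overlap_mode,
            strict_rc=self.params.strict_rc,
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(name: str):
    def deco(fn):
        def wrapper(*a, **kw):
            try:
                return fn(*a, **kw)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, exc) from exc
        return wrapper
    return deco


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage of a configured analysis; returns the manifest dict.

    Outputs land in ``config.paths.outdir``: the enrichment table, target
    gene sets, per-transcript motif profiles, the random-set motif report,
    the UTR-length report, the qPCR report with cross-platform
    correlation, and ``manifest.json``.
    """
    p = config.paths
    par = config.params
    for required in ("gtf", "fasta", "counts"):
        path = getattr(p, required)
        if not Path(path).exists():
            raise PipelineError("configuration", f"missing {required} file: {path}")
    outdir = Path(p.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    @_stage("annotation")
    def _annotation():
        import pyfaidx

        models = read_gtf(p.gtf)
        genome = pyfaidx.Fasta(str(p.fasta))
        feats = [extract_features(t, genome) for t in models]
        complete = complete_transcripts(feats)
        lengths = feature_length_table(complete)
        out = outdir / "feature_lengths.tsv"
        lengths.to_csv(out, sep="\t", index=False)
        outputs["feature_lengths"] = out
        return complete

    complete = _annotation()

    @_stage("enrichment")
    def _enrichment():
        model = RipEnrichment.from_tsv(
            p.counts,
            fold_cutoff=par.fold_cutoff,
            alpha=par.alpha,
            pseudocount=par.pseudocount,
        )
        res = model.fit()
        out = outdir / "enrichment.tsv"
        res.to_tsv(out)
        outputs["enrichment"] = out
        sets = {
            "selected": sorted(res.selected.index),
            "quartile4": sorted(res.quartile4().index),
        }
        try:
            tb = res.top_bottom(par.top_bottom_k)
            sets["quartile4_top_bottom"] = list(tb.index)
        except ValueError:
            sets["quartile4_top_bottom"] = []
        high_low = res.high_low_sets(par.n_high, par.n_low)
        sets["high"] = list(high_low[high_low["set"] == "high"].index)
        sets["low"] = list(high_low[high_low["set"] == "low"].index)
        out = outdir / "target_sets.json"
        out.write_text(json.dumps(sets, indent=1, sort_keys=True))
        outputs["target_sets"] = out
        return res, sets

    enr, sets = _enrichment()

    @_stage("motif")
    def _motif():
        spec = config.motif_spec()
        target_genes = set(sets["selected"])
        enriched_feats = [f for f in complete if f.gene_id in target_genes]
        general_feats = [f for f in complete if f.gene_id not in target_genes]
        if not enriched_feats or not general_feats:
            raise ValueError("need complete transcripts in both the target and general sets")
        enriched_prof = motif_profiles(enriched_feats, spec, par.normalization)
        general_prof = motif_profiles(general_feats, spec, par.normalization)
        out = outdir / "motif_profiles.tsv"
        pd.concat(
            [enriched_prof.assign(set="enriched"), general_prof.assign(set="general")]
        ).to_csv(out, sep="\t", index=False)
        outputs["motif_profiles"] = out
        fit = MotifEnrichment(enriched_prof, general_prof, n_sets=par.n_sets).fit(
            seed=par.seed
        )
        out = outdir / "motif_enrichment.tsv"
        fit.comparisons.to_csv(out, sep="\t", index=False)
        outputs["motif_enrichment"] = out
        out = outdir / "motif_summary.json"
        out.write_text(
            json.dumps(
                fit.summary_table.set_index("feature").to_dict(orient="index"),
                indent=1,
                sort_keys=True,
            )
        )
        outputs["motif_summary"] = out
        return fit

    _motif()

    @_stage("utr")
    def _utr():
        target_genes = set(sets["high"]) | set(sets["low"])
        target_feats = [f for f in complete if f.gene_id in target_genes]
        report = {}
        for which in ("utr5", "utr3"):
            res = UtrLengthComparison(
                [len(f.feature(which)) for f in target_feats],
                [len(f.feature(which)) for f in complete],
                which=which,
                test=par.utr_test,
            ).fit()
            report[which] = res.to_dict()
        out = outdir / "utr_report.json"
        out.write_text(json.dumps(report, indent=1, sort_keys=True))
        outputs["utr_report"] = out

    _utr()

    if p.qpcr is not None:
        @_stage("qpcr")
        def _qpcr():
            val = QpcrValidation.from_tsv(p.qpcr)
            res = val.fit()
            out = outdir / "qpcr_report.tsv"
            res.to_tsv(out)
            outputs["qpcr_report"] = out
            seq = sequencing_ip_over_input(p.counts, par.pseudocount)
            corr = res.correlate_with_sequencing(seq.to_frame("seq_ip_over_input"))
            out = outdir / "qpcr_correlation.json"
            out.write_text(
                json.dumps(
                    {
                        "pearson_log2": corr.pcc,
                        "n_genes": len(corr.paired),
                        "dropped_genes": corr.dropped_genes,
                    },
                    indent=1,
                    sort_keys=True,
                )
            )
            outputs["qpcr_correlation"] = out

        _qpcr()

    manifest = {
        "package_version": __version__,
        "seed": par.seed,
        "parameters": json.loads(par.model_dump_json()),
        "inputs": {
            name: _sha256(Path(path))
            for name, path in (
                ("gtf", p.gtf), ("fasta", p.fasta), ("counts", p.counts), ("qpcr", p.qpcr)
            )
            if path is not None and Path(path).exists()
        },
        "outputs": {name: _sha256(path) for name, path in sorted(outputs.items())},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def sequencing_ip_over_input(counts_path, pseudocount: float = 0.5) -> pd.Series:
    """Per-gene mean replicate (IP'+c)/(input'+c) on normalized counts."""
    from .enrichment import CountMatrix

    cm = CountMatrix.from_tsv(counts_path)
    norm = cm.normalized()
    reps = cm.replicates("IP")
    ratios = [
        (norm[f"IP_{i}"] + pseudocount) / (norm[f"input_{i}"] + pseudocount) for i in reps
    ]
    out = sum(ratios) / len(ratios)
    out.name = "seq_ip_over_input"
    return out


def write_fasta(genome: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in genome:
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


FIXTURE_SCALES = {
    "tiny": {"n_genes": 200, "n_sets": 20, "n_high": 3, "n_low": 3, "top_bottom_k": 1,
             "n_qpcr_each": 5},
    "default": {"n_genes": 10_000, "n_sets": 100, "n_high": 50, "n_low": 50,
                "top_bottom_k": 10, "n_qpcr_each": 25},
}


def make_fixture(outdir, scale: str = "tiny", seed: int = 7) -> Path:
    """Write a complete synthetic dataset plus ready-to-run config.yaml.

    ``tiny`` (200 genes) runs the full pipeline in seconds and is meant
    for tests; ``default`` (10,000 genes) reproduces the desk-scale study
    conditions. Returns the config path.
    """
    if scale not in FIXTURE_SCALES:
        raise ValueError(f"scale must be one of {sorted(FIXTURE_SCALES)}")
    sc = FIXTURE_SCALES[scale]
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = sim.make_truth(sc["n_genes"], seed=seed)
    models, genome, planted = sim.gen_annotation(truth.n_genes, truth)
    from .annotation import write_gtf

    write_gtf(models, outdir / "annotation.gtf")
    write_fasta(genome, outdir / "genome.fa")
    counts = sim.gen_counts(sim.gene_ids(truth.n_genes), truth, n_rep=3)
    counts.to_csv(outdir / "counts.tsv", sep="\t")
    rng_sel = np.random.default_rng([seed, 4])
    enriched = sorted(truth.enriched_genes)
    background = sorted(set(sim.gene_ids(truth.n_genes)) - truth.enriched_genes)
    k = sc["n_qpcr_each"]
    qpcr_genes = sorted(
        list(rng_sel.choice(enriched, size=min(k, len(enriched)), replace=False))
        + list(rng_sel.choice(background, size=k, replace=False))
    )
    sim.gen_qpcr(qpcr_genes, truth).to_csv(outdir / "qpcr.tsv", sep="\t", index=False)
    (outdir / "truth.json").write_text(truth.to_json())
    (outdir / "planted_motifs.json").write_text(json.dumps(planted, indent=1))
    cfg = {
        "paths": {
            "gtf": "annotation.gtf",
            "fasta": "genome.fa",
            "counts": "counts.tsv",
            "qpcr": "qpcr.tsv",
            "outdir": "results",
        },
        "params": {
            "seed": seed,
            "n_sets": sc["n_sets"],
            "n_high": sc["n_high"],
            "n_low": sc["n_low"],
            "top_bottom_k": sc["top_bottom_k"],
        },
    }
    cfg_path = outdir / "config.yaml"
    cfg_path.write_text(yaml.safe_dump(cfg, sort_keys=True))
    return cfg_path
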