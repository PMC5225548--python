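"""Synthetic RIP-seq study generator with planted, recoverable truth.

Emulates the study design the pipeline analyses: three biological IP
replicates with matched input and IgG (mock pulldown) libraries over a
negative-binomial count model; an annotated transcriptome in which every
transcript has exon/intron/5'UTR/3'UTR structure; a planted enriched gene
subset with elevated IP capture and elevated UTR motif density and UTR
lengths; and amplification-efficiency-aware qPCR Ct tables drawn from the
same underlying abundances as the count matrix.

All randomness flows from ``SyntheticTruth.seed`` through per-component
child generators, so each generator is reproducible independently of the
others.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .annotation import GenomicInterval, TranscriptModel, reverse_complement

ROLES = ("IP", "input", "IgG")
SEGMENTS = ("utr5", "cds", "utr3", "intron")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class GenerationError(ValueError):
    """Impossible generator geometry or configuration."""


@dataclass
class SyntheticTruth:
    """Planted ground truth shared by the annotation, count and qPCR generators.

    Parameters mirror the emulated study: triplicate pulldowns, a 5%
    enriched gene subset at 4-fold IP enrichment over the IgG background,
    NB dispersion 0.1 across biological replicates, and a 2% background
    capture rate for the mock pulldown. UTR length medians follow the
    mouse UTRome scale (5'UTR 160 nt, 3'UTR 607 nt); enriched genes carry
    longer UTRs (the 258/160 and 2881/607 regimes) and a 3x motif density
    in both UTRs.
    """

    seed: int
    n_genes: int = 10_000
    enriched_genes: frozenset = frozenset()
    planted_fold: float = 4.0
    nb_dispersion: float = 0.1
    background_rate: float = 0.02  # IgG capture rate beta
    library_sizes: dict = field(
        default_factory=lambda: {"IP": 2_000_000, "input": 2_000_000, "IgG": 2_000_000}
    )
    # expected planted motif occurrences per kilobase, per sequence segment
    motif_density_background: dict = field(
        default_factory=lambda: {"utr5": 0.3, "cds": 0.15, "utr3": 0.3, "intron": 0.15}
    )
    motif_density_target: dict = field(
        default_factory=lambda: {"utr5": 0.9, "cds": 0.15, "utr3": 0.9, "intron": 0.15}
    )
    # log-normal feature-length medians (nt) and the common log-sd
    utr5_median: float = 160.0
    utr3_median: float = 607.0
    cds_median: float = 900.0
    intron_median: float = 300.0
    length_log_sd: float = 0.8
    # multiplicative UTR-length scaling for enriched genes
    target_utr5_scale: float = 258.0 / 160.0
    target_utr3_scale: float = 2881.0 / 607.0
    abundance_log_sd: float = 1.0
    min_feature_length: int = 20

    def __post_init__(self) -> None:
        if self.planted_fold < 1:
            raise GenerationError("planted_fold must be >= 1")
        if self.nb_dispersion <= 0:
            raise GenerationError("nb_dispersion must be > 0")
        for d in (self.motif_density_background, self.motif_density_target):
            if any(v < 0 for v in d.values()):
                raise GenerationError("motif densities must be >= 0")

    def fold(self, gene_id: str) -> float:
        return self.planted_fold if gene_id in self.enriched_genes else 1.0

    def densities(self, gene_id: str) -> dict:
        return (
            self.motif_density_target
            if gene_id in self.enriched_genes
            else self.motif_density_background
        )

    def to_json(self) -> str:
        d = asdict(self)
        d["enriched_genes"] = sorted(self.enriched_genes)
        return json.dumps(d, indent=1, sort_keys=True)


def gene_ids(n_genes: int) -> list[str]:
    return [f"g{i:05d}" for i in range(n_genes)]


def make_truth(n_genes: int, seed: int, enriched_frac: float = 0.05, **overrides) -> SyntheticTruth:
    """Build a truth object with a randomly chosen enriched gene subset."""
    rng = np.random.default_rng([seed, 0])
    genes = gene_ids(n_genes)
    k = int(round(enriched_frac * n_genes))
    enriched = frozenset(rng.choice(genes, size=k, replace=False)) if k else frozenset()
    return SyntheticTruth(seed=seed, n_genes=n_genes, enriched_genes=enriched, **overrides)


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _plant_motif(
    rng: np.random.Generator, seq: np.ndarray, motif: str, density_per_kb: float
) -> list[int]:
    """Overwrite Poisson-many non-overlapping motif copies into ``seq``."""
    if density_per_kb <= 0:
        return []
    L = seq.size
    mlen = len(motif)
    if L < mlen:
        raise GenerationError(
            f"feature of length {L} cannot carry a {mlen}-mer motif at density > 0"
        )
    n = rng.poisson(density_per_kb * L / 1000.0)
    placed: list[int] = []
    arr = np.frombuffer(motif.encode(), dtype=np.uint8)
    for _ in range(n):
        for _attempt in range(50):
            pos = int(rng.integers(0, L - mlen + 1))
            if all(abs(pos - q) >= mlen for q in placed):
                seq[pos:pos + mlen] = arr
                placed.append(pos)
                break
    return sorted(placed)


def _lognormal_length(rng, median: float, log_sd: float, lo: int, hi: int = 50_000) -> int:
    return int(np.clip(round(rng.lognormal(np.log(median), log_sd)), lo, hi))


def gen_annotation(
    n_genes: int,
    truth: SyntheticTruth,
    motif: str = "CTCCTCCTCCTCC",
    max_transcripts: int = 3,
):
    """Generate transcript models, a genome store, and planted motif positions.

    Each gene sits on its own chromosome and carries 1-``max_transcripts``
    transcripts, each with at least one intron and non-empty UTRs so all
    transcripts pass the completeness filter. Feature lengths are
    log-normal with configurable medians; motif copies are planted as a
    Poisson process at the per-segment density of the gene's class
    (enriched vs background); the remaining sequence is i.i.d. uniform
    A/C/G/T. Returns ``(models, genome, planted)`` where ``genome`` maps
    chromosome name to sequence string and ``planted`` lists realized
    insertion sites per (transcript, segment).
    """
    if n_genes < 2:
        raise GenerationError("need at least 2 genes")
    if truth.min_feature_length < len(motif) and any(
        v > 0
        for d in (truth.motif_density_background, truth.motif_density_target)
        for v in d.values()
    ):
        raise GenerationError(
            f"min_feature_length {truth.min_feature_length} is shorter than the "
            f"{len(motif)}-mer motif while motif density is positive"
        )
    rng = np.random.default_rng([truth.seed, 1])
    lo = truth.min_feature_length
    models: list[TranscriptModel] = []
    genome: dict[str, str] = {}
    planted: list[dict] = []

    for gid in gene_ids(n_genes):
        chrom = f"chr_{gid}"
        enriched = gid in truth.enriched_genes
        dens = truth.densities(gid)
        u5_scale = truth.target_utr5_scale if enriched else 1.0
        u3_scale = truth.target_utr3_scale if enriched else 1.0
        strand = "+" if rng.random() < 0.5 else "-"
        n_tx = int(rng.integers(1, max_transcripts + 1))
        pieces: list[str] = [_bytes_to_str(_random_seq(rng, 25))]
        offset = 25
        for k in range(n_tx):
            tid = f"{gid}.t{k + 1}"
            seg_lengths = {
                "utr5": _lognormal_length(rng, truth.utr5_median * u5_scale, truth.length_log_sd, lo),
                "cds": 3 * max(_lognormal_length(rng, truth.cds_median, 0.6, 120) // 3, lo),
                "utr3": _lognormal_length(rng, truth.utr3_median * u3_scale, truth.length_log_sd, lo),
            }
            segs: dict[str, np.ndarray] = {
                name: _random_seq(rng, seg_lengths[name]) for name in ("utr5", "cds", "utr3")
            }
            n_introns = int(rng.integers(1, 4))
            introns = [
                _random_seq(rng, _lognormal_length(rng, truth.intron_median, truth.length_log_sd, lo))
                for _ in range(n_introns)
            ]
            for name in ("utr5", "cds", "utr3"):
                pos = _plant_motif(rng, segs[name], motif, dens.get(name, 0.0))
                if pos:
                    planted.append({"transcript_id": tid, "segment": name, "positions": pos})
            ipos_all = []
            for j, iseq in enumerate(introns):
                pos = _plant_motif(rng, iseq, motif, dens.get("intron", 0.0))
                ipos_all.extend(pos)
            if ipos_all:
                planted.append({"transcript_id": tid, "segment": "intron", "positions": ipos_all})

            spliced = np.concatenate([segs["utr5"], segs["cds"], segs["utr3"]])
            slen = spliced.size
            cuts = sorted(rng.choice(np.arange(1, slen), size=n_introns, replace=False).tolist())
            # assemble genomic segment (transcript orientation) and exon map
            parts: list[np.ndarray] = []
            exon_bounds: list[tuple[int, int]] = []
            gpos = 0
            prev = 0
            for cut, iseq in zip(cuts, introns):
                parts.append(spliced[prev:cut])
                exon_bounds.append((gpos, gpos + (cut - prev)))
                gpos += cut - prev
                parts.append(iseq)
                gpos += iseq.size
                prev = cut
            parts.append(spliced[prev:])
            exon_bounds.append((gpos, gpos + (slen - prev)))
            gpos += slen - prev
            segment = np.concatenate(parts)

            def to_genomic(spliced_idx: int, is_end: bool) -> int:
                shift = sum(
                    introns[i].size
                    for i, c in enumerate(cuts)
                    if (c < spliced_idx if is_end else c <= spliced_idx)
                )
                return spliced_idx + shift

            cds_lo = to_genomic(seg_lengths["utr5"], is_end=False)
            cds_hi = to_genomic(seg_lengths["utr5"] + seg_lengths["cds"], is_end=True)
            L = segment.size
            if strand == "-":
                segment = np.frombuffer(
                    reverse_complement(_bytes_to_str(segment)).encode(), dtype=np.uint8
                )
                exon_bounds = [(L - e, L - s) for s, e in exon_bounds]
                cds_lo, cds_hi = L - cds_hi, L - cds_lo
            exons = [
                GenomicInterval(chrom, offset + s, offset + e, strand)
                for s, e in sorted(exon_bounds)
            ]
            models.append(
                TranscriptModel(
                    transcript_id=tid,
                    gene_id=gid,
                    chrom=chrom,
                    strand=strand,
                    exons=exons,
                    cds_start=offset + cds_lo,
                    cds_end=offset + cds_hi,
                )
            )
            pieces.append(_bytes_to_str(segment))
            pieces.append(_bytes_to_str(_random_seq(rng, 25)))
            offset += L + 25
        genome[chrom] = "".join(pieces)
    return models, genome, planted


def _bytes_to_str(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def baseline_abundances(truth: SyntheticTruth) -> pd.Series:
    """Per-gene baseline abundance lambda, shared by counts and qPCR."""
    rng = np.random.default_rng([truth.seed, 10])
    lam = rng.lognormal(np.log(5.0), truth.abundance_log_sd, truth.n_genes)
    return pd.Series(lam, index=gene_ids(truth.n_genes), name="lambda")


def gen_counts(genes: list[str], truth: SyntheticTruth, n_rep: int = 3) -> pd.DataFrame:
    """NB count matrix for IP / input / IgG libraries, ``n_rep`` each.

    Expected counts are s_role * beta_role * lambda_g * F_g with
    F_g = planted fold for enriched genes in the IP and 1 otherwise, and
    beta_role the background capture rate for the pulldown roles. The
    per-sample scale s is set from the background composition so each
    library's expected total matches its configured size (IP totals exceed
    it by the planted enrichment mass), which makes the expected per-gene
    IP/IgG count ratio exactly the planted fold.
    """
    if n_rep < 1:
        raise GenerationError("need at least one replicate")
    rng = np.random.default_rng([truth.seed, 2])
    lam = baseline_abundances(truth).loc[genes].to_numpy()
    fold = np.array([truth.fold(g) for g in genes])
    beta = {"IP": truth.background_rate, "input": 1.0, "IgG": truth.background_rate}
    alpha = truth.nb_dispersion
    cols = {}
    for role in ROLES:
        depth = float(truth.library_sizes[role])
        s = depth / (beta[role] * lam.sum())
        mean = s * beta[role] * lam * (fold if role == "IP" else 1.0)
        for rep in range(1, n_rep + 1):
            if alpha < 1e-8:
                draw = rng.poisson(mean)
            else:
                draw = rng.poisson(rng.gamma(1.0 / alpha, alpha * mean))
            cols[f"{role}_{rep}"] = draw
    return pd.DataFrame(cols, index=pd.Index(genes, name="gene_id"))


def gen_qpcr(
    selection: list[str],
    truth: SyntheticTruth,
    ae: float | dict = 2.0,
    noise_sd: float = 0.3,
    n_tech: int = 3,
) -> pd.DataFrame:
    """qPCR Ct table (long format) consistent with the count-matrix truth.

    Ct = C0 - log_AE(relative abundance) + gaussian noise, in technical
    ``n_tech``-plicate for the IP, input and IgG roles. Abundances reuse
    the baseline lambdas of :func:`gen_counts`: input carries lambda, the
    pulldowns beta*lambda (times the planted fold in the IP), so the
    AE-corrected IP/input recovery equals beta*F on average.
    """
    rng = np.random.default_rng([truth.seed, 3])
    lam_all = baseline_abundances(truth)
    lam_ref = float(lam_all.median())
    rows = []
    for gid in selection:
        gene_ae = ae[gid] if isinstance(ae, dict) else float(ae)
        if not (1.0 < gene_ae <= 2.0):
            raise GenerationError(f"amplification efficiency must be in (1, 2], got {gene_ae}")
        lam = float(lam_all.loc[gid]) if gid in lam_all.index else lam_ref
        abundance = {
            "input": lam / lam_ref,
            "IP": truth.background_rate * truth.fold(gid) * lam / lam_ref,
            "IgG": truth.background_rate * lam / lam_ref,
        }
        for role in ROLES:
            base_ct = 22.0 - np.log(abundance[role]) / np.log(gene_ae)
            for rep in range(1, n_tech + 1):
                ct = base_ct + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
                rows.append(
                    {"gene_id": gid, "role": role, "replicate": rep,
                     "ct": round(float(ct), 4), "ae": gene_ae}
                )
    return pd.DataFrame(rows)
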