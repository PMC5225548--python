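"""Target-set characterization: poly(C) motif enrichment and UTR lengths.

Motif occurrences are exact substring matches of two literal nucleotide
strings (a cytosine-rich element and its printed reverse-form companion),
counted overlapping by default, and normalized to transcript length. A
target ("enriched") set is compared against random transcript sets drawn
from the transcriptome universe with a one-sided two-sample KS test per
feature, BH-adjusted across the random comparisons within each feature.
UTR lengths of targets are compared against the transcriptome-wide
reference with a one-sided Wilcoxon test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .annotation import FEATURES, FeatureSequences, reverse_complement
from .stats import TestResult, bh_adjust, ks_one_sided, wilcoxon_rank_sum, wilcoxon_signed_rank

DEFAULT_MOTIF_FORWARD = "CTCCTCCTCCTCC"
# the companion string searched alongside the forward motif; note this is
# the string conventionally reported with the element, not the literal
# mathematical reverse complement (see MotifSpec.strict)
DEFAULT_MOTIF_REVERSE = "GAGGAGGAGGAGG"

_DNA = set("ACGT")


@dataclass(frozen=True)
class MotifSpec:
    """Two literal motif strings and the overlap-counting mode.

    With ``strict_rc`` the reverse string is replaced by the mathematical
    reverse complement of ``forward`` (for the default poly(C) element,
    GGAGGAGGAGGAG rather than the conventionally quoted GAGGAGGAGGAGG).
    """

    forward: str = DEFAULT_MOTIF_FORWARD
    reverse: str = DEFAULT_MOTIF_REVERSE
    overlap_mode: str = "overlapping"
    strict_rc: bool = False

    def __post_init__(self) -> None:
        for s in (self.forward, self.reverse):
            if not s or set(s) - _DNA:
                raise ValueError(f"motif must be a non-empty A/C/G/T string, got {s!r}")
        if self.overlap_mode not in ("overlapping", "non-overlapping"):
            raise ValueError(f"unknown overlap_mode {self.overlap_mode!r}")

    @property
    def patterns(self) -> tuple[str, str]:
        rev = reverse_complement(self.forward) if self.strict_rc else self.reverse
        return (self.forward, rev)


def count_motif(seq: str, spec: MotifSpec) -> int:
    """Exact-match occurrences of either motif string in ``seq``.

    In overlapping mode every start position matching either pattern is
    counted. In non-overlapping mode a greedy left-to-right scan consumes
    each match, so occurrences sharing bases are counted once. Characters
    outside A/C/G/T never match.
    """
    pats = [p for p in set(spec.patterns)]
    if spec.overlap_mode == "overlapping":
        total = 0
        for pat in pats:
            i = seq.find(pat)
            while i != -1:
                total += 1
                i = seq.find(pat, i + 1)
        return total
    # greedy non-overlapping over the union of both patterns
    total = 0
    i = 0
    n = len(seq)
    minlen = min(len(p) for p in pats)
    while i <= n - minlen:
        matched = 0
        for pat in pats:
            if seq.startswith(pat, i):
                matched = len(pat)
                break
        if matched:
            total += 1
            i += matched
        else:
            i += 1
    return total


def motif_frequency(
    feats: FeatureSequences,
    spec: MotifSpec,
    normalization: str = "transcript_length",
) -> dict:
    """Per-feature motif counts and length-normalized frequencies.

    Frequencies divide the match count by the transcript length (default)
    or by the individual feature length. A zero normalization length is an
    error (complete transcripts never hit it).
    """
    if normalization not in ("transcript_length", "feature_length"):
        raise ValueError(f"unknown normalization {normalization!r}")
    row: dict = {"transcript_id": feats.transcript_id, "gene_id": feats.gene_id}
    tlen = feats.transcript_length
    for name in FEATURES:
        seq = feats.feature(name)
        cnt = count_motif(seq, spec)
        denom = tlen if normalization == "transcript_length" else len(seq)
        if denom == 0:
            raise ValueError(
                f"transcript {feats.transcript_id}: zero {normalization} for feature {name}"
            )
        row[f"{name}_count"] = cnt
        row[f"{name}_freq"] = cnt / denom
    return row


def motif_profiles(
    features: Iterable[FeatureSequences],
    spec: MotifSpec | None = None,
    normalization: str = "transcript_length",
) -> pd.DataFrame:
    """MotifProfile table (one row per transcript) for a feature collection."""
    spec = spec or MotifSpec()
    return pd.DataFrame([motif_frequency(f, spec, normalization) for f in features])


def random_sets(
    universe: Sequence[str],
    set_size: int,
    n_sets: int,
    seed: int,
) -> list[np.ndarray]:
    """Draw ``n_sets`` uniform without-replacement transcript-id samples."""
    universe = np.asarray(universe)
    if set_size > universe.size:
        raise ValueError(f"set_size {set_size} exceeds universe size {universe.size}")
    if n_sets < 1:
        raise ValueError("need at least one random set")
    rng = np.random.default_rng(seed)
    return [rng.choice(universe, size=set_size, replace=False) for _ in range(n_sets)]


class MotifEnrichment:
    """Motif-frequency enrichment of a target transcript set vs random sets.

    For each of the four transcript features, the frequency distribution of
    the target ("enriched") set is tested against ``n_sets`` random
    transcript sets of the same size drawn from the universe, using the
    one-sided KS test (alternative: target frequencies greater). P-values
    are BH-adjusted across the random comparisons within each feature.

    Parameters
    ----------
    enriched_profiles, universe_profiles : DataFrame
        Motif profile tables from :func:`motif_profiles`, computed with the
        same motif spec and normalization.
    n_sets : int
        Number of random comparison sets (default 100).
    set_size : int, optional
        Random-set size; defaults to the enriched set's size.
    """

    def __init__(
        self,
        enriched_profiles: pd.DataFrame,
        universe_profiles: pd.DataFrame,
        n_sets: int = 100,
        set_size: int | None = None,
    ):
        self.enriched = enriched_profiles
        self.universe = universe_profiles
        self.n_sets = n_sets
        self.set_size = set_size if set_size is not None else len(enriched_profiles)

    def fit(self, seed: int) -> "MotifEnrichmentResults":
        sets = random_sets(
            self.universe["transcript_id"].to_numpy(), self.set_size, self.n_sets, seed
        )
        uni = self.universe.set_index("transcript_id")
        rows = []
        for feat in FEATURES:
            col = f"{feat}_freq"
            enriched_vals = self.enriched[col].to_numpy()
            pvals, dstats = [], []
            for s in sets:
                res = ks_one_sided(enriched_vals, uni.loc[s, col].to_numpy())
                pvals.append(res.p_value)
                dstats.append(res.statistic)
            adj = bh_adjust(pvals)
            for i, (d, p, q) in enumerate(zip(dstats, pvals, adj), start=1):
                rows.append(
                    {"feature": feat, "set_index": i, "d_statistic": d, "p_value": p, "adj_p": q}
                )
        return MotifEnrichmentResults(pd.DataFrame(rows), self.n_sets, seed)


@dataclass
class MotifEnrichmentResults:
    """Per-feature random-set KS comparisons and their BH-adjusted summary."""

    comparisons: pd.DataFrame
    n_sets: int
    seed: int
    alpha: float = 0.05

    @property
    def summary_table(self) -> pd.DataFrame:
        g = self.comparisons.groupby("feature", sort=False)
        return pd.DataFrame(
            {
                "mean_adj_p": g["adj_p"].mean(),
                "n_significant": g["adj_p"].apply(lambda q: int((q < self.alpha).sum())),
                "n_comparisons": g.size(),
                "mean_d": g["d_statistic"].mean(),
            }
        ).reset_index()

    def summary(self) -> str:
        lines = [
            "Motif-frequency enrichment vs %d random transcript sets" % self.n_sets,
            "(one-sided KS, BH-adjusted within feature; seed=%d)" % self.seed,
            "",
            self.summary_table.to_string(index=False, float_format=lambda v: f"{v:.3g}"),
        ]
        return "\n".join(lines)


class UtrLengthComparison:
    """One-sided comparison of target UTR lengths against a reference.

    Tests whether target transcripts carry longer 5' or 3' UTRs than the
    transcriptome-wide reference ("UTRome"), with either the two-sample
    Wilcoxon rank-sum test (default) or the one-sample signed-rank test of
    the targets against the reference median.
    """

    def __init__(
        self,
        target_lengths,
        reference_lengths,
        which: str = "utr3",
        test: str = "rank_sum",
    ):
        if which not in ("utr5", "utr3"):
            raise ValueError("which must be 'utr5' or 'utr3'")
        if test not in ("rank_sum", "signed_rank"):
            raise ValueError("test must be 'rank_sum' or 'signed_rank'")
        self.target = np.asarray(target_lengths, dtype=float)
        self.reference = np.asarray(reference_lengths, dtype=float)
        if self.target.size == 0 or self.reference.size == 0:
            raise ValueError("both length collections must be non-empty")
        self.which = which
        self.test = test

    def fit(self) -> "UtrLengthResults":
        if self.test == "rank_sum":
            res = wilcoxon_rank_sum(self.target, self.reference, alternative="greater")
        else:
            res = wilcoxon_signed_rank(
                self.target, float(np.median(self.reference)), alternative="greater"
            )
        return UtrLengthResults(
            which=self.which,
            test=res,
            target_median=float(np.median(self.target)),
            target_mean=float(np.mean(self.target)),
            reference_median=float(np.median(self.reference)),
            reference_mean=float(np.mean(self.reference)),
            n_target=self.target.size,
            n_reference=self.reference.size,
        )


@dataclass
class UtrLengthResults:
    which: str
    test: TestResult
    target_median: float
    target_mean: float
    reference_median: float
    reference_mean: float
    n_target: int
    n_reference: int

    def to_dict(self) -> dict:
        return {
            "feature": self.which,
            "n_target": self.n_target,
            "n_reference": self.n_reference,
            "target_median": self.target_median,
            "target_mean": self.target_mean,
            "reference_median": self.reference_median,
            "reference_mean": self.reference_mean,
            "test": self.test.method,
            "p_value": self.test.p_value,
        }

    def summary(self) -> str:
        return (
            f"{self.which} length: targets (n={self.n_target}) median "
            f"{self.target_median:.0f} vs reference (n={self.n_reference}) median "
            f"{self.reference_median:.0f}; one-sided {self.test.method} p = "
            f"{self.test.p_value:.3g}"
        )
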