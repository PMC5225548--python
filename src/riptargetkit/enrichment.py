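"""RIP-seq target identification: IgG-normalized enrichment model.

:class:`RipEnrichment` is fitted to a gene x sample count matrix holding
triplicate IP, input and IgG libraries. Per replicate, the fold enrichment
of a gene is the IP/input ratio normalized to the IgG/input ratio on
size-factor-normalized counts; significance comes from a per-gene
negative-binomial Wald test of the IP pulldown against the IgG background,
BH-adjusted across genes. A gene is called a target when its mean fold
across replicates reaches the fold cutoff (default >= 2) and its adjusted
p-value the significance level (default <= 0.05).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats as _st

ROLES = ("IP", "input", "IgG")
_SAMPLE_RE = re.compile(r"^(IP|input|IgG)_(\d+)$")


class CountMatrixError(ValueError):
    pass


@dataclass
class CountMatrix:
    """Gene x sample integer counts with IP/input/IgG roles and replicates.

    Columns are named ``<role>_<replicate>`` (IP_1, input_2, IgG_3, ...);
    each role must be present and replicate indices unique within a role.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        vals = df.to_numpy()
        if not np.issubdtype(vals.dtype, np.number) or np.any(vals < 0):
            raise CountMatrixError("counts must be non-negative numbers")
        if np.any(vals != np.floor(vals)):
            raise CountMatrixError("counts must be integral")
        seen: dict[str, set[int]] = {r: set() for r in ROLES}
        for col in df.columns:
            m = _SAMPLE_RE.match(str(col))
            if not m:
                raise CountMatrixError(
                    f"sample column {col!r} does not follow '<role>_<replicate>'"
                )
            role, rep = m.group(1), int(m.group(2))
            if rep in seen[role]:
                raise CountMatrixError(f"duplicate replicate {col!r}")
            seen[role].add(rep)
        for role in ROLES:
            if not seen[role]:
                raise CountMatrixError(f"role {role!r} has no samples")

    @classmethod
    def from_tsv(cls, path) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index.name = "gene_id"
        return cls(df)

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    def role_columns(self, role: str) -> list[str]:
        cols = [c for c in self.counts.columns if str(c).startswith(f"{role}_")]
        return sorted(cols, key=lambda c: int(str(c).split("_")[1]))

    def replicates(self, role: str) -> list[int]:
        return [int(str(c).split("_")[1]) for c in self.role_columns(role)]

    def size_factors(self) -> pd.Series:
        sf = _st.size_factors(self.counts.to_numpy())
        return pd.Series(sf, index=self.counts.columns, name="size_factor")

    def normalized(self, sf: pd.Series | None = None) -> pd.DataFrame:
        sf = self.size_factors() if sf is None else sf
        return self.counts / sf


def enrichment_scores(
    counts: CountMatrix, pseudocount: float = 0.5, sf: pd.Series | None = None
) -> pd.DataFrame:
    """Per-gene, per-replicate IgG-normalized fold enrichment.

    fold_i = [(IP_i' + c)/(input_i' + c)] / [(IgG_i' + c)/(input_i' + c)]
    on size-factor-normalized counts, plus the across-replicate mean.
    Replicates are paired by index across the three roles.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    reps = {role: set(counts.replicates(role)) for role in ROLES}
    if not (reps["IP"] == reps["input"] == reps["IgG"]):
        raise CountMatrixError(
            f"replicate indices differ across roles: {sorted(reps['IP'])} / "
            f"{sorted(reps['input'])} / {sorted(reps['IgG'])}"
        )
    norm = counts.normalized(sf)
    c = pseudocount
    out = pd.DataFrame(index=counts.genes)
    for i in sorted(reps["IP"]):
        ip = norm[f"IP_{i}"] + c
        inp = norm[f"input_{i}"] + c
        igg = norm[f"IgG_{i}"] + c
        out[f"fold_{i}"] = (ip / inp) / (igg / inp)
    out["mean_fold"] = out.mean(axis=1)
    return out


def call_targets(
    scores: pd.DataFrame,
    p_values,
    testable=None,
    fold_cutoff: float = 2.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Selection rule: mean fold >= cutoff AND BH-adjusted p <= alpha.

    ``scores`` carries at least ``mean_fold`` indexed by gene; BH runs over
    the testable genes (untestable ones get adj_p 1). Both boundaries are
    inclusive. The returned table is sorted by mean fold descending with
    ties broken by adjusted p then gene id, and carries rank (1-based) and,
    over the selected genes, the quartile (4 = top 25%).
    """
    table = scores.copy()
    table["log2_mean_fold"] = np.log2(table["mean_fold"])
    table["p_value"] = np.asarray(p_values, dtype=float)
    table["testable"] = (
        np.ones(len(table), dtype=bool) if testable is None else np.asarray(testable)
    )
    adj = np.full(len(table), 1.0)
    mask = table["testable"].to_numpy()
    if mask.any():
        adj[mask] = _st.bh_adjust(table.loc[mask, "p_value"].to_numpy())
    table["adj_p"] = adj
    table["selected"] = (table["mean_fold"] >= fold_cutoff) & (table["adj_p"] <= alpha)
    table.index.name = "gene_id"
    table = (
        table.reset_index()
        .sort_values(
            by=["mean_fold", "adj_p", "gene_id"],
            ascending=[False, True, True],
            kind="mergesort",
        )
        .set_index("gene_id")
    )
    table["rank"] = np.arange(1, len(table) + 1)
    sel_rank = table.loc[table["selected"], "rank"].rank(method="first").astype(int)
    quart = pd.Series(pd.NA, index=table.index, dtype="Int64")
    if len(sel_rank):
        quart.loc[sel_rank.index] = assign_quartiles(sel_rank)
    table["quartile"] = quart
    return table


def assign_quartiles(ranked: pd.Series) -> pd.Series:
    """Quartiles from a 1-based rank over a fold-sorted table.

    Quartile 4 is the top 25% (ceiling size when the count is not
    divisible by four), quartile 1 the remainder at the bottom.
    """
    n = ranked.size
    qsize = -(-n // 4)  # ceil
    return (4 - (ranked - 1) // qsize).clip(lower=1).astype(int)


class RipEnrichment:
    """Per-gene NB enrichment model of a RIP-seq count matrix.

    Parameters
    ----------
    counts : CountMatrix
    fold_cutoff : float
        Minimum mean fold enrichment for target selection (default 2).
    alpha : float
        BH-adjusted p-value ceiling for selection (default 0.05).
    pseudocount : float
        Added to normalized counts before fold ratios (default 0.5).
    dispersion : float, optional
        Fixed NB dispersion; estimated from the replicates when omitted.
    """

    def __init__(
        self,
        counts: CountMatrix,
        fold_cutoff: float = 2.0,
        alpha: float = 0.05,
        pseudocount: float = 0.5,
        dispersion: float | None = None,
    ):
        self.counts = counts
        self.fold_cutoff = fold_cutoff
        self.alpha = alpha
        self.pseudocount = pseudocount
        self.dispersion = dispersion

    @classmethod
    def from_tsv(cls, path, **kwargs) -> "RipEnrichment":
        return cls(CountMatrix.from_tsv(path), **kwargs)

    def fit(self) -> "RipEnrichmentResults":
        cm = self.counts
        sf = cm.size_factors()
        scores = enrichment_scores(cm, self.pseudocount, sf)
        ip_cols = cm.role_columns("IP")
        igg_cols = cm.role_columns("IgG")
        wald = _st.nb_wald_matrix(
            cm.counts[ip_cols].to_numpy(),
            cm.counts[igg_cols].to_numpy(),
            sf[ip_cols].to_numpy(),
            sf[igg_cols].to_numpy(),
            dispersion=self.dispersion,
            pseudocount=self.pseudocount,
        )
        table = call_targets(
            scores,
            wald["p_value"],
            testable=wald["testable"],
            fold_cutoff=self.fold_cutoff,
            alpha=self.alpha,
        )
        input_cols = cm.role_columns("input")
        mean_input = cm.normalized(sf)[input_cols].mean(axis=1)
        return RipEnrichmentResults(
            table=table,
            fold_cutoff=self.fold_cutoff,
            alpha=self.alpha,
            size_factors_=sf,
            mean_normalized_input=mean_input,
        )


@dataclass
class RipEnrichmentResults:
    """Ranked enrichment table with selection flags and quartiles.

    ``table`` rows are sorted by mean fold (descending; ties by adjusted p
    then gene id) and carry per-replicate folds, mean/log2 fold, Wald p,
    BH-adjusted p, rank, selection flag and (for selected genes) the
    quartile within the selected set, quartile 4 being the top 25%.
    """

    table: pd.DataFrame
    fold_cutoff: float
    alpha: float
    size_factors_: pd.Series
    mean_normalized_input: pd.Series

    @property
    def selected(self) -> pd.DataFrame:
        return self.table[self.table["selected"]]

    def quartile4(self) -> pd.DataFrame:
        """Top-25% quartile of the selected (identified) genes."""
        return self.table[self.table["quartile"] == 4]

    def top_bottom(self, k: int = 10, subset: pd.DataFrame | None = None) -> pd.DataFrame:
        """First and last ``k`` rows of a rank-sorted subset (default Q4)."""
        sub = self.quartile4() if subset is None else subset
        if len(sub) < 2 * k:
            raise ValueError(f"subset of {len(sub)} rows cannot yield top+bottom {k}")
        return pd.concat([sub.head(k), sub.tail(k)])

    def high_low_sets(self, n_high: int = 50, n_low: int = 50) -> pd.DataFrame:
        """Most and least enriched selected genes, labeled high/low."""
        sel = self.selected
        if len(sel) < n_high + n_low:
            raise ValueError(
                f"only {len(sel)} selected genes; cannot take {n_high} high + {n_low} low"
            )
        high = sel.head(n_high).copy()
        high["set"] = "high"
        low = sel.tail(n_low).copy()
        low["set"] = "low"
        return pd.concat([high, low])

    def input_expressed_fraction(self, min_mean_normalized: float = 1.0) -> float:
        """Selected genes as a fraction of input-expressed genes."""
        expressed = self.mean_normalized_input >= min_mean_normalized
        if expressed.sum() == 0:
            return float("nan")
        sel = self.table["selected"].reindex(self.mean_normalized_input.index)
        return float((sel & expressed).sum() / expressed.sum())

    def summary(self) -> str:
        n = len(self.table)
        nsel = int(self.table["selected"].sum())
        frac = self.input_expressed_fraction()
        lines = [
            "RIP enrichment (NB Wald IP vs IgG; fold = IP/input normalized to IgG/input)",
            f"genes tested: {n}; targets (mean fold >= {self.fold_cutoff:g} and "
            f"BH-adjusted p <= {self.alpha:g}): {nsel}",
            f"targets as fraction of input-expressed genes: {100 * frac:.1f}%",
            "",
            "top of ranked table:",
            self.table.head(10).to_string(float_format=lambda v: f"{v:.3g}"),
        ]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t")
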