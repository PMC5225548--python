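"""Amplification-efficiency-corrected qPCR enrichment and percent input.

Technical-triplicate Ct values per gene and role (IP, input, IgG) are
averaged; the input-referenced recoveries are AE^-(Ct_IP - Ct_input) and
AE^-(Ct_IgG - Ct_input) with AE the primer pair's per-cycle amplification
efficiency (2 = perfect doubling); the IgG-normalized enrichment is their
ratio. Recoveries times 100 are the conventional percent-input values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import pearson

ROLES = ("IP", "input", "IgG")


class QpcrError(ValueError):
    pass


@dataclass
class QpcrMeasurement:
    """Ct technical replicates for one gene in one sample role."""

    gene_id: str
    role: str
    ct_values: tuple
    ae: float

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise QpcrError(f"unknown role {self.role!r}")
        if not self.ct_values or any(c <= 0 for c in self.ct_values):
            raise QpcrError(f"{self.gene_id}/{self.role}: Ct values must be positive")
        if not (1.0 < self.ae <= 2.0):
            raise QpcrError(f"{self.gene_id}: amplification efficiency must be in (1, 2]")

    @property
    def mean_ct(self) -> float:
        return float(np.mean(self.ct_values))

    @property
    def sd_ct(self) -> float:
        return float(np.std(self.ct_values, ddof=1)) if len(self.ct_values) > 1 else 0.0


def ae_corrected_enrichment(
    m_ip: QpcrMeasurement, m_input: QpcrMeasurement, m_igg: QpcrMeasurement
) -> tuple[float, float, float]:
    """(ip_value, igg_value, normalized_value) from mean Ct differences.

    ip_value = AE^-(Ct_IP - Ct_input), igg_value likewise for the mock
    pulldown, and normalized_value = ip_value / igg_value (the
    IgG-normalized enrichment). Measurements must share gene and AE.
    """
    if not (m_ip.gene_id == m_input.gene_id == m_igg.gene_id):
        raise QpcrError("measurements pair different genes")
    if not (m_ip.ae == m_input.ae == m_igg.ae):
        raise QpcrError(f"{m_ip.gene_id}: amplification efficiencies differ across roles")
    ae = m_ip.ae
    ip_value = ae ** -(m_ip.mean_ct - m_input.mean_ct)
    igg_value = ae ** -(m_igg.mean_ct - m_input.mean_ct)
    return ip_value, igg_value, ip_value / igg_value


def percent_input(value: float) -> float:
    """Recovery fraction of input expressed as a percentage."""
    if value < 0:
        raise QpcrError(f"recovery must be >= 0, got {value}")
    return 100.0 * value


class QpcrValidation:
    """AE-corrected enrichment over a long-format qPCR Ct table.

    The table needs columns gene_id, role, replicate, ct, ae; each gene
    must carry all three roles with one AE. ``fit`` reduces technical
    replicates to mean Ct and reports, per gene, the input-referenced IP
    and IgG recoveries, the IgG-normalized enrichment, and percent-input
    values (both raw and IgG-corrected).
    """

    REQUIRED = ("gene_id", "role", "replicate", "ct", "ae")

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in table.columns]
        if missing:
            raise QpcrError(f"qPCR table lacks columns {missing}")
        self.table = table

    @classmethod
    def from_tsv(cls, path) -> "QpcrValidation":
        return cls(pd.read_csv(path, sep="\t"))

    def measurements(self) -> dict[str, dict[str, QpcrMeasurement]]:
        out: dict[str, dict[str, QpcrMeasurement]] = {}
        for (gid, role), grp in self.table.groupby(["gene_id", "role"], sort=False):
            ae_vals = grp["ae"].unique()
            if ae_vals.size != 1:
                raise QpcrError(f"{gid}/{role}: inconsistent amplification efficiency")
            out.setdefault(gid, {})[role] = QpcrMeasurement(
                gene_id=gid,
                role=role,
                ct_values=tuple(grp["ct"].astype(float)),
                ae=float(ae_vals[0]),
            )
        return out

    def fit(self) -> "QpcrResults":
        rows = []
        for gid, roles in self.measurements().items():
            missing = [r for r in ROLES if r not in roles]
            if missing:
                raise QpcrError(f"gene {gid} lacks roles {missing}")
            ip_v, igg_v, norm_v = ae_corrected_enrichment(
                roles["IP"], roles["input"], roles["IgG"]
            )
            rows.append(
                {
                    "gene_id": gid,
                    "ae": roles["IP"].ae,
                    "ct_ip": roles["IP"].mean_ct,
                    "ct_input": roles["input"].mean_ct,
                    "ct_igg": roles["IgG"].mean_ct,
                    "ct_sd_ip": roles["IP"].sd_ct,
                    "ip_value": ip_v,
                    "igg_value": igg_v,
                    "normalized_value": norm_v,
                    "percent_input": percent_input(ip_v),
                    "percent_input_igg_corrected": percent_input(norm_v),
                }
            )
        return QpcrResults(pd.DataFrame(rows).set_index("gene_id"))


@dataclass
class QpcrResults:
    table: pd.DataFrame

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t")

    def summary(self) -> str:
        return (
            "qPCR AE-corrected enrichment (IP and IgG referenced to input)\n"
            + self.table[
                ["ip_value", "igg_value", "normalized_value", "percent_input"]
            ].head(10).to_string(float_format=lambda v: f"{v:.4g}")
        )

    def correlate_with_sequencing(
        self, enrichment_table: pd.DataFrame, pseudo: float = 1e-12
    ) -> "CrossPlatformResult":
        """Pearson correlation of log2 qPCR vs sequencing IP/input enrichment.

        ``enrichment_table`` must carry a per-gene sequencing IP/input
        value in a ``seq_ip_over_input`` column (or ``mean_fold`` as the
        IgG-normalized analogue of ``normalized_value``). Genes absent on
        either platform are dropped and reported.
        """
        if "seq_ip_over_input" in enrichment_table.columns:
            seq = enrichment_table["seq_ip_over_input"]
            q = self.table["ip_value"]
        else:
            seq = enrichment_table["mean_fold"]
            q = self.table["normalized_value"]
        shared = q.index.intersection(seq.index)
        dropped = sorted(set(q.index) - set(seq.index))
        if shared.size < 3:
            raise QpcrError(f"only {shared.size} genes shared between platforms (need >= 3)")
        x = np.log2(q.loc[shared].to_numpy() + pseudo)
        y = np.log2(seq.loc[shared].to_numpy() + pseudo)
        paired = pd.DataFrame(
            {"log2_qpcr": x, "log2_seq": y}, index=pd.Index(shared, name="gene_id")
        )
        return CrossPlatformResult(pearson(x, y), paired, dropped)


@dataclass
class CrossPlatformResult:
    pcc: float
    paired: pd.DataFrame
    dropped_genes: list

    def summary(self) -> str:
        return (
            f"qPCR vs sequencing enrichment: Pearson r = {self.pcc:.3f} over "
            f"{len(self.paired)} genes ({len(self.dropped_genes)} present on one platform only)"
        )
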