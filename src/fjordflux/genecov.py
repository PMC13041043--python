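"""Gene coverage and Average Genomic Copy Number (ACN) normalization.

Per-sample per-gene mapped-read counts are turned into coverage
(reads per bp of gene) and normalized against the mean coverage of three
single-copy reference genes (recA, gyrB, rpoB), yielding a
sequencing-depth-invariant "copies per genome equivalent" for each
nitrogen-cycle gene, grouped into process categories for display.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "GenePanel",
    "default_panel",
    "gene_coverage",
    "normalize_acn",
    "aggregate_process",
]


@dataclass(frozen=True)
class GenePanel:
    """gene symbol -> nitrogen-cycle process map, plus reference genes.

    Matching is case-insensitive exact; reference genes may not appear in
    the process map.
    """

    process_of: dict[str, str]
    references: tuple[str, ...] = ("recA", "gyrB", "rpoB")

    def __post_init__(self):
        lower_panel = {g.lower() for g in self.process_of}
        lower_refs = {g.lower() for g in self.references}
        clash = lower_panel & lower_refs
        if clash:
            raise ValueError(f"reference genes inside the process panel: {clash}")

    def process(self, gene: str) -> str | None:
        return self._lower_map().get(gene.lower())

    def is_reference(self, gene: str) -> bool:
        return gene.lower() in {g.lower() for g in self.references}

    def _lower_map(self) -> dict[str, str]:
        return {g.lower(): p for g, p in self.process_of.items()}

    @classmethod
    def from_dict(cls, cfg: dict) -> "GenePanel":
        return cls(process_of=dict(cfg["genes"]),
                   references=tuple(cfg.get("references",
                                            ("recA", "gyrB", "rpoB"))))

    @classmethod
    def from_yaml(cls, path) -> "GenePanel":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_panel() -> GenePanel:
    ref = resources.files("fjordflux").joinpath("data/gene_panel.yaml")
    return GenePanel.from_dict(yaml.safe_load(ref.read_text(encoding="utf-8")))


def gene_coverage(counts: pd.DataFrame, pool: str = "length_weighted"
                  ) -> pd.DataFrame:
    """Coverage = mapped reads / gene length per (sample, gene).

    Multiple contigs carrying the same gene in a sample are pooled as total
    reads over total length (``pool="length_weighted"``, default) or as the
    mean of per-contig coverages (``pool="mean"``).
    """
    required = {"sample_id", "gene_symbol", "mapped_reads", "gene_length_bp"}
    missing = required - set(counts.columns)
    if missing:
        raise ValueError(f"gene count table lacks columns: {sorted(missing)}")
    if (counts["gene_length_bp"] <= 0).any():
        raise ValueError("gene_length_bp must be positive")
    if (counts["mapped_reads"] < 0).any():
        raise ValueError("mapped_reads must be non-negative")
    grouped = counts.groupby(["sample_id", "gene_symbol"], observed=True)
    if pool == "length_weighted":
        agg = grouped[["mapped_reads", "gene_length_bp"]].sum()
        cov = agg["mapped_reads"] / agg["gene_length_bp"]
    elif pool == "mean":
        cov = grouped.apply(
            lambda g: (g["mapped_reads"] / g["gene_length_bp"]).mean(),
            include_groups=False)
    else:
        raise ValueError(f"unknown pooling mode {pool!r}")
    return cov.rename("coverage").reset_index()


def normalize_acn(coverages: pd.DataFrame,
                  panel: GenePanel | None = None) -> pd.DataFrame:
    """ACN = gene coverage / mean coverage of detected reference genes.

    One row per (sample, non-reference gene) with columns coverage, acn,
    process and n_refs (how many reference genes backed the mean).  Samples
    without any positive-coverage reference gene get acn = NaN and
    n_refs = 0.
    """
    panel = default_panel() if panel is None else panel
    rows = []
    for sample, grp in coverages.groupby("sample_id", observed=True):
        is_ref = grp["gene_symbol"].map(panel.is_reference)
        refs = grp[is_ref & (grp["coverage"] > 0)]
        ref_mean = refs["coverage"].mean() if len(refs) else np.nan
        for row in grp[~is_ref].itertuples(index=False):
            acn = row.coverage / ref_mean if len(refs) else np.nan
            rows.append({"sample_id": sample,
                         "gene_symbol": row.gene_symbol,
                         "coverage": row.coverage,
                         "acn": acn,
                         "process": panel.process(row.gene_symbol),
                         "n_refs": len(refs)})
    return pd.DataFrame(rows)


def aggregate_process(acn: pd.DataFrame,
                      panel: GenePanel | None = None) -> pd.DataFrame:
    """Sum gene ACN within each process per sample.

    Genes outside the panel are ignored; their number is reported in the
    ``n_ignored_genes`` attribute of the returned frame (pandas attrs).
    """
    panel = default_panel() if panel is None else panel
    df = acn.copy()
    df["process"] = df["gene_symbol"].map(panel.process)
    ignored = int(df["process"].isna().sum())
    out = (df.dropna(subset=["process"])
             .groupby(["sample_id", "process"], observed=True)["acn"]
             .sum().rename("acn_total").reset_index())
    out.attrs["n_ignored_genes"] = ignored
    return out
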