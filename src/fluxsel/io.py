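"""Tab-separated and YAML interchange for count tables, designs and configs.

Count tables travel as a TSV matrix (rows = genotype, or genotype+tag when
tag-level) with a sidecar design TSV; trajectories as tidy long tables.
Configuration is plain YAML mapping onto :class:`~fluxsel.chemostat.ChemostatParams`
and :class:`~fluxsel.chemostat.FeedSchedule` fields.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .chemostat import ChemostatParams, FeedSchedule
from .synthetic import CountTable

__all__ = [
    "write_counts",
    "read_counts",
    "write_design",
    "read_design",
    "load_config",
]


def write_design(design: pd.DataFrame, path) -> None:
    design.rename_axis("sample_id").to_csv(path, sep="\t")


def read_design(path) -> pd.DataFrame:
    design = pd.read_csv(path, sep="\t", index_col=0).rename_axis("sample_id")
    design["time"] = design["time"].astype(float)
    return design


def write_counts(table: CountTable, counts_path, design_path=None) -> None:
    """Write a count table; the design goes to ``design_path`` (default:
    ``<counts stem>.design.tsv`` next to the counts file)."""
    counts_path = Path(counts_path)
    table.counts.to_csv(counts_path, sep="\t")
    if design_path is None:
        design_path = counts_path.with_suffix("").with_suffix(".design.tsv")
    write_design(table.design, design_path)


def read_counts(counts_path, design_path=None) -> CountTable:
    counts_path = Path(counts_path)
    if design_path is None:
        design_path = counts_path.with_suffix("").with_suffix(".design.tsv")
    head = pd.read_csv(counts_path, sep="\t", nrows=0)
    index_cols = ["genotype_id", "tag"] if "tag" in head.columns else ["genotype_id"]
    counts = pd.read_csv(counts_path, sep="\t", index_col=index_cols)
    design = read_design(design_path).loc[counts.columns].rename_axis("sample_id")
    return CountTable(counts, design)


def load_config(path) -> dict:
    """Load a YAML config into {'params': ChemostatParams, 'schedule': FeedSchedule, ...}.

    Recognized top-level keys: ``params`` (ChemostatParams fields),
    ``schedule`` (FeedSchedule fields); anything else is passed through.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    out = dict(raw)
    if "params" in raw:
        out["params"] = ChemostatParams(**raw["params"])
    if "schedule" in raw:
        out["schedule"] = FeedSchedule(**raw["schedule"])
    return out
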