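"""Packaged reference fixtures: the published fold-change table and the
seed-target relation lists used by the enrichment stage."""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .simulate import TREATMENTS

__all__ = ["load_table2", "load_table2_homologs", "load_table3_relations",
           "load_table3_seeds", "table2_as_joined"]


def _read(name: str) -> pd.DataFrame:
    with resources.files("dopamet.data").joinpath(name).open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh, sep="\t", dtype=str).fillna("")


def load_table2() -> pd.DataFrame:
    """Published dopamine-regulated gene table: annotation, homolog and sparse
    signed fold-change columns (blank = not significant in that treatment)."""
    t = _read("table2_genes.tsv")
    for c in TREATMENTS:
        t[c] = pd.to_numeric(t[c].replace("", pd.NA))
    return t


def load_table2_homologs() -> pd.DataFrame:
    return _read("table2_homologs.tsv")


def load_table3_relations() -> pd.DataFrame:
    """Seed -> target relation records (regulator, relation_type, target, sign)."""
    return _read("table3_relations.tsv")


def load_table3_seeds() -> pd.DataFrame:
    """Per-seed summary of the published enrichment table (entity counts and
    printed p-values; the p-values are transcription only -- they depend on a
    proprietary relation database and are not recomputed here)."""
    return _read("table3_seeds.tsv")


def table2_as_joined(tissue: str) -> pd.DataFrame:
    """Reshape the fixture into the joined per-gene fold-change frame the
    classifier consumes (filled cells were significant by construction)."""
    t = load_table2()
    sub = t[t["tissue"] == tissue].set_index("gene_id")
    return sub[list(TREATMENTS)]
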