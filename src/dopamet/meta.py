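"""Cross-experiment consensus filter for dopamine-regulated transcripts.

A transcript is called dopamine-regulated when its significant fold changes
move in opposite directions under receptor agonism versus antagonism or
catecholamine depletion (a *reciprocal* pair), or in the same direction under
depletion and an antagonist (a *same-direction* pair, both manipulations
lowering dopamine signaling). Each qualifying pair implicates a receptor
subtype through the selectivity of its drugs (SKF 38393 / SCH 23390 are
D1-selective, LY 171555 / sulpiride D2-selective, MPTP+aMPT is non-selective),
which yields a D1 / D2 / both attribution per accepted gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import AGONISTS, ANTAGONISTS, TREATMENTS

__all__ = ["TreatmentResult", "ReciprocalGene", "join_by_gene", "classify_reciprocal",
           "attribute_receptor", "build_report", "run_meta"]

BLOCKERS = ("SCH", "sulpiride", "MPTP_aMPT")
DEPLETION = "MPTP_aMPT"


@dataclass(frozen=True)
class TreatmentResult:
    """Per-gene q-values and signed fold changes for one treatment-tissue."""

    tissue: str
    treatment: str
    table: pd.DataFrame  # index gene_id, columns q, fold_change

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise ValueError(f"unknown treatment: {self.treatment!r}")
        if self.table.index.has_duplicates:
            dup = self.table.index[self.table.index.duplicated()][:3].tolist()
            raise ValueError(f"duplicate gene ids in {self.treatment}: {dup}")
        q = self.table["q"].to_numpy(float)
        if np.any((q < 0) | (q > 1)):
            raise ValueError("q-values must lie in [0, 1]")


@dataclass
class Pair:
    """One qualifying treatment pair supporting a gene's acceptance."""

    first: str   # agonist for reciprocal pairs, MPTP for same-direction pairs
    second: str
    rule: str    # "reciprocal" | "same_direction"

    @property
    def subtypes(self) -> frozenset[str]:
        """Receptor subtypes implicated by this pair's drug selectivities.

        A mixed pair (e.g. a D1 agonist against the D2 antagonist) implicates
        both subtypes; MPTP+aMPT alone implicates neither, but every pair
        contains at least one receptor-selective drug by construction.
        """
        drugs = {self.first, self.second}
        out = set()
        if drugs & {"SKF", "SCH"}:
            out.add("D1")
        if drugs & {"LY", "sulpiride"}:
            out.add("D2")
        return frozenset(out)


@dataclass
class ReciprocalGene:
    gene_id: str
    tissue: str
    fold_changes: dict[str, float]  # only significant cells
    evidence: list[Pair] = field(default_factory=list)
    receptor: str = "indeterminate"


def join_by_gene(results: list[TreatmentResult], tissue: str,
                 q_threshold: float = 0.05) -> pd.DataFrame:
    """Outer-join per-treatment results on gene id for one tissue.

    Returns a frame with one fold-change column per treatment; cells are NaN
    unless the gene was measured *and* significant (q < threshold) in that
    treatment, so downstream classification sees only significant calls.
    """
    if any(r.tissue != tissue for r in results):
        bad = [r.treatment for r in results if r.tissue != tissue]
        raise ValueError(f"results from a different tissue: {bad}")
    cols = {}
    for r in results:
        sig = r.table.loc[r.table["q"] < q_threshold, "fold_change"]
        cols[r.treatment] = sig
    joined = pd.DataFrame(cols).reindex(columns=list(TREATMENTS))
    joined.index.name = "gene_id"
    return joined.dropna(how="all")


def classify_reciprocal(row: pd.Series, gene_id: str | None = None,
                        tissue: str = "") -> ReciprocalGene | None:
    """Apply the pair rules to one joined row; None when no pair qualifies.

    A gene is accepted as soon as one qualifying pair exists (the printed
    tables contain genes whose other treatment combinations do not qualify);
    every qualifying pair is recorded as evidence. A fold change of exactly
    +1.0 (zero mean log ratio) carries no direction and joins no pair.
    """
    gene_id = gene_id if gene_id is not None else str(row.name)
    fc = {t: row[t] for t in TREATMENTS if t in row.index and pd.notna(row[t])}

    def sign(t: str) -> int:
        v = fc[t]
        return 0 if v == 1.0 else (1 if v > 0 else -1)

    pairs: list[Pair] = []
    for ago in AGONISTS:
        for blk in BLOCKERS:
            if ago in fc and blk in fc and sign(ago) * sign(blk) == -1:
                pairs.append(Pair(ago, blk, "reciprocal"))
    for ant in ANTAGONISTS:
        if DEPLETION in fc and ant in fc and sign(DEPLETION) * sign(ant) == 1:
            pairs.append(Pair(DEPLETION, ant, "same_direction"))
    if not pairs:
        return None
    gene = ReciprocalGene(gene_id=gene_id, tissue=tissue, fold_changes=fc,
                          evidence=pairs)
    gene.receptor = attribute_receptor(pairs)
    return gene


def rejection_reason(row: pd.Series) -> str:
    """Machine-readable reason why a joined row was not accepted."""
    n = int(row.notna().sum())
    return "single-treatment" if n <= 1 else "non-qualifying-pattern"


def attribute_receptor(evidence: list[Pair]) -> str:
    """D1 / D2 when every qualifying pair implicates one subtype, both when
    pairs of both kinds exist, indeterminate as a guarded fallback."""
    if not evidence:
        raise ValueError("receptor attribution needs non-empty evidence")
    kinds: set[str] = set()
    for p in evidence:
        kinds |= p.subtypes
    if kinds == {"D1"}:
        return "D1"
    if kinds == {"D2"}:
        return "D2"
    if kinds == {"D1", "D2"}:
        return "both"
    return "indeterminate"


def classify_table(joined: pd.DataFrame, tissue: str
                   ) -> tuple[list[ReciprocalGene], pd.DataFrame]:
    """Classify every joined row; returns accepted genes and a rejection log."""
    accepted: list[ReciprocalGene] = []
    rejected = []
    for gene_id, row in joined.iterrows():
        res = classify_reciprocal(row, gene_id=str(gene_id), tissue=tissue)
        if res is not None:
            accepted.append(res)
        else:
            rejected.append((gene_id, rejection_reason(row)))
    log = pd.DataFrame(rejected, columns=["gene_id", "reason"]).set_index("gene_id")
    return accepted, log


def build_report(accepted: list[ReciprocalGene],
                 annotations: pd.DataFrame | None = None) -> pd.DataFrame:
    """Assemble the report table (one row per accepted gene, sparse
    fold-change columns, receptor attribution), optionally merging gene
    annotations/homologs on gene id."""
    rows = []
    for g in accepted:
        row = {"tissue": g.tissue, "gene_id": g.gene_id}
        for t in TREATMENTS:
            row[t] = g.fold_changes.get(t, np.nan)
        row["receptor"] = g.receptor
        row["evidence"] = ";".join(f"{p.rule}({p.first},{p.second})" for p in g.evidence)
        rows.append(row)
    cols = ["tissue", "gene_id", *TREATMENTS, "receptor", "evidence"]
    report = pd.DataFrame(rows, columns=cols)
    if annotations is not None and len(report):
        keep = [c for c in ("annotation", "homolog_symbol", "homolog_accession")
                if c in annotations.columns]
        report = report.merge(annotations[["gene_id", *keep]], on="gene_id", how="left")
        report = report[["tissue", "gene_id", *keep, *TREATMENTS, "receptor", "evidence"]]
    return report


def summarize(report: pd.DataFrame) -> dict:
    """Counts per tissue and per receptor attribution."""
    if not len(report):
        return {"n_genes": 0, "per_tissue": {}, "per_receptor": {}}
    return {
        "n_genes": int(len(report)),
        "per_tissue": report["tissue"].value_counts().to_dict(),
        "per_receptor": report["receptor"].value_counts().to_dict(),
    }


def run_meta(results: list[TreatmentResult], tissue: str, q_threshold: float = 0.05,
             annotations: pd.DataFrame | None = None
             ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """join -> classify -> report for one tissue; returns (report, rejection
    log, summary counts)."""
    joined = join_by_gene(results, tissue, q_threshold=q_threshold)
    accepted, log = classify_table(joined, tissue)
    report = build_report(accepted, annotations=annotations)
    return report, log, summarize(report)
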