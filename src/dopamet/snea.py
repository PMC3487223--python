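"""Sub-network enrichment analysis over a regulator-target relation table.

Each regulator ("seed") in the relation database defines a sub-network: its
known targets of one relation type (expression targets, binding partners, or
protein-modification targets). Measured platform genes are first mapped to
human symbols through a homolog map; for every seed whose targets overlap the
measured list, the expression values of the overlap are compared against the
remaining measured values with a two-sided Mann-Whitney U test. A seed is
retained when p < alpha and the overlap has more than ``min_members`` members.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["RelationDB", "HomologMap", "EnrichmentResult", "load_relations",
           "map_to_human", "build_subnetworks", "mann_whitney_u", "enrich",
           "snea_report"]

RELATION_TYPES = ("expression_target", "binding_partner", "protein_modification_target")


class RelationParseError(ValueError):
    """Malformed relation database (bad relation type or duplicate triple)."""


@dataclass(frozen=True)
class RelationDB:
    """Deduplicated (regulator, relation_type, target, sign) records."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"regulator", "relation_type", "target", "sign"}
        if not need <= set(self.records.columns):
            raise RelationParseError(f"relation table needs columns {sorted(need)}")
        bad = ~self.records["relation_type"].isin(RELATION_TYPES)
        if bad.any():
            lines = (self.records.index[bad] + 2).tolist()[:5]
            raise RelationParseError(f"unknown relation type at line(s) {lines}")
        dup = self.records.duplicated(["regulator", "relation_type", "target"])
        if dup.any():
            lines = (self.records.index[dup] + 2).tolist()[:5]
            raise RelationParseError(f"duplicate relation triple at line(s) {lines}")


def load_relations(path: str | Path) -> RelationDB:
    rec = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return RelationDB(records=rec)


UNMAPPED = ("no homolog", "unknown", "")


@dataclass(frozen=True)
class HomologMap:
    """Platform gene id -> (human symbol, accession); unmapped entries are
    explicit ('no homolog' / 'unknown'), never silently absent."""

    table: pd.DataFrame  # index gene_id, columns homolog_symbol, homolog_accession

    @classmethod
    def from_tsv(cls, path: str | Path) -> "HomologMap":
        t = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        return cls(table=t.set_index("gene_id"))

    def lookup(self, gene_id: str) -> str | None:
        """Human symbol, or None when explicitly unmapped / absent."""
        if gene_id not in self.table.index:
            return None
        sym = self.table.loc[gene_id, "homolog_symbol"]
        return sym if sym and sym.lower() not in UNMAPPED else None


def map_to_human(gene_ids: list[str], homologs: HomologMap
                 ) -> tuple[list[str], int, list[str]]:
    """Map platform ids to human symbols.

    Returns (mapped symbols in input order, unmapped count, ids missing from
    the map entirely). Unmapped genes are excluded from all downstream
    computation.
    """
    mapped, missing = [], []
    unmapped = 0
    for g in gene_ids:
        if g not in homologs.table.index:
            missing.append(g)
            unmapped += 1
            continue
        sym = homologs.lookup(g)
        if sym is None:
            unmapped += 1
        else:
            mapped.append(sym)
    return mapped, unmapped, missing


def build_subnetworks(db: RelationDB, relation_type: str) -> dict[str, frozenset[str]]:
    """Seed -> deduplicated target set for one relation type."""
    if relation_type not in RELATION_TYPES:
        raise ValueError(f"unknown relation type: {relation_type!r}")
    sub = db.records[db.records["relation_type"] == relation_type]
    return {seed: frozenset(grp["target"]) for seed, grp in sub.groupby("regulator")}


def _exact_permutation_u(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact permutation distribution of U with midranks (valid under ties).

    Enumerates every assignment of the pooled values to the two groups;
    two-sided p = P(|U - n1 n2 / 2| >= |u_obs - n1 n2 / 2|).
    """
    from itertools import combinations
    from math import comb

    n1, n2 = x.size, y.size
    total = comb(n1 + n2, n1)
    if total > 500_000:
        raise ValueError("exact enumeration too large; use mode='normal'")
    ranks = stats.rankdata(np.concatenate([x, y]))
    mu = n1 * n2 / 2.0
    base = n1 * (n1 + 1) / 2.0
    u_obs = ranks[:n1].sum() - base
    hits = sum(
        1 for idx in combinations(range(n1 + n2), n1)
        if abs(ranks[list(idx)].sum() - base - mu) >= abs(u_obs - mu) - 1e-12
    )
    return float(u_obs), hits / total


def mann_whitney_u(x, y, mode: str = "auto") -> tuple[float, float]:
    """Two-sided Mann-Whitney U test of ``x`` versus ``y``.

    ``exact`` enumerates the permutation distribution of U (valid for untied
    samples; used automatically when min(|x|,|y|) <= 8 and no ties);
    ``normal`` uses the tie-corrected normal approximation with continuity
    correction. Returns (U of x, two-sided p in (0, 1]).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        warnings.warn("all values tied across both samples; p = 1", stacklevel=2)
        return x.size * y.size / 2.0, 1.0
    has_ties = np.unique(pooled).size < pooled.size
    if mode == "auto":
        mode = "exact" if min(x.size, y.size) <= 8 else "normal"
    if mode == "exact":
        if has_ties:
            return _exact_permutation_u(x, y)
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    elif mode == "normal":
        res = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="asymptotic", use_continuity=True)
    else:
        raise ValueError("mode must be 'exact', 'normal' or 'auto'")
    p = min(max(float(res.pvalue), np.nextafter(0, 1)), 1.0)
    return float(res.statistic), p


@dataclass
class EnrichmentResult:
    seed: str
    relation_type: str
    overlap: tuple[str, ...]
    n_overlap: int
    u_statistic: float
    p_value: float
    retained: bool


def enrich(
    subnetworks: dict[str, frozenset[str]],
    expression: dict[str, float] | pd.Series,
    relation_type: str = "",
    alpha: float = 0.05,
    min_members: int = 5,
    mode: str = "normal",
) -> list[EnrichmentResult]:
    """Test every seed's overlap with the measured list against background.

    ``expression`` maps measured human symbols to an expression value (by
    convention the signed log2 fold change of one contrast). The background of
    a seed is every other measured mapped gene. Retention requires p < alpha
    and an overlap STRICTLY larger than ``min_members``. Results are sorted by
    ascending p.
    """
    expr = pd.Series(expression, dtype=float)
    measured = set(expr.index)
    results = []
    for seed, targets in subnetworks.items():
        overlap = sorted(targets & measured)
        if not overlap:
            continue
        background = sorted(measured - set(overlap))
        if not background:
            continue
        u, p = mann_whitney_u(expr[overlap].to_numpy(), expr[background].to_numpy(),
                              mode=mode)
        results.append(
            EnrichmentResult(
                seed=seed,
                relation_type=relation_type,
                overlap=tuple(overlap),
                n_overlap=len(overlap),
                u_statistic=u,
                p_value=p,
                retained=bool(p < alpha and len(overlap) > min_members),
            )
        )
    results.sort(key=lambda r: (r.p_value, r.seed))
    return results


def snea_report(results: list[EnrichmentResult], retained_only: bool = False
                ) -> pd.DataFrame:
    """Table-style report: group, seed, comma-joined overlap, p in scientific
    notation, ordered by ascending p."""
    rows = [
        {
            "group": r.relation_type,
            "seed": r.seed,
            "overlapping_entities": ", ".join(r.overlap),
            "n_overlap": r.n_overlap,
            "p_value": f"{r.p_value:.2E}",
            "retained": r.retained,
        }
        for r in sorted(results, key=lambda r: (r.p_value, r.seed))
        if r.retained or not retained_only
    ]
    return pd.DataFrame(
        rows, columns=["group", "seed", "overlapping_entities", "n_overlap",
                       "p_value", "retained"]
    )


def edge_list(results: list[EnrichmentResult], db: RelationDB,
              expression: dict[str, float] | pd.Series) -> pd.DataFrame:
    """(seed, target, sign, direction) export for graph rendering of retained
    sub-networks; direction is the sign of the target's expression value."""
    expr = pd.Series(expression, dtype=float)
    rows = []
    for r in results:
        if not r.retained:
            continue
        sub = db.records[(db.records["regulator"] == r.seed)
                         & (db.records["relation_type"] == r.relation_type)]
        signs = dict(zip(sub["target"], sub["sign"]))
        for t in r.overlap:
            rows.append({"seed": r.seed, "target": t, "sign": signs.get(t, "0"),
                         "direction": "up" if expr.get(t, 0) > 0 else "down"})
    return pd.DataFrame(rows, columns=["seed", "target", "sign", "direction"])
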