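"""End-to-end orchestration: simulate -> normalize -> SAM -> reciprocal filter
-> SNEA, with a checksummed output manifest and fixture validation."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import fixtures, meta, snea
from .gpa import normalize_batch
from .sam import SamConfig, sam_one_class
from .simulate import (SimulationConfig, TREATMENTS, generate_design,
                       generate_truth, write_arrays)

__all__ = ["RunConfig", "run_all", "validate_fixtures", "sam_per_treatment",
           "expression_for_snea"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths, thresholds and stage toggles for a full run."""

    out_dir: Path
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    q_threshold: float = 0.05
    alpha: float = 0.05
    min_members: int = 5
    snea_contrast: str = "SKF"
    run_snea: bool = True
    relations_path: Path | None = None   # defaults to the packaged fixture
    homologs_path: Path | None = None

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        if not 0 < self.q_threshold < 1 or not 0 < self.alpha < 1:
            raise ValueError("thresholds must lie in (0, 1)")
        if self.min_members < 1:
            raise ValueError("min_members must be a positive integer")


def sam_per_treatment(ratios: pd.DataFrame, rng_seed: int = 0,
                      ) -> dict[tuple[str, str], meta.TreatmentResult]:
    """Run one-class SAM on each treatment-tissue column block."""
    trt_of = ratios.attrs["treatments"]
    tis_of = ratios.attrs["tissues"]
    results = {}
    for key in sorted({(tis_of[a], trt_of[a]) for a in ratios.columns}):
        tissue, trt = key
        cols = [a for a in ratios.columns
                if trt_of[a] == trt and tis_of[a] == tissue]
        res = sam_one_class(ratios[cols], SamConfig(rng_seed=rng_seed))
        results[key] = meta.TreatmentResult(
            tissue=tissue, treatment=trt,
            table=res.table[["q", "fold_change"]],
        )
    return results


def expression_for_snea(report: pd.DataFrame, homologs: snea.HomologMap,
                        contrast: str = "SKF") -> tuple[pd.Series, int]:
    """Signed log2 fold changes of one contrast for the mapped accepted genes.

    Genes without a significant value under the contrast, or without a human
    homolog, are excluded (and counted). Values are log2 of the signed
    fold-change magnitude, keeping its sign.
    """
    import numpy as np

    vals: dict[str, float] = {}
    excluded = 0
    for row in report.itertuples(index=False):
        fc = getattr(row, contrast, None)
        sym = homologs.lookup(row.gene_id)
        if fc is None or pd.isna(fc) or sym is None:
            excluded += 1
            continue
        vals[sym] = float(np.sign(fc) * np.log2(abs(fc)))
    return pd.Series(vals), excluded


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: RunConfig) -> dict:
    """Execute the configured stages; returns the manifest (also written as
    manifest.json with per-file checksums and the echoed configuration)."""
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": [], "files": {}, "config": {
        "rng_seed": config.sim.rng_seed, "n_genes": config.sim.n_genes,
        "q_threshold": config.q_threshold, "alpha": config.alpha,
        "min_members": config.min_members, "snea_contrast": config.snea_contrast,
    }}

    def fail(stage: str, err: Exception) -> None:
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        raise RuntimeError(f"stage {stage!r} failed: {err}") from err

    # simulate
    try:
        truth = generate_truth(config.sim)
        arrays = generate_design(config.sim, truth)
        arr_dir = out / "arrays"
        write_arrays(arrays, arr_dir, seed=config.sim.rng_seed)
        truth.to_csv(out / "truth.tsv", sep="\t")
        manifest["stages"].append("simulate")
        logger.info("simulate: %d arrays, %d regulated of %d genes",
                    len(arrays), int(truth["regulated"].sum()), config.sim.n_genes)
    except Exception as e:  # noqa: BLE001 - abort with stage name
        fail("simulate", e)

    # normalize
    try:
        ratios, fits = normalize_batch(arrays)
        ratios.to_csv(out / "ratios.tsv", sep="\t", float_format="%.10g")
        with open(out / "transforms.tsv", "w", encoding="utf-8") as fh:
            fh.write("batch\tarray_index\tr11\tr12\tr21\tr22\tscale\tt1\tt2\n")
            for name, fit in fits.items():
                for i, (r, s, t) in enumerate(zip(fit.rotations, fit.scales,
                                                  fit.translations)):
                    fh.write(f"{name}\t{i}\t{r[0,0]:.10g}\t{r[0,1]:.10g}"
                             f"\t{r[1,0]:.10g}\t{r[1,1]:.10g}\t{s:.10g}"
                             f"\t{t[0]:.10g}\t{t[1]:.10g}\n")
        manifest["stages"].append("normalize")
    except Exception as e:  # noqa: BLE001
        fail("normalize", e)

    # SAM per treatment-tissue
    try:
        sam_results = sam_per_treatment(ratios, rng_seed=config.sim.rng_seed)
        for (tissue, trt), tr in sam_results.items():
            tr.table.to_csv(out / f"sam_{tissue}_{trt}.tsv", sep="\t",
                            float_format="%.6g")
        manifest["stages"].append("sam")
    except Exception as e:  # noqa: BLE001
        fail("sam", e)

    # reciprocal meta filter per tissue
    reports = {}
    try:
        for tissue in config.sim.tissues:
            trs = [tr for (tis, _), tr in sam_results.items() if tis == tissue]
            report, rejected, summary = meta.run_meta(
                trs, tissue, q_threshold=config.q_threshold)
            report.to_csv(out / f"meta_{tissue}.tsv", sep="\t", index=False,
                          float_format="%.6g")
            rejected.to_csv(out / f"meta_{tissue}_rejected.tsv", sep="\t")
            reports[tissue] = report
            logger.info("meta %s: %d accepted / %d rejected", tissue,
                        summary["n_genes"], len(rejected))
        manifest["stages"].append("meta")
    except Exception as e:  # noqa: BLE001
        fail("meta", e)

    # SNEA on the packaged relation fixture (or user-supplied tables)
    if config.run_snea:
        try:
            rel = (snea.load_relations(config.relations_path)
                   if config.relations_path else
                   snea.RelationDB(fixtures.load_table3_relations()))
            hom = (snea.HomologMap.from_tsv(config.homologs_path)
                   if config.homologs_path else
                   snea.HomologMap(fixtures.load_table2_homologs().set_index("gene_id")))
            all_results = []
            tissue0 = config.sim.tissues[0]
            expr, _ = expression_for_snea(reports[tissue0], hom,
                                          contrast=config.snea_contrast)
            if len(expr) >= 2:
                for rtype in snea.RELATION_TYPES:
                    nets = snea.build_subnetworks(rel, rtype)
                    all_results.extend(
                        snea.enrich(nets, expr, relation_type=rtype,
                                    alpha=config.alpha,
                                    min_members=config.min_members))
            snea.snea_report(all_results).to_csv(out / "snea.tsv", sep="\t",
                                                 index=False)
            manifest["stages"].append("snea")
        except Exception as e:  # noqa: BLE001
            fail("snea", e)

    for path in sorted(out.rglob("*.tsv")):
        manifest["files"][str(path.relative_to(out))] = _sha256(path)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def run_fixture_analysis(tissue: str = "Hyp", contrast: str = "SKF",
                         alpha: float = 0.05, min_members: int = 5,
                         ) -> tuple[pd.DataFrame, list[snea.EnrichmentResult]]:
    """Fixture-only mode: classify the packaged fold-change table (no
    simulation) and run SNEA over the packaged relation lists.

    Returns the reciprocal-gene report for ``tissue`` and the enrichment
    results using the ``contrast`` fold changes of the mapped accepted genes.
    """
    joined = fixtures.table2_as_joined(tissue)
    accepted, _ = meta.classify_table(joined, tissue)
    ann = fixtures.load_table2()[["gene_id", "annotation", "homolog_symbol",
                                  "homolog_accession"]]
    report = meta.build_report(accepted, annotations=ann)

    hom = snea.HomologMap(fixtures.load_table2_homologs().set_index("gene_id"))
    expr, _ = expression_for_snea(report, hom, contrast=contrast)
    rel = snea.RelationDB(fixtures.load_table3_relations())
    results: list[snea.EnrichmentResult] = []
    if len(expr) >= 2:
        for rtype in snea.RELATION_TYPES:
            nets = snea.build_subnetworks(rel, rtype)
            results.extend(snea.enrich(nets, expr, relation_type=rtype,
                                       alpha=alpha, min_members=min_members))
    return report, results


def validate_fixtures() -> pd.DataFrame:
    """Audit every packaged fold-change row against the classification rules.

    Returns one row per fixture gene with its receptor attribution and a
    ``conforming`` flag; rows whose filled cells satisfy no qualifying pair
    (present in the published table but outside its own stated rule) are
    flagged, never modified.
    """
    t = fixtures.load_table2()
    rows = []
    for rec in t.itertuples(index=False):
        fc = pd.Series({trt: getattr(rec, trt) for trt in TREATMENTS})
        res = meta.classify_reciprocal(fc, gene_id=rec.gene_id, tissue=rec.tissue)
        rows.append({
            "tissue": rec.tissue,
            "gene_id": rec.gene_id,
            "annotation": rec.annotation,
            "conforming": res is not None,
            "receptor": res.receptor if res else "",
            "reason": "" if res else meta.rejection_reason(fc),
        })
    return pd.DataFrame(rows)
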