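"""Synthetic two-color cDNA microarray generator with planted dopamine-responsive genes.

Emulates the study design of the goldfish neuroendocrine-brain experiments: five
pharmacological treatments (two D1/D2 agonists, two D1/D2 antagonists, one
catecholamine-depletion treatment) in two brain tissues, each treatment-tissue
pool hybridized on four arrays against a common control pool, the fourth array
being a dye-reversal replicate of one pool, and every gene spotted in duplicate.
A configurable fraction of genes carries a true log2 effect whose sign is
opposite between receptor agonism and antagonism/depletion, i.e. the generative
converse of the reciprocal selection rule applied downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "TwoColorArray",
    "generate_truth",
    "generate_experiment",
    "generate_design",
    "write_arrays",
    "read_arrays",
    "TREATMENTS_BY_EXPERIMENT",
    "AGONISTS",
    "ANTAGONISTS",
    "TREATMENTS",
    "TISSUES",
]

TREATMENTS_BY_EXPERIMENT = {
    "agonist": ("SKF", "LY"),
    "antagonist": ("SCH", "sulpiride"),
    "depletion": ("MPTP_aMPT",),
}
#: receptor selectivity of each drug; MPTP+aMPT depletes catecholamines globally
AGONISTS = {"SKF": "D1", "LY": "D2"}
ANTAGONISTS = {"SCH": "D1", "sulpiride": "D2"}
TREATMENTS = ("MPTP_aMPT", "SCH", "sulpiride", "SKF", "LY")
TISSUES = ("Hyp", "Tel")

#: default master seed recorded in every output header for provenance
DEFAULT_SEED = 20121102


class ConfigurationError(ValueError):
    """Raised when a SimulationConfig violates its invariants."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the simulated microarray study.

    The defaults reproduce the study design (4 hybridizations per
    treatment-tissue pool, one dye-reversal each, duplicate spots) at a
    desk-scale gene count, with 10% of genes regulated at |log2 effect| 1.0
    and per-spot log2 noise 0.25.
    """

    n_genes: int = 1000
    spot_replicates: int = 2
    experiments: tuple[str, ...] = ("agonist", "antagonist", "depletion")
    tissues: tuple[str, ...] = TISSUES
    arrays_per_pool: int = 4
    frac_regulated: float = 0.10
    effect_log2_mean: float = 1.0
    effect_log2_sd: float = 0.0
    attenuation_blocker: float = 1.0
    #: proportions of D1 / D2 / both among regulated genes
    receptor_mix: tuple[float, float, float] = (0.5, 0.3, 0.2)
    noise_sd: float = 0.25
    #: per-gene biological sd across treatment pools (log2); the study pooled
    #: 2-3 animals per tube, so pools -- not animals -- are the simulated unit
    pool_bio_sd: float = 0.10
    #: control-pool log2-expression distribution (plausible array dynamic range)
    baseline_log2_mean: float = 10.0
    baseline_log2_sd: float = 1.5
    #: per-array affine distortion in (log2 ch1, log2 ch2) space
    distortion_rotation_max_deg: float = 3.0
    distortion_scale_range: tuple[float, float] = (0.9, 1.1)
    distortion_translation_max: float = 0.5
    rng_seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        if self.spot_replicates < 1:
            raise ConfigurationError("spot_replicates must be >= 1")
        if self.arrays_per_pool < 2:
            raise ConfigurationError("arrays_per_pool must be >= 2")
        if not 0.0 <= self.frac_regulated <= 1.0:
            raise ConfigurationError("frac_regulated must lie in [0, 1]")
        if not 0.0 < self.attenuation_blocker <= 1.0:
            raise ConfigurationError("attenuation_blocker must lie in (0, 1]")
        if self.noise_sd < 0 or self.pool_bio_sd < 0:
            raise ConfigurationError("noise levels must be non-negative")
        if abs(sum(self.receptor_mix) - 1.0) > 1e-9 or min(self.receptor_mix) < 0:
            raise ConfigurationError("receptor_mix must be non-negative and sum to 1")
        unknown = set(self.experiments) - set(TREATMENTS_BY_EXPERIMENT)
        if unknown:
            raise ConfigurationError(f"unknown experiment ids: {sorted(unknown)}")

    @property
    def n_regulated(self) -> int:
        return int(round(self.frac_regulated * self.n_genes))

    @property
    def gene_ids(self) -> list[str]:
        width = max(4, len(str(self.n_genes)))
        return [f"g{i:0{width}d}" for i in range(1, self.n_genes + 1)]


@dataclass
class TwoColorArray:
    """One hybridization: duplicate-spotted intensities for two dye channels.

    ``intensity_ch1``/``intensity_ch2`` are the raw channel intensities in file
    order; when ``dye_reversed`` is set, channel 1 carries the control pool and
    channel 2 the treatment pool (the swap is resolved downstream, not here).
    """

    array_id: str
    pool_id: str
    treatment: str
    tissue: str
    dye_reversed: bool
    spots: pd.DataFrame = field(repr=False)  # spot_id, gene_id, intensity_ch1, intensity_ch2

    def __post_init__(self) -> None:
        vals = self.spots[["intensity_ch1", "intensity_ch2"]].to_numpy()
        if not np.all(np.isfinite(vals)) or np.any(vals < 0):
            raise ValueError(f"{self.array_id}: intensities must be finite and non-negative")


def _seq(config: SimulationConfig, *stream: int) -> np.random.Generator:
    """Deterministic sub-stream independent of generation order."""
    return np.random.default_rng(np.random.SeedSequence([config.rng_seed, *stream]))


def generate_truth(config: SimulationConfig) -> pd.DataFrame:
    """Draw the ground-truth regulation table.

    Returns a DataFrame indexed by gene id with a ``regulated`` flag, a
    ``receptor`` label (D1/D2/both, empty for unregulated genes) and one true
    log2 effect column per treatment. For a regulated gene the agonist effect of
    its receptor and the matching antagonist/depletion effects have strictly
    opposite signs; unregulated genes have all effects exactly zero.
    """
    rng = _seq(config, 0)
    n, n_reg = config.n_genes, config.n_regulated
    genes = config.gene_ids

    truth = pd.DataFrame(
        0.0, index=pd.Index(genes, name="gene_id"), columns=[f"effect_{t}" for t in TREATMENTS]
    )
    truth.insert(0, "regulated", False)
    truth.insert(1, "receptor", "")

    reg_idx = rng.choice(n, size=n_reg, replace=False)
    truth.iloc[reg_idx, truth.columns.get_loc("regulated")] = True

    # receptor counts by largest remainder, then a seeded shuffle
    raw = np.asarray(config.receptor_mix) * n_reg
    counts = np.floor(raw).astype(int)
    rema = np.argsort(-(raw - counts))
    for k in rema[: n_reg - counts.sum()]:
        counts[k] += 1
    labels = np.repeat(np.array(["D1", "D2", "both"]), counts)
    rng.shuffle(labels)

    att = config.attenuation_blocker
    for gi, rec in zip(reg_idx, labels):
        mag = abs(rng.normal(config.effect_log2_mean, config.effect_log2_sd))
        mag = max(mag, 1e-3)  # a regulated gene must have a nonzero effect
        e = mag * rng.choice([-1.0, 1.0])
        row = truth.index[gi]
        truth.loc[row, "receptor"] = rec
        if rec in ("D1", "both"):
            truth.loc[row, "effect_SKF"] = e
            truth.loc[row, "effect_SCH"] = -e * att
        if rec in ("D2", "both"):
            truth.loc[row, "effect_LY"] = e
            truth.loc[row, "effect_sulpiride"] = -e * att
        truth.loc[row, "effect_MPTP_aMPT"] = -e * att
    return truth


def _control_pool(config: SimulationConfig, tissue: str) -> np.ndarray:
    """Shared control-pool log2 expression vector for one tissue."""
    rng = _seq(config, 1, TISSUES.index(tissue))
    return rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, config.n_genes)


def _distort(points: np.ndarray, rng: np.random.Generator, config: SimulationConfig) -> np.ndarray:
    """Apply an affine similarity distortion about the cloud centroid."""
    theta = math.radians(rng.uniform(-config.distortion_rotation_max_deg,
                                     config.distortion_rotation_max_deg))
    lo, hi = config.distortion_scale_range
    scale = rng.uniform(lo, hi)
    trans = rng.uniform(-config.distortion_translation_max,
                        config.distortion_translation_max, 2)
    rot = np.array([[math.cos(theta), -math.sin(theta)],
                    [math.sin(theta), math.cos(theta)]])
    mu = points.mean(axis=0)
    return scale * (points - mu) @ rot + mu + trans


def generate_experiment(
    config: SimulationConfig,
    truth: pd.DataFrame,
    experiment_id: str,
    tissue: str,
) -> list[TwoColorArray]:
    """Simulate every hybridization of one experiment in one tissue.

    Each treatment yields ``arrays_per_pool`` arrays: pools 1..(k-1) plus a
    dye-reversal replicate of the last pool, all hybridized against the shared
    tissue control pool. The treatment channel is control x 2^(true effect)
    perturbed by pool-level biology and per-spot noise; the whole array is then
    distorted by its affine transform in 2-D log-intensity space.
    """
    if experiment_id not in TREATMENTS_BY_EXPERIMENT:
        raise ValueError(f"unknown experiment id: {experiment_id!r}")
    if tissue not in TISSUES:
        raise ValueError(f"unknown tissue: {tissue!r}")
    control = _control_pool(config, tissue)
    reps = config.spot_replicates
    genes = np.repeat(config.gene_ids, reps)
    spot_ids = [f"s{i:05d}" for i in range(1, len(genes) + 1)]

    arrays: list[TwoColorArray] = []
    exp_i = list(TREATMENTS_BY_EXPERIMENT).index(experiment_id)
    for trt in TREATMENTS_BY_EXPERIMENT[experiment_id]:
        trt_i = TREATMENTS.index(trt)
        rng = _seq(config, 2, exp_i, TISSUES.index(tissue), trt_i)
        effect = truth[f"effect_{trt}"].to_numpy()
        k = config.arrays_per_pool
        n_pools = k - 1  # last array replicates the final pool, dye-reversed
        pool_expr = [
            control + effect + rng.normal(0.0, config.pool_bio_sd, config.n_genes)
            for _ in range(n_pools)
        ]
        plan = [(p, False) for p in range(n_pools)] + [(n_pools - 1, True)]
        for a, (pool, reversed_) in enumerate(plan, start=1):
            t_log = np.repeat(pool_expr[pool], reps) + rng.normal(0.0, config.noise_sd, len(genes))
            c_log = np.repeat(control, reps) + rng.normal(0.0, config.noise_sd, len(genes))
            pts = np.column_stack([t_log, c_log])
            if reversed_:
                pts = pts[:, ::-1]
            pts = _distort(pts, rng, config)
            spots = pd.DataFrame(
                {
                    "spot_id": spot_ids,
                    "gene_id": genes,
                    "intensity_ch1": np.exp2(pts[:, 0]),
                    "intensity_ch2": np.exp2(pts[:, 1]),
                }
            )
            arrays.append(
                TwoColorArray(
                    array_id=f"{tissue}_{trt}_a{a}",
                    pool_id=f"{tissue}_{trt}_p{pool + 1}",
                    treatment=trt,
                    tissue=tissue,
                    dye_reversed=reversed_,
                    spots=spots,
                )
            )
    return arrays


def generate_design(config: SimulationConfig, truth: pd.DataFrame | None = None
                    ) -> list[TwoColorArray]:
    """All arrays of the full configured design (every experiment x tissue)."""
    if truth is None:
        truth = generate_truth(config)
    arrays: list[TwoColorArray] = []
    for exp in config.experiments:
        for tissue in config.tissues:
            arrays.extend(generate_experiment(config, truth, exp, tissue))
    return arrays


# ---------------------------------------------------------------------------
# TSV round-trip
# ---------------------------------------------------------------------------

_MANIFEST = "manifest.tsv"


def write_arrays(arrays: Sequence[TwoColorArray], directory: str | Path,
                 seed: int = DEFAULT_SEED) -> list[Path]:
    """Write one TSV per array plus a manifest; lossless through read_arrays."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    manifest = []
    for arr in arrays:
        path = directory / f"{arr.array_id}.tsv"
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# array_id={arr.array_id}\tpool_id={arr.pool_id}"
                     f"\ttreatment={arr.treatment}\ttissue={arr.tissue}"
                     f"\tdye_reversed={int(arr.dye_reversed)}\tseed={seed}\n")
            arr.spots.to_csv(fh, sep="\t", index=False, float_format="%.10g")
        paths.append(path)
        manifest.append(
            (arr.array_id, arr.pool_id, arr.treatment, arr.tissue, int(arr.dye_reversed))
        )
    pd.DataFrame(
        manifest, columns=["array_id", "pool_id", "treatment", "tissue", "dye_reversed"]
    ).to_csv(directory / _MANIFEST, sep="\t", index=False)
    return paths


def read_arrays(directory: str | Path) -> list[TwoColorArray]:
    """Read arrays written by :func:`write_arrays`."""
    directory = Path(directory)
    man = pd.read_csv(directory / _MANIFEST, sep="\t", dtype={"array_id": str})
    arrays = []
    for rec in man.itertuples(index=False):
        spots = pd.read_csv(directory / f"{rec.array_id}.tsv", sep="\t", comment="#",
                            dtype={"spot_id": str, "gene_id": str})
        arrays.append(
            TwoColorArray(
                array_id=rec.array_id,
                pool_id=rec.pool_id,
                treatment=rec.treatment,
                tissue=rec.tissue,
                dye_reversed=bool(rec.dye_reversed),
                spots=spots,
            )
        )
    return arrays


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    """Copy of ``config`` with a different master seed."""
    return replace(config, rng_seed=int(seed))
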