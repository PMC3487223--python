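"""Relative-standard-curve qPCR quantification with QC gates.

A dilution series of pooled cDNA (default 1:10 down to 1:31,250 in 5-fold
steps) yields a standard curve Ct = slope * log10(quantity) + intercept; the
amplification efficiency is (10^(-1/slope) - 1) * 100, with 100% meaning
perfect per-cycle doubling (slope -3.32). A curve passes QC only with
R^2 > 0.99 and efficiency in [90, 110]%; quantification refuses non-passing
curves. Sample quantities are normalized to a reference gene per sample and
treated vs control groups are compared with a two-tailed Mann-Whitney U test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .snea import mann_whitney_u

__all__ = ["QpcrPlate", "StandardCurve", "fit_standard_curve", "quantify",
           "normalize_and_test", "DEFAULT_DILUTIONS"]

logger = logging.getLogger(__name__)

#: 1:10 then 5-fold steps to 1:31,250, matching the printed series endpoints
DEFAULT_DILUTIONS = (10, 50, 250, 1250, 6250, 31250)

NO_AMP = "no-amplification"


class QcError(ValueError):
    """A plate or curve violates a QC gate."""


@dataclass(frozen=True)
class QpcrPlate:
    """Well-level plate table.

    Columns: sample_id, gene, well_type (unknown | standard | NTC | NoRT),
    dilution (positive for standard wells, blank otherwise), ct (cycle
    threshold >= 0 or 'no-amplification').
    """

    wells: pd.DataFrame

    def __post_init__(self) -> None:
        std = self.wells[self.wells["well_type"] == "standard"]
        dil = pd.to_numeric(std["dilution"], errors="coerce")
        if (dil <= 0).any() or dil.isna().any():
            raise QcError("every standard well needs a strictly positive dilution")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "QpcrPlate":
        return cls(wells=pd.read_csv(path, sep="\t", dtype={"sample_id": str,
                                                            "gene": str,
                                                            "well_type": str,
                                                            "ct": str}))

    def check_controls(self) -> None:
        """NTC / NoRT wells must show no amplification (no contamination)."""
        ctrl = self.wells[self.wells["well_type"].isin(["NTC", "NoRT"])]
        bad = ctrl[ctrl["ct"].astype(str) != NO_AMP]
        if len(bad):
            raise QcError(f"amplification in {len(bad)} negative-control well(s)")

    def numeric_ct(self, mask: pd.Series) -> pd.DataFrame:
        sub = self.wells[mask].copy()
        sub = sub[sub["ct"].astype(str) != NO_AMP]
        sub["ct"] = sub["ct"].astype(float)
        if (sub["ct"] < 0).any():
            raise QcError("negative Ct value")
        return sub


@dataclass(frozen=True)
class StandardCurve:
    slope: float
    intercept: float
    r_squared: float

    @property
    def efficiency_percent(self) -> float:
        return (10.0 ** (-1.0 / self.slope) - 1.0) * 100.0

    @property
    def passed(self) -> bool:
        return bool(self.r_squared > 0.99 and 90.0 <= self.efficiency_percent <= 110.0)


def fit_standard_curve(dilutions: np.ndarray, cts: np.ndarray) -> StandardCurve:
    """Least-squares fit of Ct against log10 relative quantity (1/dilution).

    Only dilution ratios matter: relabeling the series by a common factor
    shifts the intercept but leaves slope, R^2 and efficiency unchanged.
    """
    dilutions = np.asarray(dilutions, float)
    cts = np.asarray(cts, float)
    if np.unique(dilutions).size < 3:
        raise ValueError("need at least 3 distinct dilution points")
    if np.any(dilutions <= 0):
        raise ValueError("dilution factors must be strictly positive")
    x = np.log10(1.0 / dilutions)
    fit = stats.linregress(x, cts)
    return StandardCurve(slope=float(fit.slope), intercept=float(fit.intercept),
                         r_squared=float(fit.rvalue**2))


def quantify(ct: float | np.ndarray, curve: StandardCurve) -> float | np.ndarray:
    """Relative quantity 10^((Ct - intercept)/slope); refuses failed curves."""
    if not curve.passed:
        raise QcError(
            "standard curve failed QC: "
            f"R^2={curve.r_squared:.4f} (need > 0.99), "
            f"efficiency={curve.efficiency_percent:.1f}% (need 90-110%)"
        )
    q = 10.0 ** ((np.asarray(ct, float) - curve.intercept) / curve.slope)
    return float(q) if np.ndim(ct) == 0 else q


def _signed_ratio(r: float) -> float:
    """Fold-change sign convention shared with the microarray reports."""
    return r if r >= 1.0 else -1.0 / r


def normalize_and_test(
    target: dict[str, float],
    reference: dict[str, float],
    groups: dict[str, str],
) -> tuple[float, float]:
    """Reference-normalized group comparison.

    ``target``/``reference`` map sample id -> relative quantity for the gene
    of interest and the reference gene; ``groups`` maps sample id -> 'treated'
    or 'control'. Per-sample expression is target/reference (any sample-wide
    multiplicative factor cancels); the fold change is mean(treated) /
    mean(control) in signed convention, and p comes from a two-tailed
    Mann-Whitney U test (exact for small untied groups).
    """
    norm: dict[str, float] = {}
    for sid, t in target.items():
        r = reference.get(sid)
        if r is None:
            continue
        if r == 0:
            logger.warning("sample %s excluded: reference quantity is zero", sid)
            continue
        norm[sid] = t / r
    treated = [v for s, v in norm.items() if groups.get(s) == "treated"]
    control = [v for s, v in norm.items() if groups.get(s) == "control"]
    if not treated or not control:
        raise ValueError("both groups must contain usable samples")
    if min(len(treated), len(control)) < 3:
        raise ValueError("need at least 3 samples per group")
    fc = _signed_ratio(float(np.mean(treated)) / float(np.mean(control)))
    _, p = mann_whitney_u(np.asarray(treated), np.asarray(control), mode="auto")
    return fc, p
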