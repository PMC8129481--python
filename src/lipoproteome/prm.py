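"""Targeted PRM absolute quantification of lipoprotein-carried proteins.

Covers the downstream arithmetic of a heavy-peptide spike-in experiment:
averaging of duplicate injections, internal-standard normalization,
standard-curve fitting (used as a linearity QC gate), single-point
light/heavy quantification in fmol per ug of loaded fraction protein,
molar ratios between peptides, and a Welch comparison of fractions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

CALIBRATION_COLUMNS = ["peptide_id", "level", "replicate", "light_area", "heavy_area", "is_area"]
SAMPLE_COLUMNS = [
    "peptide_id", "sample_id", "fraction", "loaded_mass_ug", "heavy_spike_fmol",
    "light_area", "heavy_area", "is_area",
]

__all__ = [
    "PRMBatch",
    "CurveFit",
    "average_injections",
    "is_normalize",
    "fit_standard_curve",
    "quantify",
    "molar_ratio",
    "welch_test",
    "run_prm_pipeline",
]


@dataclass
class PRMBatch:
    """Calibration and measurement tables of one PRM experiment.

    ``calibration`` has one row per (peptide, spike level, injection
    replicate) with light/heavy/internal-standard peak areas.
    ``samples`` has one row per (peptide, sample) with the loaded mass,
    the per-sample heavy spike amount, and the same three areas.
    """

    calibration: pd.DataFrame
    samples: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        missing = [c for c in CALIBRATION_COLUMNS if c not in self.calibration.columns]
        if missing:
            raise ValueError(f"calibration table lacks columns: {missing}")
        if self.calibration["level"].le(0).any():
            raise ValueError("calibration levels must be positive")
        for col in ("light_area", "heavy_area", "is_area"):
            if self.calibration[col].lt(0).any():
                raise ValueError(f"negative {col} in calibration table")
        if self.calibration.groupby("peptide_id")["level"].nunique().min() < 2:
            raise ValueError("need at least 2 distinct calibration levels per peptide")
        if self.samples is not None:
            missing = [c for c in SAMPLE_COLUMNS if c not in self.samples.columns]
            if missing:
                raise ValueError(f"sample table lacks columns: {missing}")
            if self.samples["loaded_mass_ug"].le(0).any():
                raise ValueError("loaded_mass_ug must be positive")


@dataclass(frozen=True)
class CurveFit:
    slope: float
    intercept: float
    r_squared: float

    def passes_qc(self, r2_threshold: float = 0.98) -> bool:
        return self.r_squared >= r2_threshold


def average_injections(records: pd.DataFrame, keys: list[str] | None = None) -> pd.DataFrame:
    """Average the peak areas of duplicate injections.

    ``keys`` defaults to ``(peptide_id, level)``.  Each key may carry one
    or two replicate rows; more than two is an error.  Area columns are
    replaced by their arithmetic mean, single rows pass through.
    """
    if keys is None:
        keys = ["peptide_id", "level"]
    counts = records.groupby(keys, sort=False).size()
    if (counts > 2).any():
        bad = counts[counts > 2].index[0]
        raise ValueError(f"more than 2 injection replicates for key {bad!r}")
    area_cols = [c for c in ("light_area", "heavy_area", "is_area") if c in records.columns]
    other = [c for c in records.columns if c not in area_cols + keys and c != "replicate"]
    agg = {**{c: "mean" for c in area_cols}, **{c: "first" for c in other}}
    return records.groupby(keys, sort=False, as_index=False).agg(agg)


def is_normalize(records: pd.DataFrame) -> pd.DataFrame:
    """Normalize light and heavy areas by the internal-standard response.

    Each record's areas are divided by ``is_area / reference`` where the
    reference is the median ``is_area`` over the table, so a record whose
    internal standard read twice as high as typical has its areas halved.
    The light/heavy ratio within a record is unchanged.
    """
    if records["is_area"].le(0).any():
        bad = records.index[records["is_area"].le(0)][0]
        raise ValueError(f"record {bad} has non-positive internal-standard area")
    ref = float(records["is_area"].median())
    factor = records["is_area"] / ref
    out = records.copy()
    out["light_area"] = out["light_area"] / factor
    out["heavy_area"] = out["heavy_area"] / factor
    out["is_area"] = ref
    return out


def fit_standard_curve(levels: np.ndarray, areas: np.ndarray, weighting: str | None = None) -> CurveFit:
    """Least-squares line through the dilution series.

    ``weighting="1/x"`` fits weighted least squares with weights 1/level,
    common for dilution series; default is unweighted OLS.  r^2 is the
    (weighted) coefficient of determination.
    """
    levels = np.asarray(levels, dtype=float)
    areas = np.asarray(areas, dtype=float)
    if np.unique(levels).size < 2:
        raise ValueError("standard curve needs at least 2 distinct levels")
    if weighting is None:
        w = np.ones_like(levels)
    elif weighting == "1/x":
        w = 1.0 / levels
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    W = np.sum(w)
    xbar = np.sum(w * levels) / W
    ybar = np.sum(w * areas) / W
    sxx = np.sum(w * (levels - xbar) ** 2)
    sxy = np.sum(w * (levels - xbar) * (areas - ybar))
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    resid = areas - (intercept + slope * levels)
    ss_res = np.sum(w * resid**2)
    ss_tot = np.sum(w * (areas - ybar) ** 2)
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return CurveFit(slope=float(slope), intercept=float(intercept), r_squared=float(r2))


def quantify(
    light_area: float,
    heavy_area: float,
    heavy_spike_fmol: float,
    loaded_mass_ug: float,
) -> tuple[float, bool]:
    """Single-point concentration from the light/heavy area ratio.

    Returns ``(concentration fmol/ug, detected)``.  Zero heavy area means
    the spiked standard itself was not seen, so the measurement is
    undetectable: ``(nan, False)``.  Zero light area is a genuine
    below-detection endogenous signal: ``(0.0, False)``.
    """
    if heavy_spike_fmol <= 0:
        raise ValueError("heavy_spike_fmol must be positive")
    if loaded_mass_ug <= 0:
        raise ValueError("loaded_mass_ug must be positive")
    if heavy_area <= 0:
        return (float("nan"), False)
    conc = (light_area / heavy_area) * heavy_spike_fmol / loaded_mass_ug
    if light_area <= 0:
        return (0.0, False)
    return (float(conc), True)


def molar_ratio(numerator: float, denominator: float) -> float:
    """Molar ratio of two fmol/ug concentrations (e.g. PCSK9 per apoB).

    An undetected numerator (NaN) propagates as NaN, never as 0.
    """
    if math.isnan(denominator) or denominator <= 0:
        raise ValueError("denominator concentration must be positive")
    if math.isnan(numerator):
        return float("nan")
    return float(numerator / denominator)


def welch_test(group_a: np.ndarray, group_b: np.ndarray) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test, returning ``(t, df, p)``.

    Degrees of freedom via Welch-Satterthwaite; two-sided P.  Identical
    groups give t = 0, P = 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("welch_test needs at least 2 values per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = a.size, b.size
    denom = va / na + vb / nb
    if denom == 0:
        return (0.0, float(na + nb - 2), 1.0)
    t = (a.mean() - b.mean()) / math.sqrt(denom)
    df = denom**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df=df)
    return (float(t), float(df), float(p))


def run_prm_pipeline(batch: PRMBatch, r2_threshold: float = 0.98, weighting: str | None = None) -> pd.DataFrame:
    """End-to-end PRM quantification for every peptide in the batch.

    Averages injections, IS-normalizes the calibration and sample tables,
    fits a standard curve per peptide (heavy response vs spike level) as a
    linearity gate, quantifies each sample by the single-point light/heavy
    ratio, and compares fractions by mean Lp(a)/LDL ratio and Welch P.

    Returns one row per peptide with curve parameters, a QC flag, the
    per-fraction mean concentrations, their ratio, and the Welch P value
    (NaN when either fraction has under 2 detected measurements).
    """
    cal = average_injections(batch.calibration, keys=["peptide_id", "level"])
    cal = is_normalize(cal)
    rows = []
    samples = batch.samples
    if samples is not None:
        samples = is_normalize(samples)
    for pep, cal_pep in cal.groupby("peptide_id"):
        curve = fit_standard_curve(cal_pep["level"].to_numpy(), cal_pep["heavy_area"].to_numpy(), weighting=weighting)
        row = {
            "peptide_id": pep,
            "slope": curve.slope,
            "intercept": curve.intercept,
            "r_squared": curve.r_squared,
            "passes_qc": curve.passes_qc(r2_threshold),
            "mean_lpa": float("nan"),
            "mean_ldl": float("nan"),
            "ratio_lpa_ldl": float("nan"),
            "welch_p": float("nan"),
        }
        if samples is not None:
            sub = samples[samples["peptide_id"] == pep]
            conc = {"LPA": [], "LDL": []}
            for _, rec in sub.iterrows():
                c, detected = quantify(
                    rec["light_area"], rec["heavy_area"],
                    rec["heavy_spike_fmol"], rec["loaded_mass_ug"],
                )
                if detected:
                    conc[rec["fraction"]].append(c)
            if conc["LPA"]:
                row["mean_lpa"] = float(np.mean(conc["LPA"]))
            if conc["LDL"]:
                row["mean_ldl"] = float(np.mean(conc["LDL"]))
            if conc["LPA"] and conc["LDL"] and row["mean_ldl"] > 0:
                row["ratio_lpa_ldl"] = row["mean_lpa"] / row["mean_ldl"]
            if len(conc["LPA"]) >= 2 and len(conc["LDL"]) >= 2:
                _, _, p = welch_test(np.array(conc["LPA"]), np.array(conc["LDL"]))
                row["welch_p"] = p
        rows.append(row)
    return pd.DataFrame(rows).set_index("peptide_id")
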