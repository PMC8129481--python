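"""Seeded synthetic-data generators for every pipeline stage.

Three generators mirror the statistical structure the downstream stages
assume:

* :func:`simulate_lfq` — paired LPA/LDL protein-intensity matrices with
  log-normal noise, a minority of truly enriched proteins, and
  intensity-dependent (logistic, left-censoring-like) missingness.
* :func:`simulate_prm` — heavy-peptide dilution series with linear
  response, duplicate injections, and multiplicative noise.
* :func:`simulate_mr_panel` — two-sample MR summary statistics generated
  under ``beta_Y = theta * beta_X + pleiotropy + noise`` with optional
  allele flips on the outcome side to exercise harmonization.

A single global seed expands into independent substreams per stage, so
identical seeds give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .lfq import IntensityMatrix
from .prm import PRMBatch

__all__ = [
    "LfqSimTruth",
    "MrSimTruth",
    "simulate_lfq",
    "simulate_prm",
    "simulate_mr_panel",
]

_NON_PALINDROMIC_PAIRS = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]


def _log2_sd_from_cv(cv: float) -> float:
    """Natural-scale coefficient of variation -> SD on the log2 scale."""
    if cv < 0:
        raise ValueError("cv must be non-negative")
    if cv == 0:
        return 0.0
    return float(np.sqrt(np.log1p(cv**2)) / np.log(2))


@dataclass
class LfqSimTruth:
    """Ground truth of one simulated paired LFQ experiment."""

    n_proteins: int = 2000
    n_pairs: int = 6
    enriched_ids: frozenset[int] = field(default_factory=frozenset)
    log2_effect: float = 3.0
    cv: float = 0.2
    subject_sd: float = 0.25
    missing_slope: float = 0.0
    missing_intercept: float = -30.0
    base_log_intensity: np.ndarray | None = None
    peptide_counts: np.ndarray | None = None
    single_peptide_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be positive")
        if self.n_pairs < 2:
            raise ValueError("need at least 2 pairs")
        bad = [i for i in self.enriched_ids if not (0 <= i < self.n_proteins)]
        if bad:
            raise ValueError(f"enriched ids out of range: {sorted(bad)[:5]}")
        self.enriched_ids = frozenset(self.enriched_ids)


def simulate_lfq(truth: LfqSimTruth) -> IntensityMatrix:
    """Generate a paired LPA/LDL intensity matrix from the given truth.

    Sample log2 intensity = protein baseline + shared subject effect +
    ``log2_effect`` on the LPA side for enriched proteins + log-normal
    noise of coefficient of variation ``cv``.  Each observation is masked
    with probability ``expit(intercept + slope * true_log2_intensity)``
    (negative slope concentrates missingness at low abundance).  The
    default intercept of -30 makes missingness negligible.
    """
    ss = np.random.SeedSequence(truth.seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(5)]
    rng_base, rng_subj, rng_noise, rng_miss, rng_pep = rngs
    n, k = truth.n_proteins, truth.n_pairs

    if truth.base_log_intensity is None:
        base = rng_base.normal(25.0, 2.0, size=n)
    else:
        base = np.asarray(truth.base_log_intensity, dtype=float)
        if base.shape != (n,):
            raise ValueError("base_log_intensity must have one entry per protein")
    subj = rng_subj.normal(0.0, truth.subject_sd, size=k) if truth.subject_sd > 0 else np.zeros(k)
    effect = np.zeros(n)
    if truth.enriched_ids:
        effect[list(truth.enriched_ids)] = truth.log2_effect
    sd = _log2_sd_from_cv(truth.cv)

    # proteins x samples; first k columns LPA, next k LDL, paired by subject
    true_log2 = np.empty((n, 2 * k))
    true_log2[:, :k] = base[:, None] + subj[None, :] + effect[:, None]
    true_log2[:, k:] = base[:, None] + subj[None, :]
    noise = rng_noise.normal(0.0, sd, size=(n, 2 * k)) if sd > 0 else 0.0
    log2_obs = true_log2 + noise

    p_missing = np.clip(expit(truth.missing_intercept + truth.missing_slope * true_log2), 0.0, 1.0)
    mask = rng_miss.random(size=(n, 2 * k)) < p_missing

    values = np.exp2(log2_obs)
    values = np.where(mask, np.nan, values)

    protein_ids = pd.Index([f"P{i:05d}" for i in range(n)], name="protein_id")
    sample_ids = pd.Index(
        [f"LPA_{j + 1}" for j in range(k)] + [f"LDL_{j + 1}" for j in range(k)],
        name="sample_id",
    )
    condition = pd.Series(["LPA"] * k + ["LDL"] * k, index=sample_ids)
    pair_id = pd.Series([f"S{j + 1}" for j in range(k)] * 2, index=sample_ids)

    if truth.peptide_counts is None:
        pep = 2 + rng_pep.poisson(4.0, size=n)
        if truth.single_peptide_fraction > 0:
            single = rng_pep.random(n) < truth.single_peptide_fraction
            pep = np.where(single, 1, pep)
    else:
        pep = np.asarray(truth.peptide_counts, dtype=int)
        if pep.shape != (n,):
            raise ValueError("peptide_counts must have one entry per protein")

    return IntensityMatrix(
        intensities=pd.DataFrame(values, index=protein_ids, columns=sample_ids),
        condition=condition,
        pair_id=pair_id,
        peptide_counts=pd.Series(pep, index=protein_ids),
    )


def simulate_prm(
    levels: list[float] | np.ndarray,
    response: float = 5.0,
    noise_cv: float = 0.05,
    seed: int = 0,
    intercept: float = 0.0,
    peptide_id: str = "PEP1",
    is_area: float = 1e5,
    n_samples_per_fraction: int = 0,
    true_conc: dict[str, float] | None = None,
    heavy_spike_fmol: float = 20.0,
    loaded_mass_ug: float = 2.0,
) -> PRMBatch:
    """Generate a PRM dilution series (and optionally sample records).

    Heavy areas are linear in the spiked amount (``response * level +
    intercept``) up to multiplicative log-normal noise of CV
    ``noise_cv``; each level is injected twice.  When
    ``n_samples_per_fraction`` is positive, per-fraction sample records
    are generated with endogenous light areas set by ``true_conc`` (a
    mapping ``{"LPA": fmol/ug, "LDL": fmol/ug}``).
    """
    levels = np.asarray(levels, dtype=float)
    if np.unique(levels).size < 2:
        raise ValueError("need at least 2 distinct calibration levels")
    if np.any(levels <= 0):
        raise ValueError("calibration levels must be positive")
    ss = np.random.SeedSequence(seed)
    rng_cal, rng_samp = [np.random.default_rng(s) for s in ss.spawn(2)]
    sd = _log2_sd_from_cv(noise_cv) * np.log(2)  # natural-log sd

    def noisy(mean: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if sd == 0:
            return np.asarray(mean, dtype=float)
        return mean * np.exp(rng.normal(0.0, sd, size=np.shape(mean)))

    rows = []
    for level in levels:
        for rep in (1, 2):
            rows.append({
                "peptide_id": peptide_id,
                "level": level,
                "replicate": rep,
                "light_area": float(noisy(np.array(0.2 * response * level + intercept), rng_cal)),
                "heavy_area": float(noisy(np.array(response * level + intercept), rng_cal)),
                "is_area": float(noisy(np.array(is_area), rng_cal)),
            })
    calibration = pd.DataFrame(rows)

    samples = None
    if n_samples_per_fraction > 0:
        if true_conc is None:
            true_conc = {"LPA": 10.0, "LDL": 2.0}
        srows = []
        heavy_mean = response * heavy_spike_fmol
        for fraction in ("LPA", "LDL"):
            for i in range(n_samples_per_fraction):
                light_mean = response * true_conc[fraction] * loaded_mass_ug
                srows.append({
                    "peptide_id": peptide_id,
                    "sample_id": f"{fraction}_{i + 1}",
                    "fraction": fraction,
                    "loaded_mass_ug": loaded_mass_ug,
                    "heavy_spike_fmol": heavy_spike_fmol,
                    "light_area": float(noisy(np.array(light_mean), rng_samp)),
                    "heavy_area": float(noisy(np.array(heavy_mean), rng_samp)),
                    "is_area": float(noisy(np.array(is_area), rng_samp)),
                })
        samples = pd.DataFrame(srows)
    return PRMBatch(calibration=calibration, samples=samples)


@dataclass
class MrSimTruth:
    """Ground truth of one simulated two-sample MR panel."""

    n_instruments: int = 54
    theta: float = 0.4
    beta_x: np.ndarray | None = None
    se_x: float = 0.01
    se_y: float = 0.05
    pleiotropy_sd: float = 0.0
    n_null_proteins: int = 0
    n_causal_proteins: int = 1
    flip_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_instruments < 1:
            raise ValueError("need at least one instrument")
        if self.se_x <= 0 or self.se_y <= 0:
            raise ValueError("se_x and se_y must be positive")
        if self.pleiotropy_sd < 0:
            raise ValueError("pleiotropy_sd must be non-negative")
        if not (0 <= self.flip_fraction <= 1):
            raise ValueError("flip_fraction must be in [0, 1]")


def simulate_mr_panel(truth: MrSimTruth) -> tuple[pd.DataFrame, dict[str, pd.DataFrame], pd.DataFrame]:
    """Generate exposure instruments and per-protein outcome tables.

    The exposure table carries the instrument effects ``beta_X`` (drawn
    uniformly away from zero when not supplied) with nominal SE ``se_x``;
    exposure estimation noise is deliberately omitted so the first-order
    Wald-ratio theory holds exactly.  For each causal protein the outcome
    effect is ``theta * beta_X + pleiotropy + Normal(0, se_y)``; null
    proteins use ``theta = 0``.  A ``flip_fraction`` of outcome rows has
    its alleles swapped and beta negated to exercise harmonization.

    Returns ``(exposure table, {protein: outcome table}, truth table)``.
    """
    ss = np.random.SeedSequence(truth.seed)
    rng_x, rng_allele, rng_y, rng_flip = [np.random.default_rng(s) for s in ss.spawn(4)]
    k = truth.n_instruments

    if truth.beta_x is None:
        bx = rng_x.uniform(0.05, 0.3, size=k) * rng_x.choice([-1.0, 1.0], size=k)
    else:
        bx = np.asarray(truth.beta_x, dtype=float)
        if bx.shape != (k,):
            raise ValueError("beta_x must have one entry per instrument")
    variant_ids = [f"rs{i + 1:06d}" for i in range(k)]
    pairs = [_NON_PALINDROMIC_PAIRS[int(i)] for i in rng_allele.integers(0, len(_NON_PALINDROMIC_PAIRS), size=k)]
    exposure = pd.DataFrame({
        "variant_id": variant_ids,
        "effect_allele": [p[0] for p in pairs],
        "other_allele": [p[1] for p in pairs],
        "beta": bx,
        "se": truth.se_x,
        "pvalue": 2.0 * stats.norm.sf(np.abs(bx / truth.se_x)),
    })

    thetas = {}
    panel: dict[str, pd.DataFrame] = {}
    labels = [(f"causal_{i + 1:04d}", truth.theta) for i in range(truth.n_causal_proteins)]
    labels += [(f"null_{i + 1:04d}", 0.0) for i in range(truth.n_null_proteins)]
    for name, theta in labels:
        alpha = rng_y.normal(0.0, truth.pleiotropy_sd, size=k) if truth.pleiotropy_sd > 0 else 0.0
        by = theta * bx + alpha + rng_y.normal(0.0, truth.se_y, size=k)
        flip = rng_flip.random(k) < truth.flip_fraction
        out = pd.DataFrame({
            "variant_id": variant_ids,
            "effect_allele": np.where(flip, [p[1] for p in pairs], [p[0] for p in pairs]),
            "other_allele": np.where(flip, [p[0] for p in pairs], [p[1] for p in pairs]),
            "beta": np.where(flip, -by, by),
            "se": truth.se_y,
        })
        panel[name] = out
        thetas[name] = theta
    truth_table = pd.DataFrame({"protein": list(thetas), "theta": list(thetas.values())})
    return exposure, panel, truth_table
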