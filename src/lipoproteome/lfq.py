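"""Label-free differential-enrichment engine for paired lipoprotein fractions.

Implements the quantification path applied to MaxQuant-style protein-group
intensity tables: per-sample median normalization, low-percentile noise
imputation of missing values, a quantifiability filter (replicate presence
in at least one fraction plus a minimum peptide count), paired t-testing of
LPA-vs-LDL intensities, empirical-Bayes variance moderation, and
Benjamini-Hochberg FDR control.

Conventions
-----------
* Conditions are labelled ``"LPA"`` and ``"LDL"``; samples are paired by a
  subject-level ``pair_id`` that occurs exactly once per condition.
* Missing intensities are represented as ``NaN`` in the intensity frame.
* Tests run on log2 intensities by default; enrichment ratios are reported
  on the natural scale (mean LPA intensity / mean LDL intensity).
* The 1st-percentile used for imputation interpolates linearly between
  order statistics (numpy's inclusive/"linear" definition).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

CONDITIONS = ("LPA", "LDL")

__all__ = [
    "IntensityMatrix",
    "ModerationParams",
    "median_normalize",
    "impute_first_percentile",
    "quantifiability_filter",
    "paired_ratio_test",
    "fit_moderation",
    "moderated_test",
    "bh_adjust",
    "replicate_diff",
    "run_lfq_pipeline",
]


@dataclass
class IntensityMatrix:
    """Protein x sample intensity table with sample annotations.

    Parameters
    ----------
    intensities
        DataFrame indexed by protein id with one column per sample.
        ``NaN`` marks a missing (not detected) value; observed values must
        be non-negative.
    condition
        Per-sample label, one of ``"LPA"``/``"LDL"``, indexed by sample id.
    pair_id
        Per-sample subject label; each subject occurs exactly once per
        condition (paired design).
    peptide_counts
        Number of distinct peptides supporting each protein's
        quantification (>= 1), indexed by protein id.
    imputed
        Optional boolean frame marking cells that were filled in by
        :func:`impute_first_percentile`.  Normalization statistics are
        always computed on genuinely observed cells so that
        normalize-then-impute is idempotent.
    """

    intensities: pd.DataFrame
    condition: pd.Series
    pair_id: pd.Series
    peptide_counts: pd.Series
    imputed: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        n_prot, n_samp = self.intensities.shape
        if n_prot < 1 or n_samp < 1:
            raise ValueError("intensity matrix must have at least one protein and one sample")
        if not self.condition.index.equals(self.intensities.columns):
            self.condition = self.condition.reindex(self.intensities.columns)
        if not self.pair_id.index.equals(self.intensities.columns):
            self.pair_id = self.pair_id.reindex(self.intensities.columns)
        if not self.peptide_counts.index.equals(self.intensities.index):
            self.peptide_counts = self.peptide_counts.reindex(self.intensities.index)
        if self.condition.isna().any() or self.pair_id.isna().any():
            raise ValueError("every sample needs a condition and a pair_id")
        bad = set(self.condition.unique()) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown condition labels: {sorted(bad)}")
        for cond in CONDITIONS:
            pairs = self.pair_id[self.condition == cond]
            if pairs.duplicated().any():
                dup = pairs[pairs.duplicated()].iloc[0]
                raise ValueError(f"pair {dup!r} occurs more than once in condition {cond}")
        vals = self.intensities.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise ValueError("observed intensities must be non-negative")
        if (self.peptide_counts.fillna(0) < 1).any():
            raise ValueError("peptide_counts must be >= 1 for every protein")
        if self.imputed is not None and self.imputed.shape != self.intensities.shape:
            raise ValueError("imputed mask must match intensity matrix shape")

    # convenience ------------------------------------------------------

    @property
    def protein_ids(self) -> pd.Index:
        return self.intensities.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.intensities.columns

    def samples_of(self, condition: str) -> pd.Index:
        return self.sample_ids[self.condition == condition]

    @property
    def n_pairs(self) -> int:
        return int(self.pair_id.nunique())

    def observed_mask(self) -> pd.DataFrame:
        """True where a value was genuinely measured (not NaN, not imputed)."""
        obs = self.intensities.notna()
        if self.imputed is not None:
            obs &= ~self.imputed
        return obs

    def copy(self) -> "IntensityMatrix":
        return IntensityMatrix(
            intensities=self.intensities.copy(),
            condition=self.condition.copy(),
            pair_id=self.pair_id.copy(),
            peptide_counts=self.peptide_counts.copy(),
            imputed=None if self.imputed is None else self.imputed.copy(),
        )


@dataclass(frozen=True)
class ModerationParams:
    """Empirical-Bayes prior for variance moderation.

    ``d0`` is the prior degrees of freedom (may be ``inf`` when all
    variances agree), ``s0_sq`` the prior variance, and ``residual_df`` the
    per-protein residual degrees of freedom the prior was fitted against.
    """

    d0: float
    s0_sq: float
    residual_df: float

    def __post_init__(self) -> None:
        if not (self.d0 > 0):
            raise ValueError("d0 must be positive (possibly inf)")
        if not (self.s0_sq > 0):
            raise ValueError("s0_sq must be positive")


def _observed_medians(m: IntensityMatrix) -> pd.Series:
    obs = m.observed_mask()
    meds = {}
    for s in m.sample_ids:
        vals = m.intensities.loc[obs[s], s].to_numpy(dtype=float)
        if vals.size == 0:
            raise ValueError(f"sample {s!r} has no observed intensities")
        meds[s] = float(np.median(vals))
    return pd.Series(meds).reindex(m.sample_ids)


def median_normalize(m: IntensityMatrix) -> IntensityMatrix:
    """Scale each sample so observed medians match the grand median.

    The reference is the median of the per-sample observed medians; each
    sample is divided by ``median_s / reference``.  Multiplicative per
    sample, so within-sample ratios are untouched and the missing mask is
    preserved.
    """
    meds = _observed_medians(m)
    ref = float(np.median(meds.to_numpy()))
    factors = meds / ref
    out = m.copy()
    out.intensities = out.intensities.div(factors, axis=1)
    return out


def impute_first_percentile(m: IntensityMatrix, percentile: float = 1.0) -> IntensityMatrix:
    """Replace missing cells with a per-sample low-abundance noise value.

    Every missing cell in sample ``s`` is set to the given percentile
    (default 1st) of the observed intensities of ``s``.  Imputed cells are
    tracked in ``imputed`` so later normalization ignores them.
    """
    obs = m.observed_mask()
    out = m.copy()
    imputed = ~m.intensities.notna()
    if m.imputed is not None:
        imputed |= m.imputed
    for s in m.sample_ids:
        col_obs = m.intensities.loc[obs[s], s].to_numpy(dtype=float)
        if col_obs.size == 0:
            raise ValueError(f"sample {s!r} has no observed intensities")
        noise = float(np.percentile(col_obs, percentile))
        missing_now = m.intensities[s].isna()
        if missing_now.any():
            out.intensities.loc[missing_now, s] = noise
    out.imputed = imputed
    return out


def quantifiability_filter(
    m: IntensityMatrix,
    frac: float = 2.0 / 3.0,
    min_peptides: int = 2,
) -> pd.Series:
    """Flag proteins quantifiable under the replicate-presence rule.

    A protein passes iff it is observed in at least ``ceil(frac * n)``
    replicates of *either* condition and is supported by at least
    ``min_peptides`` peptides.  Evaluated on the pre-imputation mask.  The
    default ``frac`` of 2/3 encodes the 67% rule as 4-of-6 replicates.
    """
    if not (0 < frac <= 1):
        raise ValueError("frac must be in (0, 1]")
    obs = m.observed_mask()
    passes = pd.Series(False, index=m.protein_ids)
    for cond in CONDITIONS:
        cols = m.samples_of(cond)
        if len(cols) == 0:
            continue
        need = math.ceil(frac * len(cols) - 1e-9)
        passes |= obs[cols].sum(axis=1) >= need
    return passes & (m.peptide_counts >= min_peptides)


_SMALLEST_P = float(np.nextafter(0.0, 1.0))


def _paired_log2_diffs(m: IntensityMatrix) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Return (lpa, ldl, log2 lpa-ldl differences) aligned on pair ids."""
    lpa_cols = m.samples_of("LPA")
    ldl_cols = m.samples_of("LDL")
    lpa = m.intensities[lpa_cols].copy()
    ldl = m.intensities[ldl_cols].copy()
    lpa.columns = m.pair_id[lpa_cols].to_numpy()
    ldl.columns = m.pair_id[ldl_cols].to_numpy()
    ldl = ldl[lpa.columns]
    diffs = np.log2(lpa.to_numpy(dtype=float)) - np.log2(ldl.to_numpy(dtype=float))
    return lpa, ldl, pd.DataFrame(diffs, index=m.protein_ids, columns=lpa.columns)


def paired_ratio_test(m: IntensityMatrix, log_transform: bool = True) -> pd.DataFrame:
    """Paired t-test of LPA vs LDL intensities for every protein.

    Expects a normalized, imputed matrix (no missing cells).  Returns a
    DataFrame indexed by protein id with the natural-scale enrichment
    ratio (mean LPA / mean LDL), the paired t statistic and two-sided P
    (on log2 intensities unless ``log_transform`` is False), the mean and
    variance of the per-pair differences, and a zero-variance flag.

    Degenerate inputs: exactly constant zero differences give P = 1;
    a constant nonzero difference gives the smallest positive float as a
    stand-in P, with ``zero_variance`` set either way.
    """
    if m.intensities.isna().any().any():
        raise ValueError("paired_ratio_test requires an imputed (complete) matrix")
    if m.n_pairs < 2:
        raise ValueError("paired test needs at least 2 pairs")
    lpa, ldl, diffs_log = _paired_log2_diffs(m)
    if log_transform:
        d = diffs_log.to_numpy()
    else:
        d = lpa.to_numpy(dtype=float) - ldl.to_numpy(dtype=float)
    n = d.shape[1]
    mean_d = d.mean(axis=1)
    var_d = d.var(axis=1, ddof=1)
    sd = np.sqrt(var_d)
    zero_var = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean_d / (sd / math.sqrt(n))
        t = np.where(zero_var, np.sign(mean_d) * np.inf, t)
    t = np.where(zero_var & (mean_d == 0), 0.0, t)
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    p = np.where(zero_var, np.where(mean_d == 0, 1.0, _SMALLEST_P), p)
    ratio = lpa.to_numpy(dtype=float).mean(axis=1) / ldl.to_numpy(dtype=float).mean(axis=1)
    return pd.DataFrame(
        {
            "ratio": ratio,
            "t_plain": t,
            "p_plain": p,
            "mean_diff": mean_d,
            "var_diff": var_d,
            "n_pairs": n,
            "zero_variance": zero_var,
        },
        index=m.protein_ids,
    )


def _trigamma_inverse(y: np.ndarray | float) -> np.ndarray:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    y = np.atleast_1d(np.asarray(y, dtype=float))
    x = np.where(y > 1e7, 1.0 / np.sqrt(y), 0.5 + 1.0 / y)
    x = np.where(y < 1e-6, 1.0 / y, x)
    for _ in range(75):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if np.max(np.abs(dif / x)) < 1e-10:
            break
    return x


def fit_moderation(variances: np.ndarray, df: float | np.ndarray) -> ModerationParams:
    """Estimate an inverse-chi-square variance prior by moment matching.

    Matches the mean and spread of log sample variances against the
    theoretical scaled-F marginal, solving for the prior degrees of
    freedom ``d0`` and prior variance ``s0_sq``.  When the observed spread
    of log variances does not exceed what the residual degrees of freedom
    alone explain, ``d0`` is reported as ``inf`` (complete shrinkage).
    """
    variances = np.asarray(variances, dtype=float)
    ok = np.isfinite(variances) & (variances > 0)
    variances = variances[ok]
    if variances.size < 10:
        raise ValueError("need at least 10 finite positive variances to fit the prior")
    if np.isscalar(df):
        df_arr = np.full(variances.size, df, dtype=float)
    else:
        df_arr = np.asarray(df, dtype=float)[ok]
    if np.any(df_arr <= 0):
        raise ValueError("residual df must be positive")
    z = np.log(variances)
    e = z - special.digamma(df_arr / 2.0) + np.log(df_arr / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1))
    if e_var < 1e-15:
        # literally identical variances: no sampling spread to explain,
        # so the common variance itself is the prior
        return ModerationParams(d0=float("inf"), s0_sq=float(np.exp(np.mean(z))),
                                residual_df=float(np.mean(df_arr)))
    excess = e_var - float(np.mean(special.polygamma(1, df_arr / 2.0)))
    if excess > 0:
        d0 = float(2.0 * _trigamma_inverse(excess)[0])
        s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = float("inf")
        s0_sq = float(np.exp(e_mean))
    return ModerationParams(d0=d0, s0_sq=s0_sq, residual_df=float(np.mean(df_arr)))


def moderated_test(results: pd.DataFrame, params: ModerationParams) -> pd.DataFrame:
    """Add moderated t statistics to a :func:`paired_ratio_test` frame.

    Posterior variance ``(d0*s0_sq + df*s^2) / (d0 + df)``; the moderated
    t uses it in place of the sample variance and is referred to a t
    distribution with ``d0 + df`` degrees of freedom (standard normal in
    the ``d0 = inf`` limit).  ``d0 = 0`` reproduces the plain t exactly.
    """
    out = results.copy()
    n = out["n_pairs"].to_numpy(dtype=float)
    df_res = n - 1.0
    s2 = out["var_diff"].to_numpy(dtype=float)
    d0, s0 = params.d0, params.s0_sq
    if math.isinf(d0):
        s2_post = np.full_like(s2, s0)
        df_total = np.full_like(s2, np.inf)
    else:
        s2_post = (d0 * s0 + df_res * s2) / (d0 + df_res)
        df_total = d0 + df_res
    zero = s2_post == 0
    mean_d = out["mean_diff"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = mean_d / np.sqrt(s2_post / n)
        t_mod = np.where(zero, np.where(mean_d == 0, 0.0, np.sign(mean_d) * np.inf), t_mod)
    p_mod = 2.0 * stats.t.sf(np.abs(t_mod), df=df_total)
    p_mod = np.where(zero, np.where(mean_d == 0, 1.0, _SMALLEST_P), p_mod)
    out["s2_post"] = s2_post
    out["t_mod"] = t_mod
    out["p_mod"] = p_mod
    out["df_total"] = df_total
    return out


def bh_adjust(p: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P values (q values).

    ``q_(i) = min_{j >= i} m * p_(j) / j`` on the sorted P values, capped
    at 1; ties inherit the rank-based value.  Input order is preserved.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("P values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def replicate_diff(
    discovery: pd.DataFrame,
    replication: pd.DataFrame,
    alpha: float = 0.05,
    discovery_alpha: float = 1e-4,
    discovery_col: str | None = None,
) -> pd.DataFrame:
    """Cross-phase replication of differential-enrichment calls.

    Both frames must be indexed by protein id and carry ``ratio`` and
    ``p`` (or ``q``) columns.  A protein replicates iff it is significant
    in the discovery phase (``discovery_col`` below ``discovery_alpha``;
    the column defaults to ``q`` when present, else ``p``), its
    replication P is below ``alpha``, and the enrichment direction
    (ratio above vs below 1) agrees between phases.

    Returns the replicated subset of the discovery frame with a
    ``direction`` column (``"LPA"`` for ratio > 1, ``"LDL"`` otherwise).
    """
    if discovery.empty:
        out = discovery.copy()
        out["direction"] = pd.Series(dtype=str)
        return out
    if discovery_col is None:
        discovery_col = "q" if "q" in discovery.columns else "p"
    common = discovery.index.intersection(replication.index)
    disc = discovery.loc[common]
    repl = replication.loc[common]
    sig_disc = disc[discovery_col] < discovery_alpha
    sig_repl = repl["p"] < alpha
    same_dir = (disc["ratio"] > 1) == (repl["ratio"] > 1)
    keep = sig_disc & sig_repl & same_dir
    out = disc.loc[keep].copy()
    out["direction"] = np.where(out["ratio"] > 1, "LPA", "LDL")
    return out


def run_lfq_pipeline(
    m: IntensityMatrix,
    frac: float = 2.0 / 3.0,
    min_peptides: int = 2,
    log_transform: bool = True,
    percentile: float = 1.0,
) -> pd.DataFrame:
    """Full differential-enrichment pipeline on a raw intensity matrix.

    Normalizes, evaluates quantifiability on the raw mask, imputes,
    runs the paired test on the quantifiable subset, fits and applies
    variance moderation, and BH-adjusts both the plain and moderated P
    values.  Returns one row per protein; non-quantifiable proteins keep
    NaN statistics and ``quantifiable = False``.
    """
    quant = quantifiability_filter(m, frac=frac, min_peptides=min_peptides)
    obs = m.observed_mask()
    normed = median_normalize(m)
    imputed = impute_first_percentile(normed, percentile=percentile)
    stat_cols = [
        "ratio", "t_plain", "p_plain", "q_plain", "t_mod", "p_mod", "q_mod",
        "mean_diff", "var_diff", "s2_post",
    ]
    out = pd.DataFrame(index=m.protein_ids)
    out["n_obs_lpa"] = obs[m.samples_of("LPA")].sum(axis=1)
    out["n_obs_ldl"] = obs[m.samples_of("LDL")].sum(axis=1)
    out["quantifiable"] = quant
    if quant.sum() == 0:
        for col in stat_cols:
            out[col] = np.nan
        out["zero_variance"] = False
        return out
    sub = IntensityMatrix(
        intensities=imputed.intensities.loc[quant],
        condition=imputed.condition,
        pair_id=imputed.pair_id,
        peptide_counts=imputed.peptide_counts.loc[quant],
        imputed=None if imputed.imputed is None else imputed.imputed.loc[quant],
    )
    res = paired_ratio_test(sub, log_transform=log_transform)
    finite_var = res["var_diff"] > 0
    if finite_var.sum() >= 10:
        params = fit_moderation(
            res.loc[finite_var, "var_diff"].to_numpy(), df=float(res["n_pairs"].iloc[0] - 1)
        )
    else:  # too few proteins to fit a prior: fall back to no moderation
        params = ModerationParams(d0=1e-12, s0_sq=1.0, residual_df=float(res["n_pairs"].iloc[0] - 1))
    res = moderated_test(res, params)
    res["q_plain"] = bh_adjust(res["p_plain"].to_numpy())
    res["q_mod"] = bh_adjust(res["p_mod"].to_numpy())
    full = res.reindex(m.protein_ids)
    for col in stat_cols:
        out[col] = full[col].astype(float)
    zv = full["zero_variance"].to_numpy(dtype=object)
    out["zero_variance"] = np.array([bool(v) if v == v and v is not None else False for v in zv])
    return out
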