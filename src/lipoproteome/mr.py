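"""Two-sample Mendelian-randomization screen over a protein panel.

Instrument construction (genome-wide-significance filtering and greedy LD
clumping), allele harmonization of exposure and outcome summary
statistics, per-variant Wald ratios, fixed-effect inverse-variance
weighting, and Bonferroni screening across the panel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

SUMMARY_COLUMNS = ["variant_id", "effect_allele", "other_allele", "beta", "se"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

__all__ = [
    "InstrumentSet",
    "IVWResult",
    "select_instruments",
    "ld_clump",
    "harmonize",
    "wald_ratio",
    "ivw",
    "bonferroni_threshold",
    "screen",
]


@dataclass
class InstrumentSet:
    """A named, LD-independent set of exposure instruments."""

    exposure_name: str
    variants: pd.DataFrame
    p_threshold: float = 5e-8
    r2_threshold: float = 0.1

    def __post_init__(self) -> None:
        missing = [c for c in SUMMARY_COLUMNS if c not in self.variants.columns]
        if missing:
            raise ValueError(f"instrument table lacks columns: {missing}")
        if self.variants["se"].le(0).any():
            raise ValueError("instrument SEs must be positive")
        same = self.variants["effect_allele"] == self.variants["other_allele"]
        if same.any():
            raise ValueError("effect and other allele must differ")

    def __len__(self) -> int:
        return len(self.variants)


@dataclass(frozen=True)
class IVWResult:
    theta: float
    se: float
    z: float
    pvalue: float
    n_snps: int
    q_stat: float = field(default=float("nan"))


def select_instruments(assocs: pd.DataFrame, p_threshold: float = 5e-8) -> pd.DataFrame:
    """Keep rows with association P strictly below the threshold.

    A P exactly equal to the threshold is excluded (strict ``<``).  Row
    order is preserved.
    """
    if "pvalue" not in assocs.columns:
        raise ValueError("select_instruments needs a 'pvalue' column")
    return assocs.loc[assocs["pvalue"] < p_threshold].copy()


def ld_clump(assocs: pd.DataFrame, ld: pd.DataFrame, r2_threshold: float = 0.1) -> pd.DataFrame:
    """Greedy LD clumping: keep the most significant variant of each clump.

    Repeatedly takes the remaining variant with the smallest P value and
    discards every remaining variant with r^2 >= threshold against it.
    All retained pairs end up with pairwise r^2 below the threshold.
    ``ld`` must be a symmetric matrix with unit diagonal, indexed by
    variant id on both axes and covering every variant in ``assocs``.
    """
    ids = assocs["variant_id"].tolist()
    missing = [v for v in ids if v not in ld.index or v not in ld.columns]
    if missing:
        raise ValueError(f"LD matrix lacks variants: {missing[:5]}")
    sub = ld.loc[ids, ids].to_numpy(dtype=float)
    if sub.shape[0] != len(ids) or not np.allclose(sub, sub.T, atol=1e-8):
        raise ValueError("LD matrix must be symmetric over the clumped variants")
    if not np.allclose(np.diag(sub), 1.0, atol=1e-6):
        raise ValueError("LD matrix diagonal must be 1")
    if "pvalue" not in assocs.columns:
        raise ValueError("ld_clump needs a 'pvalue' column")
    order = np.argsort(assocs["pvalue"].to_numpy(), kind="mergesort")
    alive = np.ones(len(ids), dtype=bool)
    kept: list[int] = []
    for idx in order:
        if not alive[idx]:
            continue
        kept.append(idx)
        alive &= sub[idx] < r2_threshold
        alive[idx] = False
    kept_sorted = sorted(kept)
    return assocs.iloc[kept_sorted].copy()


def _is_palindromic(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(a1.upper()) == a2.upper()


def harmonize(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    allow_strand_flip: bool = True,
    palindromic_eaf_margin: float = 0.08,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Align outcome effect alleles to the exposure's reference.

    Variants are merged on ``variant_id``.  Matching alleles pass through;
    swapped alleles negate the outcome beta; strand-complement matches are
    resolved when ``allow_strand_flip``; anything else is dropped.
    Palindromic variants (A/T, C/G) are kept only when both tables carry
    an ``eaf`` column and both frequencies sit farther than
    ``palindromic_eaf_margin`` from 0.5 — the betas are then aligned by
    frequency concordance — and are dropped otherwise.

    Returns ``(aligned, dropped)``; the aligned frame carries exposure
    columns suffixed ``_x``, harmonized outcome columns suffixed ``_y``,
    and outcome alleles rewritten to the exposure's, which makes the
    operation idempotent.  Drops are data, not errors: the dropped frame
    has a ``drop_reason`` column.
    """
    merged = exposure.merge(outcome, on="variant_id", suffixes=("_x", "_y"))
    aligned_rows, dropped_rows = [], []
    has_eaf = "eaf_x" in merged.columns and "eaf_y" in merged.columns
    for _, row in merged.iterrows():
        ea_x, oa_x = str(row["effect_allele_x"]).upper(), str(row["other_allele_x"]).upper()
        ea_y, oa_y = str(row["effect_allele_y"]).upper(), str(row["other_allele_y"]).upper()
        flip = None  # None -> drop; False -> keep sign; True -> negate
        if _is_palindromic(ea_x, oa_x):
            # Allele labels cannot resolve strand for A/T and C/G variants;
            # alignment rests entirely on allele-frequency concordance.
            if {ea_y, oa_y} != {ea_x, oa_x}:
                reason = "palindromic_incompatible_alleles"
            elif has_eaf and not (math.isnan(row["eaf_x"]) or math.isnan(row["eaf_y"])):
                fx, fy = float(row["eaf_x"]), float(row["eaf_y"])
                f_aligned = fy if ea_y == ea_x else 1.0 - fy
                if abs(fx - 0.5) > palindromic_eaf_margin and abs(f_aligned - 0.5) > palindromic_eaf_margin:
                    base_flip = ea_y != ea_x  # label swap relative to exposure
                    freq_flip = (fx > 0.5) != (f_aligned > 0.5)  # labels read off the wrong strand
                    flip = base_flip ^ freq_flip
                else:
                    reason = "palindromic_ambiguous_eaf"
            else:
                reason = "palindromic_no_eaf"
        elif (ea_y, oa_y) == (ea_x, oa_x):
            flip = False
        elif (ea_y, oa_y) == (oa_x, ea_x):
            flip = True
        elif allow_strand_flip and (ea_y, oa_y) == (_COMPLEMENT.get(ea_x), _COMPLEMENT.get(oa_x)):
            flip = False
        elif allow_strand_flip and (ea_y, oa_y) == (_COMPLEMENT.get(oa_x), _COMPLEMENT.get(ea_x)):
            flip = True
        else:
            reason = "incompatible_alleles"
        if flip is None:
            rec = row.copy()
            rec["drop_reason"] = reason
            dropped_rows.append(rec)
            continue
        rec = row.copy()
        if flip:
            rec["beta_y"] = -rec["beta_y"]
            if has_eaf and not math.isnan(rec["eaf_y"]):
                rec["eaf_y"] = 1.0 - rec["eaf_y"]
        rec["effect_allele_y"] = ea_x
        rec["other_allele_y"] = oa_x
        aligned_rows.append(rec)
    aligned = pd.DataFrame(aligned_rows, columns=list(merged.columns))
    dropped = pd.DataFrame(dropped_rows, columns=list(merged.columns) + ["drop_reason"])
    return aligned.reset_index(drop=True), dropped.reset_index(drop=True)


def wald_ratio(bx: float, by: float, se_y: float, se_x: float | None = None,
               second_order: bool = False) -> tuple[float, float]:
    """Per-variant causal estimate ``by/bx`` with first-order SE.

    The default SE is ``se_y / |bx|`` (exposure uncertainty ignored);
    ``second_order=True`` adds the exposure term
    ``sqrt(se_y^2/bx^2 + by^2 se_x^2 / bx^4)``.
    """
    if bx == 0:
        raise ValueError("wald_ratio undefined for bx = 0; exclude the variant upstream")
    theta = by / bx
    if second_order:
        if se_x is None:
            raise ValueError("second_order SE needs se_x")
        se = math.sqrt(se_y**2 / bx**2 + by**2 * se_x**2 / bx**4)
    else:
        se = se_y / abs(bx)
    return (float(theta), float(se))


def ivw(thetas: np.ndarray, ses: np.ndarray, random_effects: bool = False) -> IVWResult:
    """Fixed-effect inverse-variance-weighted meta-analysis of Wald ratios.

    Weights are ``se^-2``; the estimate is the weighted mean, its SE
    ``(sum w)^-1/2``, and P comes from the standard normal.  With
    ``random_effects=True`` the SE is inflated multiplicatively by
    ``sqrt(max(1, Q/(k-1)))`` (Cochran's Q heterogeneity).
    """
    thetas = np.asarray(thetas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if thetas.size == 0:
        raise ValueError("ivw needs at least one Wald ratio")
    if np.any(ses <= 0):
        raise ValueError("all SEs must be positive")
    w = ses**-2
    theta = float(np.sum(w * thetas) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    q = float(np.sum(w * (thetas - theta) ** 2))
    if random_effects and thetas.size > 1:
        se *= math.sqrt(max(1.0, q / (thetas.size - 1)))
    z = theta / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return IVWResult(theta=theta, se=se, z=float(z), pvalue=p, n_snps=int(thetas.size), q_stat=q)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise significance threshold ``alpha / m``."""
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def screen(
    instruments: InstrumentSet,
    panel: dict[str, pd.DataFrame],
    alpha: float = 0.05,
    m: int | None = None,
    random_effects: bool = False,
    allow_strand_flip: bool = True,
) -> pd.DataFrame:
    """IVW-MR of one exposure against every protein in the panel.

    For each protein: harmonize the outcome summary statistics to the
    instrument set, form per-variant Wald ratios, meta-analyse by IVW,
    and flag Bonferroni significance at ``alpha / m`` (``m`` defaults to
    the panel size).  Proteins with no harmonizable instruments are kept
    with NaN statistics rather than dropped.  The output is sorted by P
    and carries volcano-ready ``theta`` and ``neg_log10_p`` columns.
    """
    if not panel:
        raise ValueError("panel must be non-empty")
    m_eff = len(panel) if m is None else m
    threshold = bonferroni_threshold(alpha, m_eff)
    rows = []
    for protein, outcome in panel.items():
        aligned, _ = harmonize(instruments.variants, outcome, allow_strand_flip=allow_strand_flip)
        aligned = aligned.loc[aligned["beta_x"] != 0]
        if aligned.empty:
            rows.append({
                "protein": protein, "theta": float("nan"), "se": float("nan"),
                "z": float("nan"), "pvalue": float("nan"), "n_snps": 0,
                "passes_bonferroni": False, "neg_log10_p": float("nan"),
            })
            continue
        ratios = [
            wald_ratio(r.beta_x, r.beta_y, r.se_y)
            for r in aligned.itertuples()
        ]
        thetas, ses = zip(*ratios)
        res = ivw(np.array(thetas), np.array(ses), random_effects=random_effects)
        rows.append({
            "protein": protein, "theta": res.theta, "se": res.se, "z": res.z,
            "pvalue": res.pvalue, "n_snps": res.n_snps,
            "passes_bonferroni": bool(res.pvalue < threshold),
            "neg_log10_p": -math.log10(res.pvalue) if res.pvalue > 0 else float("inf"),
        })
    out = pd.DataFrame(rows).set_index("protein")
    return out.sort_values("pvalue", kind="mergesort")
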