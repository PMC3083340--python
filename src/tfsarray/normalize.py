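"""From raw dye-swap hybridizations to per-probe fold-changes and p-values.

A competitive two-color hybridization measures, per probe, the fluorescence
of the treatment and reference samples labeled with two dyes.  The analysis
chain per hybridization is

1. feature exclusion — drop features saturated in *both* channels or flagged
   as non-uniformity outliers in *either* channel;
2. log-ratio computation — M_raw = log2(I_A / I_B) with a pseudo-intensity
   added to both channels, negated for reverse-orientation hybridizations so
   that the treatment sample is always the numerator;
3. LOWESS normalization — the smooth intensity-dependent dye bias is
   estimated by locally weighted regression of M on the mean log-intensity
   A = (log2 I_A + log2 I_B) / 2 and *subtracted* (a flat array reduces this
   to a constant shift, i.e. linear normalization is the degenerate case).

Replicate hybridizations of one comparison are then combined by
error-weighted averaging.  Each measurement is assigned a model variance

    sigma_i^2(A) = max(sigma_floor^2,
                      2 * [(sigma_mult/ln 2)^2 + (sigma_add / (2^A * ln 2))^2])

i.e. a multiplicative (proportional) component plus an additive (background)
component that dominates at low intensity — monotone non-increasing in A with
a floor.  The combined estimate is the inverse-variance weighted mean; its
standard error takes the max of the model-based and the empirical weighted
variance of the replicates so over-dispersed probes are not anti-conservative;
p-values are two-sided normal tails of z = xbar / SE.  No multiple-testing
correction is applied to per-probe p-values; the expected-by-chance count and
apparent FDR are reported downstream instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

LN2 = np.log(2.0)

#: columns required of a hybridization table
HYB_COLUMNS = [
    "probe_id",
    "gene_id",
    "channel_A_intensity",
    "channel_B_intensity",
    "dye_orientation",
    "flag_saturated_A",
    "flag_saturated_B",
    "flag_nonuniform_A",
    "flag_nonuniform_B",
]

ORIENTATIONS = ("forward", "reverse")


@dataclass(frozen=True)
class ErrorModelParams:
    """Parameters of the replicate-combination error model.

    sigma_add       : additive (background) intensity noise s.d., intensity units
    sigma_mult      : multiplicative intensity noise s.d., natural-log scale
    sigma_floor     : lower bound on the per-measurement s.d. of M (log2 units)
    pseudo_intensity: offset added to both channels before logging
    lowess_span     : LOWESS span (fraction of probes per local fit)
    min_probes      : minimum usable features required to normalize an array
    """

    sigma_add: float = 30.0
    sigma_mult: float = 0.15
    sigma_floor: float = 0.05
    pseudo_intensity: float = 1.0
    lowess_span: float = 0.3
    min_probes: int = 50

    def __post_init__(self) -> None:
        if self.sigma_add < 0 or self.sigma_mult < 0 or self.sigma_floor <= 0:
            raise ValueError("noise parameters must be non-negative (floor positive)")
        if not 0 < self.lowess_span <= 1:
            raise ValueError(f"lowess_span must be in (0, 1], got {self.lowess_span}")


def exclusion_reasons(hyb: pd.DataFrame) -> pd.Series:
    """Per-feature exclusion reason: "saturated_both", "nonuniform", or "ok".

    A feature is excluded iff it is saturated in both channels, or flagged as
    a non-uniformity outlier in either channel; saturation in a single
    channel alone is not an exclusion.
    """
    sat_both = hyb["flag_saturated_A"].astype(bool) & hyb["flag_saturated_B"].astype(bool)
    nonuni = hyb["flag_nonuniform_A"].astype(bool) | hyb["flag_nonuniform_B"].astype(bool)
    reason = pd.Series("ok", index=hyb.index, dtype=object)
    reason[nonuni] = "nonuniform"
    reason[sat_both] = "saturated_both"  # takes precedence when both apply
    return reason


def filter_features(hyb: pd.DataFrame) -> pd.DataFrame:
    """Drop excluded features (see :func:`exclusion_reasons`)."""
    return hyb[exclusion_reasons(hyb) == "ok"].reset_index(drop=True)


def lowess_normalize(
    hyb: pd.DataFrame,
    span: float | None = None,
    params: ErrorModelParams | None = None,
) -> pd.DataFrame:
    """Orientation-corrected, LOWESS-detrended log2 ratios for one array.

    Returns one row per input feature with columns ``probe_id, gene_id, A, M,
    usable, exclusion_reason``; excluded features keep their row with
    ``usable=False`` and NaN M/A.  The LOWESS trend (one robustifying
    iteration) is fit on usable features only and subtracted.

    Raises ``ValueError`` if fewer than ``params.min_probes`` usable features
    remain or the span is outside (0, 1].
    """
    p = params or ErrorModelParams()
    span = p.lowess_span if span is None else span
    if not 0 < span <= 1:
        raise ValueError(f"span must be in (0, 1], got {span}")

    reason = exclusion_reasons(hyb)
    usable = (reason == "ok").to_numpy()
    n_usable = int(usable.sum())
    if n_usable < p.min_probes:
        raise ValueError(
            f"only {n_usable} usable features; need at least {p.min_probes}"
        )

    orientation = hyb["dye_orientation"].to_numpy()
    bad = ~np.isin(orientation, ORIENTATIONS)
    if bad.any():
        raise ValueError(f"invalid dye_orientation values: {set(orientation[bad])}")

    ia = hyb["channel_A_intensity"].to_numpy(dtype=float) + p.pseudo_intensity
    ib = hyb["channel_B_intensity"].to_numpy(dtype=float) + p.pseudo_intensity
    if np.any(ia <= 0) or np.any(ib <= 0):
        raise ValueError("intensities must be non-negative")

    la, lb = np.log2(ia), np.log2(ib)
    a_val = 0.5 * (la + lb)
    m_raw = la - lb
    # orientation correction: treatment is channel A on forward arrays,
    # channel B on reverse arrays — make treatment the numerator everywhere
    m_raw = np.where(orientation == "reverse", -m_raw, m_raw)

    a_use, m_use = a_val[usable], m_raw[usable]
    trend = _robust_trend(m_use, a_use, span, min_points=p.min_probes)
    m_norm = np.full(len(hyb), np.nan)
    m_norm[usable] = m_use - trend

    out = pd.DataFrame(
        {
            "probe_id": hyb["probe_id"].to_numpy(),
            "gene_id": hyb["gene_id"].to_numpy(),
            "A": np.where(usable, a_val, np.nan),
            "M": m_norm,
            "usable": usable,
            "exclusion_reason": reason.to_numpy(),
        }
    )
    return out


def _robust_trend(
    m: np.ndarray, a: np.ndarray, span: float, min_points: int
) -> np.ndarray:
    """LOWESS trend of M on A with outlier-resistant two-stage fitting.

    A first LOWESS pass flags outliers by MAD of the residuals; the trend is
    then refit on inliers only and evaluated everywhere by interpolation.
    This keeps strongly regulated genes from pulling the bias curve toward
    themselves, including in the degenerate noise-free case where the
    residual MAD collapses to zero.
    """
    delta = 0.01 * (a.max() - a.min()) if len(a) > 1 else 0.0
    first = _sm_lowess(m, a, frac=span, it=0, delta=delta, return_sorted=True)
    fit0 = np.interp(a, first[:, 0], first[:, 1])
    resid = m - fit0
    med = np.median(resid)
    mad = np.median(np.abs(resid - med))
    if mad > 0:
        inlier = np.abs(resid - med) <= 6.0 * 1.4826 * mad
    else:
        inlier = np.abs(resid - med) <= 1e-12
    if inlier.sum() < max(min_points, 2):
        inlier = np.ones(len(m), dtype=bool)
    second = _sm_lowess(
        m[inlier], a[inlier], frac=span, it=1, delta=delta, return_sorted=True
    )
    return np.interp(a, second[:, 0], second[:, 1])


def model_variance(a_val: np.ndarray, params: ErrorModelParams) -> np.ndarray:
    """Model variance of a single log2-ratio measurement at mean intensity A."""
    intensity = np.exp2(np.asarray(a_val, dtype=float))
    per_channel = (params.sigma_mult / LN2) ** 2 + (
        params.sigma_add / (intensity * LN2)
    ) ** 2
    return np.maximum(2.0 * per_channel, params.sigma_floor**2)


def combine_replicates(
    ratios: Sequence[pd.DataFrame],
    params: ErrorModelParams | None = None,
) -> pd.DataFrame:
    """Error-weighted combination of replicate arrays into one comparison result.

    ``ratios`` are normalized tables from :func:`lowess_normalize` (any mix
    of dye orientations and pools of one comparison).  Probes with no usable
    measurement in any replicate get no result row.

    Per probe: xbar is the inverse-model-variance weighted mean of the M's;
    SE^2 = max(1 / sum(w), empirical weighted variance / n); p is the
    two-sided normal tail of xbar/SE; the signed fold is 2^xbar for
    xbar >= 0, else -2^(-xbar).
    """
    p = params or ErrorModelParams()
    if not ratios:
        raise ValueError("no replicate tables given")
    df = pd.concat([r[r["usable"]] for r in ratios], ignore_index=True)
    if df.empty:
        raise ValueError("no usable measurements in any replicate")
    m = df["M"].to_numpy(dtype=float)
    if not np.all(np.isfinite(m)):
        raise ValueError("non-finite M among usable measurements")

    w = 1.0 / model_variance(df["A"].to_numpy(), p)
    df = df.assign(_w=w, _wm=w * m)

    grp = df.groupby("probe_id", sort=True)
    sw = grp["_w"].sum()
    n_used = grp.size()
    xbar = grp["_wm"].sum() / sw

    dev2 = df["_w"].to_numpy() * (m - df["probe_id"].map(xbar).to_numpy()) ** 2
    swdev = df.assign(_d=dev2).groupby("probe_id", sort=True)["_d"].sum()
    n_arr = n_used.to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        s2 = np.where(n_arr > 1, swdev.to_numpy() / sw.to_numpy() * n_arr / (n_arr - 1), 0.0)
    se = np.sqrt(np.maximum(1.0 / sw.to_numpy(), s2 / n_arr))

    x = xbar.to_numpy()
    z = x / se
    pval = np.clip(2.0 * stats.norm.sf(np.abs(z)), 1e-300, 1.0)
    fold = np.where(x >= 0, np.exp2(x), -np.exp2(-x))

    gene = grp["gene_id"].first()
    out = pd.DataFrame(
        {
            "probe_id": xbar.index.to_numpy(),
            "gene_id": gene.to_numpy(),
            "log2_ratio": x,
            "se": se,
            "p": pval,
            "fold": fold,
            "n_used": n_used.to_numpy(),
        }
    ).reset_index(drop=True)
    return out


def process_comparison(
    hybs: Iterable[pd.DataFrame],
    params: ErrorModelParams | None = None,
) -> pd.DataFrame:
    """Normalize each replicate hybridization of a comparison and combine them."""
    p = params or ErrorModelParams()
    normalized = [lowess_normalize(h, params=p) for h in hybs]
    return combine_replicates(normalized, p)
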