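"""Age association of signature activities.

Per (signature, cancer type) stratum: values lying more than three
standard deviations from the stratum mean — in age or in attributed
mutation count — are removed (single pass), a robust linear regression
(IRLS with Tukey bisquare weights, tuning constant 4.685, scale
1.4826 x MAD, the classic ``robustfit`` defaults) estimates the slope in
mutations per year, an F test asks whether the slope differs from zero,
and the p-values from all strata are jointly Benjamini-Hochberg corrected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .extraction import ExposureMatrix


def remove_outliers(values) -> np.ndarray:
    """Indices within three standard deviations of the mean (single pass).

    Mean and sd come from the full input; boundary values exactly at
    3 sd are kept (non-strict).  A constant list (sd = 0) keeps everything.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 values for outlier screening")
    mu, sd = x.mean(), x.std(ddof=1)
    if sd == 0:
        return np.arange(x.size)
    return np.flatnonzero(np.abs(x - mu) <= 3.0 * sd)


@dataclass
class RobustFitResult:
    slope: float
    intercept: float
    p_value: float
    weights: np.ndarray
    n: int


def robust_fit(age, exposure) -> RobustFitResult:
    """Robust linear regression of exposure on age with a slope F test.

    IRLS with bisquare weights (c = 4.685, scale = 1.4826 MAD); the slope
    F test (F = (slope / se)^2 on 1 and n-2 df) uses the robust standard
    error from the IRLS covariance, which keeps the test calibrated even
    though the weights are estimated from the data.
    """
    from scipy.stats import f as f_dist

    x = np.asarray(age, dtype=float)
    y = np.asarray(exposure, dtype=float)
    if x.size != y.size:
        raise ValueError("age and exposure must have equal length")
    if x.size < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(x) == 0:
        raise ValueError("age has no variance; slope is undefined")
    X = sm.add_constant(x)
    rlm = sm.RLM(
        y, X, M=sm.robust.norms.TukeyBiweight(c=4.685),
    ).fit(scale_est="mad")
    f_stat = (rlm.params[1] / rlm.bse[1]) ** 2
    return RobustFitResult(
        slope=float(rlm.params[1]),
        intercept=float(rlm.params[0]),
        p_value=float(f_dist.sf(f_stat, 1, x.size - 2)),
        weights=np.asarray(rlm.weights),
        n=int(x.size),
    )


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class AgeScanResult:
    results: pd.DataFrame  # signature, cancer_type, n, slope, intercept, p, q
    skipped: pd.DataFrame  # signature, cancer_type, reason


def age_scan(
    exposures: ExposureMatrix,
    metadata: pd.DataFrame,
    min_n: int = 4,
) -> AgeScanResult:
    """Slope/p/q per (signature, cancer type) stratum.

    ``metadata`` must carry ``sample_id``, ``age`` and ``cancer_type``.
    Outliers in age and in exposure are removed as the union of the two
    screens; strata left with fewer than ``min_n`` samples are skipped and
    logged.  BH correction is applied jointly across all strata and
    signatures (one family).  Results are order-invariant in the samples.
    """
    meta = metadata.set_index("sample_id") if "sample_id" in metadata.columns else metadata
    missing = [s for s in exposures.samples if s not in meta.index]
    if missing:
        raise ValueError(f"samples without metadata: {missing[:5]}")
    rows, skipped = [], []
    for ctype, group in sorted(meta.loc[exposures.samples].groupby("cancer_type")):
        samples = sorted(group.index)
        ages = meta.loc[samples, "age"].to_numpy(dtype=float)
        for signature in exposures.activities.index:
            expo = exposures.activities.loc[signature, samples].to_numpy(dtype=float)
            if len(samples) < 3:
                skipped.append((signature, ctype, f"stratum of {len(samples)} samples"))
                continue
            keep = np.intersect1d(remove_outliers(ages), remove_outliers(expo))
            if keep.size < min_n:
                skipped.append(
                    (signature, ctype, f"{keep.size} samples after outlier removal")
                )
                continue
            try:
                fit = robust_fit(ages[keep], expo[keep])
            except ValueError as exc:
                skipped.append((signature, ctype, str(exc)))
                continue
            rows.append(
                {
                    "signature": signature,
                    "cancer_type": ctype,
                    "n": fit.n,
                    "slope": fit.slope,
                    "intercept": fit.intercept,
                    "p": fit.p_value,
                }
            )
    results = pd.DataFrame(rows, columns=["signature", "cancer_type", "n", "slope", "intercept", "p"])
    if len(results):
        results["q"] = bh_adjust(results["p"].to_numpy())
    else:
        results["q"] = pd.Series(dtype=float)
    skip_df = pd.DataFrame(skipped, columns=["signature", "cancer_type", "reason"])
    return AgeScanResult(results=results, skipped=skip_df)
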