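"""End-of-induction minimal residual disease (MRD) analysis.

MRD is the fraction of residual leukaemic cells measured by qPCR at the
end of induction.  It is approximately log-normal, left-censored at a
detection floor (reported as 0), and missing for a subset of patients.
This module provides the standard categorisation (the bins used in
stratified outcome tables), a continuous per-log-reduction Cox effect,
the threshold-scan that locates the most discriminative MRD cutoff for a
survival endpoint, and per-trisomy distribution-shift tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import _coxfast
from .karyotype import CHROMOSOMES
from .survival import CoxResult, logrank

#: Detection floor: fractions below this read 0 (0.001% of cells).
DEFAULT_FLOOR = 1e-5

#: Category labels (percentages of cells), in increasing order.
MRD_CATEGORIES = ("0", "0 to <0.01", "0.01 to <0.1", "0.1 to <1.0", ">=1.0")
MRD_NOT_AVAILABLE = "not available"

# Bin edges in fraction-of-cells units: 0.01% = 1e-4 etc.
_EDGES = (0.0, 1e-4, 1e-3, 1e-2)


def categorize_mrd(fraction) -> str:
    """Map an MRD fraction to its reporting bin.

    Bins (as percentages): 0, (0, 0.01), [0.01, 0.1), [0.1, 1.0), >=1.0;
    the boundary 0.01% belongs to the [0.01, 0.1) bin.  Missing values
    map to ``"not available"``.
    """
    if fraction is None or (isinstance(fraction, float) and np.isnan(fraction)):
        return MRD_NOT_AVAILABLE
    f = float(fraction)
    if f < 0:
        raise ValueError("MRD fraction must be non-negative")
    if f == 0:
        return MRD_CATEGORIES[0]
    if f < _EDGES[1]:
        return MRD_CATEGORIES[1]
    if f < _EDGES[2]:
        return MRD_CATEGORIES[2]
    if f < _EDGES[3]:
        return MRD_CATEGORIES[3]
    return MRD_CATEGORIES[4]


def neg_log10_mrd(fraction: np.ndarray, floor: float = DEFAULT_FLOOR) -> np.ndarray:
    """-log10(MRD) with zeros replaced by half the detection floor."""
    f = np.asarray(fraction, dtype=float)
    return -np.log10(np.maximum(f, floor / 2.0))


def mrd_log_hr(
    cohort: pd.DataFrame,
    endpoint: str = "relapse",
    floor: float = DEFAULT_FLOOR,
) -> CoxResult:
    """Cox effect of MRD per log reduction.

    Fits the endpoint hazard on -log10(MRD), so a hazard ratio below 1
    encodes benefit per tenfold MRD reduction.  Zeros are replaced by
    half the detection floor before the log transform; missing MRD rows
    are dropped.
    """
    mrd = cohort["mrd_fraction"]
    mask = mrd.notna().to_numpy()
    if mask.sum() == 0:
        raise ValueError("all MRD values are missing")
    x = neg_log10_mrd(mrd[mask].to_numpy(), floor)
    if np.std(x) == 0:
        raise ValueError("MRD is constant across patients")
    t = cohort.loc[mask, f"time_{endpoint}"].to_numpy(dtype=float)
    e = cohort.loc[mask, f"ind_{endpoint}"].to_numpy()
    if int(np.asarray(e).astype(bool).sum()) < 10:
        raise ValueError("fewer than 10 events with non-missing MRD")
    fit = _coxfast.fit(x[:, None], t, e)
    se = fit.se[0]
    z = fit.beta[0] / se
    return CoxResult(
        covariate="neg_log10_mrd",
        hr=float(np.exp(fit.beta[0])),
        ci95=(float(np.exp(fit.beta[0] - 1.96 * se)),
              float(np.exp(fit.beta[0] + 1.96 * se))),
        p=float(2 * stats.norm.sf(abs(z))),
        log_partial_likelihood=float(fit.loglik),
        n_events=fit.n_events,
    )


@dataclass
class ThresholdScanResult:
    """Candidate MRD cutoffs with their discrimination statistics."""

    scan: pd.DataFrame          # cutoff, chi2, p, n_low, n_high
    optimal: float              # cutoff maximising the log-rank statistic
    flat: bool                  # True when no cutoff reaches chi2 >= 3.84


def scan_thresholds(
    cohort: pd.DataFrame,
    endpoint: str = "relapse",
    min_arm_fraction: float = 0.10,
) -> ThresholdScanResult:
    """Scan all observed MRD values as candidate risk cutoffs.

    Every unique non-missing MRD value is tried as a dichotomy (MRD >=
    cutoff vs below) and scored by the log-rank statistic on the chosen
    endpoint.  Cutoffs leaving less than ``min_arm_fraction`` of the
    non-missing patients in either arm are dropped.  The optimum is the
    admissible cutoff with the largest statistic (ties broken toward the
    smaller cutoff); a scan whose best statistic stays below 3.84 (the 5%
    chi-square point) is flagged flat.
    """
    mrd = cohort["mrd_fraction"]
    mask = mrd.notna().to_numpy()
    values = mrd[mask].to_numpy(dtype=float)
    if np.unique(values).size < 2:
        raise ValueError("need at least two distinct non-missing MRD values")
    t = cohort.loc[mask, f"time_{endpoint}"].to_numpy(dtype=float)
    e = cohort.loc[mask, f"ind_{endpoint}"].to_numpy()
    n = values.size

    rows = []
    for cutoff in np.unique(values)[1:]:  # lowest value leaves an empty low arm
        high = values >= cutoff
        n_high = int(high.sum())
        if min(n_high, n - n_high) < min_arm_fraction * n:
            continue
        chi2, p = logrank([(t[~high], e[~high]), (t[high], e[high])])
        rows.append({"cutoff": float(cutoff), "chi2": chi2, "p": p,
                     "n_low": n - n_high, "n_high": n_high})
    if not rows:
        raise ValueError(
            f"no cutoff leaves at least {min_arm_fraction:.0%} of patients in each arm"
        )
    scan = pd.DataFrame(rows).sort_values("cutoff", kind="stable").reset_index(drop=True)
    best = scan["chi2"].max()
    optimal = float(scan.loc[scan["chi2"] >= best - 1e-12, "cutoff"].iloc[0])
    return ThresholdScanResult(scan=scan, optimal=optimal, flat=bool(best < 3.84))


def mrd_distribution_by_trisomy(
    cohort: pd.DataFrame,
    min_stratum: int = 20,
    floor: float = DEFAULT_FLOOR,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Rank-based shift of log-MRD for carriers of each trisomy.

    For every chromosome, compares log10 MRD of carriers against
    non-carriers with a Mann-Whitney test and reports the direction of
    the shift relative to the whole cohort (``higher``/``lower`` medians).
    Chromosomes with fewer than ``min_stratum`` informative patients on
    either side are skipped with a warning.
    """
    mrd = cohort["mrd_fraction"]
    mask = mrd.notna().to_numpy()
    logm = -neg_log10_mrd(mrd[mask].to_numpy(), floor)  # log10 scale
    overall_median = float(np.median(logm))
    rows = []
    for chrom in CHROMOSOMES:
        col = f"gain_{chrom}"
        if col not in cohort.columns:
            continue
        carrier = cohort.loc[mask, col].to_numpy().astype(bool)
        if carrier.all() or not carrier.any():
            warnings.warn(f"chromosome {chrom}: carriers equal the whole cohort "
                          "or are absent; skipped")
            continue
        if carrier.sum() < min_stratum or (~carrier).sum() < min_stratum:
            warnings.warn(f"chromosome {chrom}: stratum too small; skipped")
            continue
        stat, p = stats.mannwhitneyu(logm[carrier], logm[~carrier],
                                     alternative="two-sided")
        med = float(np.median(logm[carrier]))
        rows.append({
            "chromosome": chrom,
            "n_carriers": int(carrier.sum()),
            "median_log10_mrd": med,
            "direction": "higher" if med > overall_median else "lower",
            "p": float(p),
            "significant": bool(p < alpha),
        })
    return pd.DataFrame(rows)
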