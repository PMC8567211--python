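"""Stratified outcome tables and classifier comparisons.

Builds the table-style outputs of a HeH risk analysis: counts and
percentages by risk group with categorical association tests, outcome
rates at a fixed horizon with confidence intervals, hazard ratios of each
risk grouping against the remaining HeH cases (unadjusted and
MRD-adjusted), relapse-capture proportions, and the C-index/AUC
prediction-accuracy comparison between classifiers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from sklearn.metrics import roc_auc_score

from .mrd import neg_log10_mrd
from .survival import concordance, cox_fit, km_fit, rate_at


def round_percent(x: float) -> int:
    """Round a percentage half-up to a whole percent (table convention)."""
    return int(Decimal(str(float(x))).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def percent_of(numerator: int, denominator: int) -> int:
    """Whole-percent share, half-up (e.g. 373 of 456 -> 82)."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return round_percent(100.0 * numerator / denominator)


def categorical_association(table, seed: int = 0, n_mc: int = 100_000) -> float:
    """Exact association p-value for a counts table.

    2x2 tables use Fisher's exact test.  Larger tables use a Monte-Carlo
    exact test (fixed seed): tables are sampled conditionally on the
    margins and the p-value is the probability of a table at most as
    likely as the observed one.
    """
    a = np.asarray(table, dtype=int)
    if a.ndim != 2 or a.shape[0] < 2 or a.shape[1] < 2:
        raise ValueError("need at least a 2x2 table")
    if (a < 0).any():
        raise ValueError("counts must be non-negative")
    if (a.sum(axis=0) == 0).any() or (a.sum(axis=1) == 0).any():
        raise ValueError("empty row or column margin")
    if a.shape == (2, 2):
        return float(stats.fisher_exact(a)[1])

    def log_table_prob(x: np.ndarray) -> float:
        # multivariate hypergeometric probability given both margins
        return float(
            gammaln(x.sum(axis=1) + 1).sum()
            + gammaln(x.sum(axis=0) + 1).sum()
            - gammaln(x.sum() + 1)
            - gammaln(x + 1).sum()
        )

    rng = np.random.default_rng(seed)
    dist = stats.random_table(a.sum(axis=1), a.sum(axis=0), seed=rng)
    obs = log_table_prob(a)
    samples = dist.rvs(n_mc, method="patefield")
    probs = np.array([log_table_prob(s) for s in samples])
    return float(((probs <= obs + 1e-12).sum() + 1) / (n_mc + 1))


def relapse_capture(groups, relapsed=None) -> dict[str, int]:
    """Share of all relapses captured by each risk group, in whole percent.

    Accepts either per-patient arrays (``groups`` labels and a boolean
    ``relapsed`` indicator) or a mapping of per-group relapse counts with
    a ``"total"`` entry.
    """
    if relapsed is None:
        counts = dict(groups)
        total = counts.pop("total")
    else:
        s = pd.Series(np.asarray(relapsed).astype(bool))
        total = int(s.sum())
        counts = s.groupby(np.asarray(groups)).sum().astype(int).to_dict()
    if total == 0:
        raise ValueError("no relapses observed")
    return {g: percent_of(c, total) for g, c in counts.items()}


@dataclass
class StratifiedTable:
    """A Table-1-style block: counts (and %) per risk group by stratum."""

    counts: pd.DataFrame
    percents: pd.DataFrame
    p: float

    def __post_init__(self):
        body = self.counts.drop(columns="total")
        if not (body.sum(axis=1) == self.counts["total"]).all():
            raise ValueError("per-row counts must sum to the stated totals")


def stratified_counts(df: pd.DataFrame, stratum_col: str, group_col: str,
                      seed: int = 0) -> StratifiedTable:
    """Cross-tabulate a stratum variable against risk groups with an exact
    association p-value; percentages are within-group (column) shares."""
    tab = pd.crosstab(df[stratum_col], df[group_col])
    p = categorical_association(tab.to_numpy(), seed=seed)
    counts = tab.copy()
    counts["total"] = tab.sum(axis=1)
    pct = tab.div(tab.sum(axis=0), axis=1) * 100
    pct["total"] = counts["total"] / counts["total"].sum() * 100
    return StratifiedTable(counts=counts, percents=pct.round(1), p=p)


def _binary_auc_at_horizon(risk, times, events, horizon: float):
    """AUC for the binary 'event by horizon' outcome.

    Patients censored before the horizon without an event carry no
    outcome label and are excluded (recorded in the metadata).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(bool)
    risk = np.asarray(risk, dtype=float)
    label = events & (times <= horizon)
    usable = label | (times >= horizon)
    if label[usable].sum() == 0 or label[usable].all():
        return np.nan, int((~usable).sum())
    return (
        float(roc_auc_score(label[usable].astype(int), risk[usable])),
        int((~usable).sum()),
    )


def compare_classifiers(
    cohort: pd.DataFrame,
    classifiers: Mapping[str, Sequence],
    endpoint: str = "relapse",
    horizon: float = 10.0,
    mrd_adjust: bool = True,
) -> pd.DataFrame:
    """Compare risk groupings the way classifier tables do.

    ``classifiers`` maps a name to a boolean membership vector (True =
    in the low-risk group).  Reports, per classifier: group size, the
    horizon failure rate inside the group, the unadjusted and
    MRD-adjusted Cox HR of membership vs the remaining HeH cases, Harrell
    C and the binary AUC at the horizon.  Classifiers with an empty (or
    full) group are skipped with a warning.
    """
    t = cohort[f"time_{endpoint}"].to_numpy(dtype=float)
    e = cohort[f"ind_{endpoint}"].to_numpy()
    rows = []
    for name, member in classifiers.items():
        m = np.asarray(member).astype(bool)
        if m.all() or not m.any():
            warnings.warn(f"classifier {name!r} has an empty group; skipped")
            continue
        curve = km_fit(t[m], np.asarray(e)[m])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rate, ci = rate_at(curve, horizon, as_failure=True)
        risk = (~m).astype(float)
        cov = pd.DataFrame({"member": m.astype(float)})
        hr = cox_fit(t, e, cov)["member"]
        row = {
            "classifier": name,
            "n": int(m.sum()),
            "pct_of_cohort": percent_of(int(m.sum()), len(m)),
            f"{endpoint}_rate_{int(horizon)}y": rate,
            "rate_ci_low": ci[0],
            "rate_ci_high": ci[1],
            "hr": hr.hr, "hr_ci_low": hr.ci95[0], "hr_ci_high": hr.ci95[1],
            "hr_p": hr.p,
            "c_index": concordance(risk, t, e),
        }
        auc, n_excl = _binary_auc_at_horizon(risk, t, e, horizon)
        row["auc"] = auc
        row["auc_excluded"] = n_excl
        if mrd_adjust and "mrd_fraction" in cohort.columns:
            mask = cohort["mrd_fraction"].notna().to_numpy()
            cov2 = pd.DataFrame({
                "member": m[mask].astype(float),
                "neg_log10_mrd": neg_log10_mrd(
                    cohort.loc[mask, "mrd_fraction"].to_numpy()
                ),
            })
            hr_adj = cox_fit(t[mask], np.asarray(e)[mask], cov2)["member"]
            row["hr_mrd_adjusted"] = hr_adj.hr
            row["hr_mrd_adjusted_p"] = hr_adj.p
        rows.append(row)
    return pd.DataFrame(rows)
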