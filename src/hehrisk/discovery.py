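"""Trisomy-profile discovery pipeline.

Given a patients x chromosomes binary gain matrix and survival endpoints,
this module reproduces the full profile-discovery procedure:

1. :func:`screen_trisomies` - univariate Cox screen of every gained
   chromosome against each endpoint ("volcano table");
2. :func:`cluster_gains` - phi-correlation, average-linkage clustering of
   gain columns with per-cluster relapse hazards (Heerema-style groups);
3. :func:`select_subset_size` - for each model size k, the best subset of
   k trisomy indicators with its C-index, Mallows Cp and BIC, and the
   plateau rule that picks the optimal k;
4. :func:`best_subset_cp` / :func:`stepwise_bic` - best-subset ranking by
   Mallows Cp on a linear-probability model of the relapse indicator, and
   forward-stepwise Cox selection by BIC;
5. :func:`derive_rule` - per-pattern 10-year relapse rates over the
   selected trisomies, a 2-means split into low/high-relapse clusters,
   and the smallest boolean (DNF) rule consistent with the split.

The candidate pool excludes chromosomes gained in fewer than 5% (or more
than 95%) of patients: rarities carry almost no information and keep the
combinatorial enumeration tractable.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from lifelines.utils import concordance_index
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform
from scipy.stats import norm

from . import _coxfast
from .classify import classify_ukall_heh
from .karyotype import CHROMOSOMES, _ORDER, sort_labels

logger = logging.getLogger(__name__)

PROFILE_CHROMOSOMES = ("5", "17", "18", "20")


def gain_columns(df: pd.DataFrame) -> list[str]:
    return [c for c in df.columns if c.startswith("gain_")]


def candidate_pool(gains: pd.DataFrame, min_freq: float = 0.05) -> list[str]:
    """Chromosomes gained in at least ``min_freq`` and at most
    ``1 - min_freq`` of patients, in natural cytogenetic order."""
    freqs = {c.removeprefix("gain_"): gains[c].mean() for c in gain_columns(gains)}
    keep = [c for c, f in freqs.items() if min_freq <= f <= 1 - min_freq]
    return list(sort_labels(keep))


def _matrix(gains: pd.DataFrame, chroms: Sequence[str]) -> np.ndarray:
    return gains[[f"gain_{c}" for c in chroms]].to_numpy(dtype=float)


def _wald(fit: _coxfast.FastCoxFit) -> pd.DataFrame:
    se = fit.se
    z = fit.beta / se
    p = 2 * norm.sf(np.abs(z))
    return pd.DataFrame({
        "hr": np.exp(fit.beta),
        "ci_low": np.exp(fit.beta - 1.96 * se),
        "ci_high": np.exp(fit.beta + 1.96 * se),
        "p": p,
    })


# ---------------------------------------------------------------------------
# 1. univariate screen


def screen_trisomies(
    gains: pd.DataFrame,
    endpoints: pd.DataFrame,
    which: Sequence[str] = ("relapse", "efs", "os"),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Univariate Cox HR and p per chromosome per endpoint.

    All-constant gain columns are skipped with a warning.  The returned
    table has one row per (chromosome, endpoint) with a ``significant``
    flag at level ``alpha``.
    """
    rows = []
    for chrom in sort_labels(c.removeprefix("gain_") for c in gain_columns(gains)):
        col = gains[f"gain_{chrom}"].to_numpy(dtype=float)
        if col.std() == 0:
            warnings.warn(f"chromosome {chrom} gain is constant; skipped")
            continue
        for ep in which:
            t = endpoints[f"time_{ep}"].to_numpy(dtype=float)
            e = endpoints[f"ind_{ep}"].to_numpy()
            try:
                fit = _coxfast.fit(col[:, None], t, e)
            except (_coxfast.CoxConvergenceError, ValueError) as err:
                warnings.warn(f"chromosome {chrom} ({ep}): {err}; skipped")
                continue
            w = _wald(fit).iloc[0]
            rows.append({
                "chromosome": chrom,
                "endpoint": ep,
                "n_gained": int(col.sum()),
                "hr": w.hr, "ci_low": w.ci_low, "ci_high": w.ci_high, "p": w.p,
                "significant": bool(w.p < alpha),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# 2. chromosome-gain clustering


@dataclass
class ClusterResult:
    n_groups: int
    assignment: dict[str, int]           # chromosome -> group id (1-based)
    linkage_heights: np.ndarray
    per_group_hr: pd.DataFrame           # HR of each group vs group 1
    phi: pd.DataFrame                    # pairwise phi matrix
    stable: bool


def cluster_gains(
    gains: pd.DataFrame,
    endpoints: Optional[pd.DataFrame],
    n_groups: int,
) -> ClusterResult:
    """Cluster gain columns by phi correlation (average linkage).

    Patients are assigned to the cluster in which the largest fraction of
    the cluster's chromosomes is gained; relapse HRs of each cluster vs
    cluster 1 are then estimated from those patient-level assignments.
    The split is flagged unstable when the linkage-height gap at the cut
    is small relative to the full merge range (near-uniform heights).
    """
    chroms = [
        c.removeprefix("gain_")
        for c in gain_columns(gains)
        if gains[c].std() > 0
    ]
    chroms = list(sort_labels(chroms))
    if n_groups > len(chroms):
        raise ValueError(
            f"n_groups={n_groups} exceeds the {len(chroms)} chromosomes with variance"
        )
    X = _matrix(gains, chroms)
    phi = np.corrcoef(X, rowvar=False)
    dist = np.clip(1.0 - phi, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    Z = average(squareform(dist, checks=False))
    labels = fcluster(Z, t=n_groups, criterion="maxclust")
    # relabel contiguously in order of first appearance along chromosome order
    remap: dict[int, int] = {}
    for lab in labels:
        if lab not in remap:
            remap[lab] = len(remap) + 1
    assignment = {c: remap[l] for c, l in zip(chroms, labels)}

    heights = Z[:, 2]
    if len(heights) >= n_groups and n_groups >= 2:
        # gap between the merge that would fuse two of the n_groups clusters
        # and the previous one, relative to the full height range
        cut_gap = heights[-(n_groups - 1)] - (heights[-n_groups] if n_groups < len(heights) + 1 else 0)
        rng_h = heights.max() - heights.min() + 1e-12
        stable = bool(cut_gap / rng_h > 0.10)
    else:
        stable = True

    per_group_hr = pd.DataFrame()
    if endpoints is not None:
        group_ids = np.array([assignment[c] for c in chroms])
        frac = np.zeros((X.shape[0], n_groups))
        for g in range(1, n_groups + 1):
            cols = group_ids == g
            if cols.any():
                frac[:, g - 1] = X[:, cols].mean(axis=1)
        patient_group = frac.argmax(axis=1) + 1  # ties -> lower group id
        t = endpoints["time_relapse"].to_numpy(dtype=float)
        e = endpoints["ind_relapse"].to_numpy()
        rows = []
        for g in range(2, n_groups + 1):
            mask = (patient_group == g) | (patient_group == 1)
            if (patient_group == g).sum() == 0:
                continue
            ind = (patient_group[mask] == g).astype(float)
            if ind.std() == 0:
                continue
            try:
                fit = _coxfast.fit(ind[:, None], t[mask], e[mask])
            except (ValueError, _coxfast.CoxConvergenceError):
                continue
            w = _wald(fit).iloc[0]
            rows.append({
                "group": g, "n": int((patient_group == g).sum()),
                "hr": w.hr, "ci_low": w.ci_low, "ci_high": w.ci_high, "p": w.p,
            })
        per_group_hr = pd.DataFrame(rows)

    return ClusterResult(
        n_groups=n_groups,
        assignment=assignment,
        linkage_heights=heights,
        per_group_hr=per_group_hr,
        phi=pd.DataFrame(phi, index=chroms, columns=chroms),
        stable=stable,
    )


# ---------------------------------------------------------------------------
# 3-4. subset enumeration and selection


def enumerate_subsets(candidates: Iterable[str], k: int):
    """All size-``k`` subsets of ``candidates`` in deterministic
    lexicographic (natural chromosome) order."""
    cands = sort_labels(candidates)
    if not 1 <= k <= len(cands):
        raise ValueError(f"k={k} out of range for {len(cands)} candidates")
    return itertools.combinations(cands, k)


def _best_sse_per_size(A: np.ndarray, y: np.ndarray, k: int):
    """Best (minimal-SSE) subset of each size up to ``k`` for the linear
    model ``y ~ 1 + A[:, S]`` via Gram-matrix enumeration.

    Returns ``{size: (subset_indices, sse)}``.
    """
    n, p = A.shape
    X = np.column_stack([np.ones(n), A])
    G = X.T @ X
    b = X.T @ y
    yty = float(y @ y)
    best: dict[int, tuple[tuple[int, ...], float]] = {}
    for size in range(1, k + 1):
        best_sse, best_S = np.inf, None
        for S in itertools.combinations(range(p), size):
            idx = (0,) + tuple(s + 1 for s in S)
            Gs = G[np.ix_(idx, idx)]
            bs = b[list(idx)]
            try:
                c = np.linalg.solve(Gs, bs)
            except np.linalg.LinAlgError:
                continue
            sse = yty - float(bs @ c)
            if sse < best_sse - 1e-12:
                best_sse, best_S = sse, S
        best[size] = (best_S, best_sse)
    return best


def _subset_sse(A: np.ndarray, y: np.ndarray, cols: Sequence[int]) -> float:
    n = A.shape[0]
    X = np.column_stack([np.ones(n), A[:, list(cols)]])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return float(resid @ resid)


def mallows_cp(sse_subset: float, s2_full: float, n: int, p_subset: int) -> float:
    """Mallows Cp = SSE_p / s^2 - n + 2 (p + 1)."""
    return sse_subset / s2_full - n + 2 * (p_subset + 1)


def best_subset_cp(
    gains: pd.DataFrame,
    relapse_indicator,
    k: int,
    candidates: Optional[Sequence[str]] = None,
    min_freq: float = 0.05,
) -> pd.DataFrame:
    """Rank all size-``k`` trisomy subsets by Mallows Cp.

    Cp is computed on a linear-probability model of the binary relapse
    indicator, with the residual variance estimated from the full
    candidate model.  Raises when the full model is singular, listing the
    aliased columns.
    """
    cands = list(sort_labels(candidates)) if candidates is not None else candidate_pool(gains, min_freq)
    A = _matrix(gains, cands)
    y = np.asarray(relapse_indicator, dtype=float)
    n, p_full = A.shape
    Xf = np.column_stack([np.ones(n), A])
    rank = np.linalg.matrix_rank(Xf)
    if rank < p_full + 1:
        corr = np.corrcoef(A, rowvar=False)
        aliased = sorted({
            cands[j]
            for i in range(p_full)
            for j in range(i + 1, p_full)
            if abs(corr[i, j]) > 1 - 1e-10
        } | {cands[i] for i in range(p_full) if A[:, i].std() == 0})
        raise ValueError(f"full candidate model is singular; aliased columns: {aliased}")
    sse_full = _subset_sse(A, y, range(p_full))
    s2 = sse_full / (n - p_full - 1)
    rows = []
    for S in enumerate_subsets(cands, k):
        cols = [cands.index(c) for c in S]
        sse = _subset_sse(A, y, cols)
        rows.append({"subset": S, "sse": sse, "cp": mallows_cp(sse, s2, n, len(S))})
    return pd.DataFrame(rows).sort_values(
        ["cp", "subset"], kind="stable"
    ).reset_index(drop=True)


@dataclass
class SubsetSelectionResult:
    """Best subset per size, selection scores and the chosen model."""

    per_size: pd.DataFrame = field(default_factory=pd.DataFrame)
    chosen_k: Optional[int] = None
    chosen_subset: tuple[str, ...] = ()
    bic_trace: list = field(default_factory=list)


def plateau_choice(c_indices: Sequence[float], epsilon: float) -> int:
    """Smallest k whose increment to k+1 falls below ``epsilon``; the
    last size when the sequence never plateaus."""
    cs = list(c_indices)
    for k in range(1, len(cs)):
        if cs[k] - cs[k - 1] < epsilon:
            return k
    return len(cs)


def _cox_bic(loglik: float, p: int, n_events: int) -> float:
    return -2.0 * loglik + p * np.log(max(n_events, 1))


def select_subset_size(
    gains: pd.DataFrame,
    endpoints: pd.DataFrame,
    k_max: int = 6,
    epsilon: float = 0.005,
    min_freq: float = 0.05,
    candidates: Optional[Sequence[str]] = None,
) -> SubsetSelectionResult:
    """Find the optimal number of trisomies for outcome prediction.

    For each size k up to ``k_max``, the best subset (minimal SSE on the
    binary relapse indicator, i.e. minimal Cp at fixed size) is scored by
    the Harrell C-index of a Cox model on the subset indicators for the
    relapse endpoint, alongside its Cp and Cox BIC.  The chosen size is
    the smallest k whose C-index gain from one extra chromosome drops
    below ``epsilon``.
    """
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    cands = list(sort_labels(candidates)) if candidates is not None else candidate_pool(gains, min_freq)
    t = endpoints["time_relapse"].to_numpy(dtype=float)
    e = endpoints["ind_relapse"].to_numpy()
    n_events = int(np.asarray(e).astype(bool).sum())
    if n_events <= k_max:
        k_max = max(2, n_events - 1)
        warnings.warn(f"too few events; k_max reduced to {k_max}")
    k_max = min(k_max, len(cands))

    A = _matrix(gains, cands)
    y = np.asarray(e, dtype=float)
    n, p_full = A.shape
    sse_full = _subset_sse(A, y, range(p_full))
    s2 = sse_full / (n - p_full - 1)

    # Best subset per size: exhaustive Cox partial likelihood for small
    # pools, minimal-SSE Gram search (equivalent to minimal Cp at fixed
    # size) when enumeration with Cox fits would be too expensive.
    use_cox = len(cands) <= 10
    best: dict[int, tuple[tuple[int, ...], float]] = {}
    if use_cox:
        for k in range(1, k_max + 1):
            best_ll, best_S = -np.inf, None
            for S in itertools.combinations(range(p_full), k):
                try:
                    f = _coxfast.fit(A[:, list(S)], t, e)
                except (_coxfast.CoxConvergenceError, ValueError):
                    continue
                if f.loglik > best_ll + 1e-10:
                    best_ll, best_S = f.loglik, S
            if best_S is None:
                raise ValueError(f"no estimable subset of size {k}")
            best[k] = (best_S, _subset_sse(A, y, best_S))
    else:
        best = _best_sse_per_size(A, y, k_max)

    rows = []
    for k in range(1, k_max + 1):
        S, sse = best[k]
        subset = tuple(cands[i] for i in S)
        Xs = A[:, list(S)]
        fit = _coxfast.fit(Xs, t, e)
        eta = Xs @ fit.beta
        cidx = float(concordance_index(t, -eta, e))
        rows.append({
            "k": k,
            "subset": subset,
            "c_index": cidx,
            "cp": mallows_cp(sse, s2, n, k),
            "bic": _cox_bic(fit.loglik, k, fit.n_events),
        })
    per_size = pd.DataFrame(rows)
    chosen_k = plateau_choice(per_size["c_index"].tolist(), epsilon)
    chosen_subset = per_size.loc[per_size["k"] == chosen_k, "subset"].iloc[0]
    return SubsetSelectionResult(
        per_size=per_size, chosen_k=chosen_k, chosen_subset=tuple(chosen_subset)
    )


def stepwise_bic(
    gains: pd.DataFrame,
    endpoints: pd.DataFrame,
    candidates: Optional[Sequence[str]] = None,
    min_freq: float = 0.05,
) -> SubsetSelectionResult:
    """Forward-stepwise Cox selection on the relapse endpoint by BIC.

    BIC = -2 log PL + p log(number of events).  Chromosomes are added
    while the BIC decreases; returns the selected set and the BIC trace
    (an empty subset, with a warning, when nothing beats the null model).
    """
    cands = list(sort_labels(candidates)) if candidates is not None else candidate_pool(gains, min_freq)
    if len(cands) < 2:
        raise ValueError("need at least two candidate chromosomes")
    t = endpoints["time_relapse"].to_numpy(dtype=float)
    e = endpoints["ind_relapse"].to_numpy()
    A = _matrix(gains, cands)

    current: list[str] = []
    bic = _cox_bic(_coxfast.null_loglik(t, e), 0, int(np.asarray(e).astype(bool).sum()))
    trace = [(tuple(), bic)]
    while True:
        best_bic, best_c = bic, None
        for c in cands:
            if c in current:
                continue
            cols = [cands.index(x) for x in current + [c]]
            try:
                fit = _coxfast.fit(A[:, cols], t, e)
            except (ValueError, _coxfast.CoxConvergenceError):
                continue
            cand_bic = _cox_bic(fit.loglik, len(cols), fit.n_events)
            # strict improvement; lexicographic chromosome order breaks ties
            if cand_bic < best_bic - 1e-10:
                best_bic, best_c = cand_bic, c
        if best_c is None:
            break
        current.append(best_c)
        bic = best_bic
        trace.append((tuple(sort_labels(current)), bic))
    if not current:
        warnings.warn("no candidate improves on the null model; empty subset")
    return SubsetSelectionResult(
        chosen_subset=tuple(sort_labels(current)),
        chosen_k=len(current),
        bic_trace=trace,
    )


def exhaustive_best_bic(
    gains: pd.DataFrame,
    endpoints: pd.DataFrame,
    candidates: Sequence[str],
) -> tuple[tuple[str, ...], float]:
    """Exhaustive best-BIC subset over all 2^p - 1 candidate subsets
    (plus the null model); the independent oracle for small pools."""
    cands = sort_labels(candidates)
    t = endpoints["time_relapse"].to_numpy(dtype=float)
    e = endpoints["ind_relapse"].to_numpy()
    A = _matrix(gains, cands)
    best = ((), _cox_bic(_coxfast.null_loglik(t, e), 0, int(np.asarray(e).astype(bool).sum())))
    for k in range(1, len(cands) + 1):
        for S in itertools.combinations(range(len(cands)), k):
            try:
                fit = _coxfast.fit(A[:, list(S)], t, e)
            except (ValueError, _coxfast.CoxConvergenceError):
                continue
            bic = _cox_bic(fit.loglik, k, fit.n_events)
            if bic < best[1] - 1e-10:
                best = (tuple(cands[i] for i in S), bic)
    return best


# ---------------------------------------------------------------------------
# 5. decision-rule derivation


@dataclass(frozen=True)
class BooleanRule:
    """DNF rule over trisomy indicators: GOOD iff any clause is satisfied.

    Each clause is a tuple of ``(chromosome, required_presence)`` pairs.
    """

    variables: tuple[str, ...]
    clauses: tuple[tuple[tuple[str, bool], ...], ...]

    def evaluate(self, gains: Iterable[str]) -> bool:
        gs = frozenset(str(g) for g in gains)
        return any(
            all((c in gs) == want for c, want in clause) for clause in self.clauses
        )

    def to_dnf(self) -> str:
        def lit(c, want):
            return f"+{c}" if want else f"no +{c}"

        return " OR ".join(
            "(" + " AND ".join(lit(c, w) for c, w in clause) + ")"
            for clause in self.clauses
        )

    @property
    def n_literals(self) -> int:
        return sum(len(cl) for cl in self.clauses)


#: The published UKALL-HeH good-risk rule expressed as a DNF over the
#: four profile chromosomes (used for equivalence checks).
PUBLISHED_RULE = BooleanRule(
    variables=PROFILE_CHROMOSOMES,
    clauses=(
        (("17", True), ("18", True)),
        (("5", False), ("17", True), ("20", False)),
        (("5", False), ("18", True), ("20", False)),
    ),
)


def _km_failure_at(t: np.ndarray, e: np.ndarray, horizon: float) -> float:
    """Product-limit failure probability at a horizon (internal fast path;
    the public Kaplan-Meier API lives in :mod:`hehrisk.survival`)."""
    t = np.asarray(t, dtype=float)
    e = np.asarray(e).astype(bool)
    s = 1.0
    for v in np.unique(t[e & (t <= horizon)]):
        at_risk = int((t >= v).sum())
        d = int(((t == v) & e).sum())
        s *= 1.0 - d / at_risk
    return 1.0 - s


def _two_means_split_1d(values: np.ndarray) -> np.ndarray:
    """Exact 1-D 2-means: boolean mask of the high cluster."""
    order = np.argsort(values, kind="stable")
    v = values[order]
    n = v.size
    best_cost, best_split = np.inf, None
    for s in range(1, n):
        lo, hi = v[:s], v[s:]
        cost = ((lo - lo.mean()) ** 2).sum() + ((hi - hi.mean()) ** 2).sum()
        if cost < best_cost - 1e-15:
            best_cost, best_split = cost, s
    high = np.zeros(n, dtype=bool)
    high[order[best_split:]] = True
    return high


def _poisson_two_cluster(events: np.ndarray, person_time: np.ndarray) -> np.ndarray:
    """Exact 2-cluster split of patterns by event rate under a Poisson
    (exponential-hazard) likelihood; returns the high-rate cluster mask.

    The likelihood-optimal 2-partition is contiguous in crude-rate order,
    so all split points are tried.  Unlike Euclidean 2-means on the rates,
    this weighs each pattern by its information (events and person-time),
    which matters when pattern sizes span two orders of magnitude.
    """
    d = np.asarray(events, dtype=float)
    T = np.asarray(person_time, dtype=float)
    order = np.argsort(d / T, kind="stable")

    def seg_ll(idx) -> float:
        D, PT = d[idx].sum(), T[idx].sum()
        return D * np.log(D / PT) - D if D > 0 else 0.0

    best_ll, best_split = -np.inf, None
    for s in range(1, d.size):
        ll = seg_ll(order[:s]) + seg_ll(order[s:])
        if ll > best_ll + 1e-12:
            best_ll, best_split = ll, s
    high = np.zeros(d.size, dtype=bool)
    high[order[best_split:]] = True
    return high


@dataclass
class DerivedRule:
    rule: BooleanRule
    pattern_table: pd.DataFrame
    unobserved_patterns: list[tuple[int, ...]]


def derive_rule(
    gains: pd.DataFrame,
    endpoints: pd.DataFrame,
    chromosomes: Sequence[str] = PROFILE_CHROMOSOMES,
    horizon: float = 10.0,
    max_clauses: int = 5,
    min_pattern_frac: float = 0.005,
) -> DerivedRule:
    """Derive the good/poor decision tree over a small trisomy set.

    Computes the ``horizon``-year relapse rate (1 - Kaplan-Meier) for
    every observed presence/absence pattern of the given chromosomes,
    splits the observed patterns into low/high-relapse clusters by exact
    1-D 2-means, and returns the smallest DNF rule (fewest literals, then
    fewest clauses) over the indicators that labels every *supported*
    pattern consistently with the split (GOOD = low cluster).  Patterns
    carrying fewer than ``min_pattern_frac`` of the cohort have relapse
    rates too noisy to constrain the rule; they are tabulated but, like
    unobserved patterns, left to the rule's extrapolation.
    """
    chroms = sort_labels(chromosomes)
    m = len(chroms)
    X = _matrix(gains, chroms).astype(int)
    t = endpoints["time_relapse"].to_numpy(dtype=float)
    e = endpoints["ind_relapse"].to_numpy()

    codes = X @ (1 << np.arange(m))
    observed = np.unique(codes)
    if observed.size < 2:
        raise ValueError("only one trisomy pattern observed; cannot derive a rule")

    rows = []
    for code in observed:
        mask = codes == code
        rate = _km_failure_at(t[mask], e[mask], horizon)
        pattern = tuple(int(code >> b & 1) for b in range(m))
        rows.append({
            "pattern": pattern,
            "code": int(code),
            "n": int(mask.sum()),
            "n_relapses": int(np.asarray(e)[mask].sum()),
            "person_years": float(t[mask].sum()),
            "relapse_rate": rate,
        })
    table = pd.DataFrame(rows)

    supported = (table["n"] >= min_pattern_frac * len(codes)).to_numpy()
    if supported.sum() < 2:
        supported = np.ones(len(table), dtype=bool)
    table["supported"] = supported
    rates = table["relapse_rate"].to_numpy()
    sup_rates = rates[supported]
    if np.allclose(sup_rates, sup_rates[0]):
        raise ValueError("no discriminating rule: all patterns have equal relapse rate")
    high_sup = _poisson_two_cluster(
        table.loc[supported, "n_relapses"].to_numpy(),
        table.loc[supported, "person_years"].to_numpy(),
    )
    # label the table; unsupported patterns by nearest cluster rate (they
    # never constrain the rule)
    lo_mean = sup_rates[~high_sup].mean()
    hi_mean = sup_rates[high_sup].mean()
    high = np.abs(rates - hi_mean) < np.abs(rates - lo_mean)
    high[supported] = high_sup
    table["cluster"] = np.where(high, "high", "low")
    good_codes = set(table.loc[~high & supported, "code"])
    bad_codes = set(table.loc[high & supported, "code"])

    # enumerate all non-empty conjunctions over the m literals (present /
    # absent / unused), as bitmasks over the 2^m patterns
    all_codes = np.arange(1 << m)
    bits = (all_codes[:, None] >> np.arange(m)) & 1
    clause_defs = []
    for spec in itertools.product((None, True, False), repeat=m):
        if all(s is None for s in spec):
            continue
        mask = np.ones(1 << m, dtype=bool)
        for j, s in enumerate(spec):
            if s is not None:
                mask &= bits[:, j] == int(s)
        clause = tuple((chroms[j], s) for j, s in enumerate(spec) if s is not None)
        clause_defs.append((clause, frozenset(np.flatnonzero(mask).tolist())))

    # usable clauses cover no observed poor pattern
    usable = [
        (clause, cov) for clause, cov in clause_defs if not (cov & bad_codes)
    ]
    # minimal set cover of the observed good patterns
    target = frozenset(good_codes)
    best_rule: Optional[tuple[int, int, tuple]] = None
    usable.sort(key=lambda cv: (len(cv[0]), cv[0]))
    for r in range(1, max_clauses + 1):
        for combo in itertools.combinations(usable, r):
            covered = frozenset().union(*(cov for _, cov in combo))
            if target <= covered:
                n_lit = sum(len(cl) for cl, _ in combo)
                key = (n_lit, r, tuple(cl for cl, _ in combo))
                if best_rule is None or key < best_rule:
                    best_rule = key
        if best_rule is not None:
            break
    if best_rule is None:
        raise ValueError("no discriminating rule found within the clause budget")

    rule = BooleanRule(variables=chroms, clauses=best_rule[2])
    unobserved = [
        tuple(int(c >> b & 1) for b in range(m))
        for c in all_codes
        if c not in set(observed.tolist())
    ]
    return DerivedRule(rule=rule, pattern_table=table, unobserved_patterns=unobserved)


def rule_equivalent_to_published(rule: BooleanRule) -> bool:
    """Check logical equivalence with the published profile over all 16
    presence/absence patterns of chromosomes 5, 17, 18 and 20.

    Equivalence is semantic: variables that appear in no clause are
    irrelevant, so a rule derived over a superset of the profile
    chromosomes still qualifies when its clauses only mention the four.
    """
    used = {c for clause in rule.clauses for c, _ in clause}
    if not used <= set(PROFILE_CHROMOSOMES):
        return False
    for bits in itertools.product((0, 1), repeat=4):
        gains = {c for c, b in zip(PROFILE_CHROMOSOMES, bits) if b}
        if rule.evaluate(gains) != (classify_ukall_heh(gains).call == "GOOD"):
            return False
    return True


# ---------------------------------------------------------------------------
# full pipeline


def best_rule_subset(
    gains: pd.DataFrame,
    endpoints: pd.DataFrame,
    k: int,
    candidates: Sequence[str],
    horizon: float = 10.0,
) -> tuple[tuple[str, ...], float]:
    """Best size-``k`` subset by the performance of its derived rule.

    For every size-``k`` subset of the candidates, derives the
    pattern-level decision rule and scores the resulting good/poor split
    by the log-rank statistic on the relapse endpoint; returns the
    highest-scoring subset (ties broken lexicographically).  Scoring the
    *rule* rather than a linear predictor matters because the truth is an
    interaction: a rare trisomy can reshape the decision tree while its
    main-effect coefficient stays small.
    """
    from .survival import logrank

    t = endpoints["time_relapse"].to_numpy(dtype=float)
    e = endpoints["ind_relapse"].to_numpy()
    best_chi2, best_S = -np.inf, None
    for S in enumerate_subsets(candidates, k):
        try:
            derived = derive_rule(gains, endpoints, chromosomes=S, horizon=horizon)
        except ValueError:
            continue
        X = _matrix(gains, derived.rule.variables).astype(int)
        good = np.array([
            derived.rule.evaluate(
                {c for c, v in zip(derived.rule.variables, row) if v}
            )
            for row in X
        ])
        if good.all() or not good.any():
            continue
        chi2, _ = logrank([(t[good], np.asarray(e)[good]),
                           (t[~good], np.asarray(e)[~good])])
        if chi2 > best_chi2 + 1e-10:
            best_chi2, best_S = chi2, S
    if best_S is None:
        raise ValueError(f"no size-{k} subset yields a discriminating rule")
    return best_S, best_chi2


@dataclass
class PipelineResult:
    screen: pd.DataFrame
    size_selection: SubsetSelectionResult
    stepwise: SubsetSelectionResult
    final_subset: tuple[str, ...]
    derived: Optional[DerivedRule]

    @property
    def rule(self) -> Optional[BooleanRule]:
        return self.derived.rule if self.derived else None


def run_pipeline(
    cohort: pd.DataFrame,
    k_max: int = 6,
    epsilon: float = 0.005,
    min_freq: float = 0.05,
    alpha: float = 0.05,
    max_candidates: int = 6,
) -> PipelineResult:
    """Screen -> select size -> optimal combination -> decision rule.

    Stages: (1) univariate Cox screen on the relapse endpoint; the
    candidate set keeps the significant chromosomes ranked by p-value
    (capped at ``max_candidates``; topped up from the pool by p-value
    when fewer than four are significant).  (2) The optimal number of
    trisomies k* from the best-subset C-index plateau.  (3) The optimal
    combination: the size-k* subset whose derived decision rule best
    separates relapse risk (log-rank).  (4) Forward-stepwise BIC over the
    candidates, recorded as the parsimony cross-check.  The returned rule
    is the decision tree derived over the final combination.
    """
    screen = screen_trisomies(cohort, cohort, which=("relapse",), alpha=alpha)
    pool = candidate_pool(cohort, min_freq)
    rel = screen[(screen["endpoint"] == "relapse")
                 & screen["chromosome"].isin(pool)].sort_values("p", kind="stable")
    cand = rel.loc[rel["significant"], "chromosome"].tolist()
    if len(cand) < 4:
        cand = rel["chromosome"].head(4).tolist()
    cand = list(sort_labels(cand[:max_candidates]))

    size_sel = select_subset_size(
        cohort, cohort, k_max=min(k_max, len(cand)), epsilon=epsilon,
        candidates=cand,
    )
    k_star = size_sel.chosen_k
    final_subset, _ = best_rule_subset(cohort, cohort, k_star, cand)
    step = stepwise_bic(cohort, cohort, candidates=cand)
    derived = None
    try:
        derived = derive_rule(cohort, cohort, chromosomes=final_subset)
    except ValueError as err:
        logger.warning("rule derivation failed: %s", err)
    return PipelineResult(screen=screen, size_selection=size_sel,
                          stepwise=step, final_subset=final_subset,
                          derived=derived)


def selection_report(result: PipelineResult) -> dict:
    """JSON-serialisable summary of a pipeline run."""
    out = {
        "per_size": result.size_selection.per_size.assign(
            subset=result.size_selection.per_size["subset"].map(list)
        ).to_dict(orient="records") if not result.size_selection.per_size.empty else [],
        "chosen_k": result.size_selection.chosen_k,
        "final_subset": list(result.final_subset),
        "stepwise_subset": list(result.stepwise.chosen_subset),
        "bic_trace": [[list(s), b] for s, b in result.stepwise.bic_trace],
    }
    if result.derived is not None:
        out["rule_dnf"] = result.derived.rule.to_dnf()
        out["pattern_table"] = result.derived.pattern_table.assign(
            pattern=result.derived.pattern_table["pattern"].map(list)
        ).to_dict(orient="records")
    return out


def correlation_network_dot(phi: pd.DataFrame, threshold: float = 0.2) -> str:
    """Render the gain-correlation network as a GraphViz DOT string."""
    lines = ["graph gains {"]
    for c in phi.columns:
        lines.append(f'  "{c}";')
    for i, a in enumerate(phi.columns):
        for j in range(i + 1, len(phi.columns)):
            b = phi.columns[j]
            w = phi.iloc[i, j]
            if w >= threshold:
                lines.append(f'  "{a}" -- "{b}" [weight={w:.3f}];')
    lines.append("}")
    return "\n".join(lines)
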