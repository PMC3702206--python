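"""Cohort-level statistics: crosstabs, exact tests, frequency maps, survival.

The exact tests follow the minimum-likelihood two-sided convention: the
p-value sums the probabilities (hypergeometric for 2x2, multivariate for
r x c with fixed margins — the Freeman-Halton extension) of every table
whose point probability does not exceed the observed one, with a relative
tolerance of 1e-12 guarding floating-point ties.  The r x c test enumerates
all tables when their count fits under a cap and otherwise falls back to
seeded Monte Carlo (Patefield sampling), reporting which path ran.

Survival analysis provides the Kaplan-Meier product-limit estimator and a
Cox proportional-hazards fit by Newton-Raphson maximization of the partial
likelihood (Breslow tie handling by default, Efron behind a flag), with
Wald standard errors from the observed information.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import random_table

from .consequence import CaseConsequence
from .gene_model import GeneModel

__all__ = [
    "ContingencyTable",
    "FrequencyMap",
    "KMCurve",
    "CoxFit",
    "CoxFitError",
    "build_crosstab",
    "fisher_exact_2x2",
    "fisher_exact_rxc",
    "domain_frequency_map",
    "km_fit",
    "cox_fit",
]

log = logging.getLogger(__name__)

_TIE_RTOL = 1e-12


# ---------------------------------------------------------------------------
# contingency tables


@dataclass
class ContingencyTable:
    counts: np.ndarray
    row_labels: tuple
    col_labels: tuple

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        self.row_labels = tuple(self.row_labels)
        self.col_labels = tuple(self.col_labels)

    @property
    def row_margins(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_margins(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def build_crosstab(
    cohort: pd.DataFrame,
    row_variable: str,
    col_variable: str,
    row_order: Optional[Sequence] = None,
    col_order: Optional[Sequence] = None,
) -> ContingencyTable:
    """Crosstab of two categorical columns with pairwise missing exclusion.

    Rows with a missing value in either variable are dropped, so the
    denominator varies per variable pair (the convention behind published
    characteristic tables with uneven totals).
    """
    for var in (row_variable, col_variable):
        if var not in cohort.columns:
            raise KeyError(f"unknown variable {var!r}")
    sub = cohort[[row_variable, col_variable]].dropna()
    tab = pd.crosstab(sub[row_variable], sub[col_variable])
    if row_order is not None:
        tab = tab.reindex(index=list(row_order), fill_value=0)
    if col_order is not None:
        tab = tab.reindex(columns=list(col_order), fill_value=0)
    return ContingencyTable(
        counts=tab.to_numpy(),
        row_labels=tuple(tab.index),
        col_labels=tuple(tab.columns),
    )


def _as_counts(table) -> np.ndarray:
    if isinstance(table, ContingencyTable):
        return table.counts
    arr = np.asarray(table, dtype=np.int64)
    if arr.ndim != 2 or (arr < 0).any():
        raise ValueError("table must be a non-negative 2-D integer matrix")
    return arr


def _log_table_prob(counts: np.ndarray) -> float:
    """log P(table | margins) under the multivariate hypergeometric."""
    n = counts.sum()
    return (
        gammaln(counts.sum(axis=1) + 1).sum()
        + gammaln(counts.sum(axis=0) + 1).sum()
        - gammaln(n + 1)
        - gammaln(counts + 1).sum()
    )


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table (minimum-likelihood rule)."""
    counts = _as_counts(table)
    if counts.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {counts.shape}")
    (a, b), (c, d) = counts
    r1, c1, n = a + b, a + c, counts.sum()
    if n == 0 or r1 in (0, n) or c1 in (0, n):
        return 1.0
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    ks = np.arange(lo, hi + 1)
    logp = (
        gammaln(r1 + 1) + gammaln(n - r1 + 1) + gammaln(c1 + 1) + gammaln(n - c1 + 1)
        - gammaln(n + 1)
        - gammaln(ks + 1) - gammaln(r1 - ks + 1) - gammaln(c1 - ks + 1)
        - gammaln(n - r1 - c1 + ks + 1)
    )
    p_obs = logp[a - lo]
    include = logp <= p_obs + np.log1p(_TIE_RTOL)
    probs = np.exp(logp)
    # normalize by the enumerated mass so the all-tables case is exactly 1
    return float(min(1.0, probs[include].sum() / probs.sum()))


@dataclass(frozen=True)
class RxCResult:
    p: float
    method: str       # "enumeration" or "monte_carlo"
    n_tables: int     # tables enumerated, or MC replicates
    total_prob: Optional[float] = None  # enumerated probability mass (~1)


class _CapExceeded(Exception):
    pass


def _enumerate_log_probs(row_margins, col_margins, const, cap):
    """Yield the log probability of every table with the given margins.

    Cells are filled row by row in lexicographic order, the final column
    and final row being forced by the margins; ``const`` is the shared
    margin term of the log probability and the per-cell -log(v!) terms are
    accumulated incrementally (plain-float arithmetic keeps the recursion
    cheap).  Raises :class:`_CapExceeded` past ``cap`` tables.
    """
    import math

    rm = [int(x) for x in row_margins]
    cm = [int(x) for x in col_margins]
    r, c = len(rm), len(cm)
    n = sum(rm)
    lgf = [math.lgamma(k + 1) for k in range(n + 1)]
    out: list[float] = []
    count = 0

    def rec(i, col_left, partial):
        nonlocal count
        if i == r - 1:
            # last row forced to the remaining column margins
            lp = partial
            for v in col_left:
                lp -= lgf[v]
            count += 1
            if count > cap:
                raise _CapExceeded
            out.append(const + lp)
            return
        row_left = rm[i]
        suffix = [0] * c  # suffix[j] = col_left[j+1:] sum
        for j in range(c - 2, -1, -1):
            suffix[j] = suffix[j + 1] + col_left[j + 1]
        cells = [0] * c

        def fill(j, row_rem, partial_row):
            if j == c - 1:
                if row_rem > col_left[c - 1]:
                    return
                cells[j] = row_rem
                new_left = [col_left[k] - cells[k] for k in range(c)]
                rec(i + 1, new_left, partial_row - lgf[row_rem])
                return
            lo = max(0, row_rem - suffix[j])
            hi = min(row_rem, col_left[j])
            for v in range(lo, hi + 1):
                cells[j] = v
                fill(j + 1, row_rem - v, partial_row - lgf[v])

        fill(0, row_left, partial)

    rec(0, cm, 0.0)
    return out, count


def fisher_exact_rxc(
    table,
    max_tables: int = 5_000_000,
    B: int = 20_000,
    seed: int | None = None,
) -> RxCResult:
    """Freeman-Halton exact test for an r x c table.

    All-zero rows/columns are dropped with a warning; a table degenerate
    after dropping gives p = 1.  Full enumeration runs while the number of
    margin-compatible tables stays at or below ``max_tables``; otherwise a
    seeded Monte Carlo estimate with ``B`` Patefield-sampled tables is
    returned, ``p = (r + 1)/(B + 1)``.
    """
    counts = _as_counts(table)
    keep_r = counts.sum(axis=1) > 0
    keep_c = counts.sum(axis=0) > 0
    if not keep_r.all() or not keep_c.all():
        warnings.warn("dropping all-zero rows/columns before exact test",
                      stacklevel=2)
        counts = counts[keep_r][:, keep_c]
    if counts.shape[0] < 2 or counts.shape[1] < 2 or counts.sum() == 0:
        return RxCResult(1.0, "degenerate", 0)

    rm, cm = counts.sum(axis=1), counts.sum(axis=0)
    n = int(counts.sum())
    const = float(
        gammaln(rm + 1).sum() + gammaln(cm + 1).sum() - gammaln(n + 1)
    )
    logp_obs = _log_table_prob(counts)
    thresh = logp_obs + np.log1p(_TIE_RTOL)

    try:
        lps, n_seen = _enumerate_log_probs(rm, cm, const, cap=max_tables)
    except _CapExceeded:
        lps = None

    if lps is not None:
        probs = np.exp(np.asarray(lps))
        total = float(probs.sum())
        # conservation sanity: enumerated probabilities must sum to 1
        if abs(total - 1.0) > 1e-6:
            raise RuntimeError(f"enumeration probability mass {total} != 1")
        p = float(probs[np.asarray(lps) <= thresh].sum() / total)
        return RxCResult(min(1.0, p), "enumeration", n_seen, total_prob=total)

    rng = np.random.default_rng(seed)
    samples = np.asarray(random_table(rm, cm).rvs(B, random_state=rng))
    if samples.ndim == 2:
        samples = samples[None, :, :]
    lps_mc = const - gammaln(samples + 1).sum(axis=(1, 2))
    r_ge = int((lps_mc <= thresh).sum())
    return RxCResult((r_ge + 1) / (B + 1), "monte_carlo", B)


# ---------------------------------------------------------------------------
# domain frequency map


@dataclass
class FrequencyMap:
    table: pd.DataFrame  # index: domain, cols: fraction_direct/conservative/aggressive
    n_cases: int


def domain_frequency_map(
    cases: Sequence[CaseConsequence], model: GeneModel
) -> FrequencyMap:
    """Per-domain fraction of mutated cases affected, under all weightings."""
    if not cases:
        raise ValueError("frequency map needs >= 1 mutated case")
    n = len(cases)
    rows = []
    for d in model.domains:
        rows.append({
            "domain": d.name,
            "fraction_direct":
                sum(d.name in c.affected_direct for c in cases) / n,
            "fraction_conservative":
                sum(d.name in c.affected_conservative for c in cases) / n,
            "fraction_aggressive":
                sum(d.name in c.affected_aggressive for c in cases) / n,
        })
    return FrequencyMap(pd.DataFrame(rows).set_index("domain"), n)


# ---------------------------------------------------------------------------
# Kaplan-Meier


@dataclass
class KMCurve:
    times: np.ndarray       # distinct event times, ascending
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray    # product-limit S(t) just after each event time

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_fit(
    times: Sequence[float],
    events: Sequence[int],
    groups: Optional[Sequence] = None,
) -> dict | KMCurve:
    """Kaplan-Meier product-limit estimate, optionally per group.

    Subjects censored exactly at an event time are counted at risk at that
    time (the standard convention).  Returns a :class:`KMCurve`, or a dict
    of them keyed by group label when ``groups`` is given.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValueError("empty survival input")
    if (t < 0).any():
        raise ValueError("times must be >= 0")
    if not np.isin(e, [0, 1]).all():
        raise ValueError("events must be 0/1")
    if groups is not None:
        g = np.asarray(groups)
        return {lab: km_fit(t[g == lab], e[g == lab]) for lab in pd.unique(g)}

    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    event_times = np.unique(t[e == 1])
    at_risk = np.array([(t >= u).sum() for u in event_times])
    d = np.array([((t == u) & (e == 1)).sum() for u in event_times])
    surv = np.cumprod(1.0 - d / at_risk) if event_times.size else np.array([])
    return KMCurve(event_times, at_risk, d, surv)


# ---------------------------------------------------------------------------
# Cox proportional hazards


class CoxFitError(ValueError):
    pass


@dataclass
class CoxFit:
    params: pd.Series          # log hazard ratios
    se: pd.Series
    ci_low: pd.Series
    ci_high: pd.Series
    p: pd.Series               # Wald
    loglik: float
    iterations: int
    converged: bool
    n_used: int
    n_events: int
    warnings: list[str] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "log_hr": self.params, "se": self.se,
            "ci_low": self.ci_low, "ci_high": self.ci_high, "p": self.p,
        })


def _cox_loglik_derivs(beta, X, t, e, ties):
    """Partial log-likelihood, score and information (Breslow or Efron)."""
    order = np.argsort(-t, kind="stable")  # descending time
    Xo, to, eo = X[order], t[order], e[order]
    eta = Xo @ beta
    w = np.exp(eta)
    n, p = Xo.shape

    ll = 0.0
    score = np.zeros(p)
    info = np.zeros((p, p))
    s0 = 0.0
    s1 = np.zeros(p)
    s2 = np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        while j < n and to[j] == to[i]:
            j += 1
        for k in range(i, j):  # extend risk set by this time's subjects
            s0 += w[k]
            s1 += w[k] * Xo[k]
            s2 += w[k] * np.outer(Xo[k], Xo[k])
        dead = [k for k in range(i, j) if eo[k] == 1]
        d = len(dead)
        if d:
            xsum = Xo[dead].sum(axis=0)
            ll += eta[dead].sum()
            if ties == "breslow" or d == 1:
                ll -= d * np.log(s0)
                score += xsum - d * s1 / s0
                info += d * (s2 / s0 - np.outer(s1 / s0, s1 / s0))
            else:  # efron
                wd = w[dead].sum()
                s1d = (w[dead, None] * Xo[dead]).sum(axis=0)
                s2d = (w[dead, None, None]
                       * np.einsum("ki,kj->kij", Xo[dead], Xo[dead])).sum(axis=0)
                for m in range(d):
                    f = m / d
                    s0m = s0 - f * wd
                    s1m = s1 - f * s1d
                    s2m = s2 - f * s2d
                    ll -= np.log(s0m)
                    score += xsum / d - s1m / s0m
                    info += s2m / s0m - np.outer(s1m / s0m, s1m / s0m)
        i = j
    return ll, score, info


def cox_fit(
    covariates: pd.DataFrame,
    times: Sequence[float],
    events: Sequence[int],
    ties: str = "breslow",
    max_iter: int = 50,
    score_tol: float = 1e-8,
    loglik_tol: float = 1e-10,
) -> CoxFit:
    """Cox proportional-hazards regression by Newton-Raphson from beta = 0.

    Subjects with any missing covariate are dropped (complete-case, logged).
    Convergence when the max score component falls below ``score_tol`` or
    the log-likelihood change below ``loglik_tol``.  A constant covariate is
    a hard error; monotone likelihood (complete separation) yields a
    non-converged fit with a diagnostic rather than silent output.
    """
    if ties not in ("breslow", "efron"):
        raise ValueError(f"unknown ties method {ties!r}")
    df = pd.DataFrame(covariates).copy()
    names = list(df.columns)
    df["_t"] = np.asarray(times, dtype=float)
    df["_e"] = np.asarray(events, dtype=int)
    n_total = len(df)
    df = df.dropna()
    n_used = len(df)
    warns: list[str] = []
    if n_used < n_total:
        msg = f"dropped {n_total - n_used} subjects with missing covariates"
        warns.append(msg)
        log.info(msg)
    X = df[names].to_numpy(dtype=float)
    t = df["_t"].to_numpy()
    e = df["_e"].to_numpy()
    if e.sum() < 1:
        raise CoxFitError("no events in the data")
    const = [nm for nm, col in zip(names, X.T) if np.ptp(col) == 0]
    if const:
        raise CoxFitError(f"non-identifiable: constant covariate(s) {const}")

    beta = np.zeros(X.shape[1])
    ll_old = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        ll, score, info = _cox_loglik_derivs(beta, X, t, e, ties)
        if np.max(np.abs(score)) < score_tol or abs(ll - ll_old) < loglik_tol:
            converged = True
            break
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            warns.append("singular information matrix (possible separation)")
            break
        # step-halving safeguard
        for _ in range(20):
            ll_new, _, _ = _cox_loglik_derivs(beta + step, X, t, e, ties)
            if ll_new >= ll - 1e-12:
                break
            step = step / 2.0
        beta = beta + step
        ll_old = ll

    ll, score, info = _cox_loglik_derivs(beta, X, t, e, ties)
    if np.max(np.abs(beta)) > 15:
        converged = False
        warns.append(
            "monotone partial likelihood (complete separation): "
            "coefficient diverging"
        )
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        se = np.full(len(beta), np.nan)
        converged = False
        warns.append("information matrix not invertible at optimum")

    from scipy.stats import norm
    z = beta / se
    pvals = 2 * norm.sf(np.abs(z))
    idx = pd.Index(names)
    return CoxFit(
        params=pd.Series(beta, idx),
        se=pd.Series(se, idx),
        ci_low=pd.Series(beta - 1.96 * se, idx),
        ci_high=pd.Series(beta + 1.96 * se, idx),
        p=pd.Series(pvals, idx),
        loglik=float(ll),
        iterations=it,
        converged=converged,
        n_used=n_used,
        n_events=int(e.sum()),
        warnings=warns,
    )
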