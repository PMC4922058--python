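"""Cluster-category association: r x c Fisher exact tests with BH correction.

The two-sided Fisher p-value for an r x c contingency table is the total
null probability (multivariate hypergeometric with fixed margins) of tables
whose point probability does not exceed that of the observed table.  Small
tables are enumerated exhaustively (vectorized row-by-row composition
enumeration); larger tables fall back to margin-preserving Monte-Carlo
sampling (Patefield's algorithm) with the add-one estimator
p = (#{P(T) <= P(obs)} + 1)/(n_draws + 1).

The default test family reproduces the published analysis: seven clinical
characteristics plus the PAM50 and RPPA subtype distributions, one BH family.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from . import reference

#: Enumeration is used when the estimated number of margin-compatible tables
#: is below this bound; otherwise Monte-Carlo sampling.
MAX_EXACT_TABLES = 5_000_000


@dataclass
class ContingencyTest:
    name: str
    table: pd.DataFrame
    raw_p: float
    method: str  # "exact" | "montecarlo"
    n_draws: int | None = None
    seed: int | None = None
    adjusted_p: float | None = None


def crosstab(labels_a, labels_b, drop_na: bool = True) -> pd.DataFrame:
    """Category x category count table; NA rows/columns and all-zero rows
    dropped."""
    a = pd.Series(labels_a)
    b = pd.Series(labels_b)
    if len(a) != len(b):
        raise ValueError("label vectors must have equal length")
    table = pd.crosstab(a, b)
    if drop_na:
        table = table.drop(index="NA", errors="ignore").drop(columns="NA", errors="ignore")
    table = table.loc[table.sum(axis=1) > 0, table.sum(axis=0) > 0]
    if table.size == 0:
        raise ValueError("contingency table is empty after NA removal")
    return table


def _log_p_table(counts: np.ndarray, row: np.ndarray, col: np.ndarray) -> float:
    """Log point probability of a table under the fixed-margins null."""
    n = row.sum()
    const = (
        gammaln(row + 1).sum() + gammaln(col + 1).sum() - gammaln(n + 1)
    )
    return float(const - gammaln(counts + 1).sum())


def _enumeration_size(row: np.ndarray, col: np.ndarray) -> float:
    """Upper bound on the number of margin-compatible tables (compositions of
    each free row into c parts)."""
    c = len(col)
    rows = sorted(row.tolist())[:-1]  # last row is determined
    size = 1.0
    for r in rows:
        size *= comb(r + c - 1, c - 1)
        if size > 1e18:
            break
    return size


def _exact_p(table: np.ndarray) -> float:
    """Exhaustive two-sided p by vectorized row-by-row enumeration."""
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    order = np.argsort(row)  # enumerate small rows first, biggest row last
    r_sorted = row[order]
    c = len(col)
    # paths: remaining column margins after filling enumerated rows
    remaining = col[None, :].copy()
    logp = np.array([0.0])
    for r in r_sorted[:-1]:
        comps = _compositions(int(r), c)  # k x c
        # expand every path by every composition, keep feasible ones
        new_remaining = remaining[:, None, :] - comps[None, :, :]
        ok = (new_remaining >= 0).all(axis=2)
        pi, ci = np.nonzero(ok)
        remaining = new_remaining[pi, ci]
        logp = logp[pi] - gammaln(comps[ci] + 1).sum(axis=1)
    # last row is fully determined by the remaining margins
    logp = logp - gammaln(remaining + 1).sum(axis=1)
    const = gammaln(row + 1).sum() + gammaln(col + 1).sum() - gammaln(row.sum() + 1)
    logp = logp + const
    obs = _log_p_table(table, row, col)
    probs = np.exp(logp)
    return float(probs[logp <= obs + 1e-9].sum() / probs.sum())


_COMP_CACHE: dict[tuple[int, int], np.ndarray] = {}


def _compositions(n: int, k: int) -> np.ndarray:
    """All compositions of n into k nonnegative parts (C(n+k-1, k-1) rows)."""
    key = (n, k)
    if key in _COMP_CACHE:
        return _COMP_CACHE[key]
    if k == 1:
        out = np.array([[n]])
    else:
        parts = []
        for first in range(n + 1):
            rest = _compositions(n - first, k - 1)
            parts.append(np.column_stack([np.full(len(rest), first), rest]))
        out = np.vstack(parts)
    if len(_COMP_CACHE) < 64:
        _COMP_CACHE[key] = out
    return out


def _montecarlo_p(table: np.ndarray, n_draws: int, seed: int) -> float:
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    obs = _log_p_table(table, row, col)
    rng = np.random.default_rng(seed)
    dist = stats.random_table(row, col)
    hits = 0
    chunk = 250_000
    done = 0
    while done < n_draws:
        m = min(chunk, n_draws - done)
        draws = dist.rvs(m, method="patefield", random_state=rng)
        lp = -gammaln(draws + 1).sum(axis=(1, 2))
        lp += gammaln(row + 1).sum() + gammaln(col + 1).sum() - gammaln(row.sum() + 1)
        hits += int((lp <= obs + 1e-9).sum())
        done += m
    return (hits + 1) / (n_draws + 1)


def fisher_exact(
    table: pd.DataFrame | np.ndarray,
    method: str = "auto",
    n_draws: int = 10_000_000,
    seed: int = 0,
) -> tuple[float, str]:
    """Two-sided r x c Fisher exact p-value.

    Returns (p, method_used).  ``method`` is "auto" (enumerate when the
    margin-compatible table count is tractable, else Monte-Carlo), "exact",
    or "montecarlo".
    """
    counts = np.asarray(table, dtype=np.int64)
    if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    if (counts < 0).any():
        raise ValueError("counts must be nonnegative integers")
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        raise ValueError("table has a zero margin")
    if method == "auto":
        method = "exact" if _enumeration_size(row, col) <= MAX_EXACT_TABLES else "montecarlo"
    if method == "exact":
        return _exact_p(counts), "exact"
    if method == "montecarlo":
        return _montecarlo_p(counts, int(n_draws), seed), "montecarlo"
    raise ValueError(f"unknown method {method!r}")


def adjust_family(tests: list[ContingencyTest]) -> list[ContingencyTest]:
    """BH step-up over one family of tests (in place; returns the list)."""
    if not tests:
        raise ValueError("empty test family")
    raw = [t.raw_p for t in tests]
    if any(p is None for p in raw):
        raise ValueError("all raw p-values must be present")
    adj = multipletests(raw, method="fdr_bh")[1]
    for t, a in zip(tests, adj):
        t.adjusted_p = float(a)
    return tests


def percent_table(table: pd.DataFrame) -> pd.DataFrame:
    """Integer percentages within each cluster column (half away from zero)."""
    table = pd.DataFrame(table)
    totals = table.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("zero column total")
    pct = 100.0 * table / totals
    return np.floor(pct + 0.5).astype(int)


# ---------------------------------------------------------------------------
# Published-table test family
# ---------------------------------------------------------------------------

def reference_tables() -> dict[str, pd.DataFrame]:
    """The nine published category x cluster tables (NA and all-zero rows
    removed): seven clinical characteristics plus PAM50 and RPPA."""
    out = {}
    for name, counts in reference.CLINICAL_COUNTS.items():
        df = reference.counts_frame(counts).drop(index="NA", errors="ignore")
        out[name] = df.loc[df.sum(axis=1) > 0]
    for name, counts in reference.SUBTYPE_COUNTS.items():
        df = reference.counts_frame(counts).drop(index="NA", errors="ignore")
        out[name] = df.loc[df.sum(axis=1) > 0]
    return out


def association_tests(
    tables: dict[str, pd.DataFrame] | None = None,
    method: str = "auto",
    n_draws: int = 10_000_000,
    seed: int = 0,
) -> list[ContingencyTest]:
    """Fisher + BH over one family of category-distribution tests.

    With no argument, runs the published nine-test family.  Seeds for the
    Monte-Carlo fallback are derived per table from ``seed`` in name order.
    """
    if tables is None:
        tables = reference_tables()
    tests = []
    children = np.random.SeedSequence(seed).spawn(len(tables))
    for (name, table), child in zip(tables.items(), children):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        p, used = fisher_exact(table, method=method, n_draws=n_draws, seed=sub_seed)
        tests.append(
            ContingencyTest(
                name=name,
                table=pd.DataFrame(table),
                raw_p=p,
                method=used,
                n_draws=n_draws if used == "montecarlo" else None,
                seed=sub_seed if used == "montecarlo" else None,
            )
        )
    return adjust_family(tests)


__all__ = [
    "ContingencyTest",
    "crosstab",
    "fisher_exact",
    "adjust_family",
    "percent_table",
    "reference_tables",
    "association_tests",
    "MAX_EXACT_TABLES",
]
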