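"""Fixed-window relative metabolite quantification and per-cluster statistics.

Relative metabolite levels are obtained by trapezoidal integration of each
preprocessed spectrum over a fixed chemical-shift window per metabolite.
Cluster differences are assessed with tie-corrected Kruskal-Wallis tests,
Benjamini-Hochberg corrected across the metabolite family; the pairwise
"significant between" pattern is derived from the three pairwise two-group
rank tests, BH-corrected within each metabolite and gated by the omnibus
test.  Fold changes are log2 ratios of cluster means to the cohort mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .preprocess import SpectrumSet


@dataclass(frozen=True)
class MetaboliteSpec:
    """A named metabolite: peak positions/weights, linewidth, and the fixed
    integration window.

    ``peaks`` is a list of (center ppm, area weight); weights must sum to 1.
    ``lineshape`` is "gaussian" or "lorentzian"; FWHM is in ppm.
    """

    name: str
    peaks: tuple[tuple[float, float], ...]
    fwhm: float = 0.003
    window: tuple[float, float] = (0.0, 0.0)
    lineshape: str = "gaussian"

    def __post_init__(self) -> None:
        w = sum(wt for _, wt in self.peaks)
        if not np.isclose(w, 1.0):
            raise ValueError(f"{self.name}: peak weights sum to {w}, expected 1")
        lo, hi = self.window
        if not lo < hi:
            raise ValueError(f"{self.name}: window lo must be < hi")
        if self.fwhm <= 0:
            raise ValueError(f"{self.name}: fwhm must be positive")
        if self.lineshape not in ("gaussian", "lorentzian"):
            raise ValueError(f"{self.name}: unknown lineshape {self.lineshape!r}")

    def template(self, ppm: np.ndarray) -> np.ndarray:
        """Unit-area intensity profile of this metabolite on a ppm grid."""
        out = np.zeros_like(ppm, dtype=float)
        for center, weight in self.peaks:
            if self.lineshape == "lorentzian":
                gamma = self.fwhm / 2.0
                out += weight * (gamma / np.pi) / ((ppm - center) ** 2 + gamma**2)
            else:
                sigma = self.fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
                out += weight * np.exp(-0.5 * ((ppm - center) / sigma) ** 2) / (
                    sigma * np.sqrt(2.0 * np.pi)
                )
        return out


def _window_slice(ppm: np.ndarray, lo: float, hi: float, name: str) -> np.ndarray:
    """Indices of axis points inside [lo, hi]; error on empty or gappy windows.

    A gap larger than twice the median point spacing inside the window means
    the window straddles an excluded region, which invalidates the integral.
    """
    idx = np.nonzero((ppm >= lo) & (ppm <= hi))[0]
    if idx.size < 2:
        raise ValueError(f"{name}: integration window [{lo}, {hi}] not covered by the axis")
    if np.any(np.diff(idx) != 1):
        raise ValueError(f"{name}: integration window [{lo}, {hi}] is not contiguous on the axis")
    x = ppm[idx]
    steps = np.abs(np.diff(x))
    if steps.max() > 2.5 * np.median(np.abs(np.diff(ppm))):
        raise ValueError(f"{name}: integration window [{lo}, {hi}] overlaps an excluded region")
    return idx


def integrate_windows(
    spectra: SpectrumSet,
    specs: list[MetaboliteSpec],
    area_unit: float = 1.0,
) -> pd.DataFrame:
    """Trapezoidal window integrals, metabolite x sample, in ppm units divided
    by ``area_unit``.

    With the default ``area_unit=1`` values are plain (intensity x ppm) areas;
    the cohort pipeline passes the grid step so that values land on a
    per-grid-point scale (relative quantification is unit-free).
    """
    if area_unit <= 0:
        raise ValueError("area_unit must be positive")
    ppm = spectra.ppm
    rows = {}
    for spec in specs:
        lo, hi = spec.window
        idx = _window_slice(ppm, lo, hi, spec.name)
        x = ppm[idx]
        y = spectra.intensities[:, idx]
        area = np.abs(np.trapezoid(y, x, axis=1))
        rows[spec.name] = area / area_unit
    table = pd.DataFrame(rows, index=list(spectra.sample_ids)).T
    return table


def kruskal_wallis_bh(quant: pd.DataFrame, labels: pd.Series | dict) -> pd.DataFrame:
    """Tie-corrected Kruskal-Wallis H per metabolite with BH-adjusted p.

    ``labels`` maps sample id -> cluster label.  Returns a frame indexed by
    metabolite with columns H, p, adj_p, significant (adj_p <= 0.05).
    All-tied metabolites get H = 0, p = 1 by convention.
    """
    labels = pd.Series(labels)
    labels = labels.reindex(quant.columns)
    if labels.isna().any():
        raise ValueError("labels missing for some samples")
    groups = sorted(labels.unique())
    if len(groups) < 2:
        raise ValueError("at least two clusters required")
    cols = {g: quant.columns[labels == g] for g in groups}
    for g, c in cols.items():
        if len(c) < 2:
            raise ValueError(f"cluster {g} has fewer than 2 samples")
    H = np.empty(len(quant.index))
    p = np.empty(len(quant.index))
    for i, m in enumerate(quant.index):
        samples = [quant.loc[m, c].to_numpy(dtype=float) for g, c in cols.items()]
        allv = np.concatenate(samples)
        if np.all(allv == allv[0]):
            H[i], p[i] = 0.0, 1.0
        else:
            H[i], p[i] = stats.kruskal(*samples)
    adj = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {"H": H, "p": p, "adj_p": adj, "significant": adj <= 0.05}, index=quant.index
    )


def _pairwise_rank_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-group tie-corrected Kruskal-Wallis p (equivalent to a two-sided
    Mann-Whitney with normal-approximation tails)."""
    allv = np.concatenate([a, b])
    if np.all(allv == allv[0]):
        return 1.0
    return float(stats.kruskal(a, b)[1])


def pairwise_pattern(
    quant: pd.DataFrame,
    labels: pd.Series | dict,
    alpha: float = 0.05,
    omnibus: pd.DataFrame | None = None,
) -> pd.Series:
    """Published-style "significant between" pattern per metabolite.

    Requires exactly three clusters.  The three pairwise rank tests are BH
    corrected within each metabolite; the set of significant pairs maps to
    "all" (3 pairs), "McX vs rest" (the two pairs sharing X), "McX vs McY"
    (one pair), or "NS".  Metabolites whose omnibus BH-adjusted p exceeds
    ``alpha`` are "NS" regardless.
    """
    labels = pd.Series(labels).reindex(quant.columns)
    groups = sorted(labels.dropna().unique())
    if len(groups) != 3:
        raise ValueError(f"pairwise pattern requires exactly 3 clusters, got {len(groups)}")
    if omnibus is None:
        omnibus = kruskal_wallis_bh(quant, labels)
    cols = {g: quant.columns[labels == g] for g in groups}
    pairs = [(groups[0], groups[1]), (groups[0], groups[2]), (groups[1], groups[2])]
    out = {}
    for m in quant.index:
        if omnibus.loc[m, "adj_p"] > alpha:
            out[m] = "NS"
            continue
        raw = [
            _pairwise_rank_p(
                quant.loc[m, cols[a]].to_numpy(dtype=float),
                quant.loc[m, cols[b]].to_numpy(dtype=float),
            )
            for a, b in pairs
        ]
        adj = multipletests(raw, method="fdr_bh")[1]
        sig = [pair for pair, q in zip(pairs, adj) if q <= alpha]
        if len(sig) == 3:
            out[m] = "all"
        elif len(sig) == 2:
            (shared,) = set(sig[0]) & set(sig[1])
            out[m] = f"{shared} vs rest"
        elif len(sig) == 1:
            out[m] = f"{sig[0][0]} vs {sig[0][1]}"
        else:
            out[m] = "NS"
    return pd.Series(out, name="pattern")


def cluster_summary(quant: pd.DataFrame, labels: pd.Series | dict) -> pd.DataFrame:
    """Per-metabolite, per-cluster mean and SD (long format)."""
    labels = pd.Series(labels).reindex(quant.columns)
    recs = []
    for g in sorted(labels.dropna().unique()):
        sub = quant.loc[:, quant.columns[labels == g]]
        for m in quant.index:
            recs.append((m, g, sub.loc[m].mean(), sub.loc[m].std(ddof=1)))
    return pd.DataFrame(recs, columns=["metabolite", "cluster", "mean", "sd"])


def fold_change(quant: pd.DataFrame, labels: pd.Series | dict) -> pd.DataFrame:
    """log2(cluster mean / cohort mean), metabolite x cluster."""
    labels = pd.Series(labels).reindex(quant.columns)
    cohort = quant.mean(axis=1)
    if (cohort <= 0).any():
        bad = cohort.index[cohort <= 0].tolist()
        raise ValueError(f"non-positive cohort mean for: {', '.join(map(str, bad))}")
    out = {}
    for g in sorted(labels.dropna().unique()):
        out[g] = np.log2(quant.loc[:, quant.columns[labels == g]].mean(axis=1) / cohort)
    return pd.DataFrame(out)


def quant_table_report(
    quant: pd.DataFrame, labels: pd.Series | dict, alpha: float = 0.05
) -> pd.DataFrame:
    """Published-table-shaped report: per-cluster mean/SD, adjusted p, pattern."""
    labels = pd.Series(labels).reindex(quant.columns)
    omnibus = kruskal_wallis_bh(quant, labels)
    pattern = pairwise_pattern(quant, labels, alpha=alpha, omnibus=omnibus)
    summ = cluster_summary(quant, labels)
    wide = summ.pivot(index="metabolite", columns="cluster")
    wide.columns = [f"{stat}_{g}" for stat, g in wide.columns]
    wide = wide.loc[quant.index]
    wide["adj_p"] = omnibus["adj_p"]
    wide["pattern"] = pattern
    return wide


__all__ = [
    "MetaboliteSpec",
    "integrate_windows",
    "kruskal_wallis_bh",
    "pairwise_pattern",
    "cluster_summary",
    "fold_change",
    "quant_table_report",
]
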