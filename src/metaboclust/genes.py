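"""Expression statistics: probe collapsing, quantile normalization,
SAM-style permutation differential expression, signal-to-noise ranking, and
gene-set enrichment with phenotype permutation.

The SAM statistic is a moderated difference d = (mean difference)/(s + s0)
with the fudge factor s0 chosen from the percentiles of the per-gene pooled
SD s by minimizing the coefficient of variation of d's spread across
s-windows; q-values compare the median permutation exceedance count with the
observed exceedance count at each gene's |d|.

Gene ranking for enrichment uses the absolute signal-to-noise ratio
|mu_A - mu_B| / (sigma_A + sigma_B), with each class SD floored at
max(sigma, 0.2 |mu|) to keep low-variance genes finite.  Enrichment scores
are weighted Kolmogorov-Smirnov running sums (weight exponent 1 on the
score); NES and FDR q follow the standard sign-stratified
phenotype-permutation scheme.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def collapse_probes(matrix: pd.DataFrame, probe_to_gene: dict[str, str]) -> pd.DataFrame:
    """Average probes mapping to the same gene id; drop unmapped probes."""
    mapped = matrix.index.to_series().map(probe_to_gene)
    keep = mapped.notna()
    if not keep.any():
        raise ValueError("no probes map to a gene id")
    out = matrix.loc[keep].groupby(mapped[keep]).mean()
    out.index.name = matrix.index.name
    return out


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Classical quantile normalization.

    Each column's sorted values are replaced by the across-column means of
    the order statistics; tied values receive the mean of their quantile
    values (average ranks).
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least two samples")
    x = matrix.to_numpy(dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("non-finite expression values")
    ref = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        avg_rank = pd.Series(x[:, j]).rank(method="average").to_numpy() - 1.0
        lo = np.floor(avg_rank).astype(int)
        hi = np.ceil(avg_rank).astype(int)
        out[:, j] = 0.5 * (ref[lo] + ref[hi])
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------

@dataclass
class SamResult:
    table: pd.DataFrame  # per gene: d, s, q
    s0: float
    n_perm: int
    design: str


def _sam_stats(x: np.ndarray, groups: list[np.ndarray], s0: float) -> tuple[np.ndarray, np.ndarray]:
    """(numerator-normalized d, pooled s) for two-class or multiclass."""
    k = len(groups)
    n = sum(len(g) for g in groups)
    means = np.stack([x[:, g].mean(axis=1) for g in groups], axis=1)
    ss_within = sum(((x[:, g] - means[:, [i]]) ** 2).sum(axis=1) for i, g in enumerate(groups))
    if k == 2:
        n1, n2 = len(groups[0]), len(groups[1])
        s = np.sqrt((1.0 / n1 + 1.0 / n2) * ss_within / (n - 2))
        r = means[:, 1] - means[:, 0]
    else:
        counts = np.array([len(g) for g in groups], dtype=float)
        grand = (means * counts).sum(axis=1) / n
        between = (counts * (means - grand[:, None]) ** 2).sum(axis=1)
        s = np.sqrt((1.0 / counts).sum() * ss_within / (n - k))
        r = np.sqrt(between)
    return r / (s + s0), s


def _choose_s0(x: np.ndarray, groups: list[np.ndarray]) -> float:
    """Percentile search for the fudge factor.

    Candidates are the 0,5,...,100 percentiles of s; for each, the MAD of d
    is computed within 100 s-quantile windows and the candidate minimizing
    the coefficient of variation of those spreads is chosen.
    """
    _, s = _sam_stats(x, groups, 0.0)
    candidates = np.percentile(s, np.arange(0, 101, 5))
    edges = np.percentile(s, np.linspace(0, 100, 101))
    bins = np.clip(np.searchsorted(edges, s, side="right") - 1, 0, 99)
    best, best_cv = 0.0, np.inf
    for s0 in candidates:
        d, _ = _sam_stats(x, groups, s0)
        mads = []
        for b in range(100):
            sel = bins == b
            if sel.sum() >= 5:
                db = d[sel]
                mads.append(np.median(np.abs(db - np.median(db))))
        mads = np.asarray(mads) / 0.6745
        if len(mads) < 2 or np.median(mads) == 0:
            continue
        cv = mads.std(ddof=1) / mads.mean()
        if cv < best_cv:
            best_cv, best = cv, float(s0)
    return best


def sam_test(
    matrix: pd.DataFrame,
    y,
    design: str = "two_class",
    n_perm: int = 100,
    seed: int = 0,
    s0: float | None = None,
) -> SamResult:
    """SAM permutation differential expression.

    ``design`` is "two_class" (unpaired) or "multiclass".  q-values are the
    median number of permutation exceedances of each gene's |d| divided by
    the observed exceedance count, made monotone in |d| and clipped to 1.
    """
    y = np.asarray(pd.Series(y).reindex(matrix.columns))
    if pd.isna(y).any():
        raise ValueError("labels missing for some samples")
    classes = sorted(set(y.tolist()))
    if design == "two_class" and len(classes) != 2:
        raise ValueError("two_class design requires exactly two classes")
    if design == "multiclass" and len(classes) < 2:
        raise ValueError("multiclass design requires >= 2 classes")
    groups = [np.nonzero(y == c)[0] for c in classes]
    if min(len(g) for g in groups) < 2:
        raise ValueError("every class needs at least 2 samples")
    x = matrix.to_numpy(dtype=float)
    if s0 is None:
        s0 = _choose_s0(x, groups)
    d, s = _sam_stats(x, groups, s0)

    rng = np.random.default_rng(seed)
    abs_d = np.abs(d)
    order = np.argsort(-abs_d, kind="stable")
    sorted_abs = abs_d[order]
    counts = np.empty((n_perm, len(d)), dtype=np.int64)
    sizes = [len(g) for g in groups]
    idx_all = np.arange(len(y))
    for b in range(n_perm):
        perm = rng.permutation(idx_all)
        gperm = []
        start = 0
        for size in sizes:
            gperm.append(perm[start:start + size])
            start += size
        db, _ = _sam_stats(x, gperm, s0)
        # exceedances of each observed |d| threshold by permuted |d| values
        counts[b] = len(db) - np.searchsorted(np.sort(np.abs(db)), sorted_abs, side="left")
    med_exceed = np.median(counts, axis=0)
    obs_exceed = np.arange(1, len(d) + 1)
    q_sorted = np.minimum.accumulate((med_exceed / obs_exceed)[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    table = pd.DataFrame({"d": d, "s": s, "q": q}, index=matrix.index)
    return SamResult(table=table, s0=float(s0), n_perm=n_perm, design=design)


# ---------------------------------------------------------------------------
# Signal-to-noise ranking and GSEA
# ---------------------------------------------------------------------------

def _s2n_scores(
    x: np.ndarray, a_idx: np.ndarray, b_idx: np.ndarray, absolute: bool
) -> np.ndarray:
    mu_a = x[:, a_idx].mean(axis=1)
    mu_b = x[:, b_idx].mean(axis=1)
    sd_a = x[:, a_idx].std(axis=1, ddof=1)
    sd_b = x[:, b_idx].std(axis=1, ddof=1)
    floor = 0.2
    sd_a = np.maximum(np.maximum(sd_a, floor * np.abs(mu_a)), 1e-8)
    sd_b = np.maximum(np.maximum(sd_b, floor * np.abs(mu_b)), 1e-8)
    s2n = (mu_a - mu_b) / (sd_a + sd_b)
    return np.abs(s2n) if absolute else s2n


def s2n_rank(
    matrix: pd.DataFrame, class_a, class_b, labels=None, absolute: bool = True
) -> pd.DataFrame:
    """Per-gene signal-to-noise statistics, sorted by decreasing score.

    ``class_a``/``class_b`` are either boolean/index arrays over columns or,
    with ``labels`` given, class names.  Ties are broken by gene id.
    """
    if labels is not None:
        labels = pd.Series(labels).reindex(matrix.columns)
        a_idx = np.nonzero((labels == class_a).to_numpy())[0]
        b_idx = np.nonzero((labels == class_b).to_numpy())[0]
    else:
        a_idx = np.asarray(class_a)
        b_idx = np.asarray(class_b)
    if len(a_idx) < 2 or len(b_idx) < 2:
        raise ValueError("both classes need at least 2 samples")
    x = matrix.to_numpy(dtype=float)
    mu_a = x[:, a_idx].mean(axis=1)
    mu_b = x[:, b_idx].mean(axis=1)
    sd_a = x[:, a_idx].std(axis=1, ddof=1)
    sd_b = x[:, b_idx].std(axis=1, ddof=1)
    score = _s2n_scores(x, a_idx, b_idx, absolute)
    out = pd.DataFrame(
        {"mu_a": mu_a, "sd_a": sd_a, "mu_b": mu_b, "sd_b": sd_b, "score": score},
        index=matrix.index,
    )
    # descending score, ties broken by gene id
    order = np.lexsort((out.index.to_numpy(), -out["score"].to_numpy()))
    out = out.iloc[order]
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def enrichment_score(ranked_genes: list[str], scores: np.ndarray, members: set[str]) -> float:
    """Weighted KS running-sum enrichment score (weight exponent 1)."""
    hits = np.fromiter((g in members for g in ranked_genes), dtype=bool, count=len(ranked_genes))
    if not hits.any():
        return 0.0
    w = np.abs(scores) * hits
    wsum = w.sum()
    if wsum == 0:  # all member scores zero: fall back to unweighted steps
        w = hits.astype(float)
        wsum = w.sum()
    p_hit = np.cumsum(w) / wsum
    n_miss = (~hits).sum()
    p_miss = np.cumsum(~hits) / max(n_miss, 1)
    dev = p_hit - p_miss
    return float(dev[np.argmax(np.abs(dev))])


@dataclass
class EnrichmentResult:
    table: pd.DataFrame  # per set: size, ES, NES, q
    dropped: dict[str, int]  # set -> size outside [min,max] after restriction
    n_perm: int


def gsea(
    matrix: pd.DataFrame,
    y,
    class_a,
    class_b,
    gene_sets: dict[str, list[str]],
    n_perm: int = 1000,
    seed: int = 0,
    min_size: int = 15,
    max_size: int = 500,
) -> EnrichmentResult:
    """Gene set enrichment with phenotype permutation.

    Genes are ranked by absolute signal-to-noise between the two phenotype
    classes; sets are restricted to measured genes and size-filtered.  NES
    divides each ES by the mean |permutation ES| of the same sign; FDR q is
    the standard sign-stratified ratio of permutation to observed tail
    fractions.
    """
    labels = pd.Series(y).reindex(matrix.columns)
    a_idx = np.nonzero((labels == class_a).to_numpy())[0]
    b_idx = np.nonzero((labels == class_b).to_numpy())[0]
    if len(a_idx) < 2 or len(b_idx) < 2:
        raise ValueError("both phenotype classes need at least 2 samples")
    measured = set(matrix.index)
    sets = {}
    dropped = {}
    for name, members in gene_sets.items():
        restricted = sorted(measured.intersection(members))
        if min_size <= len(restricted) <= max_size:
            sets[name] = set(restricted)
        else:
            dropped[name] = len(restricted)
    if not sets:
        raise ValueError("no gene sets survive the size filter")

    x = matrix.to_numpy(dtype=float)
    genes = np.asarray(matrix.index)

    def all_es(aa: np.ndarray, bb: np.ndarray) -> np.ndarray:
        sc = _s2n_scores(x, aa, bb, absolute=True)
        order = np.lexsort((genes, -sc))  # descending score, gene id tie-break
        ranked = genes[order].tolist()
        rs = sc[order]
        return np.array([enrichment_score(ranked, rs, sets[name]) for name in sets])

    es_obs = all_es(a_idx, b_idx)

    rng = np.random.default_rng(seed)
    pooled = np.concatenate([a_idx, b_idx])
    es_perm = np.empty((n_perm, len(sets)))
    for bi in range(n_perm):
        perm = rng.permutation(pooled)
        es_perm[bi] = all_es(perm[: len(a_idx)], perm[len(a_idx):])

    def _nes(es: np.ndarray, perm: np.ndarray) -> np.ndarray:
        out = np.empty_like(es)
        for j, e in enumerate(es):
            same = perm[:, j][np.sign(perm[:, j]) == np.sign(e)] if e != 0 else perm[:, j]
            denom = np.abs(same).mean() if len(same) else np.nan
            out[j] = e / denom if denom and np.isfinite(denom) and denom > 0 else 0.0
        return out

    nes_obs = _nes(es_obs, es_perm)
    nes_perm = np.empty_like(es_perm)
    for bi in range(n_perm):
        nes_perm[bi] = _nes(es_perm[bi], es_perm)

    q = np.empty_like(nes_obs)
    flat_perm = nes_perm.ravel()
    for j, nes in enumerate(nes_obs):
        if nes >= 0:
            denom_obs = (nes_obs >= nes).sum() / max((nes_obs >= 0).sum(), 1)
            pos = flat_perm[flat_perm >= 0]
            num = (pos >= nes).sum() / max(len(pos), 1)
        else:
            denom_obs = (nes_obs <= nes).sum() / max((nes_obs < 0).sum(), 1)
            neg = flat_perm[flat_perm < 0]
            num = (neg <= nes).sum() / max(len(neg), 1)
        q[j] = min(1.0, num / denom_obs) if denom_obs > 0 else 1.0

    table = pd.DataFrame(
        {
            "size": [len(sets[name]) for name in sets],
            "ES": es_obs,
            "NES": nes_obs,
            "q": q,
        },
        index=list(sets),
    ).sort_values("q", kind="stable")
    return EnrichmentResult(table=table, dropped=dropped, n_perm=n_perm)


__all__ = [
    "collapse_probes",
    "quantile_normalize",
    "SamResult",
    "sam_test",
    "s2n_rank",
    "enrichment_score",
    "EnrichmentResult",
    "gsea",
]
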