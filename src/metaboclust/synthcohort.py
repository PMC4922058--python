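"""Synthetic multi-omics cohort generator.

Emulates the statistical structure of the 228-tumor breast cohort whose
summary tables are in :mod:`metaboclust.reference`:

* HR-MAS-like spectra: 18 Gaussian metabolite resonances on a 1.20-5.00 ppm
  grid, per-cluster level distributions parameterized by the published
  per-cluster means/dispersions, broad lipid peaks planted inside the five
  excluded windows, a broad background hump carrying the unassigned spectral
  area, per-point additive noise, and a per-sample multiplicative gain.
* Matched expression: log2-scale matrix whose differential genes separate
  Mc1 from both Mc2 and Mc3, with no Mc2-vs-Mc3 effects (mirroring the
  cohort, where only Mc1 differed in mRNA expression), plus a designated
  ECM gene set carrying signal and a bank of null sets.
* Categorical labels: PAM50/RPPA subtypes and clinical categories drawn per
  cluster from the published empirical proportions (NA included).

Planted metabolite levels live on the post-normalization scale of the
published table: a scalar per-metabolite calibration (fixed-point iteration
through the actual preprocessing + integration pipeline) guarantees that the
noiseless cohort-mean spectrum quantifies back to the configured means, and
the background hump keeps every noiseless spectrum's retained mean at
exactly 1 so that mean normalization is neutral and per-sample levels are
recovered faithfully.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import reference
from .preprocess import (
    DEFAULT_EXCLUDED_WINDOWS,
    PreprocessParams,
    SpectrumSet,
    preprocess,
    retained_point_mask,
)
from .quant import MetaboliteSpec, integrate_windows

RETAINED_REGION = (1.40, 4.70)

#: ppm of integrated area corresponding to one level unit.  Fixing this
#: (rather than tying it to the grid step) keeps planted levels on the same
#: published scale for any grid resolution.
DEFAULT_AREA_UNIT = 0.0005


# ---------------------------------------------------------------------------
# Default metabolite table
# ---------------------------------------------------------------------------

def default_metabolite_specs(
    fwhm: float = 0.003, lineshape: str = "gaussian"
) -> list[MetaboliteSpec]:
    """The 18 default single-resonance metabolite specs.

    Centers are approximate literature chemical shifts; windows are +-0.015
    ppm except in the crowded choline region and next to the 1.93-2.09
    exclusion window, where they are narrowed to stay pairwise disjoint and
    clear of the excluded intervals.
    """
    specs = []
    for name, center in reference.METABOLITE_PPM.items():
        half = reference.METABOLITE_HALF_WINDOW.get(name, reference.DEFAULT_HALF_WINDOW)
        specs.append(
            MetaboliteSpec(
                name=name,
                peaks=((center, 1.0),),
                fwhm=fwhm,
                window=(center - half, center + half),
                lineshape=lineshape,
            )
        )
    validate_metabolite_specs(specs)
    return specs


def validate_metabolite_specs(
    specs: list[MetaboliteSpec],
    region: tuple[float, float] = RETAINED_REGION,
    excluded: tuple[tuple[float, float], ...] = DEFAULT_EXCLUDED_WINDOWS,
) -> None:
    """Check spec invariants: centers inside the retained region and outside
    every exclusion window; windows pairwise disjoint."""
    for s in specs:
        for center, _ in s.peaks:
            if not region[0] <= center <= region[1]:
                raise ValueError(f"{s.name}: peak at {center} ppm outside region {region}")
            for a, b in excluded:
                if a <= center <= b:
                    raise ValueError(f"{s.name}: peak at {center} ppm inside exclusion ({a}, {b})")
    wins = sorted((s.window, s.name) for s in specs)
    for ((_, hi1), n1), ((lo2, _), n2) in zip(wins, wins[1:]):
        if lo2 < hi1:
            raise ValueError(f"integration windows of {n1} and {n2} overlap")


# ---------------------------------------------------------------------------
# Configuration and truth containers
# ---------------------------------------------------------------------------

@dataclass
class CohortConfig:
    """Conditions of the emulated cohort.

    ``level_table`` follows the layout of ``reference.METABOLITE_LEVELS``
    (per-cluster mean/dispersion columns).  ``dispersion`` selects whether
    the dispersion columns are per-cluster SDs (default) or standard errors
    (converted to SDs using the cluster sizes).
    """

    n_per_cluster: tuple[int, int, int] = (58, 58, 112)
    level_table: pd.DataFrame = field(default_factory=lambda: reference.METABOLITE_LEVELS.copy())
    dispersion: str = "sd"
    gain_sd: float = 0.3
    noise_sd: float = 0.001
    #: Within-cluster correlation of metabolite levels via a per-sample
    #: common "metabolic intensity" factor; marginals keep the configured
    #: per-cluster mean/SD.  Off by default: levels are drawn independently.
    level_corr: float = 0.0
    grid: tuple[float, float, float] = (1.20, 5.00, 0.0005)
    lipid_windows: tuple[tuple[float, float], ...] = DEFAULT_EXCLUDED_WINDOWS
    lipid_amp_max: float = 20.0  # x tallest metabolite peak of the mean spectrum
    lipid_fwhm: float = 0.010
    area_unit: float = DEFAULT_AREA_UNIT
    seed: int = 0
    specs: list[MetaboliteSpec] = field(default_factory=default_metabolite_specs)

    def __post_init__(self) -> None:
        if self.dispersion not in ("sd", "se"):
            raise ValueError("dispersion must be 'sd' or 'se'")
        if any(n <= 0 for n in self.n_per_cluster):
            raise ValueError("cluster counts must be positive")
        lo, hi, step = self.grid
        if step <= 0 or lo >= hi:
            raise ValueError("invalid ppm grid")
        if lo > RETAINED_REGION[0] or hi < RETAINED_REGION[1]:
            raise ValueError(f"grid must cover the retained region {RETAINED_REGION}")
        means = self.cluster_means()
        if (means.to_numpy() < 0).any():
            raise ValueError("metabolite means must be nonnegative")

    @property
    def metabolites(self) -> list[str]:
        return [s.name for s in self.specs]

    def cluster_means(self) -> pd.DataFrame:
        """Metabolite x cluster means."""
        t = self.level_table
        return pd.DataFrame(
            {c: t[f"{c.lower()}_mean"] for c in reference.CLUSTERS}
        ).loc[self.metabolites]

    def cluster_sds(self) -> pd.DataFrame:
        """Metabolite x cluster SDs (converting SE if configured)."""
        t = self.level_table
        sds = pd.DataFrame({c: t[f"{c.lower()}_sd"] for c in reference.CLUSTERS})
        if self.dispersion == "se":
            for c, n in zip(reference.CLUSTERS, self.n_per_cluster):
                sds[c] = sds[c] * np.sqrt(n)
        return sds.loc[self.metabolites]


@dataclass
class SyntheticTruth:
    """Ground truth of a generated cohort."""

    true_cluster: pd.Series
    true_levels: pd.DataFrame  # metabolite x sample
    de_genes: dict[str, list[tuple[str, float]]] = field(default_factory=dict)
    planted_sets: list[str] = field(default_factory=list)
    label_probs: dict[str, pd.DataFrame] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "true_cluster": self.true_cluster.to_dict(),
            "true_levels": {m: self.true_levels.loc[m].to_dict() for m in self.true_levels.index},
            "de_genes": {k: [[g, float(d)] for g, d in v] for k, v in self.de_genes.items()},
            "planted_sets": list(self.planted_sets),
            "label_probs": {k: v.to_dict() for k, v in self.label_probs.items()},
        }


# ---------------------------------------------------------------------------
# Spectral composition and calibration
# ---------------------------------------------------------------------------

class _SpectralModel:
    """Grid, templates and point-sum bookkeeping shared by calibration and
    spectrum generation."""

    def __init__(self, config: CohortConfig):
        self.config = config
        lo, hi, step = config.grid
        n = int(round((hi - lo) / step)) + 1
        self.step = step
        self.ppm = (lo + step * np.arange(n))[::-1].copy()  # descending axis
        self.params = PreprocessParams()
        self.retained = retained_point_mask(self.ppm, self.params)
        self.n_retained = int(self.retained.sum())
        # metabolite templates, rows = metabolites
        self.templates = np.vstack([s.template(self.ppm) for s in config.specs])
        self.template_retained_sums = self.templates[:, self.retained].sum(axis=1)
        # unassigned-signal background: flat plateau over every retained
        # point outside all integration windows (plus a one-point margin), so
        # it carries spectral area without touching any window integral and
        # with minimal leverage on Euclidean distances
        in_window = np.zeros_like(self.ppm, dtype=bool)
        for s in config.specs:
            lo, hi = s.window
            in_window |= (self.ppm >= lo - 2 * step) & (self.ppm <= hi + 2 * step)
        self.background = (self.retained & ~in_window).astype(float)
        self.background_retained_sum = self.background[self.retained].sum()

    def compose(self, scaled_levels: np.ndarray, strict: bool = False) -> np.ndarray:
        """Noiseless spectra (rows) for scaled level rows, with the background
        amplitude per sample chosen so the retained-point mean is exactly 1.

        A sample whose metabolite load alone exceeds the normalized-area
        budget gets zero background (its recovered levels then shrink under
        mean normalization, as they would in real data); with ``strict`` such
        a composition is an error instead, which calibration uses to reject
        infeasible cohort-mean configurations.
        """
        scaled_levels = np.atleast_2d(scaled_levels)
        peaks = scaled_levels @ self.templates
        deficit = self.n_retained - scaled_levels @ self.template_retained_sums
        if np.any(deficit < 0):
            if strict:
                raise ValueError(
                    "configured mean levels exceed the normalized spectral-area budget"
                )
            deficit = np.maximum(deficit, 0.0)
        return peaks + np.outer(deficit / self.background_retained_sum, self.background)

    def quantify(self, intensities: np.ndarray, sample_ids: list[str]) -> pd.DataFrame:
        ss = SpectrumSet(self.ppm, intensities, sample_ids)
        return integrate_windows(preprocess(ss, self.params), self.config.specs,
                                 area_unit=self.config.area_unit)


def calibrate_scales(
    specs: list[MetaboliteSpec],
    mean_levels: pd.Series | np.ndarray,
    config: CohortConfig | None = None,
    tol: float = 1e-3,
    max_iter: int = 10,
) -> np.ndarray:
    """Per-metabolite scale factors making the noiseless cohort-mean spectrum
    quantify back to ``mean_levels`` within ``tol`` (relative).

    Fixed-point iteration: compose the pure mean spectrum, run the standard
    preprocessing and window integration, multiply each scale by
    target/recovered, and repeat.  Metabolites with a zero target get scale 0.
    """
    if config is None:
        config = CohortConfig()
    if list(s.name for s in specs) != config.metabolites:
        config = dataclasses.replace(config, specs=specs)
    model = _SpectralModel(config)
    targets = np.asarray(mean_levels, dtype=float)
    scales = np.full(len(specs), config.area_unit)
    scales[targets == 0] = 0.0
    nz = targets > 0
    ids = ["cohort-mean"]
    for _ in range(max_iter):
        recovered = model.quantify(model.compose(scales * targets, strict=True),
                                   ids).iloc[:, 0].to_numpy()
        rel = np.abs(recovered[nz] / targets[nz] - 1.0)
        if rel.max() < tol:
            return scales
        scales[nz] *= targets[nz] / recovered[nz]
    raise RuntimeError(f"calibration did not converge within {max_iter} iterations "
                       f"(max relative error {rel.max():.2e})")


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _truncated_location(mean: float, sd: float) -> float:
    """Location mu such that a Normal(mu, sd) truncated at zero has the given
    mean.

    Plain truncation of Normal(mean, sd) inflates the realized mean (for
    high-dispersion metabolites like scyllo-inositol by ~2x), which would
    break Monte-Carlo consistency with the configured per-cluster means; the
    location is therefore moment-matched before rejection sampling.
    """
    from scipy import optimize, stats as _st

    if mean <= 0:
        raise ValueError("moment matching requires a positive mean")
    if mean / sd > 8:  # truncation mass ~0; shift numerically zero
        return mean

    def excess(mu: float) -> float:
        alpha = -mu / sd
        # inverse Mills ratio, stable for large alpha
        lam = np.exp(_st.norm.logpdf(alpha) - _st.norm.logsf(alpha))
        return mu + sd * lam - mean

    lo = mean - 40.0 * sd
    return float(optimize.brentq(excess, lo, mean, xtol=1e-10 * max(1.0, mean)))


def _truncated_normal(
    rng: np.random.Generator, mean: np.ndarray, sd: np.ndarray, size: tuple[int, int]
) -> np.ndarray:
    """Zero-truncated normal draws with the requested mean, by rejection.

    ``mean``/``sd`` are per-cell targets (broadcast to ``size``); the
    underlying location is moment-matched per unique (mean, sd) pair.
    """
    mean = np.broadcast_to(np.asarray(mean, dtype=float), size)
    sd = np.broadcast_to(np.asarray(sd, dtype=float), size)
    loc = np.empty(size)
    for m, s in {(float(m), float(s)) for m, s in zip(mean.ravel(), sd.ravel())}:
        cell = (mean == m) & (sd == s)
        if s == 0 or m == 0:
            loc[cell] = m
        else:
            loc[cell] = _truncated_location(m, s)
    out = rng.normal(loc, sd, size=size)
    for _ in range(1000):
        neg = out < 0
        if not neg.any():
            return out
        out[neg] = rng.normal(loc[neg], sd[neg])
    raise RuntimeError("truncated-normal rejection sampling did not terminate")


def _conditional_truncated_location(mean: float, sd: float, rho: float) -> float:
    """Location matching the target mean under common-factor sampling.

    With a common factor z0 and conditional zero-truncation of the
    idiosyncratic part, the marginal mean is
    E_z0[ c + si * lambda(-c/si) ],  c = loc + sd sqrt(rho) z0,
    si = sd sqrt(1-rho); the expectation is evaluated by Gauss-Hermite
    quadrature and inverted for loc.
    """
    from scipy import optimize, stats as _st

    if rho == 0.0:
        return _truncated_location(mean, sd)
    if mean / sd > 8:
        return mean
    nodes, weights = np.polynomial.hermite_e.hermegauss(64)
    weights = weights / np.sqrt(2.0 * np.pi)
    si = sd * np.sqrt(1.0 - rho)

    def marginal_mean(loc: float) -> float:
        c = loc + sd * np.sqrt(rho) * nodes
        alpha = -c / si
        lam = np.exp(_st.norm.logpdf(alpha) - _st.norm.logsf(alpha))
        return float(weights @ (c + si * lam))

    lo = mean - 40.0 * sd
    return float(optimize.brentq(lambda mu: marginal_mean(mu) - mean, lo, mean,
                                 xtol=1e-10 * max(1.0, mean)))


def _correlated_truncated_levels(
    rng: np.random.Generator,
    mean: np.ndarray,
    sd: np.ndarray,
    rho: float,
    size: tuple[int, int],
) -> np.ndarray:
    """Zero-truncated levels with a per-sample common factor.

    level_m = loc_m + sd_m (sqrt(rho) z0 + sqrt(1-rho) z_m), z0 shared within
    a sample; the idiosyncratic component is zero-truncated conditionally on
    z0 (drawn exactly, not by looping), and loc is moment-matched so the
    marginal mean equals the configured mean.  rho = 0 reduces to plain
    zero-truncated normals.
    """
    if rho == 0.0:
        return _truncated_normal(rng, mean, sd, size)
    if not 0.0 <= rho < 1.0:
        raise ValueError("level_corr must be in [0, 1)")
    from scipy.stats import truncnorm

    mean = np.broadcast_to(np.asarray(mean, dtype=float), size)
    sd = np.broadcast_to(np.asarray(sd, dtype=float), size)
    loc = np.empty(size)
    for m, s in {(float(m), float(s)) for m, s in zip(mean.ravel(), sd.ravel())}:
        cell = (mean == m) & (sd == s)
        loc[cell] = m if (s == 0 or m == 0) else _conditional_truncated_location(m, s, rho)
    z0 = rng.standard_normal(size[0])[:, None]
    common = loc + sd * np.sqrt(rho) * z0
    si = sd * np.sqrt(1.0 - rho)
    out = common + si * rng.standard_normal(size)
    neg = out < 0
    if neg.any():
        # replacing a rejected draw by an exact lower-truncated conditional
        # draw yields exactly the truncated conditional law
        a = -common[neg] / si[neg]
        zr = truncnorm.rvs(a, np.inf, size=int(neg.sum()), random_state=rng)
        out[neg] = common[neg] + si[neg] * zr
    return out


def gen_spectra(config: CohortConfig | None = None) -> tuple[SpectrumSet, SyntheticTruth]:
    """Generate the spectral cohort and its ground truth.

    Deterministic given ``config.seed``; stage-specific child generators are
    derived from the root seed in a fixed order.
    """
    if config is None:
        config = CohortConfig()
    model = _SpectralModel(config)
    r_assign, r_levels, r_lipid, r_noise, r_gain = _child_rngs(config.seed, 5)

    n_total = sum(config.n_per_cluster)
    clusters = np.repeat(np.arange(3), config.n_per_cluster)
    r_assign.shuffle(clusters)
    sample_ids = [f"S{i + 1:03d}" for i in range(n_total)]
    cluster_labels = pd.Series(
        [reference.CLUSTERS[c] for c in clusters], index=sample_ids, name="cluster"
    )

    means = config.cluster_means().to_numpy()  # metabolite x cluster
    sds = config.cluster_sds().to_numpy()
    levels = _correlated_truncated_levels(
        r_levels, means[:, clusters].T, sds[:, clusters].T, config.level_corr,
        (n_total, len(config.specs)),
    )

    scales = calibrate_scales(config.specs, means @ np.asarray(config.n_per_cluster) / n_total,
                              config)
    spectra = model.compose(levels * scales)

    # lipid peaks inside the excluded windows (removed by preprocessing)
    peak_height_max = (model.compose(scales * (means @ np.asarray(config.n_per_cluster) / n_total))
                       [0, model.retained]).max()
    sigma_l = config.lipid_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    for lo, hi in config.lipid_windows:
        center = 0.5 * (lo + hi)
        amps = r_lipid.uniform(0.0, config.lipid_amp_max * peak_height_max, size=n_total)
        spectra += np.outer(amps, np.exp(-0.5 * ((model.ppm - center) / sigma_l) ** 2))

    if (spectra < 0).any():
        raise RuntimeError("negative intensity before noise addition")

    if config.noise_sd > 0:
        noise_scale = config.noise_sd * peak_height_max
        spectra = spectra + r_noise.normal(0.0, noise_scale, size=spectra.shape)
    if config.gain_sd > 0:
        spectra = spectra * r_gain.lognormal(0.0, config.gain_sd, size=n_total)[:, None]

    truth = SyntheticTruth(
        true_cluster=cluster_labels,
        true_levels=pd.DataFrame(levels.T, index=config.metabolites, columns=sample_ids),
    )
    return SpectrumSet(model.ppm, spectra, sample_ids), truth


def gen_expression(
    truth: SyntheticTruth,
    n_genes: int = 2000,
    n_de: int = 150,
    effect_range: tuple[float, float] = (0.8, 1.6),
    frac_down: float = 0.8,
    residual_sd: float = 1.0,
    ecm_set_size: int = 50,
    ecm_signal_genes: int = 40,
    n_null_sets: int = 30,
    null_set_sizes: tuple[int, int] = (15, 500),
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Matched log2 expression matrix plus gene sets; updates ``truth``.

    Differential genes shift Mc1 relative to both Mc2 and Mc3 (majority down
    in Mc1); the Mc2-vs-Mc3 planted contrast is exactly zero for every gene.
    One designated ECM set carries signal; null sets are random draws within
    the size band.
    """
    if n_de > n_genes:
        raise ValueError("n_de cannot exceed n_genes")
    ecm_signal_genes = min(ecm_signal_genes, n_de)  # no-signal configs allowed
    if ecm_signal_genes > ecm_set_size:
        raise ValueError("ecm_signal_genes cannot exceed ecm_set_size")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    samples = list(truth.true_cluster.index)
    genes = [f"g{i + 1:05d}" for i in range(n_genes)]
    baseline = rng.normal(8.0, 1.0, size=n_genes)
    x = baseline[:, None] + rng.normal(0.0, residual_sd, size=(n_genes, len(samples)))

    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    signs = np.where(rng.random(n_de) < frac_down, -1.0, 1.0)
    deltas = signs * rng.uniform(*effect_range, size=n_de)
    in_mc1 = (truth.true_cluster == "Mc1").to_numpy()
    x[np.ix_(de_idx, np.nonzero(in_mc1)[0])] += deltas[:, None]

    de = [(genes[i], float(d)) for i, d in zip(de_idx, deltas)]
    truth.de_genes = {
        "Mc1_vs_rest": de,
        "Mc1_vs_Mc2": de,
        "Mc1_vs_Mc3": de,
        "Mc2_vs_Mc3": [],
    }

    gene_sets: dict[str, list[str]] = {}
    ecm = [genes[i] for i in de_idx[:ecm_signal_genes]]
    non_de = sorted(set(range(n_genes)) - set(de_idx.tolist()))
    ecm += [genes[i] for i in rng.choice(non_de, size=ecm_set_size - ecm_signal_genes,
                                         replace=False)]
    gene_sets["ECM_ORGANIZATION"] = sorted(ecm)
    hi = min(null_set_sizes[1], n_genes)
    for k in range(n_null_sets):
        size = int(rng.integers(null_set_sizes[0], hi + 1))
        members = rng.choice(n_genes, size=size, replace=False)
        gene_sets[f"NULL_SET_{k + 1:02d}"] = sorted(genes[i] for i in members)
    truth.planted_sets = ["ECM_ORGANIZATION"]

    expr = pd.DataFrame(x, index=genes, columns=samples)
    return expr, gene_sets


def default_label_probs(config: CohortConfig | None = None) -> dict[str, pd.DataFrame]:
    """Per-cluster multinomials from the published empirical proportions
    (NA category included); samples missing from a printed subtype table are
    folded into NA so that the non-NA conditional fractions match the table."""
    n_per_cluster = dict(zip(reference.CLUSTERS,
                             (config or CohortConfig()).n_per_cluster))
    probs = {}
    tables = dict(reference.CLINICAL_COUNTS)
    tables["pam50"] = reference.PAM50_COUNTS
    tables["rppa"] = reference.RPPA_COUNTS
    for name, counts in tables.items():
        df = reference.counts_frame(counts).astype(float)
        for c in reference.CLUSTERS:
            extra = n_per_cluster[c] - df[c].sum()
            if extra > 0:  # e.g. samples never profiled on that platform
                df.loc["NA", c] += extra
            df[c] = df[c] / df[c].sum()
        probs[name] = df
    return probs


def gen_labels(
    truth: SyntheticTruth,
    prob_tables: dict[str, pd.DataFrame] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw categorical labels per sample from per-cluster multinomials."""
    if prob_tables is None:
        prob_tables = default_label_probs()
    for name, df in prob_tables.items():
        sums = df.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError(f"{name}: per-cluster probabilities must sum to 1 (got {dict(sums)})")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    out = pd.DataFrame(index=truth.true_cluster.index)
    for name, df in prob_tables.items():
        cats = list(df.index)
        col = []
        for sid in out.index:
            c = truth.true_cluster[sid]
            col.append(cats[rng.choice(len(cats), p=df[c].to_numpy())])
        out[name] = col
    truth.label_probs = dict(prob_tables)
    return out


def gen_pathways(
    truth: SyntheticTruth,
    universe_genes: list[str],
    n_null: int = 10,
    seed: int = 0,
) -> list[dict]:
    """Pathway definitions (gene + metabolite members) with one planted
    glycerophospholipid pathway whose genes are differential Mc1-vs-rest and
    whose metabolites separate the clusters; null pathways draw random genes
    from ``universe_genes`` and metabolites without cluster differences."""
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    de = [g for g, _ in truth.de_genes.get("Mc1_vs_rest", [])]
    if len(de) < 20:
        raise ValueError("need at least 20 differential genes to plant a pathway")
    planted = {
        "name": "Glycerophospholipid metabolism",
        "genes": sorted(rng.choice(de, size=20, replace=False).tolist()),
        "metabolites": ["Glycerophosphocholine", "Phosphocholine", "Choline"],
    }
    pathways = [planted]
    ns_metabolites = ["Choline", "Glutamine", "Scyllo-inositol"]
    for k in range(n_null):
        size = int(rng.integers(10, 25))
        genes = rng.choice(universe_genes, size=size, replace=False).tolist()
        mets = rng.choice(ns_metabolites, size=2, replace=False).tolist()
        pathways.append({"name": f"Null pathway {k + 1:02d}", "genes": sorted(genes),
                         "metabolites": mets})
    truth.planted_sets = list(dict.fromkeys(truth.planted_sets + [planted["name"]]))
    return pathways


__all__ = [
    "CohortConfig",
    "SyntheticTruth",
    "default_metabolite_specs",
    "validate_metabolite_specs",
    "calibrate_scales",
    "gen_spectra",
    "gen_expression",
    "default_label_probs",
    "gen_labels",
    "gen_pathways",
]
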