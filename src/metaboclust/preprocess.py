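"""Spectral preprocessing: region crop, lipid-window exclusion, mean normalization.

HR-MAS MRS spectra of breast tissue are dominated by broad lipid resonances
that do not originate from the tumor cells.  The standard workup retains the
1.40-4.70 ppm region, removes five windows containing residual lipid peaks,
and then divides each spectrum by its own mean intensity over the retained
points so that per-sample gain (sample weight, tumor cell percentage) cancels
exactly.  Normalization is applied *after* crop/exclusion, so lipid
amplitudes cannot leak into the normalization constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Retained chemical-shift region (ppm), bounds inclusive.
DEFAULT_REGION = (1.40, 4.70)

#: Excluded lipid windows (ppm), treated as closed intervals.
DEFAULT_EXCLUDED_WINDOWS = (
    (4.27, 4.36),
    (2.70, 2.88),
    (2.20, 2.30),
    (1.93, 2.09),
    (1.50, 1.67),
)


@dataclass(frozen=True)
class PreprocessParams:
    region: tuple[float, float] = DEFAULT_REGION
    excluded_windows: tuple[tuple[float, float], ...] = DEFAULT_EXCLUDED_WINDOWS

    def __post_init__(self) -> None:
        lo, hi = self.region
        if not lo < hi:
            raise ValueError("region lo must be < hi")
        wins = sorted(self.excluded_windows)
        for a, b in wins:
            if not a < b:
                raise ValueError(f"excluded window ({a}, {b}) has lo >= hi")
            if a < lo or b > hi:
                raise ValueError(f"excluded window ({a}, {b}) outside region {self.region}")
        for (_, b1), (a2, _) in zip(wins, wins[1:]):
            if a2 <= b1:
                raise ValueError("excluded windows must be pairwise disjoint")


@dataclass
class SpectrumSet:
    """A ppm axis (descending, NMR convention), an intensity matrix, and ids.

    ``retained_mask`` records, per point of the *original* axis, whether the
    point survived crop/exclusion; it is None for raw spectra.
    """

    ppm: np.ndarray
    intensities: np.ndarray
    sample_ids: list[str]
    retained_mask: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        if self.ppm.ndim != 1:
            raise ValueError("ppm axis must be one-dimensional")
        d = np.diff(self.ppm)
        if len(d) and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("ppm axis must be strictly monotone")
        if self.intensities.shape[1] != self.ppm.size:
            raise ValueError(
                f"intensity matrix width {self.intensities.shape[1]} != axis length {self.ppm.size}"
            )
        if self.intensities.shape[0] != len(self.sample_ids):
            raise ValueError("number of sample ids != number of spectra")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids must be unique")

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    def copy(self) -> "SpectrumSet":
        return SpectrumSet(
            self.ppm.copy(),
            self.intensities.copy(),
            list(self.sample_ids),
            None if self.retained_mask is None else self.retained_mask.copy(),
        )


def retained_point_mask(ppm: np.ndarray, params: PreprocessParams) -> np.ndarray:
    """Boolean mask of points inside the region and strictly outside every
    closed excluded window."""
    lo, hi = params.region
    mask = (ppm >= lo) & (ppm <= hi)
    for a, b in params.excluded_windows:
        mask &= ~((ppm >= a) & (ppm <= b))
    return mask


def crop_and_exclude(spectra: SpectrumSet, params: PreprocessParams | None = None) -> SpectrumSet:
    """Crop to the analysis region and remove the lipid exclusion windows."""
    params = params or PreprocessParams()
    lo, hi = params.region
    if spectra.ppm.min() > hi or spectra.ppm.max() < lo:
        raise ValueError("ppm axis does not overlap the analysis region")
    mask = retained_point_mask(spectra.ppm, params)
    if not mask.any():
        raise ValueError("no spectral points retained after crop/exclusion")
    return SpectrumSet(
        spectra.ppm[mask],
        spectra.intensities[:, mask],
        list(spectra.sample_ids),
        retained_mask=mask,
    )


def mean_normalize(spectra: SpectrumSet) -> SpectrumSet:
    """Divide each spectrum by its own mean over the (retained) points."""
    means = spectra.intensities.mean(axis=1)
    zero = np.isclose(means, 0.0)
    if zero.any():
        bad = [sid for sid, z in zip(spectra.sample_ids, zero) if z]
        raise ValueError(f"zero-mean spectrum cannot be normalized: {', '.join(bad)}")
    out = spectra.copy()
    out.intensities = spectra.intensities / means[:, None]
    return out


def preprocess(spectra: SpectrumSet, params: PreprocessParams | None = None) -> SpectrumSet:
    """Crop + exclude, then mean-normalize (in that order)."""
    return mean_normalize(crop_and_exclude(spectra, params))


def write_retained_mask(path, ppm: np.ndarray, mask: np.ndarray) -> None:
    import pandas as pd

    pd.DataFrame({"ppm": ppm, "retained": mask.astype(int)}).to_csv(path, sep="\t", index=False)


__all__ = [
    "DEFAULT_REGION",
    "DEFAULT_EXCLUDED_WINDOWS",
    "PreprocessParams",
    "SpectrumSet",
    "retained_point_mask",
    "crop_and_exclude",
    "mean_normalize",
    "preprocess",
    "write_retained_mask",
]
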