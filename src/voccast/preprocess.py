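"""Crop-and-threshold reduction of GC-IMS spectra to feature vectors.

All chemical information in a GC-IMS map sits in a central region: analyte
peaks elute early on the GC axis and to the right of the reactant ion peak
(RIP) on the drift axis.  The pipeline therefore (1) crops every spectrum
with the same index-space window, (2) estimates a per-sample background model
from chemical-free regions and zeroes every cell below mean + 2 standard
deviations, and (3) flattens the result row-major into a feature vector.  A
"feature" is one cell of the cropped matrix (optionally mean-pooled over
``bin_size`` x ``bin_size`` blocks), so every selected feature maps back to a
(retention, drift) coordinate for replotting.

Thresholded values are zeroed, not subtracted, and the threshold is estimated
per sample rather than cohort-wide, which tolerates per-run baseline drift.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .io import GCIMSSpectrum

__all__ = [
    "CropWindow",
    "BackgroundModel",
    "FeatureLocation",
    "FeatureMatrix",
    "crop_spectrum",
    "estimate_background",
    "apply_threshold",
    "vectorize",
    "build_feature_matrix",
    "replot_features",
    "SpectrumPreprocessor",
]


@dataclass(frozen=True)
class CropWindow:
    """Half-open index-space rectangle [retention_lo, retention_hi) x [drift_lo, drift_hi)."""

    retention_lo: int
    retention_hi: int
    drift_lo: int
    drift_hi: int

    def __post_init__(self) -> None:
        for lo, hi, name in (
            (self.retention_lo, self.retention_hi, "retention"),
            (self.drift_lo, self.drift_hi, "drift"),
        ):
            if lo < 0 or lo >= hi:
                raise ValueError(f"invalid {name} window [{lo}, {hi}): need 0 <= lo < hi")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.retention_hi - self.retention_lo, self.drift_hi - self.drift_lo)

    @property
    def n_cells(self) -> int:
        r, d = self.shape
        return r * d

    def check_bounds(self, matrix_shape: tuple[int, int]) -> None:
        if self.retention_hi > matrix_shape[0] or self.drift_hi > matrix_shape[1]:
            raise ValueError(f"window {self} exceeds matrix shape {matrix_shape}")


@dataclass(frozen=True)
class BackgroundModel:
    """Per-sample background noise model: threshold = mean + 2 * sample SD."""

    mean: float
    sd: float
    threshold: float
    region: str = ""

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        expected = self.mean + 2.0 * self.sd
        if self.threshold != expected:
            raise ValueError("threshold must equal mean + 2*sd exactly")

    @classmethod
    def from_stats(cls, mean: float, sd: float, region: str = "") -> "BackgroundModel":
        return cls(mean=float(mean), sd=float(sd), threshold=float(mean) + 2.0 * float(sd), region=region)


@dataclass(frozen=True)
class FeatureLocation:
    """Maps a flattened feature index back to spectrum coordinates."""

    feature_index: int
    retention_index: int
    drift_index: int


@dataclass
class FeatureMatrix:
    """Per-sample feature vectors (rows) with the inverse coordinate map."""

    values: np.ndarray
    sample_ids: list[str]
    locations: list[FeatureLocation]
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (samples x features)")
        if self.values.shape[0] != len(self.sample_ids):
            raise ValueError("row count must match number of sample ids")
        if self.values.shape[1] != len(self.locations):
            raise ValueError("column count must match number of feature locations")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape[0] != self.values.shape[0]:
                raise ValueError("labels must align with rows")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=[f"f{loc.feature_index}" for loc in self.locations])
        df.insert(0, "sample_id", self.sample_ids)
        return df


def crop_spectrum(spectrum: GCIMSSpectrum, window: CropWindow) -> np.ndarray:
    """Return the window's sub-matrix (a copy; no value modified)."""
    window.check_bounds(spectrum.shape)
    return spectrum.intensities[
        window.retention_lo : window.retention_hi, window.drift_lo : window.drift_hi
    ].copy()


def _region_cells(spectrum: GCIMSSpectrum, regions: Sequence[CropWindow]) -> np.ndarray:
    cells = []
    for region in regions:
        region.check_bounds(spectrum.shape)
        cells.append(
            spectrum.intensities[
                region.retention_lo : region.retention_hi, region.drift_lo : region.drift_hi
            ].ravel()
        )
    return np.concatenate(cells)


def estimate_background(
    spectrum: GCIMSSpectrum, regions: CropWindow | Sequence[CropWindow]
) -> BackgroundModel:
    """Estimate the background model over one or more chemical-free regions.

    Uses the sample standard deviation (n-1 denominator); requires at least
    two cells.  The default pipeline regions (pre-RIP drift columns and the
    latest retention rows) are disjoint from the crop window by construction.
    """
    if isinstance(regions, CropWindow):
        regions = [regions]
    values = _region_cells(spectrum, regions)
    if values.size < 2:
        raise ValueError("background region must contain at least 2 cells")
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1))
    desc = "; ".join(
        f"rows[{r.retention_lo},{r.retention_hi})xcols[{r.drift_lo},{r.drift_hi})" for r in regions
    )
    return BackgroundModel.from_stats(mean, sd, region=desc)


def apply_threshold(matrix: np.ndarray, model: BackgroundModel) -> np.ndarray:
    """Zero every cell strictly below the model threshold; others unchanged."""
    matrix = np.asarray(matrix, dtype=float)
    if not np.all(np.isfinite(matrix)):
        raise ValueError("matrix contains non-finite values")
    out = matrix.copy()
    out[out < model.threshold] = 0.0
    return out


def _pool(matrix: np.ndarray, bin_size: int) -> np.ndarray:
    if bin_size == 1:
        return matrix
    h = (matrix.shape[0] // bin_size) * bin_size
    w = (matrix.shape[1] // bin_size) * bin_size
    trimmed = matrix[:h, :w]
    return trimmed.reshape(h // bin_size, bin_size, w // bin_size, bin_size).mean(axis=(1, 3))


def feature_locations(window: CropWindow, bin_size: int = 1) -> list[FeatureLocation]:
    """Row-major locations of each feature; bin centres for ``bin_size`` > 1."""
    h, w = window.shape
    rows = range(h // bin_size)
    cols = range(w // bin_size)
    locs = []
    idx = 0
    for i in rows:
        for j in cols:
            locs.append(
                FeatureLocation(
                    feature_index=idx,
                    retention_index=window.retention_lo + i * bin_size + bin_size // 2,
                    drift_index=window.drift_lo + j * bin_size + bin_size // 2,
                )
            )
            idx += 1
    return locs


def vectorize(
    matrix: np.ndarray, window: CropWindow, bin_size: int = 1
) -> tuple[np.ndarray, list[FeatureLocation]]:
    """Flatten a cropped (and thresholded) matrix row-major into a feature vector.

    Returns the vector and the location list mapping each entry back to
    original spectrum coordinates.  With ``bin_size`` 1 the map is a bijection
    with the window's cells.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape != window.shape:
        raise ValueError(f"matrix shape {matrix.shape} does not match window shape {window.shape}")
    pooled = _pool(matrix, bin_size)
    return pooled.ravel(), feature_locations(window, bin_size)


def build_feature_matrix(
    spectra: Sequence[GCIMSSpectrum],
    window: CropWindow,
    background_regions: CropWindow | Sequence[CropWindow],
    bin_size: int = 1,
    labels: np.ndarray | None = None,
) -> FeatureMatrix:
    """Crop, threshold and vectorize each spectrum; stack rows in input order.

    The background model is estimated and applied per sample, so each row is
    a pure function of its own spectrum.
    """
    if not spectra:
        raise ValueError("need at least one spectrum")
    shape = spectra[0].shape
    rows = []
    locations: list[FeatureLocation] = []
    for spec in spectra:
        if spec.shape != shape:
            raise ValueError(f"heterogeneous spectrum shapes: {spec.shape} vs {shape}")
        bg = estimate_background(spec, background_regions)
        cropped = crop_spectrum(spec, window)
        thresholded = apply_threshold(cropped, bg)
        vec, locations = vectorize(thresholded, window, bin_size)
        rows.append(vec)
    return FeatureMatrix(
        values=np.vstack(rows),
        sample_ids=[s.sample_id for s in spectra],
        locations=locations,
        labels=labels,
    )


def replot_features(
    spectrum: GCIMSSpectrum, selected: Sequence[FeatureLocation]
) -> pd.DataFrame:
    """Overlay markers for selected features on the original spectrum.

    Returns one row per feature with its rank (selection order), index-space
    coordinates and axis values — ready for plotting over the intensity map.
    """
    n_ret, n_drift = spectrum.shape
    records = []
    for rank, loc in enumerate(selected):
        if not (0 <= loc.retention_index < n_ret and 0 <= loc.drift_index < n_drift):
            raise ValueError(f"feature location {loc} outside spectrum bounds {spectrum.shape}")
        records.append(
            {
                "rank": rank,
                "retention_index": loc.retention_index,
                "drift_index": loc.drift_index,
                "retention_time": spectrum.retention_axis[loc.retention_index],
                "drift_time": spectrum.drift_axis[loc.drift_index],
            }
        )
    return pd.DataFrame(
        records, columns=["rank", "retention_index", "drift_index", "retention_time", "drift_time"]
    )


class SpectrumPreprocessor(TransformerMixin, BaseEstimator):
    """Sklearn-style transformer from GC-IMS spectra to feature vectors.

    Parameters
    ----------
    window : CropWindow
        Crop window applied identically to every spectrum.
    background_regions : CropWindow or sequence of CropWindow
        Chemical-free regions for the per-sample background model.
    bin_size : int, default 1
        Mean-pooling block size over the cropped matrix.
    """

    def __init__(self, window=None, background_regions=None, bin_size: int = 1):
        self.window = window
        self.background_regions = background_regions
        self.bin_size = bin_size

    def fit(self, X: Sequence[GCIMSSpectrum], y=None):
        if self.window is None or self.background_regions is None:
            raise ValueError("window and background_regions are required")
        self.locations_ = feature_locations(self.window, self.bin_size)
        self.n_features_out_ = len(self.locations_)
        return self

    def transform(self, X: Sequence[GCIMSSpectrum]) -> np.ndarray:
        fm = build_feature_matrix(list(X), self.window, self.background_regions, self.bin_size)
        return fm.values

    def feature_matrix(self, X: Sequence[GCIMSSpectrum], labels=None) -> FeatureMatrix:
        return build_feature_matrix(list(X), self.window, self.background_regions, self.bin_size, labels)
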