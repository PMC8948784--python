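"""Synthetic GC-IMS cohort generator with planted ground truth.

The clinical raw data behind this pipeline are not publicly deposited, so
every downstream stage is exercised against simulated cohorts that carry the
statistical structure the analysis assumes: a constant instrument baseline, a
high-intensity reactant-ion-peak (RIP) ridge at a fixed drift column,
Gaussian analyte peaks concentrated at early retention times (light
chemicals elute from the GC column first), additive truncated-Gaussian noise,
and — in one of two groups — a multiplicative intensity shift at a configurable
set of planted "effect" peaks.  Concentration changes scale peak height in
ion mobility spectrometry, hence the multiplicative effect model.

The generator also emits paired clinical metadata whose calprotectin / HBI /
SCCAI values fall inside the activity-definition ranges for a requested
transition-group code, closing the loop with the state labeller.

Default matrix shape is 200 x 150 — desk-scale rather than the instrument's
~11 million datapoints; every algorithm in the package is shape-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .activity import GROUP_CODES
from .io import GCIMSSpectrum, SampleRecord
from .preprocess import CropWindow, FeatureLocation

__all__ = [
    "PeakSpec",
    "CohortDesign",
    "default_design",
    "default_crop_window",
    "default_background_regions",
    "simulate_spectrum",
    "simulate_cohort",
    "simulate_metadata",
    "simulate_study",
    "effect_footprint",
]


@dataclass(frozen=True)
class PeakSpec:
    """One Gaussian analyte blob in (retention, drift) index space."""

    retention_index: int
    drift_index: int
    amplitude: float
    sigma_retention: float
    sigma_drift: float

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if self.sigma_retention <= 0 or self.sigma_drift <= 0:
            raise ValueError("peak sigmas must be positive")


@dataclass
class CohortDesign:
    """Full description of a two-group synthetic cohort.

    ``effect_multiplier`` scales the amplitude of every ``effect_peaks`` entry
    in group 1 only; 1.0 makes the two groups exchangeable (the null).
    """

    n_per_group: tuple[int, int] = (40, 40)
    matrix_shape: tuple[int, int] = (200, 150)
    rip_drift_index: int = 20
    shared_peaks: list[PeakSpec] = field(default_factory=list)
    effect_peaks: list[PeakSpec] = field(default_factory=list)
    effect_multiplier: float = 3.0
    noise_sd: float = 10.0
    baseline: float = 100.0
    rip_amplitude: float = 3000.0
    rip_sigma: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        n0, n1 = self.n_per_group
        if n0 < 2 or n1 < 2:
            raise ValueError("need at least 2 samples per group")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.baseline < 0:
            raise ValueError("baseline must be non-negative")
        if self.effect_multiplier < 0:
            raise ValueError("effect_multiplier must be non-negative")
        rows, cols = self.matrix_shape
        if not 0 <= self.rip_drift_index < cols:
            raise ValueError("rip_drift_index outside matrix bounds")
        for peak in list(self.shared_peaks) + list(self.effect_peaks):
            if not (0 <= peak.retention_index < rows and 0 <= peak.drift_index < cols):
                raise ValueError(f"peak {peak} outside matrix bounds {self.matrix_shape}")


def default_design(
    seed: int = 0,
    n_per_group: tuple[int, int] = (40, 40),
    matrix_shape: tuple[int, int] = (200, 150),
    n_shared: int = 60,
    n_effect: int = 5,
    effect_multiplier: float = 3.0,
    noise_sd: float = 10.0,
) -> CohortDesign:
    """Build a realistic design: many shared peaks biased to early retention.

    Peak geometry scales with the matrix so reduced-size designs (e.g. 50x40
    for null simulations) remain well formed.  Retention positions follow a
    truncated exponential — most analytes are light and elute early.
    """
    rng = np.random.default_rng(seed)
    rows, cols = matrix_shape
    rip = max(4, cols // 8)
    drift_lo, drift_hi = rip + max(6, cols // 15), cols - max(4, cols // 20)
    ret_hi = int(rows * 0.75)

    def draw_peaks(n: int, amp_lo: float, amp_hi: float) -> list[PeakSpec]:
        peaks = []
        for _ in range(n):
            r = int(min(ret_hi - 1, rng.exponential(scale=rows * 0.22)))
            d = int(rng.integers(drift_lo, drift_hi))
            peaks.append(
                PeakSpec(
                    retention_index=max(2, r),
                    drift_index=d,
                    amplitude=float(rng.uniform(amp_lo, amp_hi)),
                    sigma_retention=float(rng.uniform(1.5, 3.0)),
                    sigma_drift=float(rng.uniform(1.2, 2.5)),
                )
            )
        return peaks

    return CohortDesign(
        n_per_group=n_per_group,
        matrix_shape=matrix_shape,
        rip_drift_index=rip,
        shared_peaks=draw_peaks(n_shared, 100.0, 600.0),
        effect_peaks=draw_peaks(n_effect, 120.0, 250.0),
        effect_multiplier=effect_multiplier,
        noise_sd=noise_sd,
        baseline=100.0,
        seed=seed,
    )


def default_crop_window(design: CohortDesign) -> CropWindow:
    """Central region holding the chemical information: past the RIP, early rows."""
    rows, cols = design.matrix_shape
    return CropWindow(
        retention_lo=0,
        retention_hi=int(rows * 0.8),
        drift_lo=design.rip_drift_index + max(6, cols // 15),
        drift_hi=cols - max(2, cols // 60),
    )


def default_background_regions(design: CohortDesign) -> list[CropWindow]:
    """Chemical-free cells: pre-RIP drift columns plus the last 10% of rows."""
    rows, cols = design.matrix_shape
    crop = default_crop_window(design)
    pre_rip_hi = max(2, design.rip_drift_index - max(4, cols // 12))
    return [
        CropWindow(0, rows, 0, pre_rip_hi),
        CropWindow(int(rows * 0.9), rows, crop.drift_lo, crop.drift_hi),
    ]


def _peak_field(shape: tuple[int, int], peaks: Sequence[PeakSpec], scale: float = 1.0) -> np.ndarray:
    rows, cols = shape
    field_ = np.zeros(shape)
    r = np.arange(rows)[:, None]
    d = np.arange(cols)[None, :]
    for peak in peaks:
        field_ += (scale * peak.amplitude) * np.exp(
            -0.5 * ((r - peak.retention_index) / peak.sigma_retention) ** 2
            - 0.5 * ((d - peak.drift_index) / peak.sigma_drift) ** 2
        )
    return field_


def simulate_spectrum(
    design: CohortDesign,
    group: int,
    rng: np.random.Generator,
    sample_id: str = "S0",
) -> GCIMSSpectrum:
    """Draw one spectrum: baseline + RIP ridge + peaks + truncated noise.

    The final matrix is clipped at zero so every intensity satisfies the
    spectrum non-negativity invariant.
    """
    if group not in (0, 1):
        raise ValueError("group must be 0 or 1")
    rows, cols = design.matrix_shape
    d = np.arange(cols)
    rip = design.rip_amplitude * np.exp(
        -0.5 * ((d - design.rip_drift_index) / design.rip_sigma) ** 2
    )
    signal = design.baseline + rip[None, :]
    signal = signal + _peak_field(design.matrix_shape, design.shared_peaks)
    effect_scale = design.effect_multiplier if group == 1 else 1.0
    signal = signal + _peak_field(design.matrix_shape, design.effect_peaks, effect_scale)
    noise = rng.normal(0.0, design.noise_sd, size=design.matrix_shape)
    intensities = np.clip(signal + noise, 0.0, None)
    return GCIMSSpectrum(
        sample_id=sample_id,
        intensities=intensities,
        retention_axis=np.arange(rows, dtype=float) * 2.4,  # seconds; 8-minute run
        drift_axis=1.0 + np.arange(cols, dtype=float) * 0.06,  # milliseconds
        meta={"group": group, "synthetic": True},
    )


def effect_footprint(design: CohortDesign) -> list[FeatureLocation]:
    """Ground-truth cells within 2 sigma (elliptical) of any effect peak centre.

    ``feature_index`` here is the full-matrix row-major index; crop-relative
    indices depend on the window and are resolved by the caller.
    """
    rows, cols = design.matrix_shape
    mask = np.zeros(design.matrix_shape, dtype=bool)
    r = np.arange(rows)[:, None]
    d = np.arange(cols)[None, :]
    for peak in design.effect_peaks:
        maha2 = ((r - peak.retention_index) / peak.sigma_retention) ** 2 + (
            (d - peak.drift_index) / peak.sigma_drift
        ) ** 2
        mask |= maha2 <= 4.0
    return [
        FeatureLocation(feature_index=int(i * cols + j), retention_index=int(i), drift_index=int(j))
        for i, j in zip(*np.nonzero(mask))
    ]


def simulate_cohort(
    design: CohortDesign,
) -> tuple[list[GCIMSSpectrum], np.ndarray, list[FeatureLocation]]:
    """Generate the full two-group cohort, reproducibly from ``design.seed``.

    Returns spectra (group 0 first), 0/1 group labels, and the ground-truth
    effect footprint.
    """
    rng = np.random.default_rng(design.seed)
    spectra = []
    labels = []
    for group, n in zip((0, 1), design.n_per_group):
        for i in range(n):
            spectra.append(simulate_spectrum(design, group, rng, sample_id=f"G{group}-S{i:03d}"))
            labels.append(group)
    return spectra, np.asarray(labels), effect_footprint(design)


# value ranges that the state definitions map to remission / active
_FCP_RANGES = {"remission": (0.0, 100.0), "active": (250.0, 1000.0)}
_HBI_RANGES = {"remission": (0, 4), "active": (5, 17)}  # integer, half-open
_SCCAI_RANGES = {"remission": (0, 3), "active": (3, 13)}
_DIGIT_STATES = {1: ("remission", "remission"), 2: ("remission", "active"),
                 3: ("active", "active"), 4: ("active", "remission")}


def simulate_metadata(
    design: CohortDesign,
    transition: str,
    n_pairs: int | None = None,
    subtype: str = "CD",
    rng: np.random.Generator | None = None,
    patient_prefix: str | None = None,
) -> list[tuple[SampleRecord, SampleRecord]]:
    """Generate per-patient record pairs that the labeller maps to ``transition``.

    Biochemical codes (B*) draw FCP uniformly from [0, 100) for remission and
    [250, 1000] for active; clinical codes (A*) draw HBI (CD) or SCCAI
    (UC/IBDU) integers from the corresponding definitional ranges.
    """
    if transition not in GROUP_CODES:
        raise ValueError(f"unknown transition code {transition!r}")
    if rng is None:
        rng = np.random.default_rng(design.seed)
    if n_pairs is None:
        n_pairs = design.n_per_group[0]
    prefix = patient_prefix if patient_prefix is not None else transition
    letter, digit = transition[0], int(transition[1])
    states = _DIGIT_STATES[digit]
    pairs = []
    for p in range(n_pairs):
        pid = f"{prefix}-P{p:03d}"
        recs = []
        for k, state in enumerate(states):
            kwargs: dict = {}
            if letter == "B":
                lo, hi = _FCP_RANGES[state]
                kwargs["fcp"] = float(rng.uniform(lo, hi))
            elif subtype == "CD":
                lo, hi = _HBI_RANGES[state]
                kwargs["hbi"] = int(rng.integers(lo, hi))
            else:
                lo, hi = _SCCAI_RANGES[state]
                kwargs["sccai"] = int(rng.integers(lo, hi))
            recs.append(
                SampleRecord(
                    patient_id=pid,
                    sample_id=f"{pid}-T{k}",
                    seq_index=k + 1,
                    subtype=subtype,
                    **kwargs,
                )
            )
        pairs.append((recs[0], recs[1]))
    return pairs


def simulate_study(
    design: CohortDesign,
    codes: tuple[str, str] = ("B1", "B2"),
    subtype: str = "CD",
) -> tuple[list[GCIMSSpectrum], list[SampleRecord], np.ndarray, list[FeatureLocation]]:
    """Coherent end-to-end study: spectra + metadata linked by sample id.

    Group 0 patients follow ``codes[0]``, group 1 (whose first-collection
    spectra carry the planted effect) follow ``codes[1]``.  Each pair's
    *first* sample gets a spectrum — the study design predicts the state at
    the second collection from the first sample's VOC profile.
    """
    rng = np.random.default_rng(design.seed)
    spectra: list[GCIMSSpectrum] = []
    records: list[SampleRecord] = []
    labels: list[int] = []
    for group, (code, n) in enumerate(zip(codes, design.n_per_group)):
        meta_pairs = simulate_metadata(design, code, n_pairs=n, subtype=subtype, rng=rng)
        for first, second in meta_pairs:
            spec = simulate_spectrum(design, group, rng, sample_id=first.sample_id)
            spectra.append(spec)
            records.extend([first, second])
            labels.append(group)
    return spectra, records, np.asarray(labels), effect_footprint(design)


def design_to_dict(design: CohortDesign) -> dict:
    """JSON-ready representation of a design (used by the CLI)."""
    return asdict(design)


def design_from_dict(data: dict) -> CohortDesign:
    data = dict(data)
    for key in ("shared_peaks", "effect_peaks"):
        data[key] = [PeakSpec(**p) if isinstance(p, dict) else p for p in data.get(key, [])]
    for key in ("n_per_group", "matrix_shape"):
        if key in data:
            data[key] = tuple(data[key])
    return CohortDesign(**data)
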