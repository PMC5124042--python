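"""Synthetic multi-echo spin-echo phantoms and cohorts.

This module generates digital phantoms with the statistical structure a
quantitative T2 ageing analysis assumes: adjacent gray-matter-like and
white-matter-like compartments with distinct T2 values, an optional
age-dependent drift of tissue T2, Rician magnitude noise, a smooth
multiplicative bias field, and stimulated-echo contamination confined to
the first echo of the train.  Every generator is seeded and returns a
ground-truth manifest sufficient to regenerate its output bit-identically.

The signal model for a voxel of tissue with proton density ``PD`` and
transverse relaxation time ``T2(age)`` at echo time ``TE`` is

    S(TE) = PD * exp(-TE / T2(age)),

with ``T2(age) = t2_ms + t2_age_slope * (age - reference_age)``.  The first
echo is additionally scaled by ``first_echo_gain`` to emulate stimulated-echo
contamination from imperfect refocusing pulses; downstream fitting excludes
that echo.  No T1 saturation term is modelled: the emulated acquisition uses
TR = 4500 ms, long enough that longitudinal recovery is treated as complete.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "TissueSpec",
    "PhantomGeometry",
    "AcquisitionSpec",
    "SubjectRecord",
    "GroundTruth",
    "CohortGroundTruth",
    "DEFAULT_REFERENCE_AGE",
    "LAYOUTS",
    "build_geometry",
    "make_bias_field",
    "simulate_echo_train",
    "simulate_cohort",
]

#: Cohort mean age of the emulated study; injected T2 age slopes pivot here.
DEFAULT_REFERENCE_AGE = 67.3


@dataclass(frozen=True)
class TissueSpec:
    """One simulated tissue compartment.

    Parameters
    ----------
    label : str
        Short region name, e.g. ``"GM"``, ``"WM"``, ``"CA1"``, ``"SLSRSM"``.
    proton_density : float
        Equilibrium signal amplitude in arbitrary units, > 0.
    t2_ms : float
        Transverse relaxation time in ms at the reference age, > 0.
    t2_age_slope : float
        Change of T2 in ms per year of age; may be zero or negative.
    """

    label: str
    proton_density: float
    t2_ms: float
    t2_age_slope: float = 0.0

    def __post_init__(self) -> None:
        if self.proton_density <= 0:
            raise ValueError(f"proton_density must be > 0, got {self.proton_density}")
        if self.t2_ms <= 0:
            raise ValueError(f"t2_ms must be > 0, got {self.t2_ms}")

    def t2_at_age(self, age_years: float, reference_age: float = DEFAULT_REFERENCE_AGE) -> float:
        """T2 in ms at a given age; raises if the linear drift makes it nonpositive."""
        t2 = self.t2_ms + self.t2_age_slope * (age_years - reference_age)
        if t2 <= 0:
            raise ValueError(
                f"T2 of tissue {self.label!r} is {t2:.3f} ms at age {age_years}; must stay > 0"
            )
        return t2


@dataclass(frozen=True)
class PhantomGeometry:
    """Voxel label volume plus the face-connected adjacency of its compartments."""

    shape: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float]
    label_volume: np.ndarray
    layout: str
    adjacent_pairs: tuple[tuple[int, int], ...]

    @property
    def labels(self) -> tuple[int, ...]:
        """Nonzero labels present in the volume, ascending."""
        vals = np.unique(self.label_volume)
        return tuple(int(v) for v in vals if v != 0)

    def mask(self, label: int) -> np.ndarray:
        """Boolean mask of one compartment."""
        return np.asarray(self.label_volume == label)


@dataclass(frozen=True)
class AcquisitionSpec:
    """Multi-echo spin-echo acquisition parameters.

    Defaults emulate a 10-echo train with 12 ms spacing at TR 4500 ms.
    ``tr_ms`` is metadata only; no T1 weighting is simulated.
    ``first_echo_gain`` is the multiplicative stimulated-echo contamination
    applied to echo 1 only (1.0 disables it).
    """

    n_echoes: int = 10
    echo_spacing_ms: float = 12.0
    tr_ms: float = 4500.0
    noise_sigma: float = 0.0
    bias_amplitude: float = 0.0
    bias_smoothness: float = 8.0
    first_echo_gain: float = 1.10

    def __post_init__(self) -> None:
        if self.n_echoes < 2:
            raise ValueError("n_echoes must be >= 2")
        if self.echo_spacing_ms <= 0:
            raise ValueError("echo_spacing_ms must be > 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.bias_amplitude < 0:
            raise ValueError("bias_amplitude must be >= 0")

    @property
    def echo_times_ms(self) -> np.ndarray:
        """Echo times: spacing × (1..n_echoes)."""
        return self.echo_spacing_ms * np.arange(1, self.n_echoes + 1, dtype=float)


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    age_years: float
    sex: str = "unspecified"

    def __post_init__(self) -> None:
        if self.sex not in ("F", "M", "unspecified"):
            raise ValueError(f"sex must be 'F', 'M' or 'unspecified', got {self.sex!r}")


@dataclass(frozen=True)
class GroundTruth:
    """Phantom truth for one simulated volume."""

    true_t2_volume: np.ndarray  # ms per voxel; NaN in background
    label_volume: np.ndarray
    injected_slopes: dict[str, float]  # tissue label -> ms/year
    reference_age_years: float
    age_years: float
    seed: int


@dataclass
class CohortGroundTruth:
    """Manifest for a simulated cohort: everything needed to regenerate it."""

    seed: int
    subject_seeds: dict[str, int] = field(default_factory=dict)
    subject_truths: dict[str, GroundTruth] = field(default_factory=dict)
    injected_slopes: dict[str, float] = field(default_factory=dict)
    reference_age_years: float = DEFAULT_REFERENCE_AGE


# --------------------------------------------------------------------------
# geometry

LAYOUTS = ("two_compartment", "subfield_strips", "cingulate_pair")

_MIN_SHAPE = 8


def build_geometry(
    shape: Sequence[int],
    voxel_size_mm: Sequence[float] = (1.0, 1.0, 1.0),
    layout_name: str = "two_compartment",
) -> PhantomGeometry:
    """Construct a deterministic label volume for a named layout.

    Layouts place compartments as adjacent slabs inside a one-voxel background
    border, guaranteeing every labelled pair shares a face-connected boundary:

    - ``two_compartment``: GM-like (1) | WM-like (2) halves split along x.
    - ``subfield_strips``: three strips 1|2|3 along x, emulating the
      CA1 | SL/SR/SM | DG arrangement of hippocampal subfields (the middle
      strip is the white-matter-like layer bordered by gray on both sides).
    - ``cingulate_pair``: cortical GM slab (1) over adjacent WM slab (2)
      split along y.

    Returns the geometry with its list of face-adjacent label pairs.
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3:
        raise ValueError("shape must be 3D")
    if layout_name not in LAYOUTS:
        raise ValueError(f"unknown layout {layout_name!r}; known layouts: {LAYOUTS}")
    if any(s < _MIN_SHAPE for s in shape):
        raise ValueError(f"shape too small for layout {layout_name!r}: need >= {_MIN_SHAPE} per axis")

    labels = np.zeros(shape, dtype=np.int16)
    # interior excludes a one-voxel background border on every face
    ix = slice(1, shape[0] - 1)
    iy = slice(1, shape[1] - 1)
    iz = slice(1, shape[2] - 1)

    if layout_name == "two_compartment":
        half = shape[0] // 2
        labels[1:half, iy, iz] = 1
        labels[half : shape[0] - 1, iy, iz] = 2
        pairs = ((1, 2),)
    elif layout_name == "subfield_strips":
        third = (shape[0] - 2) // 3
        a, b = 1 + third, 1 + 2 * third
        labels[1:a, iy, iz] = 1  # CA1-like gray strip
        labels[a:b, iy, iz] = 2  # SL/SR/SM-like white strip
        labels[b : shape[0] - 1, iy, iz] = 3  # DG-like gray strip
        pairs = ((1, 2), (2, 3))
    else:  # cingulate_pair
        half = shape[1] // 2
        labels[ix, 1:half, iz] = 1
        labels[ix, half : shape[1] - 1, iz] = 2
        pairs = ((1, 2),)

    return PhantomGeometry(
        shape=shape,
        voxel_size_mm=tuple(float(v) for v in voxel_size_mm),
        label_volume=labels,
        layout=layout_name,
        adjacent_pairs=pairs,
    )


# --------------------------------------------------------------------------
# bias field

def make_bias_field(
    shape: Sequence[int],
    amplitude: float,
    smoothness: float = 8.0,
    seed: int = 0,
) -> np.ndarray:
    """Smooth multiplicative shading field with unit spatial mean.

    A seeded white-noise volume is Gaussian-smoothed with ``smoothness``
    voxels of correlation length, normalised so that ``amplitude`` is the
    peak deviation from 1 (field = 1 + amplitude * g / max|g|), then rescaled
    to spatial mean exactly 1.  ``amplitude`` 0 returns the all-ones field.
    Emulates the slowly varying B0/B1/coil shading that real pipelines
    suppress before contrast estimation.
    """
    shape = tuple(int(s) for s in shape)
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    if smoothness <= 0:
        raise ValueError("smoothness must be > 0")
    if amplitude == 0:
        return np.ones(shape, dtype=float)

    rng = np.random.default_rng(seed)
    g = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=smoothness)
    peak = np.abs(g).max()
    if peak == 0:  # pathological smoothing of a tiny grid
        return np.ones(shape, dtype=float)
    fld = 1.0 + amplitude * g / peak
    fld /= fld.mean()
    return fld


# --------------------------------------------------------------------------
# signal simulation

def _rician(signal: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Magnitude of (signal + complex Gaussian noise), sigma per channel."""
    re = signal + rng.normal(0.0, sigma, signal.shape)
    im = rng.normal(0.0, sigma, signal.shape)
    return np.hypot(re, im)


def simulate_echo_train(
    geometry: PhantomGeometry,
    tissues: dict[int, TissueSpec],
    acquisition: AcquisitionSpec,
    age_years: float = DEFAULT_REFERENCE_AGE,
    reference_age: float = DEFAULT_REFERENCE_AGE,
    seed: int = 0,
):
    """Simulate one 4D echo train plus its ground truth.

    The noiseless, bias-free signal at echo i >= 2 is PD * exp(-TE_i / T2(age));
    echo 1 is additionally multiplied by ``first_echo_gain``.  Rician noise is
    applied per voxel per echo when ``noise_sigma`` > 0; background (label 0)
    then contains pure Rayleigh noise.

    Returns
    -------
    (EchoTrainVolume, GroundTruth)
    """
    from .relaxometry import EchoTrainVolume  # local import avoids a cycle

    missing = [lab for lab in geometry.labels if lab not in tissues]
    if missing:
        raise ValueError(f"missing TissueSpec for labels {missing}")

    echo_times = acquisition.echo_times_ms
    labels = geometry.label_volume
    true_t2 = np.full(geometry.shape, np.nan)
    pd_vol = np.zeros(geometry.shape)
    slopes = {}
    for lab in geometry.labels:
        spec = tissues[lab]
        t2 = spec.t2_at_age(age_years, reference_age)  # raises if <= 0
        m = labels == lab
        true_t2[m] = t2
        pd_vol[m] = spec.proton_density
        slopes[spec.label] = spec.t2_age_slope

    with np.errstate(invalid="ignore", divide="ignore"):
        decay = np.exp(-echo_times[None, None, None, :] / true_t2[..., None])
    signal = pd_vol[..., None] * np.nan_to_num(decay)
    signal[..., 0] *= acquisition.first_echo_gain

    if acquisition.bias_amplitude > 0:
        bias = make_bias_field(
            geometry.shape, acquisition.bias_amplitude, acquisition.bias_smoothness, seed=seed
        )
        signal = signal * bias[..., None]

    if acquisition.noise_sigma > 0:
        rng = np.random.default_rng(seed)
        signal = _rician(signal, acquisition.noise_sigma, rng)

    volume = EchoTrainVolume(
        intensities=signal,
        echo_times_ms=echo_times,
        voxel_size_mm=geometry.voxel_size_mm,
    )
    truth = GroundTruth(
        true_t2_volume=true_t2,
        label_volume=labels,
        injected_slopes=slopes,
        reference_age_years=reference_age,
        age_years=age_years,
        seed=seed,
    )
    return volume, truth


def simulate_cohort(
    n_subjects: int,
    age_range: tuple[float, float],
    geometry: PhantomGeometry,
    tissues: dict[int, TissueSpec],
    acquisition: AcquisitionSpec,
    seed: int = 0,
    reference_age: float = DEFAULT_REFERENCE_AGE,
    female_fraction: float = 22 / 37,
):
    """Simulate a cross-sectional cohort of seeded phantom subjects.

    Ages are drawn uniformly over ``age_range``; each subject's echo train is
    generated by :func:`simulate_echo_train` with a child seed recorded in the
    manifest, so the whole cohort can be regenerated bit-identically from the
    manifest alone.  The default female fraction mirrors a 22-of-37 cohort.

    Returns
    -------
    (list[SubjectRecord], dict[str, EchoTrainVolume], dict[int, ndarray] masks,
     CohortGroundTruth)
    """
    if n_subjects < 3:
        raise ValueError("n_subjects must be >= 3")
    lo, hi = float(age_range[0]), float(age_range[1])
    if not hi > lo:
        raise ValueError("age_range must be non-degenerate")

    rng = np.random.default_rng(seed)
    ages = rng.uniform(lo, hi, n_subjects)
    sexes = np.where(rng.random(n_subjects) < female_fraction, "F", "M")
    # child seeds kept below 2**31 so they survive any 32-bit consumer
    child_seeds = rng.integers(0, 2**31 - 1, n_subjects)

    subjects: list[SubjectRecord] = []
    volumes = {}
    truth = CohortGroundTruth(seed=seed, reference_age_years=reference_age)
    width = max(3, int(math.log10(n_subjects)) + 1)
    for i in range(n_subjects):
        sid = f"sub-{i + 1:0{width}d}"
        rec = SubjectRecord(subject_id=sid, age_years=float(ages[i]), sex=str(sexes[i]))
        vol, gt = simulate_echo_train(
            geometry, tissues, acquisition,
            age_years=rec.age_years, reference_age=reference_age,
            seed=int(child_seeds[i]),
        )
        subjects.append(rec)
        volumes[sid] = vol
        truth.subject_seeds[sid] = int(child_seeds[i])
        truth.subject_truths[sid] = gt
    truth.injected_slopes = {tissues[lab].label: tissues[lab].t2_age_slope for lab in geometry.labels}

    masks = {lab: geometry.mask(lab) for lab in geometry.labels}
    return subjects, volumes, masks, truth
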