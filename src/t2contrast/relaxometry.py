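"""Voxel-wise T2 relaxometry from multi-echo spin-echo trains.

The core estimator is a mono-exponential fit performed in logarithmic space:
for retained echo times TE and intensities S, ordinary least squares of
ln(S) on TE gives slope b and intercept a, from which T2 = -1/b and
S0 = exp(a).  By default the first echo is excluded before fitting, because
imperfect refocusing pulses contaminate it with stimulated-echo signal; the
echo-summed T2-weighted image, by contrast, sums the ENTIRE train including
echo 1.

`MonoExponentialT2` / `T2MapResults` follow the model/results idiom: the
model is constructed from an :class:`EchoTrainVolume`, ``fit()`` returns the
maps plus validity and goodness-of-fit diagnostics, and the results object
derives the R2 (= 1/T2) map.  The module-level functions
(:func:`select_fit_echoes`, :func:`fit_t2_loglinear`, :func:`echo_sum`,
:func:`invert_map`) are thin wrappers over the same code.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "EchoTrainVolume",
    "T2MapResults",
    "R2Map",
    "MonoExponentialT2",
    "select_fit_echoes",
    "fit_t2_loglinear",
    "echo_sum",
    "invert_map",
    "DEFAULT_T2_BOUNDS",
]

#: Physically plausible T2 window (ms]; fits outside are marked invalid.
DEFAULT_T2_BOUNDS = (1.0, 2000.0)


@dataclass(frozen=True)
class EchoTrainVolume:
    """4D multi-echo intensity volume with per-echo acquisition times.

    ``intensities`` is (x, y, z, echo) in arbitrary units >= 0;
    ``echo_times_ms`` is strictly increasing, one entry per echo.
    """

    intensities: np.ndarray
    echo_times_ms: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        ints = np.asarray(self.intensities)
        tes = np.asarray(self.echo_times_ms, dtype=float)
        if ints.ndim != 4:
            raise ValueError("intensities must be 4D (x, y, z, echo)")
        if ints.shape[-1] != tes.size:
            raise ValueError(
                f"echo count mismatch: {ints.shape[-1]} echoes vs {tes.size} echo times"
            )
        if tes.size >= 2 and not np.all(np.diff(tes) > 0):
            raise ValueError("echo_times_ms must be strictly increasing")
        object.__setattr__(self, "intensities", ints)
        object.__setattr__(self, "echo_times_ms", tes)

    @property
    def n_echoes(self) -> int:
        return int(self.echo_times_ms.size)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape[:3]


@dataclass(frozen=True)
class R2Map:
    """Transverse relaxation rate map, R2 = 1/T2 in 1/ms."""

    r2_per_ms: np.ndarray
    validity: np.ndarray

    def to_t2(self) -> np.ndarray:
        """Reciprocal back to T2 in ms (NaN where invalid)."""
        out = np.full(self.r2_per_ms.shape, np.nan)
        out[self.validity] = 1.0 / self.r2_per_ms[self.validity]
        return out


@dataclass(frozen=True)
class T2MapResults:
    """Fitted T2 map plus diagnostics.

    t2_ms and s0 carry NaN wherever ``validity`` is False — never 0, which
    would silently corrupt downstream ROI means.  ``fit_r2`` is the
    coefficient of determination of the log-space regression (a cheap
    diagnostic, not used for exclusion).
    """

    t2_ms: np.ndarray
    s0: np.ndarray
    validity: np.ndarray
    fit_r2: np.ndarray
    echo_times_used_ms: np.ndarray
    t2_bounds: tuple[float, float] = DEFAULT_T2_BOUNDS

    def r2_map(self) -> R2Map:
        """Derive the R2 = 1/T2 map; invalid voxels propagate."""
        out = np.full(self.t2_ms.shape, np.nan)
        out[self.validity] = 1.0 / self.t2_ms[self.validity]
        return R2Map(r2_per_ms=out, validity=self.validity.copy())

    def summary(self) -> str:
        v = self.validity
        lines = [
            "Mono-exponential T2 fit (log-linear OLS)",
            f"  grid:            {self.t2_ms.shape}",
            f"  echoes used:     {np.array2string(self.echo_times_used_ms, precision=1)} ms",
            f"  valid voxels:    {int(v.sum())} / {v.size}",
        ]
        if v.any():
            lines += [
                f"  T2 median (ms):  {np.nanmedian(self.t2_ms[v]):.2f}",
                f"  fit R^2 median:  {np.nanmedian(self.fit_r2[v]):.4f}",
            ]
        return "\n".join(lines)


def select_fit_echoes(
    echo_times_ms: Sequence[float], policy: str = "drop_first"
) -> tuple[np.ndarray, np.ndarray]:
    """Choose which echoes enter the T2 fit.

    ``drop_first`` (default) excludes echo 1, whose amplitude is inflated by
    stimulated echoes; ``keep_all`` retains the full train.  At least two
    echoes must remain.

    Returns (indices, retained echo times in ms).
    """
    tes = np.asarray(echo_times_ms, dtype=float)
    if policy == "drop_first":
        idx = np.arange(1, tes.size)
    elif policy == "keep_all":
        idx = np.arange(tes.size)
    else:
        raise ValueError(f"unknown echo selection policy {policy!r}")
    if idx.size < 2:
        raise ValueError(
            f"policy {policy!r} retains {idx.size} echo(es); at least 2 required for a fit"
        )
    return idx, tes[idx]


class MonoExponentialT2:
    """Voxel-wise mono-exponential T2 model for a multi-echo spin-echo train.

    Parameters
    ----------
    echo_train : EchoTrainVolume
    echo_policy : {"drop_first", "keep_all"}
        Which echoes enter the fit; the default drops the stimulated-echo-
        contaminated first echo.
    intensity_threshold : float
        Voxels with any retained intensity <= this are marked invalid
        (the logarithm needs strictly positive input; default 0).
    t2_bounds : (low, high)
        Fits outside this half-open window (low, high] are marked invalid.

    Examples
    --------
    >>> res = MonoExponentialT2(echo_train).fit()
    >>> res.t2_ms.shape == echo_train.shape
    True
    """

    def __init__(
        self,
        echo_train: EchoTrainVolume,
        echo_policy: str = "drop_first",
        intensity_threshold: float = 0.0,
        t2_bounds: tuple[float, float] = DEFAULT_T2_BOUNDS,
    ) -> None:
        self.echo_train = echo_train
        self.echo_policy = echo_policy
        self.intensity_threshold = float(intensity_threshold)
        self.t2_bounds = (float(t2_bounds[0]), float(t2_bounds[1]))
        self._idx, self._tes = select_fit_echoes(echo_train.echo_times_ms, echo_policy)

    def fit(self) -> T2MapResults:
        """OLS of ln(intensity) on echo time, vectorised over voxels."""
        data = self.echo_train.intensities[..., self._idx]
        tes = self._tes
        positive = np.all(data > self.intensity_threshold, axis=-1) & np.all(data > 0, axis=-1)

        shape = data.shape[:3]
        t2 = np.full(shape, np.nan)
        s0 = np.full(shape, np.nan)
        gof = np.full(shape, np.nan)

        y = np.log(data[positive])  # (n_valid, n_echo)
        if y.size:
            t_mean = tes.mean()
            t_c = tes - t_mean
            sxx = float(np.dot(t_c, t_c))
            y_mean = y.mean(axis=-1)
            slope = (y @ t_c) / sxx
            intercept = y_mean - slope * t_mean

            with np.errstate(divide="ignore", over="ignore"):
                t2_v = -1.0 / slope
            s0_v = np.exp(intercept)

            resid = y - (intercept[:, None] + slope[:, None] * tes[None, :])
            ss_res = np.einsum("ij,ij->i", resid, resid)
            ss_tot = np.einsum("ij,ij->i", y - y_mean[:, None], y - y_mean[:, None])
            with np.errstate(invalid="ignore", divide="ignore"):
                r2 = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, 1.0)

            lo, hi = self.t2_bounds
            ok = np.isfinite(t2_v) & (t2_v > lo) & (t2_v <= hi)
            t2_v = np.where(ok, t2_v, np.nan)
            s0_v = np.where(ok, s0_v, np.nan)

            t2[positive] = t2_v
            s0[positive] = s0_v
            gof[positive] = r2
            valid = np.zeros(shape, dtype=bool)
            valid[positive] = ok
        else:
            valid = np.zeros(shape, dtype=bool)

        return T2MapResults(
            t2_ms=t2, s0=s0, validity=valid, fit_r2=gof,
            echo_times_used_ms=tes, t2_bounds=self.t2_bounds,
        )


def fit_t2_loglinear(
    echo_train: EchoTrainVolume,
    intensity_threshold: float = 0.0,
    t2_bounds: tuple[float, float] = DEFAULT_T2_BOUNDS,
    echo_policy: str = "drop_first",
) -> T2MapResults:
    """Fit a voxel-wise T2 map; functional shorthand for MonoExponentialT2(...).fit()."""
    return MonoExponentialT2(
        echo_train, echo_policy=echo_policy,
        intensity_threshold=intensity_threshold, t2_bounds=t2_bounds,
    ).fit()


def echo_sum(echo_train: EchoTrainVolume) -> np.ndarray:
    """T2-weighted image: voxel-wise sum over the ENTIRE echo train.

    Unlike the fit, the sum deliberately includes the first echo.
    """
    return echo_train.intensities.sum(axis=-1)


def invert_map(t2_map: T2MapResults) -> R2Map:
    """R2 = 1/T2 map from fitted results; invalid voxels propagate."""
    return t2_map.r2_map()
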