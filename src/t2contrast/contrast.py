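"""ROI extraction and gray/white contrast statistics.

Two metrics of relative signal between a gray-matter-like ROI (sample G)
and a white-matter-like ROI (sample W):

    CNR = |E(S_G) - E(S_W)| / sqrt(var(S_G) + var(S_W))
    GWR = E(S_G) / E(S_W)

The samples may be image intensities (T1-weighted or echo-summed
T2-weighted) or quantitative T2 values in ms; for T2 maps only valid
(finite) voxels contribute.  Sample variance uses the n-1 denominator by
default (configurable via ``ddof``).  The GWR orientation — which ROI is
the numerator — is fixed by the region-pair declaration, never inferred
from intensities, so the ratio keeps a single meaning across modalities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ROIMask",
    "ROISample",
    "ContrastResult",
    "extract_roi",
    "compute_cnr",
    "compute_gwr",
    "contrast_statistics",
    "cohort_contrast_table",
]

MODALITIES = ("T1w", "T2w", "T2map")


@dataclass(frozen=True)
class ROIMask:
    """Binary region mask on the image grid."""

    mask: np.ndarray
    label: str

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim != 3:
            raise ValueError("mask must be 3D")
        object.__setattr__(self, "mask", m)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class ROISample:
    """Values one mask extracts from one scalar volume (invalid voxels excluded)."""

    values: np.ndarray
    roi_label: str
    source_modality: str = "T2map"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float).ravel()
        if v.size < 2:
            raise ValueError("ROISample needs >= 2 values (variance must be estimable)")
        if not np.all(np.isfinite(v)):
            raise ValueError("ROISample must contain only finite values")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class ContrastResult:
    """CNR and GWR for one gray/white sample pair, with the moments behind them."""

    cnr: float
    gwr: float
    mean_g: float
    mean_w: float
    var_g: float
    var_w: float
    n_g: int
    n_w: int
    modality: str = "T2map"


def extract_roi(
    volume: np.ndarray,
    mask: ROIMask | np.ndarray,
    modality: str = "T2map",
    label: str | None = None,
) -> ROISample:
    """Sample the in-mask, valid (finite) voxels of a scalar volume.

    Values are returned in C (row-major) voxel order, so repeated extraction
    is order-stable.  Raises if the grids differ or fewer than 2 valid voxels
    remain after NaN exclusion.
    """
    if isinstance(mask, ROIMask):
        m, lab = mask.mask, mask.label
    else:
        m, lab = np.asarray(mask, dtype=bool), (label or "roi")
    vol = np.asarray(volume, dtype=float)
    if vol.shape != m.shape:
        raise ValueError(f"grid mismatch: volume {vol.shape} vs mask {m.shape}")
    vals = vol[m]
    vals = vals[np.isfinite(vals)]
    if vals.size < 2:
        raise ValueError(f"ROI {lab!r}: < 2 valid voxels after invalid-voxel exclusion")
    return ROISample(values=vals, roi_label=lab, source_modality=modality)


def _moments(sample: ROISample, ddof: int) -> tuple[float, float, int]:
    v = sample.values
    return float(v.mean()), float(v.var(ddof=ddof)), v.size


def _build_result(sample_g, sample_w, ddof, need_cnr, need_gwr) -> ContrastResult:
    mg, vg, ng = _moments(sample_g, ddof)
    mw, vw, nw = _moments(sample_w, ddof)
    pooled = vg + vw
    if pooled <= 0 and need_cnr:
        raise ValueError("zero pooled variance: both samples constant, CNR undefined")
    if mw == 0 and need_gwr:
        raise ValueError("zero white-matter mean: GWR undefined")
    cnr = abs(mg - mw) / np.sqrt(pooled) if pooled > 0 else np.nan
    gwr = mg / mw if mw != 0 else np.nan
    return ContrastResult(
        cnr=cnr, gwr=gwr,
        mean_g=mg, mean_w=mw, var_g=vg, var_w=vw, n_g=ng, n_w=nw,
        modality=sample_g.source_modality,
    )


def contrast_statistics(
    sample_g: ROISample, sample_w: ROISample, ddof: int = 1
) -> ContrastResult:
    """Both contrast metrics for one gray/white pair.

    CNR is symmetric in its arguments and invariant to a common positive
    rescaling; GWR is oriented gray-over-white.  Raises on zero pooled
    variance (CNR undefined) or zero white mean (GWR undefined).
    """
    return _build_result(sample_g, sample_w, ddof, need_cnr=True, need_gwr=True)


def compute_cnr(sample_g: ROISample, sample_w: ROISample, ddof: int = 1) -> ContrastResult:
    """Contrast-to-noise ratio |mean_G - mean_W| / sqrt(var_G + var_W).

    Raises on zero pooled variance (both samples constant) rather than
    returning infinity.
    """
    return _build_result(sample_g, sample_w, ddof, need_cnr=True, need_gwr=False)


def compute_gwr(sample_g: ROISample, sample_w: ROISample, ddof: int = 1) -> ContrastResult:
    """Gray-to-white ratio mean_G / mean_W.  Raises on zero white mean."""
    return _build_result(sample_g, sample_w, ddof, need_cnr=False, need_gwr=True)


def cohort_contrast_table(
    volumes: Mapping[str, Mapping[str, np.ndarray]],
    masks: Mapping[str, np.ndarray] | Mapping[str, ROIMask],
    region_pairs: Sequence[tuple[str, str]],
    ages: Mapping[str, float],
    modalities: Sequence[str] = ("T2w", "T2map"),
    ddof: int = 1,
) -> pd.DataFrame:
    """Per-subject contrast table: one row per subject x pair x modality x metric.

    Parameters
    ----------
    volumes : {subject_id: {modality: 3D array}}
    masks : {region_label: mask}; shared across subjects (native-grid cohort)
        or per-subject when values are ``{subject_id: mask}`` mappings.
    region_pairs : ordered (gray_label, white_label) tuples — the order fixes
        the GWR orientation.
    ages : {subject_id: age_years}

    A subject missing a requested volume or mask is skipped for that row with
    a logged warning; the run continues.  Rows are emitted in deterministic
    (subject, pair, modality, metric) order.
    """
    import logging

    log = logging.getLogger(__name__)
    rows = []
    for sid in sorted(volumes):
        for gray, white in region_pairs:
            for mod in modalities:
                vol = volumes[sid].get(mod)
                if vol is None:
                    log.warning("subject %s: missing %s volume; skipped", sid, mod)
                    continue
                try:
                    mg = _resolve_mask(masks, gray, sid)
                    mw = _resolve_mask(masks, white, sid)
                    sg = extract_roi(vol, mg, modality=mod, label=gray)
                    sw = extract_roi(vol, mw, modality=mod, label=white)
                    res = _build_result(sg, sw, ddof, need_cnr=False, need_gwr=False)
                except (KeyError, ValueError) as exc:
                    log.warning("subject %s pair %s/%s %s: %s; skipped", sid, gray, white, mod, exc)
                    continue
                pair = f"{gray}/{white}"
                for metric, value in (("CNR", res.cnr), ("GWR", res.gwr)):
                    if not np.isfinite(value):
                        log.warning("subject %s pair %s %s: %s undefined; skipped",
                                    sid, pair, mod, metric)
                        continue
                    rows.append({
                        "subject_id": sid,
                        "age_years": float(ages[sid]),
                        "pair": pair,
                        "modality": mod,
                        "metric": metric,
                        "value": float(value),
                        "n_g": res.n_g,
                        "n_w": res.n_w,
                    })
    return pd.DataFrame(
        rows,
        columns=["subject_id", "age_years", "pair", "modality", "metric", "value", "n_g", "n_w"],
    )


def _resolve_mask(masks, label: str, sid: str):
    m = masks[label]
    if isinstance(m, Mapping):  # per-subject masks
        m = m[sid]
    if isinstance(m, ROIMask):
        return m
    return ROIMask(mask=np.asarray(m, dtype=bool), label=label)
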