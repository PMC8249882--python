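"""Vertex-wise, global and ROI measures of longitudinal cortical change.

All change measures are log2 ratios of follow-up to baseline:
``log2(CT2/CT1)`` for thickness, ``log2(SA2/SA1)`` for vertex surface area
and ``log2((SA2*CT2)/(SA1*CT1))`` for volume, so that volume change is
exactly the sum of thickness change and area change.  Atrophy is a
negative change; percent "loss" is ``(baseline - followup)/baseline * 100``.

Thickness maps are smoothed per timepoint with a 20 mm FWHM geodesic
Gaussian kernel before the ratio; the area-change map (from registration)
enters volume unsmoothed.  The medial wall is excluded everywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._sphere import SphereLocator
from .meshcore import (
    MetricMap,
    Parcellation,
    SmoothingParams,
    SurfaceMesh,
    mean_thickness,
    smooth_metric,
    total_area,
    vertex_areas,
)
from .registration import RegistrationResult

__all__ = [
    "ChangeMaps",
    "GlobalSummary",
    "log2_change",
    "resample_followup_thickness",
    "compute_change_maps",
    "true_change_maps",
    "global_summary",
    "intrasubject_variance",
    "roi_change_table",
    "cohort_global_table",
]


@dataclass
class ChangeMaps:
    """Per-vertex log2 change maps for one subject, on the baseline grid.

    Invariant: ``volume_change = thickness_change_smoothed + area_change``
    exactly at every cortex vertex.
    """

    thickness_change: MetricMap
    thickness_change_smoothed: MetricMap
    area_change: MetricMap
    volume_change: MetricMap


@dataclass
class GlobalSummary:
    subject_id: str
    group: str
    pct_thickness_loss: float
    pct_area_loss: float
    pct_volume_loss: float


def log2_change(before: MetricMap, after: MetricMap, mask=None) -> MetricMap:
    """log2(after/before), masked vertices (and nonpositive inputs) set to NaN."""
    b = np.asarray(before.values, dtype=float)
    a = np.asarray(after.values, dtype=float)
    if a.shape != b.shape:
        raise ValueError("maps must share a grid")
    ok = (b > 0) & (a > 0)
    if mask is not None:
        m = mask.values if hasattr(mask, "values") else np.asarray(mask, bool)
        ok &= m
    if not ok.all() and mask is None:
        warnings.warn("nonpositive values masked out of log2 change", stacklevel=2)
    out = np.full(b.shape, np.nan)
    out[ok] = np.log2(a[ok] / b[ok])
    return MetricMap(out, before.mesh_name, "log2-ratio")


def resample_followup_thickness(subject, registration: RegistrationResult) -> MetricMap:
    """Follow-up thickness pulled back onto the baseline grid via the forward map."""
    vals = registration.forward.interpolate(subject.followup_thickness.values)
    return MetricMap(vals, subject.baseline.name, "mm")


def compute_change_maps(
    subject,
    registration: RegistrationResult,
    smoothing: SmoothingParams | None = None,
    smooth_ratio_instead: bool = False,
) -> ChangeMaps:
    """Thickness, area and volume change maps for one registered subject.

    The default smooths the two timepoint thickness maps separately and
    then takes the ratio; ``smooth_ratio_instead`` smooths the log-ratio
    map instead.  Volume change is the sum of smoothed thickness change and
    unsmoothed area change, so the log2 additivity identity holds exactly.
    """
    smoothing = smoothing or SmoothingParams(fwhm=20.0)
    cortex = ~subject.baseline_wall.values
    mesh = subject.baseline
    ct1 = subject.baseline_thickness
    ct2 = resample_followup_thickness(subject, registration)

    raw = log2_change(ct1, ct2, cortex)
    if smooth_ratio_instead:
        sm = smooth_metric(raw, mesh, smoothing, cortex)
        sm = MetricMap(np.where(cortex, sm.values, np.nan), mesh.name, "log2-ratio")
    else:
        ct1s = smooth_metric(ct1, mesh, smoothing, cortex)
        ct2s = smooth_metric(ct2, mesh, smoothing, cortex)
        sm = log2_change(ct1s, ct2s, cortex)

    area = MetricMap(registration.area_change.values.copy(), mesh.name, "log2-ratio")
    area.values[~cortex] = np.nan
    vol = MetricMap(sm.values + area.values, mesh.name, "log2-ratio")
    return ChangeMaps(raw, sm, area, vol)


def true_change_maps(subject, smoothing: SmoothingParams | None = None) -> ChangeMaps:
    """Change maps measured through the generator's known correspondence.

    Bypasses registration: requires a subject whose follow-up shares the
    baseline grid (``generate_cohort(..., reparam=False)``).  Used for
    inference-calibration studies where thousands of registrations would be
    pointless, since the exchangeability of the resulting maps is all that
    matters.
    """
    if subject.followup.n_vertices != subject.baseline.n_vertices:
        raise ValueError("true_change_maps requires a shared grid (reparam=False)")
    smoothing = smoothing or SmoothingParams(fwhm=20.0)
    cortex = ~subject.baseline_wall.values
    mesh = subject.baseline
    ct1, ct2 = subject.baseline_thickness, subject.followup_thickness
    raw = log2_change(ct1, ct2, cortex)
    ct1s = smooth_metric(ct1, mesh, smoothing, cortex)
    ct2s = smooth_metric(ct2, mesh, smoothing, cortex)
    sm = log2_change(ct1s, ct2s, cortex)
    va1 = vertex_areas(subject.baseline).values
    va2 = vertex_areas(subject.followup).values
    area = log2_change(MetricMap(va1, mesh.name), MetricMap(va2, mesh.name), cortex)
    vol = MetricMap(sm.values + area.values, mesh.name, "log2-ratio")
    return ChangeMaps(raw, sm, area, vol)


def global_summary(subject) -> GlobalSummary:
    """Percent loss in global mean thickness, total area and volume.

    Global thickness is the unweighted mean over cortex vertices; global
    area the vertex-area sum; volume their product — each computed on the
    timepoint's own grid with its own cortex mask.
    """
    cb = ~subject.baseline_wall.values
    cf = ~subject.followup_wall.values
    t1 = mean_thickness(subject.baseline_thickness, cb)
    t2 = mean_thickness(subject.followup_thickness, cf)
    a1 = total_area(subject.baseline, cb)
    a2 = total_area(subject.followup, cf)
    v1, v2 = t1 * a1, t2 * a2
    pct = lambda b, f: (b - f) / b * 100.0
    return GlobalSummary(
        subject_id=subject.subject_id,
        group=subject.group,
        pct_thickness_loss=pct(t1, t2),
        pct_area_loss=pct(a1, a2),
        pct_volume_loss=pct(v1, v2),
    )


def cohort_global_table(subjects) -> pd.DataFrame:
    rows = [vars(global_summary(s)) for s in subjects]
    return pd.DataFrame(rows)


def intrasubject_variance(maps: ChangeMaps, mask) -> dict[str, float]:
    """Across-vertex variance of each change map within one subject.

    The standard deviation over cortex vertices (medial wall excluded) is
    computed for smoothed-thickness, area and volume change, and squared.
    """
    m = mask.values if hasattr(mask, "values") else np.asarray(mask, bool)
    out = {}
    for key, mp in [
        ("thickness", maps.thickness_change_smoothed),
        ("area", maps.area_change),
        ("volume", maps.volume_change),
    ]:
        v = mp.values[m]
        v = v[np.isfinite(v)]
        out[key] = float(np.std(v) ** 2)
    return out


def roi_change_table(
    subjects_maps: list[tuple[object, ChangeMaps | None]],
    parcellation: Parcellation | None = None,
    wall_roi: int = 0,
) -> pd.DataFrame:
    """Per-subject, per-ROI log2 changes in mean thickness, total area, volume.

    Within each ROI, mean thickness (unweighted) and total vertex area are
    computed at both timepoints on the baseline grid; the follow-up
    timepoint's values come from the resampled thickness and the area-change
    map (ROI follow-up area = sum of vertex areas scaled by 2^area_change).
    ROI volume change is the sum of its thickness and area changes.
    """
    rows = []
    for subject, maps in subjects_maps:
        parc = parcellation or subject.parcellation
        labels = parc.roi_label
        cortex = ~subject.baseline_wall.values
        va1 = vertex_areas(subject.baseline).values
        ct1 = subject.baseline_thickness.values
        if maps is None:
            raise ValueError("ChangeMaps required per subject")
        ct_change = maps.thickness_change_smoothed.values
        a_change = maps.area_change.values
        for roi in np.unique(labels):
            if roi == wall_roi:
                continue
            sel = (labels == roi) & cortex & np.isfinite(a_change) & np.isfinite(ct_change)
            if not sel.any():
                warnings.warn(f"ROI {roi} has no usable cortex vertices; dropped", stacklevel=2)
                continue
            t1 = ct1[sel].mean()
            t2 = (ct1[sel] * 2.0 ** ct_change[sel]).mean()
            a1 = va1[sel].sum()
            a2 = (va1[sel] * 2.0 ** a_change[sel]).sum()
            d_thick = np.log2(t2 / t1)
            d_area = np.log2(a2 / a1)
            rows.append(
                {
                    "subject_id": subject.subject_id,
                    "group": subject.group,
                    "roi": int(roi),
                    "d_thick_log2": d_thick,
                    "d_area_log2": d_area,
                    "d_vol_log2": d_thick + d_area,
                }
            )
    return pd.DataFrame(rows)
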