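"""Regional reduction of vertex profiles and assembly of the modelling table.

Vertex-level profile samples are reduced per ROI and depth either by the
conventional unweighted mean or by the tissue-weighted mean, where the tissue
fraction (TF = 1 - free-water fraction) sampled at the same vertex and depth
serves as the weight.  NDI and ODI are tissue-weighted by default — a
conventional average would equally weight voxels regardless of how much
actual tissue they contain, which biases regional values near the cortex
where CSF partial volume is largest.  FA, MD and TF itself use conventional
means.  Hemisphere summaries are combined by an unweighted mean.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

from .sampling import ProfileSamples

log = logging.getLogger(__name__)

#: default weighting per metric
DEFAULT_WEIGHTING: dict[str, str] = {
    "FA": "conventional",
    "MD": "conventional",
    "NDI": "tissue",
    "ODI": "tissue",
    "TF": "conventional",
}


def _roi_rows(labels: np.ndarray, roi: int) -> np.ndarray:
    labels = np.asarray(labels)
    sel = labels == roi
    if not np.any(sel):
        raise KeyError(f"ROI {roi} not present in mesh labels")
    return sel


def conventional_roi_mean(
    samples: ProfileSamples, labels: np.ndarray, roi: int
) -> np.ndarray:
    """Unweighted mean over non-missing samples of one ROI, per depth."""
    sel = _roi_rows(labels, roi)
    vals = samples.values[sel]
    present = np.isfinite(vals)
    n = present.sum(axis=0)
    if np.any(n == 0):
        log.warning(
            "ROI %d (%s): all samples missing at %d depth(s)",
            roi, samples.source_metric, int((n == 0).sum()),
        )
    with np.errstate(invalid="ignore"):
        out = np.where(n > 0, np.nansum(np.where(present, vals, 0.0), axis=0), np.nan)
    return out / np.where(n > 0, n, 1)


def tissue_weighted_roi_mean(
    samples: ProfileSamples,
    tf_samples: ProfileSamples,
    labels: np.ndarray,
    roi: int,
) -> np.ndarray:
    """TF-weighted mean over one ROI, per depth.

    Weights are the TF samples of the same vertices at the same depth; only
    vertices where both the value and its weight are present contribute.  A
    zero total weight yields a missing value; negative weights are a data
    error.
    """
    if samples.values.shape != tf_samples.values.shape:
        raise ValueError("samples and tf_samples must share vertices and offsets")
    if samples.depth_offsets != tf_samples.depth_offsets:
        raise ValueError("samples and tf_samples must share depth offsets")
    sel = _roi_rows(labels, roi)
    x = samples.values[sel]
    w = tf_samples.values[sel]
    if np.any(w[np.isfinite(w)] < 0):
        raise ValueError("negative tissue-fraction weights")
    both = np.isfinite(x) & np.isfinite(w)
    wsum = np.where(both, w, 0.0).sum(axis=0)
    xsum = np.where(both, w * x, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(wsum > 0, xsum / np.where(wsum > 0, wsum, 1.0), np.nan)


def summarize_hemisphere(
    samples_by_metric: Mapping[str, ProfileSamples],
    labels: np.ndarray,
    weighting: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Reduce one hemisphere's samples to (roi, metric, d) summary rows.

    Depth index d counts inward: 0 = GM sample (+1 mm), 3 = SWM/DWM (-2 mm).
    Weighting schemes per metric: "conventional" (unweighted mean), "tissue"
    (TF-weighted with depth-matched weights, the default for NDI/ODI) or
    "tissue_boundary" (TF weights taken at the boundary sample for all
    depths, for sensitivity analyses).
    """
    if weighting is None:
        weighting = DEFAULT_WEIGHTING
    labels = np.asarray(labels)
    rois = sorted(int(r) for r in np.unique(labels[labels >= 0]))
    tf = samples_by_metric.get("TF")
    rows = []
    for metric, samp in samples_by_metric.items():
        scheme = weighting.get(metric, "conventional")
        for roi in rois:
            if scheme in ("tissue", "tissue_boundary"):
                if tf is None:
                    raise ValueError("tissue weighting requested but no TF samples given")
                weights = tf
                if scheme == "tissue_boundary":
                    # weight every depth by TF at the GM/WM boundary sample
                    boundary = tf.depth_offsets.index(0.0)
                    weights = ProfileSamples(
                        np.tile(tf.values[:, boundary : boundary + 1], (1, tf.values.shape[1])),
                        depth_offsets=tf.depth_offsets,
                        source_metric=tf.source_metric,
                        participant_id=tf.participant_id,
                        hemisphere=tf.hemisphere,
                    )
                vals = tissue_weighted_roi_mean(samp, weights, labels, roi)
                n_used = (
                    np.isfinite(samp.values[labels == roi])
                    & np.isfinite(weights.values[labels == roi])
                ).sum(axis=0)
            elif scheme == "conventional":
                vals = conventional_roi_mean(samp, labels, roi)
                n_used = np.isfinite(samp.values[labels == roi]).sum(axis=0)
            else:
                raise ValueError(f"unknown weighting {scheme!r}")
            for d in range(len(samp.depth_offsets)):
                rows.append(
                    {
                        "participant_id": samp.participant_id,
                        "hemisphere": samp.hemisphere,
                        "roi": roi,
                        "metric": metric,
                        "d": d,
                        "value": float(vals[d]),
                        "weighting": scheme,
                        "n_vertices_used": int(n_used[d]),
                    }
                )
    return pd.DataFrame(rows)


def average_hemispheres(left: pd.DataFrame, right: pd.DataFrame) -> pd.DataFrame:
    """Unweighted mean of the two hemisphere summaries per (roi, metric, d).

    If one hemisphere is missing, the other is returned and the row flagged.
    Both missing stays missing.
    """
    keys = ["participant_id", "roi", "metric", "d", "weighting"]
    merged = left.merge(right, on=keys, how="outer", suffixes=("_l", "_r"))
    vl, vr = merged.value_l.to_numpy(), merged.value_r.to_numpy()
    both = np.isfinite(vl) & np.isfinite(vr)
    one = np.isfinite(vl) ^ np.isfinite(vr)
    value = np.where(both, 0.5 * (vl + vr), np.where(np.isfinite(vl), vl, vr))
    if one.any():
        log.warning("hemisphere averaging: %d summaries from a single hemisphere", int(one.sum()))
    out = merged[keys].copy()
    out["value"] = value
    out["n_vertices_used"] = (
        merged.n_vertices_used_l.fillna(0) + merged.n_vertices_used_r.fillna(0)
    ).astype(int)
    out["single_hemisphere"] = one
    return out


def build_long_table(
    summaries: pd.DataFrame,
    thickness: pd.DataFrame,
    participants: pd.DataFrame,
) -> pd.DataFrame:
    """Assemble the tidy modelling table.

    One row per (participant, roi, metric, d) with columns
    ``participant_id, group, roi, metric, d, d2, y, thickness``.  Rows whose
    (participant, roi) lacks a thickness value are excluded (count logged);
    missing summaries keep their row with NaN ``y``.
    """
    out = summaries.merge(
        participants[["participant_id", "group"]], on="participant_id", how="left"
    ).merge(thickness, on=["participant_id", "roi"], how="left")
    n_before = len(out)
    out = out[np.isfinite(out.thickness_mm)]
    dropped = n_before - len(out)
    if dropped:
        log.warning("build_long_table: %d rows excluded for missing thickness", dropped)
    out = out.rename(columns={"value": "y", "thickness_mm": "thickness"})
    out["d2"] = out.d**2
    cols = ["participant_id", "group", "roi", "metric", "d", "d2", "y", "thickness"]
    out = out[cols].sort_values(["participant_id", "roi", "metric", "d"]).reset_index(drop=True)
    dup = out.duplicated(["participant_id", "roi", "metric", "d"])
    if dup.any():
        raise ValueError("long table has duplicate (participant, roi, metric, d) rows")
    return out
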