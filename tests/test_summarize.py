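import numpy as np
import pandas as pd
import pytest

from swmprofile.sampling import ProfileSamples
from swmprofile.summarize import (
    average_hemispheres,
    build_long_table,
    conventional_roi_mean,
    summarize_hemisphere,
    tissue_weighted_roi_mean,
)


def samples(values, metric="NDI", pid="p0", hemi="left"):
    return ProfileSamples(
        np.asarray(values, dtype=float),
        source_metric=metric,
        participant_id=pid,
        hemisphere=hemi,
    )


def test_conventional_mean_hand_cases():
    s = samples([[0.2] * 4, [0.4] * 4])
    labels = np.array([0, 0])
    assert np.allclose(conventional_roi_mean(s, labels, 0), 0.3)
    # all vertices equal c -> c at every depth
    s2 = samples(np.full((5, 4), 0.77))
    assert np.allclose(conventional_roi_mean(s2, np.zeros(5, dtype=int), 0), 0.77)
    with pytest.raises(KeyError):
        conventional_roi_mean(s, labels, 3)


def test_conventional_mean_matches_brute_force(rng):
    n = 60
    labels = rng.integers(0, 4, size=n)
    vals = rng.normal(0.5, 0.1, size=(n, 4))
    vals[rng.random((n, 4)) < 0.15] = np.nan
    s = samples(vals)
    for roi in range(4):
        got = conventional_roi_mean(s, labels, roi)
        for depth in range(4):
            acc = [
                vals[v, depth]
                for v in range(n)
                if labels[v] == roi and np.isfinite(vals[v, depth])
            ]
            expected = np.mean(acc) if acc else np.nan
            if np.isnan(expected):
                assert np.isnan(got[depth])
            else:
                assert got[depth] == pytest.approx(expected, rel=1e-12)


def test_tissue_weighted_mean_hand_case_and_uniform_weights(rng):
    s = samples([[0.5] * 4, [0.7] * 4])
    w = samples([[0.2] * 4, [0.8] * 4], metric="TF")
    labels = np.zeros(2, dtype=int)
    assert np.allclose(tissue_weighted_roi_mean(s, w, labels, 0), 0.66)
    # uniform TF cancels: equals the conventional mean to 1e-12
    vals = rng.normal(0.4, 0.05, size=(30, 4))
    sv = samples(vals)
    uniform = samples(np.full((30, 4), 0.63), metric="TF")
    lab = rng.integers(0, 2, size=30)
    for roi in range(2):
        tw = tissue_weighted_roi_mean(sv, uniform, lab, roi)
        cv = conventional_roi_mean(sv, lab, roi)
        assert np.allclose(tw, cv, atol=1e-12)


def test_tissue_weighted_mean_matches_brute_force(rng):
    n = 50
    labels = rng.integers(0, 3, size=n)
    vals = rng.normal(0.5, 0.1, size=(n, 4))
    tfv = rng.uniform(0.1, 1.0, size=(n, 4))
    vals[rng.random((n, 4)) < 0.1] = np.nan
    tfv[rng.random((n, 4)) < 0.1] = np.nan
    sv, sw = samples(vals), samples(tfv, metric="TF")
    for roi in range(3):
        got = tissue_weighted_roi_mean(sv, sw, labels, roi)
        for depth in range(4):
            num = den = 0.0
            for v in range(n):
                if labels[v] == roi and np.isfinite(vals[v, depth]) and np.isfinite(tfv[v, depth]):
                    num += tfv[v, depth] * vals[v, depth]
                    den += tfv[v, depth]
            expected = num / den if den > 0 else np.nan
            assert got[depth] == pytest.approx(expected, rel=1e-12)


def test_tissue_weighted_mean_error_paths():
    sv = samples([[0.5] * 4])
    neg = samples([[-0.1] * 4], metric="TF")
    with pytest.raises(ValueError):
        tissue_weighted_roi_mean(sv, neg, np.zeros(1, dtype=int), 0)
    zero_w = samples([[0.0] * 4], metric="TF")
    out = tissue_weighted_roi_mean(sv, zero_w, np.zeros(1, dtype=int), 0)
    assert np.isnan(out).all()


def test_means_bounded_by_contributing_samples(rng):
    vals = rng.uniform(0.2, 0.8, size=(40, 4))
    tfv = rng.uniform(0.1, 1.0, size=(40, 4))
    labels = np.zeros(40, dtype=int)
    sv, sw = samples(vals), samples(tfv, metric="TF")
    cv = conventional_roi_mean(sv, labels, 0)
    tw = tissue_weighted_roi_mean(sv, sw, labels, 0)
    for depth in range(4):
        col = vals[:, depth]
        for m in (cv[depth], tw[depth]):
            assert col.min() - 1e-12 <= m <= col.max() + 1e-12


def test_vertex_permutation_leaves_summaries_unchanged(rng):
    vals = rng.normal(0.5, 0.1, size=(25, 4))
    labels = rng.integers(0, 2, size=25)
    perm = rng.permutation(25)
    a = conventional_roi_mean(samples(vals), labels, 1)
    b = conventional_roi_mean(samples(vals[perm]), labels[perm], 1)
    assert np.allclose(a, b, atol=1e-12)


def test_average_hemispheres_hand_cases():
    def frame(value, hemi):
        return pd.DataFrame(
            {
                "participant_id": ["p0"],
                "hemisphere": [hemi],
                "roi": [0],
                "metric": ["NDI"],
                "d": [2],
                "value": [value],
                "weighting": ["tissue"],
                "n_vertices_used": [10],
            }
        )

    out = average_hemispheres(frame(0.30, "left"), frame(0.40, "right"))
    assert out.value.iloc[0] == pytest.approx(0.35)
    assert not out.single_hemisphere.iloc[0]
    # one hemisphere missing: fall back to the other, flagged
    out2 = average_hemispheres(frame(np.nan, "left"), frame(0.4, "right"))
    assert out2.value.iloc[0] == pytest.approx(0.4)
    assert out2.single_hemisphere.iloc[0]
    # identical hemispheres commute with the null case
    out3 = average_hemispheres(frame(0.25, "left"), frame(0.25, "right"))
    assert out3.value.iloc[0] == pytest.approx(0.25)
    # both missing stays missing
    out4 = average_hemispheres(frame(np.nan, "left"), frame(np.nan, "right"))
    assert np.isnan(out4.value.iloc[0])


def test_weighting_map_controls_which_metrics_are_tissue_weighted(rng):
    n = 30
    labels = np.zeros(n, dtype=int)
    by_metric = {
        "NDI": samples(rng.uniform(0.3, 0.6, (n, 4)), metric="NDI"),
        "TF": samples(rng.uniform(0.2, 1.0, (n, 4)), metric="TF"),
    }
    out = summarize_hemisphere(by_metric, labels)
    ndi = out[out.metric == "NDI"].sort_values("d").value.to_numpy()
    conv = conventional_roi_mean(by_metric["NDI"], labels, 0)
    tw = tissue_weighted_roi_mean(by_metric["NDI"], by_metric["TF"], labels, 0)
    assert np.allclose(ndi, tw, atol=1e-12)
    assert not np.allclose(ndi, conv, atol=1e-6)   # TF varies, so they differ
    # switching NDI to conventional reproduces the conventional mean
    out2 = summarize_hemisphere(by_metric, labels, weighting={"NDI": "conventional", "TF": "conventional"})
    ndi2 = out2[out2.metric == "NDI"].sort_values("d").value.to_numpy()
    assert np.allclose(ndi2, conv, atol=1e-12)
    # boundary weighting uses the TF sample at offset 0 for every depth
    out3 = summarize_hemisphere(by_metric, labels, weighting={"NDI": "tissue_boundary", "TF": "conventional"})
    ndi3 = out3[out3.metric == "NDI"].sort_values("d").value.to_numpy()
    boundary = by_metric["TF"].values[:, 1]   # offset 0 mm is the second column
    w = boundary[:, None] * np.ones((1, 4))
    expected = (w * by_metric["NDI"].values).sum(axis=0) / w.sum(axis=0)
    assert np.allclose(ndi3, expected, atol=1e-12)
    assert not np.allclose(ndi3, ndi, atol=1e-6)


def test_build_long_table_counts_and_missing_propagation(tiny_bundle):
    from swmprofile.pipeline import extract_long_table

    b = tiny_bundle
    long_table, summaries = extract_long_table(
        b.mesh_left, b.mesh_right, b.participants, b.thickness, b.metric_volume
    )
    n, r = len(b.participants), b.config.roi_count
    assert len(long_table) == n * r * 5 * 4
    key = ["participant_id", "roi", "metric", "d"]
    assert long_table.groupby(key).size().max() == 1
    assert np.array_equal(long_table.d2.to_numpy(), long_table.d.to_numpy() ** 2)
    # dropping one participant-ROI thickness removes exactly its 20 rows
    thinned = b.thickness[~((b.thickness.participant_id == "ctl000") & (b.thickness.roi == 1))]
    lt2, _ = extract_long_table(
        b.mesh_left, b.mesh_right, b.participants, thinned, b.metric_volume
    )
    assert len(long_table) - len(lt2) == 5 * 4
    gone = lt2[(lt2.participant_id == "ctl000") & (lt2.roi == 1)]
    assert gone.empty
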