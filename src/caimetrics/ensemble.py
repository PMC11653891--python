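"""Recording-level metric vectors and their 2-D PCA representation.

Every recording is summarized as one vector of scalar features: for each
binarization method (spike, full, signal, diff) the mean burst rate, mean
and peak network spike rate, network spike duration per threshold, network
degree per grid threshold, mean pair correlation, mean connectivity at the
strong threshold, intra/inter-cluster means, band distance means, and the
mean pairwise active-state overlap (intersection over union).  Feature
ordering is a fixed, documented schema so vectors from different recordings
are comparable.

PCA standardizes features to zero mean and unit variance (constant features
are dropped, missing entries imputed with the feature's cross-recording
mean), then projects recordings onto principal components.  The sign of each
component is fixed by making its largest-magnitude loading positive, so
projections are bit-for-bit reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from . import activity, correlation, spatial
from .binarize import METHODS, active_accuracy, binarize_matrix
from .correlation import DEFAULT_GRID
from .io import NeuronMap, TraceMatrix
from .spatial import DEFAULT_STRONG_THRESHOLD

SCHEMA_VERSION = "1"


def feature_schema(methods: Sequence[str] = METHODS,
                   nsd_thresholds: Sequence[float] = activity.NSD_THRESHOLDS,
                   degree_grid: Sequence[float] = DEFAULT_GRID) -> list[str]:
    """Canonical ordered feature names for one analysis."""
    names: list[str] = []
    for m in methods:
        names += [f"{m}:burst_rate_mean", f"{m}:nsr_mean", f"{m}:network_spike_peak"]
        names += [f"{m}:nsd_{t:g}pct_s" for t in nsd_thresholds]
        names += [f"{m}:degree_{t:.2f}" for t in degree_grid]
        names += [f"{m}:pearson_mean", f"{m}:connectivity_mean",
                  f"{m}:intracluster_mean", f"{m}:intercluster_mean",
                  f"{m}:euclid_weak_px", f"{m}:euclid_strong_px",
                  f"{m}:radial_weak_px", f"{m}:radial_strong_px",
                  f"{m}:active_accuracy_mean"]
    return names


@dataclass
class MetricVector:
    recording_id: str
    features: pd.Series  # indexed by feature name, ordered per schema


@dataclass
class StateProjection:
    """PCA embedding of recordings with its provenance."""

    scores: pd.DataFrame  # recordings x components (PC1, PC2, ...)
    explained_variance_ratio: np.ndarray
    loadings: pd.DataFrame  # features x components, unit-norm columns
    dropped_features: list[str] = field(default_factory=list)
    imputed: dict[str, int] = field(default_factory=dict)  # feature -> n imputed
    feature_means: pd.Series | None = None
    feature_sds: pd.Series | None = None


def _nanmean(values) -> float:
    arr = np.asarray([v for v in values if np.isfinite(v)], dtype=float)
    return float(arr.mean()) if arr.size else float("nan")


def _mean_active_accuracy(states: np.ndarray) -> float:
    n = states.shape[1]
    if n < 2:
        return float("nan")
    vals = [active_accuracy(states[:, a], states[:, b])
            for a in range(n) for b in range(a + 1, n)]
    return float(np.mean(vals))


def build_metric_vector(recording_id: str, traces: TraceMatrix, nmap: NeuronMap,
                        methods: Sequence[str] = METHODS,
                        strong_threshold: float = DEFAULT_STRONG_THRESHOLD,
                        nsd_thresholds: Sequence[float] = activity.NSD_THRESHOLDS,
                        degree_grid: Sequence[float] = DEFAULT_GRID) -> MetricVector:
    """Compute the full per-recording feature vector.

    Metrics that are undefined for a recording (e.g. distance means of an
    empty correlation band) are stored as NaN and imputed at PCA time.
    """
    names = feature_schema(methods, nsd_thresholds, degree_grid)
    values: dict[str, float] = {}
    for m in methods:
        raster = binarize_matrix(traces, method=m)
        rates = activity.burst_rate(raster)
        nsr = activity.network_spike_rate(raster)
        values[f"{m}:burst_rate_mean"] = float(rates.mean())
        values[f"{m}:nsr_mean"] = float(nsr.mean())
        values[f"{m}:network_spike_peak"] = activity.network_spike_peak(raster)
        nsd = activity.network_spike_duration(raster, nsd_thresholds)
        for t, v in nsd.items():
            values[f"{m}:nsd_{t:g}pct_s"] = v
        graph = correlation.pairwise_pearson(raster, threshold_grid=degree_grid)
        for t, v in correlation.network_degree(graph).items():
            values[f"{m}:degree_{t:.2f}"] = v
        pair_vals = graph.pair_values()
        values[f"{m}:pearson_mean"] = float(pair_vals.mean()) if pair_vals.size else float("nan")
        values[f"{m}:connectivity_mean"] = _nanmean(
            correlation.connectivity(graph, strong_threshold).values())
        assignment = correlation.cluster_assign(graph)
        intra, inter = correlation.intra_inter_cluster(graph, assignment)
        values[f"{m}:intracluster_mean"] = _nanmean(intra.values())
        values[f"{m}:intercluster_mean"] = _nanmean(inter.values())
        bands = spatial.band_distance_summary(graph, nmap, strong_threshold)
        values[f"{m}:euclid_weak_px"] = bands["weak"].mean_euclidean_px
        values[f"{m}:euclid_strong_px"] = bands["strong"].mean_euclidean_px
        values[f"{m}:radial_weak_px"] = bands["weak"].mean_radial_px
        values[f"{m}:radial_strong_px"] = bands["strong"].mean_radial_px
        values[f"{m}:active_accuracy_mean"] = _mean_active_accuracy(raster.states)
    series = pd.Series([values[n] for n in names], index=names, dtype=float)
    return MetricVector(recording_id, series)


def build_metric_table(recordings: Sequence[tuple[str, TraceMatrix, NeuronMap]],
                       **kwargs) -> pd.DataFrame:
    """Stack metric vectors into a recordings x features table."""
    vectors = [build_metric_vector(rid, tm, nm, **kwargs) for rid, tm, nm in recordings]
    return pd.DataFrame({v.recording_id: v.features for v in vectors}).T


def pca_project(table: pd.DataFrame, n_components: int = 2) -> StateProjection:
    """Standardized PCA of the recordings x features table.

    Zero-variance features are dropped (recorded in ``dropped_features``);
    NaN entries are imputed with the feature's cross-recording mean before
    standardization (counts in ``imputed``).  Component signs follow the
    largest-magnitude-loading-positive convention.
    """
    if table.shape[0] < 2:
        raise ValueError("PCA requires at least 2 recordings")
    x = table.astype(float).copy()
    imputed: dict[str, int] = {}
    for col in x.columns:
        n_nan = int(x[col].isna().sum())
        if n_nan:
            imputed[col] = n_nan
            x[col] = x[col].fillna(x[col].mean())
    sds = x.std(ddof=0)
    dropped = [c for c in x.columns if not np.isfinite(sds[c]) or sds[c] == 0]
    x = x.drop(columns=dropped)
    if x.shape[1] < 2:
        raise ValueError("PCA requires at least 2 features with nonzero variance")
    means = x.mean()
    z = (x - means) / x.std(ddof=0)
    k = min(n_components, z.shape[0], z.shape[1])
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(z.to_numpy())
    load = pca.components_.T  # features x components, unit-norm columns
    for c in range(k):
        dominant = np.argmax(np.abs(load[:, c]))
        if load[dominant, c] < 0:
            load[:, c] *= -1
            scores[:, c] *= -1
    comp_names = [f"PC{c + 1}" for c in range(k)]
    return StateProjection(
        scores=pd.DataFrame(scores, index=table.index, columns=comp_names),
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        loadings=pd.DataFrame(load, index=z.columns, columns=comp_names),
        dropped_features=dropped,
        imputed=imputed,
        feature_means=means,
        feature_sds=x.std(ddof=0),
    )


def loading_report(projection: StateProjection, top_k: int = 10) -> pd.DataFrame:
    """Features ranked by absolute loading, per component.

    Returns a tidy table with columns component, rank, feature, loading.
    """
    rows = []
    for comp in projection.loadings.columns:
        ranked = projection.loadings[comp].abs().sort_values(ascending=False).head(top_k)
        for rank, feat in enumerate(ranked.index, start=1):
            rows.append({"component": comp, "rank": rank, "feature": feat,
                         "loading": float(projection.loadings.loc[feat, comp])})
    return pd.DataFrame(rows)
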