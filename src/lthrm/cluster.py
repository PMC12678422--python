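"""Two-stage clustering of detected swallows into motility-pattern groups.

Feature extraction per swallow window (36 x 500):

1. a temporal change filter with kernel [-1, 0, ..., 0, 1] (length 10) is
   convolved along time per sensor row (valid mode, output length 491) and
   the response squared -- this highlights pressure changes within a
   10-sample (0.2 s) frame and suppresses static baseline pressure;
2. the squared change image is bilinearly resized to 50 x 50 and smoothed
   with a Gaussian filter (sigma = 1 pixel);
3. images are flattened (2500) and reduced to 30 principal components.

Clustering is agglomerative (Ward linkage on Euclidean distances).  The
stage-1 cluster count is chosen from a range (default 4..10); clusters
holding >= 15% of all swallows are the *main* motility categories, and all
members of the remaining clusters are pooled and re-clustered into up to 10
finer *special* groups, which is where intermittent disorders surface.

Two k-selection strategies are available:

* ``"intra"`` (default): the literal lowest mean distance of samples to
  their own cluster centroid.  This score never increases with k, so on
  data with any within-cluster spread it is biased toward the top of the
  range; it is kept as the default because it is the method's stated rule.
* ``"knee"``: the k whose score shows the largest relative drop from k-1,
  which recovers the true cluster count when it lies strictly inside the
  range.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import AgglomerativeClustering
from sklearn.decomposition import PCA

from .preprocess import resize_window

logger = logging.getLogger(__name__)

KERNEL_LEN = 10
IMAGE_SIZE = 50
N_COMPONENTS = 30


@dataclass
class ChangeFeature:
    source: tuple[str, int]
    change_image: np.ndarray  # 50 x 50, squared + smoothed, >= 0
    feature: np.ndarray  # PCA scores


@dataclass
class ClusterInfo:
    cluster_id: int
    stage: int  # 1 = main, 2 = special
    center: np.ndarray
    member_indices: np.ndarray
    closest: np.ndarray  # sample indices, nearest to center first
    most_distant: np.ndarray  # farthest from center first

    @property
    def frequency(self) -> int:
        return len(self.member_indices)


@dataclass
class ClusterReport:
    stage1_labels: np.ndarray
    stage1_k: int
    main_cluster_ids: list[int]
    final_labels: np.ndarray
    clusters: list[ClusterInfo]
    sources: list[tuple[str, int]] = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return len(self.final_labels)

    def frequencies(self) -> dict[int, int]:
        return {c.cluster_id: c.frequency for c in self.clusters}

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "stage1_k": self.stage1_k,
            "main_cluster_ids": self.main_cluster_ids,
            "stage1_labels": self.stage1_labels.tolist(),
            "final_labels": self.final_labels.tolist(),
            "sources": [list(s) for s in self.sources],
            "clusters": [
                {
                    "cluster_id": c.cluster_id,
                    "stage": c.stage,
                    "frequency": c.frequency,
                    "center": c.center.tolist(),
                    "member_indices": c.member_indices.tolist(),
                    "closest": c.closest.tolist(),
                    "most_distant": c.most_distant.tolist(),
                }
                for c in self.clusters
            ],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


# ---------------------------------------------------------------------------
# features


def change_filter(window: np.ndarray, k_len: int = KERNEL_LEN) -> np.ndarray:
    """Squared valid-mode convolution with the change kernel [-1,0,...,0,1].

    The two non-zero taps are k_len - 1 samples apart, so the response at
    offset j is (row[j + k_len - 1] - row[j])^2 and the output is
    width - k_len + 1 columns wide.
    """
    window = np.asarray(window, dtype=float)
    if k_len < 2:
        raise ValueError("kernel length must be >= 2")
    if window.shape[-1] < k_len:
        raise ValueError(
            f"window width {window.shape[-1]} shorter than kernel {k_len}"
        )
    diff = window[..., k_len - 1 :] - window[..., : window.shape[-1] - k_len + 1]
    return diff**2


def change_image(
    window: np.ndarray,
    k_len: int = KERNEL_LEN,
    image_size: int = IMAGE_SIZE,
    sigma: float = 1.0,
) -> np.ndarray:
    """Change-filtered, squared, resized and Gaussian-smoothed image."""
    filtered = change_filter(window, k_len)
    resized = resize_window(filtered, (image_size, image_size), in_shape=None)
    return gaussian_filter(resized, sigma=sigma)


def make_features(
    windows: Sequence[np.ndarray],
    sources: Sequence[tuple[str, int]] | None = None,
    n_components: int = N_COMPONENTS,
    k_len: int = KERNEL_LEN,
    image_size: int = IMAGE_SIZE,
    sigma: float = 1.0,
) -> tuple[list[ChangeFeature], PCA]:
    """Change images + PCA scores for a set of swallow windows.

    PCA is fitted on these windows themselves (per-recording clustering is
    the primary use).  Fewer than 2 swallows cannot be clustered; with
    fewer than n_components + 1 swallows the component count is reduced
    with a warning.
    """
    n = len(windows)
    if n < 2:
        raise ValueError("clustering requires at least 2 swallows")
    if sources is None:
        sources = [("", i) for i in range(n)]
    images = np.stack(
        [change_image(w, k_len, image_size, sigma) for w in windows]
    )
    flat = images.reshape(n, -1)
    max_comp = min(n - 1, flat.shape[1])
    if n_components > max_comp:
        warnings.warn(
            f"only {n} swallows: reducing PCA components "
            f"{n_components} -> {max_comp}",
            stacklevel=2,
        )
        n_components = max_comp
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(flat)
    feats = [
        ChangeFeature(source=tuple(src), change_image=img, feature=vec)
        for src, img, vec in zip(sources, images, scores)
    ]
    return feats, pca


def _feature_matrix(
    features: Sequence[ChangeFeature] | np.ndarray,
) -> np.ndarray:
    if isinstance(features, np.ndarray):
        return np.asarray(features, dtype=float)
    return np.stack([f.feature for f in features]).astype(float)


# ---------------------------------------------------------------------------
# cluster-count selection


def mean_intra_cluster_distance(X: np.ndarray, labels: np.ndarray) -> float:
    """Mean over samples of the Euclidean distance to the own-cluster centroid."""
    total = 0.0
    for lab in np.unique(labels):
        members = X[labels == lab]
        total += float(
            np.linalg.norm(members - members.mean(axis=0), axis=1).sum()
        )
    return total / len(X)


def select_k(
    features: Sequence[ChangeFeature] | np.ndarray,
    k_range: Sequence[int] = range(4, 11),
    strategy: str = "intra",
) -> int:
    """Choose the stage-1 cluster count.

    ``"intra"``: smallest mean intra-cluster distance, smallest k on ties
    (scores equal within 1e-12 relative).  ``"knee"``: largest relative
    score drop from the previous k.
    """
    X = _feature_matrix(features)
    ks = sorted(k_range)
    if len(X) < max(ks) + 1:
        raise ValueError(
            f"need at least {max(ks) + 1} samples to sweep k up to {max(ks)}"
        )
    scores = []
    for k in ks:
        labels = AgglomerativeClustering(n_clusters=k, linkage="ward").fit_predict(X)
        scores.append(mean_intra_cluster_distance(X, labels))
    scores = np.asarray(scores)
    if strategy == "intra":
        tol = 1e-12 * max(1.0, float(np.abs(scores).max()))
        best = scores.min()
        return ks[int(np.argmax(scores <= best + tol))]
    if strategy == "knee":
        prev, curr = scores[:-1], scores[1:]
        with np.errstate(divide="ignore", invalid="ignore"):
            drops = np.where(prev > 0, (prev - curr) / prev, 0.0)
        if not len(drops) or np.all(drops <= 0):
            return ks[0]
        return ks[1 + int(np.argmax(drops))]
    raise ValueError(f"unknown k-selection strategy: {strategy!r}")


# ---------------------------------------------------------------------------
# two-stage clustering


def _cluster_info(
    X: np.ndarray,
    member_indices: np.ndarray,
    cluster_id: int,
    stage: int,
    n_repr: int = 5,
) -> ClusterInfo:
    members = X[member_indices]
    center = members.mean(axis=0)
    dist = np.linalg.norm(members - center, axis=1)
    # stable order: by distance, then by sample index
    order = np.lexsort((member_indices, dist))
    n = min(n_repr, len(member_indices))
    closest = member_indices[order[:n]]
    most_distant = member_indices[order[::-1][:n]]
    return ClusterInfo(
        cluster_id=cluster_id,
        stage=stage,
        center=center,
        member_indices=np.sort(member_indices),
        closest=closest,
        most_distant=most_distant,
    )


def two_stage_cluster(
    features: Sequence[ChangeFeature] | np.ndarray,
    k_range: Sequence[int] = range(4, 11),
    strategy: str = "intra",
    main_share: float = 0.15,
    special_k: int = 10,
    n_repr: int = 5,
    sources: Sequence[tuple[str, int]] | None = None,
) -> ClusterReport:
    """Stage 1: agglomerative clustering with selected k; clusters holding
    >= ``main_share`` of all swallows are the main categories.  Stage 2:
    members of the remaining clusters are pooled and re-clustered into
    min(special_k, n_pooled) special groups."""
    X = _feature_matrix(features)
    n = len(X)
    if n < 2:
        raise ValueError("clustering requires at least 2 samples")
    feasible = [k for k in sorted(k_range) if k + 1 <= n]
    if feasible:
        k1 = select_k(X, k_range=feasible, strategy=strategy)
    else:  # fewer samples than the smallest candidate k: one cluster per gap
        k1 = min(n, min(k_range))
        logger.warning(
            "only %d swallows: skipping k sweep, using k=%d", n, k1
        )
    stage1 = AgglomerativeClustering(n_clusters=k1, linkage="ward").fit_predict(X)

    counts = np.bincount(stage1, minlength=k1)
    main_ids = [int(lab) for lab in range(k1) if counts[lab] / n >= main_share]
    pooled = np.flatnonzero(~np.isin(stage1, main_ids))

    final = np.full(n, -1, dtype=int)
    clusters: list[ClusterInfo] = []
    next_id = 0
    for lab in main_ids:
        members = np.flatnonzero(stage1 == lab)
        final[members] = next_id
        clusters.append(_cluster_info(X, members, next_id, stage=1, n_repr=n_repr))
        next_id += 1

    if len(pooled):
        k2 = min(special_k, len(pooled))
        if k2 >= 2:
            sub = AgglomerativeClustering(
                n_clusters=k2, linkage="ward"
            ).fit_predict(X[pooled])
        else:
            sub = np.zeros(len(pooled), dtype=int)
        for lab in range(sub.max() + 1):
            members = pooled[sub == lab]
            final[members] = next_id
            clusters.append(
                _cluster_info(X, members, next_id, stage=2, n_repr=n_repr)
            )
            next_id += 1

    assert np.all(final >= 0)
    src_list = list(sources) if sources is not None else (
        [f.source for f in features] if not isinstance(features, np.ndarray) else []
    )
    return ClusterReport(
        stage1_labels=stage1,
        stage1_k=k1,
        main_cluster_ids=list(range(len(main_ids))),
        final_labels=final,
        clusters=clusters,
        sources=src_list,
    )


def representatives(
    report: ClusterReport,
    features: Sequence[ChangeFeature] | np.ndarray,
    n: int = 5,
) -> dict[int, dict[str, np.ndarray]]:
    """Recompute the n closest / most distant members per final cluster."""
    X = _feature_matrix(features)
    out: dict[int, dict[str, np.ndarray]] = {}
    for c in report.clusters:
        info = _cluster_info(X, c.member_indices, c.cluster_id, c.stage, n_repr=n)
        out[c.cluster_id] = {
            "closest": info.closest,
            "most_distant": info.most_distant,
            "frequency": np.int64(info.frequency),
        }
    return out


class TwoStageClusterer(ClusterMixin, BaseEstimator):
    """sklearn-style estimator over the change-feature two-stage clustering.

    ``fit(X)`` accepts either raw swallow windows (n, 36, 500) or a
    precomputed feature matrix (n, n_features) when ``input="features"``.
    Fitted attributes: ``labels_`` (final assignment), ``report_``,
    ``features_``, ``pca_`` (windows input only).
    """

    def __init__(
        self,
        input: str = "windows",
        n_components: int = N_COMPONENTS,
        kernel_len: int = KERNEL_LEN,
        image_size: int = IMAGE_SIZE,
        gaussian_sigma: float = 1.0,
        k_min: int = 4,
        k_max: int = 10,
        strategy: str = "intra",
        main_share: float = 0.15,
        special_k: int = 10,
        n_repr: int = 5,
    ) -> None:
        self.input = input
        self.n_components = n_components
        self.kernel_len = kernel_len
        self.image_size = image_size
        self.gaussian_sigma = gaussian_sigma
        self.k_min = k_min
        self.k_max = k_max
        self.strategy = strategy
        self.main_share = main_share
        self.special_k = special_k
        self.n_repr = n_repr

    def fit(self, X, y=None, sources=None) -> "TwoStageClusterer":
        if self.input == "windows":
            feats, self.pca_ = make_features(
                X,
                sources=sources,
                n_components=self.n_components,
                k_len=self.kernel_len,
                image_size=self.image_size,
                sigma=self.gaussian_sigma,
            )
            self.features_ = np.stack([f.feature for f in feats])
            srcs = [f.source for f in feats]
        elif self.input == "features":
            self.features_ = np.asarray(X, dtype=float)
            srcs = list(sources) if sources is not None else []
        else:
            raise ValueError("input must be 'windows' or 'features'")
        self.report_ = two_stage_cluster(
            self.features_,
            k_range=range(self.k_min, self.k_max + 1),
            strategy=self.strategy,
            main_share=self.main_share,
            special_k=self.special_k,
            n_repr=self.n_repr,
            sources=srcs,
        )
        self.labels_ = self.report_.final_labels
        return self
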