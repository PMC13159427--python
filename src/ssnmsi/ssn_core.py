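"""Spatial similarity networking (SSN) over product-ion images.

Product ions that derive from the same precursor share that precursor's
spatial distribution across the tissue.  SSN exploits this: every product
ion detected in one isolation window becomes a node, pairwise spatial
similarity between their images is scored (cosine, SSE or MSE), pairs
passing a threshold are joined by an edge, and the connected components of
the resulting undirected graph are the deconvoluted precursors — one
cluster per co-isolated species.  Spatial distribution thereby acts like
chromatographic retention time: an orthogonal dimension next to accurate
mass and fragmentation.

The coherent variant pools each image into non-overlapping p×p patches
before scoring, which emphasizes regional coherence and suppresses
single-pixel noise in heterogeneous tissue.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np

from .msi_io import IncompatibleImageError, IonImage

__all__ = [
    "MetricSpec",
    "SimilarityMatrix",
    "PatchConfig",
    "ClusterParams",
    "ClusterSet",
    "ClusterComparison",
    "DeconvolutedSpectrum",
    "RecoveryReport",
    "cosine_similarity",
    "sse",
    "mse",
    "similarity_matrix",
    "build_graph",
    "connected_components",
    "pool_image",
    "coherent_ssn",
    "ssn_cluster",
    "cluster_spectrum",
    "compare_to_reference",
    "jaccard",
    "harmonize_ion_sets",
]

_METRIC_ORIENTATION = {"cosine": "similarity", "sse": "dissimilarity", "mse": "dissimilarity"}


@dataclass(frozen=True)
class MetricSpec:
    """Which spatial similarity metric to use and how images are prepared.

    Cosine similarity is scale-invariant, which makes it the metric of
    choice when comparing runs acquired under different conditions; SSE and
    MSE retain absolute-intensity differences.  For SSE/MSE the default
    per-image normalization is ``unit_max`` so that the error is bounded and
    a single dissimilarity threshold is meaningful across ion pairs.
    """

    name: str = "cosine"
    per_image_normalization: Optional[str] = None  # None -> metric default

    def __post_init__(self) -> None:
        if self.name not in _METRIC_ORIENTATION:
            raise ValueError(f"unknown metric {self.name!r}; use cosine, sse or mse")
        norm = self.per_image_normalization
        if norm is None:
            norm = "none" if self.name == "cosine" else "unit_max"
            object.__setattr__(self, "per_image_normalization", norm)
        elif norm not in ("none", "unit_max", "unit_norm"):
            raise ValueError(f"unknown normalization {norm!r}")

    @property
    def orientation(self) -> str:
        """'similarity' (edge when score >= τ) or 'dissimilarity' (<= τ)."""
        return _METRIC_ORIENTATION[self.name]


@dataclass(frozen=True)
class PatchConfig:
    """Patch pooling for the coherent SSN variant; p=1 is plain SSN."""

    patch_size: int = 4
    pooling: str = "mean"

    def __post_init__(self) -> None:
        if self.patch_size < 1:
            raise ValueError("patch_size must be >= 1")
        if self.pooling not in ("mean", "median"):
            raise ValueError("pooling must be 'mean' or 'median'")


@dataclass(frozen=True)
class ClusterParams:
    """Edge rule of the SSN graph: metric, threshold τ and optional patching.

    Ties at exactly τ are inclusive, so the edge rule is a closed condition.
    """

    threshold: float = 0.90
    metric: MetricSpec = field(default_factory=MetricSpec)
    patch: Optional[PatchConfig] = None

    def __post_init__(self) -> None:
        if self.metric.orientation == "similarity" and self.threshold < 0:
            raise ValueError("similarity thresholds must be nonnegative")
        if self.metric.orientation == "dissimilarity" and self.threshold < 0:
            raise ValueError("dissimilarity thresholds must be nonnegative")

    def passes(self, score: float) -> bool:
        if self.metric.orientation == "similarity":
            return score >= self.threshold
        return score <= self.threshold


@dataclass
class SimilarityMatrix:
    """Symmetric pairwise scores between the product-ion images of a window."""

    ions: list[float]
    S: np.ndarray
    metric: MetricSpec
    degenerate: set[float] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        k = len(self.ions)
        if self.S.shape != (k, k):
            raise ValueError("similarity matrix must be square over the ion list")


@dataclass
class ClusterSet:
    """A partition of the product ions of one window into disjoint clusters.

    Singlets are flagged but retained — unclustered ions stay available for
    rule-based annotation downstream.
    """

    clusters: list[frozenset]

    def __post_init__(self) -> None:
        seen: set = set()
        for c in self.clusters:
            if seen & set(c):
                raise ValueError("clusters must be pairwise disjoint")
            seen |= set(c)

    @property
    def nodes(self) -> set:
        out: set = set()
        for c in self.clusters:
            out |= set(c)
        return out

    @property
    def singlets(self) -> list[frozenset]:
        return [c for c in self.clusters if len(c) == 1]

    def multi_clusters(self) -> list[frozenset]:
        return [c for c in self.clusters if len(c) > 1]

    def cluster_of(self, node) -> frozenset:
        for c in self.clusters:
            if node in c:
                return c
        raise KeyError(node)

    def refines(self, other: "ClusterSet") -> bool:
        """True if every cluster here is contained in a cluster of ``other``."""
        return all(
            any(set(c) <= set(o) for o in other.clusters) for c in self.clusters
        )


@dataclass
class ClusterComparison:
    """Jaccard overlap of two or more replicate ion sets."""

    jaccard: float
    shared_ions: set
    union_ions: set
    pairwise: Optional[list[float]] = None


@dataclass
class DeconvolutedSpectrum:
    """Per-cluster reconstructed MS² spectrum, base peak scaled to 100."""

    mz: np.ndarray
    intensity: np.ndarray
    degenerate: bool = False

    def __len__(self) -> int:
        return int(np.asarray(self.mz).size)


@dataclass
class RecoveryReport:
    """Agreement of a deconvoluted spectrum with a reference standard."""

    recovered_fraction: float
    matched: list[tuple[float, float]]  # (reference m/z, deconvoluted m/z)
    missed_reference: list[float]
    extra_peaks: list[float]


# ---------------------------------------------------------------------------
# Pairwise metrics
# ---------------------------------------------------------------------------

def _joint_vectors(a: IonImage, b: IonImage) -> tuple[np.ndarray, np.ndarray]:
    if not a.compatible_with(b):
        raise IncompatibleImageError(
            "ion images must share shape and valid mask to be compared"
        )
    mask = a.valid_mask
    return a.values[mask], b.values[mask]


def _normalize(x: np.ndarray, how: str) -> np.ndarray:
    if how == "none":
        return x
    if how == "unit_max":
        m = x.max() if x.size else 0.0
        return x / m if m > 0 else x
    if how == "unit_norm":
        n = float(np.linalg.norm(x))
        return x / n if n > 0 else x
    raise ValueError(f"unknown normalization {how!r}")


def cosine_similarity(a: IonImage, b: IonImage) -> float:
    """Cosine of the two images over jointly valid pixels, in [0, 1].

    Scale-invariant: cosine(x, c·x) = 1 for any c > 0.  All-zero images are
    degenerate and score 0 against everything.
    """
    x, y = _joint_vectors(a, b)
    nx_, ny_ = float(np.linalg.norm(x)), float(np.linalg.norm(y))
    if nx_ == 0.0 or ny_ == 0.0:
        return 0.0
    return float(np.dot(x, y) / (nx_ * ny_))


def sse(a: IonImage, b: IonImage, normalization: str = "none") -> float:
    """Sum of squared differences over jointly valid pixels (≥ 0).

    Unlike cosine, SSE retains absolute-intensity differences unless a
    per-image normalization is applied first.
    """
    x, y = _joint_vectors(a, b)
    x = _normalize(x, normalization)
    y = _normalize(y, normalization)
    d = x - y
    return float(np.dot(d, d))


def mse(a: IonImage, b: IonImage, normalization: str = "none") -> float:
    """SSE divided by the number of jointly valid pixels P."""
    p = int(a.valid_mask.sum())
    if p == 0:
        return 0.0
    return sse(a, b, normalization) / p


def _pair_score(a: IonImage, b: IonImage, metric: MetricSpec) -> float:
    if metric.name == "cosine":
        return cosine_similarity(a, b)
    if metric.name == "sse":
        return sse(a, b, metric.per_image_normalization)
    return mse(a, b, metric.per_image_normalization)


def similarity_matrix(
    images: Sequence[IonImage], metric: MetricSpec = MetricSpec()
) -> SimilarityMatrix:
    """Score all unordered pairs of images once; the matrix is symmetric.

    All-zero (degenerate) images are recorded in ``degenerate`` but kept in
    the matrix, matching the retention of unclustered ions downstream.
    """
    if not images:
        raise ValueError("similarity_matrix needs at least one ion image")
    k = len(images)
    S = np.zeros((k, k))
    degenerate = set()
    for i, img in enumerate(images):
        if not np.any(img.values[img.valid_mask] > 0):
            degenerate.add(img.target_mz)
        S[i, i] = 1.0 if metric.orientation == "similarity" else 0.0
        if img.target_mz in degenerate and metric.name == "cosine":
            S[i, i] = 0.0  # cosine of an all-zero image is undefined; flagged 0
    for i in range(k):
        for j in range(i + 1, k):
            S[i, j] = S[j, i] = _pair_score(images[i], images[j], metric)
    return SimilarityMatrix(
        ions=[img.target_mz for img in images], S=S, metric=metric,
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# Graph construction and clustering
# ---------------------------------------------------------------------------

def build_graph(matrix: SimilarityMatrix, params: ClusterParams) -> nx.Graph:
    """Undirected SSN graph: nodes are product ions, edges pass the τ rule."""
    if params.metric.name != matrix.metric.name:
        raise ValueError(
            f"matrix was scored with {matrix.metric.name!r} but the cluster "
            f"params expect {params.metric.name!r}"
        )
    g = nx.Graph()
    g.add_nodes_from(matrix.ions)
    k = len(matrix.ions)
    for i in range(k):
        for j in range(i + 1, k):
            score = float(matrix.S[i, j])
            if params.passes(score):
                g.add_edge(matrix.ions[i], matrix.ions[j], score=score)
    return g


def connected_components(graph: nx.Graph) -> ClusterSet:
    """Partition the SSN graph into maximal connected components.

    Every node appears in exactly one cluster; singlets are retained.
    """
    comps = [frozenset(c) for c in nx.connected_components(graph)]
    comps.sort(key=lambda c: (-len(c), min(c)))
    return ClusterSet(clusters=comps)


def pool_image(image: IonImage, patch: PatchConfig) -> IonImage:
    """Pool an image into non-overlapping p×p patches.

    The pooling statistic runs over the valid pixels of each patch; patches
    containing no valid pixel are masked invalid.  Trailing partial patches
    at the image border are pooled from whatever pixels they contain.
    """
    p = patch.patch_size
    if p == 1:
        return image
    rows, cols = image.values.shape
    if p > rows and p > cols:
        raise ValueError(
            f"patch size {p} exceeds both image dimensions {rows}x{cols}"
        )
    out_r, out_c = math.ceil(rows / p), math.ceil(cols / p)
    values = np.zeros((out_r, out_c))
    mask = np.zeros((out_r, out_c), dtype=bool)
    stat = np.mean if patch.pooling == "mean" else np.median
    for r in range(out_r):
        for c in range(out_c):
            vals = image.values[r * p : (r + 1) * p, c * p : (c + 1) * p]
            vmask = image.valid_mask[r * p : (r + 1) * p, c * p : (c + 1) * p]
            if vmask.any():
                mask[r, c] = True
                values[r, c] = float(stat(vals[vmask]))
    return IonImage(
        values=values, valid_mask=mask, target_mz=image.target_mz,
        tolerance=image.tolerance, filter=image.filter,
    )


def ssn_cluster(
    images: Sequence[IonImage], params: ClusterParams = ClusterParams()
) -> ClusterSet:
    """Plain SSN: similarity matrix → thresholded graph → components."""
    matrix = similarity_matrix(images, params.metric)
    return connected_components(build_graph(matrix, params))


def coherent_ssn(
    images: Sequence[IonImage], params: ClusterParams
) -> ClusterSet:
    """Coherent SSN: patch-pool each image, then run the plain pipeline.

    With patch size 1 this reduces exactly to plain SSN.
    """
    patch = params.patch or PatchConfig()
    pooled = [pool_image(img, patch) for img in images]
    flat = ClusterParams(threshold=params.threshold, metric=params.metric, patch=None)
    return ssn_cluster(pooled, flat)


# ---------------------------------------------------------------------------
# Deconvoluted spectra and reproducibility
# ---------------------------------------------------------------------------

def cluster_spectrum(
    cluster: Iterable[float], images: Sequence[IonImage]
) -> DeconvolutedSpectrum:
    """Reassemble one cluster into a deconvoluted MS² spectrum.

    Each member ion contributes its mean image intensity over valid pixels;
    the spectrum is scaled so the base peak is 100.  An all-zero cluster is
    returned empty and flagged degenerate.
    """
    by_mz = {img.target_mz: img for img in images}
    members = sorted(set(cluster))
    if not members:
        return DeconvolutedSpectrum(np.empty(0), np.empty(0))
    missing = [m for m in members if m not in by_mz]
    if missing:
        raise KeyError(f"cluster ions without images: {missing}")
    mzs, intens = [], []
    for m in members:
        img = by_mz[m]
        vals = img.values[img.valid_mask]
        intens.append(float(vals.mean()) if vals.size else 0.0)
        mzs.append(m)
    intens_arr = np.asarray(intens)
    base = intens_arr.max() if intens_arr.size else 0.0
    if base <= 0:
        return DeconvolutedSpectrum(np.empty(0), np.empty(0), degenerate=True)
    return DeconvolutedSpectrum(np.asarray(mzs), 100.0 * intens_arr / base)


def compare_to_reference(
    decon: DeconvolutedSpectrum,
    reference: DeconvolutedSpectrum,
    mz_tol: float = 0.3,
    min_rel: float = 0.01,
) -> RecoveryReport:
    """Fraction of reference peaks (above ``min_rel`` of its base peak)
    recovered by the deconvoluted spectrum within ``mz_tol``.

    Reference peaks below the relative-intensity floor are excluded from the
    denominator; deconvoluted peaks absent from the reference are reported
    as extras.
    """
    ref_mz = np.asarray(reference.mz, dtype=float)
    ref_int = np.asarray(reference.intensity, dtype=float)
    dec_mz = np.asarray(decon.mz, dtype=float)
    if ref_int.size and ref_int.max() > 0:
        ref_int = ref_int / ref_int.max()
    considered = ref_mz[ref_int >= min_rel] if ref_mz.size else ref_mz
    matched, missed = [], []
    used = np.zeros(dec_mz.size, dtype=bool)
    for rm in considered:
        if dec_mz.size:
            dist = np.abs(dec_mz - rm)
            dist[used] = np.inf
            j = int(np.argmin(dist))
            if dist[j] <= mz_tol:
                matched.append((float(rm), float(dec_mz[j])))
                used[j] = True
                continue
        missed.append(float(rm))
    extras = [
        float(dm)
        for dm in dec_mz
        if not ref_mz.size or np.min(np.abs(ref_mz - dm)) > mz_tol
    ]
    frac = len(matched) / len(considered) if len(considered) else 1.0
    return RecoveryReport(
        recovered_fraction=frac, matched=matched,
        missed_reference=missed, extra_peaks=extras,
    )


def harmonize_ion_sets(
    sets: Sequence[Iterable[float]], mz_tol: float
) -> list[set[int]]:
    """Match ion m/z values across datasets onto shared canonical identifiers.

    The first set seeds the canonical centers; each later value is matched
    greedily to the nearest unused canonical center within ``mz_tol``, or
    opens a new one.  Returns one set of canonical indices per input set.
    """
    centers: list[float] = []
    out: list[set[int]] = []
    for ions in sets:
        assigned: set[int] = set()
        for mz in sorted(float(m) for m in ions):
            best, best_d = None, mz_tol
            for idx, c in enumerate(centers):
                if idx in assigned:
                    continue
                d = abs(c - mz)
                if d <= best_d:
                    best, best_d = idx, d
            if best is None:
                centers.append(mz)
                best = len(centers) - 1
            assigned.add(best)
        out.append(assigned)
    return out


def jaccard(
    sets: Sequence[Iterable],
    mz_tol: Optional[float] = None,
    pairwise: bool = False,
) -> ClusterComparison:
    """Jaccard overlap of two or more replicate ion sets.

    With ``mz_tol`` set, elements are treated as m/z values and matched
    across sets within the tolerance before comparison.  The headline value
    is the multi-way intersection-over-union; ``pairwise`` additionally
    reports all pairwise Jaccard indices.  Two empty sets compare as 1.
    """
    if len(sets) < 2:
        raise ValueError("jaccard needs at least two sets")
    if mz_tol is not None:
        id_sets = [frozenset(s) for s in harmonize_ion_sets(sets, mz_tol)]
    else:
        id_sets = [frozenset(s) for s in sets]
    inter = set(id_sets[0])
    union: set = set()
    for s in id_sets:
        inter &= s
        union |= s
    value = len(inter) / len(union) if union else 1.0
    pw = None
    if pairwise:
        pw = []
        for i in range(len(id_sets)):
            for j in range(i + 1, len(id_sets)):
                u = id_sets[i] | id_sets[j]
                pw.append(len(id_sets[i] & id_sets[j]) / len(u) if u else 1.0)
    return ClusterComparison(
        jaccard=value, shared_ions=set(inter), union_ions=set(union), pairwise=pw
    )
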