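"""Integrated-gradients attribution on the embedded input, position-summed
attribution profiles, K-means clustering of attribution tensors, and
per-cluster position/token frequency matrices for logo rendering.

The attribution for feature (i, j) of the embedded window x against a
baseline x' is the right-Riemann approximation

    ig[i, j] = (x[i, j] - x'[i, j]) * (1/m) * sum_{s=1..m} dF/dx[i, j]
               evaluated at x' + (s/m) (x - x')

so the sum includes the endpoint x and excludes x'.  Summing over the
embedding axis j gives the per-position profile (one value per residue
position).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .alphabet import EncodedWindow, ModAlphabet


class InterpretError(ValueError):
    pass


@dataclass
class IGConfig:
    m: int = 64  # Riemann steps
    baseline_mode: str = "padding"  # "padding" | "zero"

    def validate(self) -> None:
        if self.m < 1:
            raise InterpretError(f"m must be >= 1, got {self.m}")
        if self.baseline_mode not in ("padding", "zero"):
            raise InterpretError(f"unknown baseline mode {self.baseline_mode!r}")


@dataclass
class AttributionResult:
    ig: np.ndarray  # (k, embedding_dim)
    psig: np.ndarray  # (k,) == ig.sum(axis=1)
    f_x: float
    f_baseline: float
    window: EncodedWindow

    @property
    def completeness_error(self) -> float:
        """|sum(ig) - (F(x) - F(x'))| — shrinks as m grows."""
        return abs(float(self.ig.sum()) - (self.f_x - self.f_baseline))


def _baseline_for(model, window: EncodedWindow, mode: str) -> np.ndarray:
    if mode == "zero":
        return np.zeros((len(window.tokens), model.config.embedding_dim))
    pad_codes = np.zeros(len(window.tokens), dtype=np.int64)
    return model.embed(pad_codes)


def integrated_gradients(
    model, window: EncodedWindow, config: IGConfig | None = None
) -> AttributionResult:
    """Attribution of the model output to each (position, embedding-dim).

    ``model`` needs ``embed(codes)`` and ``value_and_grad_embedding(X)``;
    any object with that surface works (a linear surrogate, for instance).
    """
    config = config or IGConfig()
    config.validate()
    x = np.asarray(model.embed(window.codes), dtype=np.float64)
    xp = np.asarray(_baseline_for(model, window, config.baseline_mode))
    if x.shape != xp.shape:
        raise InterpretError(f"baseline shape {xp.shape} != input shape {x.shape}")

    m = config.m
    steps = (np.arange(1, m + 1) / m)[:, None, None]
    batch = xp[None] + steps * (x - xp)[None]  # (m, k, d)
    _, grads = model.value_and_grad_embedding(batch)
    avg_grad = grads.mean(axis=0)
    ig = (x - xp) * avg_grad

    f_x, _ = model.value_and_grad_embedding(x)
    f_b, _ = model.value_and_grad_embedding(xp)
    return AttributionResult(
        ig=ig,
        psig=ig.sum(axis=1),
        f_x=float(f_x),
        f_baseline=float(f_b),
        window=window,
    )


@dataclass
class ClusterAnalysis:
    assignments: np.ndarray  # cluster id per window
    n_clusters: int
    centroid_psig: np.ndarray  # (n_clusters, k)
    inertia_curve: list[tuple[int, float]]  # (cluster count, inertia) elbow data
    embedding_2d: np.ndarray | None = None
    seed: int = 0

    def members(self, cluster_id: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == cluster_id)


def cluster_attributions(
    results: list[AttributionResult],
    n_clusters: int = 10,
    seed: int = 0,
    *,
    standardize: bool = False,
    elbow_range: tuple[int, int] | None = None,
    compute_embedding: bool = False,
) -> ClusterAnalysis:
    """K-means on the flattened attribution tensors (before position
    summation), with an inertia-vs-cluster-count elbow curve.

    ``compute_embedding`` additionally fits a 2-D t-SNE of the tensors for
    visualization (coordinates only; no rendering).
    """
    if len(results) < n_clusters:
        raise InterpretError(
            f"{len(results)} attribution results cannot form {n_clusters} clusters"
        )
    X = np.stack([r.ig.ravel() for r in results])
    if standardize:
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd

    km = KMeans(n_clusters=n_clusters, random_state=seed, n_init=10)
    assignments = km.fit_predict(X)

    lo, hi = elbow_range or (1, min(15, len(results)))
    inertia_curve = []
    for c in range(lo, hi + 1):
        k_c = KMeans(n_clusters=c, random_state=seed, n_init=3).fit(X)
        inertia_curve.append((c, float(k_c.inertia_)))

    psig = np.stack([r.psig for r in results])
    centroid_psig = np.stack(
        [psig[assignments == c].mean(axis=0) if (assignments == c).any()
         else np.zeros(psig.shape[1])
         for c in range(n_clusters)]
    )

    embedding_2d = None
    if compute_embedding:
        from sklearn.manifold import TSNE

        perplexity = min(30.0, max(2.0, (len(results) - 1) / 3.0))
        embedding_2d = TSNE(
            n_components=2, random_state=seed, perplexity=perplexity, init="pca"
        ).fit_transform(X)

    return ClusterAnalysis(
        assignments=assignments,
        n_clusters=n_clusters,
        centroid_psig=centroid_psig,
        inertia_curve=inertia_curve,
        embedding_2d=embedding_2d,
        seed=seed,
    )


def cluster_frequency_matrix(
    analysis: ClusterAnalysis,
    cluster_id: int,
    windows: list[EncodedWindow],
    alphabet: ModAlphabet,
    *,
    half_width: int = 10,
) -> tuple[np.ndarray, list[int], list[str]]:
    """Token counts per position for one cluster, center offset 0.

    Returns ``(matrix, offsets, tokens)``: matrix rows are alphabet tokens
    (mod tokens included), columns offsets ``-half_width .. +half_width``
    relative to the window center; every column sums to the cluster size.
    """
    idx = analysis.members(cluster_id)
    if idx.size == 0:
        raise InterpretError(f"cluster {cluster_id} is empty")
    k = windows[idx[0]].k
    half = min(half_width, (k - 1) // 2)
    offsets = list(range(-half, half + 1))
    tokens = list(alphabet.tokens)
    row_of = {t: i for i, t in enumerate(tokens)}
    mat = np.zeros((len(tokens), len(offsets)), dtype=np.int64)
    center0 = (k - 1) // 2
    for i in idx:
        w = windows[i]
        for col, off in enumerate(offsets):
            mat[row_of[w.tokens[center0 + off]], col] += 1
    return mat, offsets, tokens


def attribution_table(results: list[AttributionResult]) -> list[dict]:
    """Flatten attributions to (window id, offset, token, psig) rows."""
    rows = []
    for wid, r in enumerate(results):
        k = r.window.k
        center0 = (k - 1) // 2
        for i in range(k):
            rows.append(
                {
                    "window_id": wid,
                    "protein_id": r.window.origin[0],
                    "position": r.window.origin[1],
                    "offset": i - center0,
                    "token": r.window.tokens[i],
                    "psig": float(r.psig[i]),
                }
            )
    return rows
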