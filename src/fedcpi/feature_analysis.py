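"""Representation diagnostics over the decomposed feature subspaces.

Correlation heat-map statistics, cross-center correlation summaries with
significance tests and effect sizes, seeded 2-D embedding (t-SNE), and
internal cluster-validity indices.

Cross-center matching rule: patients at different centers have no natural
correspondence, so two centers are compared through their **mean feature
profiles** — the per-dimension mean over that center's samples.  The Pearson
correlation between two centers' d-dimensional mean profiles (dimension-wise
pairing) gives one correlation per center pair; the summary reports the
mean/std over all pairs and the fraction of pairs significant at p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn import metrics as _skm
from sklearn.manifold import TSNE

__all__ = [
    "FeatureTable", "CrossCenterSummary", "corr_matrix", "cross_center_corr",
    "group_corr_test", "embed_2d", "clustering_indices",
]

GROUPS = ("personal_large", "personal_small", "interactive", "common")


@dataclass
class FeatureTable:
    matrix: np.ndarray            # (n, d)
    group: str                    # one of GROUPS
    center_id: str

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if not np.isfinite(self.matrix).all():
            raise ValueError("feature matrix must be finite")
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}")


@dataclass
class CrossCenterSummary:
    mean_corr: float
    std_corr: float
    frac_significant: float
    pair_matrix: np.ndarray       # (C, C) correlations, nan diagonal
    pair_pvalues: np.ndarray


def corr_matrix(ft: FeatureTable) -> np.ndarray:
    """d x d Pearson matrix; zero-variance columns give NaN rows/columns."""
    X = ft.matrix
    if X.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    sd = X.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(X, rowvar=False)
    R = np.asarray(R, dtype=np.float64)
    R[sd == 0, :] = np.nan
    R[:, sd == 0] = np.nan
    np.fill_diagonal(R, np.where(sd > 0, 1.0, np.nan))
    return np.clip(R, -1.0, 1.0)


def _pearson_with_p(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    if a.std() == 0 or b.std() == 0:
        return np.nan, np.nan
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)


def cross_center_corr(tables: list[FeatureTable], alpha: float = 0.05,
                      method: str = "mean_profile") -> CrossCenterSummary:
    """Cross-center consistency of a feature subspace.

    ``method="mean_profile"`` correlates the centers' per-dimension mean
    profiles (dimension-wise pairing).  ``method="geometry"`` correlates the
    vectorized upper triangles of the centers' d x d feature-correlation
    matrices — a representational-similarity comparison that asks whether
    the *structure* of the subspace (which feature pairs co-vary) is the
    same at different centers, independent of each center's mean offsets.
    The mean-profile rule saturates when all centers share the same heads
    and similar inputs; the geometry rule remains discriminative there.
    """
    if len(tables) < 2:
        raise ValueError("need at least two centers")
    d = {t.matrix.shape[1] for t in tables}
    if len(d) != 1:
        raise ValueError("feature dimension differs between centers")
    if method == "mean_profile":
        profiles = [t.matrix.mean(axis=0) for t in tables]
    elif method == "geometry":
        iu = np.triu_indices(d.pop(), k=1)
        profiles = []
        for t in tables:
            with np.errstate(invalid="ignore", divide="ignore"):
                R = np.corrcoef(t.matrix, rowvar=False)
            profiles.append(np.nan_to_num(np.asarray(R)[iu], nan=0.0))
    else:
        raise ValueError("method must be 'mean_profile' or 'geometry'")
    C = len(tables)
    R = np.full((C, C), np.nan)
    P = np.full((C, C), np.nan)
    rs, ps = [], []
    for i in range(C):
        for j in range(i + 1, C):
            r, p = _pearson_with_p(profiles[i], profiles[j])
            R[i, j] = R[j, i] = r
            P[i, j] = P[j, i] = p
            rs.append(r)
            ps.append(p)
    rs, ps = np.array(rs), np.array(ps)
    ok = np.isfinite(rs)
    return CrossCenterSummary(
        mean_corr=float(np.nanmean(rs)) if ok.any() else np.nan,
        std_corr=float(np.nanstd(rs)) if ok.any() else np.nan,
        frac_significant=float((ps[ok] < alpha).mean()) if ok.any() else np.nan,
        pair_matrix=R, pair_pvalues=P)


def group_corr_test(corrs_a, corrs_b) -> tuple[float, float, float]:
    """Compare two samples of correlations: Welch t on Fisher-z transformed
    values (variance-stabilized) and Cohen's d on the raw scale (pooled SD)."""
    a = np.asarray(corrs_a, dtype=np.float64)
    b = np.asarray(corrs_b, dtype=np.float64)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both samples need size >= 2")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if np.allclose(a.mean(), b.mean()):
            return 0.0, 1.0, 0.0
        raise ValueError("degenerate (zero-variance) samples differ in mean")
    za = np.arctanh(np.clip(a, -1 + 1e-12, 1 - 1e-12))
    zb = np.arctanh(np.clip(b, -1 + 1e-12, 1 - 1e-12))
    t, p = stats.ttest_ind(za, zb, equal_var=False)
    na, nb = len(a), len(b)
    pooled = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1))
                     / (na + nb - 2))
    d = (a.mean() - b.mean()) / pooled if pooled > 0 else 0.0
    return float(t), float(p), float(d)


def embed_2d(X: np.ndarray, perplexity: float = 30.0, seed: int = 0) -> np.ndarray:
    """Seeded t-SNE embedding to 2-D; requires n > 3 * perplexity."""
    X = np.asarray(X, dtype=np.float64)
    if X.shape[0] <= 3 * perplexity:
        raise ValueError("need n > 3 * perplexity samples")
    emb = TSNE(n_components=2, perplexity=perplexity, random_state=seed,
               init="pca").fit_transform(X)
    if not np.isfinite(emb).all():
        raise RuntimeError("embedding produced non-finite coordinates")
    return np.asarray(emb, dtype=np.float64)


def clustering_indices(X: np.ndarray, labels) -> tuple[float, float, float]:
    """(silhouette, Calinski-Harabasz, Davies-Bouldin), Euclidean.

    Degenerate 0/0 silhouette contributions (identical points, singleton
    clusters) count as 0 by convention.
    """
    X = np.asarray(X, dtype=np.float64)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need at least 2 clusters")
    if len(X) < 3:
        raise ValueError("silhouette requires at least 3 points")
    with np.errstate(invalid="ignore", divide="ignore"):
        sil_samples = _skm.silhouette_samples(X, labels)
        sil = float(np.nan_to_num(sil_samples, nan=0.0).mean())
        try:
            ch = float(_skm.calinski_harabasz_score(X, labels))
        except (ZeroDivisionError, FloatingPointError):
            ch = np.inf
        if not np.isfinite(ch):
            ch = np.inf
        db = float(_skm.davies_bouldin_score(X, labels))
    return sil, ch, db
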