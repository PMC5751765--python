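"""Feature filtering: fold a d-dimensional sample into an m x m feature matrix.

The filter runs in five stages:

1. temporary class labels from agglomerative hierarchical clustering
   (Ward linkage on Euclidean distances by default);
2. per-feature one-way ANOVA p-values against the temporary labels;
3. keep the m^2 features with the smallest p-values, where h is the number
   of features with p < cutoff and m = floor(sqrt(h));
4. order the kept features by ascending across-sample mean, so every sample
   shares one common layout;
5. reshape each sample's ordered m^2 values row-major into an m x m matrix.

The fitted :class:`FilterModel` records everything needed to fold unseen
samples identically (selected feature IDs in p-value rank order, the
mean-ascending permutation, and the training means), and serializes to JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from scipy.stats import f as f_dist

from .data_io import ExpressionMatrix, LabelVector

__all__ = [
    "FilterModel",
    "FeatureMatrixSet",
    "temp_labels",
    "anova_pvalues",
    "select_features",
    "compute_fold_order",
    "fold_samples",
    "fit_filter",
]

LINKAGES = ("ward", "single", "complete", "average", "weighted", "centroid", "median")


@dataclass(frozen=True)
class FeatureMatrixSet:
    """The n folded samples, each an m x q real matrix (q = m in the filter)."""

    matrices: np.ndarray  # shape (n, m, q)
    sample_ids: list[str]

    def __post_init__(self) -> None:
        mats = np.asarray(self.matrices, dtype=float)
        object.__setattr__(self, "matrices", mats)
        if mats.ndim != 3:
            raise ValueError("matrices must have shape (n, m, q)")
        if not np.isfinite(mats).all():
            raise ValueError("feature matrices contain non-finite values")
        if len(self.sample_ids) != mats.shape[0]:
            raise ValueError("sample_ids length does not match number of matrices")

    @property
    def n(self) -> int:
        return self.matrices.shape[0]

    @property
    def m(self) -> int:
        return self.matrices.shape[1]

    @property
    def q(self) -> int:
        return self.matrices.shape[2]


@dataclass(frozen=True)
class FilterModel:
    """Learned filtering state sufficient to fold any sample reproducibly."""

    pvalues: np.ndarray            # length d, in [0, 1]
    cutoff: float
    h: int                         # count of features with p < cutoff
    m: int                         # floor(sqrt(h)), >= 2
    selected_idx: np.ndarray       # m^2 indices into original features, ascending p
    order_idx: np.ndarray          # permutation of {0,...,m^2-1}, mean-ascending
    mean_selected: np.ndarray      # per-feature training mean on selected features
    selected_ids: list[str] = field(default_factory=list)
    linkage_method: str = "ward"

    def fold(self, E: ExpressionMatrix) -> FeatureMatrixSet:
        """Fold samples of ``E`` using the stored selection and ordering.

        Features are matched by ID, so column order in ``E`` is irrelevant.
        """
        if not self.selected_ids:
            raise ValueError("FilterModel has no stored feature IDs; cannot fold by ID")
        pos = {fid: j for j, fid in enumerate(E.feature_ids)}
        missing = [fid for fid in self.selected_ids if fid not in pos]
        if missing:
            raise ValueError(f"matrix lacks {len(missing)} selected features, e.g. {missing[:5]}")
        cols = [pos[fid] for fid in self.selected_ids]
        return fold_samples(E.values[:, cols], self.order_idx, self.m, sample_ids=E.sample_ids)

    def to_json(self, path) -> None:
        payload = {
            "cutoff": self.cutoff,
            "h": self.h,
            "m": self.m,
            "linkage": self.linkage_method,
            "selected_ids": list(self.selected_ids),
            "selected_idx": [int(i) for i in self.selected_idx],
            "order_idx": [int(i) for i in self.order_idx],
            "mean_selected": [float(x) for x in self.mean_selected],
            "pvalues_selected": [float(self.pvalues[i]) for i in self.selected_idx],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "FilterModel":
        with open(path) as fh:
            p = json.load(fh)
        d = max(p["selected_idx"]) + 1 if p["selected_idx"] else 0
        pv = np.ones(d)
        pv[np.asarray(p["selected_idx"], dtype=int)] = p["pvalues_selected"]
        return cls(
            pvalues=pv,
            cutoff=float(p["cutoff"]),
            h=int(p["h"]),
            m=int(p["m"]),
            selected_idx=np.asarray(p["selected_idx"], dtype=int),
            order_idx=np.asarray(p["order_idx"], dtype=int),
            mean_selected=np.asarray(p["mean_selected"], dtype=float),
            selected_ids=list(p["selected_ids"]),
            linkage_method=p.get("linkage", "ward"),
        )


def temp_labels(E: ExpressionMatrix, c: int, linkage_method: str = "ward") -> LabelVector:
    """Provisional hard clustering of all samples into c groups.

    Agglomerative hierarchical clustering on Euclidean distances over all d
    features; deterministic given the data.  The labels exist only to supply
    groups for the ANOVA filter, not as a clustering result.
    """
    if c < 1:
        raise ValueError("c must be >= 1")
    if c > E.n:
        raise ValueError(f"cannot form c={c} clusters from n={E.n} samples")
    if linkage_method not in LINKAGES:
        raise ValueError(f"unknown linkage {linkage_method!r}; choose from {LINKAGES}")
    if c == E.n:
        return LabelVector(np.arange(E.n), c, sample_ids=list(E.sample_ids))
    Z = linkage(pdist(E.values, metric="euclidean"), method=linkage_method)
    raw = fcluster(Z, t=c, criterion="maxclust")
    # relabel to 0..c-1 in order of first appearance (deterministic)
    remap: dict[int, int] = {}
    out = np.empty(E.n, dtype=int)
    for i, r in enumerate(raw):
        if r not in remap:
            remap[r] = len(remap)
        out[i] = remap[r]
    return LabelVector(out, c, sample_ids=list(E.sample_ids))


def anova_pvalues(E: ExpressionMatrix, lv: LabelVector) -> np.ndarray:
    """One-way ANOVA F-test p-value per feature for group mean differences.

    Vectorized across all d features from group sums of squares.  Degenerate
    features are resolved by the limits of the F statistic: p = 1 when both
    between- and within-group variation vanish, p = 0 when group means differ
    with zero within-group variation.
    """
    X = E.values
    labels = np.asarray(lv.labels)
    if labels.size != E.n:
        raise ValueError("label vector length does not match matrix")
    groups = np.unique(labels)
    if groups.size < 2:
        raise ValueError("need at least 2 non-empty groups for ANOVA")
    n, _ = X.shape
    g = groups.size

    grand = X.mean(axis=0)
    ss_between = np.zeros(X.shape[1])
    ss_within = np.zeros(X.shape[1])
    for grp in groups:
        sub = X[labels == grp]
        mu = sub.mean(axis=0)
        ss_between += sub.shape[0] * (mu - grand) ** 2
        ss_within += ((sub - mu) ** 2).sum(axis=0)

    df1, df2 = g - 1, n - g
    if df2 < 1:
        raise ValueError("within-group degrees of freedom < 1; need n > number of groups")
    # scale-aware tolerance for "zero" sums of squares
    total = ss_between + ss_within
    tiny = np.finfo(float).eps * np.maximum(total, 1.0) * n
    p = np.empty(X.shape[1])
    zero_w = ss_within <= tiny
    zero_b = ss_between <= tiny
    regular = ~zero_w
    with np.errstate(invalid="ignore", divide="ignore"):
        F = (ss_between[regular] / df1) / (ss_within[regular] / df2)
    p[regular] = f_dist.sf(F, df1, df2)
    p[zero_w & zero_b] = 1.0          # flat feature: no evidence either way
    p[zero_w & ~zero_b] = 0.0         # perfect group indicator: infinite F
    return np.clip(p, 0.0, 1.0)


def select_features(pvalues: np.ndarray, cutoff: float) -> tuple[int, int, np.ndarray]:
    """Pick the m^2 smallest-p features given a p-value cutoff.

    ``h`` counts features with p strictly below the cutoff and sets
    m = floor(sqrt(h)); the h - m^2 kept-but-excess features with the largest
    retained p-values are discarded.  Ties are broken by original feature
    index (stable sort), so selection is reproducible.
    """
    p = np.asarray(pvalues, dtype=float)
    if not (0.0 < cutoff < 1.0):
        raise ValueError(f"cutoff must lie in (0, 1), got {cutoff}")
    h = int((p < cutoff).sum())
    m = int(np.floor(np.sqrt(h)))
    if m < 2:
        raise ValueError(
            f"only h={h} features pass the cutoff {cutoff} (need >= 4 for an "
            f"m >= 2 feature matrix); try a larger cutoff"
        )
    selected = np.argsort(p, kind="stable")[: m * m]
    return h, m, selected


def compute_fold_order(E_selected: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean-ascending arrangement shared by all samples.

    ``E_selected`` is the n x m^2 matrix restricted to the selected features
    in p-value rank order.  Returns the permutation that sorts the per-feature
    across-sample means ascending (stable on ties) together with those means.
    """
    E_selected = np.asarray(E_selected, dtype=float)
    mean_selected = E_selected.mean(axis=0)
    order_idx = np.argsort(mean_selected, kind="stable")
    return order_idx, mean_selected


def fold_samples(
    E_selected: np.ndarray,
    order_idx: np.ndarray,
    m: int,
    q: int | None = None,
    sample_ids: list[str] | None = None,
) -> FeatureMatrixSet:
    """Permute each sample's selected values by ``order_idx`` and reshape.

    The reshape is row-major and bijective: unfolding a feature matrix
    recovers the ordered vector exactly.
    """
    E_selected = np.asarray(E_selected, dtype=float)
    q = m if q is None else q
    n, k = E_selected.shape
    if k != m * q:
        raise ValueError(f"expected {m * q} selected features per sample, got {k}")
    order_idx = np.asarray(order_idx, dtype=int)
    if sorted(order_idx.tolist()) != list(range(k)):
        raise ValueError("order_idx is not a permutation of the selected features")
    mats = E_selected[:, order_idx].reshape(n, m, q)
    if sample_ids is None:
        sample_ids = [f"S{i}" for i in range(n)]
    return FeatureMatrixSet(mats, list(sample_ids))


def unfold(X: np.ndarray) -> np.ndarray:
    """Inverse of the row-major reshape: matrix back to the ordered vector."""
    return np.asarray(X, dtype=float).reshape(-1)


def fit_filter(
    E: ExpressionMatrix,
    c: int,
    cutoff: float = 0.01,
    linkage_method: str = "ward",
) -> tuple[FilterModel, FeatureMatrixSet]:
    """Run the full filter and fold every sample of ``E``.

    Composes temporary labels -> ANOVA p-values -> top-m^2 selection ->
    mean-ascending ordering -> row-major reshape.  The default cutoff is
    0.01.
    """
    lv = temp_labels(E, c, linkage_method=linkage_method)
    p = anova_pvalues(E, lv)
    h, m, selected = select_features(p, cutoff)
    E_sel = E.values[:, selected]
    order_idx, mean_selected = compute_fold_order(E_sel)
    fms = fold_samples(E_sel, order_idx, m, sample_ids=list(E.sample_ids))
    model = FilterModel(
        pvalues=p,
        cutoff=float(cutoff),
        h=h,
        m=m,
        selected_idx=selected,
        order_idx=order_idx,
        mean_selected=mean_selected,
        selected_ids=[E.feature_ids[i] for i in selected],
        linkage_method=linkage_method,
    )
    return model, fms
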