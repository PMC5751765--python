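"""Seeded generators emulating the small-sample, high-dimensional regime.

Two samplers:

* :func:`simulate_vector_mixture` produces an n x d expression-style table
  with d >> n, where only a small block of features carries cluster signal
  and the rest is Gaussian noise — the regime of phenotype clustering on
  transcriptome/methylome matrices (tens to hundreds of samples, thousands
  to tens of thousands of features).
* :func:`simulate_matrix_mixture` draws feature matrices directly from a
  matrix-normal mixture with per-cluster row covariance and identity column
  covariance, for exercising the matrix-valued EM without a filtering step.

Both are pure functions of their spec (seed included): the same spec always
yields bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import ExpressionMatrix, LabelVector
from .filtering import FeatureMatrixSet

__all__ = [
    "VectorMixtureSpec",
    "MatrixMixtureSpec",
    "simulate_vector_mixture",
    "simulate_matrix_mixture",
]


@dataclass(frozen=True)
class VectorMixtureSpec:
    """Cluster sizes, dimensionality and signal strength for vector data.

    ``effect`` is the between-cluster mean spacing on informative features in
    units of the within-cluster standard deviation ``noise_sd``: cluster i's
    mean on an informative feature is i * effect * noise_sd, with a random
    per-feature sign so clusters differ in many directions.  Cluster sizes
    may be unbalanced.
    """

    n_per_cluster: tuple[int, ...]
    d: int
    n_informative: int
    effect: float
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "n_per_cluster", tuple(int(x) for x in self.n_per_cluster))
        if any(x < 1 for x in self.n_per_cluster):
            raise ValueError("every cluster needs at least one sample")
        if not (self.d >= self.n_informative >= 0):
            raise ValueError("need d >= n_informative >= 0")
        if self.effect < 0 or self.noise_sd <= 0:
            raise ValueError("effect must be >= 0 and noise_sd > 0")


@dataclass(frozen=True)
class MatrixMixtureSpec:
    """Direct matrix-normal mixture: per-cluster mean matrix and row covariance."""

    n_per_cluster: tuple[int, ...]
    means: tuple[np.ndarray, ...]        # each (m, q)
    covariances: tuple[np.ndarray, ...]  # each (m, m), symmetric PD
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "n_per_cluster", tuple(int(x) for x in self.n_per_cluster))
        means = tuple(np.asarray(M, dtype=float) for M in self.means)
        covs = tuple(np.asarray(C, dtype=float) for C in self.covariances)
        object.__setattr__(self, "means", means)
        object.__setattr__(self, "covariances", covs)
        if not (len(self.n_per_cluster) == len(means) == len(covs)):
            raise ValueError("n_per_cluster, means and covariances must align")
        m, q = means[0].shape
        for M, C in zip(means, covs):
            if M.shape != (m, q):
                raise ValueError("all mean matrices must share shape")
            if C.shape != (m, m) or not np.allclose(C, C.T, atol=1e-10):
                raise ValueError("each covariance must be symmetric m x m")
            if np.linalg.eigvalsh(C).min() <= 0:
                raise ValueError("covariances must be positive definite")

    @property
    def m(self) -> int:
        return self.means[0].shape[0]

    @property
    def q(self) -> int:
        return self.means[0].shape[1]


def simulate_vector_mixture(spec: VectorMixtureSpec) -> tuple[ExpressionMatrix, LabelVector, np.ndarray]:
    """Draw an expression matrix with a known informative-feature block.

    Returns the matrix, the ground-truth labels and the indices of the
    informative features (scattered uniformly over the d columns).
    """
    rng = np.random.default_rng(spec.seed)
    c = len(spec.n_per_cluster)
    n = sum(spec.n_per_cluster)
    labels = np.repeat(np.arange(c), spec.n_per_cluster)

    X = rng.normal(0.0, spec.noise_sd, size=(n, spec.d))
    informative = np.sort(rng.choice(spec.d, size=spec.n_informative, replace=False))
    signs = rng.choice([-1.0, 1.0], size=spec.n_informative)
    # cluster i sits at i * effect * noise_sd along each informative feature
    shift = np.outer(labels.astype(float), signs) * spec.effect * spec.noise_sd
    X[:, informative] += shift

    sample_ids = [f"S{i:04d}" for i in range(n)]
    feature_ids = [f"F{j:05d}" for j in range(spec.d)]
    E = ExpressionMatrix(X, sample_ids, feature_ids)
    lv = LabelVector(labels, c, sample_ids=sample_ids)
    return E, lv, informative


def simulate_matrix_mixture(spec: MatrixMixtureSpec) -> tuple[FeatureMatrixSet, LabelVector]:
    """Draw feature matrices X = M_z + A_z Z with A_z A_z^T = C_z.

    Z has independent standard normal entries, so each component is matrix
    normal with row covariance C_z and identity column covariance.
    """
    rng = np.random.default_rng(spec.seed)
    c = len(spec.n_per_cluster)
    n = sum(spec.n_per_cluster)
    m, q = spec.m, spec.q
    labels = np.repeat(np.arange(c), spec.n_per_cluster)

    mats = np.empty((n, m, q))
    start = 0
    for i, ni in enumerate(spec.n_per_cluster):
        A = np.linalg.cholesky(spec.covariances[i])
        Z = rng.standard_normal(size=(ni, m, q))
        mats[start : start + ni] = spec.means[i] + np.einsum("ij,kjl->kil", A, Z)
        start += ni

    sample_ids = [f"S{i:04d}" for i in range(n)]
    fms = FeatureMatrixSet(mats, sample_ids)
    lv = LabelVector(labels, c, sample_ids=sample_ids)
    return fms, lv


def random_mixture_spec(
    c: int,
    seed: int = 0,
    m: int = 5,
    q: int | None = None,
    n_total: int = 100,
    mean_scale: float = 3.0,
) -> MatrixMixtureSpec:
    """c-component matrix-normal spec with seeded means and random PD covariances.

    Component means are i.i.d. N(0, mean_scale^2) entrywise and covariances
    are identity plus a small random Wishart-like part, giving well-separated
    but non-trivial components.  Mean/covariance draws and data noise use
    separate streams derived from the one seed.
    """
    q = m if q is None else q
    mean_seed, data_seed = np.random.SeedSequence(seed).generate_state(2) % (2**31 - 1)
    rng = np.random.default_rng(int(mean_seed))
    means = tuple(mean_scale * rng.standard_normal((m, q)) for _ in range(c))
    covs = []
    for _ in range(c):
        A = rng.standard_normal((m, m)) * 0.3
        covs.append(A @ A.T + np.eye(m))
    base = n_total // c
    sizes = [base] * c
    sizes[0] += n_total - base * c
    return MatrixMixtureSpec(
        n_per_cluster=tuple(sizes), means=means, covariances=tuple(covs), seed=int(data_seed)
    )


def two_cluster_matrix_spec(
    n_per_cluster: tuple[int, int] = (50, 50),
    m: int = 5,
    q: int | None = None,
    separation: float = 4.0,
    seed: int = 0,
) -> MatrixMixtureSpec:
    """Convenience two-component spec with a given Mahalanobis mean separation.

    Both components use identity row covariance; the mean difference Delta
    satisfies sqrt(trace(Delta^T C^{-1} Delta)) = separation, spread over all
    entries with a seeded random direction.
    """
    q = m if q is None else q
    # separate streams for the mean direction and the noise draws, so the
    # direction is never replayed as a data point
    dir_seed, data_seed = np.random.SeedSequence(seed).generate_state(2) % (2**31 - 1)
    direction = np.random.default_rng(int(dir_seed)).standard_normal(size=(m, q))
    direction *= separation / np.linalg.norm(direction)
    M0 = np.zeros((m, q))
    C = np.eye(m)
    return MatrixMixtureSpec(
        n_per_cluster=tuple(n_per_cluster),
        means=(M0, direction),
        covariances=(C, C.copy()),
        seed=int(data_seed),
    )
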