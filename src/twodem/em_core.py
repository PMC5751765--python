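"""EM clustering for matrix-valued Gaussian mixtures, plus the classical
vector-space EM used as a reference.

The observation unit is a feature matrix X in R^{m x q} with per-cluster mean
M_i (m x q) and a single row covariance C_i (m x m); the column covariance is
implicitly the identity.  The class-conditional quadratic form is

    -1/2 * trace((X - M_i)^T C_i^{-1} (X - M_i))

in both density modes.  They differ only in the C-dependent normalizer:

* ``paper_literal`` uses -1/2 * log|C| — the form the method's responsibility
  ratio is written in.  Constant (2*pi) factors cancel in responsibilities,
  so cluster assignments are identical across modes; the reported
  log-likelihood is only a proper density in the exact mode.
* ``matrix_normal_exact`` uses -(q/2) * log|C| - (m*q/2) * log(2*pi), the
  exact matrix-normal density with identity column covariance, equal to a
  d = m*q multivariate Gaussian with covariance I_q (x) C (Kronecker).

All density arithmetic is in log space with log-sum-exp normalization.
Covariances are symmetrized and ridge-regularized after every M-step so that
a Cholesky factorization always exists.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from sklearn.cluster import KMeans

from .data_io import ExpressionMatrix, LabelVector
from .filtering import FeatureMatrixSet, FilterModel

__all__ = [
    "MixtureModel2D",
    "MixtureModel1D",
    "Responsibilities",
    "FitResult",
    "log_matrix_density",
    "e_step_2d",
    "m_step_2d",
    "log_likelihood_2d",
    "fit_2dem",
    "fit_em_1d",
    "predict",
]

MODES = ("paper_literal", "matrix_normal_exact")
_LOG_2PI = float(np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# model containers


@dataclass(frozen=True)
class MixtureModel2D:
    """Mixture of c matrix-valued Gaussian components.

    priors: (c,) mixing weights pi_i, nonnegative, summing to 1.
    means: (c, m, q) mean matrices M_i.
    covariances: (c, m, m) row covariances C_i, symmetric positive definite.
    """

    c: int
    priors: np.ndarray
    means: np.ndarray
    covariances: np.ndarray
    mode: str = "paper_literal"

    def __post_init__(self) -> None:
        pri = np.asarray(self.priors, dtype=float)
        means = np.asarray(self.means, dtype=float)
        covs = np.asarray(self.covariances, dtype=float)
        object.__setattr__(self, "priors", pri)
        object.__setattr__(self, "means", means)
        object.__setattr__(self, "covariances", covs)
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if pri.shape != (self.c,) or (pri < 0).any():
            raise ValueError("priors must be a nonnegative vector of length c")
        if abs(pri.sum() - 1.0) > 1e-12:
            raise ValueError("priors must sum to 1")
        if means.shape[0] != self.c or covs.shape[0] != self.c:
            raise ValueError("means/covariances first axis must equal c")
        m = means.shape[1]
        if covs.shape[1:] != (m, m):
            raise ValueError("each covariance must be m x m")
        if not np.allclose(covs, np.swapaxes(covs, 1, 2), atol=1e-10):
            raise ValueError("covariances must be symmetric")

    @property
    def m(self) -> int:
        return self.means.shape[1]

    @property
    def q(self) -> int:
        return self.means.shape[2]

    def to_json_dict(self) -> dict:
        return {
            "c": self.c,
            "mode": self.mode,
            "priors": self.priors.tolist(),
            "means": self.means.tolist(),
            "covariances": self.covariances.tolist(),
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "MixtureModel2D":
        return cls(
            c=int(d["c"]),
            priors=np.asarray(d["priors"], dtype=float),
            means=np.asarray(d["means"], dtype=float),
            covariances=np.asarray(d["covariances"], dtype=float),
            mode=d.get("mode", "paper_literal"),
        )


@dataclass(frozen=True)
class MixtureModel1D:
    """Classical Gaussian mixture: vector means mu_i and full covariances Sigma_i."""

    c: int
    priors: np.ndarray
    means: np.ndarray        # (c, d)
    covariances: np.ndarray  # (c, d, d)

    def __post_init__(self) -> None:
        object.__setattr__(self, "priors", np.asarray(self.priors, dtype=float))
        object.__setattr__(self, "means", np.asarray(self.means, dtype=float))
        object.__setattr__(self, "covariances", np.asarray(self.covariances, dtype=float))


@dataclass(frozen=True)
class Responsibilities:
    """Posterior cluster membership phi_ik, one row per sample, rows sum to 1."""

    values: np.ndarray  # (n, c)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2:
            raise ValueError("responsibilities must be 2-D (n x c)")
        if (v < -1e-12).any() or (v > 1 + 1e-12).any():
            raise ValueError("responsibilities must lie in [0, 1]")
        if not np.allclose(v.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("responsibility rows must sum to 1")


@dataclass(frozen=True)
class FitResult:
    labels: LabelVector
    responsibilities: Responsibilities
    model: MixtureModel2D | MixtureModel1D
    loglik_trace: np.ndarray
    n_iter: int
    converged: bool
    seed: int
    restart_logliks: list[float] = field(default_factory=list)
    restart_labels: list[np.ndarray] = field(default_factory=list)
    param_trace: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# densities


def _chol(C: np.ndarray):
    """Cholesky factor of C; raises LinAlgError if not positive definite."""
    return cho_factor(C, lower=True, check_finite=False)


def log_matrix_density(X, M, C, mode: str = "paper_literal") -> float:
    """Log class-conditional density of one feature matrix.

    Both modes share the trace-form quadratic; ``matrix_normal_exact`` adds
    the full matrix-normal normalizer while ``paper_literal`` keeps only the
    -1/2 log|C| term.
    """
    X = np.asarray(X, dtype=float)
    M = np.asarray(M, dtype=float)
    C = np.asarray(C, dtype=float)
    if X.shape != M.shape:
        raise ValueError("X and M must share shape")
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    m, q = X.shape
    cf = _chol(C)
    logdet = 2.0 * np.log(np.diag(cf[0])).sum()
    R = X - M
    quad = float(np.sum(R * cho_solve(cf, R, check_finite=False)))
    if mode == "paper_literal":
        return -0.5 * logdet - 0.5 * quad
    return -0.5 * q * logdet - 0.5 * m * q * _LOG_2PI - 0.5 * quad


def _log_densities(data: FeatureMatrixSet, model: MixtureModel2D) -> np.ndarray:
    """(n, c) matrix of log p(X_k | cluster i), vectorized over samples."""
    Xs = data.matrices
    n = Xs.shape[0]
    m, q = model.m, model.q
    out = np.empty((n, model.c))
    for i in range(model.c):
        cf = _chol(model.covariances[i])
        logdet = 2.0 * np.log(np.diag(cf[0])).sum()
        R = Xs - model.means[i]  # (n, m, q)
        # stack all samples' columns so one triangular solve covers them all
        B = R.transpose(1, 0, 2).reshape(m, n * q)
        sol = cho_solve(cf, B, check_finite=False).reshape(m, n, q).transpose(1, 0, 2)
        quad = np.einsum("kij,kij->k", R, sol)
        if model.mode == "paper_literal":
            out[:, i] = -0.5 * logdet - 0.5 * quad
        else:
            out[:, i] = -0.5 * q * logdet - 0.5 * m * q * _LOG_2PI - 0.5 * quad
    return out


def e_step_2d(data: FeatureMatrixSet, model: MixtureModel2D) -> Responsibilities:
    """Responsibilities phi_ik ∝ pi_i * p(X_k | cluster i), log-sum-exp normalized."""
    logd = _log_densities(data, model)
    with np.errstate(divide="ignore"):
        logpi = np.log(model.priors)
    lw = logd + logpi  # -inf where prior is 0
    mx = lw.max(axis=1, keepdims=True)
    if not np.isfinite(mx).all():
        raise FloatingPointError("a sample has zero density under every cluster")
    w = np.exp(lw - mx)
    phi = w / w.sum(axis=1, keepdims=True)
    return Responsibilities(phi)


def log_likelihood_2d(data: FeatureMatrixSet, model: MixtureModel2D) -> float:
    """Total mixture log-likelihood L = sum_k log sum_i pi_i p(X_k | i)."""
    logd = _log_densities(data, model)
    with np.errstate(divide="ignore"):
        lw = logd + np.log(model.priors)
    mx = lw.max(axis=1, keepdims=True)
    return float((mx.ravel() + np.log(np.exp(lw - mx).sum(axis=1))).sum())


# ---------------------------------------------------------------------------
# M-step and regularization


def regularize_covariance(C: np.ndarray, reg: float = 1e-6) -> np.ndarray:
    """Symmetrize and ridge a covariance until its Cholesky succeeds.

    The ridge is reg * trace(C)/m * I (absolute reg * I when the scatter is
    identically zero); if the factorization still fails the ridge escalates
    tenfold up to 1e-2 before giving up.
    """
    C = np.asarray(C, dtype=float)
    C = 0.5 * (C + C.T)
    m = C.shape[0]
    tr = float(np.trace(C))
    scale = tr / m if tr > 0 else 1.0
    lam = reg
    while lam <= 1e-2:
        Creg = C + lam * scale * np.eye(m)
        try:
            _chol(Creg)
            return Creg
        except np.linalg.LinAlgError:
            lam *= 10.0
    raise np.linalg.LinAlgError("covariance not positive definite even after maximal ridge")


def m_step_2d(
    data: FeatureMatrixSet,
    resp: Responsibilities,
    reg: float = 1e-6,
    mode: str = "paper_literal",
) -> MixtureModel2D:
    """Weighted-moment updates: pi_i, M_i, and row covariance C_i.

    C_i averages the row-scatter (X_k - M_i)(X_k - M_i)^T under the
    responsibilities, then is regularized to positive definiteness.  The
    scatter normalizer is mode-specific so that each mode's M-step maximizes
    its own objective (keeping EM monotone): ``paper_literal`` divides by the
    responsibility mass alone, while ``matrix_normal_exact`` divides by
    mass * q — the maximum-likelihood row covariance when the density carries
    the full |C|^(-q/2) normalizer.  The two coincide at q = 1.  Clusters
    with responsibility mass below 1e-8 * n are reseeded at the sample with
    the lowest maximum responsibility, with the global average covariance.
    """
    phi = resp.values
    Xs = data.matrices
    n, m, q = Xs.shape
    c = phi.shape[1]
    cov_div = float(q) if mode == "matrix_normal_exact" else 1.0
    mass = phi.sum(axis=0)

    degenerate = mass < 1e-8 * n
    priors = mass / n
    means = np.empty((c, m, q))
    covs = np.empty((c, m, m))
    for i in range(c):
        if degenerate[i]:
            continue
        w = phi[:, i]
        means[i] = np.tensordot(w, Xs, axes=(0, 0)) / mass[i]
        R = Xs - means[i]
        covs[i] = np.einsum("k,kij,klj->il", w, R, R) / (mass[i] * cov_div)
        covs[i] = regularize_covariance(covs[i], reg)

    if degenerate.any():
        ok = ~degenerate
        avg_cov = covs[ok].mean(axis=0)
        # least-claimed sample: the one no cluster is confident about
        worst = int(np.argmin(phi.max(axis=1)))
        for i in np.where(degenerate)[0]:
            means[i] = Xs[worst]
            covs[i] = regularize_covariance(avg_cov, reg)
            priors[i] = 1.0 / n
        priors = priors / priors.sum()

    return MixtureModel2D(c=c, priors=priors, means=means, covariances=covs, mode=mode)


# ---------------------------------------------------------------------------
# fitting


def _derive_seeds(seed: int, k: int) -> np.ndarray:
    """k deterministic per-restart seeds below 2**31 from one master seed."""
    return np.random.SeedSequence(seed).generate_state(k) % (2**31 - 1)


def _init_responsibilities(flat: np.ndarray, c: int, init: str, seed: int) -> np.ndarray:
    """One-hot initial responsibilities on the vectorized observations.

    ``kmeans`` (default) runs a seeded Lloyd pass with greedy k-means++
    (furthest-point flavored) seeding; ``random`` assigns labels uniformly
    while guaranteeing every cluster at least one sample.
    """
    n = flat.shape[0]
    if init == "kmeans":
        km = KMeans(n_clusters=c, n_init=1, random_state=int(seed)).fit(flat)
        assign = km.labels_.astype(int)
    elif init == "random":
        rng = np.random.default_rng(int(seed))
        assign = rng.integers(0, c, size=n)
        # guarantee non-empty clusters
        forced = rng.choice(n, size=c, replace=False)
        assign[forced] = np.arange(c)
    else:
        raise ValueError(f"unknown init {init!r}")
    onehot = np.zeros((n, c))
    onehot[np.arange(n), assign] = 1.0
    # an initially empty cluster (possible with duplicate points) gets a
    # uniform sliver so the first M-step can rescue it
    empty = onehot.sum(axis=0) == 0
    if empty.any():
        onehot[:, empty] = 1e-6
        onehot /= onehot.sum(axis=1, keepdims=True)
    return onehot


def _em_single_run(
    data: FeatureMatrixSet,
    c: int,
    seed: int,
    init: str,
    tol: float,
    max_iter: int,
    reg: float,
    mode: str,
    record_params: bool,
):
    n = data.n
    flat = data.matrices.reshape(n, -1)
    phi0 = _init_responsibilities(flat, c, init, seed)
    model = m_step_2d(data, Responsibilities(phi0), reg=reg, mode=mode)

    trace: list[float] = []
    params: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
    converged = False
    resp = None
    it = 0
    for it in range(1, max_iter + 1):
        resp = e_step_2d(data, model)
        L = log_likelihood_2d(data, model)
        trace.append(L)
        if record_params:
            params.append((model.priors.copy(), model.means.copy(), model.covariances.copy()))
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol * max(abs(trace[-2]), 1.0):
            converged = True
            break
        model = m_step_2d(data, resp, reg=reg, mode=mode)
    return model, resp, np.asarray(trace), it, converged, params


def fit_2dem(
    data: FeatureMatrixSet,
    c: int,
    *,
    init: str = "kmeans",
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
    n_restarts: int = 10,
    reg: float = 1e-6,
    mode: str = "paper_literal",
    record_params: bool = False,
) -> FitResult:
    """Fit the matrix-valued Gaussian mixture by EM with seeded restarts.

    Each restart alternates E and M steps from its own seeded initialization
    until the relative log-likelihood change drops below ``tol`` or
    ``max_iter`` is reached.  The run with the highest final log-likelihood
    supplies the returned labels and model; per-restart final log-likelihoods
    and label vectors are kept so score-averaging protocols over repetitions
    remain possible.
    """
    if c < 1:
        raise ValueError("c must be >= 1")
    if c > data.n:
        raise ValueError(f"cannot fit c={c} clusters to n={data.n} samples")
    seeds = _derive_seeds(seed, n_restarts)
    best = None
    restart_lls: list[float] = []
    restart_labs: list[np.ndarray] = []
    for rs in seeds:
        model, resp, trace, it, conv, params = _em_single_run(
            data, c, int(rs), init, tol, max_iter, reg, mode, record_params
        )
        labs = np.argmax(resp.values, axis=1)
        restart_lls.append(float(trace[-1]))
        restart_labs.append(labs)
        if best is None or trace[-1] > best[2][-1]:
            best = (model, resp, trace, it, conv, params)
    model, resp, trace, it, conv, params = best
    labels = LabelVector(np.argmax(resp.values, axis=1), c, sample_ids=list(data.sample_ids))
    return FitResult(
        labels=labels,
        responsibilities=resp,
        model=model,
        loglik_trace=trace,
        n_iter=it,
        converged=conv,
        seed=seed,
        restart_logliks=restart_lls,
        restart_labels=restart_labs,
        param_trace=params,
    )


# ---------------------------------------------------------------------------
# classical vector-space EM (reference implementation)


def _gauss_logpdf(X: np.ndarray, mu: np.ndarray, Sigma: np.ndarray) -> np.ndarray:
    """Multivariate normal log-density for each row of X."""
    d = X.shape[1]
    cf = _chol(Sigma)
    logdet = 2.0 * np.log(np.diag(cf[0])).sum()
    R = X - mu
    sol = cho_solve(cf, R.T, check_finite=False)
    quad = np.einsum("kd,dk->k", R, sol)
    return -0.5 * (logdet + d * _LOG_2PI + quad)


def fit_em_1d(
    data: np.ndarray,
    c: int,
    *,
    init: str = "kmeans",
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
    n_restarts: int = 10,
    reg: float = 1e-6,
    record_params: bool = False,
) -> FitResult:
    """Classical full-covariance Gaussian-mixture EM on an n x d table.

    This is the vector-space procedure the matrix formulation generalizes.
    With d approaching or exceeding n the d x d covariances become singular
    and the ridge dominates — the failure mode feature-matrix folding exists
    to avoid — so it is intended for small d (reference and comparison), not
    for raw omics matrices.
    """
    X = np.asarray(data, dtype=float)
    n, d = X.shape
    if c > n:
        raise ValueError(f"cannot fit c={c} clusters to n={n} samples")
    seeds = _derive_seeds(seed, n_restarts)
    best = None
    restart_lls: list[float] = []
    restart_labs: list[np.ndarray] = []
    for rs in seeds:
        phi = _init_responsibilities(X, c, init, int(rs))
        priors, means, covs = _m_step_1d(X, phi, reg)
        trace: list[float] = []
        params: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
        conv = False
        it = 0
        for it in range(1, max_iter + 1):
            logd = np.column_stack([_gauss_logpdf(X, means[i], covs[i]) for i in range(c)])
            with np.errstate(divide="ignore"):
                lw = logd + np.log(priors)
            mx = lw.max(axis=1, keepdims=True)
            L = float((mx.ravel() + np.log(np.exp(lw - mx).sum(axis=1))).sum())
            trace.append(L)
            if record_params:
                params.append((priors.copy(), means.copy(), covs.copy()))
            phi = np.exp(lw - mx)
            phi /= phi.sum(axis=1, keepdims=True)
            if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol * max(abs(trace[-2]), 1.0):
                conv = True
                break
            priors, means, covs = _m_step_1d(X, phi, reg)
        labs = np.argmax(phi, axis=1)
        restart_lls.append(trace[-1])
        restart_labs.append(labs)
        if best is None or trace[-1] > best[3][-1]:
            best = (priors, means, covs, np.asarray(trace), phi, it, conv, params)
    priors, means, covs, trace, phi, it, conv, params = best
    model = MixtureModel1D(c=c, priors=priors, means=means, covariances=covs)
    return FitResult(
        labels=LabelVector(np.argmax(phi, axis=1), c),
        responsibilities=Responsibilities(phi),
        model=model,
        loglik_trace=trace,
        n_iter=it,
        converged=conv,
        seed=seed,
        restart_logliks=restart_lls,
        restart_labels=restart_labs,
        param_trace=params,
    )


def _m_step_1d(X: np.ndarray, phi: np.ndarray, reg: float):
    n, d = X.shape
    c = phi.shape[1]
    mass = phi.sum(axis=0)
    degenerate = mass < 1e-8 * n
    priors = mass / n
    means = np.empty((c, d))
    covs = np.empty((c, d, d))
    for i in range(c):
        if degenerate[i]:
            continue
        w = phi[:, i]
        means[i] = w @ X / mass[i]
        R = X - means[i]
        covs[i] = (R.T * w) @ R / mass[i]
        covs[i] = regularize_covariance(covs[i], reg)
    if degenerate.any():
        ok = ~degenerate
        avg_cov = covs[ok].mean(axis=0)
        worst = int(np.argmin(phi.max(axis=1)))
        for i in np.where(degenerate)[0]:
            means[i] = X[worst]
            covs[i] = regularize_covariance(avg_cov, reg)
            priors[i] = 1.0 / n
        priors = priors / priors.sum()
    return priors, means, covs


# ---------------------------------------------------------------------------
# prediction on new samples


def predict(model: MixtureModel2D, filt: FilterModel, E_new: ExpressionMatrix) -> LabelVector:
    """Fold unseen samples with a stored filter and assign argmax clusters.

    Feature columns are matched by ID and the stored mean ordering is reused,
    never recomputed, so new samples land in the exact layout the model was
    trained on.
    """
    fms = filt.fold(E_new)
    resp = e_step_2d(fms, model)
    return LabelVector(np.argmax(resp.values, axis=1), model.c, sample_ids=list(E_new.sample_ids))
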