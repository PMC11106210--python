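"""Waveform-model training: principal components + Gaussian mixture.

Each training sample contributes one row ``[phi; a]`` — its normalized
frequency waveform followed by its normalized amplitude waveform — to a
design matrix X.  Principal components come from the spectral
decomposition of X'X *without* mean-centering (this deliberately differs
from conventional PCA; the normalized waveforms already live near a
common baseline, and the uncentered decomposition keeps the back-
projection of cluster means directly interpretable as waveforms).  The
projected scores are modeled by a Gaussian mixture; clusters that are
small or whose members poorly match the cluster-mean frequency waveform
are eliminated as outlier collections, and the surviving mixing
proportions are renormalized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.mixture import GaussianMixture

from .gt_processing import GTGroup

logger = logging.getLogger(__name__)

DELTA_R2_DEFAULT = 0.3   # minimum 5%-percentile CoD for a cluster to survive
DELTA_C_DEFAULT = 30     # minimum cluster size


class TrainingError(RuntimeError):
    """Model training failed (non-convergence or no surviving clusters)."""


@dataclass
class PCABasis:
    """Eigenvectors of X'X, ordered by descending eigenvalue.

    Sign convention: each component's largest-magnitude entry is positive.
    """

    components: np.ndarray = field(repr=False)   # (d, d), columns are PCs
    eigenvalues: np.ndarray = field(repr=False)  # (d,), non-increasing

    def P(self, N: int) -> np.ndarray:
        if not 1 <= N <= self.components.shape[1]:
            raise ValueError(f"N={N} outside [1, {self.components.shape[1]}]")
        return self.components[:, :N]

    def explained_variance_ratio(self) -> np.ndarray:
        total = self.eigenvalues.sum()
        return self.eigenvalues / total if total > 0 else self.eigenvalues


@dataclass
class GaussianCluster:
    mu: np.ndarray = field(repr=False)
    Sigma: np.ndarray = field(repr=False)
    p: float = 0.0
    mean_f: np.ndarray | None = field(default=None, repr=False)
    mean_a: np.ndarray | None = field(default=None, repr=False)


@dataclass
class TrainedModel:
    """Kept clusters plus the PC basis they live in."""

    r: int
    N: int
    P_N: np.ndarray = field(repr=False)          # (2*(10^r+1), N)
    eigenvalues: np.ndarray = field(repr=False)  # full spectrum, descending
    clusters: list[GaussianCluster] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    @property
    def n_window(self) -> int:
        return 10 ** self.r + 1


# ---------------------------------------------------------------------------
# design matrix and PCA
# ---------------------------------------------------------------------------

def build_design_matrix(
    group: GTGroup, train_ids: list[int] | None = None
) -> np.ndarray:
    """Stack [phi; a] rows (frequency first) for the selected samples."""
    ids = range(len(group.samples)) if train_ids is None else train_ids
    rows = []
    d = 2 * group.n_points
    for i in ids:
        s = group.samples[i]
        row = np.concatenate([s.phi, s.a])
        if row.size != d:
            raise ValueError(
                f"sample {i} has {row.size} values, expected {d}"
            )
        rows.append(row)
    if not rows:
        raise ValueError("empty training set")
    return np.asarray(rows)


def fit_pca(X: np.ndarray) -> PCABasis:
    """Spectral decomposition of X'X (uncentered), descending eigenvalues."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least two rows for the decomposition")
    gram = X.T @ X
    eigval, eigvec = np.linalg.eigh(gram)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    # orient each component so its largest-magnitude entry is positive
    flip = eigvec[np.argmax(np.abs(eigvec), axis=0), np.arange(eigvec.shape[1])] < 0
    eigvec[:, flip] *= -1.0
    return PCABasis(components=eigvec, eigenvalues=eigval)


def project(X: np.ndarray, basis: PCABasis, N: int) -> np.ndarray:
    """Scores Y = X P_N."""
    return np.asarray(X, dtype=float) @ basis.P(N)


# ---------------------------------------------------------------------------
# Gaussian mixture
# ---------------------------------------------------------------------------

def fit_gmm(
    Y: np.ndarray,
    C: int,
    seed: int,
    n_init: int = 10,
    reg_covar: float = 1e-6,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> list[GaussianCluster]:
    """EM fit of a C-component full-covariance Gaussian mixture."""
    Y = np.asarray(Y, dtype=float)
    gmm = GaussianMixture(
        n_components=C,
        covariance_type="full",
        tol=tol,
        reg_covar=reg_covar,
        max_iter=max_iter,
        n_init=n_init,
        init_params="k-means++",
        random_state=seed,
    )
    gmm.fit(Y)
    if not gmm.converged_:
        raise TrainingError(
            f"EM did not converge after {n_init} restarts "
            f"(best lower bound {gmm.lower_bound_:.6g})"
        )
    return [
        GaussianCluster(mu=gmm.means_[c].copy(),
                        Sigma=gmm.covariances_[c].copy(),
                        p=float(gmm.weights_[c]))
        for c in range(C)
    ]


def _log_gauss(Y: np.ndarray, mu: np.ndarray, Sigma: np.ndarray) -> np.ndarray:
    """Log density of N(mu, Sigma) at each row of Y."""
    N = mu.size
    L = np.linalg.cholesky(Sigma)
    diff = Y - mu
    z = np.linalg.solve(L, diff.T)
    maha = np.sum(z * z, axis=0)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    return -0.5 * (N * np.log(2 * np.pi) + logdet + maha)


def posterior_log_scores(Y: np.ndarray, clusters: list[GaussianCluster]) -> np.ndarray:
    """Unnormalized log posterior log p_c + log N(y; mu_c, Sigma_c), (m, C)."""
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    return np.column_stack(
        [np.log(c.p) + _log_gauss(Y, c.mu, c.Sigma) for c in clusters]
    )


def assign_cluster(y: np.ndarray, clusters: list[GaussianCluster]) -> int:
    """Maximum-posterior cluster of one score vector (ties -> smallest index)."""
    if not clusters:
        raise ValueError("no clusters to assign to")
    return int(np.argmax(posterior_log_scores(y, clusters)[0]))


# ---------------------------------------------------------------------------
# coefficient of determination and cluster elimination
# ---------------------------------------------------------------------------

def coefficient_of_determination(f: np.ndarray, f_ref: np.ndarray) -> float:
    """R^2 of a frequency waveform against a reference waveform.

    R^2 = 1 - ||f - f_ref||^2 / ||f - mean(f)||^2; constant f (zero total
    sum of squares) yields -inf so it always loses threshold comparisons.
    """
    f = np.asarray(f, dtype=float)
    sst = float(np.sum((f - f.mean()) ** 2))
    if sst == 0:
        return float("-inf")
    sse = float(np.sum((f - np.asarray(f_ref, dtype=float)) ** 2))
    return 1.0 - sse / sst


def back_project_mean(
    mu: np.ndarray, P_N: np.ndarray, n_points: int
) -> tuple[np.ndarray, np.ndarray]:
    """Cluster-mean waveform [f_bar; a_bar] = P_N mu, split into halves."""
    w = P_N @ np.asarray(mu, dtype=float)
    return w[:n_points], w[n_points:]


def eliminate_clusters(
    clusters: list[GaussianCluster],
    assignments: np.ndarray,
    cods: np.ndarray,
    delta_r2: float = DELTA_R2_DEFAULT,
    delta_c: int = DELTA_C_DEFAULT,
) -> list[GaussianCluster]:
    """Drop outlier clusters; renormalize the survivors' proportions.

    A cluster is eliminated if its size is below ``delta_c`` or if the 5%
    percentile (linear-interpolation quantile) of its members' CoD values
    falls below ``delta_r2``.
    """
    kept: list[GaussianCluster] = []
    for c, cluster in enumerate(clusters):
        members = np.flatnonzero(assignments == c)
        if members.size < delta_c:
            logger.info("cluster %d eliminated: size %d < %d",
                        c, members.size, delta_c)
            continue
        q5 = float(np.percentile(cods[members], 5.0))
        if q5 < delta_r2:
            logger.info("cluster %d eliminated: 5%% CoD %.3f < %.3f",
                        c, q5, delta_r2)
            continue
        kept.append(cluster)
    if not kept:
        raise TrainingError("no valid clusters survive elimination")
    total = sum(c.p for c in kept)
    for c in kept:
        c.p = c.p / total
    return kept


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def train_model(
    group: GTGroup,
    N: int,
    C: int,
    seed: int,
    train_ids: list[int] | None = None,
    delta_r2: float = DELTA_R2_DEFAULT,
    delta_c: int = DELTA_C_DEFAULT,
    **gmm_kwargs,
) -> TrainedModel:
    """Full training pass on one GT group.

    Builds the design matrix, fits the uncentered PC basis, projects to N
    dimensions, fits a C-component Gaussian mixture, scores every training
    sample's frequency waveform against its assigned cluster mean, and
    eliminates outlier clusters.
    """
    X = build_design_matrix(group, train_ids)
    basis = fit_pca(X)
    Y = project(X, basis, N)
    clusters = fit_gmm(Y, C, seed, **gmm_kwargs)
    P_N = basis.P(N)
    n_pts = group.n_points
    for cluster in clusters:
        cluster.mean_f, cluster.mean_a = back_project_mean(cluster.mu, P_N, n_pts)

    log_post = posterior_log_scores(Y, clusters)
    assignments = np.argmax(log_post, axis=1)
    cods = np.array(
        [
            coefficient_of_determination(X[i, :n_pts], clusters[assignments[i]].mean_f)
            for i in range(X.shape[0])
        ]
    )
    kept = eliminate_clusters(clusters, assignments, cods, delta_r2, delta_c)
    return TrainedModel(
        r=group.r,
        N=N,
        P_N=P_N,
        eigenvalues=basis.eigenvalues,
        clusters=kept,
        metadata={
            "seed": int(seed),
            "C": int(C),
            "delta_r2": float(delta_r2),
            "delta_c": int(delta_c),
            "m_train": int(X.shape[0]),
        },
    )
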