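"""Depth-aware mixture clustering of (n/T, log depth) points.

Per locus, the 2-D points x_i = (n/T, log depth) over all samples are fit
with a truncated Dirichlet-process Gaussian mixture

    f(x | theta) = sum_{j=1..M} pi_j N(x; mu_j, Sigma_j),

estimated by variational (Bayesian) EM under a stick-breaking DP prior, so
that superfluous components collapse to near-zero weight and the number of
effective components is inferred from the data. Gaussian components are
then *aggregated into clusters by density mode*: a fixed-point hill climb
is started from each active component mean, components whose climbs
converge to the same local maximum of f share a cluster, and the number of
distinct modes is the realised number of clusters. This lets strongly
non-Gaussian clusters (e.g. a low-depth reference smear) be represented by
several components without being over-split.

The fit itself is delegated to scikit-learn's BayesianGaussianMixture; the
mode-finding and merging layer is implemented here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import multivariate_normal
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.exceptions import ConvergenceWarning
from sklearn.mixture import BayesianGaussianMixture
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "MixtureFit",
    "DirichletModeClusterer",
    "fit_dpgmm",
    "mixture_density",
    "merge_components_to_modes",
    "assign_points",
]


@dataclass
class MixtureFit:
    """Parameters and cluster structure of a fitted mixture."""

    M: int
    weights: np.ndarray            # (M,), simplex
    means: np.ndarray              # (M, d)
    covariances: np.ndarray        # (M, d, d)
    active: np.ndarray             # (M,) bool, weight above the pruning floor
    component_to_mode: np.ndarray  # (M,) int, cluster index per component
    modes: np.ndarray              # (n_modes, d)
    assignments: np.ndarray        # (n,) cluster labels of the training points
    seed: int | None = None

    @property
    def n_clusters(self) -> int:
        return len(self.modes)


class DirichletModeClusterer(ClusterMixin, BaseEstimator):
    """Truncated DP Gaussian mixture with mode-merged clusters.

    Parameters
    ----------
    max_components:
        Truncation level M of the stick-breaking prior. The effective
        number of components is inferred; M is only an upper bound.
    alpha:
        DP concentration parameter of the stick-breaking prior.
    weight_floor, residue_mahalanobis:
        Pruning of variational residue. DP variational fits leave
        low-weight components whose collapsed covariances would spawn
        spurious density spikes; a component is treated as residue -- no
        hill climb, no assignments -- when its weight is below
        ``weight_floor`` *and* its mean lies within
        ``residue_mahalanobis`` standard deviations (Mahalanobis, under
        the heavier component's covariance) of a heavier component, i.e.
        inside that component's basin. Low-weight but isolated components
        are genuine small clusters and stay active.
    reg_covar:
        Regularisation added to covariance diagonals; also the variance
        floor for degenerate (e.g. all-identical) inputs.
    n_init:
        Number of seeded EM initialisations; the highest-lower-bound fit
        is kept.
    mean_precision_prior:
        NIW coupling between a component's mean and its covariance. The
        small default decouples them, so a tight component (e.g. the
        point mass of absent samples at n/T = 0) is not dragged toward
        the data centroid and merged with its neighbour.
    climb_tol, mode_merge_tol:
        Convergence tolerance of the fixed-point mode climb and the radius
        within which two converged modes are considered the same, both in
        per-axis standardised units.
    max_climb_iter:
        Iteration cap for each hill climb; a non-convergent climb is
        assigned to the nearest found mode.
    random_state:
        Seed; fits are deterministic given data + seed.
    """

    def __init__(
        self,
        max_components: int = 10,
        alpha: float = 1.0,
        weight_floor: float = 1e-2,
        residue_mahalanobis: float = 3.0,
        reg_covar: float = 1e-6,
        n_init: int = 5,
        mean_precision_prior: float = 1e-2,
        climb_tol: float = 1e-4,
        mode_merge_tol: float = 1e-3,
        max_climb_iter: int = 500,
        random_state: int | None = None,
    ) -> None:
        self.max_components = max_components
        self.alpha = alpha
        self.weight_floor = weight_floor
        self.residue_mahalanobis = residue_mahalanobis
        self.reg_covar = reg_covar
        self.n_init = n_init
        self.mean_precision_prior = mean_precision_prior
        self.climb_tol = climb_tol
        self.mode_merge_tol = mode_merge_tol
        self.max_climb_iter = max_climb_iter
        self.random_state = random_state

    # ------------------------------------------------------------------ fit

    def fit(self, X, y=None):
        X = self._validate_points(X)
        n = X.shape[0]
        if self.max_components < 2:
            raise ValueError("max_components must be >= 2")
        m_eff = min(self.max_components, n)
        # NIW base measure centred on the data: inverse-Wishart scale set to
        # a per-cluster share of the empirical covariance (spread / M^2)
        emp_cov = np.atleast_2d(np.cov(X.T)) + self.reg_covar * np.eye(X.shape[1])
        bgm = BayesianGaussianMixture(
            n_components=m_eff,
            covariance_type="full",
            weight_concentration_prior_type="dirichlet_process",
            weight_concentration_prior=self.alpha,
            reg_covar=self.reg_covar,
            n_init=self.n_init,
            mean_precision_prior=self.mean_precision_prior,
            covariance_prior=emp_cov / self.max_components**2,
            max_iter=500,
            random_state=self.random_state,
        )
        with warnings.catch_warnings():
            # duplicate points (e.g. many samples at n/T exactly 0 or 1) make
            # the k-means init report fewer distinct centres; expected here
            warnings.filterwarnings("ignore", category=ConvergenceWarning)
            bgm.fit(X)

        M = self.max_components
        d = X.shape[1]
        self.weights_ = np.zeros(M)
        self.weights_[:m_eff] = bgm.weights_
        self.weights_ /= self.weights_.sum()
        self.means_ = np.zeros((M, d))
        self.means_[:m_eff] = bgm.means_
        self.covariances_ = np.tile(np.eye(d), (M, 1, 1))
        self.covariances_[:m_eff] = bgm.covariances_
        self.active_ = self._prune_residue(n)
        if not self.active_.any():
            self.active_[int(np.argmax(self.weights_))] = True

        self._merge_modes()
        self.labels_ = self.predict(X)
        self._drop_empty_modes(X)
        self.n_features_in_ = d
        return self

    def _drop_empty_modes(self, X: np.ndarray) -> None:
        """A mode that owns no points is not a realised cluster.

        Residual stick-breaking mass can park a low-weight component away
        from any heavier one (so it survives residue pruning) yet attract
        no assignments; its mode is removed and its components attach to
        the nearest populated mode."""
        used = np.unique(self.labels_)
        if len(used) == len(self.modes_):
            return
        keep = [int(u) for u in sorted(used)]
        scale = self._axis_scale()
        remap = {old: new for new, old in enumerate(keep)}
        for old in range(len(self.modes_)):
            if old not in remap:
                dists = [
                    np.linalg.norm((self.modes_[old] - self.modes_[k]) / scale)
                    for k in keep
                ]
                remap[old] = int(np.argmin(dists))
        self.component_to_mode_ = np.array(
            [remap[m] for m in self.component_to_mode_]
        )
        self.modes_ = self.modes_[keep]
        self.labels_ = self.predict(X)

    def _validate_points(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("points must be a 2-D array of row vectors")
        if X.shape[0] < 2:
            raise ValueError("need at least 2 points to fit a mixture")
        if not np.isfinite(X).all():
            raise ValueError("points contain non-finite coordinates")
        return X

    def _prune_residue(self, n_points: int) -> np.ndarray:
        """Active mask: heavy components, plus light ones outside any
        heavier component's basin (see class docstring). Components with
        less than half a point of responsibility are always inactive."""
        w = self.weights_
        heavy = w > self.weight_floor
        active = heavy.copy()
        for j in np.flatnonzero(~heavy):
            if w[j] * n_points < 0.5:
                continue
            inside = False
            for i in np.flatnonzero(w > w[j]):
                diff = self.means_[j] - self.means_[i]
                d2 = diff @ np.linalg.solve(self.covariances_[i], diff)
                # basin radius grows with the heavier component's occupancy:
                # the expected extreme Mahalanobis radius of n draws is
                # ~sqrt(2 ln n), plus a fixed margin
                radius2 = self.residue_mahalanobis**2 + 2.0 * np.log(
                    max(w[i] * n_points, 1.0)
                )
                if d2 < radius2:
                    inside = True
                    break
            active[j] = not inside
        return active

    # ---------------------------------------------------------- mode search

    def _axis_scale(self) -> np.ndarray:
        """Per-axis standard deviation of the mixture (scale for tolerances)."""
        w = self.weights_[:, None]
        mean = (w * self.means_).sum(axis=0)
        second = (
            w * (np.einsum("mii->mi", self.covariances_) + self.means_ ** 2)
        ).sum(axis=0)
        var = np.maximum(second - mean**2, self.reg_covar)
        return np.sqrt(var)

    def _climb(self, x0: np.ndarray, precisions: np.ndarray, scale: np.ndarray):
        """Fixed-point ascent of the mixture density from ``x0``.

        Iterates x <- (sum_j r_j P_j)^-1 sum_j r_j P_j mu_j with
        responsibilities r_j(x); stationary points of this map are the
        stationary points of the mixture density.
        """
        x = x0.copy()
        idx = np.flatnonzero(self.active_)
        mus = self.means_[idx]
        pis = self.weights_[idx]
        precs = precisions[idx]
        for _ in range(self.max_climb_iter):
            logp = np.array(
                [
                    multivariate_normal.logpdf(x, mus[j], self.covariances_[idx[j]],
                                               allow_singular=True)
                    for j in range(len(idx))
                ]
            )
            logp += np.log(pis)
            r = np.exp(logp - logp.max())
            r /= r.sum()
            A = np.einsum("j,jab->ab", r, precs)
            b = np.einsum("j,jab,jb->a", r, precs, mus)
            x_new = np.linalg.solve(A, b)
            if np.max(np.abs(x_new - x) / scale) < self.climb_tol:
                return x_new, True
            x = x_new
        return x, False

    def _merge_modes(self) -> None:
        scale = self._axis_scale()
        precisions = np.linalg.inv(self.covariances_)
        idx = np.flatnonzero(self.active_)
        endpoints, converged = [], []
        for j in idx:
            end, ok = self._climb(self.means_[j], precisions, scale)
            endpoints.append(end)
            converged.append(ok)

        modes: list[np.ndarray] = []
        comp_mode = np.full(len(self.weights_), -1, dtype=int)
        # converged climbs define modes; stragglers attach to the nearest one
        order = sorted(range(len(idx)), key=lambda i: not converged[i])
        for i in order:
            end = endpoints[i]
            scaled = [np.linalg.norm((end - m) / scale) for m in modes]
            if converged[i]:
                match = next(
                    (k for k, dist in enumerate(scaled) if dist < self.mode_merge_tol),
                    None,
                )
            else:
                match = int(np.argmin(scaled)) if modes else None
            if match is None:
                match = len(modes)
                modes.append(end)
            comp_mode[idx[i]] = match
        # inactive components inherit the mode of the nearest active mean
        for j in np.flatnonzero(~self.active_):
            dists = [
                np.linalg.norm((self.means_[j] - self.means_[a]) / scale)
                for a in idx
            ]
            comp_mode[j] = comp_mode[idx[int(np.argmin(dists))]]
        self.component_to_mode_ = comp_mode
        self.modes_ = np.array(modes)

    # -------------------------------------------------------------- predict

    def _log_resp(self, X: np.ndarray) -> np.ndarray:
        logp = np.full((X.shape[0], len(self.weights_)), -np.inf)
        for j in np.flatnonzero(self.active_):
            logp[:, j] = multivariate_normal.logpdf(
                X, self.means_[j], self.covariances_[j], allow_singular=True
            ) + np.log(self.weights_[j])
        return logp

    def predict(self, X) -> np.ndarray:
        """Cluster labels: argmax-responsibility component, mapped to its mode.

        Ties break toward the lowest component index (np.argmax order).
        """
        check_is_fitted(self, "modes_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        comp = np.argmax(self._log_resp(X), axis=1)
        return self.component_to_mode_[comp]

    def score_samples(self, X) -> np.ndarray:
        """Log mixture density at each point (all M components)."""
        check_is_fitted(self, "modes_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        logp = np.stack(
            [
                multivariate_normal.logpdf(
                    X, self.means_[j], self.covariances_[j], allow_singular=True
                )
                + np.log(self.weights_[j])
                if self.weights_[j] > 0
                else np.full(X.shape[0], -np.inf)
                for j in range(len(self.weights_))
            ],
            axis=1,
        )
        from scipy.special import logsumexp

        return logsumexp(logp, axis=1)

    def to_fit(self) -> MixtureFit:
        check_is_fitted(self, "modes_")
        return MixtureFit(
            M=self.max_components,
            weights=self.weights_.copy(),
            means=self.means_.copy(),
            covariances=self.covariances_.copy(),
            active=self.active_.copy(),
            component_to_mode=self.component_to_mode_.copy(),
            modes=self.modes_.copy(),
            assignments=self.labels_.copy(),
            seed=self.random_state,
        )


# ---------------------------------------------------------------- functions


def fit_dpgmm(
    points,
    M: int = 10,
    prior_config: dict | None = None,
    seed: int | None = None,
) -> MixtureFit:
    """Fit the truncated DP Gaussian mixture and merge components by mode."""
    params = dict(prior_config or {})
    est = DirichletModeClusterer(max_components=M, random_state=seed, **params)
    est.fit(points)
    return est.to_fit()


def mixture_density(fit: MixtureFit, x) -> float:
    """f(x | theta) = sum_j pi_j N(x; mu_j, Sigma_j); integrates to 1."""
    x = np.asarray(x, dtype=float)
    total = 0.0
    for j in range(len(fit.weights)):
        if fit.weights[j] <= 0:
            continue
        total += fit.weights[j] * multivariate_normal.pdf(
            x, fit.means[j], fit.covariances[j], allow_singular=True
        )
    return float(total)


def merge_components_to_modes(fit: MixtureFit, tolerance: float = 1e-3):
    """Recompute the component->mode map of a fit at a given merge radius."""
    est = _estimator_from_fit(fit, mode_merge_tol=tolerance)
    est._merge_modes()
    return est.component_to_mode_.copy(), est.modes_.copy()


def assign_points(fit: MixtureFit, points) -> np.ndarray:
    """Cluster labels for new points under a fitted mixture."""
    est = _estimator_from_fit(fit)
    return est.predict(points)


def _estimator_from_fit(fit: MixtureFit, **overrides) -> DirichletModeClusterer:
    est = DirichletModeClusterer(max_components=fit.M, random_state=fit.seed, **overrides)
    est.weights_ = fit.weights.copy()
    est.means_ = fit.means.copy()
    est.covariances_ = fit.covariances.copy()
    est.active_ = fit.active.copy()
    est.component_to_mode_ = fit.component_to_mode.copy()
    est.modes_ = fit.modes.copy()
    est.labels_ = fit.assignments.copy()
    est.n_features_in_ = fit.means.shape[1]
    return est
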