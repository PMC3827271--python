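"""Kernel-ABC core: Gaussian-kernel ridge regression of parameters onto
summary statistics.

The algorithm: draw theta_i from the priors, simulate data, summarize into
s_i, for i = 1..n; then predict the posterior mean at the observed summary
s_obs by kernel ridge regression of theta onto s with a Gaussian RBF kernel
k(u, v) = exp(-||u - v||^2 / (2 sigma^2)).  With Gram matrix G and centered
targets the predictor is

    mean(theta) + k_obs^T (G + n lambda I)^{-1} (theta - mean(theta)),

one shared solve serving all parameter coordinates.  Summary coordinates are
z-standardized with training-set moments before kernel evaluation, since SFS
counts and HFS tallies live on different scales.  The bandwidth sigma^2 and
regularization lambda are chosen by seeded 10-fold cross-validation over a
grid centered on the median pairwise squared distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.spatial.distance import cdist

__all__ = [
    "SimTable",
    "KernelConfig",
    "PosteriorEstimate",
    "rbf_kernel",
    "KrrRegressor",
    "krr_posterior_mean",
    "build_simtable",
    "select_hyperparams_cv",
    "run_abc",
    "replicate_abc",
    "save_simtable",
    "load_simtable",
]


@dataclass
class SimTable:
    """Paired draws {theta_i, s_i} from the prior-predictive simulation."""

    theta: np.ndarray  # (n, p)
    s: np.ndarray  # (n, d)
    param_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.theta = np.atleast_2d(np.asarray(self.theta, dtype=float))
        self.s = np.atleast_2d(np.asarray(self.s, dtype=float))
        if self.theta.shape[0] != self.s.shape[0]:
            raise ValueError("theta and s must have one row per simulation")
        if self.theta.shape[0] < 2:
            raise ValueError("need at least two simulations")
        if not self.param_names:
            self.param_names = tuple(f"p{i}" for i in range(self.theta.shape[1]))

    @property
    def n(self) -> int:
        return self.theta.shape[0]


@dataclass(frozen=True)
class KernelConfig:
    sigma2: float
    lam: float
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.sigma2 <= 0 or self.lam <= 0:
            raise ValueError("sigma^2 and lambda must be > 0")


@dataclass
class PosteriorEstimate:
    """Replicated posterior-mean estimate: mean and SD over R repetitions."""

    mean: np.ndarray
    sd: np.ndarray
    r: int
    n: int
    param_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if self.r < 1:
            raise ValueError("need at least one replication")
        if (self.sd < 0).any():
            raise ValueError("SD must be >= 0")


def rbf_kernel(u: np.ndarray, v: np.ndarray, sigma2: float) -> float:
    """Gaussian radial basis function kernel exp(-||u-v||^2 / (2 sigma^2))."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("summary vectors must have equal length")
    if sigma2 <= 0:
        raise ValueError("sigma^2 must be > 0")
    return float(np.exp(-np.sum((u - v) ** 2) / (2.0 * sigma2)))


def _standardizer(s: np.ndarray):
    mean = s.mean(axis=0)
    sd = s.std(axis=0)
    sd = np.where(sd == 0.0, 1.0, sd)
    return mean, sd


def _sq_dists(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return cdist(a, b, metric="sqeuclidean")


def median_sq_distance(s: np.ndarray, standardize: bool = True,
                       max_rows: int = 500) -> float:
    """Median pairwise squared distance (the bandwidth median heuristic)."""
    if standardize:
        mean, sd = _standardizer(s)
        s = (s - mean) / sd
    if s.shape[0] > max_rows:
        s = s[:: s.shape[0] // max_rows + 1]
    d = _sq_dists(s, s)
    iu = np.triu_indices(d.shape[0], k=1)
    med = float(np.median(d[iu]))
    return med if med > 0 else 1.0


class KrrRegressor:
    """Fit-once kernel ridge regressor: one Gram solve serves every
    parameter coordinate and any number of prediction points."""

    def __init__(self, table: SimTable, config: KernelConfig):
        self.config = config
        s = table.s
        if config.standardize:
            self._mean, self._sd = _standardizer(s)
            s = (s - self._mean) / self._sd
        else:
            self._mean = self._sd = None
        self._s = s
        self.theta_mean = table.theta.mean(axis=0)
        n = table.n
        gram = np.exp(-_sq_dists(s, s) / (2.0 * config.sigma2))
        system = gram + n * config.lam * np.eye(n)
        try:
            factor = cho_factor(system, lower=True)
            self.alpha = cho_solve(factor, table.theta - self.theta_mean)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "singular kernel system; use a regularization lambda > 0"
            ) from exc

    def predict(self, s_obs: np.ndarray) -> np.ndarray:
        s_obs = np.asarray(s_obs, dtype=float).reshape(1, -1)
        if s_obs.shape[1] != self._s.shape[1]:
            raise ValueError("s_obs length must match the table's summary dimension")
        if self._mean is not None:
            s_obs = (s_obs - self._mean) / self._sd
        k_obs = np.exp(-_sq_dists(s_obs, self._s) / (2.0 * self.config.sigma2)).ravel()
        return self.theta_mean + k_obs @ self.alpha


def krr_posterior_mean(table: SimTable, s_obs: np.ndarray,
                       config: KernelConfig) -> np.ndarray:
    """Posterior-mean prediction at s_obs by kernel ridge regression."""
    return KrrRegressor(table, config).predict(s_obs)


def default_lambda_grid() -> np.ndarray:
    return np.geomspace(1e-6, 1e-1, 6)


def default_sigma2_grid(s: np.ndarray, standardize: bool = True) -> np.ndarray:
    med = median_sq_distance(s, standardize=standardize)
    return med * np.array([0.25, 1.0, 4.0])


def select_hyperparams_cv(table: SimTable,
                          sigma2_grid=None, lambda_grid=None,
                          folds: int = 10, seed=None,
                          standardize: bool = True) -> KernelConfig:
    """Grid search (sigma^2, lambda) minimizing K-fold held-out MSE.

    Prediction error is averaged over parameter coordinates after
    per-coordinate standardization of theta, so parameters on different
    scales weigh equally.  Folds are contiguous blocks after a seeded
    shuffle.
    """
    if table.n < folds:
        raise ValueError("need at least as many rows as folds")
    sigma2_grid = (default_sigma2_grid(table.s, standardize)
                   if sigma2_grid is None else np.asarray(sigma2_grid, dtype=float))
    lambda_grid = default_lambda_grid() if lambda_grid is None else np.asarray(lambda_grid, dtype=float)
    if len(sigma2_grid) == 0 or len(lambda_grid) == 0:
        raise ValueError("hyperparameter grids must be non-empty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    order = rng.permutation(table.n)
    fold_ids = np.array_split(order, folds)

    s = table.s
    if standardize:
        mean, sd = _standardizer(s)
        s = (s - mean) / sd
    th_mean = table.theta.mean(axis=0)
    th_sd = table.theta.std(axis=0)
    th_sd = np.where(th_sd == 0.0, 1.0, th_sd)
    theta_z = (table.theta - th_mean) / th_sd

    sq = _sq_dists(s, s)
    best = (np.inf, None)
    for sigma2 in sigma2_grid:
        gram_full = np.exp(-sq / (2.0 * sigma2))
        for lam in lambda_grid:
            err = 0.0
            for test_idx in fold_ids:
                train_idx = np.setdiff1d(np.arange(table.n), test_idx, assume_unique=False)
                g = gram_full[np.ix_(train_idx, train_idx)]
                k_test = gram_full[np.ix_(test_idx, train_idx)]
                y = theta_z[train_idx]
                y_mean = y.mean(axis=0)
                m = len(train_idx)
                factor = cho_factor(g + m * lam * np.eye(m), lower=True)
                alpha = cho_solve(factor, y - y_mean)
                pred = y_mean + k_test @ alpha
                err += float(np.mean((pred - theta_z[test_idx]) ** 2))
            err /= folds
            if err < best[0]:
                best = (err, KernelConfig(sigma2=float(sigma2), lam=float(lam),
                                          standardize=standardize))
    return best[1]


def run_abc(s_obs: np.ndarray, prior_sampler, model, n: int, seed=None,
            cv_subsample: int = 1000, folds: int = 10,
            sigma2_grid=None, lambda_grid=None,
            param_names: tuple[str, ...] = (),
            return_table: bool = False):
    """One full kernel-ABC pass.

    ``prior_sampler(rng) -> theta`` draws a parameter vector;
    ``model(theta, rng) -> s`` simulates a dataset and returns its summary
    vector.  Hyperparameters are selected by K-fold CV on a seeded subsample
    of at most ``cv_subsample`` rows, then the regression is fit on the full
    table.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    table = build_simtable(prior_sampler, model, n, rng, param_names=param_names)
    config = _select_on_subsample(table, rng, cv_subsample, folds,
                                  sigma2_grid, lambda_grid)
    estimate = krr_posterior_mean(table, s_obs, config)
    if return_table:
        return estimate, table, config
    return estimate


def build_simtable(prior_sampler, model, n: int, rng: np.random.Generator,
                   param_names: tuple[str, ...] = ()) -> SimTable:
    """Draw n (theta_i, s_i) pairs from the prior-predictive simulation."""
    thetas, summaries = [], []
    for _ in range(n):
        theta = np.asarray(prior_sampler(rng), dtype=float)
        try:
            s = np.asarray(model(theta, rng), dtype=float)
        except Exception as exc:
            raise RuntimeError(f"simulator failed at theta={theta}") from exc
        thetas.append(theta)
        summaries.append(s)
    return SimTable(theta=np.array(thetas), s=np.array(summaries),
                    param_names=param_names)


def _select_on_subsample(table: SimTable, rng, cv_subsample, folds,
                         sigma2_grid, lambda_grid) -> KernelConfig:
    if table.n > cv_subsample:
        idx = rng.choice(table.n, size=cv_subsample, replace=False)
        sub = SimTable(theta=table.theta[idx], s=table.s[idx],
                       param_names=table.param_names)
    else:
        sub = table
    return select_hyperparams_cv(sub, sigma2_grid=sigma2_grid,
                                 lambda_grid=lambda_grid, folds=folds, seed=rng)


def replicate_abc(s_obs: np.ndarray, prior_sampler, model, n: int,
                  r: int = 100, seed=None,
                  param_names: tuple[str, ...] = (), **abc_kwargs) -> PosteriorEstimate:
    """R independent kernel-ABC runs; mean and SD of the posterior means."""
    if r < 1:
        raise ValueError("need r >= 1 replications")
    root = (seed if isinstance(seed, np.random.SeedSequence)
            else np.random.SeedSequence(seed))
    estimates = []
    for child in root.spawn(r):
        rng = np.random.default_rng(child)
        estimates.append(run_abc(s_obs, prior_sampler, model, n, seed=rng,
                                 param_names=param_names, **abc_kwargs))
    estimates = np.array(estimates)
    if r == 1:
        warnings.warn("replication SD undefined with r=1; reporting 0",
                      stacklevel=2)
        sd = np.zeros(estimates.shape[1])
    else:
        sd = estimates.std(axis=0, ddof=1)
    return PosteriorEstimate(mean=estimates.mean(axis=0), sd=sd, r=r, n=n,
                             param_names=param_names or tuple(f"p{i}" for i in range(estimates.shape[1])))


# ---------------------------------------------------------------------------
# persistence: theta columns then s columns, tab-separated

def save_simtable(table: SimTable, path) -> None:
    p = table.theta.shape[1]
    header = list(table.param_names) + [f"s{i}" for i in range(table.s.shape[1])]
    data = np.hstack([table.theta, table.s])
    np.savetxt(path, data, delimiter="\t", header="\t".join(header), comments="")


def load_simtable(path, n_params: int | None = None) -> SimTable:
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
    data = np.loadtxt(path, delimiter="\t", skiprows=1)
    if n_params is None:
        n_params = sum(1 for h in header if not h.startswith("s"))
    return SimTable(theta=data[:, :n_params], s=data[:, n_params:],
                    param_names=tuple(header[:n_params]))
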