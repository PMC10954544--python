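"""Gaussian-process regression of chemistry fields over longitude/latitude.

One GP per chemistry variable, with a constant (learned) prior mean, a
Matérn covariance with independent per-axis lengthscales in degrees, and a
homoscedastic noise term.  Hyperparameters are estimated by maximizing the
exact marginal likelihood on the training split with full-batch Adam under a
cosine warm-restart learning-rate schedule and early stopping.

The kernel operates on raw (lon, lat) degrees with an anisotropic Euclidean
distance: the learned longitude lengthscale absorbs the cos-latitude
compression of east-west degree lengths, which mirrors using separate
scaling parameters for the two axes.  An isotropic variant (single shared
lengthscale) is available through :class:`GPConfig`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky

from .data_model import ChemistryPanel, SampleTable
from .preprocess import StandardizationParams, fit_standardizer

_SQRT3 = np.sqrt(3.0)
_SQRT5 = np.sqrt(5.0)
_LOG2PI = np.log(2.0 * np.pi)

JITTER = 1e-6  # diagonal regularization of the training kernel matrix


class OptimizerDivergence(RuntimeError):
    """Raised when the marginal-likelihood objective becomes non-finite."""

    def __init__(self, message: str, trace: list[float]):
        super().__init__(message)
        self.trace = trace


@dataclass(frozen=True)
class GPConfig:
    """Kernel family and optimizer settings for a single-variable GP.

    Parameters
    ----------
    nu
        Matérn smoothness; one of 0.5, 1.5, 2.5 (default 2.5).
    anisotropic
        Independent lon/lat lengthscales when True; a single shared
        lengthscale otherwise.
    init_lengthscale, init_signal_var, init_noise_var
        Optimizer initialization (degrees / standardized-variance units).
    learn_mean
        Learn the constant prior mean jointly; when False it is fixed at
        the training mean.
    lr, restart_period, patience, max_iter
        Adam step size, cosine warm-restart period (iterations), early
        stopping patience (iterations without a new best), iteration cap.
    """

    nu: float = 2.5
    anisotropic: bool = True
    init_lengthscale: float = 1.0
    init_signal_var: float = 1.0
    init_noise_var: float = 0.1
    learn_mean: bool = True
    lr: float = 0.01
    restart_period: int = 20
    patience: int = 5
    max_iter: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nu not in (0.5, 1.5, 2.5):
            raise ValueError("nu must be one of 0.5, 1.5, 2.5")
        for name in ("init_lengthscale", "init_signal_var", "init_noise_var", "lr"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def matern(r: np.ndarray, nu: float, signal_var: float = 1.0) -> np.ndarray:
    """Matérn correlation times ``signal_var`` at scaled distance ``r``."""
    if nu == 0.5:
        return signal_var * np.exp(-r)
    if nu == 1.5:
        return signal_var * (1.0 + _SQRT3 * r) * np.exp(-_SQRT3 * r)
    if nu == 2.5:
        return signal_var * (1.0 + _SQRT5 * r + 5.0 * r * r / 3.0) * np.exp(-_SQRT5 * r)
    raise ValueError("nu must be one of 0.5, 1.5, 2.5")


def _matern_dr_over_r(r: np.ndarray, nu: float, signal_var: float) -> np.ndarray:
    """(1/r) * dK/dr — finite at r = 0 for nu >= 1.5."""
    if nu == 0.5:
        return -signal_var * np.exp(-r) / np.maximum(r, 1e-10)
    if nu == 1.5:
        return -3.0 * signal_var * np.exp(-_SQRT3 * r)
    if nu == 2.5:
        return -(5.0 / 3.0) * signal_var * (1.0 + _SQRT5 * r) * np.exp(-_SQRT5 * r)
    raise ValueError("nu must be one of 0.5, 1.5, 2.5")


def _sq_diffs(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    dlon = a[:, 0][:, None] - b[:, 0][None, :]
    dlat = a[:, 1][:, None] - b[:, 1][None, :]
    return dlon * dlon, dlat * dlat


def kernel_matrix(
    a: np.ndarray,
    b: np.ndarray,
    lengthscales: Sequence[float],
    signal_var: float,
    nu: float,
) -> np.ndarray:
    """Matérn kernel between coordinate sets (lon/lat degrees)."""
    d_lon, d_lat = _sq_diffs(np.asarray(a, float), np.asarray(b, float))
    ell = np.asarray(lengthscales, float)
    r = np.sqrt(d_lon / ell[0] ** 2 + d_lat / ell[1] ** 2)
    return matern(r, nu, signal_var)


@dataclass
class FittedGP:
    """A trained single-variable GP with cached Cholesky solve.

    ``predict`` returns the posterior mean and the TOTAL predictive
    variance (epistemic plus noise) in standardized units.
    """

    config: GPConfig
    X: np.ndarray  # (n, 2) lon/lat
    y: np.ndarray  # (n,) standardized values
    lengthscales: np.ndarray  # (2,)
    signal_var: float
    noise_var: float
    mean: float
    objective: float = np.nan
    n_iter: int = 0
    _cho: tuple | None = field(default=None, repr=False)
    _alpha: np.ndarray | None = field(default=None, repr=False)

    @classmethod
    def from_params(
        cls,
        X: np.ndarray,
        y: np.ndarray,
        lengthscales,
        signal_var: float,
        noise_var: float,
        mean: float,
        config: GPConfig | None = None,
    ) -> "FittedGP":
        """Build a model directly from given hyperparameters (no fitting)."""
        gp = cls(
            config=config or GPConfig(),
            X=np.asarray(X, float),
            y=np.asarray(y, float),
            lengthscales=np.broadcast_to(np.asarray(lengthscales, float), (2,)).copy(),
            signal_var=float(signal_var),
            noise_var=float(noise_var),
            mean=float(mean),
        )
        gp._factorize()
        return gp

    def _factorize(self) -> None:
        K = kernel_matrix(self.X, self.X, self.lengthscales, self.signal_var, self.config.nu)
        K[np.diag_indices_from(K)] += self.noise_var + JITTER
        c, low = cho_factor(K, lower=True)
        self._cho = (c, low)
        self._alpha = cho_solve((c, low), self.y - self.mean)

    def predict(self, coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Posterior mean and total variance at (n, 2) lon/lat coords."""
        coords = np.asarray(coords, float).reshape(-1, 2)
        if len(coords) == 0:
            return np.empty(0), np.empty(0)
        if self._cho is None:
            self._factorize()
        Ks = kernel_matrix(coords, self.X, self.lengthscales, self.signal_var, self.config.nu)
        mean = self.mean + Ks @ self._alpha
        c, low = self._cho
        L = np.tril(c) if low else np.triu(c).T
        v = np.linalg.solve(L, Ks.T)
        var = self.signal_var + self.noise_var - np.einsum("ij,ij->j", v, v)
        return mean, np.maximum(var, self.noise_var * (1.0 - 1e-9))

    def log_marginal_likelihood(self) -> float:
        if self._cho is None:
            self._factorize()
        c, low = self._cho
        logdet = 2.0 * np.sum(np.log(np.diag(c)))
        resid = self.y - self.mean
        return float(-0.5 * resid @ self._alpha - 0.5 * logdet - 0.5 * len(self.y) * _LOG2PI)


def _objective_and_grad(
    theta: np.ndarray, X: np.ndarray, y: np.ndarray, cfg: GPConfig
) -> tuple[float, np.ndarray]:
    """Negative log marginal likelihood and gradient in the packed
    parameterization [log l_lon, (log l_lat), log sig2, log noise2, (mean)]."""
    i = 0
    log_ell = [theta[0], theta[0]] if not cfg.anisotropic else [theta[0], theta[1]]
    i = 1 if not cfg.anisotropic else 2
    signal_var = np.exp(theta[i])
    noise_var = np.exp(theta[i + 1])
    mean = theta[i + 2] if cfg.learn_mean else float(np.mean(y))
    ell = np.exp(log_ell)

    d_lon, d_lat = _sq_diffs(X, X)
    u_lon = d_lon / ell[0] ** 2
    u_lat = d_lat / ell[1] ** 2
    r = np.sqrt(u_lon + u_lat)
    K_sig = matern(r, cfg.nu, signal_var)
    K = K_sig.copy()
    K[np.diag_indices_from(K)] += noise_var + JITTER
    c, low = cho_factor(K, lower=True)
    resid = y - mean
    alpha = cho_solve((c, low), resid)
    n = len(y)
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    nll = 0.5 * resid @ alpha + 0.5 * logdet + 0.5 * n * _LOG2PI

    Kinv = cho_solve((c, low), np.eye(n))
    W = np.outer(alpha, alpha) - Kinv  # dL/dK = 0.5 * W (L = log marginal lik)

    dr = _matern_dr_over_r(r, cfg.nu, signal_var)  # (1/r) dK/dr
    grads = []
    if cfg.anisotropic:
        grads.append(0.5 * np.sum(W * (-dr * u_lon)))
        grads.append(0.5 * np.sum(W * (-dr * u_lat)))
    else:
        grads.append(0.5 * np.sum(W * (-dr * (u_lon + u_lat))))
    grads.append(0.5 * np.sum(W * K_sig))  # d/dlog signal_var
    grads.append(0.5 * noise_var * np.trace(W))  # d/dlog noise_var
    if cfg.learn_mean:
        grads.append(float(np.sum(alpha)))
    # objective is the NEGATIVE log marginal likelihood
    return float(nll), -np.asarray(grads)


def fit_gp(coords: np.ndarray, values: np.ndarray, config: GPConfig | None = None) -> FittedGP:
    """Fit a single-variable GP by maximizing the marginal likelihood.

    Full-batch Adam (learning rate from the config, default 0.01) with a
    cosine warm-restart schedule (fixed period) and early stopping once no
    new best objective is seen for ``patience`` iterations.  All parameters
    are optimized in log-space; the constant mean, when learned, on its
    natural scale.  The best parameters seen are returned.  Deterministic:
    the objective is exact, so no randomness enters the loop.
    """
    cfg = config or GPConfig()
    X = np.asarray(coords, float).reshape(-1, 2)
    y = np.asarray(values, float).ravel()
    if len(X) != len(y):
        raise ValueError("coords and values length mismatch")
    if len(y) < 3:
        raise ValueError("need at least 3 training points")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite training inputs")

    theta = []
    theta.append(np.log(cfg.init_lengthscale))
    if cfg.anisotropic:
        theta.append(np.log(cfg.init_lengthscale))
    theta.append(np.log(cfg.init_signal_var))
    theta.append(np.log(cfg.init_noise_var))
    if cfg.learn_mean:
        theta.append(float(np.mean(y)))
    theta = np.asarray(theta, float)

    m_t = np.zeros_like(theta)
    v_t = np.zeros_like(theta)
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    best_obj = np.inf
    best_theta = theta.copy()
    since_best = 0
    trace: list[float] = []
    n_iter = 0
    for t in range(1, cfg.max_iter + 1):
        obj, grad = _objective_and_grad(theta, X, y, cfg)
        trace.append(obj)
        if not np.isfinite(obj):
            raise OptimizerDivergence(
                f"non-finite objective at iteration {t}", trace
            )
        n_iter = t
        if obj < best_obj - 1e-12:
            best_obj = obj
            best_theta = theta.copy()
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.patience:
                break
        # cosine warm restarts: lr decays to ~0 within each period, then resets
        phase = (t - 1) % cfg.restart_period
        lr_t = cfg.lr * 0.5 * (1.0 + np.cos(np.pi * phase / cfg.restart_period))
        m_t = beta1 * m_t + (1 - beta1) * grad
        v_t = beta2 * v_t + (1 - beta2) * grad * grad
        m_hat = m_t / (1 - beta1**t)
        v_hat = v_t / (1 - beta2**t)
        theta = theta - lr_t * m_hat / (np.sqrt(v_hat) + eps)

    th = best_theta
    if cfg.anisotropic:
        ell = np.exp(th[:2])
        i = 2
    else:
        ell = np.exp([th[0], th[0]])
        i = 1
    signal_var = float(np.exp(th[i]))
    noise_var = float(np.exp(th[i + 1]))
    mean = float(th[i + 2]) if cfg.learn_mean else float(np.mean(y))
    gp = FittedGP(
        config=cfg,
        X=X,
        y=y,
        lengthscales=ell,
        signal_var=signal_var,
        noise_var=noise_var,
        mean=mean,
        objective=float(best_obj),
        n_iter=n_iter,
    )
    gp._factorize()
    return gp


@dataclass
class FieldModelEnsemble:
    """One fitted GP per chemistry variable, for one genus and one split.

    Holds the standardization parameters fitted on the same training split
    so that raw test chemistry can be mapped into model units.
    """

    genus: str
    panel: ChemistryPanel
    models: dict[str, FittedGP]
    standardizer: StandardizationParams | None = None

    def __post_init__(self) -> None:
        if list(self.models) != list(self.panel.names):
            raise ValueError("model order must match panel order")

    @property
    def m(self) -> int:
        return self.panel.m

    def transform(self, y: np.ndarray) -> np.ndarray:
        """Standardize a raw chemistry vector/matrix (no-op if unstandardized)."""
        if self.standardizer is None:
            return np.asarray(y, float)
        return self.standardizer.transform_values(y)

    def predict(self, coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(n, m) predictive means and total variances, standardized units."""
        coords = np.asarray(coords, float).reshape(-1, 2)
        means = np.empty((len(coords), self.m))
        variances = np.empty((len(coords), self.m))
        for j, name in enumerate(self.panel.names):
            mu, var = self.models[name].predict(coords)
            means[:, j] = mu
            variances[:, j] = var
        return means, variances

    def to_json(self, path) -> None:
        """Serialize to a single self-describing JSON archive."""
        payload = {
            "format": "chemoscape-ensemble-v1",
            "genus": self.genus,
            "panel": {"names": list(self.panel.names), "kinds": list(self.panel.kinds)},
            "standardizer": None
            if self.standardizer is None
            else {
                "names": list(self.standardizer.names),
                "means": self.standardizer.means.tolist(),
                "sds": self.standardizer.sds.tolist(),
            },
            "models": {},
        }
        for name, gp in self.models.items():
            payload["models"][name] = {
                "nu": gp.config.nu,
                "anisotropic": gp.config.anisotropic,
                "lengthscales": gp.lengthscales.tolist(),
                "signal_var": gp.signal_var,
                "noise_var": gp.noise_var,
                "mean": gp.mean,
                "X": gp.X.tolist(),
                "y": gp.y.tolist(),
            }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "FieldModelEnsemble":
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("format") != "chemoscape-ensemble-v1":
            raise ValueError("not a chemoscape ensemble archive")
        panel = ChemistryPanel(
            tuple(payload["panel"]["names"]), tuple(payload["panel"]["kinds"])
        )
        std = payload["standardizer"]
        standardizer = (
            None
            if std is None
            else StandardizationParams(
                tuple(std["names"]), np.asarray(std["means"]), np.asarray(std["sds"])
            )
        )
        models = {}
        for name, rec in payload["models"].items():
            cfg = GPConfig(nu=rec["nu"], anisotropic=rec["anisotropic"])
            models[name] = FittedGP.from_params(
                np.asarray(rec["X"]),
                np.asarray(rec["y"]),
                rec["lengthscales"],
                rec["signal_var"],
                rec["noise_var"],
                rec["mean"],
                config=cfg,
            )
        return cls(payload["genus"], panel, models, standardizer)


def fit_ensemble(
    train: SampleTable,
    config: GPConfig | None = None,
    genus: str | None = None,
    standardize: bool = True,
) -> FieldModelEnsemble:
    """Fit one GP per panel variable on a training table.

    When ``standardize`` is True (default), per-variable standardization
    parameters are estimated on this split and the GPs are trained on the
    standardized values; the ensemble then accepts raw chemistry through
    :meth:`FieldModelEnsemble.transform`.  Samples missing a variable are
    excluded from that variable's training pairs.
    """
    if len(train) == 0:
        raise ValueError("empty training table")
    cfg = config or GPConfig()
    standardizer = fit_standardizer(train) if standardize else None
    chem = train.chemistry
    if standardizer is not None:
        chem = standardizer.transform_values(chem)
    coords = train.coords
    models: dict[str, FittedGP] = {}
    for j, name in enumerate(train.panel.names):
        ok = np.isfinite(chem[:, j])
        if not ok.any():
            raise ValueError(f"variable {name!r} has no non-missing training values")
        try:
            models[name] = fit_gp(coords[ok], chem[ok, j], cfg)
        except Exception as exc:  # annotate with the variable name
            raise type(exc)(f"fitting variable {name!r}: {exc}") from exc
    if genus is None:
        genera = set(train.df["genus"].astype(str))
        genus = genera.pop() if len(genera) == 1 else "mixed"
    return FieldModelEnsemble(genus, train.panel, models, standardizer)
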