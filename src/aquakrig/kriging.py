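"""Kriging (Gaussian-process) regression of atomic properties.

Each atomic property Y (an atomic energy or one multipole component) is
modelled as a constant trend plus kernel-weighted contributions from the
training configurations,

    Y(f) = mu + sum_j a_j exp( - sum_h theta_h |f_h - f_{h,j}|^{p_h} ),

with features f = (r_OH1, r_OH2, theta_HOH), activities theta_h > 0 and
smoothness exponents p_h in (0, 2].  The weights solve a = R^{-1} (y - mu 1)
where R is the regularised kernel matrix, so the predictor interpolates the
training data up to the nugget scale.  Hyperparameters are chosen by
maximising the concentrated log-likelihood

    -(N/2) ln sigma^2_hat - (1/2) ln det R,

with mu and sigma^2 eliminated analytically, using global-best particle
swarm optimisation over log10(theta) (and optionally p).

The module follows the statsmodels convention: ``Kriging`` is the model
object bound to data, ``Kriging.fit`` returns a ``KrigingResults`` carrying
the estimates, diagnostics and ``summary()``.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib
import warnings
from typing import Callable, Sequence

import numpy as np
from scipy.linalg import cho_solve, lapack

from .geometry import N_FEAT, WaterConfiguration, feature_jacobian, features_from_positions

__all__ = [
    "Kriging",
    "KrigingResults",
    "PSOSettings",
    "SCurve",
    "kernel",
    "concentrated_log_likelihood",
    "pso_optimize",
    "train",
    "extract_features",
    "extract_target",
    "s_curve",
    "mae",
]

#: value returned by the concentrated log-likelihood when the process
#: variance underflows (e.g. constant targets): a large finite cap so that
#: optimisers treat the fit as perfect without propagating infinities.
LOGLIKE_CAP = 1.0e10

_THETA_LOG10_BOUNDS = (-3.0, 3.0)
_P_BOUNDS = (0.5, 2.0)

#: reciprocal-condition floor below which the regularised kernel matrix is
#: treated as numerically singular.  Maximum-likelihood hyperparameter
#: selection on smooth noise-free targets is driven toward arbitrarily flat,
#: near-singular kernels; this floor is the package's definition of "singular
#: despite the nugget" and confines the search to solvable models.
RCOND_MIN = 1e-9


def _validate_hyper(theta: np.ndarray, p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    p = np.atleast_1d(np.asarray(p, dtype=float))
    if np.any(theta <= 0):
        raise ValueError("all theta_h must be strictly positive")
    if np.any((p <= 0) | (p > 2)):
        raise ValueError("all p_h must lie in (0, 2]")
    return theta, p


def kernel(f_i: np.ndarray, f_j: np.ndarray, theta: np.ndarray, p: np.ndarray) -> float:
    """Correlation exp(-sum_h theta_h |f_h,i - f_h,j|^p_h) in (0, 1]."""
    theta, p = _validate_hyper(theta, p)
    d = np.abs(np.asarray(f_i, dtype=float) - np.asarray(f_j, dtype=float))
    return float(np.exp(-np.sum(theta * d**p)))


@dataclasses.dataclass(frozen=True)
class PSOSettings:
    """Global-best particle swarm settings (standard constricted values)."""

    swarm_size: int = 40
    iterations: int = 300
    inertia: float = 0.72
    cognitive: float = 1.49
    social: float = 1.49


def pso_optimize(
    objective: Callable[[np.ndarray], float],
    bounds: np.ndarray,
    swarm_size: int = 40,
    iterations: int = 300,
    rng_seed: int = 0,
    inertia: float = 0.72,
    cognitive: float = 1.49,
    social: float = 1.49,
) -> tuple[np.ndarray, float]:
    """Maximise ``objective`` over a box; deterministic given ``rng_seed``.

    bounds is (d, 2); returns (best position, best objective).  Raises if no
    initial particle has a finite objective.
    """
    bounds = np.asarray(bounds, dtype=float)
    if bounds.ndim != 2 or bounds.shape[1] != 2 or np.any(~np.isfinite(bounds)):
        raise ValueError("bounds must be a finite (d, 2) array")
    if swarm_size < 2:
        raise ValueError("swarm_size must be >= 2")
    rng = np.random.default_rng(rng_seed)
    d = bounds.shape[0]
    lo, hi = bounds[:, 0], bounds[:, 1]
    span = hi - lo

    x = rng.uniform(lo, hi, size=(swarm_size, d))
    v = rng.uniform(-span, span, size=(swarm_size, d)) * 0.1
    fvals = np.array([objective(xi) for xi in x], dtype=float)
    if not np.any(np.isfinite(fvals)):
        raise ValueError("objective is non-finite at every initial particle")
    pbest = x.copy()
    pbest_f = fvals.copy()
    g = int(np.nanargmax(np.where(np.isfinite(fvals), fvals, -np.inf)))
    gbest = x[g].copy()
    gbest_f = float(fvals[g])

    for _ in range(iterations):
        r1 = rng.random((swarm_size, d))
        r2 = rng.random((swarm_size, d))
        v = inertia * v + cognitive * r1 * (pbest - x) + social * r2 * (gbest - x)
        x = np.clip(x + v, lo, hi)
        fvals = np.array([objective(xi) for xi in x], dtype=float)
        improved = np.isfinite(fvals) & (fvals > pbest_f)
        pbest[improved] = x[improved]
        pbest_f[improved] = fvals[improved]
        k = int(np.argmax(pbest_f))
        if pbest_f[k] > gbest_f:
            gbest_f = float(pbest_f[k])
            gbest = pbest[k].copy()
    return gbest, gbest_f


class Kriging:
    """Kriging model bound to training data.

    Parameters
    ----------
    y : (N,) training targets.
    features : (N, 3) internal-coordinate features.
    property_name : label carried through to results and serialization.
    nugget_rel : diagonal regulariser relative to var(y); escalated (at most
        to 1e-6) with a warning if the kernel matrix is not positive
        definite.
    """

    def __init__(
        self,
        y: np.ndarray,
        features: np.ndarray,
        property_name: str = "property",
        nugget_rel: float = 1e-10,
    ) -> None:
        y = np.asarray(y, dtype=float).ravel()
        F = np.asarray(features, dtype=float)
        if F.ndim != 2 or F.shape[1] != N_FEAT:
            raise ValueError(f"features must be (N, {N_FEAT})")
        if len(y) != len(F):
            raise ValueError("y and features must have equal length")
        if len(y) < 2:
            raise ValueError("kriging needs at least 2 training points")
        if nugget_rel < 0:
            raise ValueError("nugget_rel must be non-negative")
        self.y = y
        self.features = F
        self.nobs = len(y)
        self.property_name = property_name
        self.nugget_rel = float(nugget_rel)
        scale = float(np.var(y))
        self.nugget_abs = nugget_rel * scale if scale > 0 else nugget_rel
        # cached |f_i - f_j| per feature, (3, N, N), plus squares (p = 2 path)
        self._absdiff = np.abs(F[:, None, :] - F[None, :, :]).transpose(2, 0, 1)
        self._absdiff_sq = self._absdiff**2
        if nugget_rel == 0.0:
            self._check_duplicates()

    def _check_duplicates(self) -> None:
        dup = (self._absdiff.sum(axis=0) == 0.0) & ~np.eye(self.nobs, dtype=bool)
        if np.any(dup & (np.abs(self.y[:, None] - self.y[None, :]) > 0)):
            raise ValueError(
                "duplicate training features with differing targets require a nonzero nugget"
            )

    def _corr_matrix(self, theta: np.ndarray, p: np.ndarray) -> np.ndarray:
        if np.all(p == 2.0):
            expo = np.tensordot(theta, self._absdiff_sq, axes=1)
        else:
            expo = np.zeros((self.nobs, self.nobs))
            for h in range(N_FEAT):
                expo += theta[h] * self._absdiff[h] ** p[h]
        return np.exp(-expo)

    def _decompose(self, theta: np.ndarray, p: np.ndarray, nugget_abs: float):
        R = self._corr_matrix(theta, p) + nugget_abs * np.eye(self.nobs)
        try:
            L = np.linalg.cholesky(R)
        except np.linalg.LinAlgError as err:
            cond = np.linalg.cond(R)
            raise np.linalg.LinAlgError(
                f"kernel matrix not positive definite (condition number {cond:.3e}) "
                f"with nugget {nugget_abs:.3e}"
            ) from err
        # cheap LAPACK reciprocal-condition estimate from the factorization
        rcond, _ = lapack.dpocon(L.T, np.linalg.norm(R, 1))
        if rcond < RCOND_MIN:
            raise np.linalg.LinAlgError(
                f"kernel matrix numerically singular despite nugget {nugget_abs:.3e}: "
                f"reciprocal condition {rcond:.3e} < {RCOND_MIN:.0e}"
            )
        return R, L

    def loglike_concentrated(
        self, theta: np.ndarray, p: np.ndarray | float = 2.0, nugget_abs: float | None = None
    ) -> float:
        """Concentrated log-likelihood with mu and sigma^2 profiled out."""
        theta, p = _validate_hyper(theta, np.broadcast_to(np.atleast_1d(p), (N_FEAT,)))
        if nugget_abs is None:
            nugget_abs = self.nugget_abs
        if np.ptp(self.y) == 0.0:
            # degenerate constant response: the trend fits exactly (sigma^2 = 0)
            return LOGLIKE_CAP
        _, L = self._decompose(theta, p, nugget_abs)
        ones = np.ones(self.nobs)
        alpha_y = cho_solve((L, True), self.y)
        alpha_1 = cho_solve((L, True), ones)
        mu = float(ones @ alpha_y) / float(ones @ alpha_1)
        resid = self.y - mu
        sigma2 = float(resid @ (alpha_y - mu * alpha_1)) / self.nobs
        logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
        if sigma2 <= 1e-300:
            return LOGLIKE_CAP
        return -0.5 * self.nobs * np.log(sigma2) - 0.5 * logdet

    def fit(
        self,
        optimize_p: bool = False,
        pso: PSOSettings | None = None,
        rng_seed: int = 0,
        theta: np.ndarray | None = None,
        p: np.ndarray | None = None,
    ) -> "KrigingResults":
        """Fit hyperparameters by PSO (or use supplied theta/p) and solve weights.

        With ``optimize_p`` false, p is held exactly at 2 for every feature.
        """
        pso = pso or PSOSettings()
        if theta is None:
            ndim = 2 * N_FEAT if optimize_p else N_FEAT
            bounds = np.array(
                [_THETA_LOG10_BOUNDS] * N_FEAT + [_P_BOUNDS] * (ndim - N_FEAT)
            )

            def objective(x: np.ndarray) -> float:
                th = 10.0 ** x[:N_FEAT]
                pp = x[N_FEAT:] if optimize_p else np.full(N_FEAT, 2.0)
                try:
                    return self.loglike_concentrated(th, pp)
                except np.linalg.LinAlgError:
                    return -np.inf

            # a small swarm can start entirely inside the ill-conditioned
            # region; retry deterministically with a larger one
            best = best_f = None
            for attempt in range(3):
                try:
                    best, best_f = pso_optimize(
                        objective,
                        bounds,
                        swarm_size=pso.swarm_size * 2**attempt,
                        iterations=pso.iterations,
                        rng_seed=rng_seed + 7919 * attempt,
                        inertia=pso.inertia,
                        cognitive=pso.cognitive,
                        social=pso.social,
                    )
                    break
                except ValueError:
                    if attempt == 2:
                        raise
                    warnings.warn(
                        f"PSO initialization infeasible for {self.property_name}; "
                        f"retrying with a larger swarm",
                        stacklevel=2,
                    )
            theta = 10.0 ** best[:N_FEAT]
            p = best[N_FEAT:] if optimize_p else np.full(N_FEAT, 2.0)
            loglike = best_f
        else:
            theta, p = _validate_hyper(theta, p if p is not None else np.full(N_FEAT, 2.0))
            loglike = self.loglike_concentrated(theta, p)

        if np.ptp(self.y) == 0.0:
            return KrigingResults(
                model=self,
                property_name=self.property_name,
                mu=float(self.y[0]),
                weights=np.zeros(self.nobs),
                theta=np.asarray(theta, dtype=float),
                p=np.asarray(p, dtype=float),
                nugget=self.nugget_abs,
                training_features=self.features,
                training_targets=self.y,
                sigma2=0.0,
                loglike=float(loglike),
            )

        nugget = self.nugget_abs
        while True:
            try:
                _, L = self._decompose(theta, p, nugget)
                break
            except np.linalg.LinAlgError:
                new = max(nugget, 1e-14) * 100.0
                if new > 1e-6 * max(float(np.var(self.y)), 1.0):
                    raise
                warnings.warn(
                    f"escalating nugget {nugget:.3e} -> {new:.3e} for "
                    f"{self.property_name}: kernel matrix ill-conditioned",
                    stacklevel=2,
                )
                nugget = new

        ones = np.ones(self.nobs)
        alpha_y = cho_solve((L, True), self.y)
        alpha_1 = cho_solve((L, True), ones)
        mu = float(ones @ alpha_y) / float(ones @ alpha_1)
        resid = self.y - mu
        weights = alpha_y - mu * alpha_1
        sigma2 = float(resid @ weights) / self.nobs
        return KrigingResults(
            model=self,
            property_name=self.property_name,
            mu=mu,
            weights=weights,
            theta=np.asarray(theta, dtype=float),
            p=np.asarray(p, dtype=float),
            nugget=nugget,
            training_features=self.features,
            training_targets=self.y,
            sigma2=sigma2,
            loglike=float(loglike),
        )


def concentrated_log_likelihood(
    theta: np.ndarray,
    p: np.ndarray,
    features: np.ndarray,
    y: np.ndarray,
    nugget_rel: float = 1e-10,
) -> float:
    """Functional wrapper around :meth:`Kriging.loglike_concentrated`."""
    return Kriging(y, features, nugget_rel=nugget_rel).loglike_concentrated(theta, p)


@dataclasses.dataclass
class KrigingResults:
    """A trained kriging predictor for one atomic property."""

    model: Kriging | None
    property_name: str
    mu: float
    weights: np.ndarray
    theta: np.ndarray
    p: np.ndarray
    nugget: float
    training_features: np.ndarray
    training_targets: np.ndarray
    sigma2: float = float("nan")
    loglike: float = float("nan")

    @property
    def n_trn(self) -> int:
        return len(self.weights)

    def _kernel_vector(self, features: np.ndarray) -> np.ndarray:
        f = np.atleast_2d(np.asarray(features, dtype=float))  # (M, 3)
        d = np.abs(f[:, None, :] - self.training_features[None, :, :])
        expo = np.einsum("h,mjh->mj", self.theta, d**self.p)
        return np.exp(-expo)  # (M, N)

    def predict(self, features: np.ndarray) -> np.ndarray | float:
        """Evaluate the predictor at (..., 3) feature vectors."""
        f = np.asarray(features, dtype=float)
        scalar = f.ndim == 1
        k = self._kernel_vector(f)
        out = self.mu + k @ self.weights
        return float(out[0]) if scalar else out

    def predict_feature_gradient(self, features: np.ndarray) -> np.ndarray:
        """Analytic dY/df at (..., 3); requires p_h = 2 for every feature."""
        if not np.all(self.p == 2.0):
            raise ValueError(
                "analytic gradients require p = 2 (gradient is discontinuous "
                "at training points otherwise)"
            )
        f = np.asarray(features, dtype=float)
        scalar = f.ndim == 1
        f2 = np.atleast_2d(f)
        diff = f2[:, None, :] - self.training_features[None, :, :]  # (M, N, 3)
        k = np.exp(-np.einsum("h,mjh->mj", self.theta, diff**2))
        grad = np.einsum("mj,mjh,h->mh", k * self.weights[None, :], diff, -2.0 * self.theta)
        return grad[0] if scalar else grad

    def predict_gradient(self, config: "WaterConfiguration | np.ndarray") -> np.ndarray:
        """d(property)/d(positions), shape (3 atoms, 3), via the chain rule."""
        pos = config.positions if isinstance(config, WaterConfiguration) else np.asarray(config)
        feats = features_from_positions(pos)
        g = self.predict_feature_gradient(feats)
        return np.einsum("f,fac->ac", g, feature_jacobian(pos))

    def training_residual(self) -> float:
        """Max |prediction - target| over the training set (interpolation check)."""
        pred = self.predict(self.training_features)
        return float(np.max(np.abs(pred - self.training_targets)))

    def summary(self) -> str:
        lines = [
            "Kriging model results",
            "=" * 54,
            f"Property:            {self.property_name}",
            f"N_trn:               {self.n_trn}",
            f"Trend mean mu:       {self.mu: .8g}",
            f"Process var sigma^2: {self.sigma2: .8g}",
            f"Nugget (absolute):   {self.nugget: .3e}",
            f"Concentrated loglik: {self.loglike: .8g}",
            "Feature        theta          p",
            "-" * 54,
        ]
        for name, th, pp in zip(("r_OH1", "r_OH2", "theta_HOH"), self.theta, self.p):
            lines.append(f"{name:<12} {th:>12.6g} {pp:>10.4g}")
        lines.append("-" * 54)
        lines.append(f"Max training residual: {self.training_residual():.3e}")
        return "\n".join(lines)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "format_version": 1,
            "property": self.property_name,
            "mu": self.mu,
            "weights": self.weights.tolist(),
            "theta": self.theta.tolist(),
            "p": self.p.tolist(),
            "nugget": self.nugget,
            "sigma2": self.sigma2,
            "loglike": self.loglike,
            "training_features": self.training_features.tolist(),
            "training_targets": self.training_targets.tolist(),
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "KrigingResults":
        if doc.get("format_version") != 1:
            raise ValueError(f"unsupported model format version {doc.get('format_version')!r}")
        try:
            return cls(
                model=None,
                property_name=doc["property"],
                mu=float(doc["mu"]),
                weights=np.asarray(doc["weights"], dtype=float),
                theta=np.asarray(doc["theta"], dtype=float),
                p=np.asarray(doc["p"], dtype=float),
                nugget=float(doc["nugget"]),
                training_features=np.asarray(doc["training_features"], dtype=float),
                training_targets=np.asarray(doc["training_targets"], dtype=float),
                sigma2=float(doc.get("sigma2", float("nan"))),
                loglike=float(doc.get("loglike", float("nan"))),
            )
        except KeyError as err:
            raise ValueError(f"model document missing required field {err}") from err

    def save(self, path: str | pathlib.Path) -> None:
        pathlib.Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | pathlib.Path) -> "KrigingResults":
        path = pathlib.Path(path)
        res = cls.from_dict(json.loads(path.read_text()))
        F = res.training_features
        if F.ndim != 2 or F.shape[1] != N_FEAT or len(res.weights) != len(F):
            raise ValueError(f"corrupted model file {path}: inconsistent array shapes")
        _validate_hyper(res.theta, res.p)
        return res


# -- property extraction and convenience training -------------------------

def extract_features(labelled: Sequence) -> np.ndarray:
    """(N, 3) feature matrix of a labelled ensemble."""
    return np.array(
        [features_from_positions(lc.config.positions) for lc in labelled]
    )


def extract_target(labelled: Sequence, kind: str, atom: int, component: int | None = None) -> np.ndarray:
    """Training targets: kind 'energy' (kJ/mol) or 'moment' (e A^l, local frame)."""
    if kind == "energy":
        return np.array([lc.atomic_energies[atom] for lc in labelled])
    if kind == "moment":
        if component is None:
            raise ValueError("moment targets need a component index 0-8")
        return np.array([lc.atomic_moments[atom].components[component] for lc in labelled])
    raise ValueError(f"unknown target kind {kind!r}")


def train(
    labelled_train: Sequence,
    kind: str = "energy",
    atom: int = 0,
    component: int | None = None,
    optimize_p: bool = False,
    nugget_rel: float = 1e-10,
    pso: PSOSettings | None = None,
    rng_seed: int = 0,
) -> KrigingResults:
    """Train one atomic-property model from a labelled training set."""
    y = extract_target(labelled_train, kind, atom, component)
    name = f"{kind}:{('O', 'H1', 'H2')[atom]}" + (
        f":{component}" if component is not None else ""
    )
    model = Kriging(y, extract_features(labelled_train), property_name=name, nugget_rel=nugget_rel)
    return model.fit(optimize_p=optimize_p, pso=pso, rng_seed=rng_seed)


# -- validation-set diagnostics -------------------------------------------

@dataclasses.dataclass
class SCurve:
    """Sorted absolute prediction errors vs cumulative % of configurations."""

    errors: np.ndarray
    cumulative_percent: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.cumulative_percent) < 0) or not np.isclose(
            self.cumulative_percent[-1], 100.0
        ):
            raise ValueError("cumulative percentage must be nondecreasing and end at 100")

    @property
    def median_error(self) -> float:
        return float(np.median(self.errors))


def _sum_errors(models: Sequence[KrigingResults], labelled_validation: Sequence, kind: str) -> np.ndarray:
    """Per-configuration |sum_A predicted - sum_A reference|.

    Energies in kJ/mol; net charge in millielectron (me).
    """
    feats = extract_features(labelled_validation)
    pred = np.sum([m.predict(feats) for m in models], axis=0)
    if kind == "energy":
        ref = np.array([lc.molecular_energy for lc in labelled_validation])
        scale = 1.0
    elif kind == "charge":
        ref = np.array([lc.net_charge for lc in labelled_validation])
        scale = 1000.0
    else:
        raise ValueError(f"unknown aggregate kind {kind!r}")
    return np.abs(pred - ref) * scale


def s_curve(models: Sequence[KrigingResults], labelled_validation: Sequence, kind: str = "energy") -> SCurve:
    """Cumulative error curve of the summed-atomic-property prediction."""
    if len(labelled_validation) == 0:
        raise ValueError("validation set must be nonempty")
    err = np.sort(_sum_errors(models, labelled_validation, kind))
    cum = 100.0 * np.arange(1, len(err) + 1) / len(err)
    return SCurve(err, cum)


def mae(models: Sequence[KrigingResults], labelled_validation: Sequence, kind: str = "energy") -> float:
    """Mean absolute error of the summed-atomic-property prediction."""
    if len(labelled_validation) == 0:
        raise ValueError("validation set must be nonempty")
    return float(np.mean(_sum_errors(models, labelled_validation, kind)))
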