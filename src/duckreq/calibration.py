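"""Calibration of the requirement model against observed flock records.

Organised in the statsmodels style: :class:`RequirementModel` is built from
an :class:`ObservationSet` (or a flock DataFrame) together with the set of
coefficients to free; its :meth:`~RequirementModel.fit` runs either damped
least squares (Levenberg-Marquardt, the default) or full-batch gradient
descent with a geometrically decaying learning rate, and returns a
:class:`RequirementFitResults` carrying the estimates, their standard
errors, convergence diagnostics and a ``summary()`` table.

The objective stacks ME and CP prediction errors, each standardised by the
observed standard deviation of its target so the two scales are
commensurate:  cost = sum of squared standardised residuals.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .breeds import BreedProfile
from .core import predict_frame
from .exceptions import ConfigurationError, InvalidInputError
from .params import FITTABLE_PARAMETERS, ModelParameters
from .utils import round_half_up

__all__ = [
    "ObservationSet",
    "RequirementModel",
    "RequirementFitResults",
    "residuals",
    "fit_lm",
    "fit_gd",
    "rmse",
    "error_reduction",
]


@dataclass
class ObservationSet:
    """Flock records with observed intake-derived requirements.

    Wraps a DataFrame in the flock CSV schema with at least ``weight_kg``,
    ``bgw_g_per_d``, ``et_c``, ``observed_me_kj`` and ``observed_cp_g``
    columns; ``provenance`` records whether the rows were simulated or read
    from a file.
    """

    frame: pd.DataFrame
    provenance: str = "file"

    def __post_init__(self) -> None:
        if len(self.frame) < 1:
            raise InvalidInputError("ObservationSet needs at least one row")
        for col in ("weight_kg", "bgw_g_per_d", "et_c", "observed_me_kj", "observed_cp_g"):
            if col not in self.frame.columns:
                raise InvalidInputError(f"ObservationSet frame missing column {col!r}")
        for col in ("observed_me_kj", "observed_cp_g"):
            v = self.frame[col].to_numpy(float)
            if not np.isfinite(v).all() or (v <= 0).any():
                raise InvalidInputError(f"{col} must be positive and finite")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def observed_me(self) -> np.ndarray:
        return self.frame["observed_me_kj"].to_numpy(float)

    @property
    def observed_cp(self) -> np.ndarray:
        return self.frame["observed_cp_g"].to_numpy(float)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, provenance: str = "file") -> "ObservationSet":
        return cls(frame=frame.reset_index(drop=True), provenance=provenance)


def residuals(
    params: ModelParameters,
    obs: ObservationSet,
    scale: tuple[float, float] | None = None,
    registry: Mapping[str, BreedProfile] | None = None,
) -> np.ndarray:
    """Standardised prediction errors, ME block then CP block.

    ``(predicted - observed) / sd(observed)`` per target; ``scale`` overrides
    the two standard deviations (needed e.g. for single-row data, where the
    observed spread is degenerate).
    """
    pred_me, pred_cp = predict_frame(obs.frame, params, registry)
    if scale is None:
        sd_me = float(np.std(obs.observed_me))
        sd_cp = float(np.std(obs.observed_cp))
    else:
        sd_me, sd_cp = map(float, scale)
    if sd_me <= 0 or sd_cp <= 0:
        raise ConfigurationError(
            "zero-variance calibration target; supply scale=(sd_me, sd_cp) explicitly"
        )
    return np.concatenate(
        [(pred_me - obs.observed_me) / sd_me, (pred_cp - obs.observed_cp) / sd_cp]
    )


@dataclass
class RequirementFitResults:
    """Estimates and diagnostics from a :class:`RequirementModel` fit."""

    params: ModelParameters
    free: tuple[str, ...]
    estimates: dict[str, float]
    bse: dict[str, float]
    method: str
    iterations: int
    converged: bool
    cost_initial: float
    cost: float
    rmse_me: float
    rmse_cp: float
    final_damping: float | None = None
    final_learning_rate: float | None = None
    message: str = ""
    cost_history: list[float] = field(default_factory=list)

    def summary(self) -> str:
        """Human-readable parameter table and convergence report."""
        lines = [
            "Requirement model calibration",
            "=" * 58,
            f"method: {self.method}    converged: {self.converged}    "
            f"iterations: {self.iterations}",
            f"cost: {self.cost_initial:.6g} -> {self.cost:.6g}",
            f"RMSE   ME: {self.rmse_me:.4g} kJ/d    CP: {self.rmse_cp:.4g} g/d",
        ]
        if self.final_damping is not None:
            lines.append(f"final damping: {self.final_damping:.3g}")
        if self.final_learning_rate is not None:
            lines.append(f"final learning rate: {self.final_learning_rate:.3g}")
        if self.message:
            lines.append(f"note: {self.message}")
        lines += ["-" * 58, f"{'parameter':<12}{'estimate':>16}{'std err':>16}"]
        for name in self.free:
            se = self.bse.get(name, float("nan"))
            lines.append(f"{name:<12}{self.estimates[name]:>16.6g}{se:>16.4g}")
        lines.append("=" * 58)
        return "\n".join(lines)

    def to_dict(self) -> dict:
        """JSON/YAML-serialisable report."""
        return {
            "method": self.method,
            "free": list(self.free),
            "estimates": dict(self.estimates),
            "std_errors": dict(self.bse),
            "iterations": self.iterations,
            "converged": self.converged,
            "cost_initial": self.cost_initial,
            "cost_final": self.cost,
            "rmse_me_kj": self.rmse_me,
            "rmse_cp_g": self.rmse_cp,
            "final_damping": self.final_damping,
            "final_learning_rate": self.final_learning_rate,
            "message": self.message,
            "cost_history": list(self.cost_history),
        }


class RequirementModel:
    """The requirement equations viewed as a regression model.

    Parameters
    ----------
    obs : ObservationSet
        Observed flock records.
    free : sequence of str
        Coefficient names to estimate; a subset of ``alpha, beta, k3_cold,
        k3_heat, a, b, bc``.
    init : ModelParameters, optional
        Starting values (and the fixed values of non-free coefficients).
    registry : mapping, optional
        Breed registry; built-ins by default.
    """

    def __init__(
        self,
        obs: ObservationSet,
        free: Sequence[str] = ("alpha", "beta", "k3_cold"),
        init: ModelParameters | None = None,
        registry: Mapping[str, BreedProfile] | None = None,
    ) -> None:
        unknown = set(free) - set(FITTABLE_PARAMETERS)
        if unknown:
            raise ConfigurationError(
                f"cannot free {sorted(unknown)}; fittable: {FITTABLE_PARAMETERS}"
            )
        self.obs = obs
        self.free = tuple(free)
        self.init = ModelParameters() if init is None else init
        self.registry = registry
        sd_me = float(np.std(obs.observed_me))
        sd_cp = float(np.std(obs.observed_cp))
        if len(obs) > 1 and (sd_me <= 0 or sd_cp <= 0):
            raise ConfigurationError("degenerate (zero-variance) calibration target")
        self._scale = (sd_me, sd_cp) if sd_me > 0 and sd_cp > 0 else (1.0, 1.0)

    @classmethod
    def from_dataframe(
        cls, frame: pd.DataFrame, provenance: str = "file", **kwargs
    ) -> "RequirementModel":
        return cls(ObservationSet.from_dataframe(frame, provenance), **kwargs)

    # -- objective -----------------------------------------------------------

    def _params_at(self, theta: np.ndarray) -> ModelParameters:
        return self.init.with_values(**dict(zip(self.free, map(float, theta))))

    def residuals_at(self, theta: np.ndarray) -> np.ndarray:
        return residuals(self._params_at(theta), self.obs, self._scale, self.registry)

    def cost_at(self, theta: np.ndarray) -> float:
        r = self.residuals_at(theta)
        return float(r @ r)

    def jacobian_at(self, theta: np.ndarray) -> np.ndarray:
        """Finite-difference Jacobian of the residual vector (central)."""
        theta = np.asarray(theta, float)
        cols = []
        for i in range(len(theta)):
            h = max(1e-6 * abs(theta[i]), 1e-8)
            up, dn = theta.copy(), theta.copy()
            up[i] += h
            dn[i] -= h
            try:
                r_dn = self.residuals_at(dn)
            except InvalidInputError:
                # one-sided when the down-step leaves the valid domain
                dn = theta
                r_dn = self.residuals_at(theta)
                h /= 2.0
            cols.append((self.residuals_at(up) - r_dn) / (2.0 * h))
        return np.column_stack(cols)

    # -- fitting -------------------------------------------------------------

    def fit(self, method: str = "lm", **kwargs) -> RequirementFitResults:
        """Estimate the free coefficients.

        ``method="lm"`` — Levenberg-Marquardt damped least squares (damping
        starts at 1e-3, multiplied by 10 on a failed step and divided by 10
        on an accepted one; stops on relative cost change < ``tol`` or
        ``max_iter``).  ``method="gd"`` — full-batch gradient descent on
        normalised coefficients with learning rate ``lr0 * decay**epoch``.
        """
        theta0 = np.array([self.init.get(name) for name in self.free], float)
        if len(self.free) == 0:
            return self._results(
                theta0, method=method, iterations=0, converged=True,
                cost0=self.cost_at(theta0), history=[],
            )
        if method == "lm":
            return self._fit_lm(theta0, **kwargs)
        if method == "gd":
            return self._fit_gd(theta0, **kwargs)
        raise ConfigurationError(f"unknown fit method {method!r}")

    def _check_identifiability(self, J: np.ndarray) -> None:
        if np.linalg.matrix_rank(J) < J.shape[1]:
            warnings.warn(
                "free parameter set is not identifiable from these data "
                "(rank-deficient Jacobian at the starting values); "
                "estimates of confounded coefficients are arbitrary",
                stacklevel=3,
            )

    def _fit_lm(
        self,
        theta0: np.ndarray,
        max_iter: int = 200,
        tol: float = 1e-8,
        damping0: float = 1e-3,
    ) -> RequirementFitResults:
        theta = theta0.copy()
        cost = self.cost_at(theta)
        cost0 = cost
        lam = damping0
        history = [cost]
        converged = False
        message = ""
        it = 0
        for it in range(1, max_iter + 1):
            r = self.residuals_at(theta)
            J = self.jacobian_at(theta)
            if it == 1:
                self._check_identifiability(J)
            g = J.T @ r
            H = J.T @ J
            diag = np.diag(H).copy()
            diag[diag <= 0] = 1.0
            accepted = False
            for _ in range(60):  # escalate damping until a step is accepted
                try:
                    step = np.linalg.solve(H + lam * np.diag(diag), -g)
                except np.linalg.LinAlgError:
                    lam *= 10.0
                    continue
                trial = theta + step
                try:
                    trial_cost = self.cost_at(trial)
                except InvalidInputError:
                    lam *= 10.0
                    continue
                if trial_cost < cost:
                    rel = (cost - trial_cost) / max(cost, 1e-300)
                    theta, cost = trial, trial_cost
                    lam = max(lam / 10.0, 1e-15)
                    accepted = True
                    history.append(cost)
                    if rel < tol:
                        converged = True
                    break
                lam *= 10.0
                if lam > 1e14:
                    break
            if not accepted:
                converged = True  # no downhill step exists at machine scale
                message = "stalled: no further cost reduction achievable"
                break
            if converged:
                break
        else:
            message = "max_iter reached without meeting the tolerance"
        return self._results(
            theta, method="lm", iterations=it, converged=converged,
            cost0=cost0, history=history, final_damping=lam, message=message,
        )

    def _fit_gd(
        self,
        theta0: np.ndarray,
        lr0: float = 0.001,
        decay: float = 0.95,
        epochs: int = 500,
        seed: int | None = None,
        shuffle: bool = False,
    ) -> RequirementFitResults:
        if lr0 <= 0:
            raise InvalidInputError(f"lr0 must be positive, got {lr0}")
        if not 0.0 < decay <= 1.0:
            raise InvalidInputError(f"decay must lie in (0, 1], got {decay}")
        rng = np.random.default_rng(seed)
        if shuffle:  # full-batch: affects float summation order only
            order = rng.permutation(len(self.obs))
            frame = self.obs.frame.iloc[order].reset_index(drop=True)
            work_obs = ObservationSet(frame, self.obs.provenance)
            work = RequirementModel(work_obs, self.free, self.init, self.registry)
        else:
            work = self

        # per-parameter learning-rate scaling: descend in coordinates scaled
        # by the initial Jacobian column norms, so one global rate suits
        # coefficients three orders of magnitude apart and the step is
        # well-conditioned regardless of units
        J0 = work.jacobian_at(theta0)
        self._check_identifiability(J0)
        scale = np.linalg.norm(J0, axis=0)
        scale[scale <= 0] = 1.0

        def grad(th: np.ndarray) -> np.ndarray:
            g = np.empty(len(th))
            for i in range(len(th)):
                h = max(1e-6 * abs(th[i]), 1e-8)
                up, dn = th.copy(), th.copy()
                up[i] += h
                dn[i] -= h
                try:
                    c_dn = work.cost_at(dn)
                    g[i] = (work.cost_at(up) - c_dn) / (2.0 * h)
                except InvalidInputError:
                    g[i] = (work.cost_at(up) - work.cost_at(th)) / h
            return g

        theta = theta0.copy()
        cost = work.cost_at(theta)
        cost0 = cost
        best_theta, best_cost = theta.copy(), cost
        history = [cost]
        rising = 0
        lr = lr0
        message = ""
        converged = True
        ep = 0
        for ep in range(1, epochs + 1):
            lr = lr0 * decay ** (ep - 1)
            trial = theta - lr * grad(theta) / scale**2
            try:
                new_cost = work.cost_at(trial)
            except InvalidInputError:
                message = "aborted: step left the valid parameter domain"
                converged = False
                break
            theta = trial
            history.append(new_cost)
            if new_cost > cost:
                rising += 1
                if rising >= 10:
                    message = "aborted: cost rose for 10 consecutive epochs (diverging)"
                    converged = False
                    break
            else:
                rising = 0
            cost = new_cost
            if cost < best_cost:
                best_cost, best_theta = cost, theta.copy()
        return self._results(
            best_theta, method="gd", iterations=ep, converged=converged,
            cost0=cost0, history=history, final_lr=lr, message=message,
        )

    # -- results assembly ----------------------------------------------------

    def _results(
        self,
        theta: np.ndarray,
        method: str,
        iterations: int,
        converged: bool,
        cost0: float,
        history: list[float],
        final_damping: float | None = None,
        final_lr: float | None = None,
        message: str = "",
    ) -> RequirementFitResults:
        params = self._params_at(theta) if len(theta) else self.init
        pred_me, pred_cp = predict_frame(self.obs.frame, params, self.registry)
        cost = self.cost_at(theta) if len(theta) else self.cost_at(np.array([]))
        bse = {name: float("nan") for name in self.free}
        if len(self.free) and len(self.obs) * 2 > len(self.free):
            try:
                J = self.jacobian_at(theta)
                dof = 2 * len(self.obs) - len(self.free)
                sigma2 = cost / dof
                cov = sigma2 * np.linalg.inv(J.T @ J)
                bse = {
                    name: float(math.sqrt(max(cov[i, i], 0.0)))
                    for i, name in enumerate(self.free)
                }
            except np.linalg.LinAlgError:
                pass
        return RequirementFitResults(
            params=params,
            free=self.free,
            estimates={name: float(v) for name, v in zip(self.free, theta)},
            bse=bse,
            method=method,
            iterations=iterations,
            converged=converged,
            cost_initial=float(cost0),
            cost=float(cost),
            rmse_me=rmse(pred_me, self.obs.observed_me),
            rmse_cp=rmse(pred_cp, self.obs.observed_cp),
            final_damping=final_damping,
            final_learning_rate=final_lr,
            message=message,
            cost_history=[float(c) for c in history],
        )


# -- functional surface ------------------------------------------------------

def fit_lm(
    obs: ObservationSet,
    init: ModelParameters | None = None,
    free: Sequence[str] = ("alpha", "beta", "k3_cold"),
    max_iter: int = 200,
    tol: float = 1e-8,
    registry: Mapping[str, BreedProfile] | None = None,
) -> RequirementFitResults:
    """Levenberg-Marquardt calibration (see :meth:`RequirementModel.fit`)."""
    model = RequirementModel(obs, free=free, init=init, registry=registry)
    return model.fit(method="lm", max_iter=max_iter, tol=tol) if free else model.fit()


def fit_gd(
    obs: ObservationSet,
    init: ModelParameters | None = None,
    free: Sequence[str] = ("alpha", "beta", "k3_cold"),
    lr0: float = 0.001,
    decay: float = 0.95,
    epochs: int = 500,
    seed: int | None = None,
    shuffle: bool = False,
    registry: Mapping[str, BreedProfile] | None = None,
) -> RequirementFitResults:
    """Decaying-learning-rate gradient descent calibration."""
    model = RequirementModel(obs, free=free, init=init, registry=registry)
    if not free:
        return model.fit()
    return model.fit(
        method="gd", lr0=lr0, decay=decay, epochs=epochs, seed=seed, shuffle=shuffle
    )


def rmse(predicted: Sequence[float], observed: Sequence[float]) -> float:
    """Root mean squared error between paired vectors."""
    p = np.asarray(predicted, float)
    o = np.asarray(observed, float)
    if p.shape != o.shape or p.size < 1:
        raise InvalidInputError(
            f"predicted and observed must be equal-length, non-empty; got {p.shape} vs {o.shape}"
        )
    return float(np.sqrt(np.mean((p - o) ** 2)))


def error_reduction(err_traditional: float, err_dynamic: float) -> int:
    """Percent reduction of an error metric, rounded half-up to an integer:
    ``100 * (traditional - dynamic) / traditional``."""
    if err_traditional <= 0:
        raise InvalidInputError("err_traditional must be positive")
    if err_dynamic < 0:
        raise InvalidInputError("err_dynamic must be >= 0")
    return int(round_half_up(100.0 * (err_traditional - err_dynamic) / err_traditional, 0))
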