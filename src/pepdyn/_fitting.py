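"""Shared nonlinear least-squares machinery for the Model/Results classes.

Thin wrapper around :func:`scipy.optimize.least_squares` that adds the two
things every fit in this package reports: parameter standard errors from the
Jacobian at the solution, and an explicit ``converged`` flag (no fit is ever
allowed to fail silently).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = ["FitCore", "fit_least_squares", "BaseResults"]


@dataclass
class FitCore:
    """Raw optimizer output shared by every Results object."""

    params: np.ndarray
    stderr: np.ndarray
    converged: bool
    residual_norm: float
    n_obs: int
    message: str = ""

    @property
    def dof(self) -> int:
        return max(self.n_obs - len(self.params), 1)


def fit_least_squares(
    residual: Callable[[np.ndarray], np.ndarray],
    x0: Sequence[float],
    bounds: tuple[Sequence[float], Sequence[float]] | None = None,
    **kwargs,
) -> FitCore:
    """Bounded least squares with covariance-based standard errors.

    Standard errors are sqrt of the diagonal of ``s^2 (J^T J)^-1`` using the
    pseudo-inverse, so rank-deficient (degenerate) fits return large but
    finite errors instead of raising.
    """
    x0 = np.asarray(x0, dtype=float)
    if bounds is None:
        bounds = (-np.inf, np.inf)
    try:
        sol = least_squares(residual, x0, bounds=bounds, **kwargs)
    except Exception as exc:  # optimizer blow-up is a flagged result, not a crash
        return FitCore(
            params=x0,
            stderr=np.full(len(x0), np.inf),
            converged=False,
            residual_norm=np.inf,
            n_obs=0,
            message=f"optimizer raised: {exc}",
        )
    n_obs = len(sol.fun)
    dof = max(n_obs - len(x0), 1)
    s_sq = 2.0 * sol.cost / dof
    try:
        jtj_inv = np.linalg.pinv(sol.jac.T @ sol.jac)
        stderr = np.sqrt(np.clip(np.diag(jtj_inv) * s_sq, 0.0, None))
    except np.linalg.LinAlgError:
        stderr = np.full(len(x0), np.inf)
    return FitCore(
        params=sol.x,
        stderr=stderr,
        converged=bool(sol.success),
        residual_norm=float(np.sqrt(2.0 * sol.cost)),
        n_obs=n_obs,
        message=sol.message,
    )


@dataclass
class BaseResults:
    """Common surface of all fit Results: named estimates + uncertainties.

    Subclasses populate ``param_names`` and expose domain-specific derived
    quantities as properties.
    """

    core: FitCore
    param_names: tuple[str, ...] = field(default_factory=tuple)

    @property
    def converged(self) -> bool:
        return self.core.converged

    @property
    def params(self) -> dict[str, float]:
        return dict(zip(self.param_names, self.core.params))

    @property
    def bse(self) -> dict[str, float]:
        """Standard errors of the parameters (statsmodels naming)."""
        return dict(zip(self.param_names, self.core.stderr))

    def summary(self) -> str:
        lines = [
            f"{type(self).__name__}",
            f"  converged: {self.core.converged}  "
            f"residual norm: {self.core.residual_norm:.4g}  n: {self.core.n_obs}",
            f"  {'parameter':<16}{'estimate':>14}{'std err':>14}",
        ]
        for name, val, err in zip(
            self.param_names, self.core.params, self.core.stderr
        ):
            lines.append(f"  {name:<16}{val:>14.6g}{err:>14.3g}")
        return "\n".join(lines)
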