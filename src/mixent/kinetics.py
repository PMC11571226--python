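"""Exponential mixing/demixing kinetics fitted to an entropy trace.

Mixing and demixing traces are well described by single-exponential
relaxation

    Delta S(t) = Delta S_0 + Delta S_inf * (1 - exp(-t / tau)),

where ``Delta S_0`` is the initial entropy of mixing, ``Delta S_0 +
Delta S_inf`` the plateau, and ``tau`` the characteristic time constant
(demixing corresponds to negative ``Delta S_inf``).  The fit is a bounded
nonlinear least squares with ``tau`` log-parameterised (hence strictly
positive) and ``Delta S_0 >= 0``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .io import EntropyTrace

__all__ = ["KineticsFit", "fit_exponential"]


@dataclass
class KineticsFit:
    """Fitted relaxation parameters with uncertainties.

    ``covariance`` is the 3x3 covariance of ``(delta_S0, delta_Sinf, tau)``
    from the linearised least-squares solution; ``residual_rms`` is in R.
    """

    delta_S0: float
    delta_Sinf: float
    tau: float
    covariance: np.ndarray
    residual_rms: float
    converged: bool

    @property
    def plateau(self) -> float:
        """Long-time limit ``delta_S0 + delta_Sinf`` in R."""
        return self.delta_S0 + self.delta_Sinf

    def predict(self, times) -> np.ndarray:
        t = np.asarray(times, dtype=float)
        return self.delta_S0 + self.delta_Sinf * (1.0 - np.exp(-t / self.tau))

    def to_record(self) -> str:
        err = np.sqrt(np.clip(np.diag(self.covariance), 0, None))
        lines = [
            f"delta_S0_R = {self.delta_S0!r}",
            f"delta_Sinf_R = {self.delta_Sinf!r}",
            f"tau_ps = {self.tau!r}",
            f"plateau_R = {self.plateau!r}",
            f"stderr_delta_S0_R = {err[0]!r}",
            f"stderr_delta_Sinf_R = {err[1]!r}",
            f"stderr_tau_ps = {err[2]!r}",
            f"residual_rms_R = {self.residual_rms!r}",
            f"converged = {self.converged}",
        ]
        return "\n".join(lines) + "\n"


def _initial_guess(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    s0 = max(float(y[0]), 0.0)
    sinf = float(y[-1] - y[0])
    span = abs(sinf)
    tau = (t[-1] - t[0]) / 3.0
    if span > 0:
        crossed = np.nonzero(np.abs(y - y[0]) >= span / 2.0)[0]
        if crossed.size:
            t_half = float(t[crossed[0]] - t[0])
            if t_half > 0:
                tau = t_half / np.log(2.0)
    tau = max(tau, 1e-6 * max(t[-1] - t[0], 1.0))
    return s0, sinf, tau


def fit_exponential(trace: EntropyTrace, direction: str = "mixing"
                    ) -> KineticsFit:
    """Fit the exponential relaxation law to an entropy trace.

    ``direction`` ("mixing" or "demixing") only sanity-checks the sign of
    the initial amplitude guess; both signs of ``delta_Sinf`` are admitted
    by the model.  Requires at least five points and a non-flat trace.
    Optimizer failure is reported through ``converged=False`` rather than
    an exception.
    """
    if direction not in ("mixing", "demixing"):
        raise ValueError("direction must be 'mixing' or 'demixing'")
    t = np.asarray(trace.times, dtype=float)
    y = np.asarray(trace.values, dtype=float)
    if len(t) < 5:
        raise ValueError("at least 5 trace points are required for a fit")
    if not np.all(np.diff(t) > 0):
        raise ValueError("trace times must be strictly increasing")
    if float(np.var(y)) < 1e-12:
        raise ValueError("trace is flat; relaxation parameters are "
                         "non-identifiable")

    t0 = t[0]
    ts = t - t0  # fit in elapsed time; t=0 at the first sample

    def residuals(theta):
        s0, sinf, log_tau = theta
        return s0 + sinf * (1.0 - np.exp(-ts / np.exp(log_tau))) - y

    s0_0, sinf_0, tau_0 = _initial_guess(t, y)
    theta0 = np.array([s0_0, sinf_0, np.log(tau_0)])
    lo = np.array([0.0, -np.inf, np.log(tau_0) - 30.0])
    hi = np.array([np.inf, np.inf, np.log(tau_0) + 30.0])
    theta0 = np.clip(theta0, lo, hi)
    try:
        res = least_squares(residuals, theta0, bounds=(lo, hi), method="trf")
        ok = bool(res.success)
    except Exception:  # pragma: no cover - scipy failures are rare
        res = None
        ok = False
    if res is None:
        return KineticsFit(s0_0, sinf_0, tau_0, np.full((3, 3), np.nan),
                           float("nan"), False)
    s0, sinf, log_tau = res.x
    tau = float(np.exp(log_tau))
    n, p = len(y), 3
    rms = float(np.sqrt(np.mean(res.fun**2)))
    dof = max(n - p, 1)
    s2 = float(np.sum(res.fun**2)) / dof
    jtj = res.jac.T @ res.jac
    try:
        cov_theta = s2 * np.linalg.inv(jtj)
    except np.linalg.LinAlgError:
        cov_theta = np.full((3, 3), np.nan)
        ok = False
    # delta-method transform from log(tau) to tau
    g = np.diag([1.0, 1.0, tau])
    cov = g @ cov_theta @ g.T
    return KineticsFit(float(s0), float(sinf), tau, cov, rms, ok)
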