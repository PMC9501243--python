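"""Least-squares estimation of equivalent-circuit parameters from reactance.

The estimation problem: given one impedance sweep, find the coefficients
(a0, b0, c0, d0) — and optionally the free exponents (p1, p2) — of the
fractional reactance model

    X(ω) = a0 + b0·ω^p1·sin(p1π/2) + c0·ω^-0.5·sin(-π/4) + d0·ω^p2·sin(p2π/2)

that minimise the sum of squared reactance residuals.  Two stages mirror how
the model is used in practice:

* **fixed-exponent stage** — p1 = -1.5, p2 = +1 held fixed; the model is then
  *linear* in the four coefficients and the estimate is the exact ordinary
  (optionally weighted) linear least-squares solution on the design matrix
  [1, ω^-1.5·sin(-3π/4), ω^-0.5·sin(-π/4), ω^p2·sin(p2π/2)].
* **free-exponent stage** — p1 < 0 and p2 > 0 are estimated as well (the
  Warburg exponent stays at -0.5).  Solved by variable projection: a bounded
  nonlinear search over (p1, p2) in which the coefficients are profiled out
  by the linear solve at every candidate exponent pair, started from a
  deterministic list of exponent pairs to guard against local minima.

The API follows the Model/Results idiom: build a :class:`ReactanceModel`
from a spectrum, call :meth:`~ReactanceModel.fit`, and read estimates,
standard errors and diagnostics off the returned
:class:`ReactanceFitResults`.  Convenience wrappers fit replicate reactors
and whole time-courses and aggregate parameters across reactors.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .circuit import (
    WARBURG_EXPONENT,
    CircuitParams,
    P1_DEFAULT,
    P2_DEFAULT,
    canonical_model_reactance,
)
from .spectra import FrequencyGrid, ImpedanceSpectrum

__all__ = [
    "ReactanceModel",
    "ReactanceFitResults",
    "ReplicateSummary",
    "fit_fixed_exponents",
    "fit_free_exponents",
    "fit_replicates",
    "fit_timecourse",
    "PARAM_NAMES",
]

logger = logging.getLogger(__name__)

PARAM_NAMES = ("a0", "b0", "c0", "d0", "p1", "p2")
COEF_NAMES = ("a0", "b0", "c0", "d0")

#: Iteration budget of the optimiser (model-evaluation cap across all starts).
MAX_ITERATIONS_DEFAULT = 50_000

#: Deterministic start list for the free-exponent search: the canonical pair
#: first, then perturbed pairs spanning the admissible box.
EXPONENT_STARTS: tuple[tuple[float, float], ...] = (
    (-1.5, 1.0),
    (-0.5, 0.5),
    (-2.5, 1.5),
    (-1.0, 1.8),
    (-2.0, 0.25),
)

P1_BOUNDS_DEFAULT = (-3.0, -0.01)
P2_BOUNDS_DEFAULT = (0.01, 2.0)

MIN_POINTS_FIXED = 5
MIN_POINTS_FREE = 7


def _sin_half_pi(p: float) -> float:
    return math.sin(p * math.pi / 2.0)


def _design_matrix(omega: np.ndarray, p1: float, p2: float, fix_d0_zero: bool) -> np.ndarray:
    cols = [
        np.ones_like(omega),
        omega**p1 * _sin_half_pi(p1),
        omega**WARBURG_EXPONENT * _sin_half_pi(WARBURG_EXPONENT),
    ]
    if not fix_d0_zero:
        cols.append(omega**p2 * _sin_half_pi(p2))
    return np.column_stack(cols)


def _solve_linear(A: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, float]:
    """Weighted linear least squares with column equilibration.

    Returns (coefficients, weighted SSR).  Column scaling keeps the solve
    well-conditioned despite coefficient magnitudes spanning ~10 decades.
    """
    sw = np.sqrt(w)
    Aw = A * sw[:, None]
    yw = y * sw
    norms = np.linalg.norm(Aw, axis=0)
    if np.any(norms == 0) :
        raise np.linalg.LinAlgError("rank-deficient design matrix (zero column)")
    coef_s, _, rank, _ = np.linalg.lstsq(Aw / norms, yw, rcond=None)
    if rank < A.shape[1]:
        raise np.linalg.LinAlgError(
            "rank-deficient design matrix: too few distinct frequencies"
        )
    coef = coef_s / norms
    resid = yw - Aw @ coef
    return coef, float(resid @ resid)


class ReactanceModel:
    """Fractional reactance model bound to one measured sweep.

    Parameters
    ----------
    reactance : array-like
        Observed reactance X(ω) in Ω, one value per grid frequency
        (capacitive reactance negative).
    grid : FrequencyGrid
        Sweep frequencies.
    weighting : {"none", "inv_absX", "inv_absZ"}
        Residual weighting.  ``"none"`` (default) is the plain unweighted
        squared-reactance loss; ``"inv_absX"`` weights each residual by
        1/|X_obs|; ``"inv_absZ"`` by 1/|Z_obs| and requires construction
        :meth:`from_spectrum`.
    """

    def __init__(
        self,
        reactance: np.ndarray,
        grid: FrequencyGrid,
        weighting: str = "none",
        z: np.ndarray | None = None,
    ) -> None:
        x = np.asarray(reactance, dtype=float)
        if x.shape != (len(grid),):
            raise ValueError("reactance must have one value per grid frequency")
        if not np.all(np.isfinite(x)):
            raise ValueError("non-finite reactance value")
        self.endog = x
        self.grid = grid
        self.weighting = weighting
        self._z = None if z is None else np.asarray(z, dtype=complex)
        self.weights = self._build_weights()

    @classmethod
    def from_spectrum(cls, spectrum: ImpedanceSpectrum, weighting: str = "none") -> "ReactanceModel":
        return cls(spectrum.reactance, spectrum.grid, weighting=weighting, z=spectrum.z)

    def _build_weights(self) -> np.ndarray:
        if self.weighting == "none":
            return np.ones_like(self.endog)
        if self.weighting == "inv_absX":
            return 1.0 / np.maximum(np.abs(self.endog), 1e-30)
        if self.weighting == "inv_absZ":
            if self._z is None:
                raise ValueError("weighting 'inv_absZ' needs the full complex sweep; "
                                 "use ReactanceModel.from_spectrum")
            return 1.0 / np.maximum(np.abs(self._z), 1e-30)
        raise ValueError(f"unknown weighting {self.weighting!r}")

    @property
    def nobs(self) -> int:
        return self.endog.size

    # ------------------------------------------------------------------ fit

    def fit(
        self,
        free_exponents: bool = False,
        p1: float = P1_DEFAULT,
        p2: float = P2_DEFAULT,
        p1_bounds: tuple[float, float] = P1_BOUNDS_DEFAULT,
        p2_bounds: tuple[float, float] = P2_BOUNDS_DEFAULT,
        max_iterations: int = MAX_ITERATIONS_DEFAULT,
        starts: Sequence[tuple[float, float]] = EXPONENT_STARTS,
        fix_d0_zero: bool = False,
    ) -> "ReactanceFitResults":
        """Estimate the circuit parameters.

        With ``free_exponents=False`` the exponents are held at (p1, p2) and
        the coefficient estimate is the exact linear least-squares solution.
        With ``free_exponents=True`` the exponents are estimated inside the
        given bounds by deterministic multi-start variable projection.

        ``fix_d0_zero`` drops the inductive term entirely (d0 = 0), an option
        that is viable for sweeps insensitive to wiring inductance; d0 is
        never pinned to a nonzero constant, which destabilises the fit.
        """
        if free_exponents:
            return self._fit_free(p1_bounds, p2_bounds, max_iterations, starts, fix_d0_zero)
        return self._fit_fixed(p1, p2, fix_d0_zero)

    def _fit_fixed(self, p1: float, p2: float, fix_d0_zero: bool) -> "ReactanceFitResults":
        n_coef = 3 if fix_d0_zero else 4
        if self.nobs < MIN_POINTS_FIXED:
            raise ValueError(
                f"need at least {MIN_POINTS_FIXED} frequency points to fit "
                f"{n_coef} coefficients, got {self.nobs}"
            )
        omega = self.grid.omega
        A = _design_matrix(omega, p1, p2, fix_d0_zero)
        coef, ssr = _solve_linear(A, self.endog, self.weights)
        if fix_d0_zero:
            coef = np.append(coef, 0.0)
        params = CircuitParams(*coef, p1=p1, p2=p2)
        return ReactanceFitResults(
            model=self,
            params=params,
            ssr=ssr,
            n_iterations_used=1,
            converged=True,
            free_exponents=False,
            fix_d0_zero=fix_d0_zero,
        )

    def _fit_free(
        self,
        p1_bounds: tuple[float, float],
        p2_bounds: tuple[float, float],
        max_iterations: int,
        starts: Sequence[tuple[float, float]],
        fix_d0_zero: bool,
    ) -> "ReactanceFitResults":
        if self.nobs < MIN_POINTS_FREE:
            raise ValueError(
                f"need at least {MIN_POINTS_FREE} frequency points for the "
                f"free-exponent fit, got {self.nobs}"
            )
        omega = self.grid.omega
        lo = np.array([p1_bounds[0], p2_bounds[0]])
        hi = np.array([p1_bounds[1], p2_bounds[1]])

        def residuals(p: np.ndarray) -> np.ndarray:
            A = _design_matrix(omega, p[0], p[1], fix_d0_zero)
            try:
                coef, _ = _solve_linear(A, self.endog, self.weights)
            except np.linalg.LinAlgError:
                # large finite penalty; keeps trf away without overflowing
                return np.full_like(self.endog, 1e12)
            return np.sqrt(self.weights) * (self.endog - A @ coef)

        budget_per_start = max(50, max_iterations // max(len(starts), 1))
        best = None
        total_nfev = 0
        any_converged = False
        for start in starts:
            x0 = np.clip(np.asarray(start, dtype=float), lo, hi)
            try:
                sol = least_squares(
                    residuals,
                    x0,
                    bounds=(lo, hi),
                    method="trf",
                    xtol=1e-14,
                    ftol=1e-14,
                    gtol=1e-14,
                    max_nfev=budget_per_start,
                )
            except Exception:  # pragma: no cover - defensive
                continue
            total_nfev += sol.nfev
            any_converged = any_converged or (sol.status > 0)
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None:  # pragma: no cover - all starts raised
            raise RuntimeError("free-exponent fit failed from every start")

        p1_hat, p2_hat = best.x
        A = _design_matrix(omega, p1_hat, p2_hat, fix_d0_zero)
        coef, ssr = _solve_linear(A, self.endog, self.weights)
        if fix_d0_zero:
            coef = np.append(coef, 0.0)
        params = CircuitParams(*coef, p1=p1_hat, p2=p2_hat)
        return ReactanceFitResults(
            model=self,
            params=params,
            ssr=ssr,
            n_iterations_used=total_nfev,
            converged=any_converged,
            free_exponents=True,
            fix_d0_zero=fix_d0_zero,
        )

    # ------------------------------------------------------------ internals

    def predict(self, params: CircuitParams) -> np.ndarray:
        return canonical_model_reactance(params, self.grid)

    def jacobian(self, params: CircuitParams, free_exponents: bool) -> np.ndarray:
        """Analytic Jacobian of the model reactance w.r.t. the parameters.

        Columns follow :data:`PARAM_NAMES`; exponent columns are included
        only for free-exponent fits.
        """
        w = self.grid.omega
        lnw = np.log(w)

        def term(p: float) -> np.ndarray:
            return w**p * _sin_half_pi(p)

        def dterm_dp(coeff: float, p: float) -> np.ndarray:
            return coeff * w**p * (lnw * _sin_half_pi(p)
                                   + (math.pi / 2.0) * math.cos(p * math.pi / 2.0))

        cols = [np.ones_like(w), term(params.p1), term(WARBURG_EXPONENT), term(params.p2)]
        if free_exponents:
            cols.append(dterm_dp(params.b0, params.p1))
            cols.append(dterm_dp(params.d0, params.p2))
        return np.column_stack(cols)


@dataclass
class ReactanceFitResults:
    """Estimates and diagnostics of one reactance fit.

    ``params`` carries the point estimates; ``bse`` their asymptotic standard
    errors from the Gauss–Newton covariance σ²(JᵀWJ)⁻¹; ``ssr`` the (weighted)
    sum of squared reactance residuals in Ω².  ``negated_report`` gives the
    sign-flipped coefficient tuple (−a0, −b0, −c0, −d0) conventionally used
    when plotting parameter trajectories of capacitive systems.
    """

    model: ReactanceModel
    params: CircuitParams
    ssr: float
    n_iterations_used: int
    converged: bool
    free_exponents: bool
    fix_d0_zero: bool = False

    @property
    def nobs(self) -> int:
        return self.model.nobs

    @property
    def n_params(self) -> int:
        k = 3 if self.fix_d0_zero else 4
        return k + (2 if self.free_exponents else 0)

    @property
    def df_resid(self) -> int:
        return self.nobs - self.n_params

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.model.predict(self.params)

    @property
    def resid(self) -> np.ndarray:
        return self.model.endog - self.fittedvalues

    @property
    def scale(self) -> float:
        """Residual variance estimate σ² = SSR / (n − k)."""
        return self.ssr / self.df_resid if self.df_resid > 0 else float("nan")

    def cov_params(self) -> np.ndarray:
        """Asymptotic covariance of (a0, b0, c0, d0[, p1, p2])."""
        J = self.model.jacobian(self.params, self.free_exponents)
        if self.fix_d0_zero:
            keep = [0, 1, 2] + ([4, 5] if self.free_exponents else [])
            J = J[:, keep]
        # column equilibration keeps the inverse sane across the ~10-decade
        # spread of coefficient scales
        norms = np.linalg.norm(J, axis=0)
        norms[norms == 0] = 1.0
        Js = J / norms
        JW = Js * self.model.weights[:, None]
        cov_scaled = self.scale * np.linalg.pinv(Js.T @ JW)
        return cov_scaled / np.outer(norms, norms)

    @property
    def bse(self) -> pd.Series:
        names = list(COEF_NAMES[: 3 if self.fix_d0_zero else 4])
        if self.free_exponents:
            names += ["p1", "p2"]
        with np.errstate(invalid="ignore"):
            se = np.sqrt(np.diag(self.cov_params()))
        out = pd.Series(0.0, index=list(PARAM_NAMES))
        out[names] = se
        return out

    @property
    def negated_report(self) -> tuple[float, float, float, float]:
        p = self.params
        return (-p.a0, -p.b0, -p.c0, -p.d0)

    def summary(self) -> str:
        p = self.params
        se = self.bse
        lines = [
            "Fractional reactance model fit",
            "=" * 46,
            f"{'n frequencies':<22}{self.nobs:>10d}",
            f"{'stage':<22}{'free-exponent' if self.free_exponents else 'fixed-exponent':>14}",
            f"{'weighting':<22}{self.model.weighting:>10}",
            f"{'SSR (Ω²)':<22}{self.ssr:>14.6g}",
            f"{'iterations used':<22}{self.n_iterations_used:>10d}",
            f"{'converged':<22}{str(self.converged):>10}",
            "-" * 46,
            f"{'param':<8}{'estimate':>14}{'std err':>14}",
        ]
        for name in PARAM_NAMES:
            val = getattr(p, name)
            lines.append(f"{name:<8}{val:>14.6g}{se[name]:>14.3g}")
        lines.append("-" * 46)
        neg = self.negated_report
        lines.append(
            "negated report (−a0, −b0, −c0, −d0): "
            + ", ".join(f"{v:.6g}" for v in neg)
        )
        return "\n".join(lines)

    def plot_fit(self, ax=None):
        """Observed vs fitted reactance against frequency (log-x)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        f = self.model.grid.frequencies
        ax.semilogx(f, self.model.endog, "o", ms=3, label="observed X")
        ax.semilogx(f, self.fittedvalues, "-", label="fitted X")
        ax.set_xlabel("frequency (Hz)")
        ax.set_ylabel("reactance X (Ω)")
        ax.legend()
        return ax


# ------------------------------------------------------------- conveniences


def fit_fixed_exponents(spectrum: ImpedanceSpectrum, **kwargs) -> ReactanceFitResults:
    """Fixed-exponent fit of one sweep (p1 = -1.5, p2 = 1 by default)."""
    weighting = kwargs.pop("weighting", "none")
    return ReactanceModel.from_spectrum(spectrum, weighting=weighting).fit(
        free_exponents=False, **kwargs
    )


def fit_free_exponents(spectrum: ImpedanceSpectrum, **kwargs) -> ReactanceFitResults:
    """Free-exponent fit of one sweep (p1, p2 estimated; Warburg at -0.5)."""
    weighting = kwargs.pop("weighting", "none")
    return ReactanceModel.from_spectrum(spectrum, weighting=weighting).fit(
        free_exponents=True, **kwargs
    )


@dataclass
class ReplicateSummary:
    """Per-parameter mean and sample standard deviation across reactors
    fitted independently at one sampling time."""

    time_h: float
    condition: str
    n_reactors: int
    mean: dict[str, float]
    std: dict[str, float]
    residual_ss_mean: float
    fits: list[ReactanceFitResults] = field(default_factory=list, repr=False)


def fit_replicates(
    spectra_at_time: Sequence[ImpedanceSpectrum], **fit_kwargs
) -> ReplicateSummary:
    """Fit each replicate reactor independently, then average the parameters.

    All sweeps must share one condition and one sampling time.  The spread is
    the sample standard deviation (ddof=1), defined as 0 for a single reactor.
    """
    if len(spectra_at_time) < 1:
        raise ValueError("need at least one spectrum")
    conditions = {sp.condition for sp in spectra_at_time}
    times = {sp.time_h for sp in spectra_at_time}
    if len(conditions) > 1:
        raise ValueError(f"mixed conditions in one replicate group: {sorted(conditions)}")
    if len(times) > 1:
        raise ValueError(f"mixed sampling times in one replicate group: {sorted(times)}")

    fits = [fit_fixed_exponents(sp, **fit_kwargs) for sp in spectra_at_time]
    table = np.array([[getattr(r.params, n) for n in COEF_NAMES] for r in fits])
    mean = dict(zip(COEF_NAMES, table.mean(axis=0)))
    if len(fits) > 1:
        std = dict(zip(COEF_NAMES, table.std(axis=0, ddof=1)))
    else:
        std = dict.fromkeys(COEF_NAMES, 0.0)
    return ReplicateSummary(
        time_h=times.pop(),
        condition=conditions.pop(),
        n_reactors=len(fits),
        mean=mean,
        std=std,
        residual_ss_mean=float(np.mean([r.ssr for r in fits])),
        fits=fits,
    )


def fit_timecourse(spectra: Sequence[ImpedanceSpectrum], **fit_kwargs) -> pd.DataFrame:
    """Fit every sweep of a time-course and summarise per (condition, hour).

    Returns a table with one row per (condition, time_h): replicate means
    and sample standard deviations of a0…d0 plus residual statistics,
    suitable for direct CSV export and for the growth-correlation step.
    """
    groups: dict[tuple[str, float], list[ImpedanceSpectrum]] = {}
    for sp in spectra:
        groups.setdefault((sp.condition, sp.time_h), []).append(sp)

    rows = []
    for (condition, time_h) in sorted(groups):
        group = groups[(condition, time_h)]
        if not group:  # pragma: no cover - defensive
            logger.warning("empty group (%s, %s h): skipped", condition, time_h)
            continue
        summ = fit_replicates(group, **fit_kwargs)
        row: dict[str, object] = {
            "time_h": time_h,
            "condition": condition,
            "n_reactors": summ.n_reactors,
        }
        for name in COEF_NAMES:
            row[f"{name}_mean"] = summ.mean[name]
            row[f"{name}_std"] = summ.std[name]
        row["residual_ss_mean"] = summ.residual_ss_mean
        rows.append(row)
    return pd.DataFrame(rows)
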