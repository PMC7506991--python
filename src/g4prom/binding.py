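"""Ligand-depletion binding isotherm for fluorescence anisotropy titrations.

One-to-one binding of a protein P to a labelled DNA ligand L at fixed total
ligand concentration. Because the labelled-DNA concentration (10 nM in the
assays this models) is not negligible relative to the dissociation constant,
the bound fraction is the quadratic (Morrison) mass-action solution rather
than the hyperbolic approximation:

    f = C / L_t,   C = 2 P_t L_t / [(P_t + L_t + Kd) + sqrt((P_t + L_t + Kd)^2 - 4 P_t L_t)]

which is the numerically stable form of the usual root (no catastrophic
cancellation at small f). Anisotropy mixes linearly with bound fraction,
r = r_free + (r_bound - r_free) * f, valid when the fluorophore quantum
yield does not change on binding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares


@dataclass(frozen=True)
class TitrationSeries:
    """One titration: anisotropy vs total protein at fixed labelled DNA."""

    protein_totals: np.ndarray  # molar, strictly increasing
    readings: np.ndarray  # anisotropy, same length
    l_total: float  # molar
    replicate_sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.protein_totals, dtype=float)
        r = np.asarray(self.readings, dtype=float)
        object.__setattr__(self, "protein_totals", p)
        object.__setattr__(self, "readings", r)
        if self.l_total <= 0:
            raise ValueError("l_total must be positive")
        if p.ndim != 1 or p.shape != r.shape:
            raise ValueError("protein grid and readings must be equal-length 1-D arrays")
        if (p < 0).any():
            raise ValueError("protein concentrations must be non-negative")
        if not (np.diff(p) > 0).all():
            raise ValueError("protein grid must be strictly increasing")
        if not np.isfinite(r).all():
            raise ValueError("readings must be finite")
        if self.replicate_sd is not None:
            sd = np.asarray(self.replicate_sd, dtype=float)
            object.__setattr__(self, "replicate_sd", sd)
            if sd.shape != r.shape or (sd <= 0).any():
                raise ValueError("replicate_sd must be positive and match readings")


@dataclass(frozen=True)
class BindingFitResult:
    kd: float | None
    r_free: float | None
    r_bound: float | None
    kd_se: float | None
    r_free_se: float | None
    r_bound_se: float | None
    rss: float | None
    converged: bool
    status: str  # "ok" | "no-binding-detected" | "not-converged"


def fraction_bound(p_total, l_total: float, kd: float):
    """Bound fraction of the labelled ligand under ligand depletion.

    Accepts a scalar or array of total protein concentrations; all
    concentrations in the same (molar) units.
    """
    if l_total <= 0:
        raise ValueError("l_total must be positive")
    if kd <= 0:
        raise ValueError("kd must be positive")
    p = np.asarray(p_total, dtype=float)
    if (p < 0).any():
        raise ValueError("p_total must be non-negative")
    s = p + l_total + kd
    disc = np.sqrt(s * s - 4.0 * p * l_total)
    complex_conc = 2.0 * p * l_total / (s + disc)
    f = complex_conc / l_total
    f = np.clip(f, 0.0, 1.0)
    return float(f) if np.isscalar(p_total) else f


def predict_anisotropy(p_total, l_total: float, kd: float, r_free: float, r_bound: float):
    """Model anisotropy: linear mixing of free and bound end states."""
    f = fraction_bound(p_total, l_total, kd)
    return r_free + (r_bound - r_free) * f


def fit_isotherm(
    series: TitrationSeries,
    init: tuple[float, float, float] | None = None,
) -> BindingFitResult:
    """Least-squares fit of (Kd, r_free, r_bound) to a titration series.

    Kd is optimised on a log scale (positivity by construction). Automatic
    initialisation takes r_free/r_bound from the extreme readings and Kd
    from the protein concentration nearest the half-maximal signal.
    Parameter standard errors come from the local curvature (Gauss-Newton
    J^T J) of the objective at the optimum. A flat series returns a
    ``no-binding-detected`` status instead of a fitted Kd, and
    non-convergence is reported explicitly.
    """
    p = series.protein_totals
    r = series.readings
    if p.size < 4:
        raise ValueError("need at least 4 titration points")
    span = float(np.ptp(r))
    if span == 0.0:
        return BindingFitResult(None, None, None, None, None, None, None, False, "no-binding-detected")

    if init is None:
        r_free0 = float(r.min())
        r_bound0 = float(r.max())
        half = 0.5 * (r_free0 + r_bound0)
        pos = p[p > 0]
        kd0 = float(pos[np.argmin(np.abs(r[p > 0] - half))]) if pos.size else 1.0
    else:
        kd0, r_free0, r_bound0 = init
        if kd0 <= 0:
            raise ValueError("initial kd must be positive")

    w = 1.0 / series.replicate_sd if series.replicate_sd is not None else 1.0

    def resid(x):
        log_kd, rf, rb = x
        return (predict_anisotropy(p, series.l_total, math.exp(log_kd), rf, rb) - r) * w

    sol = least_squares(
        resid,
        x0=[math.log(kd0), r_free0, r_bound0],
        method="trf",
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    kd = math.exp(sol.x[0])
    rss = float(np.sum(sol.fun**2))
    if not sol.success:
        return BindingFitResult(kd, sol.x[1], sol.x[2], None, None, None, rss, False, "not-converged")

    dof = max(p.size - 3, 1)
    sigma2 = rss / dof
    jtj = sol.jac.T @ sol.jac
    try:
        cov = sigma2 * np.linalg.inv(jtj)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
        kd_se = kd * se[0]  # delta method from the log scale
        rf_se, rb_se = float(se[1]), float(se[2])
    except np.linalg.LinAlgError:
        kd_se = rf_se = rb_se = float("nan")
    return BindingFitResult(
        kd=kd,
        r_free=float(sol.x[1]),
        r_bound=float(sol.x[2]),
        kd_se=float(kd_se),
        r_free_se=rf_se,
        r_bound_se=rb_se,
        rss=rss,
        converged=True,
        status="ok",
    )
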