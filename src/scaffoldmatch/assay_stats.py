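"""Assay-side calculations for transendothelial migration experiments.

Covers the quantitative readouts that accompany a peptide-grafting
campaign: migration normalizations (% inhibition vs the untreated
control, migration index vs an epitope-treated control), the constrained
three-parameter concentration-response fit for EC50 (top fixed at 100%,
Hill slope fixed at 1), the one-phase exponential decay fit for serum
half-life, and two transwell monolayer quality metrics, TEER and the
apparent permeability coefficient Papp.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "DoseResponseFit",
    "DecayFit",
    "percent_inhibition",
    "migration_index",
    "fit_ec50",
    "fit_decay",
    "teer",
    "papp",
]


def percent_inhibition(treated_count: float, untreated_count: float) -> float:
    """100 x (1 - treated/untreated); negative means enhanced migration."""
    if untreated_count <= 0:
        raise ValueError("untreated control count must be positive")
    return 100.0 * (1.0 - treated_count / untreated_count)


def migration_index(treated_count: float, control_count: float) -> float:
    """Migrated-cell ratio relative to an epitope-treated control (= 1.0)."""
    if control_count <= 0:
        raise ValueError("control count must be positive")
    return treated_count / control_count


@dataclass
class DoseResponseFit:
    ec50: float
    bottom: float
    rss: float
    converged: bool
    top: float = 100.0
    slope: float = 1.0
    reason: str = ""

    def predict(self, c: np.ndarray) -> np.ndarray:
        c = np.asarray(c, dtype=float)
        return self.bottom + (self.top - self.bottom) / (
            1.0 + 10.0 ** (np.log10(c) - math.log10(self.ec50))
        )


def _drc_model(log_ec50: float, bottom: float, logc: np.ndarray) -> np.ndarray:
    return bottom + (100.0 - bottom) / (1.0 + 10.0 ** (logc - log_ec50))


def fit_ec50(
    concentrations: np.ndarray,
    responses: np.ndarray,
    min_signal: float = 5.0,
) -> DoseResponseFit:
    """Constrained three-parameter inhibition fit: top = 100, slope = 1.

    Y = bottom + (100 - bottom) / (1 + 10^(log10 c - log10 EC50)),
    with responses in % of the untreated control.  The fit is least
    squares in linear response space, parameterized in log10(EC50), with
    a deterministic multi-start over an EC50 grid spanning the measured
    concentration range to avoid local minima.  A flat series (fitted
    span below ``min_signal`` %) is reported as not converged.
    """
    c = np.asarray(concentrations, dtype=float)
    y = np.asarray(responses, dtype=float)
    if c.shape != y.shape:
        raise ValueError("concentrations and responses must have equal length")
    if np.any(c <= 0):
        raise ValueError("concentrations must be positive")
    if len(np.unique(c)) < 4:
        raise ValueError("need at least 4 distinct concentrations")
    logc = np.log10(c)

    starts = np.linspace(logc.min(), logc.max(), 5)
    # the plateau is a migrated-cell fraction of the control: 0..100 %
    b0 = float(np.clip(y.min(), 0.0, 100.0))
    best = None
    for s in starts:
        res = least_squares(
            lambda p: _drc_model(p[0], p[1], logc) - y,
            x0=[s, b0],
            bounds=([logc.min() - 6, 0.0], [logc.max() + 6, 100.0]),
        )
        if best is None or res.cost < best.cost:
            best = res
    log_ec50, bottom = best.x
    rss = float(2 * best.cost)
    fit = DoseResponseFit(
        ec50=float(10.0**log_ec50), bottom=float(bottom), rss=rss, converged=True
    )
    if (100.0 - bottom) < min_signal:
        fit.converged = False
        fit.reason = "no inhibition signal (response flat near 100%)"
    return fit


@dataclass
class DecayFit:
    k: float  # 1/h
    y0: float  # % at t = 0
    plateau: float  # %
    rss: float
    converged: bool
    reason: str = ""

    @property
    def half_life(self) -> float:
        return math.log(2) / self.k

    def half_life_label(self, t_max: float) -> str:
        """Report '>T' when no decay could be resolved within the series."""
        if self.converged:
            return f"{self.half_life:.1f}"
        return f">{t_max:g}"

    def predict(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return (self.y0 - self.plateau) * np.exp(-self.k * t) + self.plateau


def fit_decay(
    times: np.ndarray,
    remaining: np.ndarray,
    min_drop: float = 5.0,
) -> DecayFit:
    """One-phase decay fit Y = (Y0 - plateau) exp(-k t) + plateau.

    ``remaining`` is % intact relative to t = 0 (= 100).  Plateau is
    bounded in [0, 100].  A series whose fitted curve drops by less than
    ``min_drop`` % over the measured window (e.g. a stable peptide) is
    reported as not converged; report such peptides as '>t_max'.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(remaining, dtype=float)
    if t.shape != y.shape or len(t) < 3:
        raise ValueError("need at least 3 (time, remaining) points")
    if not np.any(t == 0):
        raise ValueError("series must include t = 0 (normalized to 100)")
    t_max = float(t.max())
    if t_max <= 0:
        raise ValueError("series must extend past t = 0")

    def resid(p):
        k, y0, plateau = p
        return (y0 - plateau) * np.exp(-k * t) + plateau - y

    # start k from a log-linear guess, fall back to a mid-window rate
    k0 = 1.0 / t_max
    drop = y[np.argsort(t)]
    if drop[-1] < 50.0:
        k0 = math.log(2) / (0.5 * t_max)
    res = least_squares(
        resid,
        x0=[k0, 100.0, 0.0],
        bounds=([1e-9, 50.0, 0.0], [np.inf, 150.0, 100.0]),
    )
    k, y0, plateau = res.x
    fit = DecayFit(k=float(k), y0=float(y0), plateau=float(plateau),
                   rss=float(2 * res.cost), converged=True)
    fitted_drop = fit.predict(np.array([0.0]))[0] - fit.predict(np.array([t_max]))[0]
    if fitted_drop < min_drop or fit.half_life > 10 * t_max:
        fit.converged = False
        fit.reason = "no resolvable decay within the measured window"
    return fit


def teer(resistance_monolayer: float, resistance_blank: float, area: float) -> float:
    """Transendothelial electrical resistance, Ohm * cm^2.

    (monolayer resistance - blank insert resistance) x insert area.
    Negative values are physically suspect but returned as-is.
    """
    if area <= 0:
        raise ValueError("insert area must be positive")
    return (resistance_monolayer - resistance_blank) * area


def papp(
    c_abluminal: float,
    v_abluminal: float,
    area: float,
    c_luminal: float,
    t: float,
) -> float:
    """Apparent permeability coefficient, cm/s.

    Papp = (C_abluminal x V_abluminal) / (area x C_luminal x t), with the
    abluminal volume in cm^3 (mL), area in cm^2, time in seconds and both
    concentrations in the same units.
    """
    if area <= 0 or c_luminal <= 0 or t <= 0:
        raise ValueError("area, luminal concentration and time must be positive")
    return (c_abluminal * v_abluminal) / (area * c_luminal * t)
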