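"""Single-timepoint phosphatase kinetics.

The plate assay measures phosphate released from a phosphopeptide
dilution series after a fixed incubation (15 min by default).  With
substrate depletion neglected over that window, product obeys the
single-timepoint Michaelis-Menten form

    P = t * E * (kcat/KM) * C / (C/KM + 1)

(P product in uM, t minutes, E enzyme activity in units U, C initial
substrate in uM).  One unit U is the amount of enzyme releasing 15 uM
phosphate in 15 min from 125 uM of the standard peptide, so kcat is
expressed per unit rather than per molar enzyme; the specificity
constant kcat/KM is reported on that per-unit scale (printed unit
string "uM*min^-1*U^-1").

Because the fit is linear in kcat/KM once KM is fixed, fitting reduces
to a one-dimensional profile over KM with an analytic slope, which is
also how the profile-likelihood reliability interval for KM is built.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

#: standard assay conditions for the unit definition
STANDARD_SUBSTRATE_UM = 125.0
STANDARD_TIME_MIN = 15.0
STANDARD_PHOSPHATE_PER_UNIT_UM = 15.0


@dataclass(frozen=True)
class DilutionSeries:
    """Serial dilution of substrate in the reaction plate.

    40 ul of peptide (1.5-fold serial dilution from 1 mM) receives
    10 ul of enzyme, so the in-reaction concentration is the dilution
    value times ``mix_factor`` = 40/50.
    """

    top_concentration: float = 1000.0  # uM, pre-mix
    fold: float = 1.5
    n_steps: int = 16
    mix_factor: float = 40.0 / 50.0

    def __post_init__(self) -> None:
        if not self.fold > 1:
            raise ValueError("dilution fold must exceed 1")
        if not 0 < self.mix_factor <= 1:
            raise ValueError("mix_factor must be in (0, 1]")


def final_concentrations(series: DilutionSeries) -> np.ndarray:
    """In-reaction substrate concentrations (uM), highest first."""
    if series.n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    i = np.arange(series.n_steps)
    return series.top_concentration * series.mix_factor / series.fold ** i


@dataclass(frozen=True)
class StandardCurve:
    """Linear phosphate standard curve: A620 = slope * [Pi] + intercept."""

    slope: float  # absorbance per uM phosphate
    intercept: float = 0.0

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise ValueError("standard-curve slope must be positive")


def fit_standard_curve(phosphate_um: np.ndarray,
                       a620: np.ndarray) -> StandardCurve:
    """Least-squares line through standard readings."""
    res = stats.linregress(np.asarray(phosphate_um, float),
                           np.asarray(a620, float))
    return StandardCurve(slope=float(res.slope), intercept=float(res.intercept))


def absorbance_to_phosphate(a620, curve: StandardCurve):
    """Invert the standard curve; sub-blank readings clamp to 0.

    Returns ``(phosphate_um, n_clamped)`` where ``n_clamped`` counts
    readings below the curve intercept.
    """
    a = np.asarray(a620, dtype=float)
    p = (a - curve.intercept) / curve.slope
    n_clamped = int(np.sum(p < 0))
    return np.clip(p, 0.0, None), n_clamped


def mm_product(conc, t: float, enzyme: float,
               kcat_over_km: float, km: float):
    """Predicted product P = t*E*(kcat/KM)*C/(C/KM + 1)."""
    c = np.asarray(conc, dtype=float)
    return t * enzyme * kcat_over_km * c / (c / km + 1.0)


@dataclass
class KineticFit:
    """Result of the single-timepoint fit.

    ``kcat_over_km`` is the specificity constant per enzyme unit (the
    low-C limit of P/(t*E*C)); ``km`` in uM.  ``km_reliable`` is False
    when KM exceeds the highest assayed concentration or its 95%
    profile-likelihood interval spans more than a decade — the assay
    then only constrains kcat/KM.  ``km_ci`` is the (lo, hi) profile
    interval; ``kcat_per_unit = kcat_over_km * km`` (uM/min per U).
    """

    kcat_over_km: float
    km: float
    km_reliable: bool
    residual_sse: float
    km_ci: tuple[float, float] = (np.nan, np.nan)

    @property
    def kcat_per_unit(self) -> float:
        return self.kcat_over_km * self.km


def _profile_sse(km: float, conc: np.ndarray, product: np.ndarray,
                 t: float, enzyme: float) -> tuple[float, float]:
    """Best kcat/KM and SSE at fixed KM (linear least squares)."""
    x = t * enzyme * conc / (conc / km + 1.0)
    denom = float(np.dot(x, x))
    a = max(float(np.dot(x, product)) / denom, 0.0) if denom > 0 else 0.0
    r = product - a * x
    return a, float(np.dot(r, r))


def fit_single_timepoint_mm(conc, product, t: float,
                            enzyme: float) -> KineticFit:
    """Fit the single-timepoint Michaelis-Menten model.

    Requires >= 4 distinct concentrations, t > 0, enzyme > 0 and a
    non-zero product signal.  KM is profiled on a log grid spanning
    well beyond the assayed range and refined by bounded minimisation;
    the 95% profile-likelihood interval drives ``km_reliable``.
    """
    conc = np.asarray(conc, dtype=float)
    product = np.asarray(product, dtype=float)
    if len(np.unique(conc)) < 4:
        raise ValueError("need at least 4 distinct substrate concentrations")
    if not t > 0:
        raise ValueError("incubation time must be positive")
    if not enzyme > 0:
        raise ValueError("enzyme activity must be positive")
    if np.allclose(product, 0.0):
        raise ValueError("all product readings are zero")

    c_lo, c_hi = conc.min(), conc.max()
    grid = np.geomspace(c_lo / 100.0, c_hi * 1000.0, 400)
    sse_grid = np.array([_profile_sse(km, conc, product, t, enzyme)[1]
                         for km in grid])
    i_best = int(np.argmin(sse_grid))

    lo = grid[max(i_best - 1, 0)]
    hi = grid[min(i_best + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        lambda lk: _profile_sse(np.exp(lk), conc, product, t, enzyme)[1],
        bounds=(np.log(lo), np.log(hi)), method="bounded",
        options={"xatol": 1e-12})
    km = float(np.exp(res.x))
    kcat_over_km, sse = _profile_sse(km, conc, product, t, enzyme)

    # 95% profile-likelihood interval: SSE threshold from the F(1, n-2)
    # quantile, with a tiny absolute floor so noise-free fits (SSE ~ 0)
    # still yield a finite interval.
    n = len(conc)
    dof = max(n - 2, 1)
    f_crit = stats.f.ppf(0.95, 1, dof)
    floor = 1e-12 * float(np.dot(product, product))
    threshold = sse * (1.0 + f_crit / dof) + floor
    inside = sse_grid <= threshold
    if inside.any():
        ci_lo = float(grid[inside].min())
        ci_hi = float(grid[inside].max())
    else:  # only the refined optimum is below threshold
        ci_lo = ci_hi = km
    open_ended = inside[0] or inside[-1]
    decade_span = ci_hi / ci_lo if ci_lo > 0 else np.inf
    km_reliable = (km <= c_hi) and (decade_span <= 10.0) and not open_ended
    return KineticFit(kcat_over_km=kcat_over_km, km=km,
                      km_reliable=km_reliable, residual_sse=sse,
                      km_ci=(ci_lo, ci_hi))


def calibrate_activity(p15: float) -> float:
    """Enzyme activity (U) from phosphate released in the standard assay.

    One unit generates 15 uM phosphate in 15 min from 125 uM standard
    peptide, so activity = p15 / 15; linear in enzyme amount.
    """
    if p15 < 0:
        raise ValueError("phosphate concentration cannot be negative")
    return p15 / STANDARD_PHOSPHATE_PER_UNIT_UM


@dataclass
class PnppFit:
    """Hyperbolic fit of the pNPP normalisation assay.

    ``vmax`` is the saturating product signal (A405 scale), ``km_mm``
    the half-saturation pNPP concentration in mM.
    """

    vmax: float
    km_mm: float
    residual_sse: float

    def predict(self, conc_mm):
        c = np.asarray(conc_mm, dtype=float)
        return self.vmax * c / (c + self.km_mm)


def fit_pnpp(conc_mm, a405) -> PnppFit:
    """Fit product signal vs pNPP concentration to a hyperbola.

    Duplicate concentrations are averaged before fitting.  Used to
    scale activities across different phosphatase preparations.
    """
    conc_mm = np.asarray(conc_mm, dtype=float)
    a405 = np.asarray(a405, dtype=float)
    uniq, inv = np.unique(conc_mm, return_inverse=True)
    means = np.bincount(inv, weights=a405) / np.bincount(inv)
    if len(uniq) < 4:
        raise ValueError("need at least 4 distinct pNPP concentrations")
    if np.allclose(means, 0.0):
        raise ValueError("all readings are zero")
    fit = fit_single_timepoint_mm(uniq, means, t=1.0, enzyme=1.0)
    return PnppFit(vmax=fit.kcat_over_km * fit.km, km_mm=fit.km,
                   residual_sse=fit.residual_sse)


def efficiency_fold(fit_a: KineticFit, fit_b: KineticFit) -> float:
    """Catalytic-efficiency ratio (kcat/KM)_a / (kcat/KM)_b."""
    if not fit_b.kcat_over_km > 0:
        raise ValueError("reference catalytic efficiency must be positive")
    return fit_a.kcat_over_km / fit_b.kcat_over_km
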