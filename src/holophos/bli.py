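"""1:1 Langmuir binding model for bio-layer interferometry (BLI).

A ligand-coated sensor in analyte at concentration C responds

    association:  R(t) = Req * (1 - exp(-(kon*C + koff) * t)),
                  Req  = Rmax * C / (C + Kd)
    dissociation: R(t) = R(t_assoc) * exp(-koff * (t - t_assoc))

with Kd = koff/kon.  The module simulates sensorgrams, fits the
equilibrium (steady-state) binding isotherm for Kd and Rmax, fits the
kinetic model globally across concentrations, and computes mutant vs
wild-type affinity fold changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats


@dataclass(frozen=True)
class BindingParams:
    """1:1 Langmuir parameters; ``kd = koff/kon`` by construction."""

    kon: float   # 1/(M*s)
    koff: float  # 1/s
    rmax: float  # response units

    def __post_init__(self) -> None:
        if not (self.kon > 0 and self.koff > 0 and self.rmax > 0):
            raise ValueError("kon, koff and rmax must all be positive")

    @property
    def kd(self) -> float:
        return self.koff / self.kon

    def req(self, conc: float) -> float:
        """Equilibrium response at analyte concentration ``conc`` (M)."""
        return self.rmax * conc / (conc + self.kd)


@dataclass
class Sensorgram:
    """One association/dissociation trace at a single analyte concentration."""

    analyte_conc: float      # M
    times: np.ndarray        # s, starting at 0, strictly increasing
    responses: np.ndarray    # response units
    t_assoc: float           # s, association/dissociation boundary

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.times[0] != 0 or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must start at 0 and strictly increase")
        if not np.all(np.isfinite(self.responses)):
            raise ValueError("responses must be finite")

    def association(self) -> tuple[np.ndarray, np.ndarray]:
        m = self.times <= self.t_assoc
        return self.times[m], self.responses[m]

    def dissociation(self) -> tuple[np.ndarray, np.ndarray]:
        m = self.times > self.t_assoc
        return self.times[m], self.responses[m]

    def steady_state_response(self, tail_fraction: float = 0.05) -> float:
        """Req estimate: mean of the last ``tail_fraction`` of the
        association phase."""
        t, r = self.association()
        k = max(1, int(round(tail_fraction * len(t))))
        return float(np.mean(r[-k:]))


def model_response(params: BindingParams, conc: float, times,
                   t_assoc: float) -> np.ndarray:
    """Noise-free 1:1 model response over ``times``."""
    t = np.asarray(times, dtype=float)
    kobs = params.kon * conc + params.koff
    req = params.req(conc)
    r = np.where(t <= t_assoc,
                 req * (1.0 - np.exp(-kobs * t)),
                 req * (1.0 - np.exp(-kobs * t_assoc))
                 * np.exp(-params.koff * (t - t_assoc)))
    return r


def simulate_sensorgram(params: BindingParams, conc: float, t_assoc: float,
                        t_dissoc: float, dt: float, noise_sd: float = 0.0,
                        seed: int | None = None) -> Sensorgram:
    """Simulate one trace; ``noise_sd = 0`` gives the exact model.

    Gaussian noise is reproducible for a fixed ``seed``.
    """
    if conc < 0:
        raise ValueError("analyte concentration cannot be negative")
    if not dt > 0:
        raise ValueError("dt must be positive")
    times = np.arange(0.0, t_assoc + t_dissoc + dt / 2, dt)
    r = model_response(params, conc, times, t_assoc)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        r = r + rng.normal(0.0, noise_sd, size=r.shape)
    return Sensorgram(analyte_conc=conc, times=times, responses=r,
                      t_assoc=t_assoc)


@dataclass
class SteadyStateFit:
    """Equilibrium isotherm fit Req = Rmax*C/(C+Kd)."""

    kd: float    # M (NaN when unidentifiable)
    rmax: float
    residual_sse: float
    warnings: list[str] = field(default_factory=list)

    @property
    def kd_identifiable(self) -> bool:
        return np.isfinite(self.kd)


def fit_steady_state(conc, req) -> SteadyStateFit:
    """Least-squares fit of the equilibrium binding isotherm.

    Needs >= 3 concentrations; a span below 4-fold or a flat response
    set produces a warning (the latter returns Rmax = that response
    and an unidentifiable Kd).
    """
    conc = np.asarray(conc, dtype=float)
    req = np.asarray(req, dtype=float)
    if len(conc) < 3:
        raise ValueError("need at least 3 analyte concentrations")
    warnings: list[str] = []
    if conc.max() / conc.min() < 4.0:
        warnings.append("concentration span below 4-fold; "
                        "Kd confidence will be poor")
    if np.allclose(req, req[0], rtol=1e-9, atol=0.0):
        warnings.append("saturated regime: all responses equal, "
                        "Kd unidentifiable")
        return SteadyStateFit(kd=np.nan, rmax=float(req[0]),
                              residual_sse=0.0, warnings=warnings)

    def residuals(theta):
        log_kd, log_rmax = theta
        kd, rmax = np.exp(log_kd), np.exp(log_rmax)
        return rmax * conc / (conc + kd) - req

    # initial guess: Rmax slightly above max response, Kd at half-max
    rmax0 = max(req.max() * 1.05, 1e-12)
    half = rmax0 / 2.0
    kd0 = float(np.interp(half, np.sort(req), conc[np.argsort(req)]))
    kd0 = min(max(kd0, conc.min() / 10), conc.max() * 10)
    res = optimize.least_squares(residuals, x0=[np.log(kd0), np.log(rmax0)],
                                 xtol=1e-15, ftol=1e-15, gtol=1e-15)
    kd, rmax = np.exp(res.x)
    return SteadyStateFit(kd=float(kd), rmax=float(rmax),
                          residual_sse=float(2 * res.cost),
                          warnings=warnings)


def fit_dissociation(times, responses) -> float:
    """koff from log-linear regression of a pure dissociation phase."""
    t = np.asarray(times, dtype=float)
    r = np.asarray(responses, dtype=float)
    if np.any(r <= 0):
        raise ValueError("dissociation responses must be positive for "
                         "log-linear fitting")
    slope = stats.linregress(t, np.log(r)).slope
    return float(-slope)


def fit_kinetics(sensorgrams: list[Sensorgram]) -> tuple[BindingParams,
                                                         list[str]]:
    """Global kinetic fit of kon, koff, Rmax across sensorgrams.

    Initialised from a dissociation-phase log-linear koff and a
    steady-state isotherm fit, then refined by joint least squares in
    log-parameters.  Fitting a single concentration is allowed but
    flagged (parameters are then poorly constrained).
    """
    if not sensorgrams:
        raise ValueError("no sensorgrams supplied")
    warnings: list[str] = []
    if len({s.analyte_conc for s in sensorgrams}) < 2:
        warnings.append("single analyte concentration: local fit only")
    for s in sensorgrams:
        td, rd = s.dissociation()
        if len(td) == 0 or len(s.association()[0]) == 0:
            raise ValueError("each sensorgram needs both phases")

    # initial koff from the highest-concentration dissociation phase
    s_hi = max(sensorgrams, key=lambda s: s.analyte_conc)
    td, rd = s_hi.dissociation()
    try:
        koff0 = fit_dissociation(td - s_hi.t_assoc, rd)
        koff0 = koff0 if koff0 > 0 else 1e-3
    except ValueError:
        koff0 = 1e-3
    concs = np.array([s.analyte_conc for s in sensorgrams])
    reqs = np.array([s.steady_state_response() for s in sensorgrams])
    if len(concs) >= 3 and not np.allclose(reqs, reqs[0]):
        ss = fit_steady_state(concs, reqs)
        kd0 = ss.kd if np.isfinite(ss.kd) else np.median(concs)
        rmax0 = ss.rmax
    else:
        kd0, rmax0 = float(np.median(concs)), float(reqs.max() * 1.2)
    kon0 = koff0 / kd0

    def residuals(theta):
        p = BindingParams(*np.exp(theta))
        return np.concatenate([
            model_response(p, s.analyte_conc, s.times, s.t_assoc) - s.responses
            for s in sensorgrams])

    res = optimize.least_squares(
        residuals, x0=np.log([kon0, koff0, rmax0]),
        xtol=1e-15, ftol=1e-15, gtol=1e-15)
    kon, koff, rmax = np.exp(res.x)
    return BindingParams(kon=float(kon), koff=float(koff),
                         rmax=float(rmax)), warnings


def affinity_fold(mutant_kd: float, wildtype_kd: float) -> float:
    """Fold reduction in affinity: mutant Kd over wild-type Kd."""
    if not wildtype_kd > 0:
        raise ValueError("wild-type Kd must be positive")
    return mutant_kd / wildtype_kd
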