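"""Process-based growth model: transport-resistance dynamics to steady state.

The plant is represented by shoot and root structural mass plus carbon and
nitrogen substrate pools.  Carbon enters through the shoot, nitrogen through
the root; substrates are exchanged against a transport resistance, growth
converts substrate into structure, and turnover plus temperature-dependent
respiration remove structure.  Environmental control enters through bounded
[0, 1] modifiers — trapezoids and saturating ramps combined by Liebig's law
of the minimum — on carbon uptake, nitrogen uptake and growth.

The model is run forward under a repeating 12-month forcing cycle until the
annual mean biomass settles; that steady-state biomass, pushed through a
complementary log-log link, is the probability of the species occurring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .forcing import COLS, N_FORCING_COLS, validate_forcing
from .params import (  # noqa: F401  (re-exported API)
    CARBON_FRACTION,
    MASS_FLOOR,
    NITROGEN_FRACTION,
    RESP_FRAC,
    TTRParams,
    count_free_parameters,
)


class SteadyStateWarning(UserWarning):
    """Raised (as a warning, never an exception) on non-convergence."""


def trapezoid(x, p1, p2, p3, p4):
    """Piecewise-linear 0-1-0 response with knots ``p1 <= p2 <= p3 <= p4``.

    Zero outside ``(p1, p4)``, one on ``[p2, p3]``, linear on the limbs.
    Equal adjacent knots degrade to step transitions.
    """
    if not (p1 <= p2 <= p3 <= p4):
        raise ValueError("trapezoid knots must satisfy p1 <= p2 <= p3 <= p4")
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    out[(p2 <= x) & (x <= p3)] = 1.0
    if p2 > p1:
        rise = (p1 < x) & (x < p2)
        out[rise] = (x[rise] - p1) / (p2 - p1)
    if p4 > p3:
        fall = (p3 < x) & (x < p4)
        out[fall] = (p4 - x[fall]) / (p4 - p3)
    return out if out.ndim else float(out)


def ramp(x, s1, s2):
    """Saturating response: 0 below ``s1``, 1 above ``s2``, linear between."""
    if not s1 < s2:
        raise ValueError("ramp knots must satisfy s1 < s2")
    x = np.asarray(x, dtype=float)
    out = np.clip((x - s1) / (s2 - s1), 0.0, 1.0)
    return out if out.ndim else float(out)


def liebig(*modifiers):
    """Law of the minimum: co-limiting factors combine by the smallest."""
    if len(modifiers) == 1 and np.iterable(modifiers[0]):
        modifiers = tuple(modifiers[0])
    if not modifiers:
        raise ValueError("liebig requires at least one modifier")
    return min(float(m) for m in modifiers)


@dataclass
class PlantState:
    """Structural masses and substrate pools (all non-negative)."""

    m_s: float = 0.1   # shoot structural mass
    m_r: float = 0.1   # root structural mass
    c_s: float = 0.01  # shoot carbon substrate
    c_r: float = 0.01  # root carbon substrate
    n_s: float = 0.001  # shoot nitrogen substrate
    n_r: float = 0.001  # root nitrogen substrate

    def as_array(self) -> np.ndarray:
        return np.array([self.m_s, self.m_r, self.c_s, self.c_r,
                         self.n_s, self.n_r])

    @property
    def biomass(self) -> float:
        return self.m_s + self.m_r


def photosynthesis_modifier_standard(t_day, radiation, moisture, p: TTRParams):
    """Standard-variant carbon-gain modifier (trapezoid x two ramps, Liebig)."""
    return np.minimum(
        trapezoid(t_day, p.beta1, p.beta2, p.beta3, p.beta4),
        np.minimum(ramp(radiation, p.beta5, p.beta6),
                   ramp(moisture, p.beta7, p.beta8)),
    )


def monthly_fluxes(state: PlantState, forcing_month, p: TTRParams,
                   photo_modifier: float | None = None) -> dict[str, float]:
    """Instantaneous fluxes for one month's forcing.

    ``forcing_month`` maps ``t_day, t_soil, moisture, radiation, nitrogen``
    to scalars.  ``photo_modifier`` overrides the standard-variant carbon
    modifier (the Farquhar pathway supplies it).  Signed transports are
    positive shoot-to-root (carbon) and root-to-shoot (nitrogen).
    """
    f = forcing_month
    if photo_modifier is None:
        photo_modifier = float(photosynthesis_modifier_standard(
            f["t_day"], f["radiation"], f["moisture"], p))
    f_n = liebig(
        trapezoid(f["moisture"], p.gamma1, p.gamma2, p.gamma3, p.gamma4),
        ramp(f["nitrogen"], p.gamma5, p.gamma6),
        ramp(f["t_soil"], p.gamma7, p.gamma8),
    )
    f_g = float(trapezoid(f["t_day"], p.delta1, p.delta2, p.delta3, p.delta4))
    m_s = max(state.m_s, MASS_FLOOR)
    m_r = max(state.m_r, MASS_FLOOR)
    uptake_c = p.sigma_c * photo_modifier * m_s / (1.0 + m_s / p.k_m)
    uptake_n = p.sigma_n * f_n * m_r / (1.0 + m_r / p.k_m)
    growth_s = p.growth_rate * f_g * state.c_s * state.n_s / m_s
    growth_r = p.growth_rate * f_g * state.c_r * state.n_r / m_r
    denom = p.r_trans * (1.0 / m_s + 1.0 / m_r)
    transport_c = (state.c_s / m_s - state.c_r / m_r) / denom
    transport_n = (state.n_r / m_r - state.n_s / m_s) / denom
    loss_rate = p.m_turn + RESP_FRAC * float(ramp(f["t_day"], p.rho1, p.rho2))
    return {
        "uptake_c": uptake_c,
        "uptake_n": uptake_n,
        "growth_s": growth_s,
        "growth_r": growth_r,
        "transport_c": transport_c,
        "transport_n": transport_n,
        "loss_s": loss_rate * m_s,
        "loss_r": loss_rate * m_r,
        "f_photo": photo_modifier,
        "f_nitrogen": f_n,
        "f_growth": f_g,
    }


def step(state: PlantState, forcing_month, p: TTRParams, dt: float,
         photo_modifier: float | None = None) -> PlantState:
    """Explicit Euler update over ``dt`` months.

    Growth consumes carbon and nitrogen substrate with fixed stoichiometric
    fractions; pools are floored at a small positive mass and substrate
    pools are capped at the structural mass they sit in (concentrations
    cannot exceed one), which bounds the dynamics.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    for key in ("t_day", "t_soil", "moisture", "radiation", "nitrogen"):
        if not np.isfinite(forcing_month[key]):
            raise ValueError(f"non-finite forcing value for {key!r}")
    fl = monthly_fluxes(state, forcing_month, p, photo_modifier)
    m_s = state.m_s + dt * (fl["growth_s"] - fl["loss_s"])
    m_r = state.m_r + dt * (fl["growth_r"] - fl["loss_r"])
    c_s = state.c_s + dt * (fl["uptake_c"] - CARBON_FRACTION * fl["growth_s"]
                            - fl["transport_c"])
    c_r = state.c_r + dt * (fl["transport_c"] - CARBON_FRACTION * fl["growth_r"])
    n_s = state.n_s + dt * (fl["transport_n"] - NITROGEN_FRACTION * fl["growth_s"])
    n_r = state.n_r + dt * (fl["uptake_n"] - NITROGEN_FRACTION * fl["growth_r"]
                            - fl["transport_n"])
    m_s = max(m_s, MASS_FLOOR)
    m_r = max(m_r, MASS_FLOOR)
    return PlantState(
        m_s=m_s,
        m_r=m_r,
        c_s=min(max(c_s, MASS_FLOOR), m_s),
        c_r=min(max(c_r, MASS_FLOOR), m_r),
        n_s=min(max(n_s, MASS_FLOOR), m_s),
        n_r=min(max(n_r, MASS_FLOOR), m_r),
    )


def steady_state_biomass(forcing, p: TTRParams, *, substeps: int = 10,
                         tol: float = 1e-4, max_years: int = 200,
                         init_mass: float = 0.1,
                         fphoto_ext: np.ndarray | None = None,
                         warn: bool = True):
    """Annual-mean biomass after the yearly cycle has settled.

    ``forcing`` is one canonical 49-column row or an ``(n, 49)`` matrix
    (see :mod:`ttrsdm.forcing`).  The model cycles through the 12 months
    until the year-over-year relative change of mean annual biomass falls
    below ``tol`` or ``max_years`` is reached (the last value is returned
    with a :class:`SteadyStateWarning`, never an exception).  For the
    Farquhar variant pass the per-cell-month modifier via ``fphoto_ext``.
    """
    forcing = np.asarray(forcing, dtype=float)
    single = forcing.ndim == 1
    X = validate_forcing(np.atleast_2d(forcing))
    B, conv = batch_steady_state(
        np.atleast_2d(p.vector), X, fphoto_ext=fphoto_ext, substeps=substeps,
        tol=tol, max_years=max_years, init_mass=init_mass)
    if warn and not conv.all():
        warnings.warn(
            f"{int((~conv).sum())} steady-state run(s) did not converge "
            f"within {max_years} years; returning last annual mean",
            SteadyStateWarning, stacklevel=2)
    B = B[0]
    return float(B[0]) if single else B


def batch_steady_state(param_matrix, X, *, fphoto_ext=None, substeps=10,
                       tol=1e-4, max_years=200, init_mass=0.1):
    """Kernel wrapper: (S, 29) parameters x (C, 49) forcing -> (S, C)."""
    param_matrix = np.ascontiguousarray(param_matrix, dtype=float)
    X = np.asarray(X, dtype=float)
    tday = np.ascontiguousarray(X[:, COLS["t_day"]])
    tsoil = np.ascontiguousarray(X[:, COLS["t_soil"]])
    W = np.ascontiguousarray(X[:, COLS["moisture"]])
    R = np.ascontiguousarray(X[:, COLS["radiation"]])
    nsoil = np.ascontiguousarray(X[:, 48])
    if fphoto_ext is None:
        ext = np.zeros((1, 12))
        use_ext = False
    else:
        ext = np.ascontiguousarray(fphoto_ext, dtype=float)
        if ext.shape != (X.shape[0], 12):
            raise ValueError("fphoto_ext must have shape (n_cells, 12)")
        use_ext = True
    return _kernels.steady_state_batch(
        param_matrix, tday, tsoil, W, R, nsoil, ext, use_ext,
        substeps, tol, max_years, MASS_FLOOR, RESP_FRAC,
        CARBON_FRACTION, NITROGEN_FRACTION, init_mass)


def effective_temperature_response(p: TTRParams, t_grid) -> np.ndarray:
    """Liebig minimum of the photosynthesis and growth temperature
    trapezoids along ``t_grid`` (a structural diagnostic; for niche
    recovery use :func:`thermal_niche_curve`, which probes behaviour)."""
    t_grid = np.asarray(t_grid, float)
    photo = trapezoid(t_grid, p.beta1, p.beta2, p.beta3, p.beta4)
    growth = trapezoid(t_grid, p.delta1, p.delta2, p.delta3, p.delta4)
    return np.minimum(photo, growth)


def thermal_niche_curve(p: TTRParams, t_values, template_forcing,
                        fphoto_fn=None, **sim_kw) -> np.ndarray:
    """Realized suitability along a constant-temperature probe.

    For each probe temperature the model is run on a synthetic cell whose
    daytime and soil temperatures equal that value in every month while
    moisture, radiation and nitrogen are held at the column means of
    ``template_forcing``.  This measures the model's thermal response as
    behaviour (how parameter combinations interact), not as any single
    knot set — during inverse estimation the temperature constraint can be
    absorbed by several parameter blocks at once.  ``fphoto_fn`` maps the
    probe forcing matrix to an external ``(n, 12)`` photosynthesis
    modifier for the Farquhar variant.
    """
    t_values = np.asarray(t_values, float)
    template = np.asarray(template_forcing, float).mean(axis=0)
    X = np.tile(template, (len(t_values), 1))
    X[:, COLS["t_day"]] = t_values[:, None]
    X[:, COLS["t_soil"]] = t_values[:, None]
    fphoto = fphoto_fn(X) if fphoto_fn is not None else None
    B = steady_state_biomass(X, p, warn=False, fphoto_ext=fphoto, **sim_kw)
    return suitability(B, p.phi)


def thermal_niche_midpoint(p: TTRParams, t_lo: float, t_hi: float,
                           template_forcing, n: int = 61,
                           frac: float = 0.5, **kw) -> float:
    """Midpoint of the half-maximum span of the realized thermal niche.

    NaN when the probe suitability is zero over the whole scan.
    """
    t = np.linspace(t_lo, t_hi, n)
    r = thermal_niche_curve(p, t, template_forcing, **kw)
    peak = r.max()
    if peak <= 0:
        return float("nan")
    near = t[r >= frac * peak]
    return float((near.min() + near.max()) / 2.0)


def suitability(biomass, phi: float):
    """Complementary log-log link from steady-state biomass to probability.

    ``p = 1 - exp(-B*/phi)``, i.e. a cloglog link with linear predictor
    ``ln B* - ln phi``; a bijection from biomass in [0, inf) to [0, 1).
    """
    if phi <= 0:
        raise ValueError("phi must be positive")
    biomass = np.asarray(biomass, dtype=float)
    if np.any(biomass < 0):
        raise ValueError("biomass must be non-negative")
    out = -np.expm1(-biomass / phi)
    return float(out) if out.ndim == 0 else out
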