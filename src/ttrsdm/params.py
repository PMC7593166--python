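"""Parameter vector for the transport-resistance growth model.

The model has 29 free parameters in the standard variant.  The first eight
(``beta1..beta8``) shape the photosynthesis response to daytime temperature
(trapezoid), solar radiation (saturating ramp) and soil moisture (saturating
ramp).  In the Farquhar variant these eight are fixed physiology rather than
free parameters, leaving 21 to estimate.

Layout of the full 29-element vector (index: name):

====== ============ ==========================================================
0-3    beta1..4     photosynthesis temperature trapezoid knots (degC)
4-5    beta5,6      photosynthesis radiation ramp (MJ m-2 day-1)
6-7    beta7,8      photosynthesis soil-moisture ramp (fraction)
8-11   gamma1..4    nitrogen-uptake soil-moisture trapezoid (fraction)
12-13  gamma5,6     nitrogen-uptake soil-nitrogen ramp (g m-2)
14-15  gamma7,8     nitrogen-uptake soil-temperature ramp (degC)
16-19  delta1..4    growth temperature trapezoid (degC)
20-21  rho1,2       respiration temperature ramp (degC)
22     sigma_c      maximal specific carbon uptake (month-1)
23     sigma_n      maximal specific nitrogen uptake (month-1)
24     growth_rate  growth coefficient g (month-1)
25     k_m          structural-mass saturation constant (mass)
26     m_turn       structural turnover rate (month-1)
27     r_trans      transport resistance constant
28     phi          suitability scale of the complementary log-log link
====== ============ ==========================================================

Trapezoid knots must be non-decreasing and ramp knots strictly increasing;
the fitting layer guarantees this through a cumulative-increment
reparameterization (optimize ``p1`` and non-negative increments), so the
simulator may assume ordered knots.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

N_PARAMS = 29

PARAM_NAMES = (
    "beta1", "beta2", "beta3", "beta4", "beta5", "beta6", "beta7", "beta8",
    "gamma1", "gamma2", "gamma3", "gamma4", "gamma5", "gamma6", "gamma7", "gamma8",
    "delta1", "delta2", "delta3", "delta4",
    "rho1", "rho2",
    "sigma_c", "sigma_n", "growth_rate", "k_m", "m_turn", "r_trans", "phi",
)

# slices of the full vector
PHOTO_TRAP = slice(0, 4)
PHOTO_RAD_RAMP = slice(4, 6)
PHOTO_MOIST_RAMP = slice(6, 8)
N_MOIST_TRAP = slice(8, 12)
N_SOILN_RAMP = slice(12, 14)
N_TEMP_RAMP = slice(14, 16)
GROWTH_TRAP = slice(16, 20)
RESP_RAMP = slice(20, 22)
RATES = slice(22, 29)

#: indices of log-scale (positive rate) parameters
RATE_INDICES = tuple(range(22, 29))

#: fixed constants shared by both variants (not free parameters)
RESP_FRAC = 0.2      # respiration loss as a fraction of the turnover rate scale
CARBON_FRACTION = 0.45   # carbon substrate consumed per unit new structure
NITROGEN_FRACTION = 0.03  # nitrogen substrate consumed per unit new structure
MASS_FLOOR = 1e-9

VARIANTS = ("standard", "farquhar")

_FARQUHAR_FIXED = tuple(range(8))  # beta1..beta8 are fixed physiology


def free_parameter_indices(variant: str) -> tuple[int, ...]:
    """Indices of the free (estimated) parameters for a model variant."""
    if variant == "standard":
        return tuple(range(N_PARAMS))
    if variant == "farquhar":
        return tuple(i for i in range(N_PARAMS) if i not in _FARQUHAR_FIXED)
    raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")


def count_free_parameters(variant: str) -> int:
    """Number of parameters estimated from distribution data (29 or 21)."""
    return len(free_parameter_indices(variant))


def validate_vector(vec: np.ndarray) -> None:
    """Raise ``ValueError`` on ordering violations or non-positive rates."""
    vec = np.asarray(vec, dtype=float)
    if vec.shape != (N_PARAMS,):
        raise ValueError(f"parameter vector must have length {N_PARAMS}")
    if not np.all(np.isfinite(vec)):
        raise ValueError("parameter vector contains non-finite values")
    for name, sl in (("beta1..4", PHOTO_TRAP), ("gamma1..4", N_MOIST_TRAP),
                     ("delta1..4", GROWTH_TRAP)):
        knots = vec[sl]
        if np.any(np.diff(knots) < 0):
            raise ValueError(f"trapezoid knots {name} must be non-decreasing")
    for name, sl in (("beta5,6", PHOTO_RAD_RAMP), ("beta7,8", PHOTO_MOIST_RAMP),
                     ("gamma5,6", N_SOILN_RAMP), ("gamma7,8", N_TEMP_RAMP),
                     ("rho1,2", RESP_RAMP)):
        lo, hi = vec[sl]
        if not lo < hi:
            raise ValueError(f"ramp knots {name} must satisfy s1 < s2")
    if np.any(vec[RATES] <= 0):
        raise ValueError("rate parameters and phi must be positive")


@dataclass
class TTRParams:
    """A full parameter vector plus the variant that decides which are free."""

    vector: np.ndarray
    variant: str = "standard"

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=float).copy()
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        validate_vector(self.vector)

    def __getattr__(self, name: str):
        try:
            idx = PARAM_NAMES.index(name)
        except ValueError:
            raise AttributeError(name) from None
        return self.vector[idx]

    @property
    def free_values(self) -> np.ndarray:
        return self.vector[list(free_parameter_indices(self.variant))]

    @property
    def n_free(self) -> int:
        return count_free_parameters(self.variant)

    def replace(self, **updates: float) -> "TTRParams":
        vec = self.vector.copy()
        for name, value in updates.items():
            vec[PARAM_NAMES.index(name)] = value
        return TTRParams(vec, self.variant)

    def to_dict(self) -> dict[str, float]:
        return {n: float(v) for n, v in zip(PARAM_NAMES, self.vector)}

    @classmethod
    def from_dict(cls, d: dict[str, float], variant: str = "standard") -> "TTRParams":
        return cls(np.array([d[n] for n in PARAM_NAMES], dtype=float), variant)


# ---------------------------------------------------------------------------
# reparameterization: ordered knots <-> unconstrained box
# ---------------------------------------------------------------------------

@dataclass
class ParameterSpace:
    """Box-constrained search space in increment/log coordinates.

    Trapezoids are parameterized as (first knot, three non-negative
    increments); ramps as (first knot, one positive increment); rates and
    ``phi`` in log10.  Every point of the box therefore decodes to a valid
    ordered parameter vector, keeping the optimizer total.
    """

    variant: str
    lower: np.ndarray = field(repr=False)
    upper: np.ndarray = field(repr=False)
    fixed_full: np.ndarray | None = field(default=None, repr=False)
    #: per-coordinate role: "knot" (first trapezoid/ramp knot), "increment"
    #: (non-negative knot spacing) or "log_rate"
    kinds: tuple[str, ...] | None = None

    _TRAPS = (PHOTO_TRAP, N_MOIST_TRAP, GROWTH_TRAP)
    _RAMPS = (PHOTO_RAD_RAMP, PHOTO_MOIST_RAMP, N_SOILN_RAMP, N_TEMP_RAMP, RESP_RAMP)

    @property
    def n_dim(self) -> int:
        return len(self.lower)

    @property
    def bounds(self) -> list[tuple[float, float]]:
        return list(zip(self.lower.tolist(), self.upper.tolist()))

    def decode(self, z: np.ndarray) -> np.ndarray:
        """Map points of the box to full 29-parameter vectors.

        Accepts shape ``(n_dim,)`` or ``(pop, n_dim)``; returns the matching
        ``(29,)`` or ``(pop, 29)`` array of valid ordered vectors.
        """
        z_in = np.asarray(z, dtype=float)
        z = np.atleast_2d(z_in)
        free = free_parameter_indices(self.variant)
        full = np.tile(
            self.fixed_full if self.fixed_full is not None else np.zeros(N_PARAMS),
            (z.shape[0], 1),
        )
        work = np.empty((z.shape[0], N_PARAMS))
        work[:, list(free)] = z
        for sl in self._TRAPS:
            if sl.start in free:
                work[:, sl] = np.cumsum(work[:, sl], axis=1)
        for sl in self._RAMPS:
            if sl.start in free:
                work[:, sl.start + 1] = work[:, sl.start] + work[:, sl.start + 1]
        work[:, RATES] = 10.0 ** work[:, RATES]
        full[:, list(free)] = work[:, list(free)]
        return full[0] if z_in.ndim == 1 else full


def default_space(
    forcing,
    variant: str = "standard",
    fixed_full: np.ndarray | None = None,
) -> ParameterSpace:
    """Search space spanning the observed forcing ranges (+/-20%).

    Trapezoid/ramp knots cover the training range of their driving variable
    widened by 20% of that range; positive rates are log-uniform over four
    decades; ``phi`` over six (it must track the spread of steady-state
    biomass across candidate physiologies).
    """
    from .forcing import COLS  # local import to avoid a cycle

    forcing = np.asarray(forcing, dtype=float)

    def rng_of(cols) -> tuple[float, float]:
        vals = forcing[:, cols].ravel()
        lo, hi = float(vals.min()), float(vals.max())
        pad = 0.2 * max(hi - lo, 1e-6)
        return lo - pad, hi + pad

    t_lo, t_hi = rng_of(COLS["t_day"])
    ts_lo, ts_hi = rng_of(COLS["t_soil"])
    w_lo, w_hi = rng_of(COLS["moisture"])
    r_lo, r_hi = rng_of(COLS["radiation"])
    n_lo, n_hi = rng_of(COLS["nitrogen"])

    kinds: list[str] = []

    def trap(lo, hi):
        span = hi - lo
        kinds.extend(["knot", "increment", "increment", "increment"])
        return [(lo, hi)] + [(0.0, span)] * 3

    def ramp(lo, hi):
        span = hi - lo
        kinds.extend(["knot", "increment"])
        return [(lo, hi), (1e-3 * span, span)]

    per_index: list[tuple[float, float]] = []
    per_index += trap(t_lo, t_hi)          # beta1..4
    per_index += ramp(r_lo, r_hi)          # beta5,6
    per_index += ramp(w_lo, w_hi)          # beta7,8
    per_index += trap(w_lo, w_hi)          # gamma1..4
    per_index += ramp(n_lo, n_hi)          # gamma5,6
    per_index += ramp(ts_lo, ts_hi)        # gamma7,8
    per_index += trap(t_lo, t_hi)          # delta1..4
    per_index += ramp(t_lo, t_hi)          # rho1,2
    per_index += [(-2.0, 2.0)]             # log10 sigma_c
    per_index += [(-2.0, 2.0)]             # log10 sigma_n
    per_index += [(-2.0, 2.0)]             # log10 growth_rate
    per_index += [(-1.0, 3.0)]             # log10 k_m
    per_index += [(-3.0, 1.0)]             # log10 m_turn
    per_index += [(-2.0, 2.0)]             # log10 r_trans
    per_index += [(-3.0, 3.0)]             # log10 phi
    kinds.extend(["log_rate"] * 7)

    free = free_parameter_indices(variant)
    sel = [per_index[i] for i in free]
    lower = np.array([b[0] for b in sel])
    upper = np.array([b[1] for b in sel])
    if variant == "farquhar" and fixed_full is None:
        fixed_full = np.zeros(N_PARAMS)
        # placeholder ordered values for the unused beta block
        fixed_full[PHOTO_TRAP] = (0.0, 1.0, 2.0, 3.0)
        fixed_full[PHOTO_RAD_RAMP] = (0.0, 1.0)
        fixed_full[PHOTO_MOIST_RAMP] = (0.0, 1.0)
    return ParameterSpace(variant=variant, lower=lower, upper=upper,
                          fixed_full=fixed_full,
                          kinds=tuple(kinds[i] for i in free))
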