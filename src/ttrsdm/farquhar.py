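"""C3 Farquhar-type photosynthesis as a fixed carbon-gain modifier.

Instead of estimating the eight photosynthesis response parameters from
distribution data, this variant computes net assimilation from Rubisco- and
RuBP-regeneration-limited rates with textbook C3 constants, normalizes it to
the reference rate at 25 degC under saturating light, and multiplies by a
fixed soil-moisture ramp.  The result is a [0, 1] modifier that drops into
the growth model's carbon-uptake pathway, removing eight free parameters
(29 -> 21).

Units: temperatures degC, radiation MJ m-2 day-1 (converted internally to a
photosynthetic photon flux density), pressures in microbar/millibar
equivalents with CO2 expressed in ppm (ambient fixed at 338 ppm).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

R_GAS = 8.314  # J mol-1 K-1
T_REF_K = 298.15

#: radiation (MJ m-2 day-1) -> PPFD (umol m-2 s-1): 50% PAR fraction,
#: 4.57 umol per J of PAR, spread over a 12-h photoperiod.
RADIATION_TO_PPFD = 1e6 * 0.5 * 4.57 / (12 * 3600)

SATURATING_PPFD = 2000.0  # umol m-2 s-1


@dataclass
class FarquharConstants:
    """Kinetic constants of the C3 model (von Caemmerer-style defaults).

    Maximum carboxylation and electron-transport rates use a peaked
    Arrhenius response (activation energy plus a high-temperature
    deactivation term); Michaelis constants, CO2 compensation point and
    dark respiration use plain Arrhenius scaling.
    """

    vcmax25: float = 80.0        # umol m-2 s-1
    jmax25: float = 128.0        # 1.6 * vcmax25
    kc25: float = 259.0          # ubar
    ko25: float = 179.0          # mbar
    gamma_star25: float = 38.6   # ubar
    rd25: float = 0.8            # 0.01 * vcmax25
    oxygen: float = 205.0        # mbar
    ca: float = 338.0            # ppm, ambient CO2 (approximate 1980 value)
    ci_ratio: float = 0.7        # intercellular : ambient CO2
    alpha: float = 0.3           # quantum yield (mol e- per mol photons)
    theta: float = 0.7           # light-response curvature
    ea_vcmax: float = 64800.0    # J mol-1
    ea_jmax: float = 37000.0
    ea_kc: float = 59430.0
    ea_ko: float = 36000.0
    ea_gamma_star: float = 23450.0
    ea_rd: float = 66400.0
    deactivation_h: float = 200000.0   # J mol-1
    entropy: float = 650.0             # J mol-1 K-1
    moisture_ramp: tuple[float, float] = (0.05, 0.35)
    radiation_to_ppfd: float = RADIATION_TO_PPFD

    def to_dict(self) -> dict:
        d = asdict(self)
        d["moisture_ramp"] = list(self.moisture_ramp)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "FarquharConstants":
        d = dict(d)
        if "moisture_ramp" in d:
            d["moisture_ramp"] = tuple(d["moisture_ramp"])
        return cls(**d)


DEFAULT_CONSTANTS = FarquharConstants()


def arrhenius(k25, ea, t_celsius):
    """Arrhenius temperature scaling relative to 25 degC."""
    t_celsius = np.asarray(t_celsius, dtype=float)
    if np.any(t_celsius <= -273.15):
        raise ValueError("temperature below absolute zero")
    if np.any(np.asarray(k25) <= 0):
        raise ValueError("k25 must be positive")
    tk = t_celsius + 273.15
    out = k25 * np.exp(ea * (t_celsius - 25.0) / (T_REF_K * R_GAS * tk))
    return float(out) if out.ndim == 0 else out


def _peaked(k25, ea, t_celsius, h_d, entropy):
    """Arrhenius rise with high-temperature deactivation (peaked response)."""
    tk = np.asarray(t_celsius, dtype=float) + 273.15
    base = arrhenius(k25, ea, t_celsius)
    num = 1.0 + np.exp((T_REF_K * entropy - h_d) / (T_REF_K * R_GAS))
    den = 1.0 + np.exp((tk * entropy - h_d) / (tk * R_GAS))
    return base * num / den


def electron_transport(ppfd, jmax, alpha, theta):
    """Smaller root of the non-rectangular hyperbola light response."""
    i2 = alpha * np.asarray(ppfd, dtype=float)
    b = i2 + jmax
    disc = np.sqrt(b * b - 4.0 * theta * i2 * jmax)
    return (b - disc) / (2.0 * theta)


def net_assimilation(t_day, radiation, constants: FarquharConstants = DEFAULT_CONSTANTS,
                     *, ppfd: np.ndarray | None = None):
    """Net CO2 assimilation rate (umol m-2 s-1); negative in the dark.

    The gross rate is the Liebig-style minimum of the Rubisco-limited and
    RuBP-regeneration-limited rates at ``Ci = ci_ratio * Ca``; temperature-
    scaled dark respiration is subtracted.
    """
    c = constants
    if ppfd is None:
        radiation = np.asarray(radiation, dtype=float)
        if np.any(radiation < 0):
            raise ValueError("radiation must be non-negative")
        ppfd = radiation * c.radiation_to_ppfd
    vcmax = _peaked(c.vcmax25, c.ea_vcmax, t_day, c.deactivation_h, c.entropy)
    jmax = _peaked(c.jmax25, c.ea_jmax, t_day, c.deactivation_h, c.entropy)
    kc = arrhenius(c.kc25, c.ea_kc, t_day)
    ko = arrhenius(c.ko25, c.ea_ko, t_day)
    gamma_star = arrhenius(c.gamma_star25, c.ea_gamma_star, t_day)
    rd = arrhenius(c.rd25, c.ea_rd, t_day)
    ci = c.ci_ratio * c.ca
    a_c = vcmax * (ci - gamma_star) / (ci + kc * (1.0 + c.oxygen / ko))
    j = electron_transport(ppfd, jmax, c.alpha, c.theta)
    a_j = j * (ci - gamma_star) / (4.0 * ci + 8.0 * gamma_star)
    out = np.minimum(a_c, a_j) - rd
    out = np.asarray(out, dtype=float)
    return float(out) if out.ndim == 0 else out


def reference_assimilation(constants: FarquharConstants = DEFAULT_CONSTANTS) -> float:
    """Net assimilation at 25 degC under saturating light (normalizer)."""
    return float(net_assimilation(25.0, None, constants, ppfd=SATURATING_PPFD))


def photosynthesis_modifier(t_day, radiation, moisture,
                            constants: FarquharConstants = DEFAULT_CONSTANTS):
    """Normalized [0, 1] carbon-gain modifier for the growth model.

    ``max(A, 0) / A_ref`` clipped to [0, 1], times a fixed (non-estimated)
    soil-moisture ramp — the Farquhar model itself carries no soil-moisture
    dependence, but moisture limitation of carbon gain must persist.
    """
    a = net_assimilation(t_day, radiation, constants)
    a_ref = reference_assimilation(constants)
    from .ttr import ramp  # fixed moisture limitation, shared functional form

    s1, s2 = constants.moisture_ramp
    mod = np.clip(np.maximum(a, 0.0) / a_ref, 0.0, 1.0) * ramp(moisture, s1, s2)
    mod = np.asarray(mod, dtype=float)
    return float(mod) if mod.ndim == 0 else mod


def modifier_table(X, constants: FarquharConstants = DEFAULT_CONSTANTS) -> np.ndarray:
    """Per-cell-month modifier ``(n_cells, 12)`` from a canonical forcing matrix."""
    from .forcing import COLS

    X = np.asarray(X, dtype=float)
    return photosynthesis_modifier(
        X[:, COLS["t_day"]], X[:, COLS["radiation"]], X[:, COLS["moisture"]],
        constants)
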