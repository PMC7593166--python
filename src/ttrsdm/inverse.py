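"""Inverse parameterization of the process-based model.

The physiological parameters are estimated from distribution data alone: a
candidate parameter vector is run to steady-state biomass at every
occurrence cell, biomass is mapped to occurrence probability through the
complementary log-log link, the Bernoulli likelihood of the
presence/pseudoabsence labels is evaluated, and a differential evolution
(DE) genetic algorithm searches the parameter space.  Ordered trapezoid
knots are guaranteed by optimizing first-knot + non-negative increments
(see :class:`ttrsdm.params.ParameterSpace`), which keeps the objective
total over the whole search box.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import farquhar as fq
from . import ttr
from .forcing import unique_forcing, validate_forcing
from .params import (N_PARAMS, ParameterSpace, TTRParams, default_space,
                     free_parameter_indices)

EPS_PROB = 1e-9


class TooFewPresencesError(ValueError):
    """A model fit needs more than 15 presence cells with complete forcing."""


def bernoulli_nll(probs, labels) -> float:
    """Negative Bernoulli log-likelihood with probabilities clipped to
    ``[1e-9, 1 - 1e-9]``."""
    p = np.clip(np.asarray(probs, float), EPS_PROB, 1.0 - EPS_PROB)
    y = np.asarray(labels, float)
    if p.shape != y.shape or y.size == 0:
        raise ValueError("probs and labels must be equal-length and non-empty")
    return float(-(y * np.log(p) + (1.0 - y) * np.log1p(-p)).sum())


@dataclass
class DEResult:
    x: np.ndarray
    fun: float
    trace: np.ndarray          # best objective value per generation
    n_evaluations: int
    seed: int


def differential_evolution(objective, bounds, pop_size: int | None = None,
                           F: float = 0.8, CR: float = 0.9,
                           max_gen: int = 150, seed: int = 0,
                           init: np.ndarray | None = None) -> DEResult:
    """Classic DE/rand/1/bin minimization.

    ``objective`` is called on a ``(pop, dim)`` matrix and must return a
    ``(pop,)`` vector (NaN is treated as +inf).  Mutation ``v = a + F (b -
    c)`` with distinct random members, binomial crossover at rate ``CR``
    (one coordinate always inherited from the mutant), greedy selection.
    The best-so-far objective is monotonically non-increasing and the whole
    run is reproducible from ``seed``.  Default population is ``10 * dim``.
    """
    lower = np.array([b[0] for b in bounds], float)
    upper = np.array([b[1] for b in bounds], float)
    if not (np.all(np.isfinite(lower)) and np.all(np.isfinite(upper))):
        raise ValueError("bounds must be finite")
    dim = len(bounds)
    if pop_size is None:
        pop_size = 10 * dim
    if pop_size < 4:
        raise ValueError("pop_size must be at least 4")
    rng = np.random.default_rng(seed)

    def as_values(Z):
        vals = np.asarray(objective(Z), float)
        return np.where(np.isnan(vals), np.inf, vals)

    if init is None:
        pop = lower + rng.random((pop_size, dim)) * (upper - lower)
    else:
        pop = np.clip(np.asarray(init, float), lower, upper)
        pop_size = pop.shape[0]
    fitness = as_values(pop)
    n_eval = pop_size
    trace = [float(fitness.min())]

    for _ in range(max_gen):
        idx = np.arange(pop_size)
        choices = np.empty((pop_size, 3), int)
        for i in range(pop_size):
            choices[i] = rng.choice(np.delete(idx, i), size=3, replace=False)
        a, b, c = pop[choices[:, 0]], pop[choices[:, 1]], pop[choices[:, 2]]
        mutant = np.clip(a + F * (b - c), lower, upper)
        cross = rng.random((pop_size, dim)) < CR
        j_rand = rng.integers(0, dim, size=pop_size)
        cross[idx, j_rand] = True
        trial = np.where(cross, mutant, pop)
        trial_fit = as_values(trial)
        n_eval += pop_size
        improved = trial_fit <= fitness
        pop[improved] = trial[improved]
        fitness[improved] = trial_fit[improved]
        trace.append(float(fitness.min()))

    best = int(fitness.argmin())
    return DEResult(x=pop[best].copy(), fun=float(fitness[best]),
                    trace=np.asarray(trace), n_evaluations=n_eval, seed=seed)


@dataclass
class FitResult:
    best_params: TTRParams
    nll: float
    n_evaluations: int
    converged: bool
    seed: int
    variant: str
    trace: np.ndarray = field(repr=False)


def make_objective(X, y, variant: str = "standard",
                   space: ParameterSpace | None = None,
                   farquhar_constants: fq.FarquharConstants = fq.DEFAULT_CONSTANTS,
                   substeps: int = 3, max_years: int = 60):
    """Population-batched Bernoulli objective over the search box.

    Duplicate forcing rows share one steady-state simulation per candidate.
    The integration settings here are the fitting-time choices (coarser
    sub-stepping and a shorter horizon than the reference defaults; see the
    methods note).  Returns ``(objective, space)``.
    """
    X = validate_forcing(np.asarray(X, float))
    y = np.asarray(y, float)
    Xu, inverse = unique_forcing(X)
    if space is None:
        space = default_space(X, variant)
    fphoto = fq.modifier_table(Xu, farquhar_constants) if variant == "farquhar" else None

    def objective(Z):
        Z = np.atleast_2d(Z)
        full = space.decode(Z)
        B, _ = ttr.batch_steady_state(full, Xu, fphoto_ext=fphoto,
                                      substeps=substeps, tol=1e-4,
                                      max_years=max_years)
        phi = full[:, N_PARAMS - 1][:, None]
        p = -np.expm1(-B / phi)
        p = np.clip(p[:, inverse], EPS_PROB, 1.0 - EPS_PROB)
        return -(y * np.log(p) + (1.0 - y) * np.log1p(-p)).sum(axis=1)

    return objective, space


def envelope_candidates(X, y, space: ParameterSpace) -> np.ndarray:
    """Climate-envelope starting points built from the presence data.

    Classic bioclimatic-envelope candidates: response plateaus set to
    presence-cell quantiles of each driver, ramps saturating near the low
    end of the presence range, mid-range rates, and a few cloglog scales.
    These give the optimizer immediately informative (if crude) models to
    refine; they use only the training data, never the generating truth.
    """
    from .forcing import COLS
    from .params import (GROWTH_TRAP, N_MOIST_TRAP, N_SOILN_RAMP,
                         N_TEMP_RAMP, PHOTO_MOIST_RAMP, PHOTO_RAD_RAMP,
                         PHOTO_TRAP, RESP_RAMP)

    pres = np.asarray(X, float)[np.asarray(y, int) == 1]
    # two envelope readings: per-cell annual means (where presence cells
    # sit once the model has integrated the seasonal cycle) and pooled
    # monthly values (what individual months reach); different species
    # geometries favour one or the other, so both seed the population
    by_mode = {
        "annual": {
            "t_day": pres[:, COLS["t_day"]].mean(axis=1),
            "t_soil": pres[:, COLS["t_soil"]].mean(axis=1),
            "moisture": pres[:, COLS["moisture"]].mean(axis=1),
            "radiation": pres[:, COLS["radiation"]].mean(axis=1),
            "nitrogen": pres[:, 48],
        },
        "monthly": {
            "t_day": pres[:, COLS["t_day"]].ravel(),
            "t_soil": pres[:, COLS["t_soil"]].ravel(),
            "moisture": pres[:, COLS["moisture"]].ravel(),
            "radiation": pres[:, COLS["radiation"]].ravel(),
            "nitrogen": pres[:, 48],
        },
    }
    monthly_span = {
        k: float(pres[:, COLS[k]].max() - pres[:, COLS[k]].min())
        for k in ("t_day", "t_soil", "moisture", "radiation")
    }
    monthly_span["nitrogen"] = float(pres[:, 48].max() - pres[:, 48].min())

    free = free_parameter_indices(space.variant)
    out = []
    for mode, drivers in by_mode.items():
        def trap_z(name, q_lo, q_hi):
            lo, hi = np.quantile(drivers[name], [q_lo, q_hi])
            pad = 0.25 * max(monthly_span[name], 1e-3)
            return [lo - pad, pad, hi - lo, pad]

        def ramp_z(name):
            lo = drivers[name].min()
            pad = 0.1 * max(monthly_span[name], 1e-3)
            return [lo - pad, 2 * pad]

        for (q_lo, q_hi) in ((0.25, 0.75), (0.10, 0.90)):
            for phi_log in (0.0, 1.0, 2.0):
                z = np.empty(N_PARAMS)
                z[PHOTO_TRAP] = trap_z("t_day", q_lo, q_hi)
                z[PHOTO_RAD_RAMP] = ramp_z("radiation")
                z[PHOTO_MOIST_RAMP] = ramp_z("moisture")
                z[N_MOIST_TRAP] = trap_z("moisture", q_lo, q_hi)
                z[N_SOILN_RAMP] = ramp_z("nitrogen")
                z[N_TEMP_RAMP] = ramp_z("t_soil")
                z[GROWTH_TRAP] = trap_z("t_day", 0.02, 0.98)
                z[RESP_RAMP] = [np.quantile(drivers["t_day"], 0.9),
                                0.2 * monthly_span["t_day"] + 1e-3]
                z[22:29] = (0.0, -0.3, 0.0, 0.7, -0.3, 0.0, phi_log)
                out.append(np.clip(z[list(free)], space.lower, space.upper))
    return np.asarray(out)


def initial_population(space: ParameterSpace, pop_size: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Permissive-biased starting population for the physiological search.

    A uniformly random parameter vector almost always produces zero biomass
    everywhere (five Liebig-combined modifiers must be jointly non-zero),
    leaving the likelihood flat and the search without a signal.  Half the
    population is therefore biased toward wide trapezoids and low ramp
    thresholds — models that predict presence broadly, which the selection
    pressure then narrows — and the other half is uniform over the box.
    """
    lower, upper = space.lower, space.upper
    span = upper - lower
    pop = lower + rng.random((pop_size, len(lower))) * span
    n_biased = pop_size // 2
    for j, kind in enumerate(space.kinds or ()):
        lo, up, sp = lower[j], upper[j], span[j]
        if kind == "knot":
            pop[:n_biased, j] = lo + rng.uniform(0.0, 0.3, n_biased) * sp
        elif kind == "increment":
            pop[:n_biased, j] = rng.uniform(0.3, 1.0, n_biased) * up
        else:  # log_rate: middle half of the log-range
            pop[:n_biased, j] = rng.uniform(lo + 0.25 * sp, up - 0.25 * sp,
                                            n_biased)
    return pop


class TTRSDM:
    """Process-based species distribution model, inversely parameterized.

    scikit-learn-style estimator: ``fit(X, y)`` takes the canonical
    49-column forcing matrix (:mod:`ttrsdm.forcing`) and presence (1) /
    pseudoabsence (0) labels, and estimates the free physiological
    parameters (29 for ``variant="standard"``, 21 for ``"farquhar"``) by
    differential evolution on the Bernoulli likelihood.

    Parameters
    ----------
    variant : "standard" (estimated photosynthesis responses) or "farquhar"
        (fixed C3 photosynthesis physiology).
    pop_size, mutation, recombination, max_gen : DE settings (desk-scale
        defaults; the low-level :func:`differential_evolution` default of
        ``10 * dim`` members is impractical here).
    substeps, max_years : fitting-time integration settings.
    min_presences : refuse to fit below this many presence records.

    Attributes (after ``fit``)
    --------------------------
    params_ : fitted :class:`TTRParams`; nll_ : best negative
    log-likelihood; converged_ : best value unchanged over the last 20% of
    generations; result_ : full :class:`FitResult`.
    """

    def __init__(self, variant: str = "standard", pop_size: int = 32,
                 mutation: float = 0.8, recombination: float = 0.9,
                 max_gen: int = 40, substeps: int = 3, max_years: int = 60,
                 min_presences: int = 15, random_state: int = 0,
                 farquhar_constants: fq.FarquharConstants = fq.DEFAULT_CONSTANTS):
        self.variant = variant
        self.pop_size = pop_size
        self.mutation = mutation
        self.recombination = recombination
        self.max_gen = max_gen
        self.substeps = substeps
        self.max_years = max_years
        self.min_presences = min_presences
        self.random_state = random_state
        self.farquhar_constants = farquhar_constants

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in (
            "variant", "pop_size", "mutation", "recombination", "max_gen",
            "substeps", "max_years", "min_presences", "random_state",
            "farquhar_constants")}

    def set_params(self, **kw) -> "TTRSDM":
        for k, v in kw.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y) -> "TTRSDM":
        X = validate_forcing(np.asarray(X, float))
        y = np.asarray(y, int)
        n_presence_cells = len(np.unique(X[y == 1], axis=0))
        if n_presence_cells < self.min_presences:
            raise TooFewPresencesError(
                f"{n_presence_cells} presence cells with complete forcing; "
                f"at least {self.min_presences} required")
        objective, space = make_objective(
            X, y, self.variant, substeps=self.substeps,
            max_years=self.max_years,
            farquhar_constants=self.farquhar_constants)
        self.space_ = space
        init = initial_population(
            space, self.pop_size,
            np.random.default_rng(np.random.SeedSequence(
                entropy=self.random_state, spawn_key=(1,))))
        hints = envelope_candidates(X, y, space)
        init[: len(hints)] = hints[: len(init)]
        res = differential_evolution(
            objective, space.bounds, pop_size=self.pop_size,
            F=self.mutation, CR=self.recombination, max_gen=self.max_gen,
            seed=self.random_state, init=init)
        # plateau of the best value over the final 20% of generations;
        # trivially short runs are never reported as converged
        tail = max(1, int(0.2 * self.max_gen))
        converged = self.max_gen >= 10 and bool(
            np.isclose(res.trace[-1], res.trace[-tail - 1], rtol=1e-9,
                       atol=0.0))
        self.params_ = TTRParams(space.decode(res.x), self.variant)
        self.nll_ = res.fun
        self.converged_ = converged
        self.result_ = FitResult(best_params=self.params_, nll=res.fun,
                                 n_evaluations=res.n_evaluations,
                                 converged=converged, seed=self.random_state,
                                 variant=self.variant, trace=res.trace)
        self.n_features_in_ = X.shape[1]
        return self

    def predict_suitability(self, X, *, substeps: int | None = None,
                            max_years: int | None = None) -> np.ndarray:
        """Occurrence probability at new forcing rows (cloglog of biomass)."""
        X = validate_forcing(np.asarray(X, float))
        Xu, inverse = unique_forcing(X)
        fphoto = (fq.modifier_table(Xu, self.farquhar_constants)
                  if self.variant == "farquhar" else None)
        B, _ = ttr.batch_steady_state(
            np.atleast_2d(self.params_.vector), Xu, fphoto_ext=fphoto,
            substeps=substeps or self.substeps,
            max_years=max_years or self.max_years)
        return ttr.suitability(B[0], self.params_.phi)[inverse]

    def predict_proba(self, X) -> np.ndarray:
        p = self.predict_suitability(X)
        return np.column_stack([1.0 - p, p])

    def predict(self, X) -> np.ndarray:
        return (self.predict_suitability(X) >= 0.5).astype(int)


def fit_species(occurrences, forcing, variant: str = "standard",
                budget: int = 40, seed: int = 0, **kw) -> FitResult:
    """Functional wrapper: fit one species and return the :class:`FitResult`.

    ``occurrences`` is a table with a ``presence`` column aligned with the
    rows of ``forcing``; ``budget`` is the number of DE generations.
    """
    y = np.asarray(occurrences["presence"], int)
    est = TTRSDM(variant=variant, max_gen=budget, random_state=seed, **kw)
    est.fit(forcing, y)
    return est.result_
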