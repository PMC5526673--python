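"""Core model objects for the quorum-sensing population model.

The model describes a well-mixed population of ``N`` individuals, each
carrying a continuous phenotype ``p in [0, 1]`` — the *production degree* of
autoinducer signalling molecules (0 = non-producer, 1 = full producer).
Production is costly: an individual reproduces at rate ``phi(p) = 1 - s*p``
with selection strength ``0 <= s < 1``.  At division events, offspring may
respond to the sensed population-average production level ``<p>`` by
adopting ``R(<p>)``, where ``R`` is the *response function* of the
quorum-sensing circuit.

This module defines the parameter containers, the response-function
families, initial phenotype distributions, and the two state
representations shared by the stochastic simulator (vectors of degrees)
and the mean-field integrator (finite weighted atomic measures).
"""

from __future__ import annotations

import abc
import math
from dataclasses import dataclass, field
from typing import Callable, NamedTuple, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.stats import truncnorm, uniform as _uniform_dist

__all__ = [
    "ModelParams",
    "NoiseSettings",
    "PopulationState",
    "AtomMeasure",
    "ResponseFunction",
    "SinusoidalResponse",
    "LinearResponse",
    "HillBistableResponse",
    "PitchforkResponse",
    "TabulatedResponse",
    "response_from_config",
    "InitialDistribution",
    "FixedPoint",
    "fitness",
    "response_eval",
    "response_fixed_points",
    "sample_initial",
    "KAPPA_MAX",
]

#: Largest up-regulation magnitude for which x + kappa*sin(pi x) stays in [0, 1].
KAPPA_MAX = 1.0 / math.pi

# Tolerances of the fixed-point finder.
_FP_GRID = 1001            # grid resolution 1e-3 on [0, 1]
_FP_POLISH_TOL = 1e-10
_FP_MARGINAL_TOL = 1e-6    # |R'(x) - 1| below this => "marginal"


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NoiseSettings:
    """Standard deviations of the three optional noise channels.

    ``sigma_inherit`` perturbs the copied ancestral degree, ``sigma_perceive``
    perturbs the sensed average before the response function is applied and
    ``sigma_respond`` perturbs the response function's output.  Perturbations
    are Gaussian and the result is clipped back to [0, 1].  All zero (the
    default) reproduces the noise-free model exactly.
    """

    sigma_inherit: float = 0.0
    sigma_perceive: float = 0.0
    sigma_respond: float = 0.0

    def __post_init__(self) -> None:
        for name in ("sigma_inherit", "sigma_perceive", "sigma_respond"):
            v = getattr(self, name)
            if not (v >= 0.0):
                raise ValueError(f"{name} must be >= 0, got {v!r}")

    @property
    def any_noise(self) -> bool:
        return (self.sigma_inherit > 0 or self.sigma_perceive > 0
                or self.sigma_respond > 0)


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the stochastic quorum-sensing process.

    N : population size (constant; Moran-type birth-death scheme), >= 2.
    s : selection strength, 0 <= s < 1; fitness phi(p) = 1 - s*p.
    lam : response probability, 0 <= lam <= 1; per-offspring probability of
        adopting R(<p>) at a division event instead of the ancestor's degree.
    noise : optional noise channels, see :class:`NoiseSettings`.
    seed : master random seed; all randomness of a run derives from it.
    """

    N: int
    s: float
    lam: float
    noise: NoiseSettings = field(default_factory=NoiseSettings)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (isinstance(self.N, (int, np.integer)) and self.N >= 2):
            raise ValueError(f"N must be an integer >= 2, got {self.N!r}")
        if not (0.0 <= self.s < 1.0):
            raise ValueError(f"selection strength s must satisfy 0 <= s < 1, got {self.s!r}")
        if not (0.0 <= self.lam <= 1.0):
            raise ValueError(f"response probability lam must lie in [0, 1], got {self.lam!r}")


# ---------------------------------------------------------------------------
# fitness
# ---------------------------------------------------------------------------

def fitness(p, s: float):
    """Reproduction rate ``phi(p) = 1 - s*p`` of a degree-``p`` producer.

    Affine and decreasing in ``p``: producing autoinducers is metabolically
    costly, so the non-producer reproduces fastest (``phi(0) = 1``).  Always
    strictly positive since ``s < 1``.

    Accepts scalars or arrays of production degrees.
    """
    if not (0.0 <= s < 1.0):
        raise ValueError(f"selection strength s must satisfy 0 <= s < 1, got {s!r}")
    arr = np.asarray(p, dtype=float)
    if np.any(arr < 0.0) or np.any(arr > 1.0):
        raise ValueError("production degree p must lie in [0, 1]")
    out = 1.0 - s * arr
    return float(out) if np.isscalar(p) or arr.ndim == 0 else out


# ---------------------------------------------------------------------------
# response functions
# ---------------------------------------------------------------------------

class FixedPoint(NamedTuple):
    """A root of R(x) = x with its linear stability under x -> R(x)."""

    location: float
    stability: str  # "stable" | "unstable" | "marginal"


# integer tags used by the compiled simulation kernel
_KIND_LINEAR = 0
_KIND_SINUSOIDAL = 1
_KIND_HILL = 2
_KIND_PITCHFORK = 3
_KIND_TABLE = 4

_EMPTY = np.empty(0, dtype=float)


class ResponseFunction(abc.ABC):
    """Map R: [0,1] -> [0,1] from sensed average production to adopted degree.

    The response function coarse-grains every biochemical step between
    perception of the population cue and adjustment of the individual's
    production.  Fixed points of R are the possible homogeneous absorbing
    states of the dynamics; their stability under iteration classifies the
    circuit as monostable (up-regulation everywhere) or bistable
    (threshold, 'all-or-none' regulation).
    """

    family: str = "abstract"

    def __call__(self, x):
        arr = np.asarray(x, dtype=float)
        if np.any(arr < 0.0) or np.any(arr > 1.0):
            raise ValueError("sensed average must lie in [0, 1]")
        out = self._eval(arr)
        return float(out) if np.isscalar(x) or arr.ndim == 0 else out

    @abc.abstractmethod
    def _eval(self, x: np.ndarray) -> np.ndarray: ...

    def derivative(self, x):
        """dR/dx, analytic where the family permits."""
        arr = np.asarray(x, dtype=float)
        out = self._deriv(arr)
        return float(out) if np.isscalar(x) or arr.ndim == 0 else out

    @abc.abstractmethod
    def _deriv(self, x: np.ndarray) -> np.ndarray: ...

    def fixed_points(self) -> list[FixedPoint]:
        """All solutions of R(x) = x on [0, 1] with stability labels.

        Roots are located by sign-change bracketing of R(x) - x on a grid of
        resolution 1e-3 and polished by Brent's method; stability follows
        from R'(x): < 1 stable, > 1 unstable, |R'-1| < 1e-6 flagged
        "marginal".  Endpoints are tested explicitly (one-sided).
        """
        return response_fixed_points(self)

    # hooks for the compiled simulation kernel -----------------------------
    def _kernel_spec(self) -> tuple[int, float, float, np.ndarray, np.ndarray]:
        xs = np.linspace(0.0, 1.0, 2049)
        return (_KIND_TABLE, 0.0, 0.0, xs, self._eval(xs))

    def _config_dict(self) -> dict:
        return {"family": self.family}


class LinearResponse(ResponseFunction):
    """Identity response R(x) = x: the adopted degree equals the sensed cue.

    Every point is a (marginal) fixed point; a linear response admits no
    heterogeneous stationary state.
    """

    family = "linear"

    def _eval(self, x):
        return np.array(x, dtype=float, copy=True)

    def _deriv(self, x):
        return np.ones_like(np.asarray(x, dtype=float))

    def _kernel_spec(self):
        return (_KIND_LINEAR, 0.0, 0.0, _EMPTY, _EMPTY)


class SinusoidalResponse(ResponseFunction):
    """Monostable up-regulating response ``R(x) = x + kappa*sin(pi*x)``.

    For ``kappa in (0, 1/pi]`` this satisfies R(x) > x on (0, 1): production
    is up-regulated at every sensed level, with an unstable fixed point at 0
    and a stable one at 1.  ``kappa`` scales the magnitude of up-regulation
    and is restricted to [0, 1/pi] so that R stays within [0, 1].
    """

    family = "sinusoidal"

    def __init__(self, kappa: float):
        if not (0.0 <= kappa <= KAPPA_MAX + 1e-15):
            raise ValueError(
                f"kappa must lie in [0, 1/pi] ~= [0, {KAPPA_MAX:.6f}], got {kappa!r}")
        self.kappa = float(kappa)

    def _eval(self, x):
        return x + self.kappa * np.sin(np.pi * x)

    def _deriv(self, x):
        return 1.0 + self.kappa * np.pi * np.cos(np.pi * x)

    def _kernel_spec(self):
        return (_KIND_SINUSOIDAL, self.kappa, 0.0, _EMPTY, _EMPTY)

    def _config_dict(self):
        return {"family": self.family, "kappa": self.kappa}


class HillBistableResponse(ResponseFunction):
    """Bistable ('all-or-none') threshold response built from a Hill function.

    ``R(x) = x^n (1 + K^n) / (x^n + K^n)`` with Hill coefficient ``n``
    (``coefficient``) and threshold ``K`` (``threshold``), rescaled so that
    R(0) = 0 and R(1) = 1 exactly.  For ``n > 1`` this yields the sketched
    three-fixed-point structure: stable 'off' state at 0, stable 'on' state
    at 1, and an unstable intermediate threshold; production is
    down-regulated below the threshold and up-regulated above it.
    """

    family = "hill_bistable"

    def __init__(self, coefficient: float = 4.0, threshold: float = 0.5):
        if coefficient <= 0:
            raise ValueError("Hill coefficient must be > 0")
        if not (0.0 < threshold < 1.0):
            raise ValueError("Hill threshold must lie in (0, 1)")
        self.coefficient = float(coefficient)
        self.threshold = float(threshold)

    def _eval(self, x):
        n, K = self.coefficient, self.threshold
        xn = np.power(x, n)
        return xn * (1.0 + K**n) / (xn + K**n)

    def _deriv(self, x):
        n, K = self.coefficient, self.threshold
        x = np.asarray(x, dtype=float)
        xn = np.power(x, n)
        with np.errstate(divide="ignore", invalid="ignore"):
            d = (1.0 + K**n) * n * np.power(x, n - 1.0) * K**n / (xn + K**n) ** 2
        # limit at x = 0: 0 for n > 1, (1+K^n)/K^n * ... finite for n = 1
        if n > 1:
            d = np.where(x == 0.0, 0.0, d)
        elif n == 1:
            d = np.where(x == 0.0, (1.0 + K) / K, d)
        return d

    def _kernel_spec(self):
        return (_KIND_HILL, self.coefficient, self.threshold, _EMPTY, _EMPTY)

    def _config_dict(self):
        return {"family": self.family, "coefficient": self.coefficient,
                "threshold": self.threshold}


class PitchforkResponse(ResponseFunction):
    """Cubic-perturbed identity ``R(x) = x + a*(x-1/2) - b*(x-1/2)^3``.

    A response family with a supercritical pitchfork bifurcation of its
    fixed-point structure at ``a = 0``: for ``a < 0`` the midpoint 1/2 is the
    unique stable fixed point, for ``a > 0`` it loses stability to a
    symmetric pair at ``1/2 +- sqrt(a/b)``.  Used to probe the divergence of
    relaxation time scales at bifurcations of the response function.
    """

    family = "pitchfork"

    def __init__(self, a: float, b: float = 1.0):
        self.a = float(a)
        self.b = float(b)
        if b <= 0:
            raise ValueError("cubic coefficient b must be > 0")
        grid = np.linspace(0.0, 1.0, 2001)
        vals = self._eval(grid)
        if vals.min() < -1e-12 or vals.max() > 1.0 + 1e-12:
            raise ValueError(
                f"pitchfork response with a={a}, b={b} leaves [0, 1]")

    def _eval(self, x):
        u = np.asarray(x, dtype=float) - 0.5
        return x + self.a * u - self.b * u**3

    def _deriv(self, x):
        u = np.asarray(x, dtype=float) - 0.5
        return 1.0 + self.a - 3.0 * self.b * u**2

    def _kernel_spec(self):
        return (_KIND_PITCHFORK, self.a, self.b, _EMPTY, _EMPTY)

    def _config_dict(self):
        return {"family": self.family, "a": self.a, "b": self.b}


class TabulatedResponse(ResponseFunction):
    """Response defined by a table of (x, R(x)) pairs, linearly interpolated."""

    family = "table"

    def __init__(self, xs: Sequence[float], ys: Sequence[float]):
        xs = np.asarray(xs, dtype=float)
        ys = np.asarray(ys, dtype=float)
        if xs.ndim != 1 or xs.shape != ys.shape or xs.size < 2:
            raise ValueError("table needs two equal-length columns with >= 2 rows")
        if np.any(np.diff(xs) <= 0):
            raise ValueError("table x values must be strictly increasing")
        if xs[0] > 0.0 or xs[-1] < 1.0:
            raise ValueError("table must cover [0, 1]")
        if np.any(ys < -1e-12) or np.any(ys > 1.0 + 1e-12):
            raise ValueError("table response values must lie in [0, 1]")
        self.xs = xs
        self.ys = np.clip(ys, 0.0, 1.0)

    def _eval(self, x):
        return np.interp(x, self.xs, self.ys)

    def _deriv(self, x):
        # central difference; tables carry no analytic derivative
        h = 1e-6
        x = np.asarray(x, dtype=float)
        lo = np.clip(x - h, 0.0, 1.0)
        hi = np.clip(x + h, 0.0, 1.0)
        return (np.interp(hi, self.xs, self.ys) - np.interp(lo, self.xs, self.ys)) / (hi - lo)

    def _kernel_spec(self):
        return (_KIND_TABLE, 0.0, 0.0, self.xs, self.ys)

    def _config_dict(self):
        return {"family": self.family, "xs": self.xs.tolist(), "ys": self.ys.tolist()}


_RESPONSE_FAMILIES: dict[str, Callable[..., ResponseFunction]] = {
    "linear": lambda **kw: LinearResponse(),
    "sinusoidal": lambda **kw: SinusoidalResponse(**kw),
    "hill_bistable": lambda **kw: HillBistableResponse(**kw),
    "pitchfork": lambda **kw: PitchforkResponse(**kw),
    "table": lambda **kw: TabulatedResponse(**kw),
}


def response_from_config(family: str, **params) -> ResponseFunction:
    """Build a response function from its family name and parameters."""
    try:
        factory = _RESPONSE_FAMILIES[family]
    except KeyError:
        raise ValueError(
            f"unknown response family {family!r}; "
            f"choose from {sorted(_RESPONSE_FAMILIES)}") from None
    return factory(**params)


def response_eval(R: ResponseFunction, x):
    """Evaluate a response function at sensed average x (functional form)."""
    return R(x)


def response_fixed_points(R: ResponseFunction) -> list[FixedPoint]:
    """Locate and classify all fixed points of R on [0, 1].

    Sign-change bracketing of f(x) = R(x) - x on a uniform grid (resolution
    1e-3), polished with Brent's method to 1e-10; stability from R'(x).
    Roots where |R'(x) - 1| < 1e-6 are flagged "marginal" rather than
    silently classified.  A response that is the identity to within
    tolerance on the whole grid returns its endpoints flagged marginal.
    """
    grid = np.linspace(0.0, 1.0, _FP_GRID)
    f = np.asarray(R(grid)) - grid

    if np.max(np.abs(f)) < 1e-12:
        # degenerate: R == identity, a continuum of marginal fixed points
        return [FixedPoint(0.0, "marginal"), FixedPoint(1.0, "marginal")]

    roots: list[float] = []
    # explicit endpoint checks (one-sided roots have no sign change)
    if abs(f[0]) < 1e-12:
        roots.append(0.0)
    if abs(f[-1]) < 1e-12:
        roots.append(1.0)
    for k in range(len(grid) - 1):
        a, b = f[k], f[k + 1]
        if a == 0.0 and grid[k] not in roots:
            roots.append(grid[k])
        elif a * b < 0.0:
            r = brentq(lambda x: float(R(x)) - x, grid[k], grid[k + 1],
                       xtol=_FP_POLISH_TOL)
            roots.append(float(r))

    out: list[FixedPoint] = []
    for r in sorted(set(round(r, 12) for r in roots)):
        d = float(R.derivative(r))
        if abs(d - 1.0) < _FP_MARGINAL_TOL:
            stab = "marginal"
        elif d < 1.0:
            stab = "stable"
        else:
            stab = "unstable"
        out.append(FixedPoint(float(r), stab))
    return out


# ---------------------------------------------------------------------------
# population state
# ---------------------------------------------------------------------------

@dataclass
class PopulationState:
    """Microscopic state p = (p_1, ..., p_N) of the stochastic process.

    ``time`` is the elapsed model time in units where a population of pure
    non-producers experiences one reproduction per individual per unit on
    average.
    """

    degrees: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        self.degrees = np.asarray(self.degrees, dtype=float)
        if self.degrees.ndim != 1 or self.degrees.size < 2:
            raise ValueError("degrees must be a 1-d vector of length >= 2")
        if np.any(self.degrees < 0.0) or np.any(self.degrees > 1.0):
            raise ValueError("all production degrees must lie in [0, 1]")

    @property
    def N(self) -> int:
        return self.degrees.size

    def mean(self) -> float:
        return float(self.degrees.mean())

    def variance(self) -> float:
        return float(self.degrees.var())

    def copy(self) -> "PopulationState":
        return PopulationState(self.degrees.copy(), self.time)


# ---------------------------------------------------------------------------
# atomic measures
# ---------------------------------------------------------------------------

#: atoms closer than this are merged (weight-weighted centroid)
MERGE_EPS = 1e-4
#: atoms below this weight are pruned by the integrator
WEIGHT_FLOOR = 1e-14
_NORM_TOL = 1e-9


@dataclass
class AtomMeasure:
    """Finite weighted set of point masses on [0, 1] representing the
    production distribution rho.

    Locations are kept sorted and strictly increasing; atoms closer than the
    merge tolerance are combined at their weight-weighted centroid.  Weights
    are positive and renormalized to total mass 1 on construction (an input
    farther than 1e-9 from normalized is rejected unless ``normalize=True``).
    """

    locations: np.ndarray
    weights: np.ndarray

    def __init__(self, locations, weights, *, normalize: bool = False,
                 merge_eps: float = MERGE_EPS):
        locs = np.asarray(locations, dtype=float).ravel()
        w = np.asarray(weights, dtype=float).ravel()
        if locs.shape != w.shape or locs.size == 0:
            raise ValueError("locations and weights must be equal-length, non-empty")
        if np.any(locs < 0.0) or np.any(locs > 1.0):
            raise ValueError("atom locations must lie in [0, 1]")
        if np.any(w < 0.0):
            raise ValueError("atom weights must be nonnegative")
        total = w.sum()
        if total <= 0.0:
            raise ValueError("total mass must be positive")
        if not normalize and abs(total - 1.0) > _NORM_TOL:
            raise ValueError(
                f"weights must sum to 1 within {_NORM_TOL} (got {total!r}); "
                "pass normalize=True to rescale")
        w = w / total

        order = np.argsort(locs, kind="stable")
        locs, w = locs[order], w[order]
        locs, w = _merge_atoms(locs, w, merge_eps)
        w = w / w.sum()  # exact renormalization after merging

        self.locations = locs
        self.weights = w

    @classmethod
    def delta(cls, location: float) -> "AtomMeasure":
        return cls([location], [1.0])

    @classmethod
    def from_samples(cls, values: np.ndarray, merge_eps: float = MERGE_EPS) -> "AtomMeasure":
        """Empirical measure of a sample vector (equal weights, merged)."""
        vals, counts = np.unique(np.asarray(values, dtype=float), return_counts=True)
        return cls(vals, counts.astype(float), normalize=True, merge_eps=merge_eps)

    @property
    def n_atoms(self) -> int:
        return self.locations.size

    def mean(self) -> float:
        return float(self.weights @ self.locations)

    def variance(self) -> float:
        m = self.mean()
        return float(self.weights @ (self.locations - m) ** 2)

    def total_mass(self) -> float:
        return float(self.weights.sum())

    def copy(self) -> "AtomMeasure":
        out = object.__new__(AtomMeasure)
        out.locations = self.locations.copy()
        out.weights = self.weights.copy()
        return out


def _merge_atoms(locs: np.ndarray, w: np.ndarray, eps: float):
    """Combine sorted atoms closer than eps at their weighted centroid."""
    if locs.size <= 1 or not np.any(np.diff(locs) < eps):
        return locs, w
    out_l: list[float] = []
    out_w: list[float] = []
    cur_l, cur_w = locs[0], w[0]
    for k in range(1, locs.size):
        if locs[k] - cur_l < eps:
            tot = cur_w + w[k]
            if tot > 0:
                cur_l = (cur_l * cur_w + locs[k] * w[k]) / tot
            cur_w = tot
        else:
            out_l.append(cur_l)
            out_w.append(cur_w)
            cur_l, cur_w = locs[k], w[k]
    out_l.append(cur_l)
    out_w.append(cur_w)
    return np.asarray(out_l), np.asarray(out_w)


# ---------------------------------------------------------------------------
# initial distributions
# ---------------------------------------------------------------------------

class InitialDistribution:
    """Initial distribution rho_0 of production degrees on [0, 1].

    Families
    --------
    uniform : flat on [lo, hi] within [0, 1] (a quasi-continuous start).
    atoms : finite point masses, e.g. a two-type producer/non-producer mix.
    truncated_gaussian : normal(mu, sigma) truncated to [0, 1].
    table : tabulated density, linearly interpolated and normalized.

    Exposes the initial mean ``p̄_0``, the initial mean fitness
    ``φ̄_0 = 1 - s p̄_0``, i.i.d. sampling for the stochastic layer and an
    equal-mass atomic discretization for the mean-field layer.
    """

    def __init__(self, family: str, **params):
        self.family = family
        self.params = dict(params)
        if family == "uniform":
            lo = float(params.get("lo", 0.0))
            hi = float(params.get("hi", 1.0))
            if not (0.0 <= lo < hi <= 1.0):
                raise ValueError("uniform support must satisfy 0 <= lo < hi <= 1")
            self._lo, self._hi = lo, hi
            self._dist = _uniform_dist(loc=lo, scale=hi - lo)
        elif family == "atoms":
            atoms = params.get("atoms")
            if atoms is None:
                locs = params["locations"]
                w = params["weights"]
            else:
                locs = list(atoms.keys())
                w = list(atoms.values())
            self._atoms = AtomMeasure(locs, w, normalize=True)
        elif family == "truncated_gaussian":
            mu = float(params["mu"])
            sigma = float(params["sigma"])
            if sigma <= 0:
                raise ValueError("truncated_gaussian sigma must be > 0")
            a, b = (0.0 - mu) / sigma, (1.0 - mu) / sigma
            self._dist = truncnorm(a, b, loc=mu, scale=sigma)
        elif family == "table":
            xs = np.asarray(params["xs"], dtype=float)
            ps = np.asarray(params["ps"], dtype=float)
            if xs.ndim != 1 or xs.shape != ps.shape or xs.size < 2:
                raise ValueError("table needs two equal-length columns with >= 2 rows")
            if np.any(np.diff(xs) <= 0) or xs[0] < 0 or xs[-1] > 1:
                raise ValueError("table x values must increase within [0, 1]")
            if np.any(ps < 0) or np.trapezoid(ps, xs) <= 0:
                raise ValueError("table density must be nonnegative with positive mass")
            self._xs = xs
            self._ps = ps / np.trapezoid(ps, xs)
            # numeric cdf on a fine grid for quantiles and sampling
            fine = np.union1d(xs, np.linspace(xs[0], xs[-1], 4001))
            pdf = np.interp(fine, self._xs, self._ps)
            cdf = np.concatenate([[0.0], np.cumsum(np.diff(fine) * (pdf[:-1] + pdf[1:]) / 2)])
            self._fine = fine
            self._cdf = cdf / cdf[-1]
        else:
            raise ValueError(
                f"unknown initial-distribution family {family!r}; choose from "
                "['uniform', 'atoms', 'truncated_gaussian', 'table']")

    # --- moments ---------------------------------------------------------

    def mean(self) -> float:
        """Initial mean production degree p̄_0."""
        if self.family == "atoms":
            return self._atoms.mean()
        if self.family == "table":
            return float(np.trapezoid(self._fine * np.interp(self._fine, self._xs, self._ps),
                                      self._fine))
        return float(self._dist.mean())

    def variance(self) -> float:
        if self.family == "atoms":
            return self._atoms.variance()
        if self.family == "table":
            m = self.mean()
            pdf = np.interp(self._fine, self._xs, self._ps)
            return float(np.trapezoid((self._fine - m) ** 2 * pdf, self._fine))
        return float(self._dist.var())

    def mean_fitness(self, s: float) -> float:
        """Initial mean fitness φ̄_0 = 1 - s * p̄_0."""
        if not (0.0 <= s < 1.0):
            raise ValueError("selection strength s must satisfy 0 <= s < 1")
        return 1.0 - s * self.mean()

    # --- sampling and discretization -------------------------------------

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.family == "atoms":
            idx = rng.choice(self._atoms.n_atoms, size=n, p=self._atoms.weights)
            return self._atoms.locations[idx]
        if self.family == "table":
            u = rng.random(n)
            return np.interp(u, self._cdf, self._fine)
        return self._dist.rvs(size=n, random_state=rng)

    def quantile(self, q) -> np.ndarray:
        q = np.asarray(q, dtype=float)
        if self.family == "atoms":
            cum = np.cumsum(self._atoms.weights)
            idx = np.searchsorted(cum, q, side="left")
            idx = np.clip(idx, 0, self._atoms.n_atoms - 1)
            return self._atoms.locations[idx]
        if self.family == "table":
            return np.interp(q, self._cdf, self._fine)
        return self._dist.ppf(q)

    def to_atoms(self, n_atoms: int = 400) -> AtomMeasure:
        """Equal-mass atomic discretization at quantile midpoints.

        For the atoms family, the exact atoms are returned unchanged.
        """
        if self.family == "atoms":
            return self._atoms.copy()
        q = (np.arange(n_atoms) + 0.5) / n_atoms
        locs = np.clip(self.quantile(q), 0.0, 1.0)
        return AtomMeasure(locs, np.full(n_atoms, 1.0 / n_atoms), normalize=True)

    # --- density (continuous families) ------------------------------------

    def pdf(self, p) -> np.ndarray:
        """Density rho_0(p); raises for the purely atomic family."""
        if self.family == "atoms":
            raise ValueError("atoms family has no density")
        if self.family == "table":
            return np.interp(p, self._xs, self._ps, left=0.0, right=0.0)
        return self._dist.pdf(p)

    def _config_dict(self) -> dict:
        out = {"family": self.family}
        out.update(self.params)
        return out

    def __repr__(self) -> str:  # pragma: no cover
        return f"InitialDistribution({self.family!r}, {self.params!r})"


def sample_initial(dist: InitialDistribution, N: int, seed: int) -> PopulationState:
    """Draw an i.i.d. initial population of N production degrees.

    Bit-reproducible for a fixed seed.
    """
    if N < 2:
        raise ValueError("population size N must be >= 2")
    rng = np.random.default_rng(seed)
    degrees = np.clip(dist.sample(N, rng), 0.0, 1.0)
    return PopulationState(degrees, time=0.0)
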