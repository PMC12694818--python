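"""The Kimura distribution of allele frequency under pure random drift, and a
simulation-based neutral null for heteroplasmy-shift data.

The end state of neutral drift from an initial mutant fraction ``p`` is a
mixture of point masses at 0 (loss) and 1 (fixation) with a continuous
density on (0, 1).  It is parameterised here by the drift parameter ``b`` in
``[0, 1)``; the end-state variance is ``p(1-p)(1-b)``.  For a haploid
Wright-Fisher population of ``N`` copies after ``t`` generations,
``b = (1 - 1/N)**t``.

The classical series solution expands in Gauss hypergeometric terms
``F(1-i, i+2, 2, x)``; these are evaluated through the stable Jacobi
polynomial identity ``F(1-i, i+2, 2, x) = P_{i-1}^{(1,1)}(1-2x) / i``:

.. math::

    f(x)  &= \\sum_{i\\ge 1} i(i+1)(2i+1)\\,pq\\,F_i(p)F_i(x)\\,b^{i(i+1)/2} \\\\
    P_0   &= q - \\sum_{i\\ge 1} (2i+1)\\,pq\\,F_i(p)\\,b^{i(i+1)/2} \\\\
    P_1   &= p + \\sum_{i\\ge 1} (2i+1)\\,pq\\,(-1)^i F_i(p)\\,b^{i(i+1)/2}

with ``q = 1-p`` (both boundary forms use the Jacobi reflection
``F_i(1-p) = (-1)^{i-1} F_i(p)``).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy.special import eval_jacobi

from .errors import ConvergenceError, InsufficientDataError
from .core import log_shifts

__all__ = [
    "KimuraParams",
    "KimuraDistribution",
    "kimura_distribution",
    "kimura_sample",
    "wright_fisher_b",
    "BEstimate",
    "estimate_b",
    "NeutralNullResult",
    "neutral_null_test",
]

_MAX_TERMS = 500
_GRID_POINTS = 2001
#: below this end-state variance the distribution is treated as degenerate at p
_DEGENERATE_VARIANCE = 1e-6
#: weights below this underflow guard are dropped outright
_MIN_WEIGHT = 1e-300


def wright_fisher_b(n_copies: int, generations: int) -> float:
    """Drift parameter of ``generations`` Wright-Fisher steps at ``n_copies``."""
    if n_copies < 2 or generations < 0:
        raise ValueError("need n_copies >= 2 and generations >= 0")
    return (1.0 - 1.0 / n_copies) ** generations


@dataclass(frozen=True)
class KimuraParams:
    """Initial mutant fraction ``p`` and drift parameter ``b``.

    ``b = 1`` (no drift at all) is accepted only as a limit: values so close
    to 1 that the end-state variance is negligible yield a degenerate
    distribution concentrated at ``p``.
    """

    p: float
    b: float

    def __post_init__(self):
        if not (0.0 < self.p < 1.0):
            raise ValueError(f"p must lie in (0, 1), got {self.p}")
        if not (0.0 <= self.b <= 1.0):
            raise ValueError(f"b must lie in [0, 1], got {self.b}")

    @property
    def variance(self) -> float:
        """End-state variance ``p(1-p)(1-b)`` including the boundary masses."""
        return self.p * (1.0 - self.p) * (1.0 - self.b)


def _f_term(i: int, x) -> np.ndarray:
    """``F(1-i, i+2, 2, x)`` via the Jacobi polynomial recurrence (stable)."""
    return eval_jacobi(i - 1, 1, 1, 1.0 - 2.0 * np.asarray(x, dtype=float)) / i


@lru_cache(maxsize=8)
def _gauss_legendre_01(n: int) -> tuple[np.ndarray, np.ndarray]:
    nodes, weights = np.polynomial.legendre.leggauss(n)
    return 0.5 * (nodes + 1.0), 0.5 * weights


class KimuraDistribution:
    """Loss/fixation masses plus a continuous density on (0, 1).

    Build instances through :func:`kimura_distribution`.
    """

    def __init__(self, params: KimuraParams, tolerance: float = 1e-6):
        if not (0.0 < tolerance <= 1e-3):
            raise ValueError("tolerance must lie in (0, 1e-3]")
        self.params = params
        self.tolerance = tolerance
        p, b = params.p, params.b
        q = 1.0 - p

        if params.variance < _DEGENERATE_VARIANCE:
            # no-drift limit: all mass concentrates at p
            self.degenerate = True
            self.loss_mass = 0.0
            self.fixation_mass = 0.0
            self.truncation_order = 0
            self._i = np.empty(0, dtype=int)
            self._dens_coef = np.empty(0)
            self._grid = None
            return
        self.degenerate = False

        target = tolerance * 1e-3
        idx: list[int] = []
        fi_p: list[float] = []
        wts: list[float] = []
        residual = math.inf
        for i in range(1, _MAX_TERMS + 1):
            log_w = 0.5 * i * (i + 1) * math.log(b) if b > 0 else -math.inf
            if log_w < math.log(_MIN_WEIGHT):
                residual = 0.0
                break
            w = math.exp(log_w)
            # |F_i| <= 1 on [0,1], so this bounds the density term supremum
            residual = i * (i + 1) * (2 * i + 1) * p * q * w
            idx.append(i)
            fi_p.append(float(_f_term(i, p)))
            wts.append(w)
            if residual < target:
                break
        else:
            raise ConvergenceError(
                f"Kimura series did not converge within {_MAX_TERMS} terms "
                f"(residual bound {residual:.3g})",
                residual=residual,
            )

        self.truncation_order = len(idx)
        i_arr = np.asarray(idx, dtype=float)
        fi_p_arr = np.asarray(fi_p)
        w_arr = np.asarray(wts)
        base = (2.0 * i_arr + 1.0) * p * q * fi_p_arr * w_arr
        self._i = np.asarray(idx, dtype=int)
        self._dens_coef = i_arr * (i_arr + 1.0) * base
        signs = np.where(self._i % 2 == 0, 1.0, -1.0)
        # boundary-mass series; the fixation form uses the Jacobi reflection
        # F_i(1-p) = (-1)^(i-1) F_i(p)
        self.loss_mass = float(q - np.sum(base))
        self.fixation_mass = float(p + np.sum(signs * base))
        # numerical dust at very strong drift can push masses a hair outside [0,1]
        self.loss_mass = min(max(self.loss_mass, 0.0), 1.0)
        self.fixation_mass = min(max(self.fixation_mass, 0.0), 1.0)
        self._grid = None

        total = self.total_mass()
        if abs(total - 1.0) > max(tolerance, 1e-6):
            raise ConvergenceError(
                f"mass conservation violated: total {total:.8f}",
                residual=abs(total - 1.0),
            )

    # -- pointwise density -------------------------------------------------

    def density(self, x) -> np.ndarray:
        """Continuous part of the distribution, evaluated pointwise on (0, 1)."""
        x = np.asarray(x, dtype=float)
        if self.degenerate:
            return np.zeros_like(x)
        out = np.zeros_like(x)
        for i, c in zip(self._i, self._dens_coef):
            out += c * _f_term(int(i), x)
        return out

    # -- moments -----------------------------------------------------------

    def _quadrature(self) -> tuple[np.ndarray, np.ndarray]:
        # density is a polynomial of degree truncation_order - 1; n nodes
        # integrate x^2 * f exactly once 2n - 1 >= degree + 2
        n = max(64, self.truncation_order // 2 + 8)
        return _gauss_legendre_01(n)

    def interior_mass(self) -> float:
        if self.degenerate:
            return 0.0
        x, w = self._quadrature()
        return float(np.sum(w * self.density(x)))

    def total_mass(self) -> float:
        """``P0 + P1 + integral of f``; equals 1 for a converged series."""
        if self.degenerate:
            return 1.0
        return self.loss_mass + self.fixation_mass + self.interior_mass()

    def mean(self) -> float:
        """First moment including boundary masses; equals ``p``."""
        if self.degenerate:
            return self.params.p
        x, w = self._quadrature()
        return float(self.fixation_mass + np.sum(w * x * self.density(x)))

    def variance(self) -> float:
        """Second central moment including masses; equals ``p(1-p)(1-b)``."""
        if self.degenerate:
            return 0.0
        x, w = self._quadrature()
        m2 = self.fixation_mass + float(np.sum(w * x * x * self.density(x)))
        return m2 - self.mean() ** 2

    # -- sampling ----------------------------------------------------------

    def _cdf_grid(self) -> tuple[np.ndarray, np.ndarray]:
        """Interior CDF tabulated on a uniform grid, renormalised so the
        mixture (P0, interior, P1) sums to exactly 1."""
        if self._grid is None:
            x = np.linspace(0.0, 1.0, _GRID_POINTS)
            f = self.density(x)
            np.maximum(f, 0.0, out=f)
            steps = 0.5 * (f[1:] + f[:-1]) * np.diff(x)
            cdf = np.concatenate([[0.0], np.cumsum(steps)])
            interior = 1.0 - self.loss_mass - self.fixation_mass
            if cdf[-1] > 0:
                cdf *= interior / cdf[-1]
            self._grid = (x, cdf)
        return self._grid

    def sample(self, n: int, rng: np.random.Generator | int | None = None) -> np.ndarray:
        """Draw ``n`` i.i.d. values from the mixture.

        Boundary atoms are resolved first from a uniform draw; interior draws
        use inverse-CDF interpolation on the tabulated grid.
        """
        if n < 1:
            raise ValueError("n must be >= 1")
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        if self.degenerate:
            warnings.warn("degenerate Kimura distribution: all samples equal p",
                          stacklevel=2)
            return np.full(n, self.params.p)
        u = rng.random(n)
        out = np.empty(n)
        p0 = self.loss_mass
        p1 = self.fixation_mass
        lost = u < p0
        fixed = u > 1.0 - p1
        interior = ~(lost | fixed)
        out[lost] = 0.0
        out[fixed] = 1.0
        if interior.any():
            x, cdf = self._cdf_grid()
            out[interior] = np.interp(u[interior] - p0, cdf, x)
        return out


def kimura_distribution(params: KimuraParams | None = None,
                        tolerance: float = 1e-6,
                        *, p: float | None = None,
                        b: float | None = None) -> KimuraDistribution:
    """Construct the drift distribution for ``params`` (or ``p=…, b=…``)."""
    if params is None:
        if p is None or b is None:
            raise ValueError("provide KimuraParams or both p and b")
        params = KimuraParams(p=p, b=b)
    return KimuraDistribution(params, tolerance=tolerance)


def kimura_sample(dist: KimuraDistribution, n: int,
                  seed: np.random.Generator | int | None = None) -> np.ndarray:
    """Seeded i.i.d. sampling; see :meth:`KimuraDistribution.sample`."""
    return dist.sample(n, rng=seed)


# ---------------------------------------------------------------------------
# Drift-parameter estimation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BEstimate:
    """Moment estimate of the drift parameter from (h0, h) pairs."""

    b_hat: float
    at_upper_limit: bool = False
    clamped_low: bool = False

    def __float__(self) -> float:  # allows use where a bare float is expected
        return self.b_hat


def estimate_b(h0: Sequence[float], h: Sequence[float] | None = None) -> BEstimate:
    """Variance-matching estimator ``b_hat = 1 - sum((h-h0)^2) / sum(h0(1-h0))``.

    Accepts either two parallel arrays or a single sequence of ``(h0, h)``
    pairs.  The raw estimate is clamped into ``[0, 1)``; clamping in either
    direction is flagged on the returned :class:`BEstimate`.
    """
    if h is None:
        arr = np.asarray(list(h0), dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("expected a sequence of (h0, h) pairs")
        h0arr, harr = arr[:, 0], arr[:, 1]
    else:
        h0arr = np.asarray(h0, dtype=float)
        harr = np.asarray(h, dtype=float)
    if h0arr.size < 2:
        raise InsufficientDataError("estimate_b needs at least 2 pairs")
    if np.any((h0arr <= 0) | (h0arr >= 1)):
        raise ValueError("all h0 must be interior (0, 1)")
    denom = float(np.sum(h0arr * (1.0 - h0arr)))
    raw = 1.0 - float(np.sum((harr - h0arr) ** 2)) / denom
    if raw >= 1.0:  # zero dispersion: no drift detected, b -> 1 limit
        warnings.warn("no dispersion between h and h0; b_hat at its b->1 limit",
                      stacklevel=2)
        return BEstimate(b_hat=1.0 - 1e-12, at_upper_limit=True)
    if raw < 0.0:
        warnings.warn(f"raw drift estimate {raw:.4f} < 0; clamped to 0",
                      stacklevel=2)
        return BEstimate(b_hat=0.0, clamped_low=True)
    return BEstimate(b_hat=raw)


# ---------------------------------------------------------------------------
# Simulation-based neutral null on the log-shift scale
# ---------------------------------------------------------------------------

@dataclass
class NeutralNullResult:
    """Observed log shifts against a pooled Kimura-drift null."""

    observed_shifts: np.ndarray
    simulated_shifts: np.ndarray
    multiplier: int
    b_hat: float
    ks_statistic: float
    p_value: float
    mean_difference: float
    n_observed: int
    n_simulated: int
    boundary_exclusions: dict = field(default_factory=dict)

    def density_curves(self, n_grid: int = 256) -> dict[str, np.ndarray]:
        """Gaussian-KDE density coordinates for plotting parity."""
        from scipy.stats import gaussian_kde

        lo = min(self.observed_shifts.min(), self.simulated_shifts.min())
        hi = max(self.observed_shifts.max(), self.simulated_shifts.max())
        pad = 0.05 * (hi - lo + 1e-9)
        x = np.linspace(lo - pad, hi + pad, n_grid)
        return {
            "x": x,
            "observed_density": gaussian_kde(self.observed_shifts)(x),
            "simulated_density": gaussian_kde(self.simulated_shifts)(x),
        }


def _ks_distance(sample: np.ndarray, ref_sorted: np.ndarray) -> float:
    """Two-sample KS distance of ``sample`` against a (large) sorted pool,
    evaluated at the sample's jump points."""
    s = np.sort(sample)
    n = s.size
    ref_cdf = np.searchsorted(ref_sorted, s, side="right") / ref_sorted.size
    grid = np.arange(1, n + 1) / n
    d_plus = np.max(grid - ref_cdf)
    d_minus = np.max(ref_cdf - (grid - 1.0 / n))
    return float(max(d_plus, d_minus))


def _pair_arrays(pairs) -> tuple[np.ndarray, np.ndarray, list]:
    h0, h, keys = [], [], []
    for rec in pairs:
        if hasattr(rec, "mother_h"):
            h0.append(rec.mother_h)
            h.append(rec.pup_h)
            keys.append(getattr(rec, "mother_id", None))
        else:
            a, bb = rec
            h0.append(a)
            h.append(bb)
            keys.append(None)
    if any(k is None for k in keys):
        keys = [f"{v:.12g}" for v in h0]  # group by maternal value
    return np.asarray(h0), np.asarray(h), keys


def neutral_null_test(pairs, multiplier: int = 1000,
                      seed: int | None = 0, n_null: int = 199,
                      boundary_policy: str = "exclude") -> NeutralNullResult:
    """Compare observed transmission shifts against a simulated neutral null.

    The drift parameter is estimated from the pairs by variance matching, so
    the null is matched in dispersion and the comparison is sensitive to
    location/shape departures (selection).  For every mother, ``multiplier``
    draws from ``Kimura(h0, b_hat)`` form the pooled null; observed and
    simulated values are transformed to log shifts (boundary draws handled by
    ``boundary_policy`` and counted).  The two-sample KS distance of the
    observed shifts against the pool is referred to ``n_null`` re-simulated
    datasets of the observed size, giving a Monte-Carlo p-value.

    Draws are split into per-mother streams keyed by the mother's rank in the
    sorted mother list, so results do not depend on input record order.
    """
    h0_all, h_all, keys = _pair_arrays(pairs)
    usable = (h0_all > 0) & (h0_all < 1)
    n_dropped_mothers = int((~usable).sum())
    h0_all, h_all = h0_all[usable], h_all[usable]
    keys = [k for k, u in zip(keys, usable) if u]
    if h0_all.size < 10:
        raise InsufficientDataError(
            f"neutral_null_test needs >= 10 usable pairs, got {h0_all.size}")

    b_hat = estimate_b(h0_all, h_all).b_hat

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        obs_shifts, obs_excluded = log_shifts(h_all, h0_all, policy=boundary_policy)

    # deterministic mother ordering -> order-invariant stream splitting
    order = sorted(set(keys))
    mother_index = {k: j for j, k in enumerate(order)}

    key_arr = np.asarray(keys, dtype=object)
    pool_parts: list[np.ndarray] = []
    pool_h0_parts: list[np.ndarray] = []
    null_parts: list[list[np.ndarray]] = [[] for _ in range(n_null)]
    null_h0_parts: list[list[np.ndarray]] = [[] for _ in range(n_null)]
    for key in order:
        sel = key_arr == key
        m = int(sel.sum())
        h0_m = float(h0_all[sel][0])
        dist = kimura_distribution(p=h0_m, b=b_hat)
        rng = np.random.default_rng([0 if seed is None else seed,
                                     mother_index[key]])
        draws = dist.sample(m * (multiplier + n_null), rng=rng)
        pool_parts.append(draws[: m * multiplier])
        pool_h0_parts.append(np.full(m * multiplier, h0_m))
        rest = draws[m * multiplier:].reshape(n_null, m)
        h0_block = np.full(m, h0_m)
        for r in range(n_null):
            null_parts[r].append(rest[r])
            null_h0_parts[r].append(h0_block)

    pool_h = np.concatenate(pool_parts)
    pool_h0 = np.concatenate(pool_h0_parts)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sim_shifts, sim_excluded = log_shifts(pool_h, pool_h0,
                                              policy=boundary_policy)

    sim_sorted = np.sort(sim_shifts)
    ks_obs = _ks_distance(obs_shifts, sim_sorted)

    exceed = 0
    for r in range(n_null):
        rep_h = np.concatenate(null_parts[r])
        rep_h0 = np.concatenate(null_h0_parts[r])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep_shifts, _ = log_shifts(rep_h, rep_h0, policy=boundary_policy)
        if rep_shifts.size == 0:
            continue
        if _ks_distance(rep_shifts, sim_sorted) >= ks_obs:
            exceed += 1
    p_value = (1 + exceed) / (1 + n_null)

    return NeutralNullResult(
        observed_shifts=obs_shifts,
        simulated_shifts=sim_shifts,
        multiplier=multiplier,
        b_hat=b_hat,
        ks_statistic=ks_obs,
        p_value=p_value,
        mean_difference=float(obs_shifts.mean() - sim_shifts.mean()),
        n_observed=int(obs_shifts.size),
        n_simulated=int(sim_shifts.size),
        boundary_exclusions={
            "observed": int(obs_excluded),
            "simulated": int(sim_excluded),
            "noninterior_mothers": n_dropped_mothers,
        },
    )
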