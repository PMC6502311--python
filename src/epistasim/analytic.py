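"""Closed-form trajectory of relative hybrid fitness.

Under divergence with constant mean within-population epistasis
(eps_w), constant mean between-population epistasis (eps_b), a
fraction F of the n substitutions in population 1 (symmetry parameter
v = F(1-F)), additive dominance of independent effects (h = 1/2) and
small fitness effects, relative F1 hybrid fitness is approximately

    w_H(n) = exp{ eps_b * alpha1 * v * n^2
                  - eps_w * (1/2 - alpha1) * [ (1/2 - v) n^2 - n/2 ] }

The first term collects the interactions first created in hybrids
(between-population pairs, each heterozygous, hence scaled by the
epistatic dominance alpha1); the second collects the parental
within-population interactions that hybrids lose.  With v = 1/4 and
alpha1 = 1/4 the quadratic terms cancel when eps_b = eps_w, so log
hybrid fitness is exactly linear in n — no snowball.  When
0 < eps_b < eps_w there is a transient heterosis phase that ends,
and postzygotic isolation begins, at the positive root of the log
trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq


def symmetry_v(F: float) -> float:
    """Symmetry of divergence v = F(1-F).

    1/4 when substitutions accrue at equal rates in the two
    populations, 0 when only one population evolves.
    """
    if not 0 <= F <= 1:
        raise ValueError(f"F must lie in [0, 1], got {F}")
    return F * (1.0 - F)


@dataclass(frozen=True)
class AnalyticParams:
    """Parameters of the closed-form hybrid-fitness trajectory.

    Either ``F`` or ``v`` may be given; supplying ``F`` sets
    ``v = F(1-F)``. ``n`` is the total number of substitutions across
    both populations, treated as a nonnegative real.
    """

    eps_w: float
    eps_b: float
    alpha1: float = 0.25
    v: float | None = None
    F: float | None = None
    n: float = 0.0

    def __post_init__(self) -> None:
        if self.F is not None:
            v_from_f = symmetry_v(self.F)
            if self.v is not None and not np.isclose(self.v, v_from_f, atol=1e-12):
                raise ValueError("inconsistent F and v supplied")
            object.__setattr__(self, "v", v_from_f)
        if self.v is None:
            object.__setattr__(self, "v", 0.25)
        if not 0 <= self.v <= 0.25:
            raise ValueError(f"v must lie in [0, 1/4], got {self.v}")
        if not 0 <= self.alpha1 <= 1:
            raise ValueError("alpha1 must lie in [0, 1]")
        if self.n < 0:
            raise ValueError("n must be nonnegative")


def log_relative_fitness(
    params: AnalyticParams, n: float | np.ndarray | None = None
) -> float | np.ndarray:
    """Log of the closed-form relative hybrid fitness at n substitutions."""
    if n is None:
        n = params.n
    n = np.asarray(n, dtype=float)
    out = params.eps_b * params.alpha1 * params.v * n**2 - params.eps_w * (
        0.5 - params.alpha1
    ) * ((0.5 - params.v) * n**2 - 0.5 * n)
    return out if out.ndim else float(out)


def analytic_relative_fitness(
    params: AnalyticParams, n: float | np.ndarray | None = None
) -> float | np.ndarray:
    """Closed-form relative hybrid fitness w_H at n total substitutions."""
    return np.exp(log_relative_fitness(params, n))


def heterosis_window(
    eps_w: float,
    eps_b: float,
    v: float = 0.25,
    alpha1: float = 0.25,
) -> float | None:
    """Smallest positive n at which log w_H returns to zero.

    The log trajectory is a quadratic through the origin,
    Q n^2 + L n with Q = eps_b*alpha1*v - eps_w*(1/2-alpha1)*(1/2-v)
    and L = eps_w*(1/2-alpha1)/2, so a finite crossing exists exactly
    when -L/Q > 0; its location is refined numerically.  Returns
    ``None`` when hybrid fitness never recrosses 1 for n > 0.
    """
    params = AnalyticParams(eps_w=eps_w, eps_b=eps_b, v=v, alpha1=alpha1)
    quad = eps_b * alpha1 * v - eps_w * (0.5 - alpha1) * (0.5 - v)
    lin = eps_w * (0.5 - alpha1) * 0.5
    if quad == 0 or lin == 0:
        return None
    n_star = -lin / quad
    if n_star <= 0:
        return None
    # refine by root-finding on the full expression
    f = lambda n: log_relative_fitness(params, n)
    lo, hi = 0.5 * n_star, 1.5 * n_star
    if f(lo) * f(hi) > 0:  # pathological scaling; widen
        lo, hi = 1e-12, 10 * n_star
    return float(brentq(f, lo, hi, xtol=1e-12, rtol=1e-12))


def trajectory_table(
    params: AnalyticParams, n_max: int
) -> "np.ndarray":
    """(n, w_H) pairs for integer substitution counts 0..n_max."""
    n = np.arange(n_max + 1, dtype=float)
    return np.column_stack([n, analytic_relative_fitness(params, n)])
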