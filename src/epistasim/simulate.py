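"""Sequential substitution in two allopatric populations.

Divergence is modelled in the mutation-limited (origin-fixation)
regime: populations are monomorphic except for one new mutation at a
time, and evolution is a sequence of fixation events.  At each step
every locus not yet fixed in either population is a candidate; its
probability of fixation is computed from its background-dependent
effective selection coefficient and dominance (the independent effect
compounded with epistatic interactions with mutations already fixed in
the same population) via Kimura's diffusion approximation, and one
locus is drawn with probability proportional to that fixation
probability.  No locus may fix in both populations.

The diffusion fixation probability of a new mutation at initial
frequency p = 1/(2 N_e) is

    u = int_0^p G(x) dx / int_0^1 G(x) dx,
    G(x) = exp{ -2 N_e sigma x [2 omega + (1 - 2 omega) x] }

which reduces to (1 - e^-sigma) / (1 - e^-2 N_e sigma) at additive
dominance (omega = 1/2).  The general case is integrated numerically
with the quadratic exponent handled in log space, so that strongly
deleterious mutations underflow cleanly to u = 0 rather than
overflowing the integrand.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial.legendre import leggauss

from epistasim.fitness import BackgroundProducts, DominanceParams
from epistasim.network import EpistasisNetwork

__all__ = [
    "SimulationConfig",
    "PopulationState",
    "FixationEvent",
    "DivergenceResult",
    "fixation_probability",
    "candidate_weights",
    "fix_next",
    "run_divergence",
    "run_replicates",
]


# ---------------------------------------------------------------------------
# Kimura diffusion fixation probability
# ---------------------------------------------------------------------------

# Gauss-Legendre nodes on geometrically shrinking segments of [0, 1].
# The integrand exp(-a y^2 - b y) is monotone decreasing on the
# canonical segment, with a decay scale anywhere between O(1) and
# O(1e-12); geometric segments resolve every scale at once.
def _build_grid(n_segments: int = 57, order: int = 12, floor: float = 1e-14):
    edges = np.concatenate([[0.0], np.geomspace(floor, 1.0, n_segments)])
    gx, gw = leggauss(order)
    xs, ws = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        half = 0.5 * (hi - lo)
        xs.append(lo + half * (gx + 1.0))
        ws.append(half * gw)
    return np.concatenate(xs), np.concatenate(ws)


_GRID_X, _GRID_W = _build_grid()


def _log_canonical(a: np.ndarray, b: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """log of int_0^Y exp(-a y^2 - b y) dy for a monotone-decreasing integrand.

    Requires b >= 0 and 2 a Y + b >= 0 (integrand falls from 1 at 0);
    exp never exceeds 1, so only harmless underflow can occur.
    """
    y = Y[:, None] * _GRID_X[None, :]
    f = -(a[:, None] * y + b[:, None]) * y
    with np.errstate(under="ignore"):
        vals = np.exp(f)
    return np.log(Y) + np.log(vals @ _GRID_W)


def _log_integral(a: np.ndarray, b: np.ndarray, U: float) -> np.ndarray:
    """log of int_0^U exp(-a x^2 - b x) dx for arbitrary quadratic exponents.

    The exponent's extremum at x* = -b / (2a) may fall inside (0, U);
    the integral is split there so each piece is monotone and can be
    rescaled by its own peak value before exponentiation.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n = a.shape[0]
    Uv = np.full(n, float(U))
    out = np.empty(n)

    slope0 = -b          # f'(0)
    slopeU = -(2 * a * U + b)  # f'(U)

    dec = (slope0 <= 0) & (slopeU <= 0)          # falling throughout
    inc = (slope0 >= 0) & (slopeU >= 0) & ~dec   # rising throughout
    interior = ~(dec | inc)                      # extremum inside (0, U)

    if np.any(dec):
        out[dec] = _log_canonical(a[dec], b[dec], Uv[dec])
    if np.any(inc):
        # reverse about U: offset by the peak value f(U)
        fU = -(a[inc] * U + b[inc]) * U
        out[inc] = fU + _log_canonical(a[inc], -(2 * a[inc] * U + b[inc]), Uv[inc])
    if np.any(interior):
        ai, bi = a[interior], b[interior]
        xs = -bi / (2 * ai)
        fs = -(ai * xs + bi) * xs
        res = np.empty(xs.shape[0])
        peak = ai > 0  # interior maximum: rise to x*, fall after
        if np.any(peak):
            left = _log_canonical(ai[peak], np.zeros(peak.sum()), xs[peak])
            right = _log_canonical(ai[peak], np.zeros(peak.sum()), U - xs[peak])
            res[peak] = fs[peak] + np.logaddexp(left, right)
        trough = ~peak  # interior minimum: fall to x*, rise after
        if np.any(trough):
            at, bt = ai[trough], bi[trough]
            xt = xs[trough]
            left = _log_canonical(at, bt, xt)
            fU = -(at * U + bt) * U
            right = fU + _log_canonical(at, -(2 * at * U + bt), U - xt)
            res[trough] = np.logaddexp(left, right)
        out[interior] = res
    return out


def _u_closed_form(sigma: np.ndarray, N: float) -> np.ndarray:
    """(1 - e^-sigma) / (1 - e^-2N sigma), stable for large |2N sigma|."""
    sigma = np.asarray(sigma, dtype=float)
    with np.errstate(over="ignore"):
        den = np.expm1(-2.0 * N * sigma)
        num = np.expm1(-sigma)
    u = np.where(np.isfinite(den) & (den != 0), -num / np.where(den == 0, 1, -den), 0.0)
    return np.clip(u, 0.0, 1.0)


def _u_from_selection(
    sigma: np.ndarray,
    het_sel: np.ndarray,
    effective_size: float,
    force_quadrature: bool = False,
) -> np.ndarray:
    """Vectorised fixation probability from homozygous selection ``sigma``
    and heterozygous selection ``het_sel = sigma * omega``."""
    sigma = np.atleast_1d(np.asarray(sigma, dtype=float))
    het_sel = np.atleast_1d(np.asarray(het_sel, dtype=float))
    N = float(effective_size)
    p = 1.0 / (2.0 * N)
    u = np.full(sigma.shape, p)

    lethal = sigma <= -1.0
    neutral = (sigma == 0.0) & (het_sel == 0.0)
    a = 2.0 * N * (sigma - 2.0 * het_sel)  # quadratic coefficient of -log G
    b = 4.0 * N * het_sel
    additive = (a == 0.0) & ~neutral & ~lethal & (not force_quadrature)
    general = ~(lethal | neutral | additive)

    if np.any(additive):
        u[additive] = _u_closed_form(sigma[additive], N)
    if np.any(general):
        ag, bg = a[general], b[general]
        log_u = _log_integral(ag, bg, p) - _log_integral(ag, bg, 1.0)
        with np.errstate(under="ignore"):
            u[general] = np.clip(np.exp(log_u), 0.0, 1.0)
    u[lethal] = 0.0
    return u


def fixation_probability(
    sigma: float,
    omega: float,
    effective_size: float,
    force_quadrature: bool = False,
) -> float:
    """Kimura diffusion fixation probability of a new mutation.

    ``sigma`` and ``omega`` are the (effective) selection coefficient
    and dominance; the initial frequency is one copy, 1/(2 N_e).
    Neutral mutations fix with probability exactly 1/(2 N_e); at
    ``omega = 1/2`` the additive closed form is used unless
    ``force_quadrature`` requests the numerical path (useful for
    validating the quadrature).  ``sigma <= -1`` is lethal (u = 0).
    """
    if sigma <= -1.0:
        return 0.0
    u = _u_from_selection(
        np.array([sigma]), np.array([sigma * omega]), effective_size,
        force_quadrature=force_quadrature,
    )
    return float(u[0])


# ---------------------------------------------------------------------------
# Simulation configuration and state
# ---------------------------------------------------------------------------


@dataclass
class SimulationConfig:
    """Parameters of a divergence run.

    ``alternation`` is ``"strict"`` (populations fix in turn, realising
    F = 1/2) or ``"random"`` (the next fixing population is drawn with
    probability weight ``rate_ratio`` for A versus 1 for B, giving
    asymmetric divergence when ``rate_ratio != 1``).
    """

    effective_size: float = 1e6
    fixations_per_population: int = 50
    dominance: DominanceParams = field(default_factory=DominanceParams)
    alternation: str = "strict"
    rate_ratio: float = 1.0
    seed: int = 0
    replicate_count: int = 1

    def __post_init__(self) -> None:
        if self.effective_size < 2:
            raise ValueError("effective_size must be >= 2")
        if self.fixations_per_population < 1:
            raise ValueError("fixations_per_population must be >= 1")
        if self.alternation not in ("strict", "random"):
            raise ValueError(f"unknown alternation scheme {self.alternation!r}")
        if self.rate_ratio <= 0:
            raise ValueError("rate_ratio must be positive")
        if self.replicate_count < 1:
            raise ValueError("replicate_count must be >= 1")


@dataclass
class PopulationState:
    """Ordered set of loci fixed in one diverging population."""

    label: str
    fixed: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class FixationEvent:
    step: int
    population: str
    locus: str
    sigma_at_fixation: float
    fixation_probability: float


@dataclass
class DivergenceResult:
    """One replicate: final states, audit trail and per-step trajectory."""

    replicate: int
    pop_A: PopulationState
    pop_B: PopulationState
    events: list[FixationEvent]
    trajectory: pd.DataFrame
    stuck: bool = False


# ---------------------------------------------------------------------------
# Reference (small-scale) candidate machinery
# ---------------------------------------------------------------------------


def candidate_weights(
    network: EpistasisNetwork,
    state_self: PopulationState,
    state_other: PopulationState,
    config: SimulationConfig,
) -> dict[str, float]:
    """Fixation-probability weight of every available locus.

    Available loci are those fixed in neither population; each weight
    is the Kimura fixation probability of the locus's effective
    selection coefficient in ``state_self``'s background.  Weights are
    unnormalised.
    """
    taken = set(state_self.fixed) | set(state_other.fixed)
    bp = BackgroundProducts(network, config.dominance)
    for lab in state_self.fixed:
        bp.add_fixed(network.index(lab))
    avail = np.array(
        [k for k, lab in enumerate(network.locus_ids) if lab not in taken],
        dtype=np.int64,
    )
    if avail.size == 0:
        return {}
    u = _u_from_selection(
        bp.sigma(avail), bp.het_selection(avail), config.effective_size
    )
    return {network.locus_ids[k]: float(w) for k, w in zip(avail, u)}


def fix_next(
    network: EpistasisNetwork,
    state_self: PopulationState,
    state_other: PopulationState,
    config: SimulationConfig,
    rng: np.random.Generator,
    step: int = 0,
) -> FixationEvent:
    """Sample one fixation in ``state_self`` proportional to fixation
    probability and append it to the state."""
    weights = candidate_weights(network, state_self, state_other, config)
    labels = list(weights)
    w = np.array([weights[l] for l in labels])
    total = w.sum()
    if total <= 0:
        raise StuckPopulationError(state_self.label)
    bp = BackgroundProducts(network, config.dominance)
    for lab in state_self.fixed:
        bp.add_fixed(network.index(lab))
    choice = labels[rng.choice(len(labels), p=w / total)]
    idx = network.index(choice)
    sigma = float(bp.sigma(np.array([idx]))[0])
    event = FixationEvent(
        step=step,
        population=state_self.label,
        locus=choice,
        sigma_at_fixation=sigma,
        fixation_probability=float(weights[choice]),
    )
    state_self.fixed.append(choice)
    return event


class StuckPopulationError(RuntimeError):
    """No candidate locus has positive fixation probability."""

    def __init__(self, label: str) -> None:
        super().__init__(f"population {label} has no fixable mutation")
        self.label = label


# ---------------------------------------------------------------------------
# Full divergence run (incremental fast path)
# ---------------------------------------------------------------------------


class _FitnessLedger:
    """Incremental log-fitness and epistasis-component bookkeeping.

    Tracks parental log fitness, hybrid log fitness and the sums of
    epistatic coefficients among fixed pairs so each fixation costs
    O(neighbours) rather than O(pairs).  Lethal factors (clamped to 0)
    appear as -inf log fitness.
    """

    def __init__(self, network: EpistasisNetwork, dom: DominanceParams) -> None:
        self.net = network
        self.dom = dom
        self.log_parent = {"A": 0.0, "B": 0.0}
        self.log_hybrid = 0.0
        self.sum_within = {"A": 0.0, "B": 0.0}
        self.sum_between = 0.0
        self.members: dict[str, set[int]] = {"A": set(), "B": set()}

    @staticmethod
    def _log_factor(x: float) -> float:
        return math.log(x) if x > 0 else -math.inf

    def add(self, pop: str, idx: int) -> None:
        net, dom = self.net, self.dom
        other = "B" if pop == "A" else "A"
        s_i = net.s[idx]
        h_i = net.h[idx]
        self.log_parent[pop] += self._log_factor(1.0 + s_i)
        self.log_hybrid += self._log_factor(1.0 + h_i * s_i)
        neigh, eps = net.adjacency()[idx]
        for j, e in zip(neigh, eps):
            if j in self.members[pop]:
                self.log_parent[pop] += self._log_factor(1.0 + e)
                self.log_hybrid += self._log_factor(1.0 + dom.alpha1 * e)
                self.sum_within[pop] += e
            elif j in self.members[other]:
                self.log_hybrid += self._log_factor(1.0 + dom.alpha1 * e)
                self.sum_between += e
        self.members[pop].add(idx)

    def relative_hybrid_fitness(self) -> float:
        la, lb = self.log_parent["A"], self.log_parent["B"]
        m = max(la, lb)
        if m == -math.inf:
            return math.nan
        log_mean = m + math.log(0.5 * (math.exp(la - m) + math.exp(lb - m)))
        return math.exp(self.log_hybrid - log_mean)

    def components(self) -> tuple[float, float, float]:
        nA, nB = len(self.members["A"]), len(self.members["B"])
        wA = self.sum_within["A"] / (nA * (nA - 1) / 2) if nA >= 2 else math.nan
        wB = self.sum_within["B"] / (nB * (nB - 1) / 2) if nB >= 2 else math.nan
        bt = self.sum_between / (nA * nB) if nA and nB else math.nan
        return wA, wB, bt


def _next_population(
    config: SimulationConfig,
    counts: dict[str, int],
    rng: np.random.Generator,
    step: int,
) -> str:
    full = config.fixations_per_population
    open_pops = [p for p in ("A", "B") if counts[p] < full]
    if len(open_pops) == 1:
        return open_pops[0]
    if config.alternation == "strict":
        return "A" if step % 2 == 0 else "B"
    pA = config.rate_ratio / (config.rate_ratio + 1.0)
    return "A" if rng.random() < pA else "B"


def run_divergence(
    network: EpistasisNetwork,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    replicate: int = 0,
) -> DivergenceResult:
    """Simulate one replicate of divergence to the configured depth.

    Populations accumulate fixations under the alternation scheme until
    each holds ``fixations_per_population`` loci.  After every fixation
    the relative hybrid fitness and the mean epistatic coefficients
    among fixed pairs (within each population and between them) are
    recorded.  A replicate in which no candidate can fix is flagged
    ``stuck`` and returned truncated.
    """
    if network.n_loci < 2 * config.fixations_per_population:
        raise ValueError(
            "network must hold at least 2 * fixations_per_population loci"
        )
    if rng is None:
        rng = np.random.default_rng(config.seed)
    dom = config.dominance
    n = network.n_loci

    bp = {"A": BackgroundProducts(network, dom), "B": BackgroundProducts(network, dom)}
    available = np.ones(n, dtype=bool)
    u0 = _u_from_selection(
        bp["A"].sigma(np.arange(n)), bp["A"].het_selection(np.arange(n)),
        config.effective_size,
    )
    u = {"A": u0.copy(), "B": u0.copy()}

    ledger = _FitnessLedger(network, dom)
    states = {"A": PopulationState("A"), "B": PopulationState("B")}
    counts = {"A": 0, "B": 0}
    events: list[FixationEvent] = []
    rows: list[tuple] = [(replicate, 0, 0, 0, 1.0, math.nan, math.nan, math.nan)]
    stuck = False

    total = 2 * config.fixations_per_population
    for step in range(total):
        pop = _next_population(config, counts, rng, step)
        w = np.where(available, u[pop], 0.0)
        wsum = w.sum()
        if wsum <= 0:
            stuck = True
            break
        idx = int(rng.choice(n, p=w / wsum))
        sigma = float(bp[pop].sigma(np.array([idx]))[0])
        events.append(
            FixationEvent(
                step=step,
                population=pop,
                locus=network.locus_ids[idx],
                sigma_at_fixation=sigma,
                fixation_probability=float(u[pop][idx]),
            )
        )
        states[pop].fixed.append(network.locus_ids[idx])
        counts[pop] += 1
        available[idx] = False
        ledger.add(pop, idx)

        # only this population's background changed, and only at the
        # fixed locus's neighbours
        neigh = bp[pop].add_fixed(idx)
        changed = neigh[available[neigh]] if neigh.size else neigh
        if changed.size:
            u[pop][changed] = _u_from_selection(
                bp[pop].sigma(changed), bp[pop].het_selection(changed),
                config.effective_size,
            )
        wA, wB, bt = ledger.components()
        rows.append(
            (
                replicate,
                counts["A"] + counts["B"],
                counts["A"],
                counts["B"],
                ledger.relative_hybrid_fitness(),
                wA,
                wB,
                bt,
            )
        )

    trajectory = pd.DataFrame(
        rows,
        columns=[
            "replicate", "n", "n_A", "n_B", "w_H",
            "eps_within_A", "eps_within_B", "eps_between",
        ],
    )
    return DivergenceResult(
        replicate=replicate,
        pop_A=states["A"],
        pop_B=states["B"],
        events=events,
        trajectory=trajectory,
        stuck=stuck,
    )


def run_replicates(
    network: EpistasisNetwork,
    config: SimulationConfig,
    progress: bool = False,
) -> list[DivergenceResult]:
    """Run ``config.replicate_count`` independent replicates.

    Each replicate's random stream is derived from the global seed and
    the replicate index, so enlarging the replicate count never
    perturbs earlier replicates.
    """
    iterator = range(config.replicate_count)
    if progress:
        try:
            from tqdm import tqdm

            iterator = tqdm(iterator, desc="replicates")
        except ImportError:
            pass
    results = []
    for r in iterator:
        rng = np.random.default_rng([config.seed, r])
        results.append(run_divergence(network, config, rng=rng, replicate=r))
    return results


def trajectory_table(results: list[DivergenceResult]) -> pd.DataFrame:
    """Concatenate per-replicate trajectories (stuck replicates excluded)."""
    kept = [r.trajectory for r in results if not r.stuck]
    if not kept:
        raise ValueError("no completed replicates")
    return pd.concat(kept, ignore_index=True)
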