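"""Epistatic interaction networks from double-knockout fitness screens.

A network holds, for a set of loci, the independent selection
coefficient ``s_i`` of a knockout (single-mutant relative fitness
minus one), a per-locus dominance coefficient ``h_i``, and a sparse
symmetric map of pairwise epistatic coefficients ``eps_ij``.  Pairs
absent from the map interact with coefficient exactly zero, which is
also the defined epistasis of the common ancestor.

Three measures of epistasis are supported.  Writing ``W_i`` for the
single-knockout fitness and ``W_ij`` for the double knockout:

* ``multiplicative`` — ``eps = W_ij / (W_i * W_j) - 1``; the double
  mutant's deviation from the product of the singles, so that
  ``W_ij = (1 + s_i)(1 + s_j)(1 + eps)`` holds exactly.
* ``additive`` — ``eps = W_ij - W_i - W_j + 1``; deviation from
  additivity of fitness deficits.
* ``costanzo`` — ``eps = W_ij - W_i * W_j``; the unscaled residual
  used by the SGA genetic-interaction screens.

The synthetic generator draws networks whose marginal statistics mimic
genome-scale knockout screens: mostly-deleterious independent effects
with a mildly beneficial tail, near-zero-centred pairwise epistasis,
and a positive coupling between a mutation's independent effect and
the mean of its epistatic interactions.
"""

from __future__ import annotations

import gzip
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

MEASURES = ("multiplicative", "additive", "costanzo")

#: Column mapping for the 2016 genome-scale SGA release distributed at
#: thecellmap.org (tab-delimited, one header row).
COSTANZO_2016_COLUMNS = {
    "query_id": "Query allele name",
    "array_id": "Array allele name",
    "w_query": "Query single mutant fitness (SMF)",
    "w_array": "Array SMF",
    "w_double": "Double mutant fitness",
    "reported_epsilon": "Genetic interaction score (ε)",
    "p_value": "P-value",
}

_REQUIRED_FIELDS = ("query_id", "array_id", "w_query", "w_array", "w_double")
_OPTIONAL_FIELDS = ("reported_epsilon", "p_value")


@dataclass
class KnockoutRecord:
    """One row of a double-knockout fitness table.

    Fitness values are relative to wild type (wild type = 1) and must
    be nonnegative when present; a ``None`` marks a value the screen
    did not report.
    """

    query_id: str
    array_id: str
    w_query: float | None
    w_array: float | None
    w_double: float | None
    reported_epsilon: float | None = None
    p_value: float | None = None

    def __post_init__(self) -> None:
        if self.query_id == self.array_id:
            raise ValueError(f"self-pair record for locus {self.query_id!r}")
        for name in ("w_query", "w_array", "w_double"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")

    @property
    def complete(self) -> bool:
        return (
            self.w_query is not None
            and self.w_array is not None
            and self.w_double is not None
        )


class EpistasisNetwork:
    """Loci with independent effects and a sparse symmetric epistasis map."""

    def __init__(
        self,
        locus_ids: Sequence[str],
        s: Sequence[float],
        h: Sequence[float] | float | None = None,
        epsilon: Mapping[tuple[str, str], float] | None = None,
        measure: str = "multiplicative",
        metadata: dict | None = None,
    ) -> None:
        if measure not in MEASURES:
            raise ValueError(f"unknown measure {measure!r}; expected one of {MEASURES}")
        self.locus_ids = list(locus_ids)
        if len(set(self.locus_ids)) != len(self.locus_ids):
            raise ValueError("duplicate locus ids")
        self.s = np.asarray(s, dtype=float)
        if self.s.shape != (len(self.locus_ids),):
            raise ValueError("s must have one entry per locus")
        if np.any(self.s < -1):
            raise ValueError("selection coefficients must be >= -1")
        if h is None:
            h = 0.5
        if np.isscalar(h):
            self.h = np.full(len(self.locus_ids), float(h))
        else:
            self.h = np.asarray(h, dtype=float)
            if self.h.shape != (len(self.locus_ids),):
                raise ValueError("h must have one entry per locus")
        self.measure = measure
        self.metadata = dict(metadata or {})
        self._index = {lab: k for k, lab in enumerate(self.locus_ids)}
        self._eps: dict[tuple[int, int], float] = {}
        if epsilon is not None:
            for (a, b), value in epsilon.items():
                self._set_eps(a, b, float(value))
        self._adjacency: list[tuple[np.ndarray, np.ndarray]] | None = None

    # -- construction ------------------------------------------------

    def _set_eps(self, a: str, b: str, value: float) -> None:
        i, j = self._index[a], self._index[b]
        if i == j:
            raise ValueError(f"self-pair epistasis for locus {a!r}")
        if value < -1:
            raise ValueError("epistatic coefficients must be >= -1")
        key = (i, j) if i < j else (j, i)
        prev = self._eps.get(key)
        if prev is not None and not math.isclose(prev, value, rel_tol=0, abs_tol=1e-12):
            raise ValueError(f"conflicting epsilon for pair ({a!r}, {b!r})")
        self._eps[key] = value
        self._adjacency = None

    # -- queries -----------------------------------------------------

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    @property
    def n_pairs(self) -> int:
        return len(self._eps)

    def index(self, label: str) -> int:
        try:
            return self._index[label]
        except KeyError:
            raise KeyError(f"unknown locus {label!r}") from None

    def epsilon_of(self, a: str, b: str) -> float:
        """Epistatic coefficient for an unordered pair (0 if unstored)."""
        i, j = self.index(a), self.index(b)
        if i == j:
            raise ValueError("epsilon is defined for distinct loci only")
        return self._eps.get((i, j) if i < j else (j, i), 0.0)

    def epsilon_by_index(self, i: int, j: int) -> float:
        return self._eps.get((i, j) if i < j else (j, i), 0.0)

    def pairs(self) -> Iterable[tuple[str, str, float]]:
        for (i, j), value in self._eps.items():
            yield self.locus_ids[i], self.locus_ids[j], value

    def pair_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Stored pairs as parallel (i, j, eps) arrays of locus indices."""
        if not self._eps:
            return (
                np.empty(0, dtype=np.int64),
                np.empty(0, dtype=np.int64),
                np.empty(0, dtype=float),
            )
        keys = np.array(list(self._eps.keys()), dtype=np.int64)
        vals = np.array(list(self._eps.values()), dtype=float)
        return keys[:, 0], keys[:, 1], vals

    def adjacency(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """Per-locus (neighbour index array, eps array), cached."""
        if self._adjacency is None:
            lists: list[tuple[list[int], list[float]]] = [
                ([], []) for _ in self.locus_ids
            ]
            for (i, j), value in self._eps.items():
                lists[i][0].append(j)
                lists[i][1].append(value)
                lists[j][0].append(i)
                lists[j][1].append(value)
            self._adjacency = [
                (np.asarray(n, dtype=np.int64), np.asarray(e, dtype=float))
                for n, e in lists
            ]
        return self._adjacency

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EpistasisNetwork):
            return NotImplemented
        return (
            self.locus_ids == other.locus_ids
            and np.array_equal(self.s, other.s)
            and np.array_equal(self.h, other.h)
            and self._eps == other._eps
            and self.measure == other.measure
        )

    # -- serialization -----------------------------------------------

    def save(self, prefix: str | Path) -> None:
        """Write ``<prefix>.loci.tsv``, ``<prefix>.pairs.tsv`` and
        ``<prefix>.meta.yaml``."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        loci = pd.DataFrame(
            {"locus_id": self.locus_ids, "s": self.s, "h": self.h}
        )
        loci.to_csv(f"{prefix}.loci.tsv", sep="\t", index=False,
                    float_format="%.17g")
        ii, jj, ee = self.pair_arrays()
        pairs = pd.DataFrame(
            {
                "locus_i": [self.locus_ids[i] for i in ii],
                "locus_j": [self.locus_ids[j] for j in jj],
                "epsilon": ee,
            }
        )
        pairs.to_csv(f"{prefix}.pairs.tsv", sep="\t", index=False,
                     float_format="%.17g")
        with open(f"{prefix}.meta.yaml", "w") as fh:
            yaml.safe_dump(
                {"measure": self.measure, "metadata": self.metadata}, fh
            )

    @classmethod
    def load(cls, prefix: str | Path) -> "EpistasisNetwork":
        prefix = Path(prefix)
        loci = pd.read_csv(f"{prefix}.loci.tsv", sep="\t", dtype={"locus_id": str},
                           float_precision="round_trip")
        pairs = pd.read_csv(
            f"{prefix}.pairs.tsv", sep="\t", dtype={"locus_i": str, "locus_j": str},
            float_precision="round_trip",
        )
        with open(f"{prefix}.meta.yaml") as fh:
            meta = yaml.safe_load(fh) or {}
        eps = {
            (a, b): e
            for a, b, e in zip(pairs["locus_i"], pairs["locus_j"], pairs["epsilon"])
        }
        return cls(
            locus_ids=list(loci["locus_id"]),
            s=loci["s"].to_numpy(),
            h=loci["h"].to_numpy(),
            epsilon=eps,
            measure=meta.get("measure", "multiplicative"),
            metadata=meta.get("metadata") or {},
        )


# ---------------------------------------------------------------------------
# Loading and fitting interaction tables
# ---------------------------------------------------------------------------


def _open_text(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def load_interaction_table(
    paths: Sequence[str | Path],
    column_map: Mapping[str, str] | None = None,
) -> list[KnockoutRecord]:
    """Read tab-delimited double-knockout tables into records.

    Files are concatenated in input order, one record per data row.
    ``column_map`` maps the logical field names (``query_id``,
    ``array_id``, ``w_query``, ``w_array``, ``w_double`` and optionally
    ``reported_epsilon``, ``p_value``) to header names; it defaults to
    the 2016 genome-scale SGA release layout. Fitness cells that are
    empty or unparseable yield records with that field absent.
    """
    cmap = dict(COSTANZO_2016_COLUMNS if column_map is None else column_map)
    missing_fields = [f for f in _REQUIRED_FIELDS if f not in cmap]
    if missing_fields:
        raise ValueError(f"column_map lacks required fields: {missing_fields}")

    records: list[KnockoutRecord] = []
    for path in paths:
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(path)
        with _open_text(path) as fh:
            df = pd.read_csv(fh, sep="\t", dtype=str)
        absent = [c for c in cmap.values() if c not in df.columns]
        if absent:
            raise ValueError(
                f"{path}: columns {absent} not found; available: {list(df.columns)}"
            )
        numeric = {}
        for f in ("w_query", "w_array", "w_double") + _OPTIONAL_FIELDS:
            if f in cmap:
                numeric[f] = pd.to_numeric(df[cmap[f]], errors="coerce")
        for k in range(len(df)):
            def _get(f: str) -> float | None:
                if f not in numeric:
                    return None
                v = numeric[f].iloc[k]
                return None if pd.isna(v) else float(v)

            records.append(
                KnockoutRecord(
                    query_id=str(df[cmap["query_id"]].iloc[k]),
                    array_id=str(df[cmap["array_id"]].iloc[k]),
                    w_query=_get("w_query"),
                    w_array=_get("w_array"),
                    w_double=_get("w_double"),
                    reported_epsilon=_get("reported_epsilon"),
                    p_value=_get("p_value"),
                )
            )
    return records


def filter_complete(records: Iterable[KnockoutRecord]) -> list[KnockoutRecord]:
    """Retain records reporting both single fitnesses and the double.

    No significance filtering is applied: weak interactions carry
    information about the distribution of epistatic effects and
    dropping them by p-value would bias it toward large effects.
    """
    return [r for r in records if r.complete]


def estimate_effects(
    records: Sequence[KnockoutRecord],
    measure: str = "multiplicative",
    dedup: str = "mean",
    use_reported: bool = False,
    fitness_tolerance: float = 1e-6,
) -> EpistasisNetwork:
    """Fit per-locus selection coefficients and pairwise epistasis.

    Loci are identified by allele name; a locus measured in several
    strains or orientations has its single-mutant fitness resolved by
    ``dedup`` (``"mean"`` averages, ``"first"`` keeps the first seen).
    Pairs measured in both orientations are symmetrized by averaging
    the per-record epistasis values.  Under the multiplicative measure
    a pair with ``W_i * W_j == 0`` has undefined epistasis; such pairs
    are dropped and counted in ``network.metadata["dropped_zero_fitness_pairs"]``
    (a locus with single fitness 0 has ``s = -1`` and can never fix, so
    nothing downstream is lost).

    With ``use_reported=True`` and ``measure="costanzo"`` the published
    interaction score column is taken verbatim instead of being
    recomputed from the fitness columns.
    """
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}; expected one of {MEASURES}")
    if dedup not in ("mean", "first"):
        raise ValueError(f"unknown dedup strategy {dedup!r}")
    if use_reported and measure != "costanzo":
        raise ValueError("use_reported is only meaningful with measure='costanzo'")

    single: dict[str, list[float]] = {}
    pair_eps: dict[tuple[str, str], list[float]] = {}
    dropped_zero = 0

    for r in records:
        if not r.complete:
            raise ValueError("estimate_effects requires complete records; "
                             "apply filter_complete first")
        single.setdefault(r.query_id, []).append(r.w_query)
        single.setdefault(r.array_id, []).append(r.w_array)
        if use_reported:
            if r.reported_epsilon is None:
                continue
            eps = r.reported_epsilon
        elif measure == "multiplicative":
            denom = r.w_query * r.w_array
            if denom == 0:
                dropped_zero += 1
                continue
            eps = r.w_double / denom - 1.0
        elif measure == "additive":
            eps = r.w_double - r.w_query - r.w_array + 1.0
        else:  # costanzo
            eps = r.w_double - r.w_query * r.w_array
        key = (r.query_id, r.array_id) if r.query_id < r.array_id else (
            r.array_id, r.query_id)
        pair_eps.setdefault(key, []).append(eps)

    locus_ids = sorted(single)
    s = np.empty(len(locus_ids))
    for k, lab in enumerate(locus_ids):
        obs = single[lab]
        spread = max(obs) - min(obs)
        if spread > fitness_tolerance and dedup == "mean":
            warnings.warn(
                f"locus {lab!r}: single-mutant fitness spread {spread:.3g} "
                f"exceeds tolerance; resolved by averaging",
                stacklevel=2,
            )
        w = float(np.mean(obs)) if dedup == "mean" else obs[0]
        s[k] = w - 1.0

    eps_map = {key: float(np.mean(vals)) for key, vals in pair_eps.items()}
    # multiplicative fits can dip below -1 when the double mutant is
    # unexpectedly sick; clamp at the lethal bound
    eps_map = {k: max(v, -1.0) for k, v in eps_map.items()}
    s = np.maximum(s, -1.0)
    return EpistasisNetwork(
        locus_ids=locus_ids,
        s=s,
        epsilon=eps_map,
        measure=measure,
        metadata={
            "dropped_zero_fitness_pairs": dropped_zero,
            "n_records": len(records),
            "dedup": dedup,
        },
    )


# ---------------------------------------------------------------------------
# Network-level statistics
# ---------------------------------------------------------------------------


def mean_interaction_profile(network: EpistasisNetwork) -> pd.DataFrame:
    """Per-locus mean of all stored epistatic coefficients.

    Returns a frame with one row per locus: ``locus_id``,
    ``mean_epsilon`` (0 for loci with no stored pairs) and ``n_pairs``
    (0 flags a locus with no interactions).
    """
    if network.n_loci == 0:
        raise ValueError("empty network")
    total = np.zeros(network.n_loci)
    count = np.zeros(network.n_loci, dtype=np.int64)
    ii, jj, ee = network.pair_arrays()
    np.add.at(total, ii, ee)
    np.add.at(total, jj, ee)
    np.add.at(count, ii, 1)
    np.add.at(count, jj, 1)
    mean = np.divide(total, count, out=np.zeros_like(total), where=count > 0)
    return pd.DataFrame(
        {"locus_id": network.locus_ids, "mean_epsilon": mean, "n_pairs": count}
    )


def effect_correlation(network: EpistasisNetwork) -> dict[str, float]:
    """OLS fit of the mean interaction profile on the independent effect.

    Only loci with at least one stored pair enter the regression.
    Returns ``slope``, ``intercept`` and the single-predictor
    ``adjusted_R2``.
    """
    import statsmodels.api as sm

    profile = mean_interaction_profile(network)
    keep = profile["n_pairs"] > 0
    if keep.sum() < 3:
        raise ValueError("need at least 3 loci with stored interactions")
    x = network.s[keep.to_numpy()]
    y = profile.loc[keep, "mean_epsilon"].to_numpy()
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    return {
        "slope": float(fit.params[1]),
        "intercept": float(fit.params[0]),
        "adjusted_R2": float(fit.rsquared_adj),
    }


# ---------------------------------------------------------------------------
# Synthetic networks
# ---------------------------------------------------------------------------


@dataclass
class SyntheticNetworkSpec:
    """Parameters of the synthetic network generator.

    Defaults emulate the marginal statistics of genome-scale knockout
    screens in budding yeast: independent effects from a three-component
    normal mixture (strongly deleterious knockouts, a bulk of mildly
    deleterious ones, and a mildly beneficial tail), pairwise epistasis
    drawn around ``coupling * (s_i + s_j)`` — producing the observed
    positive correlation between a mutation's independent effect and
    its mean epistatic effect — with residual scale
    ``epsilon_noise_sd``, and a stored-pair density comparable to the
    measured fraction of locus pairs in those screens.
    """

    n_loci: int = 1000
    s_weights: tuple[float, ...] = (0.05, 0.75, 0.20)
    s_means: tuple[float, ...] = (-0.35, -0.03, 0.01)
    s_sds: tuple[float, ...] = (0.10, 0.02, 0.01)
    coupling: float = 0.2
    epsilon_noise_sd: float = 0.05
    pair_density: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_loci < 2:
            raise ValueError("n_loci must be >= 2")
        if not 0 <= self.pair_density <= 1:
            raise ValueError("pair_density must lie in [0, 1]")
        if not (len(self.s_weights) == len(self.s_means) == len(self.s_sds)):
            raise ValueError("mixture weights/means/sds must have equal length")
        if any(w < 0 for w in self.s_weights):
            raise ValueError("mixture weights must be nonnegative")
        if not math.isclose(sum(self.s_weights), 1.0, rel_tol=0, abs_tol=1e-9):
            raise ValueError("mixture weights must sum to 1")
        if any(sd < 0 for sd in self.s_sds):
            raise ValueError("mixture scales must be nonnegative")
        if self.epsilon_noise_sd < 0:
            raise ValueError("epsilon_noise_sd must be nonnegative")


def generate_synthetic(spec: SyntheticNetworkSpec) -> EpistasisNetwork:
    """Draw a reproducible synthetic epistasis network.

    Identical specs (including seed) produce bit-identical networks.
    Selection and epistatic coefficients are clipped at the lethal
    bound of -1.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_loci
    comp = rng.choice(len(spec.s_weights), size=n, p=np.asarray(spec.s_weights))
    s = rng.normal(np.asarray(spec.s_means)[comp], np.asarray(spec.s_sds)[comp])
    s = np.maximum(s, -1.0)

    iu, ju = np.triu_indices(n, k=1)
    n_pairs_total = iu.size
    k = int(round(spec.pair_density * n_pairs_total))
    if k == n_pairs_total:
        sel = np.arange(n_pairs_total)
    else:
        sel = rng.choice(n_pairs_total, size=k, replace=False)
        sel.sort()
    pi, pj = iu[sel], ju[sel]
    eps = rng.normal(spec.coupling * (s[pi] + s[pj]), spec.epsilon_noise_sd)
    eps = np.maximum(eps, -1.0)

    width = len(str(n - 1))
    locus_ids = [f"L{idx:0{width}d}" for idx in range(n)]
    eps_map = {
        (locus_ids[a], locus_ids[b]): float(e) for a, b, e in zip(pi, pj, eps)
    }
    return EpistasisNetwork(
        locus_ids=locus_ids,
        s=s,
        epsilon=eps_map,
        measure="multiplicative",
        metadata={"generator": "synthetic", "seed": spec.seed},
    )
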