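"""Multi-set overlap statistics for DE gene lists.

Given DE gene sets drawn from a common pool of expressed genes, this module
tabulates exclusive Euler regions, computes the exact expectation of the
all-way intersection under independent uniform draws without replacement,
simulates the null distribution of the intersection size, and reports an
add-one permutation p-value ``(1 + #{null >= observed}) / (B + 1)`` together
with fold enrichment (observed / simulated mean).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import prod

import numpy as np

MAX_EULER_SETS = 10


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets over a fixed pool of ``pool_size`` expressed genes."""

    pool_size: int
    sets: dict[str, frozenset] = field(default_factory=dict)

    def __post_init__(self):
        if self.pool_size <= 0:
            raise ValueError("pool_size must be positive")
        object.__setattr__(
            self, "sets", {name: frozenset(s) for name, s in self.sets.items()}
        )
        for name, s in self.sets.items():
            if len(s) > self.pool_size:
                raise ValueError(
                    f"set {name!r} has {len(s)} genes but the pool holds {self.pool_size}"
                )

    @property
    def sizes(self) -> list[int]:
        return [len(s) for s in self.sets.values()]


@dataclass(frozen=True)
class OverlapResult:
    """Observed vs simulated all-way overlap of a gene-set collection."""

    observed: int
    expected: float  # simulation mean
    expected_analytic: float  # N * prod(size_i / N)
    expected_se: float  # sd(simulated) / sqrt(B)
    fold_enrichment: float
    p_value: float
    n_iterations: int
    seed: int
    alternative: str = "enrichment"


def observed_overlap(collection: GeneSetCollection) -> int:
    """Size of the intersection of all sets in the collection."""
    sets = list(collection.sets.values())
    if len(sets) < 2:
        raise ValueError("need at least two sets to intersect")
    return len(frozenset.intersection(*sets))


def euler_regions(collection: GeneSetCollection) -> dict[str, int]:
    """Exclusive region counts for every nonempty membership signature.

    Signatures are strings like ``"A&B&!C"`` listing member sets and, with a
    ``!`` prefix, non-member sets, in the collection's set order.  Counts sum
    to the size of the union.
    """
    names = list(collection.sets)
    if not names:
        raise ValueError("need at least one set")
    if len(names) > MAX_EULER_SETS:
        raise ValueError(
            f"refusing to tabulate {len(names)} sets (> {MAX_EULER_SETS}): "
            "2^k regions would be impractical"
        )
    union = frozenset.union(*collection.sets.values())
    regions: dict[str, int] = {}
    for gene in union:
        membership = [gene in collection.sets[n] for n in names]
        sig = "&".join(n if m else f"!{n}" for n, m in zip(names, membership))
        regions[sig] = regions.get(sig, 0) + 1
    return regions


def expected_overlap(sizes: list[int], pool_size: int) -> float:
    """Exact expected all-way intersection of independent uniform subsets.

    By linearity, each of the ``N`` pool genes lands in every set with
    probability ``prod(size_i / N)``, so the expectation is
    ``N * prod(size_i / N)``.
    """
    if pool_size <= 0:
        raise ValueError("pool_size must be positive")
    for s in sizes:
        if not 0 <= s <= pool_size:
            raise ValueError(f"set size {s} outside [0, {pool_size}]")
    return pool_size * prod(s / pool_size for s in sizes)


def simulate_overlap_null(
    sizes: list[int], pool_size: int, n_iterations: int = 10000, seed: int = 0
) -> np.ndarray:
    """Simulated null all-way overlaps of uniformly drawn gene sets.

    Each iteration draws every set uniformly without replacement from the
    pool and records the size of the all-way intersection.  Deterministic
    under the seed.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    for s in sizes:
        if s > pool_size:
            raise ValueError(f"set size {s} exceeds pool size {pool_size}")
    rng = np.random.default_rng(seed)
    k = len(sizes)
    out = np.empty(n_iterations, dtype=np.int64)
    membership = np.zeros(pool_size, dtype=np.int16)
    for b in range(n_iterations):
        membership[:] = 0
        for s in sizes:
            idx = rng.choice(pool_size, size=s, replace=False)
            membership[idx] += 1
        out[b] = int((membership == k).sum())
    return out


def overlap_test(
    collection: GeneSetCollection,
    n_iterations: int = 10000,
    seed: int = 0,
    alternative: str = "enrichment",
) -> OverlapResult:
    """Simulation-based test of the all-way DE gene-set overlap.

    The add-one p-value counts the observed configuration as one null draw,
    so ``p >= 1 / (B + 1)``.  Fold enrichment is observed over the simulation
    mean; when the simulation mean is zero, the analytic expectation is
    substituted if positive, otherwise fold enrichment is reported missing.
    """
    if alternative not in ("enrichment", "depletion"):
        raise ValueError("alternative must be 'enrichment' or 'depletion'")
    obs = observed_overlap(collection)
    sims = simulate_overlap_null(collection.sizes, collection.pool_size, n_iterations, seed)
    if alternative == "enrichment":
        hits = int((sims >= obs).sum())
    else:
        hits = int((sims <= obs).sum())
    p = (1 + hits) / (n_iterations + 1)
    expected = float(sims.mean())
    expected_se = float(sims.std(ddof=1) / np.sqrt(n_iterations)) if n_iterations > 1 else float("nan")
    analytic = expected_overlap(collection.sizes, collection.pool_size)
    denom = expected if expected > 0 else (analytic if analytic > 0 else float("nan"))
    fold = obs / denom if denom and np.isfinite(denom) else float("nan")
    return OverlapResult(
        observed=obs,
        expected=expected,
        expected_analytic=analytic,
        expected_se=expected_se,
        fold_enrichment=fold,
        p_value=p,
        n_iterations=n_iterations,
        seed=seed,
        alternative=alternative,
    )
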