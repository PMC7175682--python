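"""Diet-breadth rarefaction on integer-transformed pollen-load data.

Diet breadth (the number of distinct pollen types a bee species collects)
grows with sample size, so species sampled unequally are compared at a
standardised number of loads by rarefaction: subsampling without replacement
and averaging the distinct-taxon count.

The load data are percentages, not counts, so they are first made integer:
each taxon's percentage of the aggregate diet is multiplied by the number of
loads to give a whole-pollen-load equivalent (40% of 14 loads -> 5.6 loads),
then by ten and rounded, so one unit is a tenth of a load (5.6 loads -> 56
units). Rarefaction to a target of ``k`` loads draws ``10 k`` units without
replacement.

:func:`rarefy` is the Monte-Carlo procedure (1000 draws by default);
:func:`rarefy_exact` is the hypergeometric closed form

    E[S] = sum_t 1 - C(N - N_t, n) / C(N, n)

used as an analytic oracle and fast path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.special import gammaln

__all__ = [
    "PollenCountVector",
    "RarefiedBreadth",
    "integer_transform",
    "rarefy",
    "rarefy_exact",
    "UNITS_PER_LOAD",
]

#: One rarefaction unit is a tenth of a pollen load.
UNITS_PER_LOAD = 10


@dataclass
class PollenCountVector:
    """Integer pollen-unit counts per taxon for one bee species."""

    bee_species: str
    counts: dict[str, int]
    n_loads: int

    @property
    def total_units(self) -> int:
        return sum(self.counts.values())

    @property
    def richness(self) -> int:
        return sum(1 for c in self.counts.values() if c > 0)


@dataclass
class RarefiedBreadth:
    """Expected distinct pollen types at a standardised number of loads."""

    bee_species: str
    target_loads: int
    expected_richness: float
    resample_sd: float
    n_resamples: int
    seed: int


def _round_half_away(x: float) -> int:
    # counts are non-negative here; ties round away from zero
    return int(math.floor(x + 0.5))


def integer_transform(
    shares: Mapping[str, float],
    n_loads: int,
    rounding: str = "half_away",
    bee_species: str = "",
) -> PollenCountVector:
    """Convert percentage shares into tenth-of-a-load integer counts.

    count(t) = round(share(t)/100 x n_loads x 10). Taxa rounding to zero are
    dropped. ``rounding`` is "half_away" (default) or "half_even".
    """
    if n_loads < 1:
        raise ValueError("n_loads must be >= 1")
    total = sum(shares.values())
    if abs(total - 100.0) > 0.5:
        raise ValueError(f"shares sum to {total:.2f}, expected 100 ± 0.5")
    rounder = _round_half_away if rounding == "half_away" else lambda x: round(x)
    counts = {}
    for taxon, share in shares.items():
        c = rounder(share / 100.0 * n_loads * UNITS_PER_LOAD)
        if c > 0:
            counts[taxon] = c
    return PollenCountVector(bee_species=bee_species, counts=counts, n_loads=n_loads)


def rarefy_exact(counts: PollenCountVector, subsample_units: int) -> float:
    """Hypergeometric expectation of distinct-taxon count in a subsample.

    E[S] = sum over taxa of 1 - C(N - N_t, n)/C(N, n), with N the pooled
    units, N_t the taxon's units and n the subsample size. Computed in
    log-space to stay stable for large pools.
    """
    N = counts.total_units
    n = int(subsample_units)
    if n > N:
        raise ValueError(f"subsample of {n} units exceeds total {N}")
    if n < 0:
        raise ValueError("subsample_units must be >= 0")

    def logC(a: int, b: int) -> float:
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    expected = 0.0
    for c in counts.counts.values():
        if c <= 0:
            continue
        if N - c < n:
            expected += 1.0  # taxon cannot be missed
        else:
            expected += 1.0 - math.exp(logC(N - c, n) - logC(N, n))
    return expected


def rarefy(
    counts: PollenCountVector,
    target_loads: int,
    n_resamples: int = 1000,
    seed: int = 0,
) -> RarefiedBreadth:
    """Monte-Carlo rarefaction to ``target_loads`` standardised loads.

    Draws ``target_loads x 10`` units without replacement from the pooled
    unit vector, ``n_resamples`` times, and reports the mean and standard
    deviation of the distinct-taxon count. Reproducible given ``seed``.
    """
    n_units = int(target_loads) * UNITS_PER_LOAD
    N = counts.total_units
    if n_units > N:
        raise ValueError(
            f"{counts.bee_species or 'sample'}: subsample of {n_units} units "
            f"exceeds total {N}"
        )
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")

    taxa = [t for t, c in sorted(counts.counts.items()) if c > 0]
    pool = np.repeat(np.arange(len(taxa)), [counts.counts[t] for t in taxa])
    rng = np.random.default_rng(seed)
    richness = np.empty(n_resamples, dtype=np.int64)
    for i in range(n_resamples):
        draw = rng.choice(pool, size=n_units, replace=False)
        richness[i] = np.unique(draw).size
    return RarefiedBreadth(
        bee_species=counts.bee_species,
        target_loads=int(target_loads),
        expected_richness=float(richness.mean()),
        resample_sd=float(richness.std(ddof=1)) if n_resamples > 1 else 0.0,
        n_resamples=n_resamples,
        seed=seed,
    )
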