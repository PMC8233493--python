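"""Heterogeneous recombination and mutation rate maps.

Both maps are step functions over bp windows. The mutation map is
renormalized so its genome-wide mean equals a target per-site rate
(default 1e-8/site/generation); recombination maps follow the HapMap text
convention (position, rate in cM/Mb) and windows with missing data inherit
the previous window's rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["StepMap", "RateMaps", "uniform_rate_maps"]


@dataclass(frozen=True)
class StepMap:
    """Piecewise-constant per-site rate over [0, length).

    ``breaks`` has n+1 increasing bp boundaries starting at 0; ``rates`` has
    n per-site per-generation values.
    """

    breaks: np.ndarray
    rates: np.ndarray

    def __post_init__(self) -> None:
        b = np.asarray(self.breaks, dtype=float)
        r = np.asarray(self.rates, dtype=float)
        if b.ndim != 1 or r.ndim != 1 or b.size != r.size + 1:
            raise ValueError("need n+1 breaks for n rates")
        if np.any(np.diff(b) <= 0):
            raise ValueError("breaks must be strictly increasing")
        if np.any(r < 0):
            raise ValueError("rates must be non-negative")
        object.__setattr__(self, "breaks", b)
        object.__setattr__(self, "rates", r)

    @property
    def length(self) -> float:
        return float(self.breaks[-1])

    @property
    def total_mass(self) -> float:
        """Sum over sites of the per-site rate (rate x window length)."""
        return float(np.sum(np.diff(self.breaks) * self.rates))

    @property
    def mean_rate(self) -> float:
        return self.total_mass / self.length

    def rate_at(self, positions: np.ndarray) -> np.ndarray:
        idx = np.clip(np.searchsorted(self.breaks, positions, side="right") - 1, 0, self.rates.size - 1)
        return self.rates[idx]

    def rescaled_to_mean(self, target_mean: float) -> "StepMap":
        if self.total_mass == 0:
            raise ValueError("cannot rescale an all-zero map")
        return StepMap(self.breaks, self.rates * (target_mean / self.mean_rate))

    def sample_positions(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """n integer bp positions drawn with density proportional to the map."""
        mass = np.diff(self.breaks) * self.rates
        cum = np.cumsum(mass)
        if cum[-1] <= 0:
            raise ValueError("map has zero total mass")
        u = rng.random(n) * cum[-1]
        w = np.searchsorted(cum, u, side="right")
        lo, hi = self.breaks[w], self.breaks[w + 1]
        return np.floor(lo + rng.random(n) * (hi - lo)).astype(np.int64)

    def to_msprime(self):
        import msprime

        return msprime.RateMap(position=self.breaks, rate=self.rates)


@dataclass(frozen=True)
class RateMaps:
    """Recombination + mutation step maps over the same chromosome."""

    recombination: StepMap
    mutation: StepMap

    def __post_init__(self) -> None:
        if abs(self.recombination.length - self.mutation.length) > 0.5:
            raise ValueError("recombination and mutation maps must cover the same span")

    @property
    def length(self) -> float:
        return self.recombination.length

    def normalized(self, target_mean_mu: float) -> "RateMaps":
        """Mutation map rescaled so the genome-wide mean equals the target."""
        return RateMaps(self.recombination, self.mutation.rescaled_to_mean(target_mean_mu))


def uniform_rate_maps(length: int, rec: float, mu: float) -> RateMaps:
    breaks = np.array([0.0, float(length)])
    return RateMaps(
        recombination=StepMap(breaks, np.array([rec])),
        mutation=StepMap(breaks, np.array([mu])),
    )
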