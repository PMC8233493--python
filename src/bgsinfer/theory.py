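"""Analytical predictions for diversity and the SFS under BGS and size change.

Background selection (BGS) reduces diversity at a neutral site linked to
sites under purifying selection; at equilibrium this is summarized by
``B = pi / pi0``. This module provides:

* the classical deterministic prediction of equilibrium B around a genome
  layout, integrated over a discrete DFE;
* the apparent B during a non-equilibrium transient, obtained by treating
  BGS as a uniform rescaling of the population size in neutral
  pairwise-coalescence theory;
* expected pairwise diversity trajectories under piecewise histories; and
* the expected (relative) site frequency spectrum for an arbitrary
  piecewise-constant history, with exponential epochs discretized, using
  the classical spectral representation of coalescence times
  (Polanski & Kimmel 2003).

B enters all of these only as a multiplier of N(t); it rescales the
timescale of drift without directly reshaping the spectrum.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.special import gammaln

from .genomes import Demography, DiscreteDFE, Epoch, GenomeLayout

__all__ = [
    "BValue",
    "ExpectedSFS",
    "equilibrium_B",
    "apparent_B_after_change",
    "expected_pi_trajectory",
    "expected_sfs_pk",
    "expected_segregating_sites",
]


@dataclass(frozen=True)
class BValue:
    """Diversity with BGS relative to its neutral expectation (pi/pi0)."""

    B: float
    reliable: bool = True
    note: str = ""


@dataclass(frozen=True)
class ExpectedSFS:
    """Expected relative SFS: p[b-1] = P(a SNP has b derived copies)."""

    p: np.ndarray
    n_hap: int
    theta_per_site: float | None = None  # expected segregating proportion scale

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        if p.shape != (self.n_hap - 1,):
            raise ValueError("p must have n_hap - 1 entries")
        if np.any(p <= 0):
            raise ValueError("expected SFS classes must be positive")
        if abs(p.sum() - 1.0) > 1e-10:
            raise ValueError("p must sum to 1")
        object.__setattr__(self, "p", p)


# ---------------------------------------------------------------------------
# Equilibrium B (deterministic prediction)
# ---------------------------------------------------------------------------

def _recombination_fraction(distance_bp: np.ndarray, rec_rate: float) -> np.ndarray:
    """Haldane map: crossover rate per bp to recombination fraction (cap 1/2)."""
    return 0.5 * (1.0 - np.exp(-2.0 * rec_rate * distance_bp))


def equilibrium_B(
    focal_pos: int,
    layout: GenomeLayout,
    dfe: DiscreteDFE,
    mu_del: float,
    rec_rate: float,
    quad_points: int = 32,
    weak_mass_warn: float = 0.05,
) -> BValue:
    """Deterministic equilibrium B at a neutral focal position.

    Classical prediction ``B = exp(-sum_j u * t_j / (t_j + r_j (1-t_j))^2)``
    over selected sites j, with heterozygous effect ``t = s/2``, per-site
    deleterious mutation rate ``u = mu_del`` and recombination fraction
    ``r_j`` between the focal and selected site. The expectation over the
    DFE is taken bin-wise by Gauss-Legendre quadrature in s.

    The formula assumes deterministic mutation-selection balance and is
    unreliable when appreciable DFE mass lies at 2*Nanc*s < 10; the result
    is flagged (``reliable=False``) in that case rather than suppressed.
    """
    if mu_del < 0 or rec_rate < 0:
        raise ValueError("rates must be non-negative")
    nodes, weights = np.polynomial.legendre.leggauss(quad_points)
    exponent = 0.0
    for (lo, hi), f_cls in zip(dfe.bin_bounds, dfe.f):
        if f_cls <= 0:
            continue
        s_lo, s_hi = lo / (2 * dfe.Nanc), hi / (2 * dfe.Nanc)
        # map nodes to the s interval
        s_vals = 0.5 * (s_hi - s_lo) * nodes + 0.5 * (s_hi + s_lo)
        w_vals = weights * 0.5  # average, not integral: weights sum to 2
        t = 0.5 * s_vals  # heterozygous effect
        t = np.maximum(t, 1e-300)
        contrib = 0.0
        for es, ee in layout.exon_intervals:
            sites = np.arange(es, ee)
            d = np.abs(sites - focal_pos)
            r = _recombination_fraction(d.astype(float), rec_rate)
            # sum over sites of E_s[ u t / (t + r(1-t))^2 ]
            denom = (t[None, :] + r[:, None] * (1.0 - t[None, :])) ** 2
            contrib += float(np.sum((mu_del * t[None, :] / denom) @ w_vals))
        exponent += f_cls * contrib
    # classes 0 and 1 lie entirely below 2*Nanc*s = 10
    weak_mass = dfe.f[0] + dfe.f[1]
    reliable = weak_mass <= weak_mass_warn
    note = "" if reliable else (
        f"{weak_mass:.0%} of DFE mass has 2*Nanc*s < 10; deterministic "
        "formula overpredicts BGS there — simulate instead"
    )
    if not reliable:
        warnings.warn(note, stacklevel=2)
    return BValue(B=float(np.exp(-exponent)), reliable=reliable, note=note)


# ---------------------------------------------------------------------------
# Pairwise diversity under piecewise histories
# ---------------------------------------------------------------------------

def _pair_coalescence_time(demography: Demography, B: float = 1.0) -> float:
    """E[T2] in generations, for the history with all sizes scaled by B."""
    total = 0.0
    surv = 1.0  # P(pair not yet coalesced)
    start = 0.0
    for e in demography.epochs:
        if e.mode == "constant" or e.initial_size == e.final_size:
            rate = 1.0 / (2.0 * B * e.initial_size)
            if e.duration is None:
                total += surv / rate
                return total
            x = rate * e.duration
            total += surv * (1.0 - math.exp(-x)) / rate
            surv *= math.exp(-x)
        else:
            # exponential segment: integrate numerically
            if e.duration is None:
                raise ValueError("open-ended epoch must be constant")
            grid = np.linspace(0.0, e.duration, 2049)
            sizes = e.initial_size * (e.final_size / e.initial_size) ** (
                grid / e.duration
            )
            rates = 1.0 / (2.0 * B * sizes)
            lam = np.concatenate([[0.0], np.cumsum(
                0.5 * (rates[1:] + rates[:-1]) * np.diff(grid)
            )])
            total += surv * np.trapezoid(np.exp(-lam), grid)
            surv *= math.exp(-lam[-1])
        start += e.duration
    raise ValueError("history must end with an open-ended epoch")


def expected_pi_trajectory(demography: Demography, B: float, mu: float):
    """pi(t) = 2*mu*E[pair coalescence time] as a function of time.

    Returns a callable of ``t``, the forward time elapsed since the
    configured epochs began playing out: ``pi(t)`` is the diversity of a
    sample taken when only ``t`` of the ``change_time`` generations have
    elapsed. ``t = 0`` gives the ancestral equilibrium value and
    ``t >= change_time`` the present-day value. Continuous in t.
    """
    if not (0 < B <= 1 + 1e-9):
        raise ValueError("B must lie in (0, 1]")
    span = demography.change_time

    def pi(t: float) -> float:
        if t < 0:
            raise ValueError("t must be non-negative")
        if t > span:
            # the change has fully played out; the population has sat at
            # the present-day size for the remaining t - span generations
            extra = Epoch(t - span, demography.Ncur, demography.Ncur, "constant")
            dem_t = Demography(epochs=(extra,) + demography.epochs)
            return 2.0 * mu * _pair_coalescence_time(dem_t, B)
        # truncate the history: sampling happens t generations into the
        # change period, so drop the most recent (span - t) generations
        remaining = span - t
        eps: list[Epoch] = []
        acc = 0.0
        for e in demography.epochs:
            if e.duration is None:
                eps.append(e)
                break
            if acc + e.duration <= remaining + 1e-9:
                acc += e.duration  # entirely in the unseen future
                continue
            cut = max(0.0, remaining - acc)
            if cut > 0:
                # drop the recent part of this epoch
                if e.mode == "exponential":
                    x = cut / e.duration
                    ni = e.initial_size * (e.final_size / e.initial_size) ** x
                    eps.append(Epoch(e.duration - cut, ni, e.final_size, "exponential"))
                else:
                    eps.append(Epoch(e.duration - cut, e.initial_size, e.final_size, e.mode))
                acc += e.duration
            else:
                eps.append(e)
                acc += e.duration
        dem_t = Demography(epochs=tuple(eps))
        return 2.0 * mu * _pair_coalescence_time(dem_t, B)

    return pi


def apparent_B_after_change(
    B0: float, demography: Demography, t_elapsed: float
) -> BValue:
    """Apparent B measured t_elapsed generations into a size change.

    ``B0`` is the equilibrium B in the ancestral population (typically
    measured from simulation). The selected-region diversity trajectory is
    the neutral pairwise solution with all sizes multiplied by B0, the
    neutral trajectory the same with B = 1; their ratio is the apparent
    B-hat. At t = 0 and t -> infinity it returns B0 (pure rescaling);
    during the transient the region with smaller Ne responds faster, so
    under this model B-hat <= B0 throughout a decline transient and
    B-hat >= B0 throughout a growth transient.
    """
    if t_elapsed < 0:
        raise ValueError("t_elapsed must be non-negative")
    if not (0 < B0 <= 1 + 1e-9):
        raise ValueError("B0 must lie in (0, 1]")
    mu = 1.0  # cancels in the ratio
    pi_sel = expected_pi_trajectory(demography, B0, mu)(t_elapsed)
    pi_neu = expected_pi_trajectory(demography, 1.0, mu)(t_elapsed)
    return BValue(B=pi_sel / pi_neu)


# ---------------------------------------------------------------------------
# Expected SFS under piecewise-constant histories (Polanski-Kimmel)
# ---------------------------------------------------------------------------

def _discretize(demography: Demography, B: float, min_steps: int = 50,
                rel_tol: float = 1e-4) -> tuple[np.ndarray, np.ndarray]:
    """(epoch boundaries, diploid sizes) with exponential epochs stepped.

    Returns breaks t_0=0 < t_1 < ... (time ago, generations) and sizes per
    interval (the last extends to infinity), all sizes multiplied by B.
    Exponential epochs are replaced by >= ``min_steps`` piecewise-constant
    steps, doubling until the relative change in E[T2] is below rel_tol.
    """

    def build(steps: int) -> tuple[np.ndarray, np.ndarray]:
        breaks = [0.0]
        sizes: list[float] = []
        t = 0.0
        for e in demography.epochs:
            if e.duration is None:
                sizes.append(e.final_size * B)
                break
            if e.mode == "constant":
                breaks.append(t + e.duration)
                sizes.append(e.initial_size * B)
            else:
                grid = np.linspace(0.0, e.duration, steps + 1)
                mids = 0.5 * (grid[1:] + grid[:-1])
                for g, m in zip(grid[1:], mids):
                    breaks.append(t + g)
                    sizes.append(
                        e.initial_size
                        * (e.final_size / e.initial_size) ** (m / e.duration)
                        * B
                    )
            t += e.duration
        return np.asarray(breaks), np.asarray(sizes)

    has_exp = any(e.mode == "exponential" for e in demography.epochs)
    steps = min_steps
    breaks, sizes = build(steps)
    if not has_exp:
        return breaks, sizes
    ref = _et2_piecewise(breaks, sizes)
    while steps < 3200:
        steps *= 2
        b2, s2 = build(steps)
        val = _et2_piecewise(b2, s2)
        if abs(val - ref) <= rel_tol * abs(ref):
            return b2, s2
        breaks, sizes, ref = b2, s2, val
    return breaks, sizes


def _et2_piecewise(breaks: np.ndarray, sizes: np.ndarray) -> float:
    total, surv = 0.0, 1.0
    for i, N in enumerate(sizes):
        rate = 1.0 / (2.0 * N)
        if i + 1 < breaks.size:
            d = breaks[i + 1] - breaks[i]
            x = rate * d
            total += surv * (1.0 - math.exp(-x)) / rate
            surv *= math.exp(-x)
        else:
            total += surv / rate
    return total


def _lambda_integrals(breaks: np.ndarray, sizes: np.ndarray, n: int) -> np.ndarray:
    """lambda_j = integral_0^inf exp(-C(j,2) * Lam(t)) dt for j = 2..n.

    Lam(t) is the pair-coalescence intensity integral dt'/(2 N(t')).
    """
    j = np.arange(2, n + 1)
    c = j * (j - 1) / 2.0
    lam = np.zeros_like(c)
    Lam0 = 0.0
    for i, N in enumerate(sizes):
        rate = 1.0 / (2.0 * N)
        if i + 1 < breaks.size:
            d = breaks[i + 1] - breaks[i]
            dLam = rate * d
            lam += np.exp(-c * Lam0) * (1.0 - np.exp(-c * dLam)) / (c * rate)
            Lam0 += dLam
        else:
            lam += np.exp(-c * Lam0) / (c * rate)
    return lam


@lru_cache(maxsize=8)
def _tavare_coefficients(n: int) -> np.ndarray:
    """M[k-2, j-2] such that E[S_k] = sum_j M[k,j] * lambda_j.

    From the distribution of the number of ancestral lineages (Tavare 1984):
    P(A(t) = k) = sum_{j>=k} exp(-C(j,2) Lam(t)) * rho_{jk}, with
    rho_{jk} = (2j-1)(-1)^(j-k) * k_(j-1) * n_[j] / (k! (j-k)! n_(j)),
    where a_(b) and a_[b] are rising and falling factorials. Integrating
    over t converts each exponential into the corresponding lambda_j.
    Alternating signs limit this to moderate n (~50) in double precision.
    """
    M = np.zeros((n - 1, n - 1))
    for k in range(2, n + 1):
        for j in range(k, n + 1):
            # log magnitudes via gammaln; signs tracked separately
            lg = (
                math.log(2 * j - 1)
                + gammaln(k + j - 1) - gammaln(k)      # k_(j-1)
                + gammaln(n + 1) - gammaln(n - j + 1)  # n_[j]
                - gammaln(k + 1)
                - gammaln(j - k + 1)
                - (gammaln(n + j) - gammaln(n))        # n_(j)
            )
            M[k - 2, j - 2] = (-1.0) ** (j - k) * math.exp(lg)
    return M


@lru_cache(maxsize=8)
def _subtend_probability(n: int) -> np.ndarray:
    """P[k-2, b-1] = P(an edge while k lineages subtends b of n leaves).

    Classical combinatorial identity: C(n-b-1, k-2) / C(n-1, k-1).
    """
    P = np.zeros((n - 1, n - 1))
    for k in range(2, n + 1):
        for b in range(1, n - k + 2):
            P[k - 2, b - 1] = math.comb(n - b - 1, k - 2) / math.comb(n - 1, k - 1)
    return P


def expected_sfs_pk(
    demography: Demography,
    B: float,
    n_hap: int,
    mu: float | None = None,
) -> ExpectedSFS:
    """Expected relative SFS for a B-rescaled piecewise history.

    The expected count of sites with b derived copies is
    ``mu * L * sum_k k * E[S_k] * P(b | k)`` where E[S_k] is the expected
    time the sample spends with k ancestral lineages under the rescaled
    history, and P(b | k) the standard subtending-leaves probability. Only
    ratios are returned (plus, when ``mu`` is given, the per-site expected
    segregating proportion via ``theta_per_site``).

    Precision degrades for n_hap beyond ~50 because of the alternating
    sums in the lineage-count distribution; such calls are rejected.
    """
    if n_hap < 2:
        raise ValueError("n_hap must be >= 2")
    if n_hap > 50:
        raise ValueError(
            "expected_sfs_pk is numerically unstable for n_hap > 50; "
            "use a smaller sample (the analyses here use n_hap = 20)"
        )
    if not (0 < B <= 1 + 1e-9):
        raise ValueError("B must lie in (0, 1]")
    breaks, sizes = _discretize(demography, B)
    lam = _lambda_integrals(breaks, sizes, n_hap)
    M = _tavare_coefficients(n_hap)
    ES = M @ lam  # expected time with k = 2..n lineages
    k = np.arange(2, n_hap + 1, dtype=float)
    P = _subtend_probability(n_hap)
    xi = (k * ES) @ P  # proportional to E[count with b derived copies]
    if np.any(xi <= 0):
        raise FloatingPointError("numerical instability in expected SFS")
    theta = None if mu is None else float(mu * xi.sum())
    return ExpectedSFS(p=xi / xi.sum(), n_hap=n_hap, theta_per_site=theta)


def expected_segregating_sites(
    demography: Demography, L: float, n_hap: int, mu: float, B: float = 1.0
) -> float:
    """Expected number of segregating sites in a sample of n_hap haplotypes.

    ``mu * L * sum_k k * E[S_k]`` (total branch length times mutation
    rate); at equilibrium this reduces to ``theta * L * a_{n-1}`` with
    ``theta = 4*N*mu`` and ``a_m`` the harmonic number.
    """
    if n_hap > 50:
        # harmonic-sum route valid only at equilibrium; use the generic
        # piecewise E[T2]-based branch-length sum instead
        return _expected_S_large_n(demography, L, n_hap, mu, B)
    breaks, sizes = _discretize(demography, B)
    lam = _lambda_integrals(breaks, sizes, n_hap)
    M = _tavare_coefficients(n_hap)
    ES = M @ lam
    k = np.arange(2, n_hap + 1, dtype=float)
    return float(mu * L * (k * ES).sum())


def _expected_S_large_n(
    demography: Demography, L: float, n_hap: int, mu: float, B: float
) -> float:
    """Total-branch-length expectation valid for large n at equilibrium.

    For non-equilibrium histories with n > 50 an equilibrium epoch-matched
    value is not available in closed form here; only constant histories
    are accepted.
    """
    if len(demography.epochs) != 1:
        raise ValueError("large-n expected S implemented for equilibrium only")
    N = demography.epochs[0].initial_size * B
    a = np.sum(1.0 / np.arange(1, n_hap))
    return float(4.0 * N * mu * L * a)
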