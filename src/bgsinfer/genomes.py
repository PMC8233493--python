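"""Genome architecture, discrete DFE, demographic histories, and rescaling.

These are the shared domain objects: a :class:`GenomeLayout` tiles genes
(exons alternating with introns) and intergenic tracts over a chromosome; a
:class:`DiscreteDFE` holds the four-class distribution of fitness effects in
bins of the scaled selection coefficient ``2*Nanc*s``; a :class:`Demography`
is a piecewise population-size history; and :func:`rescale` applies the
standard population-scaling transformation ``Q`` that preserves ``4*N*mu``,
``4*N*r`` and ``2*N*s`` while shrinking the population.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "GenomeLayout",
    "DiscreteDFE",
    "Epoch",
    "Demography",
    "ScaledParams",
    "SimParams",
    "build_genome_layout",
    "enumerate_dfe_grid",
    "sample_selection_coefficient",
    "rescale",
    "equilibrium",
    "exponential_growth",
    "instantaneous_decline",
]

Interval = tuple[int, int]


def _total_length(intervals: Sequence[Interval]) -> int:
    return sum(e - s for s, e in intervals)


@dataclass(frozen=True)
class GenomeLayout:
    """Coordinates of exons/introns/intergenic tracts tiled over a chromosome.

    All intervals are 0-based, half-open ``[start, end)`` and jointly tile
    ``[0, chrom_length)``. Every gene consists of ``exons_per_gene`` exons of
    fixed length alternating with ``exons_per_gene - 1`` introns; genes are
    separated by intergenic tracts, with a leading intergenic tract before
    the first gene.
    """

    chrom_count: int
    chrom_length: int
    gene_intervals: tuple[Interval, ...]
    exon_intervals: tuple[Interval, ...]
    intron_intervals: tuple[Interval, ...]
    intergenic_intervals: tuple[Interval, ...]

    @property
    def n_genes(self) -> int:
        return len(self.gene_intervals)

    @property
    def functional_fraction(self) -> float:
        """Fraction of the chromosome under direct selection (exonic)."""
        return _total_length(self.exon_intervals) / self.chrom_length

    @property
    def exon_bp(self) -> int:
        return _total_length(self.exon_intervals)

    def validate(self) -> None:
        tiles = sorted(
            list(self.exon_intervals)
            + list(self.intron_intervals)
            + list(self.intergenic_intervals)
        )
        if not tiles or tiles[0][0] != 0 or tiles[-1][1] != self.chrom_length:
            raise ValueError("intervals do not span [0, chrom_length)")
        for (s0, e0), (s1, e1) in zip(tiles, tiles[1:]):
            if e0 != s1:
                raise ValueError(f"gap or overlap between {(s0, e0)} and {(s1, e1)}")

    def exon_mask(self) -> np.ndarray:
        """Boolean per-bp array, True at exonic (selected) positions."""
        m = np.zeros(self.chrom_length, dtype=bool)
        for s, e in self.exon_intervals:
            m[s:e] = True
        return m


def build_genome_layout(
    exon_bp: int,
    exons_per_gene: int,
    intron_bp: int,
    intergenic_bp: int,
    target_chrom_bp: float,
    chrom_count: int = 1,
) -> GenomeLayout:
    """Tile genes over a chromosome of approximately ``target_chrom_bp``.

    The number of genes is ``round(target / (gene_bp + intergenic_bp))`` with
    ``gene_bp = exons_per_gene*exon_bp + (exons_per_gene-1)*intron_bp``.  The
    chromosome starts with a leading intergenic tract and its total length is
    ``intergenic_bp + n_genes*(gene_bp + intergenic_bp) - 1`` (the final
    intergenic tract is one base shorter).  With the defaults of 350-bp exons
    and eight exons per gene this reproduces the gene counts and chromosome
    lengths of the 5%/10%/20% functional-density genome configurations
    (2,737/5,164/11,278 genes; 150,018,599/150,029,949/150,003,699 bp).
    """
    for name, v in [
        ("exon_bp", exon_bp),
        ("exons_per_gene", exons_per_gene),
        ("intron_bp", intron_bp),
        ("intergenic_bp", intergenic_bp),
    ]:
        if v <= 0:
            raise ValueError(f"{name} must be positive, got {v}")
    gene_bp = exons_per_gene * exon_bp + (exons_per_gene - 1) * intron_bp
    unit = gene_bp + intergenic_bp
    if target_chrom_bp < unit:
        raise ValueError("target_chrom_bp smaller than a single gene+intergenic unit")
    # round-half-up at .5 boundaries (matches the printed genome10 count)
    n_genes = int(math.floor(target_chrom_bp / unit + 0.5))

    exons: list[Interval] = []
    introns: list[Interval] = []
    genes: list[Interval] = []
    intergenic: list[Interval] = [(0, intergenic_bp)]
    pos = intergenic_bp
    for _ in range(n_genes):
        gstart = pos
        for j in range(exons_per_gene):
            exons.append((pos, pos + exon_bp))
            pos += exon_bp
            if j < exons_per_gene - 1:
                introns.append((pos, pos + intron_bp))
                pos += intron_bp
        genes.append((gstart, pos))
        intergenic.append((pos, pos + intergenic_bp))
        pos += intergenic_bp
    # final intergenic tract is one base shorter
    last_s, last_e = intergenic[-1]
    intergenic[-1] = (last_s, last_e - 1)
    total = pos - 1

    layout = GenomeLayout(
        chrom_count=chrom_count,
        chrom_length=total,
        gene_intervals=tuple(genes),
        exon_intervals=tuple(exons),
        intron_intervals=tuple(introns),
        intergenic_intervals=tuple(intergenic),
    )
    layout.validate()
    return layout


# ---------------------------------------------------------------------------
# Discrete DFE
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiscreteDFE:
    """Four-class discrete DFE over bins of the scaled coefficient 2*Nanc*s.

    ``f`` gives the proportion of new deleterious mutations falling in each
    bin of ``2*Nanc*s``: effectively neutral ``[0, 1)``, weakly deleterious
    ``[1, 10)``, moderately deleterious ``[10, 100)`` and strongly
    deleterious ``[100, 2*Nanc)``.  Within a bin the scaled coefficient is
    uniformly distributed.  ``s`` is the homozygous fitness reduction;
    mutations are semidominant (h = 0.5).  ``Nanc`` is the ancestral diploid
    size the bins refer to.  ``strictly_neutral_class0`` forces s = 0 for
    class-0 draws (used for purely neutral control simulations).
    """

    f: tuple[float, float, float, float]
    Nanc: int
    h: float = 0.5
    strictly_neutral_class0: bool = False

    def __post_init__(self) -> None:
        f = np.asarray(self.f, dtype=float)
        if f.shape != (4,):
            raise ValueError("f must have exactly four entries")
        if np.any(f < -1e-12) or np.any(f > 1 + 1e-12):
            raise ValueError("each f_i must lie in [0, 1]")
        if abs(f.sum() - 1.0) > 1e-12:
            raise ValueError(f"f must sum to 1, got {f.sum()!r}")
        if self.Nanc < 1:
            raise ValueError("Nanc must be a positive diploid count")

    @property
    def bin_bounds(self) -> tuple[tuple[float, float], ...]:
        """The four [low, high) intervals of 2*Nanc*s."""
        return ((0.0, 1.0), (1.0, 10.0), (10.0, 100.0), (100.0, 2.0 * self.Nanc))

    def with_nanc(self, Nanc: int) -> "DiscreteDFE":
        return replace(self, Nanc=Nanc)


#: The six DFE parameterizations studied, by name.
NAMED_DFES: dict[str, tuple[float, float, float, float]] = {
    "neutral": (1.0, 0.0, 0.0, 0.0),
    "DFE1": (0.1, 0.7, 0.1, 0.1),
    "DFE2": (0.1, 0.1, 0.7, 0.1),
    "DFE3": (0.1, 0.1, 0.1, 0.7),
    "DFE4": (0.25, 0.25, 0.25, 0.25),
    "DFE5": (0.5, 0.0, 0.0, 0.5),
    "DFE6": (0.7, 0.0, 0.0, 0.3),
}


def named_dfe(name: str, Nanc: int, strictly_neutral_class0: bool = False) -> DiscreteDFE:
    """Return one of the named DFEs (neutral, DFE1..DFE6) for a given Nanc."""
    try:
        f = NAMED_DFES[name]
    except KeyError:
        raise KeyError(f"unknown DFE {name!r}; choose from {sorted(NAMED_DFES)}") from None
    return DiscreteDFE(f=f, Nanc=Nanc, strictly_neutral_class0=strictly_neutral_class0)


def enumerate_dfe_grid(step: float, Nanc: int = 5000) -> list[DiscreteDFE]:
    """All 4-class DFEs with proportions on the grid {0, step, ..., 1}.

    The count is C(1/step + 3, 3); with step = 0.05 there are 1,771 grid
    points, the DFE realizations marginalized over in the nuisance-DFE ABC.
    """
    m = 1.0 / step
    k = round(m)
    if abs(m - k) > 1e-9:
        raise ValueError(f"1/step must be an integer, got 1/{step} = {m}")
    out = []
    for a in range(k + 1):
        for b in range(k + 1 - a):
            for c in range(k + 1 - a - b):
                d = k - a - b - c
                out.append(
                    DiscreteDFE(
                        f=(a / k, b / k, c / k, d / k),
                        Nanc=Nanc,
                    )
                )
    assert len(out) == math.comb(k + 3, 3)
    return out


def sample_selection_coefficient(
    dfe: DiscreteDFE, rng: np.random.Generator
) -> tuple[int, float]:
    """Draw (class index, s) for one new mutation.

    The class is a categorical draw with probabilities ``f``; within the
    class, ``2*Nanc*s`` is uniform on the bin, so ``s`` is uniform on
    ``[low/(2*Nanc), high/(2*Nanc))``.
    """
    u = rng.random()
    cdf = np.cumsum(dfe.f)
    cls = int(np.searchsorted(cdf, u, side="right"))
    cls = min(cls, 3)
    if cls == 0 and dfe.strictly_neutral_class0:
        return 0, 0.0
    low, high = dfe.bin_bounds[cls]
    two_ns = rng.uniform(low, high)
    return cls, two_ns / (2.0 * dfe.Nanc)


def sample_selection_coefficients(
    dfe: DiscreteDFE, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized draw of n (class, s) pairs; same law as the scalar version."""
    cdf = np.cumsum(dfe.f)
    cls = np.searchsorted(cdf, rng.random(n), side="right")
    np.minimum(cls, 3, out=cls)
    bounds = np.array(dfe.bin_bounds)
    low, high = bounds[cls, 0], bounds[cls, 1]
    two_ns = rng.uniform(low, high)
    s = two_ns / (2.0 * dfe.Nanc)
    if dfe.strictly_neutral_class0:
        s[cls == 0] = 0.0
    return cls, s


# ---------------------------------------------------------------------------
# Demography
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Epoch:
    """One segment of a piecewise size history, ordered backwards in time.

    ``duration`` is in generations (None only for the terminal, open-ended
    epoch). ``initial_size`` is the diploid size at the epoch's recent end,
    ``final_size`` at its ancient end.  ``mode`` is "constant" or
    "exponential"; exponential epochs interpolate size geometrically.
    """

    duration: float | None
    initial_size: float
    final_size: float
    mode: str = "constant"

    def __post_init__(self) -> None:
        if self.initial_size <= 0 or self.final_size <= 0:
            raise ValueError("population sizes must be positive")
        if self.duration is not None and self.duration <= 0:
            raise ValueError("epoch duration must be positive")
        if self.mode not in ("constant", "exponential"):
            raise ValueError(f"unknown epoch mode {self.mode!r}")
        if self.mode == "constant" and self.initial_size != self.final_size:
            raise ValueError("constant epoch must have equal initial/final sizes")


@dataclass(frozen=True)
class Demography:
    """Piecewise diploid population-size history, present first.

    Epochs are ordered backwards in time and must end with an open-ended
    (``duration=None``) epoch, so the history covers all of the past.
    """

    epochs: tuple[Epoch, ...]
    label: str = ""

    def __post_init__(self) -> None:
        if not self.epochs:
            raise ValueError("at least one epoch required")
        if self.epochs[-1].duration is not None:
            raise ValueError("last epoch must be open-ended (duration=None)")
        for e in self.epochs[:-1]:
            if e.duration is None:
                raise ValueError("only the last epoch may be open-ended")

    @property
    def Nanc(self) -> float:
        """Ancestral (pre-change) diploid size: the terminal epoch's size."""
        return self.epochs[-1].final_size

    @property
    def Ncur(self) -> float:
        """Present-day diploid size."""
        return self.epochs[0].initial_size

    @property
    def change_time(self) -> float:
        """Generations before present at which the ancestral epoch begins."""
        return sum(e.duration for e in self.epochs[:-1])

    def size_at(self, t_ago: float) -> float:
        """Diploid size t_ago generations before the present."""
        if t_ago < 0:
            raise ValueError("t_ago must be non-negative")
        start = 0.0
        for e in self.epochs:
            if e.duration is None or t_ago < start + e.duration:
                if e.mode == "constant":
                    return e.initial_size
                x = (t_ago - start) / e.duration
                return e.initial_size * (e.final_size / e.initial_size) ** x
            start += e.duration
        return self.epochs[-1].final_size  # pragma: no cover

    def scaled(self, B: float) -> "Demography":
        """All sizes multiplied by B (background-selection rescaling)."""
        if not (0 < B <= 1 + 1e-9):
            raise ValueError("B must lie in (0, 1]")
        eps = tuple(
            Epoch(e.duration, e.initial_size * B, e.final_size * B, e.mode)
            for e in self.epochs
        )
        return Demography(epochs=eps, label=f"{self.label}*B={B:g}" if self.label else "")

    def to_msprime(self):
        """Equivalent single-population msprime Demography."""
        import msprime

        dem = msprime.Demography()
        dem.add_population(name="pop", initial_size=self.Ncur)
        t = 0.0
        for i, e in enumerate(self.epochs):
            if i == 0:
                if e.mode == "exponential":
                    # growth rate alpha such that N(t_ago) = Ncur * exp(-alpha*t_ago)
                    alpha = math.log(e.initial_size / e.final_size) / e.duration
                    dem.add_population_parameters_change(
                        time=0, initial_size=e.initial_size, growth_rate=alpha
                    )
            else:
                if e.mode == "exponential":
                    alpha = math.log(e.initial_size / e.final_size) / e.duration
                else:
                    alpha = 0.0
                dem.add_population_parameters_change(
                    time=t, initial_size=e.initial_size, growth_rate=alpha
                )
            if e.duration is None:
                break
            t += e.duration
        if self.epochs[-1].duration is None and len(self.epochs) > 1:
            pass  # terminal change already added above
        dem.sort_events()
        return dem


def equilibrium(N: float = 5000) -> Demography:
    """Constant-size history."""
    return Demography(
        epochs=(Epoch(None, N, N, "constant"),), label=f"equilibrium(N={N:g})"
    )


def exponential_growth(
    Nanc: float = 1000, Ncur: float = 30000, T: float = 1000
) -> Demography:
    """Recent exponential growth (default 30-fold over T generations)."""
    return Demography(
        epochs=(
            Epoch(T, Ncur, Nanc, "exponential"),
            Epoch(None, Nanc, Nanc, "constant"),
        ),
        label=f"growth({Nanc:g}->{Ncur:g},T={T:g})",
    )


def instantaneous_decline(
    Nanc: float = 12300, Ncur: float = 2100, T: float = 1000
) -> Demography:
    """Instantaneous decline (default ~6-fold) T generations ago."""
    return Demography(
        epochs=(
            Epoch(T, Ncur, Ncur, "constant"),
            Epoch(None, Nanc, Nanc, "constant"),
        ),
        label=f"decline({Nanc:g}->{Ncur:g},T={T:g})",
    )


def preset_demography(name: str, fold: float | None = None) -> Demography:
    """Built-in histories: equilibrium, growth, decline, and 2-fold variants."""
    if name == "equilibrium":
        return equilibrium()
    if name == "growth":
        return exponential_growth()
    if name == "decline":
        return instantaneous_decline()
    if name == "growth2x":
        return exponential_growth(Nanc=5000, Ncur=10000, T=1000)
    if name == "decline2x":
        return instantaneous_decline(Nanc=5000, Ncur=2500, T=1000)
    raise KeyError(f"unknown demography preset {name!r}")


# ---------------------------------------------------------------------------
# Rescaling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimParams:
    """Unscaled per-site rates plus a demography; the rescale() input bundle."""

    demography: Demography
    mu: float
    rec: float
    s: float | None = None


@dataclass(frozen=True)
class ScaledParams:
    """Parameter bundle after population rescaling by Q.

    N -> N/Q, s -> s*Q, mu -> mu*Q, r -> r*Q, t -> t/Q; the composite
    parameters 4*N*mu, 4*N*r and 2*N*s are invariant.
    """

    Q: float
    demography: Demography
    mu: float
    rec: float
    s: float | None = None


def rescale(params: SimParams, Q: float) -> ScaledParams:
    """Apply the rescaling factor Q to a parameter bundle."""
    if Q < 1:
        raise ValueError("Q must be >= 1")
    eps = []
    for e in params.demography.epochs:
        ni, nf = e.initial_size / Q, e.final_size / Q
        if ni < 2 or nf < 2:
            raise ValueError(
                f"rescaling by Q={Q} collapses an epoch below 2 diploids "
                f"({e.initial_size:g}->{ni:g})"
            )
        d = None if e.duration is None else e.duration / Q
        eps.append(Epoch(d, ni, nf, e.mode))
    dem = Demography(
        epochs=tuple(eps),
        label=f"{params.demography.label}/Q={Q:g}" if params.demography.label else "",
    )
    return ScaledParams(
        Q=Q,
        demography=dem,
        mu=params.mu * Q,
        rec=params.rec * Q,
        s=None if params.s is None else params.s * Q,
    )
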