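"""Composite-likelihood fitting of demographic models to an observed SFS.

Four single-population models are fitted: equilibrium (one parameter, N),
instantaneous size change (Nanc, Ncur, T), exponential size change
(Nanc, Ncur, T), and an instantaneous bottleneck (Nanc, intensity, T).
The likelihood is multinomial over SFS classes (treating sites as
independent) with the class probabilities given by the analytic expected
SFS of the candidate history; model choice uses AIC with either the
standard penalty of 2 per parameter or the stricter 25x variant, and
Akaike weights w(i) = exp(-Delta_i/2) / sum_j exp(-Delta_j/2).

The expected SFS replaces a simulation-based likelihood engine with a
deterministic analytic one; at the SFS level the two are equivalent, and
the analytic route is fast and exactly reproducible.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .genomes import Demography, Epoch
from .sumstats import SFS
from .theory import ExpectedSFS, expected_sfs_pk

__all__ = [
    "DemographicModelSpec",
    "FitResult",
    "ModelChoice",
    "MODELS",
    "expected_sfs_model",
    "composite_loglik",
    "fit_model",
    "fit_all_models",
    "aic",
    "akaike_weights",
    "pool_replicates",
]

SIZE_BOUNDS = (100.0, 500_000.0)
TIME_BOUNDS = (100.0, 10_000.0)
INTENSITY_BOUNDS = (1e-5, 2.0)
_BOTTLENECK_EPS = 1e-6  # pulse implemented as an epoch of this duration


@dataclass(frozen=True)
class DemographicModelSpec:
    """One of the four candidate demographic models and its parameter box."""

    model_id: str
    param_names: tuple[str, ...]
    bounds: tuple[tuple[float, float], ...]
    log_scale: tuple[bool, ...]

    @property
    def k(self) -> int:
        return len(self.param_names)


MODELS: dict[str, DemographicModelSpec] = {
    "equilibrium": DemographicModelSpec(
        "equilibrium", ("N",), (SIZE_BOUNDS,), (True,)
    ),
    "instantaneous_change": DemographicModelSpec(
        "instantaneous_change",
        ("Nanc", "Ncur", "T"),
        (SIZE_BOUNDS, SIZE_BOUNDS, TIME_BOUNDS),
        (True, True, True),
    ),
    "exponential_change": DemographicModelSpec(
        "exponential_change",
        ("Nanc", "Ncur", "T"),
        (SIZE_BOUNDS, SIZE_BOUNDS, TIME_BOUNDS),
        (True, True, True),
    ),
    "instantaneous_bottleneck": DemographicModelSpec(
        "instantaneous_bottleneck",
        ("Nanc", "intensity", "T"),
        (SIZE_BOUNDS, INTENSITY_BOUNDS, TIME_BOUNDS),
        (True, True, True),
    ),
}


def model_demography(spec: DemographicModelSpec, params: dict[str, float]) -> Demography:
    """Map (model, parameters) to a piecewise history."""
    for name, (lo, hi) in zip(spec.param_names, spec.bounds):
        v = params[name]
        if not (lo <= v <= hi):
            raise ValueError(f"{spec.model_id}: {name}={v:g} outside [{lo:g}, {hi:g}]")
    m = spec.model_id
    if m == "equilibrium":
        N = params["N"]
        return Demography(epochs=(Epoch(None, N, N, "constant"),))
    if m == "instantaneous_change":
        return Demography(
            epochs=(
                Epoch(params["T"], params["Ncur"], params["Ncur"], "constant"),
                Epoch(None, params["Nanc"], params["Nanc"], "constant"),
            )
        )
    if m == "exponential_change":
        return Demography(
            epochs=(
                Epoch(params["T"], params["Ncur"], params["Nanc"], "exponential"),
                Epoch(None, params["Nanc"], params["Nanc"], "constant"),
            )
        )
    if m == "instantaneous_bottleneck":
        # coalescent-intensity pulse I at time T: a vanishing-duration epoch
        # with size eps/(2I) adds exactly I to the pair intensity integral
        N, I, T = params["Nanc"], params["intensity"], params["T"]
        nb = _BOTTLENECK_EPS / (2.0 * I)
        return Demography(
            epochs=(
                Epoch(T, N, N, "constant"),
                Epoch(_BOTTLENECK_EPS, nb, nb, "constant"),
                Epoch(None, N, N, "constant"),
            )
        )
    raise KeyError(m)


def expected_sfs_model(
    spec: DemographicModelSpec,
    params: dict[str, float],
    n_hap: int,
    mu: float | None = None,
) -> ExpectedSFS:
    """Analytic expected SFS of the candidate model."""
    return expected_sfs_pk(model_demography(spec, params), 1.0, n_hap, mu=mu)


def composite_loglik(
    obs: SFS, expected: ExpectedSFS, include_monomorphic: bool = False
) -> float:
    """Multinomial log-likelihood of the observed SFS classes.

    Without the monomorphic class: sum_b O_b * ln p_b with p the relative
    SFS over classes 1..n-1. With it, the expected segregating proportion
    per site (``expected.theta_per_site``, requiring the expected SFS to
    have been built with a mutation rate) scales the polymorphic classes
    and the zero class takes the complement — this is what anchors
    absolute population sizes.
    """
    if obs.folded:
        raise ValueError("fitting uses the unfolded SFS")
    if obs.n_hap != expected.n_hap:
        raise ValueError("sample size mismatch between observed and expected SFS")
    O = obs.counts[1 : obs.n_hap].astype(float)
    if O.sum() == 0:
        raise ValueError("observed SFS has no polymorphic sites")
    if include_monomorphic:
        if expected.theta_per_site is None:
            raise ValueError("include_monomorphic requires an expected SFS with mu")
        seg = min(expected.theta_per_site, 0.999999)
        p = np.concatenate([[1.0 - seg], seg * expected.p])
        Ofull = np.concatenate([[float(obs.counts[0])], O])
    else:
        p = expected.p
        Ofull = O
    with np.errstate(divide="ignore"):
        lp = np.log(p)
    if np.any((Ofull > 0) & ~np.isfinite(lp)):
        warnings.warn("expected class probability 0 with observed counts; lnL = -inf")
        return -math.inf
    return float(np.sum(np.where(Ofull > 0, Ofull * lp, 0.0)))


@dataclass
class FitResult:
    """Best fit of one model: estimates, likelihood, and AIC variants."""

    model_id: str
    params: dict[str, float]
    loglik: float
    k: int
    n_restarts: int
    converged: bool

    @property
    def L10(self) -> float:
        return self.loglik / math.log(10.0)

    @property
    def aic(self) -> float:
        return aic(self.k, self.loglik, penalty=2.0)

    @property
    def aic25(self) -> float:
        return aic(self.k, self.loglik, penalty=25.0)


def aic(k: int, loglik: float, penalty: float = 2.0) -> float:
    """penalty * k - 2 * lnL (penalty 2 = standard AIC, 25 = strict variant)."""
    if k < 0:
        raise ValueError("k must be non-negative")
    return penalty * k - 2.0 * loglik


def fit_model(
    obs: SFS,
    spec: DemographicModelSpec,
    n_restarts: int = 50,
    seed: int = 0,
    mu: float | None = None,
    include_monomorphic: bool = False,
) -> FitResult:
    """Bounded derivative-free multistart maximization of the composite lnL.

    Starting points are drawn uniformly within the parameter box (on log
    scale for log-scale parameters); each is refined with Nelder-Mead
    under box bounds; the best restart is returned. Deterministic given
    the seed.
    """
    if obs.counts[1 : obs.n_hap].sum() == 0:
        raise ValueError("observed SFS has no polymorphic sites")
    rng = np.random.default_rng(seed)
    n_hap = obs.n_hap

    lo = np.array([b[0] for b in spec.bounds])
    hi = np.array([b[1] for b in spec.bounds])
    logs = np.array(spec.log_scale)

    def to_params(x: np.ndarray) -> dict[str, float]:
        v = np.where(logs, np.exp(x), x)
        v = np.clip(v, lo, hi)
        return dict(zip(spec.param_names, v))

    def neg_ll(x: np.ndarray) -> float:
        try:
            exp_sfs = expected_sfs_model(spec, to_params(x), n_hap, mu=mu)
        except (ValueError, FloatingPointError):
            return 1e12
        ll = composite_loglik(obs, exp_sfs, include_monomorphic=include_monomorphic)
        return 1e12 if not np.isfinite(ll) else -ll

    xlo = np.where(logs, np.log(lo), lo)
    xhi = np.where(logs, np.log(hi), hi)
    best: tuple[float, np.ndarray] | None = None
    any_converged = False
    for _ in range(n_restarts):
        x0 = rng.uniform(xlo, xhi)
        res = optimize.minimize(
            neg_ll,
            x0,
            method="Nelder-Mead",
            bounds=list(zip(xlo, xhi)),
            options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 400},
        )
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best[0]:
            best = (res.fun, res.x)
    assert best is not None
    if best[0] >= 1e12:
        raise RuntimeError(f"no restart of {spec.model_id} reached a finite likelihood")
    return FitResult(
        model_id=spec.model_id,
        params=to_params(best[1]),
        loglik=-best[0],
        k=spec.k,
        n_restarts=n_restarts,
        converged=any_converged,
    )


@dataclass
class ModelChoice:
    """AIC comparison across candidate models."""

    model_ids: list[str]
    aics: np.ndarray
    deltas: np.ndarray = field(init=False)
    weights: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.aics = np.asarray(self.aics, dtype=float)
        if self.aics.size == 0:
            raise ValueError("need at least one model")
        if np.any(~np.isfinite(self.aics)):
            raise ValueError("non-finite AIC")
        self.deltas = self.aics - self.aics.min()
        w = np.exp(-0.5 * self.deltas)
        self.weights = w / w.sum()

    @property
    def selected(self) -> str:
        order = np.lexsort((np.arange(len(self.model_ids)), -self.weights))
        return self.model_ids[order[0]]


def akaike_weights(aics: list[float], model_ids: list[str] | None = None) -> ModelChoice:
    """Akaike weights of evidence from a list of AICs."""
    ids = model_ids or [f"model{i}" for i in range(len(aics))]
    return ModelChoice(model_ids=list(ids), aics=np.asarray(aics, dtype=float))


def fit_all_models(
    obs: SFS,
    model_ids: list[str] | None = None,
    n_restarts: int = 50,
    seed: int = 0,
    mu: float | None = None,
    include_monomorphic: bool = False,
    penalty: float = 2.0,
) -> tuple[dict[str, FitResult], ModelChoice]:
    """Fit every candidate model and rank them by (possibly strict) AIC."""
    ids = model_ids or list(MODELS)
    seeds = np.random.SeedSequence(seed).spawn(len(ids))
    fits = {
        m: fit_model(
            obs,
            MODELS[m],
            n_restarts=n_restarts,
            seed=int(s.generate_state(1)[0] % (2**31 - 1)),
            mu=mu,
            include_monomorphic=include_monomorphic,
        )
        for m, s in zip(ids, seeds)
    }
    aics = [aic(f.k, f.loglik, penalty=penalty) for f in fits.values()]
    return fits, ModelChoice(model_ids=list(fits), aics=np.asarray(aics))


def pool_replicates(fits_per_replicate: list[dict[str, FitResult]]) -> dict[str, FitResult]:
    """Per model, the best (maximum-likelihood) fit across data replicates.

    Mirrors taking the maximum of maximum likelihoods over replicates
    before computing AIC for replicate studies.
    """
    if not fits_per_replicate:
        raise ValueError("no replicates")
    out: dict[str, FitResult] = {}
    for rep in fits_per_replicate:
        for m, f in rep.items():
            if m not in out or f.loglik > out[m].loglik:
                out[m] = f
    return out
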