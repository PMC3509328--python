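"""Observables, single-parameter calcium fitting, and Hill analysis.

In a stopped-flow experiment the drop in pyrene fluorescence is proportional
to myosin-S1 binding to actin in the strongly bound (R) state, so the model
quantity compared with data is g(t) = fraction of actin sites *not* in the
R-state.  The only calcium-dependent parameter is the TnI-actin detachment
rate k_-I; fitting it at each calcium level yields the equilibrium constant
K_B = k_-I / k_Io = 1/K_I, whose sigmoidal dependence on pCa is summarised
by a Hill fit.

The published stopped-flow dataset is not deposited, so a synthetic-
transient generator (simulator output, affine-normalised, plus i.i.d.
Gaussian noise) stands in for it in recovery experiments; it carries its
ground truth for parameter-recovery tests.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit, minimize_scalar

from .kinetics import RateConstants, STRONG
from .params import ChainParams, ParameterError

logger = logging.getLogger(__name__)


@dataclass
class Transient:
    """Time course of the not-R-state fraction and auxiliary series."""

    t: np.ndarray
    frac_not_R: np.ndarray
    frac_weak: np.ndarray | None = None
    frac_strong: np.ndarray | None = None
    frac_tni_bound: np.ndarray | None = None
    M_free: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.frac_not_R = np.asarray(self.frac_not_R, dtype=float)
        if self.t.shape != self.frac_not_R.shape:
            raise ValueError("time and signal arrays must have equal length")
        if self.t.size > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("time axis must be strictly increasing")
        if np.any((self.frac_not_R < -1e-9) | (self.frac_not_R > 1 + 1e-9)):
            raise ValueError("frac_not_R must lie in [0, 1]")

    @property
    def normalized(self) -> np.ndarray:
        """Min-max rescaled trace in [0, 1] over the recorded window."""
        lo, hi = self.frac_not_R.min(), self.frac_not_R.max()
        if hi == lo:
            return np.zeros_like(self.frac_not_R)
        return (self.frac_not_R - lo) / (hi - lo)


def fluorescence_proxy(n_strong: np.ndarray, n_A: int) -> np.ndarray:
    """Not-R-state fraction 1 - n_strong/n_A, the pyrene-fluorescence proxy."""
    return 1.0 - np.asarray(n_strong, dtype=float) / n_A


@dataclass
class FitResult:
    """Outcome of the single-parameter k_-I fit."""

    k_TnI_off_hat: float
    K_B_hat: float
    scale: float
    offset: float
    sse: float
    n_strands: int
    seed: int
    flat_objective: bool = False
    scan: list = field(default_factory=list)   # (k_-I, SSE) pairs examined
    best_curve: np.ndarray | None = None       # fitted model on obs time grid


def _affine_sse(obs: np.ndarray, model: np.ndarray) -> tuple[float, float, float]:
    """SSE of obs against a*model + b with (a, b) profiled in closed form."""
    mm = model - model.mean()
    denom = float(mm @ mm)
    if denom <= 0:
        a = 0.0
    else:
        a = float(mm @ (obs - obs.mean())) / denom
    b = float(obs.mean() - a * model.mean())
    resid = obs - (a * model + b)
    return float(resid @ resid), a, b


def fit_k_TnI_off(observed: Transient, config, params: ChainParams,
                  constants: RateConstants,
                  bounds: tuple[float, float] = (5.0, 6000.0),
                  n_grid: int = 7, xatol: float = 0.01,
                  max_refine_iter: int = 12,
                  conditioner=None) -> FitResult:
    """Estimate k_-I by matching simulated to observed normalised transients.

    1-D search over log10 k_-I: a coarse grid scan brackets the minimum,
    then bounded scalar minimisation (Brent) refines it.  Every candidate
    simulation uses the same seed (common random numbers), which makes the
    stochastic objective effectively smooth in k_-I.  Affine scale/offset
    nuisance parameters are profiled out in closed form per candidate, since
    the instrument span of normalised fluorescence is not knowable.
    """
    from .engine import run_transient

    if observed.t.size < 4:
        raise ValueError("observed transient too short to fit")
    obs = np.asarray(observed.frac_not_R, dtype=float)
    scan: list = []
    cache: dict[float, tuple[float, float, float, np.ndarray]] = {}

    def objective(log10_k: float) -> float:
        k = 10.0 ** float(log10_k)
        if k in cache:
            return cache[k][0]
        sim = run_transient(config, params, constants=replace(constants, k_TnI_off=k),
                            conditioner=conditioner)
        model = np.interp(observed.t, sim.t, sim.frac_not_R)
        sse, a, b = _affine_sse(obs, model)
        cache[k] = (sse, a, b, a * model + b)
        scan.append((k, sse))
        return sse

    lo, hi = math.log10(bounds[0]), math.log10(bounds[1])
    grid = np.linspace(lo, hi, n_grid)
    sse_grid = np.array([objective(g) for g in grid])
    i_best = int(np.argmin(sse_grid))
    if i_best == 0 or i_best == n_grid - 1:
        # minimum at a search edge: warn rather than extrapolate
        warnings.warn("k_-I objective minimised at a search bound; "
                      "result may be unreliable", RuntimeWarning, stacklevel=2)
        b_lo = grid[max(i_best - 1, 0)]
        b_hi = grid[min(i_best + 1, n_grid - 1)]
    else:
        b_lo, b_hi = grid[i_best - 1], grid[i_best + 1]
    minimize_scalar(objective, bounds=(b_lo, b_hi), method="bounded",
                    options={"xatol": xatol, "maxiter": max_refine_iter})
    k_hat = min(cache, key=lambda kk: cache[kk][0])
    sse, a, b, curve = cache[k_hat]

    # flatness diagnostic: SSE spread across the scanned range relative to
    # the total variation of the observed trace
    sses = np.array([s for _, s in scan])
    ss_tot = float(((obs - obs.mean()) ** 2).sum())
    flat = bool((sses.max() - sses.min()) < 0.05 * max(ss_tot, 1e-300))
    if flat:
        warnings.warn(
            "objective nearly flat in k_-I (insensitive regime, e.g. high "
            "calcium); the estimate constrains K_B only weakly",
            RuntimeWarning, stacklevel=2)
    return FitResult(
        k_TnI_off_hat=k_hat,
        K_B_hat=k_hat / constants.k_TnI_on,
        scale=a, offset=b, sse=sse,
        n_strands=config.n_strands, seed=config.seed,
        flat_objective=flat, scan=scan, best_curve=curve,
    )


@dataclass
class HillFit:
    """Four-parameter log-logistic summary of the K_B - pCa relationship."""

    h: float
    pCa50: float
    K_min: float
    K_max: float

    def predict(self, pCa: np.ndarray) -> np.ndarray:
        ca = 10.0 ** (-np.asarray(pCa, dtype=float))
        ca50 = 10.0 ** (-self.pCa50)
        return self.K_min + (self.K_max - self.K_min) * ca ** self.h \
            / (ca50 ** self.h + ca ** self.h)


def hill_fit(K_B: Sequence[float], pCa: Sequence[float]) -> HillFit:
    """Least-squares Hill fit K_B([Ca]) = K_min + (K_max-K_min) Ca^h/(Ca50^h+Ca^h)."""
    K_B = np.asarray(K_B, dtype=float)
    pCa = np.asarray(pCa, dtype=float)
    if K_B.size != pCa.size:
        raise ValueError("K_B and pCa must have equal length")
    if K_B.size < 4:
        raise ValueError("need at least 4 points to fit the 4-parameter sigmoid")
    ca = 10.0 ** (-pCa)

    def model(ca, h, pca50, kmin, kmax):
        ca50 = 10.0 ** (-pca50)
        return kmin + (kmax - kmin) * ca ** h / (ca50 ** h + ca ** h)

    p0 = (2.0, float(np.median(pCa)), float(K_B.min()), float(K_B.max()))
    popt, _ = curve_fit(model, ca, K_B, p0=p0, maxfev=20000)
    h, pca50, kmin, kmax = (float(v) for v in popt)
    if kmin > kmax:
        # reflected solution: same curve with h < 0 convention normalised away
        kmin, kmax, h = kmax, kmin, -h
    return HillFit(h=h, pCa50=pca50, K_min=kmin, K_max=kmax)


def make_synthetic_transient(true_K_B: float, config, params: ChainParams,
                             constants: RateConstants, noise_sd: float = 0.01,
                             seed: int | None = None,
                             conditioner=None) -> Transient:
    """Simulated noisy stand-in for an undeposited stopped-flow trace.

    Runs the simulator at k_-I = K_B * k_Io and adds i.i.d. Gaussian noise
    of SD ``noise_sd`` to the not-R fraction (clipped to [0, 1]).  The true
    parameters are recorded in ``meta`` for recovery experiments.
    """
    from .engine import run_transient

    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    if seed is not None:
        config = replace(config, seed=seed)
    sim = run_transient(config, params,
                        constants=constants.with_K_B(true_K_B),
                        conditioner=conditioner)
    rng = np.random.default_rng(None if seed is None else seed + 1)
    noisy = sim.frac_not_R + rng.normal(0.0, noise_sd, sim.frac_not_R.size) \
        if noise_sd > 0 else sim.frac_not_R.copy()
    noisy = np.clip(noisy, 0.0, 1.0)
    meta = dict(sim.meta)
    meta.update({"true_K_B": true_K_B, "noise_sd": noise_sd,
                 "noise_free": sim.frac_not_R})
    return Transient(t=sim.t, frac_not_R=noisy, frac_weak=sim.frac_weak,
                     frac_strong=sim.frac_strong,
                     frac_tni_bound=sim.frac_tni_bound, M_free=sim.M_free,
                     meta=meta)


def sensitivity_xi(base_config, params: ChainParams, constants: RateConstants,
                   rel_changes: Sequence[float] = (-0.2, 0.2)):
    """Transient family under rescaled confined persistence length 1/xi.

    For each relative change, alpha and sigma_o are re-derived from the
    scaled 1/xi at fixed kappa, and a matched-seed transient is run.
    Returns (base transient, {rel_change: transient}, divergence dict of
    RMS differences of the not-R fraction against the base trace).
    """
    from .engine import run_transient

    base = run_transient(base_config, params, constants)
    family: dict[float, Transient] = {}
    divergence: dict[float, float] = {}
    for rc in rel_changes:
        scaled = params.with_inv_xi(params.inv_xi * (1.0 + rc))
        tr = run_transient(base_config, scaled, constants)
        family[rc] = tr
        divergence[rc] = float(np.sqrt(np.mean(
            (tr.frac_not_R - base.frac_not_R) ** 2)))
    return base, family, divergence


def cluster_stats(site_state: np.ndarray, rng: np.random.Generator | None = None,
                  n_null: int = 1):
    """Run-length statistics of strongly bound myosin along each strand.

    Returns (run_lengths, null_run_lengths): contiguous STRONG run lengths
    pooled over strands, and the same for occupancy-matched random
    permutations of each strand (``n_null`` permutations per strand).
    Clustering shows as a larger mean run length than the permuted null.
    """
    site_state = np.atleast_2d(site_state)
    if rng is None:
        rng = np.random.default_rng(0)

    def runs(row: np.ndarray) -> list[int]:
        is_s = row == STRONG
        if not is_s.any():
            return []
        d = np.diff(np.concatenate([[0], is_s.view(np.int8), [0]]))
        starts = np.flatnonzero(d == 1)
        ends = np.flatnonzero(d == -1)
        return (ends - starts).tolist()

    obs: list[int] = []
    null: list[int] = []
    for row in site_state:
        obs.extend(runs(row))
        for _ in range(n_null):
            null.extend(runs(rng.permutation(row)))
    return np.asarray(obs, dtype=int), np.asarray(null, dtype=int)
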