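"""Chain-regulated transition rates and per-step transition probabilities.

The chain fluctuates much faster than the binding kinetics, so an effective
rate is the unregulated rate scaled by the fraction of time the chain spends
past the relevant angular threshold.  With Gaussian fluctuations
N(phi_bar_i, sigma_i) at site i these fractions are complementary-error-
function weights:

* TnI rebinding requires phi <= phi_minus:
      r_I = 1/2 erfc[(phi_bar_i - phi_minus) / (sqrt(2) sigma_i)]
* weak myosin binding requires phi >= phi_o:
      r_M1 = 1/2 erfc[(phi_o - phi_bar_i) / (sqrt(2) sigma_i)]
* weak->strong isomerisation requires phi >= phi_plus:
      r_M2 = 1/2 erfc[(phi_plus - phi_bar_i) / (sqrt(2) sigma_i)]

Each effective rate is the closed-state rate scaled by r / r_o, where r_o is
the same weight evaluated for the free chain (phi_o, sigma_o).  TnI
detachment (k_-I, the single calcium-dependent rate), myosin detachment and
reverse isomerisation are unregulated.  An empirical crowding factor
delta = 1 - 0.82 (n_AM / n_A) slows weak binding at high occupancy.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.special import erfc

from .params import ParameterError

SQRT2 = math.sqrt(2.0)

# site states of the myosin subsystem
FREE, WEAK, STRONG = 0, 1, 2


class TimestepError(ValueError):
    """A per-step transition probability bin exceeded 1."""


@dataclass(frozen=True)
class RateConstants:
    """Unregulated kinetic constants; k_TnI_off is the calcium-dependent one.

    Units: k_on_weak_2nd in M^-1 s^-1 (second-order weak binding), all
    others s^-1.
    """

    k_on_weak_2nd: float = 4.2e6   # k_M1o
    k_off_weak: float = 20.0       # k_-M1
    k_iso_fwd: float = 500.0       # k_M2o
    k_iso_rev: float = 5.0         # k_-M2
    k_TnI_on: float = 100.0        # k_Io, closed-state TnI rebinding
    k_TnI_off: float = 1200.0      # k_-I, set by [Ca2+]

    def __post_init__(self) -> None:
        for name in ("k_on_weak_2nd", "k_off_weak", "k_iso_fwd", "k_iso_rev",
                     "k_TnI_on", "k_TnI_off"):
            v = getattr(self, name)
            if v < 0 or not math.isfinite(v):
                raise ParameterError(f"{name} must be >= 0 and finite, got {v}")

    @property
    def K_I(self) -> float:
        """TnI-actin equilibrium constant k_Io / k_-I (closed-state)."""
        return self.k_TnI_on / self.k_TnI_off

    @property
    def K_B(self) -> float:
        """Blocked-state equilibrium constant, 1/K_I = k_-I / k_Io."""
        return self.k_TnI_off / self.k_TnI_on

    @property
    def K_M2(self) -> float:
        """Isomerisation equilibrium constant k_M2o / k_-M2."""
        return self.k_iso_fwd / self.k_iso_rev

    def with_K_B(self, K_B: float) -> "RateConstants":
        """Same constants with k_TnI_off set to K_B * k_TnI_on."""
        if K_B <= 0:
            raise ParameterError(f"K_B must be positive, got {K_B}")
        return replace(self, k_TnI_off=K_B * self.k_TnI_on)


def _tail_weight(phi_bar, sigma, threshold, above: bool):
    """P(phi >= threshold) (above=True) or P(phi <= threshold) for N(phi_bar, sigma).

    Vectorised; handles the sigma -> 0 limit (0, 1/2 or 1 by the sign of
    phi_bar - threshold).
    """
    phi_bar = np.asarray(phi_bar, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma < 0):
        raise ParameterError("sigma must be >= 0")
    diff = (phi_bar - threshold) if above else (threshold - phi_bar)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sigma > 0, -diff / (SQRT2 * np.where(sigma > 0, sigma, 1.0)), 0.0)
        w = 0.5 * erfc(z)
    w = np.where(sigma == 0,
                 np.where(diff > 0, 1.0, np.where(diff < 0, 0.0, 0.5)),
                 w)
    if w.ndim == 0:
        return float(w)
    return w


def weight_TnI_rebind(phi_bar_deg, sigma_deg, phi_minus_deg):
    """r_I: fraction of time the chain lies at phi <= phi_minus."""
    return _tail_weight(phi_bar_deg, sigma_deg, phi_minus_deg, above=False)


def weight_myosin(phi_bar_deg, sigma_deg, threshold_deg):
    """r_M1 (threshold phi_o) or r_M2 (threshold phi_plus): time past threshold."""
    return _tail_weight(phi_bar_deg, sigma_deg, threshold_deg, above=True)


def effective_k_TnI_on(r_I, r_I_o: float, k_TnI_on: float):
    """Chain-weighted TnI rebinding rate k_I = (r_I / r_I_o) k_Io (s^-1)."""
    if not (r_I_o > 0):
        raise ParameterError(
            "closed-state TnI weight r_I_o must be positive "
            "(phi_minus must lie below phi_o)")
    return np.asarray(r_I) / r_I_o * k_TnI_on


def effective_myosin_rates(r_M1, r_M2, constants: RateConstants,
                           free_myosin_conc: float,
                           r_M1_o: float = 0.5, r_M2_o: float | None = None,
                           sigma_o_deg: float | None = None,
                           phi_plus_deg: float | None = None):
    """Chain-weighted pseudo-first-order weak-binding and isomerisation rates.

    k_M1(s_i) = (r_M1 / r_M1_o) k_M1o [M]  and  k_M2(s_i) = (r_M2 / r_M2_o) k_M2o.
    r_M1_o is 1/2 for the free chain at phi_o; r_M2_o may be supplied directly
    or derived from (sigma_o, phi_plus).
    """
    if free_myosin_conc < 0:
        raise ParameterError(f"free myosin concentration must be >= 0, got {free_myosin_conc}")
    if r_M2_o is None:
        if sigma_o_deg is None or phi_plus_deg is None:
            raise ParameterError("supply r_M2_o or (sigma_o_deg, phi_plus_deg)")
        r_M2_o = weight_myosin(0.0, sigma_o_deg, phi_plus_deg)
    k_M1 = np.asarray(r_M1) / r_M1_o * constants.k_on_weak_2nd * free_myosin_conc
    k_M2 = np.asarray(r_M2) / r_M2_o * constants.k_iso_fwd
    return k_M1, k_M2


def crowding_delta(n_AM, n_A):
    """Empirical crowding factor delta = 1 - 0.82 (n_AM / n_A), in [0.18, 1]."""
    n_AM = np.asarray(n_AM, dtype=float)
    if np.any(n_AM < 0) or np.any(n_AM > n_A):
        raise ParameterError("require 0 <= n_AM <= n_A")
    out = 1.0 - 0.82 * (n_AM / n_A)
    return float(out) if out.ndim == 0 else out


def free_myosin_conc(fraction_bound: float, M_tot: float, A_tot: float) -> float:
    """[M] = [M_tot] - f [A_tot], floored at zero (with a warning) on depletion."""
    if not (0.0 <= fraction_bound <= 1.0):
        raise ParameterError(f"fraction bound must lie in [0, 1], got {fraction_bound}")
    if M_tot < 0 or A_tot < 0:
        raise ParameterError("concentrations must be >= 0")
    m = M_tot - fraction_bound * A_tot
    if m < 0:
        warnings.warn("myosin depletion exceeds supply; [M] floored at 0",
                      RuntimeWarning, stacklevel=2)
        return 0.0
    return m


@dataclass
class TransitionProbs:
    """Per-step probability bins for one strand (Metropolis-style fixed dt).

    Myosin-site arrays have length n_sites; TnI arrays length n_regulatory.
    Bins not applicable to the current state are zero (weak binding only at
    FREE sites, isomerisation only at WEAK, reverse isomerisation only at
    STRONG, detachment only from WEAK); the remainder to 1 is "no change".
    """

    p_M1: np.ndarray
    p_mM1: np.ndarray
    p_M2: np.ndarray
    p_mM2: np.ndarray
    p_I: np.ndarray
    p_mI: np.ndarray


def build_transition_probs(site_state: np.ndarray, tni_bound: np.ndarray,
                           tni_sites: np.ndarray,
                           phi_bar_deg: np.ndarray, sigma_deg: np.ndarray,
                           params, constants: RateConstants, dt: float,
                           free_M: float, delta: float,
                           warn_threshold: float = 0.05) -> TransitionProbs:
    """Per-site transition probability bins for one strand.

    Normalisation note: the r/r_o weighting enters exactly once, through the
    effective rates, i.e. p_M1 = delta (r_M1/r_M1_o) k_M1o [M] dt; at the
    closed state this reduces to delta k_M1o [M] dt.

    ``tni_sites`` holds 0-based monomer indices of the regulatory sites;
    TnI rebinding probability is forced to zero where the monomer carries
    any bound myosin.
    """
    if dt <= 0:
        raise ParameterError(f"dt must be positive, got {dt}")
    n = site_state.size
    r_I_o = weight_TnI_rebind(params.phi_o_deg, params.sigma_o_deg, params.phi_minus_deg)
    r_M2_o = weight_myosin(params.phi_o_deg, params.sigma_o_deg, params.phi_plus_deg)

    r_M1 = weight_myosin(phi_bar_deg, sigma_deg, params.phi_o_deg)
    r_M2 = weight_myosin(phi_bar_deg, sigma_deg, params.phi_plus_deg)
    k_M1, k_M2 = effective_myosin_rates(r_M1, r_M2, constants, free_M,
                                        r_M2_o=r_M2_o)

    p_M1 = np.where(site_state == FREE, delta * k_M1 * dt, 0.0)
    p_mM1 = np.where(site_state == WEAK, constants.k_off_weak * dt, 0.0)
    p_M2 = np.where(site_state == WEAK, k_M2 * dt, 0.0)
    p_mM2 = np.where(site_state == STRONG, constants.k_iso_rev * dt, 0.0)

    r_I = weight_TnI_rebind(phi_bar_deg[tni_sites], sigma_deg[tni_sites],
                            params.phi_minus_deg)
    k_I = effective_k_TnI_on(r_I, r_I_o, constants.k_TnI_on)
    occupied = site_state[tni_sites] != FREE
    p_I = np.where(~tni_bound & ~occupied, k_I * dt, 0.0)
    p_mI = np.where(tni_bound, constants.k_TnI_off * dt, 0.0)

    mx = max(p_M1.max(initial=0), (p_mM1 + p_M2).max(initial=0),
             p_mM2.max(initial=0), p_I.max(initial=0), p_mI.max(initial=0))
    if mx > 1.0:
        raise TimestepError(
            f"transition probability bin {mx:.3f} exceeds 1; reduce dt")
    if mx > warn_threshold:
        warnings.warn(
            f"largest per-step transition probability {mx:.3f} exceeds "
            f"{warn_threshold}; consider a smaller dt", RuntimeWarning,
            stacklevel=2)
    return TransitionProbs(p_M1, p_mM1, p_M2, p_mM2, p_I, p_mI)
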