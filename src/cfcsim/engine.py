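"""Fixed-timestep stochastic simulation of an ensemble of regulated strands.

Each subsystem is one strand of an actin double helix (N = 700 monomers,
a regulatory TnI site on every seventh monomer starting from the third) with
its own confined Tm-Tn chain.  Per Monte Carlo step two drawings are made:
one over the regulatory sites (TnI detach / rebind) and one over all actin
sites (free <-> weak <-> strong myosin-S1 transitions), with per-site
transition probabilities built from the chain-regulated rates.  Bound TnI
and strongly bound myosin pin the chain, so every binding event feeds back
on the rates at neighbouring sites.

Two implementation choices keep ensembles of thousands of strands tractable
without changing the sampled process:

* Chain state at a site is obtained by conditioning the free-chain Gaussian
  field on the pin values near that site (:class:`ChainConditioner`), using
  the exact site covariance precomputed once by the banded solver.
  Correlations decay as exp(-xi d), so restricting to the nearest pins
  within a ~3.5 persistence-length window reproduces the whole-chain
  constrained solve to high accuracy.
* Per-site Bernoulli transitions are sampled by thinning: for each pool of
  same-state sites a binomial count is drawn at a per-pool upper bound on
  the per-site probability, the candidate sites are chosen uniformly, and
  each candidate is accepted with p_i / p_max.  The per-site marginals and
  independence are identical to naive per-site uniform draws.

Myosin depletion is tracked ensemble-wide ([M] = [M_tot] - f [A_tot], f the
bound-site fraction) as is the crowding factor delta = 1 - 0.82 f.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .chainmech import ChainSolver, PinningProfile
from .kinetics import (FREE, STRONG, WEAK, RateConstants, TimestepError,
                       weight_myosin, weight_TnI_rebind)
from .params import DEG, ChainParams, ParameterError

logger = logging.getLogger(__name__)

TNI_FIRST_SITE = 2   # 0-based index of the first regulatory monomer (third)
TNI_PERIOD = 7


def tni_site_indices(n_sites: int) -> np.ndarray:
    """0-based monomer indices carrying a TnI (every 7th from the third)."""
    return np.arange(TNI_FIRST_SITE, n_sites, TNI_PERIOD)


@dataclass(frozen=True)
class SimConfig:
    """Run conditions for one stopped-flow-style simulation."""

    A_tot: float                  # total actin monomer concentration (M)
    M_tot: float                  # total myosin-S1 concentration (M)
    duration: float               # simulated time after mixing (s)
    n_strands: int = 2000         # CFC subsystems (2 per filament)
    n_sites: int = 700
    dt: float = 1e-5              # s
    seed: int = 0
    record_interval: int = 100    # steps between records
    burn_in: float = 0.5          # s of TnI-only pre-equilibration
    start_tni_bound: bool = True  # cold start: all TnI bound before burn-in
    chain_coupling: bool = True   # False: no pinning feedback (mass-action limit)

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ParameterError(f"dt must be positive, got {self.dt}")
        if self.duration < 0 or self.burn_in < 0:
            raise ParameterError("duration and burn_in must be >= 0")
        if self.n_strands < 1 or self.n_strands % 2:
            raise ParameterError(
                f"n_strands must be a positive even number (two strands per "
                f"filament), got {self.n_strands}")
        if self.A_tot < 0 or self.M_tot < 0:
            raise ParameterError("concentrations must be >= 0")
        if self.record_interval < 1:
            raise ParameterError("record_interval must be >= 1")


class ChainConditioner:
    """Chain state at actin sites by windowed Gaussian conditioning.

    The free chain is a Gaussian field with site covariance
    G = kBT K^-1 (precomputed by the banded solver).  Pinning constrains
    site values, so the constrained mean and SD at site i given pin sites p
    with angles a are the standard conditional moments

        phi_bar_i = G[i,p] G[p,p]^-1 a,
        sigma_i^2 = G[i,i] - G[i,p] G[p,p]^-1 G[p,i].

    Correlations decay as exp(-xi d), so only pins within ``window``
    monomers matter; of those, the ``max_pins_side`` nearest on each side
    are kept (pins beyond the retained ones are strongly screened).  The
    result matches the whole-chain constrained solve to well below the
    Monte Carlo noise of any feasible ensemble.
    """

    def __init__(self, params: ChainParams, n_sites: int, refine: int = 4,
                 window: int | None = None, max_pins_side: int = 6):
        self.params = params
        self.n_sites = int(n_sites)
        spacing = params.monomer_spacing
        if window is None:
            # correlation beyond the window below exp(-10) ~ 5e-5
            window = int(math.ceil(10.0 / (params.xi * spacing)))
        self.window = int(window)
        self.max_pins_side = int(max_pins_side)
        solver = ChainSolver(params, n_sites, refine=refine)
        self.G = solver.site_covariance()       # rad^2, (n_sites, n_sites)
        self.sigma_site_deg = np.sqrt(np.diag(self.G)) / DEG

    def evaluate(self, pin_code: np.ndarray, strand_idx: np.ndarray,
                 site_idx: np.ndarray, phi_minus_deg: float,
                 phi_plus_deg: float) -> tuple[np.ndarray, np.ndarray]:
        """Mean angle and SD (degrees) at candidate (strand, site) pairs.

        ``pin_code`` is (n_strands, n_sites) int8 with 0 = unpinned,
        1 = bound TnI (phi_minus), 2 = strong myosin (phi_plus).
        """
        m = strand_idx.size
        if m == 0:
            z = np.zeros(0)
            return z, z.copy()
        C = self.window
        n_sites = self.n_sites
        nk = self.max_pins_side
        offs = np.arange(-C, C + 1)
        cols = site_idx[:, None] + offs[None, :]
        valid = (cols >= 0) & (cols < n_sites)
        codes = np.where(valid,
                         pin_code[strand_idx[:, None], np.clip(cols, 0, n_sites - 1)],
                         0)
        angles_rad = np.array([0.0, phi_minus_deg, phi_plus_deg]) * DEG

        pinned = codes[:, C] > 0
        phi = np.zeros(m)
        sig = self.sigma_site_deg[site_idx].copy()

        # nearest nk pin columns on each side (masked distance, argpartition)
        kl = np.arange(C)
        big = 10 * C
        dist_l = np.where(codes[:, :C] > 0, C - kl[None, :], big)
        dist_r = np.where(codes[:, C + 1:] > 0, kl[None, :] + 1, big)
        sel_l = np.argpartition(dist_l, min(nk, C - 1), axis=1)[:, :nk]
        sel_r = np.argpartition(dist_r, min(nk, C - 1), axis=1)[:, :nk]
        pin_cols = np.concatenate([sel_l, C + 1 + sel_r], axis=1)
        pin_ok = np.concatenate([np.take_along_axis(dist_l, sel_l, 1) < big,
                                 np.take_along_axis(dist_r, sel_r, 1) < big], axis=1)
        any_pins = pin_ok.any(axis=1) & ~pinned
        if any_pins.any():
            rows = np.flatnonzero(any_pins)
            pc = pin_cols[rows]
            ok = pin_ok[rows]
            psites = np.clip(site_idx[rows][:, None] + (pc - C), 0, n_sites - 1)
            a = angles_rad[codes[rows[:, None], pc]] * ok
            w = ok.shape[1]
            Gpp = self.G[psites[:, :, None], psites[:, None, :]]
            gsp = self.G[site_idx[rows][:, None], psites]
            # neutralise empty slots: unit diagonal row/col, zero coupling
            mask2 = ok[:, :, None] & ok[:, None, :]
            eye = np.eye(w)[None, :, :]
            Gpp = np.where(mask2, Gpp, eye)
            Gpp = Gpp + 1e-12 * eye
            gsp = gsp * ok
            rhs = np.stack([a, gsp], axis=2)
            sol = np.linalg.solve(Gpp, rhs)
            phi_r = np.einsum("ij,ij->i", gsp, sol[:, :, 0])
            var_r = self.G[site_idx[rows], site_idx[rows]] \
                - np.einsum("ij,ij->i", gsp, sol[:, :, 1])
            phi[rows] = phi_r / DEG
            sig[rows] = np.sqrt(np.maximum(var_r, 0.0)) / DEG
        if pinned.any():
            phi[pinned] = angles_rad[codes[pinned, C]] / DEG
            sig[pinned] = 0.0
        return phi, sig


def _choose_distinct(rng: np.random.Generator, n: int, k: int) -> np.ndarray:
    """k distinct uniform integers from [0, n) (unordered set semantics)."""
    if k >= n:
        return np.arange(n)
    idx = np.unique(rng.integers(0, n, size=k + (k >> 2) + 8))
    while idx.size < k:
        extra = rng.integers(0, n, size=k)
        idx = np.unique(np.concatenate([idx, extra]))
    if idx.size > k:
        idx = idx[rng.permutation(idx.size)[:k]]
    return idx


@dataclass
class TransientRecord:
    """Raw per-interval records accumulated during a run."""

    t: list = field(default_factory=list)
    frac_not_R: list = field(default_factory=list)
    frac_weak: list = field(default_factory=list)
    frac_strong: list = field(default_factory=list)
    frac_tni_bound: list = field(default_factory=list)
    M_free: list = field(default_factory=list)


class Ensemble:
    """State and dynamics of an ensemble of independent CFC strands."""

    def __init__(self, config: SimConfig, params: ChainParams,
                 constants: RateConstants,
                 conditioner: ChainConditioner | None = None,
                 backend: str = "auto"):
        self.config = config
        self.params = params
        self.constants = constants
        self.tables = conditioner if conditioner is not None \
            else ChainConditioner(params, config.n_sites)
        S, N = config.n_strands, config.n_sites
        self.tni_cols = tni_site_indices(N)
        self.I = self.tni_cols.size
        self.site_state = np.zeros((S, N), dtype=np.uint8)
        self.tni_bound = np.full((S, self.I), config.start_tni_bound)
        self.pin_code = np.zeros((S, N), dtype=np.int8)
        if config.start_tni_bound and config.chain_coupling:
            self.pin_code[:, self.tni_cols] = 1
        self.n_weak = 0
        self.n_strong = 0
        self.n_tni_bound = int(self.tni_bound.sum())
        self.n_A = S * N
        self.time = 0.0
        self.rng = np.random.default_rng(config.seed)
        # closed-state normalisers
        self.r_I_o = float(weight_TnI_rebind(params.phi_o_deg, params.sigma_o_deg,
                                             params.phi_minus_deg))
        self.r_M2_o = float(weight_myosin(params.phi_o_deg, params.sigma_o_deg,
                                          params.phi_plus_deg))
        if not self.r_I_o > 0:
            raise ParameterError("phi_minus must lie below phi_o (r_I_o = 0)")
        self._validate_dt()
        from . import _kernel
        if backend == "auto":
            backend = "numba" if _kernel.HAVE_NUMBA else "numpy"
        if backend not in ("numba", "numpy"):
            raise ValueError(f"unknown backend {backend!r}")
        if backend == "numba" and not _kernel.HAVE_NUMBA:
            raise ValueError("numba backend requested but numba is unavailable")
        self.backend = backend
        self._kernel_state: dict | None = None

    # ------------------------------------------------------------------
    @property
    def n_AM(self) -> int:
        return self.n_weak + self.n_strong

    @property
    def fraction_bound(self) -> float:
        return self.n_AM / self.n_A

    def _validate_dt(self) -> None:
        c, dt = self.constants, self.config.dt
        bounds = {
            "TnI detachment": c.k_TnI_off * dt,
            "TnI rebinding": c.k_TnI_on / self.r_I_o * dt,
            "weak binding": 2.0 * c.k_on_weak_2nd * self.config.M_tot * dt,
            "weak-site transitions": (c.k_off_weak + c.k_iso_fwd / self.r_M2_o) * dt,
            "reverse isomerisation": c.k_iso_rev * dt,
        }
        worst = max(bounds.values())
        if worst > 1.0:
            name = max(bounds, key=bounds.get)
            raise TimestepError(
                f"per-step probability bound for {name} is {worst:.2f} > 1; "
                "reduce dt")
        if worst > 0.05:
            logger.warning(
                "largest per-step transition probability bound is %.3f "
                "(> 0.05); consider reducing dt for convergence studies", worst)

    # ------------------------------------------------------------------
    def _eval_chain(self, strand_idx: np.ndarray, site_idx: np.ndarray,
                    pin_code: np.ndarray | None = None):
        pc = self.pin_code if pin_code is None else pin_code
        return self.tables.evaluate(pc, strand_idx, site_idx,
                                    self.params.phi_minus_deg,
                                    self.params.phi_plus_deg)

    def step(self, myosin_active: bool = True) -> None:
        """Advance the ensemble by one Monte Carlo time step.

        Both drawings are evaluated against the start-of-step state (chain
        pinning, free-myosin pool, crowding), then applied: TnI updates
        first, then myosin updates, with TnI rebinding taking precedence
        over weak binding on the same monomer within a step.
        """
        cfg, c = self.config, self.constants
        rng = self.rng
        dt = cfg.dt
        S, N = cfg.n_strands, cfg.n_sites
        self._invalidate_kernel()   # direct stepping bypasses pool bookkeeping

        f = self.fraction_bound
        M_free = max(cfg.M_tot - f * cfg.A_tot, 0.0) if myosin_active else 0.0
        delta = 1.0 - 0.82 * f

        # --- draw candidate sites for every pool -----------------------
        detach_sel = rev_sel = weak_detach_sel = None
        rebind_cand = bind_cand = iso_cand = None
        u_iso = None
        if c.k_TnI_off > 0 and self.n_tni_bound > 0:
            k = rng.binomial(self.n_tni_bound, min(c.k_TnI_off * dt, 1.0))
            if k:
                bound_flat = np.flatnonzero(self.tni_bound.ravel())
                detach_sel = bound_flat[_choose_distinct(rng, bound_flat.size, k)]
        if c.k_TnI_on > 0 and self.n_tni_bound < self.tni_bound.size:
            p_max_I = c.k_TnI_on / self.r_I_o * dt
            elig = ~self.tni_bound & (self.site_state[:, self.tni_cols] == FREE)
            elig_flat = np.flatnonzero(elig.ravel())
            if elig_flat.size:
                k = rng.binomial(elig_flat.size, min(p_max_I, 1.0))
                if k:
                    rebind_cand = elig_flat[_choose_distinct(rng, elig_flat.size, k)]
        n_free = self.n_A - self.n_AM
        if M_free > 0 and n_free > 0:
            p_max_M1 = 2.0 * delta * c.k_on_weak_2nd * M_free * dt
            k = rng.binomial(n_free, min(p_max_M1, 1.0))
            if k:
                free_flat = np.flatnonzero((self.site_state == FREE).ravel())
                bind_cand = free_flat[_choose_distinct(rng, free_flat.size, k)]
        if self.n_weak > 0:
            p_det = c.k_off_weak * dt
            p_pool = p_det + c.k_iso_fwd / self.r_M2_o * dt
            if p_pool > 0:
                k = rng.binomial(self.n_weak, min(p_pool, 1.0))
                if k:
                    weak_flat = np.flatnonzero((self.site_state == WEAK).ravel())
                    cand = weak_flat[_choose_distinct(rng, weak_flat.size, k)]
                    # one uniform decides detach vs (candidate) isomerisation
                    u = rng.random(cand.size) * p_pool
                    det = u < p_det
                    weak_detach_sel = cand[det]
                    iso_cand = cand[~det]
                    u_iso = u[~det] - p_det
        if self.n_strong > 0 and c.k_iso_rev > 0:
            k = rng.binomial(self.n_strong, min(c.k_iso_rev * dt, 1.0))
            if k:
                strong_flat = np.flatnonzero((self.site_state == STRONG).ravel())
                rev_sel = strong_flat[_choose_distinct(rng, strong_flat.size, k)]

        # --- one chain-state evaluation for all candidates --------------
        rebind_sel = bind_sel = weak_iso_sel = None
        parts = []
        if rebind_cand is not None:
            parts.append((rebind_cand // self.I, self.tni_cols[rebind_cand % self.I]))
        if bind_cand is not None:
            parts.append((bind_cand // N, bind_cand % N))
        if iso_cand is not None and iso_cand.size:
            parts.append((iso_cand // N, iso_cand % N))
        if parts:
            s_all = np.concatenate([q[0] for q in parts])
            i_all = np.concatenate([q[1] for q in parts])
            phi, sig = self._eval_chain(s_all, i_all)
            pos = 0
            if rebind_cand is not None:
                nseg = rebind_cand.size
                r_I = weight_TnI_rebind(phi[pos:pos + nseg], sig[pos:pos + nseg],
                                        self.params.phi_minus_deg)
                # acceptance p_i/p_max = (r_I/r_I_o) k_Io dt / (k_Io dt / r_I_o)
                rebind_sel = rebind_cand[rng.random(nseg) < np.atleast_1d(r_I)]
                pos += nseg
            if bind_cand is not None:
                nseg = bind_cand.size
                r_M1 = weight_myosin(phi[pos:pos + nseg], sig[pos:pos + nseg],
                                     self.params.phi_o_deg)
                # acceptance delta (r/0.5) k [M] dt / (2 delta k [M] dt) = r_M1
                bind_sel = bind_cand[rng.random(nseg) < np.atleast_1d(r_M1)]
                pos += nseg
            if iso_cand is not None and iso_cand.size:
                r_M2 = weight_myosin(phi[pos:], sig[pos:], self.params.phi_plus_deg)
                p_iso = np.atleast_1d(r_M2) / self.r_M2_o * c.k_iso_fwd * dt
                weak_iso_sel = iso_cand[u_iso < p_iso]

        # --- apply: TnI first ------------------------------------------
        tb = self.tni_bound.ravel()
        couple = cfg.chain_coupling
        if detach_sel is not None and detach_sel.size:
            tb[detach_sel] = False
            s_idx, t_idx = detach_sel // self.I, detach_sel % self.I
            if couple:
                self.pin_code[s_idx, self.tni_cols[t_idx]] = 0
            self.n_tni_bound -= detach_sel.size
        if rebind_sel is not None and rebind_sel.size:
            tb[rebind_sel] = True
            s_idx, t_idx = rebind_sel // self.I, rebind_sel % self.I
            if couple:
                self.pin_code[s_idx, self.tni_cols[t_idx]] = 1
            self.n_tni_bound += rebind_sel.size

        ss = self.site_state.ravel()
        pc = self.pin_code.ravel()
        if weak_detach_sel is not None and weak_detach_sel.size:
            ss[weak_detach_sel] = FREE
            self.n_weak -= weak_detach_sel.size
        if rev_sel is not None and rev_sel.size:
            ss[rev_sel] = WEAK
            if couple:
                pc[rev_sel] = 0
            self.n_strong -= rev_sel.size
            self.n_weak += rev_sel.size
        if bind_sel is not None and bind_sel.size:
            # a TnI that rebound this step blocks binding on its monomer
            ok = (pc[bind_sel] != 1) & (ss[bind_sel] == FREE)
            bind_sel = bind_sel[ok]
            ss[bind_sel] = WEAK
            self.n_weak += bind_sel.size
        if weak_iso_sel is not None and weak_iso_sel.size:
            ok = ss[weak_iso_sel] == WEAK
            weak_iso_sel = weak_iso_sel[ok]
            ss[weak_iso_sel] = STRONG
            if couple:
                pc[weak_iso_sel] = 2
            self.n_weak -= weak_iso_sel.size
            self.n_strong += weak_iso_sel.size

        self.time += dt

    # ------------------------------------------------------------------
    def _kernel_arrays(self) -> dict:
        """(Re)build pool bookkeeping and scratch for the compiled backend."""
        from . import _kernel

        cfg = self.config
        S, N = cfg.n_strands, cfg.n_sites
        flat_state = self.site_state.ravel()
        m_list = np.zeros((3, S * N), dtype=np.int64)
        m_pos = np.zeros(S * N, dtype=np.int64)
        m_sz = np.zeros(3, dtype=np.int64)
        for pid in (FREE, WEAK, STRONG):
            members = np.flatnonzero(flat_state == pid)
            m_list[pid, : members.size] = members
            m_pos[members] = np.arange(members.size)
            m_sz[pid] = members.size
        nT = S * self.I
        flat_tni = self.tni_bound.ravel()
        t_list = np.zeros((2, nT), dtype=np.int64)
        t_pos = np.zeros(nT, dtype=np.int64)
        t_sz = np.zeros(2, dtype=np.int64)
        for pid, mask in ((0, flat_tni), (1, ~flat_tni)):
            members = np.flatnonzero(mask)
            t_list[pid, : members.size] = members
            t_pos[members] = np.arange(members.size)
            t_sz[pid] = members.size
        nk = self.tables.max_pins_side
        state = {
            "m_list": m_list, "m_pos": m_pos, "m_sz": m_sz,
            "t_list": t_list, "t_pos": t_pos, "t_sz": t_sz,
            "G": self.tables.G,
            "sigma_site": self.tables.sigma_site_deg * DEG,
            "ev_buf": np.zeros((6, S * N), dtype=np.int64),
            "mark_m": np.zeros(S * N, dtype=np.int64),
            "mark_t": np.zeros(nT, dtype=np.int64),
            "stamp": np.zeros(1, dtype=np.int64),
            "scratch_f": np.zeros(2 * nk, dtype=np.int64),
            "scratch_af": np.zeros(2 * nk, dtype=np.float64),
            "scratch_A": np.zeros((2 * nk, 2 * nk), dtype=np.float64),
            "scratch_L": np.zeros((2 * nk, 2 * nk), dtype=np.float64),
            "scratch_y": np.zeros(4 * nk, dtype=np.float64),
            "scratch_xa": np.zeros(2 * nk, dtype=np.float64),
            "scratch_xg": np.zeros(2 * nk, dtype=np.float64),
        }
        if not getattr(self, "_kernel_seeded", False):
            _kernel.seed_kernel_rng(self.config.seed)
            self._kernel_seeded = True
        return state

    def _run_kernel(self, n_steps: int, myosin_active: bool) -> None:
        from . import _kernel

        if self._kernel_state is None:
            self._kernel_state = self._kernel_arrays()
        ks = self._kernel_state
        cfg, c, p = self.config, self.constants, self.params
        _kernel.step_chunk(
            n_steps, self.site_state, self.tni_bound, self.pin_code,
            self.tni_cols,
            ks["m_list"], ks["m_pos"], ks["m_sz"],
            ks["t_list"], ks["t_pos"], ks["t_sz"],
            ks["G"], ks["sigma_site"], self.tables.window,
            self.tables.max_pins_side,
            p.phi_minus_rad, p.phi_plus_rad, p.phi_o_rad,
            self.r_I_o, self.r_M2_o,
            c.k_on_weak_2nd, c.k_off_weak, c.k_iso_fwd, c.k_iso_rev,
            c.k_TnI_on, c.k_TnI_off,
            cfg.dt, cfg.A_tot, cfg.M_tot, myosin_active,
            cfg.chain_coupling,
            ks["ev_buf"], ks["mark_m"], ks["mark_t"], ks["stamp"],
            ks["scratch_f"], ks["scratch_af"], ks["scratch_A"],
            ks["scratch_L"], ks["scratch_y"], ks["scratch_xa"],
            ks["scratch_xg"])
        self.n_weak = int(ks["m_sz"][1])
        self.n_strong = int(ks["m_sz"][2])
        self.n_tni_bound = int(ks["t_sz"][0])
        self.time += n_steps * cfg.dt

    def _invalidate_kernel(self) -> None:
        self._kernel_state = None

    # ------------------------------------------------------------------
    def equilibrate(self, burn_in: float | None = None) -> None:
        """TnI-only dynamics (no myosin) for the burn-in period."""
        t_eq = self.config.burn_in if burn_in is None else burn_in
        n_steps = int(round(t_eq / self.config.dt))
        if self.backend == "numba":
            self._run_kernel(n_steps, myosin_active=False)
        else:
            for _ in range(n_steps):
                self.step(myosin_active=False)
        self.time = 0.0

    def run(self, record: TransientRecord | None = None) -> TransientRecord:
        """Advance for the configured duration, recording the observables."""
        cfg = self.config
        rec = record if record is not None else TransientRecord()
        n_steps = int(round(cfg.duration / cfg.dt))
        self._record(rec)
        done = 0
        while done < n_steps:
            chunk = min(cfg.record_interval, n_steps - done)
            if self.backend == "numba":
                self._run_kernel(chunk, myosin_active=True)
            else:
                for _ in range(chunk):
                    self.step()
            done += chunk
            self._record(rec)
            if done % 100000 < cfg.record_interval:
                logger.info("t = %.3f s: not-R %.4f, weak %.4f, strong %.4f, "
                            "TnI bound %.4f", self.time,
                            1 - self.n_strong / self.n_A,
                            self.n_weak / self.n_A, self.n_strong / self.n_A,
                            self.n_tni_bound / self.tni_bound.size)
        return rec

    def _record(self, rec: TransientRecord) -> None:
        f = self.fraction_bound
        rec.t.append(self.time)
        rec.frac_not_R.append(1.0 - self.n_strong / self.n_A)
        rec.frac_weak.append(self.n_weak / self.n_A)
        rec.frac_strong.append(self.n_strong / self.n_A)
        rec.frac_tni_bound.append(self.n_tni_bound / self.tni_bound.size)
        rec.M_free.append(max(self.config.M_tot - f * self.config.A_tot, 0.0))

    # ------------------------------------------------------------------
    def snapshot(self) -> dict:
        """Copy of the discrete state, restorable via :meth:`restore`."""
        return {
            "time": self.time,
            "site_state": self.site_state.copy(),
            "tni_bound": self.tni_bound.copy(),
        }

    def restore(self, snap: dict) -> None:
        self.time = float(snap["time"])
        self.site_state = snap["site_state"].copy()
        self.tni_bound = snap["tni_bound"].copy()
        self.pin_code = np.zeros_like(self.pin_code)
        self.pin_code[:, self.tni_cols] = self.tni_bound.astype(np.int8)
        self.pin_code[self.site_state == STRONG] = 2
        self.n_weak = int((self.site_state == WEAK).sum())
        self.n_strong = int((self.site_state == STRONG).sum())
        self.n_tni_bound = int(self.tni_bound.sum())
        self._invalidate_kernel()

    def chain_profile(self, strand: int) -> tuple[np.ndarray, np.ndarray]:
        """Pair-approximation (phi_bar, sigma) in degrees at all sites of one strand."""
        sites = np.arange(self.config.n_sites)
        return self._eval_chain(np.full(sites.size, strand), sites)

    def pinning_profile(self, strand: int) -> PinningProfile:
        """Exact-solver pinning profile for one strand's current state."""
        tni_sites = self.tni_cols[self.tni_bound[strand]] + 1
        strong_sites = np.flatnonzero(self.site_state[strand] == STRONG) + 1
        return PinningProfile.from_occupancy(
            tni_sites.tolist(), strong_sites.tolist(), self.config.n_sites,
            self.params.phi_minus_deg, self.params.phi_plus_deg)


def run_transient(config: SimConfig, params: ChainParams,
                  constants: RateConstants,
                  conditioner: ChainConditioner | None = None,
                  ensemble_out: list | None = None):
    """Equilibrate at the given calcium level, mix with myosin, record.

    Returns an :class:`~cfcsim.observe_fit.Transient`.
    """
    from .observe_fit import Transient

    ens = Ensemble(config, params, constants, conditioner)
    ens.equilibrate()
    rec = ens.run()
    if ensemble_out is not None:
        ensemble_out.append(ens)
    return Transient(
        t=np.asarray(rec.t),
        frac_not_R=np.asarray(rec.frac_not_R),
        frac_weak=np.asarray(rec.frac_weak),
        frac_strong=np.asarray(rec.frac_strong),
        frac_tni_bound=np.asarray(rec.frac_tni_bound),
        M_free=np.asarray(rec.M_free),
        meta={"config": config, "K_B": constants.K_B,
              "k_TnI_off": constants.k_TnI_off},
    )
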