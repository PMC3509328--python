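"""Flat-text configuration, transient/snapshot files, and run manifests.

All interchange formats are plain text: configs are ``key = value`` lines
(units encoded in the key names, matching the published symbols), transients
and snapshots are tab-delimited columns, manifests are ``key: value`` lines.
Interface units: concentrations in uM, times in s, angles in degrees.
"""

from __future__ import annotations

import datetime
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .engine import SimConfig
from .kinetics import RateConstants
from .observe_fit import Transient
from .params import ChainParams


class ConfigError(ValueError):
    """Malformed configuration or data file."""


def read_flat_config(path) -> dict[str, str]:
    """Parse ``key = value`` lines; '#' starts a comment; blank lines skipped."""
    out: dict[str, str] = {}
    for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"{path}:{ln}: expected 'key = value', got {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        if not key or not value:
            raise ConfigError(f"{path}:{ln}: empty key or value in {raw!r}")
        if key in out:
            raise ConfigError(f"{path}:{ln}: duplicate key {key!r}")
        out[key] = value
    return out


def _get(cfg: dict, key: str, cast, default=None):
    if key not in cfg:
        if default is None:
            raise ConfigError(f"missing required config key {key!r}")
        return default
    try:
        return cast(cfg[key])
    except ValueError as exc:
        raise ConfigError(f"config key {key!r}: {exc}") from exc


def chain_params_from_config(cfg: dict[str, str]) -> ChainParams:
    """ChainParams from flat keys; defaults are the published Table values."""
    from .params import table1_defaults

    ref, _ = table1_defaults()
    kappa = _get(cfg, "kappa_pN_nm4", float, ref.kappa)
    inv_xi = _get(cfg, "inv_xi_nm", float, 1.0 / ref.xi)
    kBT = _get(cfg, "kBT_pN_nm", float, ref.kBT)
    kwargs = dict(
        phi_minus_deg=_get(cfg, "phi_minus_deg", float, ref.phi_minus_deg),
        phi_plus_deg=_get(cfg, "phi_plus_deg", float, ref.phi_plus_deg),
        monomer_spacing=_get(cfg, "monomer_spacing_nm", float, ref.monomer_spacing),
    )
    if "alpha_pN" in cfg or "sigma_o_deg" in cfg:
        return ChainParams(
            kappa=kappa, xi=1.0 / inv_xi,
            alpha=_get(cfg, "alpha_pN", float, ref.alpha),
            sigma_o_deg=_get(cfg, "sigma_o_deg", float, ref.sigma_o_deg),
            kBT=kBT, consistency_tol=_get(cfg, "consistency_tol", float, 0.05),
            **kwargs)
    return ChainParams.from_mechanics(kappa, 1.0 / inv_xi, kBT, **kwargs)


def rate_constants_from_config(cfg: dict[str, str]) -> RateConstants:
    base = RateConstants(
        k_on_weak_2nd=_get(cfg, "k_M1_0_per_M_s", float, 4.2e6),
        k_off_weak=_get(cfg, "k_mM1_per_s", float, 20.0),
        k_iso_fwd=_get(cfg, "k_M2_0_per_s", float, 500.0),
        k_iso_rev=_get(cfg, "k_mM2_per_s", float, 5.0),
        k_TnI_on=_get(cfg, "k_I_0_per_s", float, 100.0),
        k_TnI_off=_get(cfg, "k_mI_per_s", float, 1200.0),
    )
    if "K_B" in cfg:
        base = base.with_K_B(_get(cfg, "K_B", float))
    return base


def sim_config_from_config(cfg: dict[str, str]) -> SimConfig:
    return SimConfig(
        A_tot=_get(cfg, "A_tot_uM", float) * 1e-6,
        M_tot=_get(cfg, "M_tot_uM", float) * 1e-6,
        duration=_get(cfg, "duration_s", float),
        n_strands=_get(cfg, "n_strands", int, 2000),
        n_sites=_get(cfg, "n_sites", int, 700),
        dt=_get(cfg, "dt_s", float, 1e-5),
        seed=_get(cfg, "seed", int, 0),
        record_interval=_get(cfg, "record_interval", int, 100),
        burn_in=_get(cfg, "burn_in_s", float, 0.5),
    )


def chain_params_to_config(p: ChainParams) -> str:
    lines = [
        f"kappa_pN_nm4 = {p.kappa:.6g}",
        f"alpha_pN = {p.alpha:.6g}",
        f"inv_xi_nm = {1.0 / p.xi:.6g}",
        f"sigma_o_deg = {p.sigma_o_deg:.6g}",
        f"phi_minus_deg = {p.phi_minus_deg:.6g}",
        f"phi_plus_deg = {p.phi_plus_deg:.6g}",
        f"kBT_pN_nm = {p.kBT:.6g}",
        f"monomer_spacing_nm = {p.monomer_spacing:.6g}",
    ]
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
TRANSIENT_HEADER = ("time_s", "frac_not_R", "frac_weak", "frac_strong",
                    "frac_TnI_bound", "M_free_molar")


def write_transient(tr: Transient, path) -> None:
    cols = [tr.t, tr.frac_not_R]
    for aux in (tr.frac_weak, tr.frac_strong, tr.frac_tni_bound, tr.M_free):
        cols.append(aux if aux is not None else np.full_like(tr.t, np.nan))
    data = np.column_stack(cols)
    header = "\t".join(TRANSIENT_HEADER)
    np.savetxt(path, data, delimiter="\t", header=header, comments="",
               fmt="%.8g")


def read_transient(path) -> Transient:
    """Full six-column transient file written by :func:`write_transient`."""
    data = np.loadtxt(path, delimiter="\t", skiprows=1, ndmin=2)
    if data.shape[1] < 2:
        raise ConfigError(f"{path}: expected >= 2 columns")
    return Transient(t=data[:, 0], frac_not_R=data[:, 1],
                     frac_weak=data[:, 2] if data.shape[1] > 2 else None,
                     frac_strong=data[:, 3] if data.shape[1] > 3 else None,
                     frac_tni_bound=data[:, 4] if data.shape[1] > 4 else None,
                     M_free=data[:, 5] if data.shape[1] > 5 else None)


def read_observed_transient(path) -> Transient:
    """Two-column delimited text (time_s, normalized fluorescence).

    Header line optional; delimiter any whitespace, comma or tab.  Raises
    :class:`ConfigError` naming the offending line on malformed input.
    """
    times: list[float] = []
    values: list[float] = []
    lines = Path(path).read_text().splitlines()
    for ln, raw in enumerate(lines, start=1):
        line = raw.strip().replace(",", " ")
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 2:
            raise ConfigError(f"{path}:{ln}: expected two columns, got {raw!r}")
        try:
            t_val, f_val = float(parts[0]), float(parts[1])
        except ValueError:
            if ln == 1 and not times:
                continue        # header line
            raise ConfigError(f"{path}:{ln}: non-numeric data {raw!r}") from None
        times.append(t_val)
        values.append(f_val)
    if not times:
        raise ConfigError(f"{path}: no data rows found")
    t = np.asarray(times)
    if t.size > 1 and not np.all(np.diff(t) > 0):
        bad = int(np.argmax(np.diff(t) <= 0)) + 2
        raise ConfigError(f"{path}: time column not strictly increasing at "
                          f"data row {bad}")
    v = np.asarray(values)
    # observed traces are arbitrary normalised fluorescence; map onto [0, 1]
    lo, hi = v.min(), v.max()
    scaled = (v - lo) / (hi - lo) if hi > lo else np.zeros_like(v)
    return Transient(t=t, frac_not_R=scaled,
                     meta={"source": str(path), "raw": v})


def write_snapshot(path, site_state: np.ndarray, tni_bound: np.ndarray,
                   phi_bar_deg: np.ndarray | None = None,
                   sigma_deg: np.ndarray | None = None) -> None:
    """Columnar archive: strand, site, state, tni_bound, phi_bar_deg, sigma_deg."""
    S, N = site_state.shape
    with open(path, "w") as fh:
        fh.write("strand\tsite\tstate\ttni_bound\tphi_bar_deg\tsigma_deg\n")
        from .engine import tni_site_indices
        cols = tni_site_indices(N)
        for s in range(S):
            bound_sites = set(cols[tni_bound[s]].tolist())
            for i in range(N):
                phi = phi_bar_deg[s, i] if phi_bar_deg is not None else math.nan
                sig = sigma_deg[s, i] if sigma_deg is not None else math.nan
                fh.write(f"{s}\t{i}\t{int(site_state[s, i])}\t"
                         f"{int(i in bound_sites)}\t{phi:.4f}\t{sig:.4f}\n")


@dataclass
class RunManifest:
    """Reproducibility record for one CLI run."""

    command: str
    config: dict
    seed: int
    started: str
    finished: str = ""
    outputs: tuple[str, ...] = ()

    def to_text(self) -> str:
        lines = [f"command: {self.command}",
                 f"seed: {self.seed}",
                 f"started: {self.started}",
                 f"finished: {self.finished}"]
        for k, v in sorted(self.config.items()):
            lines.append(f"config.{k}: {v}")
        for out in self.outputs:
            lines.append(f"output: {out}")
        return "\n".join(lines) + "\n"

    @staticmethod
    def now() -> str:
        return datetime.datetime.now(datetime.timezone.utc).isoformat()
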