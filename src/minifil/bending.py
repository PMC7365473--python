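"""Worm-like-chain splaying of a partially attached myosin rod.

For a rod pair at stagger ``s`` the mobile (second) rod is attached to its
partner along its C-terminal contour segment of length ``L_o`` (the overlap),
then departs along a tangent-continuous circular arc of radius ``R`` and arc
length ``L_a``, then continues straight.  The bending energy of the arc is
the worm-like-chain expression

    E_bend = l_p k_B T L_a / (2 R^2)

with persistence length l_p = 130 nm.  For each (s, L_o) cell the arc
parameters are fixed by minimising total (electrostatic + bending) energy on
a grid R in [75, 300] nm, L_a in [15, 40] nm, optionally against a straight
(no-bend) candidate.

Geometry convention: the bent rod's C-terminal tip sits inside the straight
partner's span (tip-first attachment), so the maximum overlap at stagger s is
L_max(s) = min(L_A - s, L_B) for both orientations.  For identical rods this
coincides with the straight-pair stagger convention; only the second rod of
an ordered pair ever bends.
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np

from .electrostatics import ElectrostaticParams, chain_interaction_energy
from .rod_model import ChargeChain

logger = logging.getLogger("minifil")


@dataclasses.dataclass
class WLCParams:
    """Worm-like-chain stiffness and the (R, L_a) minimisation grid."""

    persistence_length: float = 130.0
    r_range: tuple[float, float] = (75.0, 300.0)
    la_range: tuple[float, float] = (15.0, 40.0)
    r_steps: int = 16
    la_steps: int = 11
    include_straight: bool = True

    def __post_init__(self) -> None:
        if self.persistence_length <= 0:
            raise ValueError("persistence length must be positive")
        for name, (lo, hi) in (("r_range", self.r_range), ("la_range", self.la_range)):
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must be positive and ordered")
        if self.r_steps < 2 or self.la_steps < 2:
            raise ValueError("grid needs at least 2 steps per axis")

    @property
    def r_grid(self) -> np.ndarray:
        return np.linspace(self.r_range[0], self.r_range[1], self.r_steps)

    @property
    def la_grid(self) -> np.ndarray:
        return np.linspace(self.la_range[0], self.la_range[1], self.la_steps)

    def candidates(self) -> list[tuple[float, float]]:
        """(R, L_a) pairs in tie-break preference order: R desc, L_a asc."""
        return [
            (float(r), float(la))
            for r in self.r_grid[::-1]
            for la in self.la_grid
        ]


@dataclasses.dataclass
class BendGeometry:
    """Optimal bend of one landscape cell; energies in k_B T, lengths nm.

    ``radius`` is ``inf`` for the straight (no-bend) configuration.
    """

    stagger: float
    overlap: float
    radius: float
    arc_length: float
    bend_energy: float
    electro_energy: float

    @property
    def total_energy(self) -> float:
        return self.bend_energy + self.electro_energy

    @property
    def is_straight(self) -> bool:
        return math.isinf(self.radius)


def bending_energy(radius: float, arc_length: float, persistence_length: float = 130.0) -> float:
    """WLC energy l_p L_a / (2 R^2) of a circular arc, in k_B T."""
    if arc_length < 0:
        raise ValueError("arc length must be non-negative")
    if math.isinf(radius):
        return 0.0
    if radius <= 0:
        raise ValueError("bend radius must be positive")
    return persistence_length * arc_length / (2.0 * radius**2)


def max_overlap(chain_a: ChargeChain, chain_b: ChargeChain, stagger: float) -> float:
    """Largest geometrically possible overlap L_max(s), nm."""
    return min(chain_a.rod_length - stagger, chain_b.rod_length)


def bent_rod_coordinates(
    chain: ChargeChain,
    stagger: float,
    overlap: float,
    radius: float,
    arc_length: float,
    orientation: str,
    params: ElectrostaticParams,
    partner_length: float,
) -> np.ndarray:
    """Site coordinates of the bent (second) rod of a pair.

    The rod is straight along its C-terminal contour segment of length
    ``overlap`` (lying parallel to the partner axis at the lateral
    separation), bends away along a circular arc (radius ``radius``, arc
    length ``arc_length``), then continues straight along the final tangent.
    ``radius=inf`` gives the fully straight rod.  An arc longer than the
    remaining contour is clamped with a logged warning.  The partner rod is
    assumed on the z-axis with site i at z = i * spacing (see
    :func:`minifil.electrostatics.place_straight_pair`).
    """
    if orientation not in ("parallel", "antiparallel"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if stagger < 0:
        raise ValueError("negative staggers are not considered")
    if overlap < 0:
        raise ValueError("overlap must be non-negative")
    d = params.lateral_separation
    L = chain.rod_length
    if orientation == "parallel":
        z_tip, u = partner_length - stagger, -1.0
    else:
        z_tip, u = stagger, 1.0
    # contour position of each site measured from the C-terminal tip
    c = (chain.n_sites - 1 - np.arange(chain.n_sites)) * chain.spacing
    remaining = L - overlap
    la = arc_length
    if not math.isinf(radius) and la > remaining + 1e-9:
        logger.warning(
            "arc length %.3g nm exceeds remaining contour %.3g nm; clamped", la, remaining
        )
        la = max(remaining, 0.0)
    y = np.full(chain.n_sites, d)
    z = z_tip + u * c
    if not math.isinf(radius) and la > 0 and remaining > 0:
        t = c - overlap
        on_arc = (t > 0) & (t <= la)
        past = t > la
        theta = t[on_arc] / radius
        z_b = z_tip + u * overlap
        z[on_arc] = z_b + u * radius * np.sin(theta)
        y[on_arc] = d + radius * (1.0 - np.cos(theta))
        alpha = la / radius
        z_e = z_b + u * radius * math.sin(alpha)
        y_e = d + radius * (1.0 - math.cos(alpha))
        tt = t[past] - la
        z[past] = z_e + u * tt * math.cos(alpha)
        y[past] = y_e + tt * math.sin(alpha)
    return np.column_stack([np.zeros_like(z), y, z])


def optimize_bend(
    chain_a: ChargeChain,
    chain_b: ChargeChain,
    orientation: str,
    stagger: float,
    overlap: float,
    e_params: ElectrostaticParams | None = None,
    wlc_params: WLCParams | None = None,
) -> BendGeometry:
    """Grid-minimal bend of rod B at one (s, L_o) cell (reference path).

    Evaluates the full-chain electrostatic energy (all charges of both rods,
    including the bent-away tail) plus the WLC bending energy for every
    (R, L_a) grid candidate; returns the minimum.  Ties break toward larger
    R then smaller L_a.  Arcs longer than the remaining contour are clamped,
    so the candidate family tends to the straight rod as L_o approaches
    L_max.  The straight (no-bend) configuration is itself a candidate only
    where it is geometrically consistent with the cell's overlap — at
    L_o = L_max the whole rod is attached and staying straight is an option
    (``include_straight``); at smaller overlaps a straight rod would
    contact its partner over L_max, not L_o, so it is not admitted there.
    This is the literal per-cell enumeration; :func:`energy_landscape` uses
    an equivalent fast engine.
    """
    e_params = e_params or ElectrostaticParams()
    wlc_params = wlc_params or WLCParams()
    lmax = max_overlap(chain_a, chain_b, stagger)
    if overlap > lmax + 1e-9:
        raise ValueError(f"overlap {overlap} exceeds L_max(s) = {lmax:.4g} nm")
    za = chain_a.axial_positions
    coords_a = np.column_stack([np.zeros_like(za), np.zeros_like(za), za])

    at_top = overlap >= lmax - 1e-9 or overlap >= chain_b.rod_length - 1e-9
    cands: list[tuple[float, float]] = []
    if wlc_params.include_straight and at_top:
        cands.append((math.inf, 0.0))
    cands.extend(wlc_params.candidates())
    if not cands:
        raise ValueError("empty candidate grid")

    best: BendGeometry | None = None
    remaining = chain_b.rod_length - overlap
    for r, la in cands:
        la_eff = la if math.isinf(r) else min(la, max(remaining, 0.0))
        coords_b = bent_rod_coordinates(
            chain_b, stagger, overlap, r, la_eff, orientation, e_params,
            partner_length=chain_a.rod_length,
        )
        e_el = chain_interaction_energy(
            chain_a.charges, coords_a, chain_b.charges, coords_b, e_params
        )
        e_bd = bending_energy(r, la_eff, wlc_params.persistence_length)
        if best is None or e_el + e_bd < best.total_energy - 1e-12:
            best = BendGeometry(stagger, overlap, r, la_eff, e_bd, e_el)
    assert best is not None
    return best


@dataclasses.dataclass
class OverlapPotential:
    """Total energy V(L_o) at fixed stagger: the 1-D potential for kinetics.

    ``overlaps`` (nm, increasing, starting at 0) and ``energies`` (k_B T);
    the last grid point is the exact maximum overlap L_max(s).
    ``reference_mfpt``, when set (synthetic test potentials), maps
    ``(x0, D)`` to the closed-form mean first passage time.
    """

    stagger: float
    overlaps: np.ndarray
    energies: np.ndarray
    labels: tuple[str, str] = ("", "")
    orientation: str = ""
    reference_mfpt: object = None

    def __post_init__(self) -> None:
        self.overlaps = np.asarray(self.overlaps, dtype=float)
        self.energies = np.asarray(self.energies, dtype=float)
        if self.overlaps.size != self.energies.size or self.overlaps.size < 2:
            raise ValueError("overlaps and energies must match and have >= 2 points")
        if np.any(np.diff(self.overlaps) <= 0):
            raise ValueError("overlaps must be strictly increasing")

    @property
    def l_max(self) -> float:
        return float(self.overlaps[-1])

    def energy_at(self, x: float | np.ndarray) -> float | np.ndarray:
        """Linear interpolation of V between grid points (k_B T)."""
        return np.interp(x, self.overlaps, self.energies)


@dataclasses.dataclass
class EnergyLandscape:
    """Minimised total energy over (stagger, overlap) for one ordered pair.

    Rectangular arrays indexed ``[i_s, i_lo]``; cells with
    ``overlap > L_max(s)`` are geometrically inaccessible and hold NaN.
    ``top_*`` arrays carry the cell at the exact per-stagger maximum overlap
    (which generally falls between rectangular grid columns).
    """

    orientation: str
    labels: tuple[str, str]
    staggers: np.ndarray
    overlaps: np.ndarray
    e_total: np.ndarray
    e_elec: np.ndarray
    e_bend: np.ndarray
    r_opt: np.ndarray
    la_opt: np.ndarray
    lmax: np.ndarray
    top_e_total: np.ndarray
    top_e_elec: np.ndarray
    top_e_bend: np.ndarray

    @property
    def accessible(self) -> np.ndarray:
        return self.overlaps[None, :] <= self.lmax[:, None] + 1e-9

    def to_dataframe(self):
        """Long-format table (one row per cell) for TSV export."""
        import pandas as pd

        i_s, i_lo = np.meshgrid(
            np.arange(self.staggers.size), np.arange(self.overlaps.size), indexing="ij"
        )
        return pd.DataFrame(
            {
                "s_nm": self.staggers[i_s.ravel()],
                "Lo_nm": self.overlaps[i_lo.ravel()],
                "R_nm": self.r_opt.ravel(),
                "La_nm": self.la_opt.ravel(),
                "E_bend_kBT": self.e_bend.ravel(),
                "E_elec_kBT": self.e_elec.ravel(),
                "E_total_kBT": self.e_total.ravel(),
                "accessible": self.accessible.ravel(),
            }
        )


def energy_landscape(
    chain_a: ChargeChain,
    chain_b: ChargeChain,
    orientation: str,
    s_grid: np.ndarray | None = None,
    lo_step: float | None = None,
    e_params: ElectrostaticParams | None = None,
    wlc_params: WLCParams | None = None,
    engine: str = "fast",
) -> EnergyLandscape:
    """Optimal-bend energy landscape over a (s, L_o) grid.

    Default grids are lattice-aligned: staggers and overlaps advance in steps
    of 7 lattice sites (1.019 nm).  ``engine='fast'`` uses the lattice
    engine (exact attached segment, tabulated near field for the arc);
    ``engine='reference'`` runs the literal per-cell
    :func:`optimize_bend` enumeration and is only practical for toy chains.
    """
    e_params = e_params or ElectrostaticParams()
    wlc_params = wlc_params or WLCParams()
    spacing = chain_a.spacing
    if s_grid is None:
        ks_grid = np.arange(0, chain_a.n_sites, 7)
    else:
        ks_f = np.asarray(s_grid, dtype=float) / spacing
        ks_grid = np.round(ks_f).astype(int)
        if np.any(np.abs(ks_f - ks_grid) > 1e-6):
            if engine == "fast":
                raise ValueError(
                    "fast engine requires lattice-aligned staggers; "
                    "pass multiples of the 0.1456 nm spacing or engine='reference'"
                )
        if np.any(ks_grid < 0) or np.any(ks_grid > chain_a.n_sites - 1):
            raise ValueError("staggers outside [0, rod length]")
    lo_step_sites = 7 if lo_step is None else max(1, int(round(lo_step / spacing)))

    staggers = ks_grid * spacing
    n_s = ks_grid.size
    lo_all_max = min(chain_a.n_sites, chain_b.n_sites) - 1
    lo_idx_global = np.arange(0, lo_all_max + 1, lo_step_sites)
    overlaps = lo_idx_global * spacing
    shape = (n_s, lo_idx_global.size)
    e_total = np.full(shape, np.nan)
    e_elec = np.full(shape, np.nan)
    e_bend = np.full(shape, np.nan)
    r_opt = np.full(shape, np.nan)
    la_opt = np.full(shape, np.nan)
    lmax = np.empty(n_s)
    top_e_total = np.empty(n_s)
    top_e_elec = np.empty(n_s)
    top_e_bend = np.empty(n_s)

    if engine == "fast":
        from ._engine import LandscapeEngine

        eng = LandscapeEngine(chain_a, chain_b, orientation, e_params, wlc_params)
        for i, ks in enumerate(ks_grid):
            col = eng.stagger_column(int(ks), lo_step_sites)
            n_reg = col["lo_sites"].size
            # the last entry is the exact L_max cell; regular cells precede it
            reg = n_reg - 1 if col["lo_sites"][-1] % lo_step_sites else n_reg
            sel = slice(0, min(reg, lo_idx_global.size))
            nfill = sel.stop
            e_total[i, :nfill] = col["e_total"][:nfill]
            e_elec[i, :nfill] = col["e_elec"][:nfill]
            e_bend[i, :nfill] = col["e_bend"][:nfill]
            r_opt[i, :nfill] = col["r_opt"][:nfill]
            la_opt[i, :nfill] = col["la_opt"][:nfill]
            lmax[i] = col["lo_sites"][-1] * spacing
            top_e_total[i] = col["e_total"][-1]
            top_e_elec[i] = col["e_elec"][-1]
            top_e_bend[i] = col["e_bend"][-1]
    elif engine == "reference":
        for i, ks in enumerate(ks_grid):
            s = ks * spacing
            lmax_idx = min(chain_a.n_sites - 1 - ks, chain_b.n_sites - 1)
            lmax[i] = lmax_idx * spacing
            for j, lo_idx in enumerate(lo_idx_global):
                if lo_idx > lmax_idx:
                    break
                bg = optimize_bend(
                    chain_a, chain_b, orientation, s, lo_idx * spacing,
                    e_params, wlc_params,
                )
                e_total[i, j] = bg.total_energy
                e_elec[i, j] = bg.electro_energy
                e_bend[i, j] = bg.bend_energy
                r_opt[i, j] = bg.radius
                la_opt[i, j] = bg.arc_length
            bg = optimize_bend(
                chain_a, chain_b, orientation, s, lmax[i], e_params, wlc_params
            )
            top_e_total[i] = bg.total_energy
            top_e_elec[i] = bg.electro_energy
            top_e_bend[i] = bg.bend_energy
    else:
        raise ValueError(f"unknown engine {engine!r}")

    return EnergyLandscape(
        orientation, (chain_a.label, chain_b.label), staggers, overlaps,
        e_total, e_elec, e_bend, r_opt, la_opt, lmax,
        top_e_total, top_e_elec, top_e_bend,
    )


def overlap_potential(landscape: EnergyLandscape, stagger: float) -> OverlapPotential:
    """Extract V(L_o) at one stagger from a landscape.

    ``stagger`` must lie within the landscape's stagger range; a value
    between grid points falls back to the nearest column (logged).  The
    returned potential ends with the exact L_max(s) cell.
    """
    s_arr = landscape.staggers
    if stagger < s_arr.min() - 1e-9 or stagger > s_arr.max() + 1e-9:
        raise ValueError(f"stagger {stagger} nm outside landscape grid")
    i = int(np.argmin(np.abs(s_arr - stagger)))
    if abs(s_arr[i] - stagger) > 1e-6:
        logger.info(
            "stagger %.4g nm not on grid; using nearest column %.4g nm",
            stagger, s_arr[i],
        )
    acc = landscape.accessible[i]
    x = landscape.overlaps[acc]
    v = landscape.e_total[i, acc]
    keep = ~np.isnan(v)
    x, v = x[keep], v[keep]
    if x.size == 0 or landscape.lmax[i] > x[-1] + 1e-9:
        x = np.append(x, landscape.lmax[i])
        v = np.append(v, landscape.top_e_total[i])
    return OverlapPotential(
        float(s_arr[i]), x, v, landscape.labels, landscape.orientation
    )
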