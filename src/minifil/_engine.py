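"""Fast evaluation of bent-pair energy landscapes.

The per-cell grid minimisation of :func:`minifil.bending.optimize_bend` is
exact but repeats the full pairwise sum for every (s, L_o, R, L_a) tuple.
This engine exploits the charge lattice instead:

* the attached (straight) segment of the bent rod sits on the same axial
  lattice as the partner, so its energy is an exact prefix sum of per-site
  energies obtained from one convolution of the partner's charges with the
  lattice pair kernel;
* arc and tail sites see the partner through a tabulated near field
  Phi(y, z) (energy per unit charge), sampled on the lattice in z and at
  0.05 nm in y, and read off by bilinear interpolation.  Sites farther from
  the partner axis than the pair cutoff contribute exactly zero, as in the
  cutoff pairwise sum.

Agreement with the reference enumeration is at the level of the bilinear
interpolation error, ~1e-3 k_B T per cell.
"""

from __future__ import annotations

import math

import numpy as np

from .bending import WLCParams
from .electrostatics import ElectrostaticParams, lattice_kernel
from .rod_model import ChargeChain

_HY = 0.05  # y-resolution of the near-field table, nm


class LandscapeEngine:
    """Precomputed state for one ordered chain pair and orientation."""

    def __init__(
        self,
        chain_a: ChargeChain,
        chain_b: ChargeChain,
        orientation: str,
        e_params: ElectrostaticParams,
        wlc_params: WLCParams,
    ) -> None:
        if orientation not in ("parallel", "antiparallel"):
            raise ValueError(f"unknown orientation {orientation!r}")
        if e_params.pair_cutoff is None and (
            e_params.screening_length is None or not math.isfinite(e_params.screening_length)
        ):
            raise ValueError(
                "the fast landscape engine needs a finite pair cutoff or "
                "screening length; use the reference engine instead"
            )
        self.chain_a = chain_a
        self.chain_b = chain_b
        self.orientation = orientation
        self.e = e_params
        self.wlc = wlc_params
        self.spacing = chain_a.spacing
        self.qa = chain_a.charges
        self.qt = chain_b.charges[::-1].copy()  # tip-first order
        self.na = chain_a.n_sites
        self.nb = chain_b.n_sites
        d = e_params.lateral_separation
        self.ymax = (
            e_params.pair_cutoff
            if e_params.pair_cutoff is not None
            else d + 25.0 * e_params.screening_length
        )

        kern = lattice_kernel(e_params)
        self.m_half = (kern.size - 1) // 2
        # per-site straight energies: g[p + m_half] = sum_i qa[i] K(p - i)
        self.g = np.convolve(self.qa, kern)

        # near-field table T[iy, j]: z = (j - m_half) * spacing, y = d + iy*_HY
        ny = int(math.ceil((self.ymax - d) / _HY)) + 2
        yv = d + _HY * np.arange(ny)
        mm = np.arange(-self.m_half, self.m_half + 1) * self.spacing
        r = np.sqrt(yv[:, None] ** 2 + mm[None, :] ** 2)
        k = self.e.bjerrum_length / r * np.exp(-self.e.kappa * r)
        if self.e.pair_cutoff is not None:
            k[r > self.e.pair_cutoff] = 0.0
        self.table = np.array([np.convolve(self.qa, row) for row in k])
        self.ny, self.ncol = self.table.shape
        self.d = d

        self._candidates = self._precompute_candidates()
        self._chg_idx = np.nonzero(self.qt)[0]
        self._chg_q = self.qt[self._chg_idx]

    # -- candidate geometry -------------------------------------------------
    def _precompute_candidates(self):
        """Arc-site offsets (y, axial advance) per (R, L_a) candidate.

        For arc-coordinate t measured from the bend start, the lateral
        deviation and axial advance are

            t <= L_a:  y = d + R (1 - cos(t/R)),  zeta = R sin(t/R)
            t >  L_a:  straight continuation at the exit tangent angle L_a/R.

        Sites are at t = m * spacing; the list is truncated where y exceeds
        the cutoff (zero contribution beyond, exactly as in the pairwise sum).
        """
        out = []
        self._max_arc = 1
        nb_arc_cap = self.nb - 1
        for r_bend, la in self.wlc.candidates():
            alpha = la / r_bend
            # largest t with y <= ymax (tail: y grows linearly in t)
            y_la = self.d + r_bend * (1.0 - math.cos(min(alpha, math.pi)))
            if y_la >= self.ymax:
                # cutoff reached inside the arc
                cos_lim = 1.0 - (self.ymax - self.d) / r_bend
                t_lim = r_bend * math.acos(max(cos_lim, -1.0))
            else:
                t_lim = la + (self.ymax - y_la) / max(math.sin(alpha), 1e-12)
            m_arc = min(int(math.ceil(t_lim / self.spacing)) + 1, nb_arc_cap)
            m_arc = max(m_arc, 1)
            t = self.spacing * np.arange(1, m_arc + 1)
            y = np.empty_like(t)
            zeta = np.empty_like(t)
            on = t <= la
            theta = t[on] / r_bend
            y[on] = self.d + r_bend * (1.0 - np.cos(theta))
            zeta[on] = r_bend * np.sin(theta)
            tt = t[~on] - la
            y[~on] = self.d + r_bend * (1.0 - math.cos(alpha)) + tt * math.sin(alpha)
            zeta[~on] = r_bend * math.sin(alpha) + tt * math.cos(alpha)

            iy = np.floor((y - self.d) / _HY).astype(np.intp)
            fy = (y - self.d) / _HY - iy
            y_ok = iy <= self.ny - 2
            iy = np.clip(iy, 0, self.ny - 2)
            sign = -1.0 if self.orientation == "parallel" else 1.0
            jf = sign * zeta / self.spacing + self.m_half
            j0 = np.floor(jf).astype(np.intp)
            fz = jf - j0
            out.append(
                {
                    "R": r_bend,
                    "La": la,
                    "iy": iy,
                    "w_y": np.where(y_ok, fy, 0.0),
                    "y_ok": y_ok,
                    "j0": j0,
                    "fz": fz,
                }
            )
            self._max_arc = max(self._max_arc, m_arc)
        return out

    # -- per-stagger evaluation ---------------------------------------------
    def stagger_column(self, k_s: int, lo_step_sites: int = 7):
        """Minimised energies for all overlap cells at stagger index ``k_s``.

        Returns a dict with the overlap grid (site units, last entry = exact
        L_max) and per-cell arrays: e_total, e_elec, e_bend, r_opt, la_opt.
        The straight configuration competes only at the L_o = L_max cell,
        where it is geometrically consistent (see
        :func:`minifil.bending.optimize_bend`); arc sums run over the bent
        rod's charged sites only.
        """
        na, nb, mh = self.na, self.nb, self.m_half
        lmax_idx = min(na - 1 - k_s, nb - 1)
        if lmax_idx < 0:
            raise ValueError(f"stagger index {k_s} beyond rod A")
        l_arr = np.arange(0, lmax_idx + 1, lo_step_sites)
        if l_arr[-1] != lmax_idx:
            l_arr = np.append(l_arr, lmax_idx)

        # exact per-site straight energies and prefix sums
        ci = np.arange(nb)
        if self.orientation == "parallel":
            p = na - 1 - k_s - ci
        else:
            p = k_s + ci
        idx = p + mh
        valid = (idx >= 0) & (idx < self.g.size)
        w_site = np.where(valid, self.qt * self.g[np.clip(idx, 0, self.g.size - 1)], 0.0)
        w_cum = np.cumsum(w_site)
        e_attached = w_cum[l_arr]
        e_full_straight = w_cum[-1]

        if self.orientation == "parallel":
            base = na - 1 - k_s - l_arr  # lattice z-index of the bend start
        else:
            base = k_s + l_arr

        lp = self.wlc.persistence_length
        n_lo = l_arr.size
        n_cand = len(self._candidates)
        e_elec = np.empty((n_cand, n_lo))
        e_bend = np.empty((n_cand, n_lo))
        remaining = (nb - 1 - l_arr) * self.spacing

        # arc contributions: only charged sites of the bent rod matter
        chg = self._chg_idx  # contour-from-tip indices of charged sites
        m_mat = chg[:, None] - l_arr[None, :]  # arc-site index per (site, cell)
        in_arc = m_mat >= 1
        mi = np.clip(m_mat, 1, None) - 1  # index into candidate arrays
        qv = self._chg_q[:, None]
        for ic, cand in enumerate(self._candidates):
            n_arc = cand["iy"].size
            live = in_arc & (m_mat <= n_arc)
            mc = np.clip(mi, 0, n_arc - 1)
            iy = cand["iy"][mc]
            fy = cand["w_y"][mc]
            j = cand["j0"][mc] + base[None, :]
            fz = cand["fz"][mc]
            ok = live & cand["y_ok"][mc] & (j >= 0) & (j <= self.ncol - 2)
            jc = np.clip(j, 0, self.ncol - 2)
            t00 = self.table[iy, jc]
            t10 = self.table[iy + 1, jc]
            t01 = self.table[iy, jc + 1]
            t11 = self.table[iy + 1, jc + 1]
            val = (1 - fy) * ((1 - fz) * t00 + fz * t01) + fy * ((1 - fz) * t10 + fz * t11)
            e_arc = np.where(ok, qv * val, 0.0).sum(axis=0)
            la_eff = np.minimum(cand["La"], np.maximum(remaining, 0.0))
            e_bend[ic] = lp * la_eff / (2.0 * cand["R"] ** 2)
            e_elec[ic] = e_attached + e_arc

        e_tot = e_elec + e_bend
        best = np.argmin(e_tot, axis=0)  # first minimum = preferred tie-break
        cols = np.arange(n_lo)
        out_tot = e_tot[best, cols]
        out_elec = e_elec[best, cols]
        out_bend = e_bend[best, cols]
        r_opt = np.array([self._candidates[b]["R"] for b in best])
        la_opt = np.minimum(
            np.array([self._candidates[b]["La"] for b in best]),
            np.maximum(remaining, 0.0),
        )
        # straight configuration at the geometrically consistent top cell
        if self.wlc.include_straight and e_full_straight <= out_tot[-1] + 1e-12:
            out_tot[-1] = e_full_straight
            out_elec[-1] = e_full_straight
            out_bend[-1] = 0.0
            r_opt[-1], la_opt[-1] = math.inf, 0.0
        return {
            "lo_sites": l_arr,
            "e_total": out_tot,
            "e_elec": out_elec,
            "e_bend": out_bend,
            "r_opt": r_opt,
            "la_opt": la_opt,
            "e_full_straight": float(e_full_straight),
        }
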