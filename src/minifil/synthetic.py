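"""Synthetic charge chains and test potentials with known structure.

The myosin II rod carries a 196-residue charge repeat: alternating 98-residue
stretches of net negative and near-neutral charge, capped by a positively
charged C-terminal tip (the assembly critical domain).  Parallel staggers at
odd multiples of 98 residues align the tip with a negative stretch, which is
why the experimentally observed staggers sit at 14.3, 43.2 and 72 nm.

:func:`make_periodic_rod` builds a rod with exactly this skeleton: five
98-site negative blocks alternating with neutral blocks, and a 98-site
C-terminal tip whose +2e sites mirror the -2e pattern of the blocks
(charge-complementary, so tip-over-block alignment is sharply optimal and the
parallel self-scan has strict minima at staggers of exactly 98, 294 and 490
sites).  Site patterns are drawn once from a seeded generator and placed
symmetrically inside each block.  Block/tip total charges default to ±16 e:
the repeat-alignment energy dip grows linearly with amplitude while the
finite-rod envelope tilt (net-charged rod, shrinking overlap) grows
quadratically, so moderate amplitudes keep the scan minima pinned exactly at
the repeat alignments; amplitudes near the real NM2 windowed charge (~±40 e)
shift them by a few sites.  Everything else about real rods
(isoform-specific charge statistics, skip residues) is *not* emulated.

:func:`make_test_potential` supplies 1-D potentials whose mean first passage
times have closed forms, for validating the kinetics quadrature.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .bending import OverlapPotential
from .rod_model import AXIAL_SPACING_NM, ChargeChain


@dataclasses.dataclass
class SyntheticRodSpec:
    """Design of a synthetic periodic rod.

    ``negative_block_amplitude`` and ``tip_amplitude`` are the *total* charge
    (units e) of one 98-site negative block and of the tip; they are realised
    as -2e/+2e sites at matching offsets, so both must be multiples of 4
    (site pairs are placed symmetrically inside the half-period).
    """

    n_sites: int = 1085
    repeat_period: int = 196
    negative_block_amplitude: float = -16.0
    tip_length: int | None = None
    tip_amplitude: float = 16.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.repeat_period % 2 or self.repeat_period < 4:
            raise ValueError("repeat_period must be an even count >= 4")
        if self.n_sites < self.repeat_period:
            raise ValueError("n_sites must be at least one repeat period")
        if self.tip_length is None:
            self.tip_length = self.repeat_period // 2
        if self.tip_length > self.n_sites:
            raise ValueError("tip longer than the rod")
        if self.negative_block_amplitude > 0 or self.tip_amplitude < 0:
            raise ValueError(
                "negative_block_amplitude must be <= 0 and tip_amplitude >= 0"
            )
        for name, amp in (
            ("negative_block_amplitude", self.negative_block_amplitude),
            ("tip_amplitude", self.tip_amplitude),
        ):
            if abs(amp) / 2 != int(abs(amp) / 2) or int(abs(amp) / 2) % 2:
                raise ValueError(f"{name} must be a multiple of 4 e")
        half = self.repeat_period // 2
        if abs(self.negative_block_amplitude) / 2 > half or self.tip_amplitude / 2 > self.tip_length:
            raise ValueError("amplitude requires more sites than available")


def _symmetric_offsets(n_pairs: int, half: int, rng: np.random.Generator) -> np.ndarray:
    """2*n_pairs distinct offsets in [0, half), symmetric about its centre."""
    left = rng.choice(half // 2, size=n_pairs, replace=False)
    return np.sort(np.concatenate([left, half - 1 - left]))


def make_periodic_rod(spec: SyntheticRodSpec | None = None, label: str = "synthetic_rod") -> ChargeChain:
    """Deterministic synthetic rod with the 196-site charge repeat.

    Layout, measured from the C-terminal tip (site index n_sites - 1):
    positive tip over the first ``tip_length`` sites, then alternating
    negative / neutral 98-site blocks starting with a negative one, for as
    many full periods as fit.  The tip's +2e sites sit at the same offsets as
    each block's -2e sites.
    """
    spec = spec or SyntheticRodSpec()
    half = spec.repeat_period // 2
    rng = np.random.default_rng(spec.seed)
    n_block = int(abs(spec.negative_block_amplitude) / 2)
    n_tip = int(spec.tip_amplitude / 2)
    charges_from_tip = np.zeros(spec.n_sites)

    offsets = (
        _symmetric_offsets(n_block // 2, half, rng) if n_block else np.array([], int)
    )
    if n_tip:
        if spec.tip_length == half and n_tip == n_block:
            tip_offsets = offsets
        else:
            tip_offsets = _symmetric_offsets(n_tip // 2, spec.tip_length, rng)
        charges_from_tip[tip_offsets] = 2.0
    block_start = spec.tip_length if spec.tip_length > half else half
    start = block_start
    while start + half <= spec.n_sites:
        charges_from_tip[start + offsets] = -2.0
        start += spec.repeat_period
    # chain arrays run N-terminus -> C-terminus
    return ChargeChain(label, charges_from_tip[::-1].copy())


def make_test_potential(kind: str, **params) -> OverlapPotential:
    """Analytic 1-D overlap potentials with known mean first passage times.

    kinds:
      ``flat``        V = 0 on [0, L];  T1 = (2 L x0 - x0^2) / (2 D)
      ``linear``      V = slope * x;    T1 = (x0 - (1 - e^{-k(L - x0)}
                      ... evaluated in closed form, see ``reference_mfpt``
      ``single_well`` V = -depth on [center - width/2, center + width/2]

    Parameters: ``length`` (nm, default 100), ``n`` grid points (default
    1001), plus ``slope`` (k_B T/nm), ``depth`` (k_B T), ``center``,
    ``width`` as applicable.  The returned potential carries a
    ``reference_mfpt(x0, D)`` closed form where one exists (flat, linear).
    """
    length = float(params.pop("length", 100.0))
    n = int(params.pop("n", 1001))
    x = np.linspace(0.0, length, n)
    if kind == "flat":
        params.pop("slope", None)
        v = np.zeros_like(x)

        def ref(x0: float, diffusion: float = 1.0) -> float:
            return (2.0 * length * x0 - x0**2) / (2.0 * diffusion)

    elif kind == "linear":
        k = float(params.pop("slope", 0.1))
        v = k * x
        if k == 0.0:

            def ref(x0: float, diffusion: float = 1.0) -> float:
                return (2.0 * length * x0 - x0**2) / (2.0 * diffusion)

        else:

            def ref(x0: float, diffusion: float = 1.0, _k=k) -> float:
                # int_0^{x0} e^{kz} (e^{-kz} - e^{-kL})/k dz
                return (
                    x0 - np.exp(-_k * length) * (np.exp(_k * x0) - 1.0) / _k
                ) / (_k * diffusion)

    elif kind == "single_well":
        depth = float(params.pop("depth", 5.0))
        center = float(params.pop("center", length / 2.0))
        width = float(params.pop("width", length / 4.0))
        v = np.where(np.abs(x - center) <= width / 2.0, -depth, 0.0)
        ref = None
    else:
        raise ValueError(f"unknown test potential kind {kind!r}")
    if params:
        raise TypeError(f"unexpected parameters {sorted(params)}")
    return OverlapPotential(
        0.0, x, v, labels=("test", "test"), orientation="", reference_mfpt=ref
    )
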