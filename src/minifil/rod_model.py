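"""Charge-chain construction for coiled-coil myosin rods.

The ~160 nm coiled-coil tail of a myosin II dimer is coarse-grained into a
linear chain of point charges on a rigid axial lattice with 0.1456 nm between
neighbouring residues.  Each rod residue contributes one charge site: +2e for
Arg/Lys, -2e for Asp/Glu (the factor 2 accounts for the two heavy chains of
the dimer), 0 otherwise.  Residues at heptad positions *a* and *d* face the
hydrophobic core of the coiled-coil and have their charges cancelled.  Skip
residues -- isolated insertions that interrupt the heptad phase -- are kept as
charge sites; their label is never *a*/*d*, so their charges survive.

Residue coordinates in files and records are 1-based inclusive; site indices
on a :class:`ChargeChain` are 0-based.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

#: Axial rise per residue of the coiled-coil, nm.
AXIAL_SPACING_NM = 0.1456

#: Per-residue charge of a heavy-chain *dimer* rod, units of e.
RESIDUE_CHARGE_E = {"R": 2, "K": 2, "D": -2, "E": -2}

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

HEPTAD_CYCLE = "abcdefg"
REGISTER_LABELS = set(HEPTAD_CYCLE) | {"skip", "none"}

#: Hydrophobic residues used by the heuristic phase suggestion.
_CORE_HYDROPHOBIC = set("LIVMAF")


@dataclasses.dataclass
class HeavyChainRecord:
    """One myosin heavy chain with its modelled rod interval.

    ``rod_start``/``rod_end`` are 1-based inclusive residue indices delimiting
    the coiled-coil rod; ``skip_positions`` are 1-based indices of skip
    residues inside that interval.
    """

    id: str
    residues: str
    rod_start: int = 1
    rod_end: int | None = None
    skip_positions: list[int] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        self.residues = self.residues.upper()
        if self.rod_end is None:
            self.rod_end = len(self.residues)
        if not self.residues:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = [
            (i + 1, aa)
            for i, aa in enumerate(self.residues)
            if aa not in STANDARD_AA
        ]
        if bad:
            pos, aa = bad[0]
            raise ValueError(
                f"record {self.id!r}: non-standard residue {aa!r} at position {pos}"
            )
        if not (1 <= self.rod_start <= self.rod_end <= len(self.residues)):
            raise ValueError(
                f"record {self.id!r}: rod interval [{self.rod_start}, {self.rod_end}] "
                f"outside sequence of length {len(self.residues)}"
            )
        for p in self.skip_positions:
            if not (self.rod_start <= p <= self.rod_end):
                raise ValueError(
                    f"record {self.id!r}: skip position {p} outside rod interval"
                )

    @property
    def rod_sequence(self) -> str:
        return self.residues[self.rod_start - 1 : self.rod_end]

    @property
    def rod_length(self) -> int:
        return self.rod_end - self.rod_start + 1


@dataclasses.dataclass
class HeptadRegister:
    """Per-residue heptad labels (a-g, 'skip' or 'none') over a rod interval."""

    assignment: list[str]

    def __post_init__(self) -> None:
        for i, lab in enumerate(self.assignment):
            if lab not in REGISTER_LABELS:
                raise ValueError(f"invalid register label {lab!r} at offset {i}")

    def __len__(self) -> int:
        return len(self.assignment)

    def __iter__(self):
        return iter(self.assignment)


@dataclasses.dataclass
class ChargeChain:
    """Ordered point charges on the 0.1456 nm axial lattice.

    ``charges[i]`` (units of e, values in {-2, 0, +2}) sits at axial position
    ``i * spacing`` nm; index 0 is the N-terminal end of the rod, the last
    index the C-terminal tip.
    """

    label: str
    charges: np.ndarray
    spacing: float = AXIAL_SPACING_NM

    def __post_init__(self) -> None:
        self.charges = np.asarray(self.charges, dtype=float)
        if self.charges.ndim != 1 or self.charges.size == 0:
            raise ValueError("charges must be a non-empty 1-D array")
        if not np.isin(self.charges, (-2.0, 0.0, 2.0)).all():
            raise ValueError("site charges must be -2, 0 or +2 e")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")

    @property
    def n_sites(self) -> int:
        return self.charges.size

    @property
    def axial_positions(self) -> np.ndarray:
        return np.arange(self.n_sites) * self.spacing

    @property
    def rod_length(self) -> float:
        """Contour length of the rod, nm."""
        return (self.n_sites - 1) * self.spacing

    @property
    def total_charge(self) -> float:
        return float(self.charges.sum())

    def reversed(self) -> "ChargeChain":
        return ChargeChain(self.label + "_rev", self.charges[::-1].copy(), self.spacing)

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "site_index": np.arange(self.n_sites),
                "axial_position_nm": self.axial_positions,
                "charge_e": self.charges,
            }
        )
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, label: str | None = None) -> "ChargeChain":
        df = pd.read_csv(path, sep="\t", comment="#")
        return cls(label or Path(path).stem, df["charge_e"].to_numpy())


@dataclasses.dataclass
class ChargeProfile:
    """Sliding-window net charge along a rod (window in residues, charge in e)."""

    window: int
    center_positions: np.ndarray
    windowed_charge: np.ndarray


def read_fasta(path: str | Path) -> list[HeavyChainRecord]:
    """Read heavy-chain records from a FASTA file.

    Rod boundaries default to the full sequence; override them afterwards or
    through the run configuration.  Lowercase sequence letters are accepted
    and normalised to uppercase.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _validate_fasta_lines(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(HeavyChainRecord(id=rec.id, residues=str(rec.seq)))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def _validate_fasta_lines(path: Path) -> None:
    """Light syntactic pass so parse errors can name the offending line."""
    seen_header = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                seen_header = True
                continue
            if not seen_header:
                raise ValueError(
                    f"{path}:{lineno}: sequence data before first '>' header"
                )
            if not line.isalpha():
                raise ValueError(f"{path}:{lineno}: invalid sequence line {line!r}")
    if not seen_header:
        raise ValueError(f"{path}: empty or headerless FASTA file")


def assign_register(
    record: HeavyChainRecord,
    mode: str = "fallback",
    register_path: str | Path | None = None,
    phase: str = "a",
) -> HeptadRegister:
    """Return the heptad register over the record's rod interval.

    ``mode='file'`` reads a two-column TSV (1-based residue_index, label)
    aligned to the rod interval, e.g. as produced from a paircoil run.
    ``mode='fallback'`` cycles a..g from ``phase``; residues listed in
    ``record.skip_positions`` are labelled ``skip`` and interrupt the cycle
    without advancing the phase.
    """
    n = record.rod_length
    if mode == "file":
        if register_path is None:
            raise ValueError("mode='file' requires register_path")
        df = pd.read_csv(
            register_path, sep="\t", comment="#", names=["residue_index", "label"],
            header=None, skipinitialspace=True,
        )
        # tolerate a header row
        if str(df.iloc[0, 0]).strip().lower() in {"residue_index", "index"}:
            df = df.iloc[1:]
        idx = df["residue_index"].astype(int).to_numpy()
        labels = df["label"].astype(str).str.strip().to_numpy()
        if len(idx) != n or idx[0] != record.rod_start or idx[-1] != record.rod_end:
            raise ValueError(
                f"register file covers residues {idx[0]}..{idx[-1]} "
                f"({len(idx)} rows) but rod interval is "
                f"{record.rod_start}..{record.rod_end} ({n} residues)"
            )
        return HeptadRegister(list(labels))
    if mode == "fallback":
        if phase not in HEPTAD_CYCLE:
            raise ValueError(f"phase must be one of {HEPTAD_CYCLE!r}, got {phase!r}")
        skips = set(record.skip_positions)
        out: list[str] = []
        k = HEPTAD_CYCLE.index(phase)
        for res in range(record.rod_start, record.rod_end + 1):
            if res in skips:
                out.append("skip")
            else:
                out.append(HEPTAD_CYCLE[k % 7])
                k += 1
        return HeptadRegister(out)
    raise ValueError(f"unknown register mode {mode!r}")


def suggest_register_phase(record: HeavyChainRecord) -> str:
    """Heuristic start phase for the fallback register.

    Scores each of the seven possible phases by how many hydrophobic residues
    land on the buried *a*/*d* positions and returns the best.  This is a
    convenience for sequences lacking an external register annotation, not a
    coiled-coil predictor; skip positions are honoured as in
    :func:`assign_register`.
    """
    best, best_score = "a", -1
    for phase in HEPTAD_CYCLE:
        reg = assign_register(record, mode="fallback", phase=phase)
        score = sum(
            aa in _CORE_HYDROPHOBIC
            for aa, lab in zip(record.rod_sequence, reg)
            if lab in ("a", "d")
        )
        if score > best_score:
            best, best_score = phase, score
    return best


def build_charge_chain(
    record: HeavyChainRecord, register: HeptadRegister
) -> ChargeChain:
    """Translate a rod sequence plus register into a :class:`ChargeChain`.

    One site per rod residue (skip residues included); Arg/Lys -> +2e,
    Asp/Glu -> -2e, all other residues 0; any residue at register position
    *a* or *d* is cancelled to 0 regardless of identity.
    """
    seq = record.rod_sequence
    if len(register) != len(seq):
        raise ValueError(
            f"register length {len(register)} != rod length {len(seq)}"
        )
    charges = np.zeros(len(seq))
    for i, (aa, lab) in enumerate(zip(seq, register)):
        if aa not in STANDARD_AA:
            raise ValueError(
                f"unknown residue code {aa!r} at residue {record.rod_start + i}"
            )
        q = RESIDUE_CHARGE_E.get(aa, 0)
        if lab in ("a", "d"):
            q = 0
        charges[i] = q
    return ChargeChain(record.id, charges)


def sliding_window_profile(chain: ChargeChain, window: int = 98) -> ChargeProfile:
    """Net charge summed over a sliding residue window along the rod.

    The default 98-residue window is half the 196-residue charge repeat and
    resolves the positive C-terminal tip and the five regions of increased
    net negativity of the NM2 rod.
    """
    if not (1 <= window <= chain.n_sites):
        raise ValueError(
            f"window {window} must be in [1, {chain.n_sites}] for this chain"
        )
    sums = np.convolve(chain.charges, np.ones(window), mode="valid")
    centers = (np.arange(sums.size) + (window - 1) / 2.0) * chain.spacing
    return ChargeProfile(window, centers, sums)
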