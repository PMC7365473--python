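"""Run configuration and the file-to-file pipeline behind the CLI.

A :class:`RunConfig` collects every tunable of the model (solvent and
screening parameters, worm-like-chain grid, kinetics settings, grids, input
sequences or the synthetic-rod spec) and round-trips through YAML.  Each
output file starts with ``# key = value`` provenance comments recording the
full parameter set that produced it.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import kinetics as kin
from .bending import WLCParams, energy_landscape
from .electrostatics import ElectrostaticParams, potential_field, stagger_scan_straight
from .rod_model import (
    ChargeChain,
    HeavyChainRecord,
    assign_register,
    build_charge_chain,
    read_fasta,
    sliding_window_profile,
)
from .synthetic import SyntheticRodSpec, make_periodic_rod, make_test_potential

logger = logging.getLogger("minifil")

COMMANDS = (
    "chain", "profile", "scan", "landscape",
    "contact-time", "matrix", "potential-field", "fixtures",
)


@dataclasses.dataclass
class SequenceEntry:
    """Per-record rod annotation: boundaries, register source, skips."""

    rod_start: int = 1
    rod_end: int | None = None
    phase: str = "a"
    skip_positions: list[int] = dataclasses.field(default_factory=list)
    register_file: str | None = None


@dataclasses.dataclass
class RunConfig:
    output_dir: str = "minifil_out"
    log_level: str = "INFO"
    orientation: str = "parallel"
    fasta: str | None = None
    records: dict[str, SequenceEntry] = dataclasses.field(default_factory=dict)
    electrostatics: ElectrostaticParams = dataclasses.field(
        default_factory=ElectrostaticParams
    )
    wlc: WLCParams = dataclasses.field(default_factory=WLCParams)
    synthetic: SyntheticRodSpec = dataclasses.field(default_factory=SyntheticRodSpec)
    x0: float = kin.DEFAULT_X0
    diffusion: float = 1.0
    window: int = 98
    s_step_nm: float | None = None
    lo_step_nm: float | None = None
    field_radius_nm: float = 2.0

    # -- serialisation ------------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["electrostatics"].pop("_cutoff_explicit", None)
        d["wlc"]["r_range"] = list(self.wlc.r_range)
        d["wlc"]["la_range"] = list(self.wlc.la_range)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        if "electrostatics" in d:
            e = dict(d["electrostatics"])
            d["electrostatics"] = ElectrostaticParams(
                **e, _cutoff_explicit="pair_cutoff" in e
            )
        if "wlc" in d:
            w = dict(d["wlc"])
            for key in ("r_range", "la_range"):
                if key in w:
                    w[key] = tuple(w[key])
            d["wlc"] = WLCParams(**w)
        if "synthetic" in d:
            d["synthetic"] = SyntheticRodSpec(**d["synthetic"])
        if "records" in d:
            d["records"] = {
                k: SequenceEntry(**v) if isinstance(v, dict) else v
                for k, v in d["records"].items()
            }
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    # -- provenance ---------------------------------------------------------
    def provenance_lines(self) -> list[str]:
        out = []
        for key, val in sorted(_flatten(self.to_dict()).items()):
            out.append(f"# {key} = {val}")
        return out


def _flatten(d: dict, prefix: str = "") -> dict[str, Any]:
    flat: dict[str, Any] = {}
    for k, v in d.items():
        key = f"{prefix}{k}"
        if isinstance(v, dict):
            flat.update(_flatten(v, key + "."))
        else:
            flat[key] = v
    return flat


def write_table(df, path: Path, config: RunConfig) -> None:
    """TSV with a provenance header recording the full configuration."""
    with open(path, "w") as fh:
        fh.write("\n".join(config.provenance_lines()) + "\n")
        df.to_csv(fh, sep="\t", index=False)


def load_chains(config: RunConfig) -> list[ChargeChain]:
    """Charge chains from the configured FASTA (or the synthetic rod)."""
    if config.fasta is None:
        return [make_periodic_rod(config.synthetic)]
    chains = []
    for record in read_fasta(config.fasta):
        entry = config.records.get(record.id, SequenceEntry())
        rec = HeavyChainRecord(
            record.id,
            record.residues,
            rod_start=entry.rod_start,
            rod_end=entry.rod_end or len(record.residues),
            skip_positions=list(entry.skip_positions),
        )
        if entry.register_file:
            reg = assign_register(rec, "file", register_path=entry.register_file)
        else:
            reg = assign_register(rec, "fallback", phase=entry.phase)
        chains.append(build_charge_chain(rec, reg))
    return chains


def run_pipeline(config: RunConfig, command: str) -> list[Path]:
    """Execute one pipeline command; returns the written output files."""
    if command not in COMMANDS:
        raise ValueError(f"unknown command {command!r}; choose from {COMMANDS}")
    logging.basicConfig(level=config.log_level)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    e, w = config.electrostatics, config.wlc
    written: list[Path] = []

    if command == "fixtures":
        import pandas as pd

        chain = make_periodic_rod(config.synthetic)
        path = out / "fixture_rod.tsv"
        write_table(
            pd.DataFrame(
                {
                    "site_index": np.arange(chain.n_sites),
                    "axial_position_nm": chain.axial_positions,
                    "charge_e": chain.charges,
                }
            ),
            path, config,
        )
        written.append(path)
        for kind in ("flat", "linear", "single_well"):
            pot = make_test_potential(kind)
            p = out / f"fixture_potential_{kind}.tsv"
            write_table(
                pd.DataFrame({"Lo_nm": pot.overlaps, "V_kBT": pot.energies}),
                p, config,
            )
            written.append(p)
        return written

    chains = load_chains(config)
    pair = (chains[0], chains[1] if len(chains) > 1 else chains[0])

    import pandas as pd

    if command == "chain":
        for chain in chains:
            path = out / f"chain_{chain.label}.tsv"
            write_table(
                pd.DataFrame(
                    {
                        "site_index": np.arange(chain.n_sites),
                        "axial_position_nm": chain.axial_positions,
                        "charge_e": chain.charges,
                    }
                ),
                path, config,
            )
            written.append(path)
    elif command == "profile":
        for chain in chains:
            prof = sliding_window_profile(chain, config.window)
            path = out / f"charge_profile_{chain.label}.tsv"
            write_table(
                pd.DataFrame(
                    {
                        "center_nm": prof.center_positions,
                        "windowed_charge_e": prof.windowed_charge,
                    }
                ),
                path, config,
            )
            written.append(path)
    elif command == "scan":
        scan = stagger_scan_straight(
            *pair, config.orientation, s_step=config.s_step_nm, params=e
        )
        path = out / f"scan_{config.orientation}.tsv"
        write_table(
            pd.DataFrame({"stagger_nm": scan.staggers, "energy_kBT": scan.energies}),
            path, config,
        )
        written.append(path)
    elif command == "landscape":
        s_grid = _stagger_grid(pair[0], config)
        land = energy_landscape(
            *pair, config.orientation, s_grid=s_grid, lo_step=config.lo_step_nm,
            e_params=e, wlc_params=w,
        )
        path = out / f"landscape_{config.orientation}.tsv"
        write_table(land.to_dataframe(), path, config)
        written.append(path)
    elif command == "contact-time":
        s_grid = _stagger_grid(pair[0], config)
        prof = kin.contact_time_profile(
            *pair, config.orientation, s_grid=s_grid, e_params=e, wlc_params=w,
            x0=config.x0, diffusion=config.diffusion, lo_step=config.lo_step_nm,
        )
        path = out / f"contact_time_{config.orientation}.tsv"
        write_table(prof.to_dataframe(), path, config)
        written.append(path)
    elif command == "matrix":
        s_grid = _stagger_grid(pair[0], config)
        mat = kin.heterodimer_matrix(
            chains, config.orientation, s_grid=s_grid, e_params=e, wlc_params=w,
            x0=config.x0, lo_step=config.lo_step_nm,
        )
        path = out / f"matrix_{config.orientation}.tsv"
        write_table(mat.summary(), path, config)
        written.append(path)
    elif command == "potential-field":
        for chain in chains:
            z = np.arange(-5.0, chain.rod_length + 5.0, 0.25)
            field = potential_field(chain, config.field_radius_nm, z, e)
            path = out / f"potential_field_{chain.label}.tsv"
            write_table(
                pd.DataFrame({"z_nm": field.z, "phi_kBT_per_e": field.phi}),
                path, config,
            )
            written.append(path)
    return written


def _stagger_grid(chain: ChargeChain, config: RunConfig) -> np.ndarray | None:
    if config.s_step_nm is None:
        return None
    step_sites = max(1, int(round(config.s_step_nm / chain.spacing)))
    return np.arange(0, chain.n_sites, step_sites) * chain.spacing
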