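"""File formats and run configuration.

Systems travel as standard multi-model PDB files (MODEL/ENDMDL blocks are
snapshot frames) paired with a per-atom parameter TSV matched by serial
number; matrices and series are CSV; reports are JSON.  Coordinates are in
Angstrom, energies in kcal/mol, charges in elementary charges; residue
numbering is taken from the PDB unchanged.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import biotite.structure as struc
import biotite.structure.io.pdb as pdb
import numpy as np
import pandas as pd
import yaml

from .ensemble import Ensemble
from .ff_energy import AtomRecord, MolecularSystem, SelectionError, SolventModelParams

logger = logging.getLogger("bindmode")

PARAM_COLUMNS = [
    "serial", "charge", "lj_rmin_half", "lj_epsilon", "gb_radius",
    "gb_screen", "sasa_radius", "p1", "p2", "p3", "p4",
]


@dataclass
class RunConfig:
    """Thresholds, solvent settings and bookkeeping for a pipeline run."""

    hotspot_threshold: float = 0.5
    differential_threshold: float = 0.5
    pocket_cutoff: float = 5.0
    matrix_eps: float = 0.005
    sensitivity_fold: float = 5.0
    temperature: float = 298.15
    cluster_k: int = 4
    icosa_depth: int = 3
    seed: int = 0
    solvent: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("hotspot_threshold", "differential_threshold",
                     "pocket_cutoff", "matrix_eps", "sensitivity_fold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def solvent_params(self) -> SolventModelParams:
        return SolventModelParams(temperature=self.temperature, **self.solvent)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**(yaml.safe_load(Path(path).read_text()) or {}))


# ---------------------------------------------------------------------------
# PDB + parameter table
# ---------------------------------------------------------------------------


def read_system(
    pdb_path: str | Path,
    param_path: str | Path,
    ligand_spec: str,
) -> tuple[MolecularSystem, Ensemble]:
    """Read a multi-model PDB and its parameter TSV into a system + ensemble.

    ``ligand_spec`` is either a chain identifier (``chain:X``) or a residue
    name; matching atoms form the ligand segment.  Parameter rows are matched
    to atoms by serial number, and any unmatched serial is a hard error.
    """
    pdb_file = pdb.PDBFile.read(str(pdb_path))
    stack = pdb_file.get_structure(model=None, extra_fields=["atom_id", "charge"])
    params = pd.read_csv(param_path, sep="\t")
    missing_cols = set(PARAM_COLUMNS) - set(params.columns)
    if missing_cols:
        raise SelectionError(f"parameter table missing columns {sorted(missing_cols)}")
    by_serial = params.set_index("serial")
    if by_serial.index.has_duplicates:
        raise SelectionError("duplicate serials in parameter table")

    if ligand_spec.startswith("chain:"):
        is_ligand = stack.chain_id == ligand_spec.split(":", 1)[1]
    else:
        is_ligand = stack.res_name == ligand_spec
    if not is_ligand.any() or is_ligand.all():
        raise SelectionError(f"ligand spec {ligand_spec!r} selects 0 or all atoms")

    serials = stack.atom_id
    unmatched = sorted(set(serials.tolist()) - set(by_serial.index.tolist()))
    if unmatched:
        raise SelectionError(f"no parameters for serials {unmatched}")

    coords0 = stack.coord[0]
    atoms = []
    ligand_label = "LIG"
    for i in range(stack.array_length()):
        row = by_serial.loc[int(serials[i])]
        segment = "ligand" if is_ligand[i] else "receptor"
        if segment == "ligand":
            ligand_label = str(stack.res_name[i])
        atoms.append(
            AtomRecord(
                serial=int(serials[i]),
                name=str(stack.atom_name[i]),
                residue_index=int(stack.res_id[i]),
                residue_name=str(stack.res_name[i]),
                segment=segment,
                coords=tuple(float(v) for v in coords0[i]),
                charge=float(row["charge"]),
                lj_rmin_half=float(row["lj_rmin_half"]),
                lj_epsilon=float(row["lj_epsilon"]),
                gb_radius=float(row["gb_radius"]),
                gb_screen=float(row["gb_screen"]),
                sasa_radius=float(row["sasa_radius"]),
                lcpo_p=(float(row["p1"]), float(row["p2"]),
                        float(row["p3"]), float(row["p4"])),
            )
        )
    system = MolecularSystem(atoms, ligand_label=ligand_label)
    return system, Ensemble(system=system, frames=np.asarray(stack.coord))


def write_system(
    system: MolecularSystem,
    frames: np.ndarray,
    pdb_path: str | Path,
    param_path: str | Path,
) -> None:
    """Write a system to a multi-model PDB plus its parameter TSV."""
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    n = system.n_atoms
    arr = struc.AtomArray(n)
    arr.coord = frames[0]
    arr.chain_id = np.array(
        ["L" if a.segment == "ligand" else "A" for a in system.atoms]
    )
    arr.res_id = np.array([a.residue_index for a in system.atoms])
    arr.res_name = np.array([a.residue_name for a in system.atoms])
    arr.atom_name = np.array([a.name for a in system.atoms])
    arr.element = np.array(
        [a.name.lstrip("0123456789")[:1].upper() for a in system.atoms]
    )
    arr.set_annotation("atom_id", np.array([a.serial for a in system.atoms]))
    arr.hetero = np.array([a.segment == "ligand" for a in system.atoms])

    stack = struc.stack([arr] * len(frames))
    stack.coord = frames
    out = pdb.PDBFile()
    out.set_structure(stack)
    out.write(str(pdb_path))

    table = pd.DataFrame(
        [
            {
                "serial": a.serial,
                "charge": a.charge,
                "lj_rmin_half": a.lj_rmin_half,
                "lj_epsilon": a.lj_epsilon,
                "gb_radius": a.gb_radius,
                "gb_screen": a.gb_screen,
                "sasa_radius": a.sasa_radius,
                "p1": a.lcpo_p[0],
                "p2": a.lcpo_p[1],
                "p3": a.lcpo_p[2],
                "p4": a.lcpo_p[3],
            }
            for a in system.atoms
        ],
        columns=PARAM_COLUMNS,
    )
    table.to_csv(param_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------


def write_series_csv(series, path: str | Path) -> None:
    """Per-frame scalar series as a two-column CSV (frame, value)."""
    pd.DataFrame(
        {"frame": np.arange(len(series.values)), "value": series.values}
    ).to_csv(path, index=False)


def write_report(results: dict, out_dir: str | Path, config: RunConfig | None = None) -> dict:
    """Write a results bundle to ``out_dir``; returns {name: written path}.

    Recognized keys: ``energy_stats`` ({ligand: EnergyStats}) -> two-decimal
    "mean ± sem" CSV; ``profile`` (ResidueProfile) -> per-residue CSV;
    ``matrix`` (DataFrame) -> CSV with residue labels in the first column;
    ``newick`` (str); ``report`` (JSON-serializable dict).  The run config and
    seed are echoed alongside for reproducibility.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    if "energy_stats" in results:
        rows = [
            {
                "ligand": lig,
                "dg_mmgbsa": st.format_total(),
                "e_vdw": round(st.mean.e_vdw, 2),
                "e_ele": round(st.mean.e_ele, 2),
                "g_pol": round(st.mean.g_pol, 2),
                "g_nonpol": round(st.mean.g_nonpol, 2),
                "n_frames": st.n_frames,
            }
            for lig, st in results["energy_stats"].items()
        ]
        path = out / "energies.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        written["energy_stats"] = path

    if "profile" in results:
        profile = results["profile"]
        rows = [
            {"residue": f"{profile.residue_names.get(idx, 'RES')}{idx}",
             **eb.as_dict()}
            for idx, eb in profile
        ]
        path = out / "per_residue.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        written["profile"] = path

    if "matrix" in results:
        path = out / "matrix.csv"
        results["matrix"].to_csv(path, index_label="residue")
        written["matrix"] = path

    if "newick" in results:
        path = out / "tree.nwk"
        path.write_text(results["newick"] + "\n")
        written["newick"] = path

    if "report" in results:
        path = out / "report.json"
        path.write_text(json.dumps(results["report"], indent=2, sort_keys=True))
        written["report"] = path

    if config is not None:
        config.to_yaml(out / "config.yaml")
        written["config"] = out / "config.yaml"
        logger.info("report written to %s with seed %d", out, config.seed)
    return written
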