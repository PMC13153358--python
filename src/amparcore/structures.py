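"""Atomic-model I/O and subunit bookkeeping for tetrameric AMPA-receptor cores.

The tetramer has four non-equivalent subunit positions named A, B, C, D.
In the GluA1/A2 di-heteromer, GluA1 occupies the A/C positions and GluA2
the B/D positions.  All geometric measurements downstream address atoms by
(chain, author residue number, atom name); this module owns that resolution
step, including per-chain numbering offsets for models whose deposited
numbering differs from mature-protein numbering.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, NamedTuple, Sequence

import numpy as np
import yaml
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile
import biotite.structure.io.pdbx as pdbx

__all__ = [
    "AtomRecord",
    "StructureModel",
    "SubunitMap",
    "StructureError",
    "read_structure",
    "write_structure",
    "select_calpha",
    "apply_subunit_map",
    "load_subunit_config",
    "default_glua1a2_config",
]

_WATER_NAMES = {"HOH", "WAT", "TIP3", "TIP", "SOL", "H2O", "DOD"}


class StructureError(ValueError):
    """Raised for unreadable files, empty models, or unresolvable selections."""


class AtomRecord(NamedTuple):
    chain_id: str
    residue_number: int
    residue_name: str
    atom_name: str
    element: str
    position: np.ndarray  # (3,) Angstrom
    is_hetero: bool = False
    is_water: bool = False


def _infer_element(atom_name: str) -> str:
    """Element from the leading alphabetic characters of the atom name.

    PDB columns occasionally omit the element; a leading character guess
    covers C/N/O/S/P/H plus two-letter cases that matter for vdW radii.
    """
    name = atom_name.strip().lstrip("0123456789")
    if not name:
        raise StructureError(f"cannot infer element from atom name {atom_name!r}")
    two = name[:2].upper()
    if two in {"CL", "BR", "FE", "ZN", "MG", "MN", "NA", "CA"} and len(name) > 1:
        # Only accept a two-letter element when it is not a standard
        # protein-atom name (CA alpha-carbon, CB, ND1, ...).
        if two == "CA" and atom_name.strip() == "CA":
            return "C"
        if two in {"CL", "BR", "FE", "ZN", "MG", "MN"}:
            return two.capitalize()
        if two == "NA" and atom_name.strip() == "NA":
            return "Na"
    return name[0].upper()


@dataclass
class StructureModel:
    """A single-conformer atomic model backed by a biotite ``AtomArray``."""

    atoms: struc.AtomArray
    label: str = ""

    def __post_init__(self) -> None:
        if self.atoms.array_length() == 0:
            raise StructureError(f"model {self.label!r} contains zero atoms")
        elem = self.atoms.element
        missing = (elem == "") | (elem == " ")
        if np.any(missing):
            inferred = [
                _infer_element(n) for n in self.atoms.atom_name[missing]
            ]
            elem = elem.copy()
            elem[missing] = inferred
            self.atoms.element = elem
        if not np.all(np.isfinite(self.atoms.coord)):
            raise StructureError(f"model {self.label!r} has non-finite coordinates")
        keys = list(
            zip(self.atoms.chain_id, self.atoms.res_id, self.atoms.atom_name)
        )
        if len(set(keys)) != len(keys):
            seen, dups = set(), set()
            for k in keys:
                if k in seen:
                    dups.add(k)
                seen.add(k)
            raise StructureError(
                f"duplicate (chain, residue, atom) triples in {self.label!r}: "
                f"{sorted(dups)[:5]}"
            )

    # -- basic introspection -------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return self.atoms.array_length()

    def chains(self) -> list[str]:
        return sorted(set(self.atoms.chain_id))

    def n_residues(self) -> int:
        return len(set(zip(self.atoms.chain_id, self.atoms.res_id)))

    def records(self) -> Iterator[AtomRecord]:
        a = self.atoms
        for i in range(a.array_length()):
            res = str(a.res_name[i])
            yield AtomRecord(
                chain_id=str(a.chain_id[i]),
                residue_number=int(a.res_id[i]),
                residue_name=res,
                atom_name=str(a.atom_name[i]),
                element=str(a.element[i]),
                position=a.coord[i].copy(),
                is_hetero=bool(a.hetero[i]),
                is_water=res in _WATER_NAMES,
            )

    def subset(self, mask: np.ndarray, label: str | None = None) -> "StructureModel":
        return StructureModel(self.atoms[mask], label or self.label)

    @classmethod
    def from_records(
        cls, records: Sequence[AtomRecord], label: str = ""
    ) -> "StructureModel":
        arr = struc.AtomArray(len(records))
        arr.coord = np.array([r.position for r in records], dtype=float)
        arr.chain_id = np.array([r.chain_id for r in records])
        arr.res_id = np.array([r.residue_number for r in records])
        arr.res_name = np.array([r.residue_name for r in records])
        arr.atom_name = np.array([r.atom_name for r in records])
        arr.element = np.array([r.element for r in records])
        arr.hetero = np.array([r.is_hetero for r in records])
        return cls(arr, label)


def read_structure(
    path: str | Path, format: str | None = None, model: int | None = 1
) -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    ``model=1`` (default) keeps model 1 of multi-model files, matching
    single-conformation cryo-EM use; trajectory readers request all models
    themselves.  Altloc handling keeps the first conformer.  Waters and
    ligands are retained and flagged by residue name.
    """
    path = Path(path)
    if not path.exists():
        raise StructureError(f"file not found: {path}")
    fmt = format or (
        "mmcif" if path.suffix.lower() in {".cif", ".mmcif"} else "pdb"
    )
    try:
        if fmt.lower() in {"mmcif", "cif", "pdbx"}:
            cif = pdbx.CIFFile.read(str(path))
            atoms = pdbx.get_structure(cif, model=model, altloc="first")
        elif fmt.lower() == "pdb":
            pdb = PDBFile.read(str(path))
            atoms = pdb.get_structure(model=model, altloc="first")
        else:
            raise StructureError(f"unknown structure format {format!r}")
    except StructureError:
        raise
    except Exception as exc:  # biotite raises various parse errors
        raise StructureError(f"could not parse {path} as {fmt}: {exc}") from exc
    if atoms.array_length() == 0:
        raise StructureError(f"{path} parsed to an empty model")
    return StructureModel(atoms, label=path.stem)


def write_structure(model: StructureModel, path: str | Path) -> Path:
    """Write to PDB or mmCIF, chosen by file suffix."""
    path = Path(path)
    if path.suffix.lower() in {".cif", ".mmcif"}:
        cif = pdbx.CIFFile()
        pdbx.set_structure(cif, model.atoms)
        cif.write(str(path))
    else:
        pdb = PDBFile()
        pdb.set_structure(model.atoms)
        pdb.write(str(path))
    return path


def select_calpha(
    model: StructureModel, chain: str, residues: Sequence[int]
) -> np.ndarray:
    """Cα coordinates for the requested residues, in request order.

    Raises :class:`StructureError` listing every residue that is absent or
    lacks a CA atom.
    """
    a = model.atoms
    mask = (a.chain_id == chain) & (a.atom_name == "CA")
    res_ids = a.res_id[mask]
    coords = a.coord[mask]
    index = {int(r): i for i, r in enumerate(res_ids)}
    missing = [r for r in residues if int(r) not in index]
    if missing:
        raise StructureError(
            f"chain {chain!r} of {model.label!r}: no CA atom for residues {missing}"
        )
    return np.array([coords[index[int(r)]] for r in residues], dtype=float)


# -- subunit mapping ---------------------------------------------------------


def _expand_ranges(ranges: Sequence[Sequence[int]]) -> list[int]:
    out: list[int] = []
    for lo, hi in ranges:
        if hi < lo:
            raise StructureError(f"invalid residue range ({lo}, {hi})")
        out.extend(range(int(lo), int(hi) + 1))
    return out


@dataclass
class SubunitMap:
    """Position → chain assignment plus lobe and gate-residue definitions.

    ``lobes`` maps subunit identity (e.g. ``GluA1``) to a dict with keys
    ``lbd``, ``d1``, ``d2``, each a list of inclusive residue ranges in
    mature-protein numbering.  ``landmarks`` holds the per-identity D1/D2
    marker residues used for lobe-separation distances.  ``offsets`` shifts
    mature numbering to the model's author numbering per chain.
    """

    positions: dict[str, str]                     # position -> chain_id
    identities: dict[str, str]                    # position -> subunit identity
    lobes: dict[str, dict[str, list[list[int]]]]  # identity -> lobe ranges
    gate_residues: dict[str, dict[str, int]]      # identity -> label -> resid
    landmarks: dict[str, dict[str, int]] = field(default_factory=dict)
    offsets: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        pos = set(self.positions)
        if pos != {"A", "B", "C", "D"}:
            raise StructureError(f"positions must be A, B, C, D; got {sorted(pos)}")
        if len(set(self.positions.values())) != 4:
            raise StructureError("the four positions must map to distinct chains")
        if self.identities["A"] != self.identities["C"] or (
            self.identities["B"] != self.identities["D"]
        ):
            raise StructureError(
                "di-heteromer identities must agree across A/C and across B/D"
            )

    def chain(self, position: str) -> str:
        return self.positions[position]

    def identity(self, position: str) -> str:
        return self.identities[position]

    def offset(self, position: str) -> int:
        return self.offsets.get(self.positions[position], 0)

    def lobe_residues(self, position: str, lobe: str) -> list[int]:
        """Author-numbered residues of a lobe (``lbd``/``d1``/``d2``) at a position."""
        ident = self.identities[position]
        ranges = self.lobes[ident][lobe]
        off = self.offset(position)
        return [r + off for r in _expand_ranges(ranges)]

    def gate_residue(self, position: str, label: str) -> int:
        ident = self.identities[position]
        return self.gate_residues[ident][label] + self.offset(position)

    def landmark(self, position: str, lobe: str) -> int:
        ident = self.identities[position]
        return self.landmarks[ident][lobe] + self.offset(position)


def load_subunit_config(source: str | Path | dict) -> SubunitMap:
    """Build a :class:`SubunitMap` from a YAML file or an equivalent dict."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            cfg = yaml.safe_load(fh)
    else:
        cfg = dict(source)
    return SubunitMap(
        positions=dict(cfg["positions"]),
        identities=dict(cfg["identities"]),
        lobes={k: dict(v) for k, v in cfg["lobes"].items()},
        gate_residues={k: dict(v) for k, v in cfg["gate_residues"].items()},
        landmarks={k: dict(v) for k, v in cfg.get("landmarks", {}).items()},
        offsets=dict(cfg.get("offsets", {})),
    )


def default_glua1a2_config() -> SubunitMap:
    """The packaged GluA1/A2 convention: GluA1 at A/C, GluA2 at B/D."""
    ref = importlib.resources.files("amparcore") / "data" / "glua1a2.yaml"
    with importlib.resources.as_file(ref) as p:
        return load_subunit_config(p)


def apply_subunit_map(model: StructureModel, config: SubunitMap | dict) -> SubunitMap:
    """Validate a subunit map against a model.

    Checks that every mapped chain exists and that every lobe range resolves
    to at least 3 Cα atoms (the minimum any superposition downstream needs).
    Returns the validated map; raises :class:`StructureError` naming all
    problems otherwise.
    """
    smap = config if isinstance(config, SubunitMap) else load_subunit_config(config)
    chains = set(model.chains())
    problems: list[str] = []
    for pos, ch in smap.positions.items():
        if ch not in chains:
            problems.append(f"position {pos}: chain {ch!r} absent from model")
    if problems:
        raise StructureError("; ".join(problems))
    a = model.atoms
    for pos in "ABCD":
        ch = smap.chain(pos)
        present = set(
            int(r) for r in a.res_id[(a.chain_id == ch) & (a.atom_name == "CA")]
        )
        for lobe in ("lbd", "d1", "d2"):
            wanted = smap.lobe_residues(pos, lobe)
            hits = [r for r in wanted if r in present]
            if len(hits) < 3:
                rng = smap.lobes[smap.identity(pos)][lobe]
                problems.append(
                    f"position {pos} (chain {ch}): lobe {lobe!r} ranges {rng} "
                    f"resolve to {len(hits)} CA atoms"
                )
    if problems:
        raise StructureError("; ".join(problems))
    return smap
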