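"""Multi-model structure parsing and interface-region extraction.

An NMR-derived complex is deposited as an ensemble of alternative coordinate
models.  This module loads such ensembles (PDB or mmCIF, via gemmi), measures
minimum heavy-atom distances between a query chain (the E2) and a partner
chain (the E3), and aggregates "within cutoff" calls over the ensemble into
contiguous interface regions.

Conventions
-----------
* Author residue numbering is preserved everywhere; nothing is renumbered.
* Alternate locations are resolved to the first conformer.
* Hydrogens are kept in the data model but excluded from distance
  measurements unless explicitly requested (heavy-atom distances are the
  conventional reading of a "within 6 Å" criterion on NMR models, which
  contain hydrogens).
* A distance exactly equal to the cutoff counts as inside (``<=``).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import gemmi
import numpy as np
from scipy.spatial import cKDTree

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

STANDARD_RESIDUES = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


@dataclass(frozen=True)
class Atom:
    """A single atom with its label, element and position (Å)."""

    name: str
    element: str
    coords: tuple[float, float, float]
    is_hydrogen: bool
    is_sidechain: bool

    def __post_init__(self):
        if not self.element:
            raise ValueError("element must be nonempty")
        if not all(math.isfinite(c) for c in self.coords):
            raise ValueError(f"non-finite coordinates for atom {self.name}")


@dataclass
class Residue:
    """One residue of one model; key is (chain_id, seq_number, insertion_code)."""

    chain_id: str
    seq_number: int
    insertion_code: str
    name: str
    atoms: list[Atom]

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_number, self.insertion_code)

    @property
    def is_standard(self) -> bool:
        return self.name in STANDARD_RESIDUES

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def coord_array(self, include_hydrogens: bool = False) -> np.ndarray:
        atoms = self.atoms if include_hydrogens else self.heavy_atoms()
        if not atoms:
            return np.empty((0, 3))
        return np.array([a.coords for a in atoms], dtype=float)


Model = list[Residue]


@dataclass
class StructureEnsemble:
    """An ordered set of models of the same complex (e.g. an NMR ensemble)."""

    models: list[Model]
    source_id: str = ""

    def __post_init__(self):
        if not self.models:
            raise ValueError("ensemble must contain at least one model")
        ref = {(r.chain_id, r.seq_number, r.insertion_code, r.name) for r in self.models[0]}
        for i, model in enumerate(self.models[1:], start=2):
            got = {(r.chain_id, r.seq_number, r.insertion_code, r.name) for r in model}
            if got != ref:
                raise ValueError(
                    f"model {i} residue set differs from model 1 "
                    f"(e.g. {sorted(got ^ ref)[:3]})"
                )

    @property
    def n_models(self) -> int:
        return len(self.models)

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.models[0]:
            seen.setdefault(r.chain_id, None)
        return list(seen)

    def chain_residues(self, model_index: int, chain_id: str) -> list[Residue]:
        res = [r for r in self.models[model_index] if r.chain_id == chain_id]
        res.sort(key=lambda r: (r.seq_number, r.insertion_code))
        return res

    def sequence(self, chain_id: str) -> str:
        """One-letter sequence of a chain (model 1, standard residues as letters)."""
        return "".join(
            THREE_TO_ONE.get(r.name, "X") for r in self.chain_residues(0, chain_id)
        )


@dataclass
class InterfaceRegion:
    """A contiguous run of interface residues on the query chain."""

    chain_id: str
    start: int
    end: int
    members: list[int]
    support: dict[int, int] = field(default_factory=dict)

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError("region start must be <= end")
        if self.members != sorted(self.members):
            raise ValueError("members must be sorted")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


# ---------------------------------------------------------------------------
# Parsing / serialization
# ---------------------------------------------------------------------------

def _atom_from_gemmi(atom: gemmi.Atom) -> Atom:
    name = atom.name.strip()
    return Atom(
        name=name,
        element=atom.element.name,
        coords=(atom.pos.x, atom.pos.y, atom.pos.z),
        is_hydrogen=atom.is_hydrogen(),
        is_sidechain=name not in BACKBONE_ATOMS,
    )


def load_ensemble(
    path: str | Path,
    format: Literal["pdb", "mmcif", "auto"] = "auto",
    source_id: str | None = None,
) -> StructureEnsemble:
    """Load a (possibly multi-model) structure into a :class:`StructureEnsemble`.

    PDB files without MODEL/ENDMDL records yield a single-model ensemble.
    Alternate locations are resolved to the first conformer; hydrogens are
    retained and flagged.  Non-standard residues are carried through with a
    warning (they are excluded later from alanine scanning).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "auto":
        fmt = gemmi.CoorFormat.Detect
    elif format == "pdb":
        fmt = gemmi.CoorFormat.Pdb
    elif format == "mmcif":
        fmt = gemmi.CoorFormat.Mmcif
    else:
        raise ValueError(f"unknown format {format!r}")
    st = gemmi.read_structure(str(path), format=fmt)
    st.remove_alternative_conformations()  # keep first altloc only
    models: list[Model] = []
    nonstandard: set[str] = set()
    for gm in st:
        model: Model = []
        for chain in gm:
            for gres in chain:
                res = Residue(
                    chain_id=chain.name,
                    seq_number=gres.seqid.num,
                    insertion_code=(gres.seqid.icode or " ").strip(),
                    name=gres.name,
                    atoms=[_atom_from_gemmi(a) for a in gres],
                )
                if not res.is_standard:
                    nonstandard.add(res.name)
                model.append(res)
        models.append(model)
    if not models or all(len(m) == 0 for m in models):
        raise ValueError(f"empty structure: {path}")
    if nonstandard:
        warnings.warn(
            f"non-standard residues carried through: {sorted(nonstandard)}",
            stacklevel=2,
        )
    return StructureEnsemble(models=models, source_id=source_id or path.stem)


def write_ensemble(ensemble: StructureEnsemble, path: str | Path) -> None:
    """Serialize an ensemble back to a multi-MODEL PDB file (via gemmi)."""
    st = gemmi.Structure()
    st.name = ensemble.source_id or "ensemble"
    for mi, model in enumerate(ensemble.models, start=1):
        gm = gemmi.Model(mi)
        chains: dict[str, gemmi.Chain] = {}
        for res in model:
            ch = chains.get(res.chain_id)
            if ch is None:
                ch = gemmi.Chain(res.chain_id)
                chains[res.chain_id] = ch
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.seq_number, res.insertion_code or " ")
            for a in res.atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element)
                ga.pos = gemmi.Position(*a.coords)
                gres.add_atom(ga)
            ch.add_residue(gres)
        for ch in chains.values():
            gm.add_chain(ch)
        st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# Distances and interface calls
# ---------------------------------------------------------------------------

def _chain_coords(model: Model, chain_id: str, include_hydrogens: bool) -> np.ndarray:
    arrays = [
        r.coord_array(include_hydrogens)
        for r in model
        if r.chain_id == chain_id
    ]
    arrays = [a for a in arrays if len(a)]
    if not arrays:
        return np.empty((0, 3))
    return np.vstack(arrays)


def min_interchain_distance(
    model: Model,
    residue: Residue,
    partner_chain: str,
    include_hydrogens: bool = False,
) -> float:
    """Minimum Euclidean distance from any atom of *residue* to any atom of
    *partner_chain*, under the hydrogen policy.  ``inf`` if the partner chain
    has no atoms."""
    if not any(r.key == residue.key for r in model):
        raise ValueError(f"residue {residue.key} not found in model")
    q = residue.coord_array(include_hydrogens)
    p = _chain_coords(model, partner_chain, include_hydrogens)
    if len(p) == 0 or len(q) == 0:
        return float("inf")
    d = np.linalg.norm(q[:, None, :] - p[None, :, :], axis=-1)
    return float(d.min())


Aggregation = Literal["any_model", "all_models"] | tuple[str, int]


def _required_count(aggregation: Aggregation, n_models: int) -> int:
    if aggregation == "any_model":
        return 1
    if aggregation == "all_models":
        return n_models
    if (
        isinstance(aggregation, tuple)
        and len(aggregation) == 2
        and aggregation[0] == "min_count"
    ):
        k = int(aggregation[1])
        if not 1 <= k <= n_models:
            raise ValueError(f"min_count {k} outside 1..{n_models}")
        return k
    raise ValueError(f"unknown aggregation rule: {aggregation!r}")


def interface_residues(
    ensemble: StructureEnsemble,
    query_chain: str,
    partner_chain: str,
    cutoff_angstrom: float = 6.0,
    aggregation: Aggregation = "any_model",
    include_hydrogens: bool = False,
) -> dict[int, int]:
    """Residue numbers of *query_chain* within ``cutoff`` of *partner_chain*.

    Returns ``{seq_number: support}`` where support counts the models in which
    the residue met the cutoff; only residues meeting the aggregation rule are
    included.  The boundary is inclusive (distance == cutoff counts).
    """
    chains = ensemble.chains()
    for c in (query_chain, partner_chain):
        if c not in chains:
            raise ValueError(f"chain {c!r} not present (have {chains})")
    support: dict[int, int] = {}
    for mi, model in enumerate(ensemble.models):
        partner = _chain_coords(model, partner_chain, include_hydrogens)
        if len(partner) == 0:
            raise ValueError(f"partner chain {partner_chain!r} empty in model {mi + 1}")
        tree = cKDTree(partner)
        for res in ensemble.chain_residues(mi, query_chain):
            q = res.coord_array(include_hydrogens)
            if len(q) == 0:
                continue
            dmin = float(np.min(tree.query(q)[0]))
            if dmin <= cutoff_angstrom:
                support[res.seq_number] = support.get(res.seq_number, 0) + 1
    need = _required_count(aggregation, ensemble.n_models)
    return {num: cnt for num, cnt in sorted(support.items()) if cnt >= need}


def merge_regions(
    residue_numbers: Iterable[int],
    max_gap: int = 3,
    chain_id: str = "",
    support: Mapping[int, int] | None = None,
) -> list[InterfaceRegion]:
    """Merge sorted residue numbers into maximal runs, closing gaps of at most
    ``max_gap`` missing positions.  Empty input yields an empty list."""
    numbers = sorted(set(int(n) for n in residue_numbers))
    if not numbers:
        return []
    support = dict(support or {})
    regions: list[InterfaceRegion] = []
    run = [numbers[0]]
    for n in numbers[1:]:
        if n - run[-1] - 1 <= max_gap:
            run.append(n)
        else:
            regions.append(_make_region(chain_id, run, support))
            run = [n]
    regions.append(_make_region(chain_id, run, support))
    return regions


def _make_region(chain_id: str, run: list[int], support: Mapping[int, int]) -> InterfaceRegion:
    return InterfaceRegion(
        chain_id=chain_id,
        start=run[0],
        end=run[-1],
        members=list(run),
        support={n: support[n] for n in run if n in support},
    )


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def regions_to_tsv(regions: Sequence[InterfaceRegion], path: str | Path) -> None:
    lines = ["chain\tstart\tend\tlength\tresidues\tsupport"]
    for reg in regions:
        residues = ",".join(str(m) for m in reg.members)
        supp = ",".join(str(reg.support.get(m, 0)) for m in reg.members)
        lines.append(f"{reg.chain_id}\t{reg.start}\t{reg.end}\t{reg.length}\t{residues}\t{supp}")
    Path(path).write_text("\n".join(lines) + "\n")


def run_metadata_json(
    path: str | Path,
    *,
    cutoff: float,
    aggregation: Aggregation,
    max_gap: int,
    include_hydrogens: bool,
    source_id: str,
    n_models: int,
    regions: Sequence[InterfaceRegion],
) -> None:
    agg = aggregation if isinstance(aggregation, str) else f"min_count:{aggregation[1]}"
    payload = {
        "source_id": source_id,
        "n_models": n_models,
        "cutoff_angstrom": cutoff,
        "aggregation": agg,
        "max_gap": max_gap,
        "include_hydrogens": include_hydrogens,
        "regions": [
            {
                "chain": r.chain_id,
                "start": r.start,
                "end": r.end,
                "members": r.members,
                "support": {str(k): v for k, v in r.support.items()},
            }
            for r in regions
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
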