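"""Seeded generators for every input the pipeline consumes, with ground truth.

Three generators mirror the three data modalities:

* :func:`simulate_complex` — a toy two-chain multi-model "NMR ensemble" with
  planted inter-chain contacts of known class in known model subsets, written
  as a multi-MODEL PDB file.
* :func:`simulate_family` — an E2-like aligned sequence family with a planted
  degenerate motif in the high-activity group and controlled near-duplicate
  pairs, written as aligned FASTA plus a labels TSV.
* :func:`simulate_image_pair` — a two-channel image pair with a known
  supra-threshold overlap fraction, written as TIFFs plus an ROI mask.

Every generator records a :class:`SyntheticTruth` (full parameters including
the seed, plus the planted ground truth) so tests consume truth only through
that record.  The same (kind, parameters, seed) regenerates byte-identical
files; the pseudo-random stream is numpy's PCG64, noted in the truth record.

Toy geometry
------------
Synthetic residues use real amino-acid atom names and elements on an
idealized linear side-chain scaffold: CA atoms lie on the x axis 5.0 Å
apart, side chains extend along +/-y with 1.3 Å steps and small z offsets at
branches.  The spacing is wider than a real peptide so that the guarantee
"every non-planted residue is > 8 Å from the partner chain" is satisfiable
with short side chains; contact *classification* (which only sees atom
names, elements and distances) is unaffected.

This module also builds the packaged stand-ins for the two external
reference inputs the published procedure used (an E2-E3 NMR ensemble and a
labelled E2 alignment).  Both are SYNTHETIC stand-ins constructed to carry
the published ground truth (three interface regions M1-K9 / E60-P65 /
L87-Q103, strongest contacts at R5/F63/P97, and a high-group [D/E]xP[F/Y]KP
motif at reference span 60-65); only the UBE2L3 reference sequence itself is
the real protein sequence.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .structure import (
    Atom,
    ONE_TO_THREE,
    Residue,
    StructureEnsemble,
    write_ensemble,
)

# ---------------------------------------------------------------------------
# Truth record
# ---------------------------------------------------------------------------


@dataclass
class SyntheticTruth:
    """Machine-readable ground truth written alongside every generated input."""

    kind: str  # ensemble | family | image
    parameters: dict
    truth: dict

    def to_json(self, path: str | Path) -> None:
        payload = {
            "kind": self.kind,
            "parameters": self.parameters,
            "truth": self.truth,
            "rng": "numpy-PCG64",
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        d = json.loads(Path(path).read_text())
        return cls(kind=d["kind"], parameters=d["parameters"], truth=d["truth"])


# ---------------------------------------------------------------------------
# Idealized side-chain templates: name -> [(atom, element, level, z_offset)]
# level k sits 1.53 + 1.3*(k-1) Å from CA along the side-chain direction.
# ---------------------------------------------------------------------------

SIDECHAIN_TEMPLATES: dict[str, list[tuple[str, str, int, float]]] = {
    "ALA": [("CB", "C", 1, 0.0)],
    "ARG": [("CB", "C", 1, 0.0), ("CG", "C", 2, 0.0), ("CD", "C", 3, 0.0),
            ("NE", "N", 4, 0.0), ("CZ", "C", 5, 0.0),
            ("NH1", "N", 6, 0.7), ("NH2", "N", 6, -0.7)],
    "ASN": [("CB", "C", 1, 0.0), ("CG", "C", 2, 0.0),
            ("OD1", "O", 3, 0.7), ("ND2", "N", 3, -0.7)],
    "ASP": [("CB", "C", 1, 0.0), ("CG", "C", 2, 0.0),
            ("OD1", "O", 3, 1.5), ("OD2", "O", 3, -1.5)],
    "CYS": [("CB", "C", 1, 0.0), ("SG", "S", 2, 0.0)],
    "GLN": [("CB", "C", 1, 0.0), ("CG", "C", 2, 0.0), ("CD", "C", 3, 0.0),
            ("OE1", "O", 4, 0.7), ("NE2", "N", 4, -0.7)],
    "GLU": [("CB", "C", 1, 0.0), ("CG", "C", 2, 0.0), ("CD", "C", 3, 0.0),
            ("OE1", "O", 4, 1.5), ("OE2", "O", 4, -1.5)],
    "GLY": [],
    "HIS": [("CB", "C", 1, 0.0), ("CG", "C", 2, 0.0),
            ("ND1", "N", 3, 0.7), ("CD2", "C", 3, -0.7),
            ("CE1", "C", 4, 0.7), ("NE2", "N", 4, -0.7)],
    "ILE": [("CB", "C", 1, 0.0), ("CG1", "C", 2, 0.7), ("CG2", "C", 2, -0.7),
            ("CD1", "C", 3, 0.7)],
    "LEU": [("CB", "C", 1, 0.0), ("CG", "C", 2, 0.0),
            ("CD1", "C", 3, 0.7), ("CD2", "C", 3, -0.7)],
    "LYS": [("CB", "C", 1, 0.0), ("CG", "C", 2, 0.0), ("CD", "C", 3, 0.0),
            ("CE", "C", 4, 0.0), ("NZ", "N", 5, 0.0)],
    "MET": [("CB", "C", 1, 0.0), ("CG", "C", 2, 0.0), ("SD", "S", 3, 0.0),
            ("CE", "C", 4, 0.0)],
    "PHE": [("CB", "C", 1, 0.0), ("CG", "C", 2, 0.0),
            ("CD1", "C", 3, 0.7), ("CD2", "C", 3, -0.7),
            ("CE1", "C", 4, 0.7), ("CE2", "C", 4, -0.7), ("CZ", "C", 5, 0.0)],
    "PRO": [("CB", "C", 1, 0.0), ("CG", "C", 2, 0.0), ("CD", "C", 3, 0.0)],
    "SER": [("CB", "C", 1, 0.0), ("OG", "O", 2, 0.0)],
    "THR": [("CB", "C", 1, 0.0), ("OG1", "O", 2, 0.7), ("CG2", "C", 2, -0.7)],
    "TRP": [("CB", "C", 1, 0.0), ("CG", "C", 2, 0.0),
            ("CD1", "C", 3, 0.7), ("CD2", "C", 3, -0.7),
            ("NE1", "N", 4, 0.7), ("CE2", "C", 4, -0.7), ("CE3", "C", 4, -1.4),
            ("CZ2", "C", 5, 0.7), ("CZ3", "C", 5, -0.7), ("CH2", "C", 6, 0.0)],
    "TYR": [("CB", "C", 1, 0.0), ("CG", "C", 2, 0.0),
            ("CD1", "C", 3, 0.7), ("CD2", "C", 3, -0.7),
            ("CE1", "C", 4, 0.7), ("CE2", "C", 4, -0.7), ("CZ", "C", 5, 0.0),
            ("OH", "O", 6, 0.0)],
    "VAL": [("CB", "C", 1, 0.0), ("CG1", "C", 2, 0.7), ("CG2", "C", 2, -0.7)],
}

CA_SPACING = 5.0  # Å between consecutive CA atoms along the toy chain


def _depth(level: int) -> float:
    return 1.53 + 1.3 * (level - 1)


def _build_residue(
    chain_id: str,
    seq_number: int,
    name: str,
    ca: np.ndarray,
    direction: float,  # +1 side chain toward +y, -1 toward -y
) -> Residue:
    # backbone lies flat in the chain plane (carbonyl O offset in z) so it
    # never reaches toward the partner regardless of side-chain direction
    atoms = [
        Atom("N", "N", tuple(ca + np.array([-1.2, 0.0, 0.0])), False, False),
        Atom("CA", "C", tuple(ca), False, False),
        Atom("C", "C", tuple(ca + np.array([1.2, 0.0, 0.0])), False, False),
        Atom("O", "O", tuple(ca + np.array([1.2, 0.0, 1.2])), False, False),
    ]
    for atom_name, element, level, z in SIDECHAIN_TEMPLATES[name]:
        pos = ca + np.array([0.0, direction * _depth(level), z])
        atoms.append(Atom(atom_name, element, tuple(pos), False, True))
    return Residue(
        chain_id=chain_id,
        seq_number=seq_number,
        insertion_code="",
        name=name,
        atoms=atoms,
    )


def _atom_pos(res: Residue, atom_name: str) -> np.ndarray:
    for a in res.atoms:
        if a.name == atom_name:
            return np.asarray(a.coords)
    raise KeyError(f"atom {atom_name} not in {res.name}{res.seq_number}")


# ---------------------------------------------------------------------------
# Planted contacts
# ---------------------------------------------------------------------------

# class -> (forced query residue, designated query atom, partner placements)
# A placement is (partner residue name, designated partner atom,
#                 (dx, dy_above_query_atom, dz)).
CLASS_TABLE: dict[str, tuple[str, str, list[tuple[str, str, tuple[float, float, float]]]]] = {
    "salt_bridge": ("LYS", "NZ", [("GLU", "OE1", (0.0, 3.2, 0.0))]),
    "hydrogen_bond": ("GLN", "NE2", [("SER", "OG", (0.0, 3.0, 0.0))]),
    "hydrophobic": ("LEU", "CD1", [("LEU", "CD1", (0.0, 4.2, 0.0))]),
    "generic": ("PHE", "CZ", [("ALA", "CB", (0.0, 4.8, 0.0))]),
    # composite used to plant unambiguous hot spots: one salt bridge plus two
    # hydrogen bonds (>= 4 kcal/mol with the default weight table)
    "hotspot": ("LYS", "NZ", [("GLU", "OE1", (0.0, 3.2, 0.0)),
                              ("SER", "OG", (1.8, 2.5, 0.0)),
                              ("SER", "OG", (-1.8, 2.5, 0.0))]),
}

# designated contact atom when the query residue identity is imposed (the
# reference stand-in uses the real reference sequence)
TERMINAL_ATOM = {
    "ARG": "NH1", "LYS": "NZ", "ASP": "OD1", "GLU": "OE1", "GLN": "NE2",
    "ASN": "ND2", "SER": "OG", "THR": "OG1", "TYR": "OH", "HIS": "NE2",
    "PHE": "CZ", "TRP": "CZ2", "LEU": "CD1", "ILE": "CD1", "VAL": "CG1",
    "MET": "CE", "CYS": "SG", "PRO": "CD", "ALA": "CB",
}

# distance window (min, max) a designated pair must satisfy per class
CLASS_WINDOWS = {
    "salt_bridge": (2.0, 4.0),
    "hydrogen_bond": (2.0, 3.5),
    "hydrophobic": (2.5, 4.5),
    "generic": (4.5, 5.0),
}


@dataclass(frozen=True)
class Plant:
    """One planted inter-chain contact site on the query chain."""

    residue: int  # query residue number (1-based)
    contact_class: str
    models: tuple[int, ...] = ()  # 1-based model indices; empty = all models
    query_residue_name: str | None = None  # override the class default
    query_atom: str | None = None
    placements: tuple[tuple[str, str, tuple[float, float, float]], ...] | None = None

    def resolved(self) -> tuple[str, str, list[tuple[str, str, tuple[float, float, float]]]]:
        default_res, default_atom, default_place = CLASS_TABLE[self.contact_class]
        res = self.query_residue_name or default_res
        atom = self.query_atom or (
            TERMINAL_ATOM[res] if self.query_residue_name else default_atom
        )
        places = list(self.placements) if self.placements is not None else default_place
        return res, atom, places


DISPLACEMENT = 25.0  # Å shift applied to partner residues in inactive models


def simulate_complex(
    seed: int,
    n_models: int = 10,
    query_length: int = 20,
    planted_contacts: Sequence[Plant] = (),
    jitter_sd: float = 0.05,
    query_sequence: str | None = None,
    out_dir: str | Path | None = None,
    source_id: str = "synthetic-complex",
    max_retries: int = 50,
) -> tuple[StructureEnsemble, SyntheticTruth]:
    """Generate a two-chain multi-model ensemble with planted contacts.

    Chain A is the query, chain B the partner.  Each planted contact is
    realized, in exactly its model subset, at a distance inside its class
    window; every non-planted query residue stays > 8 Å from the partner
    chain in every model.  Per-model Gaussian jitter (sd ``jitter_sd`` Å) is
    re-drawn until those guarantees hold.
    """
    rng = np.random.default_rng(seed)
    plants = list(planted_contacts)
    for p in plants:
        if not 1 <= p.residue <= query_length:
            raise ValueError(f"planted residue {p.residue} outside 1..{query_length}")
        if p.contact_class not in CLASS_TABLE:
            raise ValueError(f"unknown contact class {p.contact_class!r}")
    if len({p.residue for p in plants}) != len(plants):
        raise ValueError("duplicate planted residues")

    # query sequence: imposed, or random with planted identities forced
    aa_pool = [n for n in SIDECHAIN_TEMPLATES if n != "GLY"]  # keep CB everywhere
    if query_sequence is None:
        names = [aa_pool[i] for i in rng.integers(0, len(aa_pool), size=query_length)]
    else:
        if len(query_sequence) != query_length:
            raise ValueError("query_sequence length mismatch")
        names = [ONE_TO_THREE[c] for c in query_sequence.upper()]
    planted_by_res = {p.residue: p for p in plants}
    for num, p in planted_by_res.items():
        res_name, _, _ = p.resolved()
        names[num - 1] = res_name

    # base (jitter-free) geometry
    query_base: list[Residue] = []
    for i, name in enumerate(names, start=1):
        ca = np.array([CA_SPACING * (i - 1), 0.0, 0.0])
        direction = +1.0 if i in planted_by_res else -1.0
        query_base.append(_build_residue("A", i, name, ca, direction))

    partner_base: list[Residue] = []
    partner_of_plant: dict[int, list[int]] = {}
    pnum = 0
    for p in plants:
        res_name, q_atom, places = p.resolved()
        q_res = query_base[p.residue - 1]
        q_pos = _atom_pos(q_res, q_atom)
        idxs = []
        for pres_name, p_atom, (dx, dy, dz) in places:
            pnum += 1
            target = q_pos + np.array([dx, dy, dz])
            # partner side chain points -y; CA sits depth above the target atom
            template = {a: (lvl, z) for a, _, lvl, z in SIDECHAIN_TEMPLATES[pres_name]}
            lvl, z = template[p_atom]
            ca = target + np.array([0.0, _depth(lvl), -z])
            partner_base.append(_build_residue("B", pnum, pres_name, ca, -1.0))
            idxs.append(pnum - 1)
        partner_of_plant[p.residue] = idxs

    active_models = {
        p.residue: set(p.models) if p.models else set(range(1, n_models + 1))
        for p in plants
    }

    models = []
    for mi in range(1, n_models + 1):
        for _attempt in range(max_retries):
            model = _jitter_model(
                query_base, partner_base, partner_of_plant, active_models, mi,
                jitter_sd, rng,
            )
            if _verify_model(model, planted_by_res, partner_of_plant, active_models, mi):
                models.append(model)
                break
        else:
            raise RuntimeError(
                f"infeasible geometry: model {mi} failed verification "
                f"{max_retries} times (jitter_sd={jitter_sd})"
            )

    ensemble = StructureEnsemble(models=models, source_id=source_id)
    truth = SyntheticTruth(
        kind="ensemble",
        parameters={
            "seed": int(seed),
            "n_models": n_models,
            "query_length": query_length,
            "jitter_sd": jitter_sd,
            "ca_spacing": CA_SPACING,
            "query_sequence": query_sequence,
            "planted_contacts": [dataclasses.asdict(p) for p in plants],
        },
        truth={
            "interface_residues": sorted(planted_by_res),
            "contact_classes": {str(p.residue): p.contact_class for p in plants},
            "model_support": {
                str(num): sorted(active_models[num]) for num in planted_by_res
            },
            "hot_spots": sorted(
                p.residue for p in plants if p.contact_class == "hotspot"
            ),
        },
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_ensemble(ensemble, out_dir / "complex.pdb")
        truth.to_json(out_dir / "complex.truth.json")
    return ensemble, truth


def _jitter_model(query_base, partner_base, partner_of_plant, active_models, mi,
                  jitter_sd, rng):
    model = []
    for res in query_base:
        model.append(_jittered(res, np.zeros(3), jitter_sd, rng))
    inactive = {
        idx
        for num, idxs in partner_of_plant.items()
        for idx in idxs
        if mi not in active_models[num]
    }
    for i, res in enumerate(partner_base):
        shift = np.array([0.0, DISPLACEMENT, 0.0]) if i in inactive else np.zeros(3)
        model.append(_jittered(res, shift, jitter_sd, rng))
    return model


def _jittered(res: Residue, shift: np.ndarray, sd: float, rng) -> Residue:
    atoms = []
    for a in res.atoms:
        noise = rng.normal(0.0, sd, size=3) if sd > 0 else np.zeros(3)
        atoms.append(
            Atom(a.name, a.element, tuple(np.asarray(a.coords) + shift + noise),
                 a.is_hydrogen, a.is_sidechain)
        )
    return Residue(res.chain_id, res.seq_number, res.insertion_code, res.name, atoms)


def _verify_model(model, planted_by_res, partner_of_plant, active_models, mi) -> bool:
    query = [r for r in model if r.chain_id == "A"]
    partner = [r for r in model if r.chain_id == "B"]
    partner_close = [
        r for r in partner
        if min(a.coords[1] for a in r.atoms) < DISPLACEMENT - 5.0
    ]
    p_coords = (
        np.vstack([r.coord_array() for r in partner_close])
        if partner_close else np.empty((0, 3))
    )
    # designated pairs inside their class windows
    for num, plant in planted_by_res.items():
        res_name, q_atom, places = plant.resolved()
        q_res = query[num - 1]
        q_pos = _atom_pos(q_res, q_atom)
        active = mi in active_models[num]
        for (pres_name, p_atom, _), pidx in zip(places, partner_of_plant[num]):
            p_res = partner[pidx]
            d = float(np.linalg.norm(q_pos - _atom_pos(p_res, p_atom)))
            if active:
                cls = plant.contact_class
                if cls == "hotspot":
                    lo, hi = CLASS_WINDOWS["salt_bridge" if p_atom == "OE1" else "hydrogen_bond"]
                else:
                    lo, hi = CLASS_WINDOWS[cls]
                if not lo < d <= hi:
                    return False
            elif d < 8.0:
                return False
    # all non-planted query residues stay clear of the partner chain
    if len(p_coords):
        for r in query:
            if r.seq_number in planted_by_res and mi in active_models[r.seq_number]:
                continue
            q = r.coord_array()
            dmin = float(np.min(np.linalg.norm(q[:, None, :] - p_coords[None], axis=-1)))
            if dmin <= 8.0:
                return False
    return True


# ---------------------------------------------------------------------------
# Sequence families
# ---------------------------------------------------------------------------

AA20 = "ACDEFGHIKLMNPQRSTVWY"
_WILDCARD_FILL = ("A", "D", "K")  # three residues from three classes


def simulate_family(
    seed: int,
    n_high: int = 8,
    n_low: int = 6,
    motif: str = "[D/E]xP[F/Y]KP",
    region_start: int = 60,
    sequence_length: int = 154,
    background: Mapping[str, float] | None = None,
    high_conservation: float = 1.0,
    low_spoiler: Sequence[int] | None = None,
    identity_pairs: Sequence[tuple[str, float]] | None = None,
    out_dir: str | Path | None = None,
):
    """Generate an aligned, labelled family with the motif planted in the
    high group at *region_start* (1-based) and violated by the low group.

    ``low_spoiler`` lists 1-based motif positions to scramble in the low
    group (default: every non-wildcard position).  ``identity_pairs`` adds
    near-duplicates: for each (record id, identity) a copy of that record
    with exactly ``round((1-identity)*L)`` substituted positions is appended.

    Returns ``(records, labels, truth)`` where records is a list of
    (id, sequence) in order and labels maps id -> high/low.
    """
    from .consensus import parse_motif

    rng = np.random.default_rng(seed)
    spec = parse_motif(motif)
    m = len(spec)
    if region_start < 1 or region_start + m - 1 > sequence_length:
        raise ValueError("motif does not fit in sequence_length at region_start")
    if n_high < 2:
        raise ValueError("need at least two high-group sequences")
    for pos in spec.positions:
        if pos.kind == "class" and len(pos.residues) > n_high:
            raise ValueError("class alternative larger than the high group")
    if background is None:
        bg_letters, bg_probs = list(AA20), None
    else:
        bg_letters = sorted(background)
        total = sum(background.values())
        bg_probs = [background[a] / total for a in bg_letters]

    def draw_bg(size):
        return rng.choice(bg_letters, size=size, p=bg_probs)

    high_seqs = [list(draw_bg(sequence_length)) for _ in range(n_high)]
    for k, pos in enumerate(spec.positions):
        for i, seq in enumerate(high_seqs):
            conserved = high_conservation >= 1.0 or rng.random() < high_conservation
            if pos.kind == "fixed":
                aa = pos.residues[0] if conserved else str(draw_bg(1)[0])
            elif pos.kind == "class":
                aa = pos.residues[i % len(pos.residues)] if conserved else str(draw_bg(1)[0])
            else:
                # round-robin over three distinct classes: the column can
                # never be read as fixed or single-class
                aa = _WILDCARD_FILL[i % len(_WILDCARD_FILL)]
            seq[region_start - 1 + k] = aa

    if low_spoiler is None:
        low_spoiler = [k + 1 for k, p in enumerate(spec.positions) if p.kind != "wildcard"]
    low_seqs = [list(draw_bg(sequence_length)) for _ in range(n_low)]
    for k, pos in enumerate(spec.positions):
        for seq in low_seqs:
            if (k + 1) in low_spoiler and pos.kind != "wildcard":
                aa = str(draw_bg(1)[0])
                while pos.matches(aa):
                    aa = str(draw_bg(1)[0])
            else:
                aa = (
                    pos.residues[int(rng.integers(len(pos.residues)))]
                    if pos.kind != "wildcard"
                    else str(draw_bg(1)[0])
                )
            seq[region_start - 1 + k] = aa

    records: list[tuple[str, str]] = []
    labels: dict[str, str] = {}
    for i, seq in enumerate(high_seqs, start=1):
        rid = f"HIGH_{i:02d}"
        records.append((rid, "".join(seq)))
        labels[rid] = "high"
    for i, seq in enumerate(low_seqs, start=1):
        rid = f"LOW_{i:02d}"
        records.append((rid, "".join(seq)))
        labels[rid] = "low"

    dup_truth = []
    if identity_pairs:
        by_id = dict(records)
        for j, (src, identity) in enumerate(identity_pairs, start=1):
            if src not in by_id:
                raise ValueError(f"identity_pairs source {src!r} unknown")
            n_mut = int(round((1.0 - identity) * sequence_length))
            seq = list(by_id[src])
            sites = rng.choice(sequence_length, size=n_mut, replace=False)
            for s in sites:
                aa = str(draw_bg(1)[0])
                while aa == seq[s]:
                    aa = str(draw_bg(1)[0])
                seq[s] = aa
            rid = f"{src}_dup{j}"
            records.append((rid, "".join(seq)))
            labels[rid] = labels[src]
            dup_truth.append({"id": rid, "source": src, "target_identity": identity})

    truth = SyntheticTruth(
        kind="family",
        parameters={
            "seed": int(seed),
            "n_high": n_high,
            "n_low": n_low,
            "motif": motif,
            "region_start": region_start,
            "sequence_length": sequence_length,
            "high_conservation": high_conservation,
            "low_spoiler": list(low_spoiler),
            "identity_pairs": [list(p) for p in identity_pairs] if identity_pairs else [],
        },
        truth={
            "motif": motif,
            "region_span": [region_start, region_start + m - 1],
            "reference_id": "HIGH_01",
            "labels": labels,
            "duplicates": dup_truth,
            "high_match": {rid: True for rid in labels if labels[rid] == "high"},
            "low_match": {rid: False for rid in labels if labels[rid] == "low"},
        },
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_family(records, labels, out_dir / "family.afa", out_dir / "family.labels.tsv")
        truth.to_json(out_dir / "family.truth.json")
    return records, labels, truth


def write_family(
    records: Sequence[tuple[str, str]],
    labels: Mapping[str, str],
    fasta_path: str | Path,
    labels_path: str | Path,
) -> None:
    with open(fasta_path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    with open(labels_path, "w") as fh:
        for rid, _ in records:
            fh.write(f"{rid}\t{labels[rid]}\n")


# ---------------------------------------------------------------------------
# Image pairs
# ---------------------------------------------------------------------------

def simulate_image_pair(
    seed: int,
    shape: tuple[int, int] = (64, 64),
    overlap_fraction: float = 0.5,
    intensity_model: str = "uniform",
    noise_sd: float = 0.0,
    thresholds: tuple[float, float] = (50.0, 50.0),
    out_dir: str | Path | None = None,
):
    """Two-channel image pair whose true weighted colocalization coefficient
    is known analytically.

    Channel A occupies a central block of the ROI; channel B covers the first
    ``round(overlap_fraction * |A|)`` of A's pixels in raster order.  With
    uniform intensities and ``noise_sd = 0`` the coefficient equals the
    realized overlap fraction exactly; the truth records the analytic value
    (intensity-weighted for the gradient model).

    Returns ``(channel_a, channel_b, mask, truth)`` as uint16 arrays.
    """
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ValueError("overlap_fraction outside [0, 1]")
    rng = np.random.default_rng(seed)
    h, w = shape
    mask = np.zeros(shape, dtype=bool)
    mask[h // 8 : h - h // 8, w // 8 : w - w // 8] = True  # central ROI

    a = np.zeros(shape, dtype=float)
    b = np.zeros(shape, dtype=float)
    # channel-A support: central block, size divisible by 4
    ah, aw = (h // 2) & ~1, (w // 2) & ~1
    r0, c0 = (h - ah) // 2, (w - aw) // 2
    support = np.zeros(shape, dtype=bool)
    support[r0 : r0 + ah, c0 : c0 + aw] = True
    n_a = int(support.sum())
    if intensity_model == "uniform":
        a[support] = 200.0
    elif intensity_model == "gradient":
        rows = np.linspace(100.0, 300.0, ah)[:, None]
        a[r0 : r0 + ah, c0 : c0 + aw] = np.broadcast_to(rows, (ah, aw))
    else:
        raise ValueError(f"unknown intensity model {intensity_model!r}")

    n_overlap = int(round(overlap_fraction * n_a))
    flat_idx = np.flatnonzero(support.ravel())[:n_overlap]
    b_flat = b.ravel()
    b_flat[flat_idx] = 200.0
    b = b_flat.reshape(shape)

    a_vals = a[support]
    overlap_mask = np.zeros(shape, dtype=bool)
    overlap_mask.ravel()[flat_idx] = True
    analytic = (
        float(a[overlap_mask].sum() / a_vals.sum()) if a_vals.sum() > 0 else 0.0
    )

    if noise_sd > 0:
        a = np.clip(a + rng.normal(0.0, noise_sd, size=shape), 0, 65535)
        b = np.clip(b + rng.normal(0.0, noise_sd, size=shape), 0, 65535)
    a16 = np.round(a).astype(np.uint16)
    b16 = np.round(b).astype(np.uint16)

    truth = SyntheticTruth(
        kind="image",
        parameters={
            "seed": int(seed),
            "shape": list(shape),
            "overlap_fraction": overlap_fraction,
            "intensity_model": intensity_model,
            "noise_sd": noise_sd,
            "thresholds": list(thresholds),
        },
        truth={
            "analytic_coefficient": analytic,
            "realized_overlap_fraction": n_overlap / n_a,
            "n_support_pixels": n_a,
            "thr_a": thresholds[0],
            "thr_b": thresholds[1],
        },
    )
    if out_dir is not None:
        import tifffile

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(out_dir / "channel_a.tif", a16)
        tifffile.imwrite(out_dir / "channel_b.tif", b16)
        tifffile.imwrite(out_dir / "mask.tif", mask.astype(np.uint8) * 255)
        truth.to_json(out_dir / "image.truth.json")
    return a16, b16, mask, truth


# ---------------------------------------------------------------------------
# Packaged stand-ins for the external reference inputs (SYNTHETIC)
# ---------------------------------------------------------------------------

# Human UBE2L3 (UbcH7), 154 residues.  This is the real reference sequence;
# it anchors author numbering for regions and the motif span.
UBE2L3_SEQUENCE = (
    "MAASRRLMKELEEIRKCGMKNFRNIQVDEANLLTWQGLIVPDNPPYDKGAFRIEINFPAE"
    "YPFKPPKITFKTKIYHPNIDEKGQVCLPVISAENWKPATKTDQVIQSLIALVNDPQPEHP"
    "LRADLAEEYSKDRKKFCKNAEEFTKKYGEKRPVD"
)

# Planted contact sites of the reference-complex stand-in.  They realize the
# three published interface regions under (cutoff 6 Å, any-model, max_gap 3)
# and make R5 / F63 / P97 the strongest surrogate-ΔAffinity sites.
_REFERENCE_PLANTS: list[Plant] = [
    Plant(1, "hydrophobic", query_residue_name="MET", query_atom="CE"),
    Plant(5, "salt_bridge", query_residue_name="ARG", query_atom="NH1"),
    Plant(9, "hydrogen_bond", query_residue_name="LYS", query_atom="NZ",
          placements=(("SER", "OG", (0.0, 3.0, 0.0)),)),
    Plant(60, "generic", query_residue_name="GLU", query_atom="OE1"),
    Plant(63, "hydrophobic", query_residue_name="PHE", query_atom="CZ",
          placements=(("LEU", "CD1", (0.0, 2.9, 0.0)),)),
    Plant(65, "generic", query_residue_name="PRO", query_atom="CD"),
    Plant(87, "hydrophobic", query_residue_name="LEU", query_atom="CD1"),
    Plant(90, "hydrophobic", query_residue_name="ILE", query_atom="CD1"),
    Plant(93, "hydrogen_bond", query_residue_name="GLU", query_atom="OE1",
          placements=(("SER", "OG", (0.0, 3.0, 0.0)),)),
    Plant(97, "hydrophobic", query_residue_name="PRO", query_atom="CD",
          placements=(("LEU", "CD1", (0.0, 2.9, 0.0)),)),
    Plant(100, "generic", query_residue_name="LYS", query_atom="NZ"),
    Plant(103, "generic", query_residue_name="GLN", query_atom="NE2"),
]

REFERENCE_REGIONS = [(1, 9), (60, 65), (87, 103)]
REFERENCE_STRONG_SITES = (5, 63, 97)


def reference_complex(
    seed: int = 613, n_models: int = 10, out_dir: str | Path | None = None
) -> tuple[StructureEnsemble, SyntheticTruth]:
    """SYNTHETIC stand-in for the E2-E3 NMR ensemble the published procedure
    analyzed (which cannot be redistributed here).

    Chain A carries the real UBE2L3 sequence on the toy scaffold; chain B is
    a pseudo-partner whose planted contacts reproduce the published ground
    truth: 10 models, interface regions M1-K9 / E60-P65 / L87-Q103 at 6 Å
    with any-model aggregation and max_gap 3, and R5/F63/P97 as the
    top-ranked surrogate-ΔAffinity sites (R5 the lone >2.5 kcal/mol hot
    spot).  It validates the procedure, not the deposited coordinates.
    """
    ensemble, truth = simulate_complex(
        seed=seed,
        n_models=n_models,
        query_length=len(UBE2L3_SEQUENCE),
        planted_contacts=_REFERENCE_PLANTS,
        jitter_sd=0.05,
        query_sequence=UBE2L3_SEQUENCE,
        source_id="synthetic-ube2l3-complex",
        out_dir=None,
    )
    truth.truth["expected_regions"] = [list(r) for r in REFERENCE_REGIONS]
    truth.truth["strong_sites"] = list(REFERENCE_STRONG_SITES)
    truth.truth["hot_spots"] = [5]
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_ensemble(ensemble, out_dir / "synthetic_ube2l3_complex.pdb")
        truth.to_json(out_dir / "synthetic_ube2l3_complex.truth.json")
    return ensemble, truth


# window at reference positions 60-65 for each stand-in family member
_FAMILY_WINDOWS_HIGH = {
    "UBE2D_syn": "DSPFKP",
    "UBE2C_syn": "ELPYKP",
    "UBE2E1_syn": "DTPFKP",
    "UBE2E3_syn": "EAPYKP",
    "UBE2J2_syn": "DVPFKP",
}
_FAMILY_WINDOWS_LOW = {
    "UBE2A_syn": "QTPHKA",
    "UBE2N_syn": "EYPMAA",
    "UBE2V1_syn": "GGLSDE",
    "UBE2R2_syn": "KDAFKP",
}


def reference_family(
    seed: int = 1202, out_dir: str | Path | None = None
) -> tuple[list[tuple[str, str]], dict[str, str], SyntheticTruth]:
    """SYNTHETIC stand-in for the labelled E2 alignment used to derive the
    consensus motif.

    Only the UBE2L3 record is the real protein sequence; every ``*_syn``
    record is generator-built: an independent random background with a
    hand-set window at reference positions 60-65.  High-group windows carry
    [D/E] x P [F/Y] K P variation; low-group windows violate the motif.  The
    four UBE2D paralog stand-ins are mutual near-duplicates (>60% pairwise
    identity) so the redundancy filter keeps exactly one; the two UBE2A/B
    stand-ins likewise.  All sequences are length 154 and gap-free, so the
    "alignment" is the trivial one.
    """
    rng = np.random.default_rng(seed)
    L = len(UBE2L3_SEQUENCE)
    win = slice(59, 65)

    def background_with_window(window: str) -> str:
        seq = list(rng.choice(list(AA20), size=L))
        seq[win] = list(window)
        return "".join(seq)

    def mutate_outside_window(seq: str, fraction: float) -> str:
        out = list(seq)
        candidates = [i for i in range(L) if not 59 <= i < 65]
        n_mut = int(round(fraction * len(candidates)))
        for i in rng.choice(candidates, size=n_mut, replace=False):
            aa = str(rng.choice(list(AA20)))
            while aa == out[i]:
                aa = str(rng.choice(list(AA20)))
            out[i] = aa
        return "".join(out)

    records: list[tuple[str, str]] = [("UBE2L3", UBE2L3_SEQUENCE)]
    labels: dict[str, str] = {"UBE2L3": "high"}

    d_ancestor = background_with_window(_FAMILY_WINDOWS_HIGH["UBE2D_syn"])
    for i in range(1, 5):
        seq = d_ancestor if i == 1 else mutate_outside_window(d_ancestor, 0.15)
        records.append((f"UBE2D{i}_syn", seq))
        labels[f"UBE2D{i}_syn"] = "high"
    for rid in ("UBE2C_syn", "UBE2E1_syn", "UBE2E3_syn", "UBE2J2_syn"):
        records.append((rid, background_with_window(_FAMILY_WINDOWS_HIGH[rid])))
        labels[rid] = "high"

    a_seq = background_with_window(_FAMILY_WINDOWS_LOW["UBE2A_syn"])
    records.append(("UBE2A_syn", a_seq))
    labels["UBE2A_syn"] = "low"
    records.append(("UBE2B_syn", mutate_outside_window(a_seq, 0.10)))
    labels["UBE2B_syn"] = "low"
    for rid in ("UBE2N_syn", "UBE2V1_syn", "UBE2R2_syn"):
        records.append((rid, background_with_window(_FAMILY_WINDOWS_LOW[rid])))
        labels[rid] = "low"

    truth = SyntheticTruth(
        kind="family",
        parameters={"seed": int(seed), "sequence_length": L},
        truth={
            "motif": "[D/E]xP[F/Y]KP",
            "region_span": [60, 65],
            "reference_id": "UBE2L3",
            "labels": labels,
            "expected_single_representative": ["UBE2D", "UBE2A"],
            "real_sequences": ["UBE2L3"],
        },
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_family(
            records, labels,
            Path(out_dir) / "synthetic_e2_family.afa",
            Path(out_dir) / "synthetic_e2_family.labels.tsv",
        )
        truth.to_json(Path(out_dir) / "synthetic_e2_family.truth.json")
    return records, labels, truth
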