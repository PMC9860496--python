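"""Surrogate computational alanine scanning over a structure ensemble.

The published hot-spot calls behind this workflow came from a proprietary
physics-based alanine-scanning module.  This package instead scores each
residue with an explicit, documented contact-count surrogate: truncating a
side chain to CB removes its side-chain atoms, and the binding-affinity loss
(ΔAffinity, kcal/mol) is the weighted count of inter-chain contacts those
atoms made, classified by a first-match rule table (salt bridge, hydrogen
bond, hydrophobic, generic).  The weights are calibration constants chosen so
that a buried salt-bridge-plus-hydrogen-bond residue exceeds the conventional
2.5 kcal/mol hot-spot threshold; every cross-study claim is made on rankings
and planted-truth recovery, never on matching the proprietary scorer's
absolute values.

Hot spots are residues whose ensemble-averaged ΔAffinity is strictly greater
than the threshold (default 2.5 kcal/mol).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .structure import Atom, Model, Residue, StructureEnsemble

# Charged side-chain groups (residue name -> atom names).
POSITIVE_ATOMS = {
    "LYS": {"NZ"},
    "ARG": {"NH1", "NH2", "NE"},
    "HIS": {"ND1", "NE2"},
}
NEGATIVE_ATOMS = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
}

# Contact-class distance ceilings (Å) and per-pair weights (kcal/mol).
SALT_BRIDGE_MAX = 4.0
HBOND_MAX = 3.5
HYDROPHOBIC_MAX = 4.5
GENERIC_MAX = 5.0

DEFAULT_WEIGHTS: dict[str, float] = {
    "salt_bridge": 2.0,
    "hydrogen_bond": 1.0,
    "hydrophobic": 0.5,
    "generic": 0.1,
}
# The hydrophobic + generic contribution is capped per residue so that broad
# packing surfaces cannot outrank specific polar interactions.
APOLAR_CAP = 2.0


@dataclass(frozen=True)
class ContactRecord:
    """One classified inter-chain atom-pair contact."""

    query_residue: tuple[str, int]
    partner_residue: tuple[str, int]
    query_atom: str
    partner_atom: str
    distance: float
    contact_class: str

    def __post_init__(self):
        if self.distance <= 0:
            raise ValueError("contact distance must be positive")


def _charge(res_name: str, atom_name: str) -> int:
    if atom_name in POSITIVE_ATOMS.get(res_name, ()):
        return +1
    if atom_name in NEGATIVE_ATOMS.get(res_name, ()):
        return -1
    return 0


def classify_contact(
    query_atom: Atom,
    query_res_name: str,
    partner_atom: Atom,
    partner_res_name: str,
    distance: float,
) -> str | None:
    """Classify one heavy-atom pair; first matching rule wins.

    Order: salt bridge (oppositely charged groups, <= 4.0 Å), hydrogen bond
    (both N/O, <= 3.5 Å), hydrophobic (both C, <= 4.5 Å), generic (<= 5.0 Å),
    else ``None``.
    """
    if query_atom.is_hydrogen or partner_atom.is_hydrogen:
        raise ValueError("classify_contact takes heavy atoms only")
    qc = _charge(query_res_name, query_atom.name)
    pc = _charge(partner_res_name, partner_atom.name)
    if qc * pc < 0 and distance <= SALT_BRIDGE_MAX:
        return "salt_bridge"
    if (
        query_atom.element in ("N", "O")
        and partner_atom.element in ("N", "O")
        and distance <= HBOND_MAX
    ):
        return "hydrogen_bond"
    if query_atom.element == "C" and partner_atom.element == "C" and distance <= HYDROPHOBIC_MAX:
        return "hydrophobic"
    if distance <= GENERIC_MAX:
        return "generic"
    return None


def _sidechain_beyond_cb(residue: Residue) -> list[Atom]:
    """Heavy side-chain atoms removed by an alanine truncation (CB retained)."""
    return [
        a
        for a in residue.heavy_atoms()
        if a.is_sidechain and a.name != "CB"
    ]


def residue_contacts(
    model: Model,
    residue: Residue,
    partner_chain: str,
) -> list[ContactRecord]:
    """All classified contacts between the residue's beyond-CB side-chain atoms
    and partner-chain heavy atoms.  Each (query atom, partner atom) pair is
    counted once at its first-matching class."""
    records: list[ContactRecord] = []
    q_atoms = _sidechain_beyond_cb(residue)
    if not q_atoms:
        return records
    for pres in model:
        if pres.chain_id != partner_chain:
            continue
        for pa in pres.heavy_atoms():
            pv = np.asarray(pa.coords)
            for qa in q_atoms:
                d = float(np.linalg.norm(np.asarray(qa.coords) - pv))
                cls = classify_contact(qa, residue.name, pa, pres.name, d)
                if cls is not None:
                    records.append(
                        ContactRecord(
                            query_residue=(residue.name, residue.seq_number),
                            partner_residue=(pres.name, pres.seq_number),
                            query_atom=qa.name,
                            partner_atom=pa.name,
                            distance=d,
                            contact_class=cls,
                        )
                    )
    return records


def score_contacts(
    contacts: Iterable[ContactRecord],
    weights: Mapping[str, float] | None = None,
    apolar_cap: float = APOLAR_CAP,
) -> float:
    """Weighted contact sum with the hydrophobic+generic contribution capped."""
    w = dict(DEFAULT_WEIGHTS)
    if weights:
        w.update(weights)
    polar = 0.0
    apolar = 0.0
    for c in contacts:
        if c.contact_class in ("salt_bridge", "hydrogen_bond"):
            polar += w[c.contact_class]
        else:
            apolar += w[c.contact_class]
    return polar + min(apolar, apolar_cap)


def ala_ddg(
    model: Model,
    residue: Residue,
    partner_chain: str,
    weights: Mapping[str, float] | None = None,
    apolar_cap: float = APOLAR_CAP,
) -> float:
    """Surrogate ΔAffinity for mutating *residue* to alanine in one model.

    Gly and Ala return 0 by definition (no atoms beyond CB); Pro is truncated
    like any other residue.
    """
    if not residue.is_standard:
        raise ValueError(f"non-standard residue {residue.name} cannot be scanned")
    if residue.name in ("GLY", "ALA"):
        return 0.0
    return score_contacts(
        residue_contacts(model, residue, partner_chain), weights, apolar_cap
    )


@dataclass
class DeltaAffinityProfile:
    """Per-residue, per-model surrogate ΔAffinity with ensemble averages."""

    per_model: dict[tuple[int, int], float]  # (seq_number, model_index 1-based) -> value
    average: dict[int, float]
    threshold: float
    hot_spots: set[int] = field(default_factory=set)

    def ranked(self) -> list[tuple[int, float]]:
        """Residues sorted by decreasing average (ties by residue number)."""
        return sorted(self.average.items(), key=lambda kv: (-kv[1], kv[0]))


def scan_ensemble(
    ensemble: StructureEnsemble,
    residues: Iterable[int],
    query_chain: str,
    partner_chain: str,
    threshold: float = 2.5,
    weights: Mapping[str, float] | None = None,
    apolar_cap: float = APOLAR_CAP,
) -> DeltaAffinityProfile:
    """Alanine-scan the given residue numbers of *query_chain* against
    *partner_chain* in every model; average over models; call hot spots with
    strict inequality (average > threshold).  Non-standard residues are
    skipped with a warning upstream (they never enter via interface regions
    built from standard chains)."""
    wanted = sorted(set(int(r) for r in residues))
    if not wanted:
        raise ValueError("empty residue set")
    per_model: dict[tuple[int, int], float] = {}
    for mi, model in enumerate(ensemble.models, start=1):
        by_num = {
            r.seq_number: r
            for r in model
            if r.chain_id == query_chain and r.is_standard
        }
        for num in wanted:
            res = by_num.get(num)
            if res is None:
                raise ValueError(
                    f"residue {num} not present (or non-standard) in chain "
                    f"{query_chain!r}, model {mi}"
                )
            per_model[(num, mi)] = ala_ddg(model, res, partner_chain, weights, apolar_cap)
    average = {
        num: float(np.mean([per_model[(num, mi)] for mi in range(1, ensemble.n_models + 1)]))
        for num in wanted
    }
    hot = {num for num, v in average.items() if v > threshold}
    return DeltaAffinityProfile(
        per_model=per_model, average=average, threshold=threshold, hot_spots=hot
    )


def profile_to_tsv(
    profile: DeltaAffinityProfile,
    ensemble: StructureEnsemble,
    query_chain: str,
    path: str | Path,
) -> None:
    n = ensemble.n_models
    names = {
        r.seq_number: r.name for r in ensemble.chain_residues(0, query_chain)
    }
    header = ["residue", "name"] + [f"model_{i}" for i in range(1, n + 1)] + [
        "average",
        "hot_spot",
    ]
    lines = ["\t".join(header)]
    for num in sorted(profile.average):
        vals = [f"{profile.per_model[(num, mi)]:.4f}" for mi in range(1, n + 1)]
        lines.append(
            "\t".join(
                [str(num), names.get(num, "?")]
                + vals
                + [f"{profile.average[num]:.4f}", str(int(num in profile.hot_spots))]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def load_weights_config(path: str | Path) -> dict[str, float]:
    """Read a weights override file: one `class<TAB or =>value` pair per line."""
    weights: dict[str, float] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        key, _, val = line.replace("=", "\t").partition("\t")
        key = key.strip()
        if key not in DEFAULT_WEIGHTS:
            raise ValueError(f"unknown contact class {key!r} in weights config")
        weights[key] = float(val)
    return weights
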