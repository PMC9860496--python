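"""Shared fixtures: synthetic reference stand-ins and oracle helpers.

All fixtures are generated programmatically at test time; nothing binary is
stored in the repository.
"""

from __future__ import annotations

import numpy as np
import pytest

from e2face.consensus import AlignmentRecord, LabelledAlignment
from e2face.structure import Atom, Residue
from e2face.synthetic import reference_complex, reference_family


@pytest.fixture(scope="session")
def ref_complex():
    """Synthetic stand-in ensemble for the E2-E3 complex (10 models)."""
    return reference_complex()


@pytest.fixture(scope="session")
def ref_family():
    """Synthetic stand-in labelled E2 family (records, labels, truth)."""
    return reference_family()


@pytest.fixture(scope="session")
def ref_alignment(ref_family) -> LabelledAlignment:
    records, labels, _ = ref_family
    return LabelledAlignment(
        records=[AlignmentRecord(rid, seq, labels[rid]) for rid, seq in records],
        reference_id="UBE2L3",
    )


def make_atom(name: str, element: str, xyz, sidechain: bool = True) -> Atom:
    return Atom(name=name, element=element, coords=tuple(float(c) for c in xyz),
                is_hydrogen=element == "H", is_sidechain=sidechain)


def make_residue(chain: str, num: int, name: str, atoms) -> Residue:
    return Residue(chain_id=chain, seq_number=num, insertion_code="", name=name,
                   atoms=list(atoms))


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def brute_force_interface(ensemble, query_chain, partner_chain, cutoff,
                          include_hydrogens=False):
    """All-pairs distance enumeration, independent of the KD-tree path.

    Returns {residue_number: support_count}.
    """
    support: dict[int, int] = {}
    for model in ensemble.models:
        partner_atoms = [
            a
            for r in model
            if r.chain_id == partner_chain
            for a in (r.atoms if include_hydrogens else r.heavy_atoms())
        ]
        for res in model:
            if res.chain_id != query_chain:
                continue
            atoms = res.atoms if include_hydrogens else res.heavy_atoms()
            hit = False
            for qa in atoms:
                for pa in partner_atoms:
                    d = float(
                        np.sqrt(sum((x - y) ** 2 for x, y in zip(qa.coords, pa.coords)))
                    )
                    if d <= cutoff:
                        hit = True
                        break
                if hit:
                    break
            if hit:
                support[res.seq_number] = support.get(res.seq_number, 0) + 1
    return support


def regex_motif_oracle(sequence: str, motif) -> list[int]:
    """Overlapping-window motif search via the re module (independent of
    match_motif's window loop)."""
    import re

    parts = []
    for spec in motif.positions:
        if spec.kind == "fixed":
            parts.append(re.escape(spec.residues[0]))
        elif spec.kind == "class":
            parts.append("[" + "".join(spec.residues) + "]")
        else:
            parts.append(".")
    pattern = re.compile("(?=(" + "".join(parts) + "))")
    return [m.start() + 1 for m in pattern.finditer(sequence)]


def pixel_loop_coloc(a, b, mask, thr_a, thr_b) -> float:
    """Per-pixel summation oracle for the weighted colocalization coefficient."""
    num = 0.0
    den = 0.0
    h, w = a.shape
    for i in range(h):
        for j in range(w):
            if not mask[i, j]:
                continue
            if a[i, j] > thr_a:
                den += float(a[i, j])
                if b[i, j] > thr_b:
                    num += float(a[i, j])
    return num / den if den else 0.0
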