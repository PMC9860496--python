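"""Group-differential conservation and degenerate consensus motifs.

Given a multiple sequence alignment of an enzyme family labelled into a
high-activity and a low-activity group, this module removes redundant
sequences (greedy pairwise-identity filter), profiles alignment columns
anchored to a reference span, and synthesizes a degenerate consensus motif:
each position is a fixed residue, a residue-class alternative such as
``[D/E]``, or a wildcard ``x``.  Motifs can be rendered, parsed back, and
scanned against ungapped sequences.

Alignment reading goes through Bio.AlignIO (aligned FASTA and Clustal);
alignment *construction* is upstream of this package.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

from Bio import AlignIO

GAP = "-"

# Six-set physicochemical partition of the 20 standard residues.  This is a
# documented constant (not configuration): it is the partition under which
# acidic [D/E] and aromatic [F/Y] alternatives are single-class.
RESIDUE_CLASSES: dict[str, frozenset[str]] = {
    "acidic": frozenset("DE"),
    "basic": frozenset("KRH"),
    "aromatic": frozenset("FWY"),
    "aliphatic": frozenset("AILMV"),
    "polar": frozenset("CNQST"),
    "special": frozenset("GP"),
}

_CLASS_OF = {aa: name for name, members in RESIDUE_CLASSES.items() for aa in members}


@dataclass
class AlignmentRecord:
    id: str
    seq: str
    label: Literal["high", "low", "unlabelled"]


@dataclass
class LabelledAlignment:
    """An alignment whose records carry a high/low activity label."""

    records: list[AlignmentRecord]
    reference_id: str

    def __post_init__(self):
        if not self.records:
            raise ValueError("alignment has no records")
        lengths = {len(r.seq) for r in self.records}
        if len(lengths) != 1:
            raise ValueError(f"aligned sequences differ in length: {sorted(lengths)}")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sequence ids")
        ref = self.get(self.reference_id)
        if ref is None:
            raise ValueError(f"reference {self.reference_id!r} missing from alignment")
        if ref.label != "high":
            raise ValueError("reference sequence must be labelled 'high'")

    @property
    def n_columns(self) -> int:
        return len(self.records[0].seq)

    def get(self, rec_id: str) -> AlignmentRecord | None:
        for r in self.records:
            if r.id == rec_id:
                return r
        return None

    def group(self, label: str) -> list[AlignmentRecord]:
        return [r for r in self.records if r.label == label]


def read_alignment(
    path: str | Path,
    labels: Mapping[str, str] | str | Path,
    reference_id: str,
    format: Literal["fasta_aligned", "clustal"] = "fasta_aligned",
) -> LabelledAlignment:
    """Read an aligned FASTA or Clustal file plus an id→label mapping.

    *labels* may be a mapping or a path to a two-column TSV (id, high|low).
    Every record id must be labelled.
    """
    fmt = {"fasta_aligned": "fasta", "clustal": "clustal"}.get(format)
    if fmt is None:
        raise ValueError(f"unknown alignment format {format!r}")
    msa = AlignIO.read(str(path), fmt)
    if not isinstance(labels, Mapping):
        labels = read_labels(labels)
    records = []
    for rec in msa:
        if rec.id not in labels:
            raise ValueError(f"no label for sequence id {rec.id!r}")
        label = labels[rec.id]
        if label not in ("high", "low", "unlabelled"):
            raise ValueError(f"bad label {label!r} for {rec.id!r}")
        records.append(AlignmentRecord(id=rec.id, seq=str(rec.seq).upper(), label=label))
    return LabelledAlignment(records=records, reference_id=reference_id)


def read_labels(path: str | Path) -> dict[str, str]:
    labels: dict[str, str] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"labels file line not two-column TSV: {raw!r}")
        labels[parts[0]] = parts[1]
    return labels


# ---------------------------------------------------------------------------
# Identity and redundancy filtering
# ---------------------------------------------------------------------------

def pairwise_identity(a: str, b: str) -> float:
    """Fraction of identical residues over columns where at least one sequence
    has a residue; gap-vs-gap columns are excluded from the denominator and
    gap-vs-residue counts as a mismatch."""
    if len(a) != len(b):
        raise ValueError("aligned sequences must have equal length")
    matches = 0
    denom = 0
    for ca, cb in zip(a, b):
        if ca == GAP and cb == GAP:
            continue
        denom += 1
        if ca == cb:
            matches += 1
    return matches / denom if denom else 0.0


@dataclass
class RemovalLogEntry:
    removed_id: str
    kept_id: str
    identity: float


def redundancy_filter(
    alignment: LabelledAlignment,
    identity_threshold: float = 0.60,
) -> tuple[list[AlignmentRecord], list[RemovalLogEntry]]:
    """Greedy keep-first redundancy filter with the reference forced first.

    Scanning in input order (reference moved to the front), a record is
    removed if its identity to any already-kept record is strictly greater
    than the threshold.  Returns the kept records and a removal log naming
    the kept record that triggered each removal.
    """
    ref = alignment.get(alignment.reference_id)
    ordered = [ref] + [r for r in alignment.records if r.id != alignment.reference_id]
    kept: list[AlignmentRecord] = []
    log: list[RemovalLogEntry] = []
    for rec in ordered:
        trigger = None
        for k in kept:
            ident = pairwise_identity(rec.seq, k.seq)
            if ident > identity_threshold:
                trigger = RemovalLogEntry(removed_id=rec.id, kept_id=k.id, identity=ident)
                break
        if trigger is None:
            kept.append(rec)
        else:
            log.append(trigger)
    return kept, log


# ---------------------------------------------------------------------------
# Reference coordinates and column profiles
# ---------------------------------------------------------------------------

def map_reference_positions(
    alignment: LabelledAlignment, start: int, end: int
) -> list[int]:
    """Alignment columns (0-based) of the reference's ungapped residues
    *start*..*end* (1-based, inclusive)."""
    if start < 1 or start > end:
        raise ValueError("invalid span")
    ref = alignment.get(alignment.reference_id)
    columns = []
    pos = 0
    for col, ch in enumerate(ref.seq):
        if ch == GAP:
            continue
        pos += 1
        if start <= pos <= end:
            columns.append(col)
    if pos < end:
        raise ValueError(
            f"span {start}..{end} exceeds ungapped reference length {pos}"
        )
    return columns


@dataclass
class ColumnProfile:
    """Per-group residue frequencies (over non-gap symbols) for one column."""

    column: int
    frequencies: dict[str, dict[str, float]]
    gap_fraction: dict[str, float]


def profile_columns(
    records: Sequence[AlignmentRecord],
    columns: Iterable[int],
    groups: Sequence[str] = ("high", "low"),
) -> list[ColumnProfile]:
    profiles = []
    for col in columns:
        freqs: dict[str, dict[str, float]] = {}
        gaps: dict[str, float] = {}
        for g in groups:
            seqs = [r.seq[col] for r in records if r.label == g]
            if not seqs:
                freqs[g] = {}
                gaps[g] = 0.0
                continue
            non_gap = [c for c in seqs if c != GAP]
            gaps[g] = 1.0 - len(non_gap) / len(seqs)
            counts: dict[str, int] = {}
            for c in non_gap:
                counts[c] = counts.get(c, 0) + 1
            total = len(non_gap)
            freqs[g] = {aa: n / total for aa, n in sorted(counts.items())}
        profiles.append(ColumnProfile(column=col, frequencies=freqs, gap_fraction=gaps))
    return profiles


# ---------------------------------------------------------------------------
# Motifs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PositionSpec:
    """One motif position: fixed residue, class alternative, or wildcard."""

    kind: Literal["fixed", "class", "wildcard"]
    residues: tuple[str, ...] = ()

    def __post_init__(self):
        if self.kind == "fixed" and len(self.residues) != 1:
            raise ValueError("fixed spec takes exactly one residue")
        if self.kind == "class":
            if len(self.residues) < 2:
                raise ValueError("class spec needs >= 2 residues")
            if list(self.residues) != sorted(set(self.residues)):
                raise ValueError("class residues must be distinct and alphabetical")
        if self.kind == "wildcard" and self.residues:
            raise ValueError("wildcard spec takes no residues")

    def matches(self, aa: str) -> bool:
        if self.kind == "wildcard":
            return True
        return aa in self.residues


@dataclass
class ConsensusMotif:
    positions: list[PositionSpec]
    reference_span: tuple[int, int] | None = None

    def __post_init__(self):
        if self.reference_span is not None:
            start, end = self.reference_span
            if end - start + 1 != len(self.positions):
                raise ValueError("span length must equal number of positions")

    def __len__(self) -> int:
        return len(self.positions)


def derive_consensus(
    records: Sequence[AlignmentRecord],
    columns: Sequence[int],
    tau_fix: float = 0.9,
    tau_class: float = 0.9,
    use_low_group_filter: bool = False,
    tau_low: float = 0.5,
    reference_span: tuple[int, int] | None = None,
) -> ConsensusMotif:
    """Derive a degenerate consensus from the HIGH group of *records* at the
    given columns.

    Per column: a residue with frequency >= tau_fix becomes a fixed position;
    otherwise the most frequent residues whose cumulative frequency reaches
    tau_class become a class alternative if there are at least two of them and
    all fall in one physicochemical class; otherwise the position is a
    wildcard.  Columns whose high-group gap fraction is >= 0.5 are wildcards.
    With the optional low-group filter, a fixed/class position is demoted to
    wildcard when the low group matches it with frequency > tau_low.
    """
    if not columns:
        raise ValueError("empty column selection")
    high = [r for r in records if r.label == "high"]
    if len(high) < 2:
        raise ValueError("need >= 2 high-group records after filtering")
    low = [r for r in records if r.label == "low"]
    positions: list[PositionSpec] = []
    for col in columns:
        spec = _column_spec(high, col, tau_fix, tau_class)
        if use_low_group_filter and spec.kind != "wildcard" and low:
            non_gap = [r.seq[col] for r in low if r.seq[col] != GAP]
            if non_gap:
                match_freq = sum(spec.matches(aa) for aa in non_gap) / len(non_gap)
                if match_freq > tau_low:
                    spec = PositionSpec(kind="wildcard")
        positions.append(spec)
    return ConsensusMotif(positions=positions, reference_span=reference_span)


def _column_spec(
    high: Sequence[AlignmentRecord], col: int, tau_fix: float, tau_class: float
) -> PositionSpec:
    symbols = [r.seq[col] for r in high]
    non_gap = [c for c in symbols if c != GAP]
    if len(non_gap) / len(symbols) <= 0.5:  # gap fraction >= 0.5
        return PositionSpec(kind="wildcard")
    counts: dict[str, int] = {}
    for c in non_gap:
        counts[c] = counts.get(c, 0) + 1
    total = len(non_gap)
    # deterministic order: frequency descending, then alphabetical
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    if ranked[0][1] / total >= tau_fix:
        return PositionSpec(kind="fixed", residues=(ranked[0][0],))
    cum = 0.0
    chosen: list[str] = []
    for aa, n in ranked:
        chosen.append(aa)
        cum += n / total
        if cum >= tau_class:
            break
    if cum >= tau_class and len(chosen) >= 2:
        classes = {_CLASS_OF.get(aa) for aa in chosen}
        if len(classes) == 1 and None not in classes:
            return PositionSpec(kind="class", residues=tuple(sorted(chosen)))
    return PositionSpec(kind="wildcard")


def motif_to_string(motif: ConsensusMotif) -> str:
    """Render a motif: fixed -> 'P', class -> '[D/E]', wildcard -> 'x'."""
    parts = []
    for spec in motif.positions:
        if spec.kind == "fixed":
            parts.append(spec.residues[0])
        elif spec.kind == "class":
            parts.append("[" + "/".join(spec.residues) + "]")
        else:
            parts.append("x")
    return "".join(parts)


def parse_motif(text: str, reference_span: tuple[int, int] | None = None) -> ConsensusMotif:
    """Parse the grammar produced by :func:`motif_to_string`."""
    positions: list[PositionSpec] = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch == "x":
            positions.append(PositionSpec(kind="wildcard"))
            i += 1
        elif ch == "[":
            j = text.find("]", i)
            if j < 0:
                raise ValueError(f"unterminated class set in motif {text!r}")
            residues = tuple(sorted(text[i + 1 : j].split("/")))
            positions.append(PositionSpec(kind="class", residues=residues))
            i = j + 1
        elif ch.isalpha() and ch.isupper():
            positions.append(PositionSpec(kind="fixed", residues=(ch,)))
            i += 1
        else:
            raise ValueError(f"bad motif character {ch!r} in {text!r}")
    return ConsensusMotif(positions=positions, reference_span=reference_span)


def match_motif(sequence: str, motif: ConsensusMotif) -> list[int]:
    """1-based start positions of every window of *sequence* satisfying the
    motif; a sequence shorter than the motif yields no matches."""
    n, m = len(sequence), len(motif)
    hits = []
    for start in range(n - m + 1):
        if all(motif.positions[k].matches(sequence[start + k]) for k in range(m)):
            hits.append(start + 1)
    return hits


def classify_sequences(
    sequences: Mapping[str, str],
    motif: ConsensusMotif,
    region_window: tuple[int, int] | None = None,
) -> dict[str, bool]:
    """Per-id motif match table over ungapped sequences.

    With *region_window* (1-based start..end on each sequence), only the
    anchored window is tested; otherwise any window may match.
    """
    if len(motif) == 0:
        raise ValueError("motif must be non-empty")
    out: dict[str, bool] = {}
    for sid, seq in sequences.items():
        seq = seq.replace(GAP, "")
        if region_window is not None:
            start, end = region_window
            window = seq[start - 1 : end]
            out[sid] = len(window) == len(motif) and all(
                spec.matches(aa) for spec, aa in zip(motif.positions, window)
            )
        else:
            out[sid] = bool(match_motif(seq, motif))
    return out


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def consensus_report(
    path: str | Path,
    *,
    motif: ConsensusMotif,
    kept: Sequence[AlignmentRecord],
    removed: Sequence[RemovalLogEntry],
    parameters: Mapping[str, object],
) -> None:
    payload = {
        "motif": motif_to_string(motif),
        "reference_span": list(motif.reference_span) if motif.reference_span else None,
        "kept_ids": [r.id for r in kept],
        "removed": [
            {"removed": e.removed_id, "kept": e.kept_id, "identity": round(e.identity, 4)}
            for e in removed
        ],
        "parameters": dict(parameters),
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
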