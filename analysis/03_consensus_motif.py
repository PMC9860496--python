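#!/usr/bin/env python
"""Stage 3 — redundancy-filter the labelled E2 family and derive the motif.

Builds the packaged synthetic stand-in alignment (real UBE2L3 reference plus
generator-built high/low paralog stand-ins), removes sequences > 60%
identical to an already-kept record, maps reference residues 60-65 onto
alignment columns, derives the degenerate consensus from the high group, and
classifies every family member against it.

Writes results/consensus.json and results/motif_matches.tsv.
"""

import dataclasses
from pathlib import Path

from e2face.consensus import (
    AlignmentRecord,
    LabelledAlignment,
    classify_sequences,
    consensus_report,
    derive_consensus,
    map_reference_positions,
    motif_to_string,
    redundancy_filter,
)
from e2face.synthetic import reference_family, write_family

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    records, labels, truth = reference_family()
    write_family(records, labels, RESULTS / "e2_family.afa",
                 RESULTS / "e2_family.labels.tsv")
    aln = LabelledAlignment(
        [AlignmentRecord(i, s, labels[i]) for i, s in records], "UBE2L3")

    kept, removed = redundancy_filter(aln, identity_threshold=0.60)
    print(f"redundancy filter kept {len(kept)} of {len(aln.records)} records:")
    for e in removed:
        print(f"  removed {e.removed_id} ({e.identity:.0%} identical to {e.kept_id})")

    cols = map_reference_positions(dataclasses.replace(aln, records=kept), 60, 65)
    motif = derive_consensus(kept, cols, reference_span=(60, 65))
    motif_str = motif_to_string(motif)
    print(f"high-group consensus at reference span 60-65: {motif_str}")

    consensus_report(
        RESULTS / "consensus.json", motif=motif, kept=kept, removed=removed,
        parameters={"identity_threshold": 0.60, "tau_fix": 0.9, "tau_class": 0.9,
                    "low_filter": False, "span": [60, 65]},
    )
    table = classify_sequences({r.id: r.seq for r in aln.records}, motif,
                               region_window=(60, 65))
    lines = ["id\tlabel\tmatch"]
    for rec in aln.records:
        lines.append(f"{rec.id}\t{rec.label}\t{int(table[rec.id])}")
    (RESULTS / "motif_matches.tsv").write_text("\n".join(lines) + "\n")
    n_high = sum(table[r.id] for r in aln.records if r.label == "high")
    n_low = sum(table[r.id] for r in aln.records if r.label == "low")
    print(f"motif matches: {n_high}/{sum(r.label == 'high' for r in aln.records)} "
          f"high-group, {n_low}/{sum(r.label == 'low' for r in aln.records)} low-group")


if __name__ == "__main__":
    main()
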