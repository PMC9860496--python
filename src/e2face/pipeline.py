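"""End-to-end orchestration: structure → regions → alanine scan → consensus.

A :class:`RunConfig` collects every stage parameter; :func:`run_pipeline`
executes the stages in order, persisting each stage's artifact before the
next starts so a failed run retains its partial outputs, and writes a run
manifest (effective config + input checksums) that makes the run
reproducible byte for byte.
"""

from __future__ import annotations

import configparser
import dataclasses
import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import alascan, consensus, structure

logger = logging.getLogger("e2face")


@dataclass
class RunConfig:
    # structure stage
    structure_path: str = ""
    structure_format: str = "auto"
    query_chain: str = "A"
    partner_chain: str = "B"
    cutoff: float = 6.0
    aggregation: str = "any"  # any | all | count:K
    max_gap: int = 3
    include_hydrogens: bool = False
    # alanine-scan stage
    threshold: float = 2.5
    weights_config: str = ""
    # consensus stage
    alignment_path: str = ""
    alignment_format: str = "fasta_aligned"
    labels_path: str = ""
    reference_id: str = ""
    span_start: int = 0
    span_end: int = 0
    identity_threshold: float = 0.60
    tau_fix: float = 0.9
    tau_class: float = 0.9
    low_filter: bool = False
    tau_low: float = 0.5
    # bookkeeping
    seed: int = 0
    out_dir: str = "e2face_out"

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Flat key=value config with one section per stage; unknown keys are
        an error so typos fail fast."""
        parser = configparser.ConfigParser()
        with open(path) as fh:
            parser.read_file(fh)
        cfg = cls()
        fields = {f.name: f for f in dataclasses.fields(cls)}
        for section in parser.sections():
            for key, value in parser.items(section):
                if key not in fields:
                    raise ValueError(f"unknown config key {key!r} in [{section}]")
                ftype = fields[key].type
                if ftype == "bool":
                    setattr(cfg, key, parser.getboolean(section, key))
                elif ftype == "int":
                    setattr(cfg, key, int(value))
                elif ftype == "float":
                    setattr(cfg, key, float(value))
                else:
                    setattr(cfg, key, value)
        return cfg

    def aggregation_rule(self):
        if self.aggregation in ("any", "any_model"):
            return "any_model"
        if self.aggregation in ("all", "all_models"):
            return "all_models"
        if self.aggregation.startswith("count:"):
            return ("min_count", int(self.aggregation.split(":", 1)[1]))
        raise ValueError(f"bad aggregation {self.aggregation!r}")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run structure → regions → ala-scan → consensus → motif scan.

    Returns the summary dict (also written to ``summary.json``).  On a stage
    failure a :class:`StageError` naming the stage is raised; artifacts of
    completed stages remain on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter("%(asctime)s [%(stage)s] %(message)s"))
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
    summary: dict = {"stages": []}

    def log(stage: str, msg: str):
        logger.info(msg, extra={"stage": stage})

    manifest = {
        "config": dataclasses.asdict(config),
        "inputs": {},
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    for key in ("structure_path", "alignment_path", "labels_path"):
        p = getattr(config, key)
        if p and Path(p).exists():
            manifest["inputs"][key] = _sha256(Path(p))
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    # --- structure stage -------------------------------------------------
    stage = "structure"
    try:
        ensemble = structure.load_ensemble(config.structure_path, config.structure_format)
        log(stage, f"loaded {ensemble.n_models} models from {config.structure_path}")
    except Exception as exc:
        raise StageError(stage, exc)

    stage = "interface"
    try:
        support = structure.interface_residues(
            ensemble,
            config.query_chain,
            config.partner_chain,
            cutoff_angstrom=config.cutoff,
            aggregation=config.aggregation_rule(),
            include_hydrogens=config.include_hydrogens,
        )
        regions = structure.merge_regions(
            support, max_gap=config.max_gap, chain_id=config.query_chain, support=support
        )
        structure.regions_to_tsv(regions, out / "regions.tsv")
        structure.run_metadata_json(
            out / "regions.json",
            cutoff=config.cutoff,
            aggregation=config.aggregation_rule(),
            max_gap=config.max_gap,
            include_hydrogens=config.include_hydrogens,
            source_id=ensemble.source_id,
            n_models=ensemble.n_models,
            regions=regions,
        )
        summary["stages"].append(stage)
        summary["regions"] = [[r.start, r.end] for r in regions]
        log(stage, f"{len(regions)} interface regions")
    except Exception as exc:
        raise StageError(stage, exc)

    stage = "alascan"
    try:
        weights = (
            alascan.load_weights_config(config.weights_config)
            if config.weights_config
            else None
        )
        members = [m for r in regions for m in r.members]
        profile = alascan.scan_ensemble(
            ensemble,
            members,
            config.query_chain,
            config.partner_chain,
            threshold=config.threshold,
            weights=weights,
        )
        alascan.profile_to_tsv(profile, ensemble, config.query_chain, out / "ala_scan.tsv")
        summary["stages"].append(stage)
        summary["hot_spots"] = sorted(profile.hot_spots)
        log(stage, f"hot spots: {sorted(profile.hot_spots)}")
    except Exception as exc:
        raise StageError(stage, exc)

    stage = "consensus"
    try:
        aln = consensus.read_alignment(
            config.alignment_path,
            config.labels_path,
            config.reference_id,
            format=config.alignment_format,
        )
        kept, removed = consensus.redundancy_filter(aln, config.identity_threshold)
        columns = consensus.map_reference_positions(
            dataclasses.replace(aln, records=kept), config.span_start, config.span_end
        )
        motif = consensus.derive_consensus(
            kept,
            columns,
            tau_fix=config.tau_fix,
            tau_class=config.tau_class,
            use_low_group_filter=config.low_filter,
            tau_low=config.tau_low,
            reference_span=(config.span_start, config.span_end),
        )
        motif_str = consensus.motif_to_string(motif)
        consensus.consensus_report(
            out / "consensus.json",
            motif=motif,
            kept=kept,
            removed=removed,
            parameters={
                "identity_threshold": config.identity_threshold,
                "tau_fix": config.tau_fix,
                "tau_class": config.tau_class,
                "low_filter": config.low_filter,
                "tau_low": config.tau_low,
                "span": [config.span_start, config.span_end],
            },
        )
        summary["stages"].append(stage)
        summary["motif"] = motif_str
        log(stage, f"motif: {motif_str}")
    except Exception as exc:
        raise StageError(stage, exc)

    stage = "scan"
    try:
        table = consensus.classify_sequences(
            {r.id: r.seq for r in aln.records},
            motif,
            region_window=(config.span_start, config.span_end),
        )
        lines = ["id\tlabel\tmatch"]
        for rec in aln.records:
            lines.append(f"{rec.id}\t{rec.label}\t{int(table[rec.id])}")
        (out / "motif_matches.tsv").write_text("\n".join(lines) + "\n")
        summary["stages"].append(stage)
        summary["match_table"] = table
    except Exception as exc:
        raise StageError(stage, exc)

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary
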