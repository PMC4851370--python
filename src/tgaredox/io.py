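"""File I/O: FASTA, result tables and YAML configuration."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .motif import ClassifierParams, MotifCall, ReferenceMotif

__all__ = [
    "read_fasta",
    "write_fasta",
    "calls_to_frame",
    "load_motif_config",
    "load_species_map",
]


def read_fasta(path) -> list[tuple[str, str]]:
    return [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Iterable[tuple[str, str]], path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records),
        str(path),
        "fasta",
    )


def calls_to_frame(calls: Iterable[tuple[MotifCall, bool]]) -> pd.DataFrame:
    """Motif calls (with best flags) as the standard result table."""
    rows = [
        {
            "seq_id": c.seq_id,
            "window_start": c.window_start,
            "strand": c.strand,
            "window_seq": c.window_seq,
            "deviations": c.deviations,
            "core_present": c.core_present,
            "core_strand": c.core_strand,
            "motif_class": c.motif_class,
            "canonical_partial": c.canonical_partial,
            "best_flag": best,
        }
        for c, best in calls
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "seq_id", "window_start", "strand", "window_seq", "deviations",
            "core_present", "core_strand", "motif_class", "canonical_partial",
            "best_flag",
        ],
    )
    for col in ("window_start", "deviations"):
        df[col] = df[col].astype("Int64")
    return df


def load_motif_config(path) -> tuple[ReferenceMotif, ClassifierParams]:
    """Load the reference motif and classifier thresholds from YAML.

    Expected keys: ``reference: {sequence, hexamer_offset, core,
    degenerate_positions}`` and ``classifier: {max_dev_full,
    min_dev_partial_report, core_both_strands, count_degenerate_as_match}``;
    missing classifier keys fall back to defaults.
    """
    cfg = yaml.safe_load(Path(path).read_text())
    ref_cfg = cfg["reference"]
    ref = ReferenceMotif(
        sequence=ref_cfg["sequence"],
        hexamer_offset=int(ref_cfg["hexamer_offset"]),
        core=ref_cfg.get("core", "TGACG"),
        degenerate_positions={
            int(k): frozenset(str(v)) for k, v in ref_cfg.get(
                "degenerate_positions", {}
            ).items()
        }
        or None,
    )
    params = ClassifierParams(**cfg.get("classifier", {}))
    return ref, params


def load_species_map(path) -> dict[str, str]:
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ValueError("species map YAML must be a mapping id -> species")
    return {str(k): str(v) for k, v in data.items()}
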