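"""Equivalent-cysteine calling and N-terminal extension annotation.

A reference TGA-family protein (PAN-like) carries redox-active cysteines at
known residue positions — by default 27, 68, 87, 114, 154 in the N-terminal
extension and 340 in the C-terminal region.  Given a protein multiple
alignment containing the reference, this module maps each reference position
to its alignment column and reports, per homolog, the residue occupying that
column ("equivalent" means a cysteine at the exact column).  It also
annotates the homolog N-termini: the stretch preceding the basic (bZIP)
region, its length, and its percent identity to the reference N-terminus.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "ProteinAlignment",
    "CysCall",
    "CysEquivalenceTable",
    "NTerminusAnnotation",
    "NTermParams",
    "DEFAULT_REFERENCE_POSITIONS",
    "map_position",
    "call_equivalents",
    "detect_bzip_start",
    "annotate_n_terminus",
]

DEFAULT_REFERENCE_POSITIONS = (27, 68, 87, 114, 154, 340)

GAP = "-"


@dataclass
class ProteinAlignment:
    """An ordered protein multiple alignment with a designated reference row."""

    records: list[tuple[str, str]]
    reference_id: str

    def __post_init__(self):
        if not self.records:
            raise ValueError("alignment is empty")
        lengths = {len(s) for _, s in self.records}
        if len(lengths) != 1:
            raise ValueError(f"aligned sequences have unequal lengths {sorted(lengths)}")
        self.records = [(i, s.upper()) for i, s in self.records]
        if self.reference_id not in self.ids:
            raise ValueError(f"reference id {self.reference_id!r} not in alignment")

    @property
    def ids(self) -> list[str]:
        return [i for i, _ in self.records]

    @property
    def length(self) -> int:
        return len(self.records[0][1])

    def row(self, seq_id: str) -> str:
        for i, s in self.records:
            if i == seq_id:
                return s
        raise KeyError(seq_id)

    def ungapped(self, seq_id: str) -> str:
        return self.row(seq_id).replace(GAP, "")

    @classmethod
    def from_file(cls, path, reference_id: str, fmt: str | None = None) -> "ProteinAlignment":
        """Read an aligned FASTA or Clustal file via Bio.AlignIO."""
        from Bio import AlignIO

        if fmt is None:
            fmt = "clustal" if str(path).endswith((".aln", ".clustal")) else "fasta"
        aln = AlignIO.read(str(path), fmt)
        return cls([(r.id, str(r.seq)) for r in aln], reference_id)


def map_position(aln: ProteinAlignment, ref_pos: int) -> int:
    """Alignment column (0-based) of the ref_pos-th (1-based) reference residue."""
    if ref_pos < 1:
        raise ValueError(f"ref_pos must be >= 1, got {ref_pos}")
    ref_row = aln.row(aln.reference_id)
    seen = 0
    for col, ch in enumerate(ref_row):
        if ch != GAP:
            seen += 1
            if seen == ref_pos:
                return col
    raise ValueError(
        f"ref_pos {ref_pos} beyond ungapped reference length {seen}"
    )


@dataclass(frozen=True)
class CysCall:
    id: str
    position: int  # 1-based reference residue index
    column: int  # 0-based alignment column
    residue_found: str
    is_cysteine: bool


@dataclass
class CysEquivalenceTable:
    reference_positions: list[int]
    entries: list[CysCall]

    def equivalent_count(self, seq_id: str) -> int:
        return sum(1 for e in self.entries if e.id == seq_id and e.is_cysteine)

    @property
    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for e in self.entries:
            out.setdefault(e.id, 0)
            if e.is_cysteine:
                out[e.id] += 1
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (e.id, e.position, e.column, e.residue_found, e.is_cysteine)
                for e in self.entries
            ],
            columns=["id", "position", "column", "residue", "is_cysteine"],
        )


def call_equivalents(
    aln: ProteinAlignment,
    positions: Sequence[int] = DEFAULT_REFERENCE_POSITIONS,
) -> CysEquivalenceTable:
    """Report the residue of every homolog at each reference-cysteine column.

    A gap at the mapped column is reported as ``-`` and never cysteine;
    comparison is case-insensitive and ``X`` is never cysteine-equivalent.
    """
    cols = {p: map_position(aln, p) for p in positions}
    entries = []
    for seq_id, row in aln.records:
        for p in positions:
            res = row[cols[p]]
            entries.append(
                CysCall(
                    id=seq_id,
                    position=p,
                    column=cols[p],
                    residue_found=res,
                    is_cysteine=res == "C",
                )
            )
    return CysEquivalenceTable(list(positions), entries)


@dataclass(frozen=True)
class NTermParams:
    """Thresholds for N-terminus classification.

    ``significant_identity_pct`` — minimum percent identity against the
    reference N-terminus to call the extension homology SIGNIFICANT (a
    conventional twilight-zone cut).  ``min_extension_length`` — residues
    required before the basic region for the extension to count at all.
    ``bzip_window`` / ``bzip_basic_fraction`` — detector window width and
    minimum K/R fraction for locating the basic region.
    """

    significant_identity_pct: float = 30.0
    min_extension_length: int = 20
    bzip_window: int = 16
    bzip_basic_fraction: float = 0.4


@dataclass(frozen=True)
class NTerminusAnnotation:
    id: str
    bzip_start: int | None  # 1-based; None when undetectable
    extension_length: int | None
    pct_identity_vs_ref_nterm: float | None
    homology_class: str  # SIGNIFICANT | LOW | ABSENT | NA
    truncated: bool = False


def detect_bzip_start(
    protein_seq: str,
    params: NTermParams = NTermParams(),
) -> int | None:
    """First window of width w whose K/R fraction reaches the threshold.

    Returns the 1-based start of that window or None.  The bZIP basic region
    of TGA factors sits close to the N-terminus and is rich in lysine and
    arginine, which is what this heuristic keys on; config-supplied
    coordinates always take precedence over detection.
    """
    seq = protein_seq.upper().replace(GAP, "")
    w = params.bzip_window
    if len(seq) < w:
        return None
    basic = [1 if c in "KR" else 0 for c in seq]
    run = sum(basic[:w])
    best = 0 if run / w >= params.bzip_basic_fraction else None
    i = 0
    while best is None and i + w < len(seq):
        run += basic[i + w] - basic[i]
        i += 1
        if run / w >= params.bzip_basic_fraction:
            best = i
    if best is None:
        return None
    # anchor on the first basic residue of the qualifying window so the
    # reported start is the basic region itself, not leading non-basic slack
    while best < len(seq) and not basic[best]:
        best += 1
    return best + 1


def annotate_n_terminus(
    aln: ProteinAlignment,
    seq_id: str,
    bzip_start_map: Mapping[str, int] | None = None,
    params: NTermParams = NTermParams(),
    *,
    truncated_ids: Iterable[str] = (),
) -> NTerminusAnnotation:
    """Annotate one homolog's N-terminal extension.

    ``extension_length`` counts ungapped residues before the homolog's basic
    region; percent identity is computed over alignment columns N-terminal of
    the *reference's* basic-region column, across columns where neither
    sequence is gapped.  Ids listed in ``truncated_ids`` (e.g. homologs with
    no defined start codon) are flagged and given no extension length.
    """
    if seq_id not in aln.ids:
        raise ValueError(f"id {seq_id!r} absent from alignment")
    bzip_start_map = bzip_start_map or {}

    if seq_id in set(truncated_ids):
        return NTerminusAnnotation(seq_id, None, None, None, "NA", truncated=True)

    def bzip_of(sid: str) -> int | None:
        if sid in bzip_start_map:
            return int(bzip_start_map[sid])
        return detect_bzip_start(aln.ungapped(sid), params)

    ref_bzip = bzip_of(aln.reference_id)
    own_bzip = bzip_of(seq_id)
    if own_bzip is None or ref_bzip is None:
        return NTerminusAnnotation(seq_id, own_bzip, None, None, "NA")

    extension_length = own_bzip - 1
    ref_bzip_col = map_position(aln, ref_bzip)
    ref_row = aln.row(aln.reference_id)
    own_row = aln.row(seq_id)
    compared = matched = 0
    for col in range(ref_bzip_col):
        a, b = ref_row[col], own_row[col]
        if a != GAP and b != GAP:
            compared += 1
            if a == b and a != "X":
                matched += 1
    pct = 100.0 * matched / compared if compared else 0.0

    if extension_length < params.min_extension_length:
        cls = "ABSENT"
    elif pct >= params.significant_identity_pct:
        cls = "SIGNIFICANT"
    else:
        cls = "LOW"
    return NTerminusAnnotation(seq_id, own_bzip, extension_length, pct, cls)
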