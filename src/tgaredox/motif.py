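"""Scan nucleotide sequences for AAGAAT-element candidates and classify them.

The element modelled here is a 33-bp regulatory motif from the second intron
of *AGAMOUS*: it carries an AAGAAT hexamer (whose first A is degenerate and
may be C or T) and a central TGACG core, the minimal binding requirement for
TGA-family bZIP transcription factors.  Candidates anchored at a (degenerate)
hexamer occurrence are aligned against a fixed-length reference window and
classified by an ungapped deviation count plus core presence:

* ``FULL``    — TGACG core present (either strand) and at most
  ``max_dev_full`` (default 7) deviations from the reference window.
* ``PARTIAL`` — hexamer present but FULL criteria fail.  Windows lacking the
  core with more than ``min_dev_partial_report`` (default 15) deviations are
  additionally flagged as *canonical* partial motifs.
* ``ABSENT``  — the sequence contains no hexamer occurrence at all.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "ReferenceMotif",
    "ClassifierParams",
    "MotifCall",
    "DEFAULT_REFERENCE",
    "revcomp",
    "find_hexamer_sites",
    "extract_window",
    "count_deviations",
    "has_tga_core",
    "classify",
    "scan_sequence",
    "scan_records",
]

HEXAMER = "AAGAAT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID = set("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse-complement a nucleotide string (alphabet ACGTN; N maps to N)."""
    for i, ch in enumerate(seq):
        if ch.upper() not in _VALID:
            raise ValueError(f"non-nucleotide character {ch!r} at position {i}")
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ReferenceMotif:
    """The fixed-length reference element a candidate window is compared to.

    Parameters
    ----------
    sequence
        Reference window (default length 33) containing the AAGAAT hexamer.
    hexamer_offset
        0-based index of the hexamer within the window.
    core
        TGA-factor core binding site (default ``TGACG``).
    degenerate_positions
        Window index -> set of nucleotides that count as a match there.  By
        default the first hexamer position admits {A, C, T}.
    """

    sequence: str
    hexamer_offset: int
    core: str = "TGACG"
    degenerate_positions: Mapping[int, frozenset] | None = None

    def __post_init__(self):
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not set(seq) <= _VALID:
            bad = sorted(set(seq) - _VALID)
            raise ValueError(f"reference contains non-nucleotide characters {bad}")
        if self.hexamer_offset < 0 or self.hexamer_offset + len(HEXAMER) > len(seq):
            raise ValueError("hexamer_offset places the hexamer outside the window")
        if seq[self.hexamer_offset : self.hexamer_offset + len(HEXAMER)] != HEXAMER:
            raise ValueError(
                f"reference lacks {HEXAMER} at offset {self.hexamer_offset}"
            )
        if self.degenerate_positions is None:
            object.__setattr__(
                self,
                "degenerate_positions",
                {self.hexamer_offset: frozenset("ACT")},
            )
        else:
            object.__setattr__(
                self,
                "degenerate_positions",
                {int(k): frozenset(v) for k, v in self.degenerate_positions.items()},
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def hexamer_pattern(self) -> str:
        """Regex for the hexamer with degeneracy applied at its own positions."""
        parts = []
        for i, ch in enumerate(HEXAMER):
            allowed = self.degenerate_positions.get(self.hexamer_offset + i)
            if allowed and ch in allowed:
                parts.append("[" + "".join(sorted(allowed)) + "]")
            else:
                parts.append(ch)
        return "".join(parts)


# Synthetic default window for tests and examples: AAGAAT hexamer at offset 4
# and the TGACG core in reverse-complement orientation (CGTCA), the orientation
# in which the core occurs in the Arabidopsis element.  Configure the real
# 33-bp AGAMOUS-intron element via ReferenceMotif for genomic work.
DEFAULT_REFERENCE = ReferenceMotif(
    sequence="TCCTAAGAATATAACGTCAGGATTCATTGGCAT",
    hexamer_offset=4,
)


@dataclass(frozen=True)
class ClassifierParams:
    """Thresholds of the full/partial discrimination rule."""

    max_dev_full: int = 7
    min_dev_partial_report: int = 15
    core_both_strands: bool = True
    count_degenerate_as_match: bool = True

    def validate(self, window_length: int) -> None:
        if not 0 <= self.max_dev_full < self.min_dev_partial_report <= window_length:
            raise ValueError(
                "require 0 <= max_dev_full < min_dev_partial_report <= window length"
            )


@dataclass(frozen=True)
class MotifCall:
    """One classified candidate window (or an ABSENT placeholder).

    ``window_start`` is the 0-based forward-strand coordinate of the leftmost
    base of the window; ``window_seq`` is given in reference orientation, i.e.
    for a minus-strand call it is the reverse complement of the forward slice.
    """

    seq_id: str
    window_start: int | None
    strand: str  # '+', '-', or '.' for ABSENT
    window_seq: str | None
    deviations: int | None
    core_present: bool
    core_strand: str  # '+', '-', 'none'
    motif_class: str  # FULL | PARTIAL | ABSENT
    canonical_partial: bool = False


def find_hexamer_sites(seq: str, ref: ReferenceMotif) -> list[tuple[int, str]]:
    """Locate (degenerate) AAGAAT hexamer occurrences on both strands.

    Returns ``(position, strand)`` pairs in forward coordinates, where
    ``position`` is the 0-based start of the 6-mer on the forward strand.
    Sorted by position with '+' before '-' at ties.
    """
    seq = seq.upper()
    pat = ref.hexamer_pattern()
    fwd = re.compile("(?=(" + pat + "))")
    hits = [(m.start(), "+") for m in fwd.finditer(seq)]
    # A minus-strand hexamer reads as the reverse complement on the forward
    # strand; build that pattern from the degenerate one.
    rc_pat = "".join(
        reversed(
            [
                "[" + "".join(sorted(revcomp(c) for c in p[1:-1])) + "]"
                if p.startswith("[")
                else revcomp(p)
                for p in re.findall(r"\[[A-Z]+\]|[A-Z]", pat)
            ]
        )
    )
    rev = re.compile("(?=(" + rc_pat + "))")
    hits += [(m.start(), "-") for m in rev.finditer(seq)]
    hits.sort(key=lambda h: (h[0], h[1] != "+"))
    return hits


def extract_window(
    seq: str, hit_position: int, strand: str, ref: ReferenceMotif
) -> tuple[str, int] | None:
    """Cut the L-nt window whose hexamer aligns with the reference's offset.

    Returns ``(window_seq, window_start)`` with the window in reference
    orientation, or None when the window would overrun either sequence end.
    """
    seq = seq.upper()
    L = ref.length
    if strand == "+":
        start = hit_position - ref.hexamer_offset
    elif strand == "-":
        # rc(seq[start:start+L]) must carry the hexamer at hexamer_offset
        start = hit_position + len(HEXAMER) + ref.hexamer_offset - L
    else:
        raise ValueError(f"invalid strand {strand!r}")
    if start < 0 or start + L > len(seq):
        return None
    window = seq[start : start + L]
    if strand == "-":
        window = revcomp(window)
    return window, start


def count_deviations(window_seq: str, ref: ReferenceMotif, *, count_degenerate_as_match: bool = True) -> int:
    """Ungapped Hamming deviation count of a window against the reference.

    A position listed in ``degenerate_positions`` matches any letter of its
    allowed set (unless the policy disables this); N always deviates.
    """
    window_seq = window_seq.upper()
    if len(window_seq) != ref.length:
        raise ValueError(
            f"window length {len(window_seq)} != reference length {ref.length}"
        )
    dev = 0
    for i, (w, r) in enumerate(zip(window_seq, ref.sequence)):
        if w == "N":
            dev += 1
            continue
        allowed = ref.degenerate_positions.get(i) if count_degenerate_as_match else None
        if allowed is not None:
            if w not in allowed:
                dev += 1
        elif w != r:
            dev += 1
    return dev


def has_tga_core(
    window_seq: str, ref: ReferenceMotif, params: ClassifierParams
) -> tuple[bool, str]:
    """Test for the TGACG core in the window, on either strand by default.

    Returns ``(core_present, core_strand)``; with occurrences on both strands
    the strand of the leftmost occurrence wins.
    """
    window_seq = window_seq.upper()
    occ: list[tuple[int, str]] = []
    i = window_seq.find(ref.core)
    if i >= 0:
        occ.append((i, "+"))
    if params.core_both_strands:
        j = window_seq.find(revcomp(ref.core))
        if j >= 0:
            occ.append((j, "-"))
    if not occ:
        return False, "none"
    occ.sort(key=lambda o: (o[0], o[1] != "+"))
    return True, occ[0][1]


def classify(
    window_seq: str,
    ref: ReferenceMotif,
    params: ClassifierParams,
    *,
    seq_id: str = "",
    window_start: int | None = None,
    strand: str = "+",
) -> MotifCall:
    """Apply the full/partial discrimination rule to one candidate window.

    FULL requires the core and at most ``max_dev_full`` deviations; every
    other hexamer-anchored window is PARTIAL.  A PARTIAL window without core
    and with more than ``min_dev_partial_report`` deviations carries the
    canonical-partial flag.
    """
    params.validate(ref.length)
    dev = count_deviations(
        window_seq, ref, count_degenerate_as_match=params.count_degenerate_as_match
    )
    core_present, core_strand = has_tga_core(window_seq, ref, params)
    if core_present and dev <= params.max_dev_full:
        cls = "FULL"
        canonical = False
    else:
        cls = "PARTIAL"
        canonical = (not core_present) and dev > params.min_dev_partial_report
    return MotifCall(
        seq_id=seq_id,
        window_start=window_start,
        strand=strand,
        window_seq=window_seq.upper(),
        deviations=dev,
        core_present=core_present,
        core_strand=core_strand,
        motif_class=cls,
        canonical_partial=canonical,
    )


_CLASS_RANK = {"FULL": 0, "PARTIAL": 1, "ABSENT": 2}


def _call_order(call: MotifCall):
    return (
        _CLASS_RANK[call.motif_class],
        call.deviations,
        call.window_start,
        call.strand != "+",
    )


def scan_sequence(
    seq: str,
    ref: ReferenceMotif = DEFAULT_REFERENCE,
    params: ClassifierParams = ClassifierParams(),
    *,
    seq_id: str = "",
) -> tuple[MotifCall, list[MotifCall]]:
    """Classify every hexamer-anchored candidate window in one sequence.

    Returns ``(best, all_calls)``.  The best call has the highest class
    (FULL > PARTIAL), breaking ties by fewer deviations, then leftmost
    window start, then '+' strand.  A sequence with no hexamer hit yields a
    single ABSENT call.
    """
    if not seq:
        raise ValueError("empty sequence")
    calls: list[MotifCall] = []
    for pos, strand in find_hexamer_sites(seq, ref):
        extracted = extract_window(seq, pos, strand, ref)
        if extracted is None:
            continue
        window, start = extracted
        calls.append(
            classify(
                window, ref, params, seq_id=seq_id, window_start=start, strand=strand
            )
        )
    if not calls:
        absent = MotifCall(
            seq_id=seq_id,
            window_start=None,
            strand=".",
            window_seq=None,
            deviations=None,
            core_present=False,
            core_strand="none",
            motif_class="ABSENT",
        )
        return absent, [absent]
    calls.sort(key=_call_order)
    return calls[0], calls


def scan_records(
    records: Iterable[tuple[str, str]],
    ref: ReferenceMotif = DEFAULT_REFERENCE,
    params: ClassifierParams = ClassifierParams(),
    *,
    all_hits: bool = False,
):
    """Scan ``(id, sequence)`` records; yield MotifCalls with best flags.

    Yields ``(call, is_best)`` pairs per record; with ``all_hits`` False only
    the best call per record is yielded.
    """
    for seq_id, seq in records:
        best, calls = scan_sequence(seq, ref, params, seq_id=seq_id)
        if all_hits:
            for c in calls:
                yield c, c is best
        else:
            yield best, True
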