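"""Seeded synthetic inputs for every pipeline stage.

Three generators emulate the data each stage consumes, with exact truth
tables so downstream recovery is scoreable without re-reading generator
internals:

* :func:`gen_intron` — an i.i.d.-background intron with reference-motif
  copies planted at controlled deviation counts, with or without an intact
  TGACG core (the core is broken by a two-nucleotide exchange, the edit size
  shown to abolish TGA binding).
* :func:`gen_protein_family` — a designed protein family alignment: a
  reference with cysteines at the profiled positions, homologs with chosen
  N-terminal extension lengths, per-position cysteine patterns and target
  N-terminal identities.
* :func:`gen_mass_list` — observed neutral-mass lists from an in-silico
  digest with planted modification hypotheses plus Gaussian measurement
  noise.

All generators are deterministic functions of their seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import massdelta
from .cysprofile import NTermParams, ProteinAlignment
from .motif import (
    DEFAULT_REFERENCE,
    ClassifierParams,
    ReferenceMotif,
    classify,
    revcomp,
)

__all__ = [
    "PlantedMotif",
    "HomologDesign",
    "gen_intron",
    "gen_protein_family",
    "gen_mass_list",
]

_NT = np.array(list("ACGT"))


@dataclass(frozen=True)
class PlantedMotif:
    """One motif copy to plant: deviation count, core status, 0-based position."""

    deviations: int
    core_intact: bool
    position: int


def _random_background(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_NT, size=length, p=p))


def _core_spans(ref: ReferenceMotif) -> list[tuple[int, int]]:
    """Spans of every core occurrence (either orientation) in the reference."""
    spans = []
    for pat in (ref.core, revcomp(ref.core)):
        start = 0
        while True:
            i = ref.sequence.find(pat, start)
            if i < 0:
                break
            spans.append((i, i + len(pat)))
            start = i + 1
    return spans


def _plant_window(
    rng: np.random.Generator,
    ref: ReferenceMotif,
    deviations: int,
    core_intact: bool,
    params: ClassifierParams,
    max_tries: int = 200,
) -> tuple[str, int]:
    """Build a reference copy with exactly `deviations` substitutions.

    Substitutions avoid the hexamer and every core occurrence so the count is
    realized exactly; when the core is to be broken, two core nucleotides are
    exchanged in addition (adding 2 to the realized deviation count).  The
    realized window is re-scored and redrawn until deviations, core status
    and class match the design, keeping truth tables exact.
    """
    L = ref.length
    hex_span = set(range(ref.hexamer_offset, ref.hexamer_offset + 6))
    core_pos = set()
    for a, b in _core_spans(ref):
        core_pos.update(range(a, b))
    free = sorted(set(range(L)) - hex_span - core_pos - set(ref.degenerate_positions))
    if deviations > len(free):
        raise ValueError(
            f"cannot realize {deviations} deviations: only {len(free)} free positions"
        )
    for _ in range(max_tries):
        window = list(ref.sequence)
        for i in rng.choice(len(free), size=deviations, replace=False):
            pos = free[int(i)]
            choices = [c for c in "ACGT" if c != window[pos]]
            window[pos] = choices[int(rng.integers(len(choices)))]
        realized_dev = deviations
        if not core_intact:
            # two-nucleotide exchange inside the (first) core occurrence
            a, b = _core_spans(ref)[0]
            idx = rng.choice(b - a, size=2, replace=False)
            for j in idx:
                pos = a + int(j)
                choices = [c for c in "ACGT" if c != window[pos]]
                window[pos] = choices[int(rng.integers(len(choices)))]
            realized_dev += 2
        w = "".join(window)
        call = classify(w, ref, params)
        if call.deviations == realized_dev and call.core_present == core_intact:
            return w, realized_dev
    raise RuntimeError("failed to realize planted window design")


def gen_intron(
    planted: Sequence[PlantedMotif],
    *,
    seed: int,
    intron_length: int = 500,
    background_gc: float = 0.36,
    ref: ReferenceMotif = DEFAULT_REFERENCE,
    params: ClassifierParams = ClassifierParams(),
    seq_id: str = "synthetic_intron",
) -> tuple[tuple[str, str], pd.DataFrame]:
    """One synthetic intron record plus its truth table.

    The default background GC of 0.36 approximates Arabidopsis intron
    composition.  Returns ``((id, sequence), truth)`` where truth has one row
    per planted motif: position, requested and realized deviations, core
    status, and the class the classifier is expected to call.
    """
    rng = np.random.default_rng(seed)
    L = ref.length
    occupied: list[tuple[int, int]] = []
    for pm in planted:
        if pm.position < 0 or pm.position + L > intron_length:
            raise ValueError(f"planted motif at {pm.position} does not fit")
        for a, b in occupied:
            if pm.position < b and a < pm.position + L:
                raise ValueError("overlapping planted windows")
        occupied.append((pm.position, pm.position + L))

    seq = list(_random_background(rng, intron_length, background_gc))
    rows = []
    for pm in planted:
        window, realized = _plant_window(
            rng, ref, pm.deviations, pm.core_intact, params
        )
        seq[pm.position : pm.position + L] = window
        call = classify(window, ref, params)
        rows.append(
            {
                "position": pm.position,
                "requested_deviations": pm.deviations,
                "deviations": realized,
                "core_intact": pm.core_intact,
                "expected_class": call.motif_class,
            }
        )
    truth = pd.DataFrame(
        rows,
        columns=[
            "position",
            "requested_deviations",
            "deviations",
            "core_intact",
            "expected_class",
        ],
    )
    return (seq_id, "".join(seq)), truth


@dataclass(frozen=True)
class HomologDesign:
    """Design for one synthetic homolog.

    ``cys_pattern`` is a string over the profiled reference positions, 'C'
    for an equivalent cysteine and 'X' for its absence (realized as serine).
    ``nterm_identity`` is the target fractional identity of the aligned
    extension columns to the reference N-terminus.
    """

    id: str
    extension_length: int
    cys_pattern: str
    nterm_identity: float = 0.8


_AA_NO_KRC = np.array(list("ADEFGHILMNPQSTVWY"))  # no K/R (bZIP detector), no C


def gen_protein_family(
    designs: Sequence[HomologDesign],
    *,
    seed: int,
    reference_id: str = "REF",
    reference_length: int = 360,
    bzip_start: int = 167,
    cys_positions: Sequence[int] = (27, 68, 87, 114, 154),
    always_cys: Sequence[int] = (340,),
    nterm_params: NTermParams = NTermParams(),
) -> tuple[ProteinAlignment, pd.DataFrame]:
    """A designed family alignment plus per-homolog truth table.

    The reference carries cysteines at ``cys_positions`` (N-terminal of the
    basic region at ``bzip_start``) and at ``always_cys`` (present in every
    homolog, emulating the universally conserved C-terminal cysteine).  Each
    homolog shares the reference body from the basic region onward; its
    extension occupies the C-terminal-most extension columns, gap-padded at
    the alignment's N-terminal edge, with identity to the reference tuned to
    the design target.  Truth rows hold the expected equivalent-cysteine
    count (pattern positions actually covered by the extension), the realized
    N-terminal identity and the expected homology class.
    """
    rng = np.random.default_rng(seed)
    ext_ref = bzip_start - 1
    for p in cys_positions:
        if not 1 <= p <= ext_ref:
            raise ValueError(f"cys position {p} outside the reference extension")
    for d in designs:
        if len(d.cys_pattern) > len(cys_positions):
            raise ValueError(
                f"{d.id}: pattern longer than the profiled position list"
            )
        if d.extension_length > ext_ref:
            raise ValueError(f"{d.id}: extension longer than the reference's")

    ref_seq = list(rng.choice(_AA_NO_KRC, size=reference_length))
    w = nterm_params.bzip_window
    ref_seq[ext_ref : ext_ref + w] = list("KR" * (w // 2) + "K" * (w % 2))
    for p in list(cys_positions) + list(always_cys):
        ref_seq[p - 1] = "C"
    ref_seq = "".join(ref_seq)

    records = [(reference_id, ref_seq)]
    rows = []
    for d in designs:
        pattern = d.cys_pattern.upper().ljust(len(cys_positions), "X")
        e = d.extension_length
        body = ref_seq[ext_ref:]
        ext_cols = range(ext_ref - e, ext_ref)  # alignment columns of the extension
        ext = []
        for col in ext_cols:
            if rng.random() < d.nterm_identity:
                ext.append(ref_seq[col])
            else:
                choices = _AA_NO_KRC[_AA_NO_KRC != ref_seq[col]]
                ext.append(str(rng.choice(choices)))
        row = ["-"] * (ext_ref - e) + ext + list(body)
        # apply the cysteine pattern at the mapped columns
        expected = 0
        for p, ch in zip(cys_positions, pattern):
            col = p - 1
            if row[col] == "-":
                continue
            if ch == "C":
                row[col] = "C"
                expected += 1
            else:
                row[col] = "S"
        for p in always_cys:
            row[p - 1] = "C"
        row = "".join(row)
        records.append((d.id, row))

        compared = matched = 0
        for col in range(ext_ref):
            if row[col] != "-":
                compared += 1
                if row[col] == ref_seq[col]:
                    matched += 1
        pct = 100.0 * matched / compared if compared else 0.0
        if e < nterm_params.min_extension_length:
            cls = "ABSENT"
        elif pct >= nterm_params.significant_identity_pct:
            cls = "SIGNIFICANT"
        else:
            cls = "LOW"
        rows.append(
            {
                "id": d.id,
                "extension_length": e,
                "expected_equivalent_count": expected,
                "realized_nterm_identity_pct": pct,
                "expected_homology_class": cls,
            }
        )
    truth = pd.DataFrame(rows)
    aln = ProteinAlignment(records, reference_id)
    return aln, truth


def gen_mass_list(
    protein: str,
    planted: Sequence[tuple[int, str]],
    *,
    seed: int,
    noise_sd: float = 0.01,
    max_missed: int = 1,
    scale: str = "monoisotopic",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Observed-mass list with planted cysteine modifications plus truth.

    ``planted`` pairs a peptide index (into the AspN digest of ``protein``)
    with a hypothesis kind (NONE / GLUTATHIONYLATION / INTRA_DISULFIDE).
    Observed mass = predicted(hypothesis) + Normal(0, noise_sd).  Returns
    ``(observed, truth)`` DataFrames; observed has columns (id, mass), truth
    adds the generating peptide span, kind and noiseless predicted mass.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    peptides = massdelta.digest(protein, max_missed=max_missed)
    hyp_factory = {
        "NONE": massdelta.NONE,
        "GLUTATHIONYLATION": massdelta.GLUTATHIONYLATION,
        "INTRA_DISULFIDE": massdelta.INTRA_DISULFIDE,
    }
    obs_rows, truth_rows = [], []
    for k, (idx, kind) in enumerate(planted):
        pep = peptides[idx]
        try:
            hyp = hyp_factory[kind]()
        except KeyError:
            raise ValueError(f"unknown planted hypothesis kind {kind!r}") from None
        predicted = massdelta.apply_hypothesis(pep, hyp, scale)  # raises if inapplicable
        mass = predicted + rng.normal(0.0, noise_sd) if noise_sd else predicted
        obs_id = f"obs{k:03d}"
        obs_rows.append({"id": obs_id, "mass": mass})
        truth_rows.append(
            {
                "id": obs_id,
                "peptide_index": idx,
                "peptide_span": pep.span,
                "kind": kind,
                "predicted_mass": predicted,
            }
        )
    return pd.DataFrame(obs_rows), pd.DataFrame(truth_rows)
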