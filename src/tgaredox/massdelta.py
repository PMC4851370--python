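"""In-silico AspN digestion and delta-mass assignment of cysteine modifications.

The workflow mirrors a neutral-mass-level MS comparison: digest a protein
with endoproteinase AspN (cleaving N-terminal to aspartate), compute peptide
masses, enumerate modification hypotheses for cysteine-containing peptides —
S-glutathionylation (+305.06816 Da monoisotopic per site; a glutathione
moiety joined by a mixed disulfide, i.e. GSH minus two hydrogens), intra- and
inter-peptide disulfide bridges (-2.01565 Da per bond; the loss of two
hydrogen atoms) — and assign observed neutral masses to the nearest
hypothesis within tolerance.  Fragment-spectrum interpretation is out of
scope; ETD evidence for a disulfide enters only as a user-supplied flag.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Peptide",
    "ModificationHypothesis",
    "MassMatch",
    "NONE",
    "GLUTATHIONYLATION",
    "INTRA_DISULFIDE",
    "INTER_DISULFIDE",
    "MONO_RESIDUE_MASS",
    "AVG_RESIDUE_MASS",
    "WATER_MONO",
    "PROTON",
    "HYDROGEN_ATOM",
    "GLUTATHIONE_DELTA_MONO",
    "DISULFIDE_DELTA_MONO",
    "CARBAMIDOMETHYL_MONO",
    "digest",
    "peptide_mass",
    "apply_hypothesis",
    "apply_hypotheses",
    "enumerate_candidates",
    "match_masses",
    "neutral_from_mz",
    "mz_from_neutral",
    "protein_cys_report",
]

# Monoisotopic atomic masses, Da (CODATA/AME values).
_ATOM = {"H": 1.00782503207, "C": 12.0, "N": 14.0030740048,
         "O": 15.9949146196, "S": 31.97207100}

# Residue (amino-acid minus water) elemental compositions, (C, H, N, O, S).
_RESIDUE_FORMULA: dict[str, tuple[int, int, int, int, int]] = {
    "G": (2, 3, 1, 1, 0), "A": (3, 5, 1, 1, 0), "S": (3, 5, 1, 2, 0),
    "P": (5, 7, 1, 1, 0), "V": (5, 9, 1, 1, 0), "T": (4, 7, 1, 2, 0),
    "C": (3, 5, 1, 1, 1), "L": (6, 11, 1, 1, 0), "I": (6, 11, 1, 1, 0),
    "N": (4, 6, 2, 2, 0), "D": (4, 5, 1, 3, 0), "Q": (5, 8, 2, 2, 0),
    "K": (6, 12, 2, 1, 0), "E": (5, 7, 1, 3, 0), "M": (5, 9, 1, 1, 1),
    "H": (6, 7, 3, 1, 0), "F": (9, 9, 1, 1, 0), "R": (6, 12, 4, 1, 0),
    "Y": (9, 9, 1, 2, 0), "W": (11, 10, 2, 1, 0),
}

# Monoisotopic residue masses, Da, summed from the elemental compositions.
MONO_RESIDUE_MASS: dict[str, float] = {
    aa: c * _ATOM["C"] + h * _ATOM["H"] + n * _ATOM["N"] + o * _ATOM["O"] + s * _ATOM["S"]
    for aa, (c, h, n, o, s) in _RESIDUE_FORMULA.items()
}
# Average residue masses, Da.
AVG_RESIDUE_MASS: dict[str, float] = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167,
    "V": 99.1326, "T": 101.1051, "C": 103.1388, "L": 113.1594,
    "I": 113.1594, "N": 114.1038, "D": 115.0886, "Q": 128.1307,
    "K": 128.1741, "E": 129.1155, "M": 131.1926, "H": 137.1411,
    "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}
WATER_MONO = 2 * _ATOM["H"] + _ATOM["O"]  # 18.010565
WATER_AVG = 18.01528
PROTON = 1.00727646677
HYDROGEN_ATOM = 1.00782503207

# Glutathione C10H17N3O6S is 307.083806 Da (mono); attachment through a mixed
# disulfide loses two hydrogens, hence the net adduct below.  Reported in the
# field as a nominal "+306 Da" shift.
GLUTATHIONE_DELTA_MONO = (  # 305.068156
    10 * _ATOM["C"] + 15 * _ATOM["H"] + 3 * _ATOM["N"] + 6 * _ATOM["O"] + _ATOM["S"]
)
GLUTATHIONE_DELTA_AVG = 305.307
DISULFIDE_DELTA_MONO = -2 * HYDROGEN_ATOM  # -2.015650
DISULFIDE_DELTA_AVG = -2.0159
CARBAMIDOMETHYL_MONO = 57.021464
CARBAMIDOMETHYL_AVG = 57.0513


@dataclass(frozen=True)
class Peptide:
    """A digest fragment with 1-based inclusive coordinates in its parent."""

    sequence: str
    start: int
    end: int
    missed_cleavages: int
    cys_positions: tuple[int, ...] = ()

    def __post_init__(self):
        if len(self.sequence) != self.end - self.start + 1:
            raise ValueError("sequence length inconsistent with coordinates")

    @property
    def n_cys(self) -> int:
        return len(self.cys_positions)

    @property
    def span(self) -> str:
        return f"{self.start}-{self.end}"


@dataclass(frozen=True)
class ModificationHypothesis:
    kind: str  # NONE | GLUTATHIONYLATION | INTRA_DISULFIDE | INTER_DISULFIDE
    delta_mono: float
    delta_avg: float
    required_cys: int
    multiplicity: int = 1

    def delta(self, scale: str) -> float:
        return self.delta_mono if scale == "monoisotopic" else self.delta_avg

    @property
    def label(self) -> str:
        if self.multiplicity > 1:
            return f"{self.kind}x{self.multiplicity}"
        return self.kind


def NONE() -> ModificationHypothesis:
    return ModificationHypothesis("NONE", 0.0, 0.0, required_cys=0)


def GLUTATHIONYLATION(multiplicity: int = 1) -> ModificationHypothesis:
    """S-glutathionylation of `multiplicity` cysteines (one GS- adduct each)."""
    return ModificationHypothesis(
        "GLUTATHIONYLATION",
        GLUTATHIONE_DELTA_MONO * multiplicity,
        GLUTATHIONE_DELTA_AVG * multiplicity,
        required_cys=multiplicity,
        multiplicity=multiplicity,
    )


def INTRA_DISULFIDE(multiplicity: int = 1) -> ModificationHypothesis:
    """`multiplicity` disulfide bonds inside one peptide (2 Cys each)."""
    return ModificationHypothesis(
        "INTRA_DISULFIDE",
        DISULFIDE_DELTA_MONO * multiplicity,
        DISULFIDE_DELTA_AVG * multiplicity,
        required_cys=2 * multiplicity,
        multiplicity=multiplicity,
    )


def INTER_DISULFIDE() -> ModificationHypothesis:
    """One disulfide bond linking two peptides (1 Cys per partner)."""
    return ModificationHypothesis(
        "INTER_DISULFIDE",
        DISULFIDE_DELTA_MONO,
        DISULFIDE_DELTA_AVG,
        required_cys=1,
    )


def digest(
    protein: str,
    *,
    max_missed: int = 0,
    cleave_before: str = "D",
) -> list[Peptide]:
    """AspN in-silico digest: cleave immediately N-terminal to every D.

    ``cleave_before="DE"`` switches to the broader vendor specificity that
    also cuts before glutamate.  Peptides with 0..max_missed missed cleavages
    are returned in order of start coordinate; the 0-missed peptides
    concatenate to the input protein.
    """
    if not protein:
        raise ValueError("empty protein")
    protein = protein.upper()
    cuts = sorted(
        {0, len(protein)}
        | {i for i, c in enumerate(protein) if i > 0 and c in cleave_before}
    )
    peptides: list[Peptide] = []
    for mc in range(max_missed + 1):
        for a, b in zip(cuts, cuts[mc + 1 :]):
            seq = protein[a:b]
            peptides.append(
                Peptide(
                    sequence=seq,
                    start=a + 1,
                    end=b,
                    missed_cleavages=mc,
                    cys_positions=tuple(
                        a + 1 + i for i, c in enumerate(seq) if c == "C"
                    ),
                )
            )
    peptides.sort(key=lambda p: (p.start, p.end))
    return peptides


def peptide_mass(sequence: str, scale: str = "monoisotopic") -> float:
    """Neutral peptide mass: sum of residue masses plus one water."""
    if scale not in ("monoisotopic", "average"):
        raise ValueError(f"unknown mass scale {scale!r}")
    if not sequence:
        raise ValueError("empty peptide sequence")
    table = MONO_RESIDUE_MASS if scale == "monoisotopic" else AVG_RESIDUE_MASS
    water = WATER_MONO if scale == "monoisotopic" else WATER_AVG
    total = water
    for res in sequence.upper():
        try:
            total += table[res]
        except KeyError:
            raise ValueError(f"unknown or massless residue {res!r}") from None
    return total


def apply_hypothesis(
    peptides: Peptide | tuple[Peptide, Peptide],
    hypothesis: ModificationHypothesis,
    scale: str = "monoisotopic",
    *,
    fixed_cys_delta: float = 0.0,
) -> float:
    """Predicted neutral mass of peptide(s) under one modification hypothesis.

    ``fixed_cys_delta`` adds a fixed per-cysteine modification (e.g.
    carbamidomethylation from iodoacetamide blocking) to the base mass of
    cysteines NOT consumed by the hypothesis.
    """
    if hypothesis.kind == "INTER_DISULFIDE":
        if not (isinstance(peptides, tuple) and len(peptides) == 2):
            raise ValueError("INTER_DISULFIDE requires a pair of peptides")
        p1, p2 = peptides
        if p1.n_cys < 1 or p2.n_cys < 1:
            raise ValueError("each inter-disulfide partner needs >= 1 cysteine")
        base = peptide_mass(p1.sequence, scale) + peptide_mass(p2.sequence, scale)
        free_cys = p1.n_cys + p2.n_cys - 2
        return base + hypothesis.delta(scale) + fixed_cys_delta * free_cys
    if isinstance(peptides, tuple):
        raise ValueError(f"{hypothesis.kind} applies to a single peptide")
    pep = peptides
    if pep.n_cys < hypothesis.required_cys:
        raise ValueError(
            f"{hypothesis.label} needs {hypothesis.required_cys} cysteines, "
            f"peptide {pep.span} has {pep.n_cys}"
        )
    free_cys = pep.n_cys - hypothesis.required_cys
    return (
        peptide_mass(pep.sequence, scale)
        + hypothesis.delta(scale)
        + fixed_cys_delta * free_cys
    )


def apply_hypotheses(
    peptide: Peptide,
    hypotheses: Sequence[ModificationHypothesis],
    scale: str = "monoisotopic",
) -> float:
    """Stack single-peptide hypotheses, respecting the cysteine budget.

    A cysteine engaged by one modification is unavailable to another, so the
    summed ``required_cys`` must not exceed the peptide's cysteine count.
    """
    need = sum(h.required_cys for h in hypotheses)
    if need > peptide.n_cys:
        raise ValueError(
            f"hypothesis stack needs {need} cysteines, peptide has {peptide.n_cys}"
        )
    return peptide_mass(peptide.sequence, scale) + sum(
        h.delta(scale) for h in hypotheses
    )


@dataclass(frozen=True)
class Candidate:
    peptides: tuple[Peptide, ...]
    hypothesis: ModificationHypothesis
    predicted_mass: float

    @property
    def label(self) -> str:
        spans = "+".join(p.span for p in self.peptides)
        return f"{spans}:{self.hypothesis.label}"


def enumerate_candidates(
    peptides: Sequence[Peptide],
    hypotheses: Sequence[ModificationHypothesis] | None = None,
    *,
    scale: str = "monoisotopic",
    max_inter_pairs: int | None = None,
    fixed_cys_delta: float = 0.0,
) -> list[Candidate]:
    """All applicable (peptide(s), hypothesis) combinations, sorted by mass.

    Cysteine-containing peptides only for cysteine hypotheses; inter-peptide
    disulfides enumerate unordered pairs of cysteine peptides (optionally
    capped at ``max_inter_pairs``).
    """
    if hypotheses is None:
        hypotheses = [NONE(), GLUTATHIONYLATION(), INTRA_DISULFIDE(), INTER_DISULFIDE()]
    out: list[Candidate] = []
    singles = [h for h in hypotheses if h.kind != "INTER_DISULFIDE"]
    inter = [h for h in hypotheses if h.kind == "INTER_DISULFIDE"]
    for pep in peptides:
        for hyp in singles:
            if pep.n_cys >= hyp.required_cys:
                out.append(
                    Candidate(
                        (pep,),
                        hyp,
                        apply_hypothesis(
                            pep, hyp, scale, fixed_cys_delta=fixed_cys_delta
                        ),
                    )
                )
    if inter:
        cys_peps = [p for p in peptides if p.n_cys >= 1]
        pairs = itertools.combinations(cys_peps, 2)
        if max_inter_pairs is not None:
            pairs = itertools.islice(pairs, max_inter_pairs)
        for p1, p2 in pairs:
            for hyp in inter:
                out.append(
                    Candidate(
                        (p1, p2),
                        hyp,
                        apply_hypothesis(
                            (p1, p2), hyp, scale, fixed_cys_delta=fixed_cys_delta
                        ),
                    )
                )
    out.sort(key=lambda c: c.predicted_mass)
    return out


@dataclass(frozen=True)
class MassMatch:
    observed_mass: float
    candidate: Candidate | None
    delta: float | None
    within_tolerance: bool
    ambiguous: bool
    n_within_tolerance: int


def match_masses(
    observed: Iterable[float],
    candidates: Sequence[Candidate],
    tol: float = 0.5,
    *,
    unit: str = "Da",
) -> list[MassMatch]:
    """Assign each observed neutral mass to the nearest candidate within tol.

    ``unit`` may be "Da" or "ppm" (ppm is taken relative to the predicted
    mass).  A mass with >= 2 candidates inside the tolerance is flagged
    ambiguous; masses with none are reported unmatched.
    """
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    if unit not in ("Da", "ppm"):
        raise ValueError(f"unknown tolerance unit {unit!r}")
    matches = []
    for obs in observed:
        within = []
        for cand in candidates:
            limit = tol if unit == "Da" else tol * 1e-6 * cand.predicted_mass
            d = obs - cand.predicted_mass
            if abs(d) <= limit:
                within.append((abs(d), cand, d))
        if not within:
            matches.append(MassMatch(obs, None, None, False, False, 0))
            continue
        within.sort(key=lambda t: t[0])
        _, best, delta = within[0]
        matches.append(
            MassMatch(obs, best, delta, True, len(within) >= 2, len(within))
        )
    return matches


def neutral_from_mz(mz: float, z: int) -> float:
    """Neutral mass from m/z at charge z (positive mode): M = z*mz - z*mp."""
    if z < 1:
        raise ValueError(f"charge must be >= 1, got {z}")
    if mz <= 0:
        raise ValueError("m/z must be positive")
    return z * mz - z * PROTON


def mz_from_neutral(mass: float, z: int) -> float:
    if z < 1:
        raise ValueError(f"charge must be >= 1, got {z}")
    return (mass + z * PROTON) / z


def protein_cys_report(
    protein: str,
    *,
    nterm_boundary: int = 166,
    variant_substitutions: Mapping[int, str] | None = None,
    scale: str = "average",
) -> dict:
    """Summary of a protein's cysteine complement and an optional variant mass.

    Reports the total cysteine count, the count within the N-terminal region
    (residues 1..nterm_boundary), the most C-terminal cysteine position, the
    wild-type mass and, when ``variant_substitutions`` (1-based position ->
    replacement residue) is given, the substituted variant's mass in Da.
    """
    protein = protein.upper()
    cys = [i + 1 for i, c in enumerate(protein) if c == "C"]
    report = {
        "length": len(protein),
        "total_cys": len(cys),
        "nterm_cys": sum(1 for p in cys if p <= nterm_boundary),
        "cys_positions": cys,
        "most_cterminal_cys": cys[-1] if cys else None,
        "mass_da": peptide_mass(protein, scale),
    }
    if variant_substitutions:
        var = list(protein)
        for pos, res in variant_substitutions.items():
            if not 1 <= pos <= len(protein):
                raise ValueError(f"substitution position {pos} out of range")
            var[pos - 1] = res.upper()
        report["variant_sequence"] = "".join(var)
        report["variant_mass_da"] = peptide_mass("".join(var), scale)
    return report
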