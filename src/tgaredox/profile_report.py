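"""Join per-sequence results into per-species profiles on a species tree.

This reproduces the comparative summary stage: each species gets a motif
class for its regulatory intron (FULL / PARTIAL / ABSENT), an N-terminus
homology class for its TGA homolog(s) (SIGNIFICANT / LOW / ABSENT) and an
equivalent-cysteine count, rendered as a presence/absence table alongside an
ASCII cladogram of a user-supplied Newick species tree.  Species with
multiple homologs keep per-homolog sub-rows; the species-level row carries
the maximum equivalent-cysteine count and the best class in each column.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import pandas as pd

__all__ = [
    "HomologRow",
    "SpeciesProfile",
    "build_profiles",
    "profiles_to_frame",
    "frame_to_profiles",
    "render_on_tree",
]

_MOTIF_ORDER = {"FULL": 0, "PARTIAL": 1, "ABSENT": 2, "NA": 3}
_NTERM_ORDER = {"SIGNIFICANT": 0, "LOW": 1, "ABSENT": 2, "NA": 3}


@dataclass(frozen=True)
class HomologRow:
    homolog_id: str
    motif_class: str
    nterm_class: str
    equivalent_cys_count: int | None


@dataclass
class SpeciesProfile:
    species: str
    motif_class: str  # FULL | PARTIAL | ABSENT | NA
    nterm_class: str  # SIGNIFICANT | LOW | ABSENT | NA
    equivalent_cys_count: int | None
    flags: str = ""
    homologs: list[HomologRow] = field(default_factory=list)


def _best(values, order) -> str:
    vals = [v for v in values if v in order]
    return min(vals, key=order.__getitem__) if vals else "NA"


def build_profiles(
    motif_calls: pd.DataFrame | None,
    cys_counts: pd.DataFrame | None,
    nterm: pd.DataFrame | None,
    species_map: dict[str, str],
    *,
    species: list[str] | None = None,
) -> list[SpeciesProfile]:
    """Aggregate per-sequence tables into one profile per species.

    ``motif_calls`` needs columns (seq_id, motif_class); ``cys_counts``
    (id, equivalent_count); ``nterm`` (id, homology_class).  ``species_map``
    joins sequence/homolog ids to species names; ids without a mapping are
    warned about and reported as their own NA-flagged rows.  ``species``
    optionally forces the output rows (e.g. all tree leaves), adding all-NA
    rows for species absent from every input.
    """
    per_species: dict[str, dict] = {}

    def bucket(name: str) -> dict:
        return per_species.setdefault(
            name, {"motif": {}, "cys": {}, "nterm": {}, "flags": set()}
        )

    def species_of(seq_id: str) -> str:
        if seq_id in species_map:
            return species_map[seq_id]
        warnings.warn(f"id {seq_id!r} has no species mapping", stacklevel=2)
        b = bucket(str(seq_id))
        b["flags"].add("unmapped-id")
        return str(seq_id)

    if motif_calls is not None:
        for row in motif_calls.itertuples(index=False):
            sp = species_of(row.seq_id)
            bucket(sp)["motif"][row.seq_id] = row.motif_class
    if cys_counts is not None:
        for row in cys_counts.itertuples(index=False):
            sp = species_of(row.id)
            bucket(sp)["cys"][row.id] = int(row.equivalent_count)
    if nterm is not None:
        for row in nterm.itertuples(index=False):
            sp = species_of(row.id)
            bucket(sp)["nterm"][row.id] = row.homology_class

    names = species if species is not None else sorted(per_species)
    profiles = []
    for name in names:
        data = per_species.get(
            name, {"motif": {}, "cys": {}, "nterm": {}, "flags": set()}
        )
        homolog_ids = sorted(set(data["cys"]) | set(data["nterm"]))
        homologs = [
            HomologRow(
                homolog_id=h,
                motif_class="NA",
                nterm_class=data["nterm"].get(h, "NA"),
                equivalent_cys_count=data["cys"].get(h),
            )
            for h in homolog_ids
        ]
        cys_values = [c for c in data["cys"].values() if c is not None]
        profiles.append(
            SpeciesProfile(
                species=name,
                motif_class=_best(data["motif"].values(), _MOTIF_ORDER),
                nterm_class=_best(data["nterm"].values(), _NTERM_ORDER),
                equivalent_cys_count=max(cys_values) if cys_values else None,
                flags=";".join(sorted(data["flags"])),
                homologs=homologs if len(homologs) > 1 else [],
            )
        )
    return profiles


_COLUMNS = [
    "species",
    "row_type",
    "homolog_id",
    "motif_class",
    "nterm_class",
    "equivalent_cys_count",
    "flags",
]


def profiles_to_frame(profiles: list[SpeciesProfile]) -> pd.DataFrame:
    """Flatten profiles (species rows + homolog sub-rows) to a tidy frame."""
    rows = []
    for p in profiles:
        rows.append(
            (
                p.species,
                "species",
                "",
                p.motif_class,
                p.nterm_class,
                p.equivalent_cys_count,
                p.flags,
            )
        )
        for h in p.homologs:
            rows.append(
                (
                    p.species,
                    "homolog",
                    h.homolog_id,
                    h.motif_class,
                    h.nterm_class,
                    h.equivalent_cys_count,
                    "",
                )
            )
    df = pd.DataFrame(rows, columns=_COLUMNS)
    df["equivalent_cys_count"] = df["equivalent_cys_count"].astype("Int64")
    return df


def frame_to_profiles(df: pd.DataFrame) -> list[SpeciesProfile]:
    """Inverse of :func:`profiles_to_frame` (lossless round-trip)."""
    profiles: list[SpeciesProfile] = []
    for row in df.itertuples(index=False):
        count = None if pd.isna(row.equivalent_cys_count) else int(row.equivalent_cys_count)
        flags = "" if pd.isna(row.flags) else str(row.flags)
        # a TSV round trip reads the literal string "NA" back as NaN
        motif = "NA" if pd.isna(row.motif_class) else row.motif_class
        nterm = "NA" if pd.isna(row.nterm_class) else row.nterm_class
        if row.row_type == "species":
            profiles.append(
                SpeciesProfile(
                    species=row.species,
                    motif_class=motif,
                    nterm_class=nterm,
                    equivalent_cys_count=count,
                    flags=flags,
                )
            )
        else:
            hid = "" if pd.isna(row.homolog_id) else str(row.homolog_id)
            profiles[-1].homologs.append(HomologRow(hid, motif, nterm, count))
    return profiles


def _normalize(name: str) -> str:
    return " ".join(name.replace("_", " ").split()).casefold()


def render_on_tree(
    profiles: list[SpeciesProfile],
    newick: str,
    *,
    normalize_names: bool = True,
) -> tuple[str, pd.DataFrame, list[str]]:
    """Annotate a Newick species tree with per-leaf profile glyphs.

    Returns ``(text, matrix, unplaced)``: an ASCII cladogram followed by one
    profile line per leaf in tree traversal order, the machine-readable
    profile matrix (leaf order), and the species that had profiles but no
    matching leaf.  Leaf matching is exact or, with ``normalize_names``,
    case/underscore-insensitive.  Polytomies are accepted; topology is never
    altered.
    """
    try:
        tree = dendropy.Tree.get(data=newick, schema="newick")
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"unparseable Newick tree: {exc}") from exc

    key = _normalize if normalize_names else (lambda s: s)
    by_name = {key(p.species): p for p in profiles}
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter() if lf.taxon is not None]

    placed = set()
    ordered: list[SpeciesProfile] = []
    for label in leaves:
        p = by_name.get(key(label))
        if p is None:
            p = SpeciesProfile(label, "NA", "NA", None)
        else:
            placed.add(key(label))
        ordered.append(p)
    unplaced = [p.species for p in profiles if key(p.species) not in placed]

    matrix = profiles_to_frame(ordered)

    lines = [tree.as_ascii_plot(plot_metric="level").rstrip()]
    lines.append("")
    lines.append(f"{'species':<30} motif     nterm        cys")
    for label, p in zip(leaves, ordered):
        cys = "NA" if p.equivalent_cys_count is None else str(p.equivalent_cys_count)
        lines.append(
            f"{label:<30} {p.motif_class:<9} {p.nterm_class:<12} {cys}"
        )
        for h in p.homologs:
            hcys = "NA" if h.equivalent_cys_count is None else str(h.equivalent_cys_count)
            lines.append(
                f"  - {h.homolog_id:<26} {h.motif_class:<9} {h.nterm_class:<12} {hcys}"
            )
    if unplaced:
        lines.append("")
        lines.append("profiles without a tree leaf: " + ", ".join(unplaced))
    return "\n".join(lines) + "\n", matrix, unplaced
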