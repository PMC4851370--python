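"""Call equivalent cysteines and N-terminus classes in a designed family.

Generates a protein family alignment: a reference with cysteines at
positions 27/68/87/114/154 in its N-terminal extension, a full five-cysteine
homolog, a four-of-five homolog (second cysteine replaced by serine), and a
short low-homology extension.  The equivalent-cysteine count is the number
of reference-cysteine alignment columns occupied by a cysteine in each
homolog; the N-terminus class compares extension length and identity.
"""

from tgaredox.cysprofile import annotate_n_terminus, call_equivalents
from tgaredox.synthetic import HomologDesign, gen_protein_family

aln, truth = gen_protein_family(
    [
        HomologDesign("five_cys", 160, "CCCCC"),
        HomologDesign("four_cys", 160, "CXCCC"),
        HomologDesign("short_ext", 60, "XXXXX", nterm_identity=0.1),
    ],
    seed=11,
)

table = call_equivalents(aln, (27, 68, 87, 114, 154))
print("equivalent cysteines (of 5 queried positions):")
for seq_id in aln.ids:
    ann = annotate_n_terminus(aln, seq_id)
    print(f"  {seq_id:<12} cys={table.equivalent_count(seq_id)}  "
          f"extension={ann.extension_length:>3} residues  "
          f"identity={ann.pct_identity_vs_ref_nterm:5.1f}%  "
          f"class={ann.homology_class}")
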