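"""Join motif and cysteine results into per-species profiles on a cladogram.

Mimics a comparative summary: each species gets its intron's motif class,
its homologs' N-terminus class and the maximum equivalent-cysteine count; a
species with two homologs (here with 2 and 3 cysteines) keeps per-homolog
sub-rows.  The ASCII cladogram renders a user-supplied Newick species tree.
"""

import pandas as pd

from tgaredox.profile_report import build_profiles, render_on_tree

motifs = pd.DataFrame(
    {"seq_id": ["at_ag", "th_ag", "sl_ag"],
     "motif_class": ["FULL", "FULL", "PARTIAL"]}
)
cys = pd.DataFrame(
    {"id": ["at_pan", "th_tga_a", "th_tga_b", "sl_tga"],
     "equivalent_count": [5, 2, 3, 0]}
)
nterm = pd.DataFrame(
    {"id": ["at_pan", "th_tga_a", "th_tga_b", "sl_tga"],
     "homology_class": ["SIGNIFICANT", "LOW", "SIGNIFICANT", "ABSENT"]}
)
species_map = {
    "at_ag": "Arabidopsis thaliana", "at_pan": "Arabidopsis thaliana",
    "th_ag": "Tarenaya hassleriana", "th_tga_a": "Tarenaya hassleriana",
    "th_tga_b": "Tarenaya hassleriana",
    "sl_ag": "Solanum lycopersicum", "sl_tga": "Solanum lycopersicum",
}
tree = "((Arabidopsis_thaliana,Tarenaya_hassleriana),Solanum_lycopersicum);"

profiles = build_profiles(motifs, cys, nterm, species_map)
text, matrix, unplaced = render_on_tree(profiles, tree)
print(text)
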