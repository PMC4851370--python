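"""Assign observed peptide masses to cysteine-modification hypotheses.

Digests a cysteine-bearing protein with AspN (cleaving before aspartate),
plants three modifications into a noisy observed-mass list, and matches each
observed neutral mass to the hypothesis with the smallest mass error within
a 0.5 Da tolerance.  S-glutathionylation shifts a peptide by +305.068 Da
(the glutathione adduct), an intramolecular disulfide by -2.016 Da (the loss
of two hydrogen atoms).
"""

from tgaredox.massdelta import digest, enumerate_candidates, match_masses
from tgaredox.synthetic import gen_mass_list

PROTEIN = "MAC" + "GLVK" * 5 + "DCC" + "STYW" * 5 + "DAC" + "PQNH" * 5

obs, truth = gen_mass_list(
    PROTEIN,
    [(0, "GLUTATHIONYLATION"), (1, "INTRA_DISULFIDE"), (2, "NONE")],
    seed=3,
    noise_sd=0.01,
)

peptides = digest(PROTEIN, max_missed=1)
print(f"AspN digest: {len(peptides)} peptides (0-1 missed cleavages)")

candidates = enumerate_candidates(peptides)
matches = match_masses(obs["mass"], candidates, tol=0.5)

print(f"{'observed':>12}  {'peptide':<8} {'hypothesis':<18} {'delta (Da)':>10}")
for m in matches:
    span = "+".join(p.span for p in m.candidate.peptides)
    print(f"{m.observed_mass:12.4f}  {span:<8} "
          f"{m.candidate.hypothesis.label:<18} {m.delta:10.4f}")
print("\ntruth:", ", ".join(truth["kind"]))
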