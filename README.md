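# tgaredox

Sequence- and mass-level analysis of redox-regulated TGA transcription
factors and their target *cis*-element.

Plant TGA bZIP transcription factors bind TGACG-containing regulatory
elements. One such element — a 33-bp motif in the second intron of the
floral regulator *AGAMOUS*, carrying an AAGAAT hexamer and a central TGACG
core — is bound by the factor PERIANTHIA (PAN), whose DNA binding is
controlled by redox modifications of cysteines in a PAN-specific N-terminal
extension. This package implements the computational side of that analysis
as a reusable, fully testable pipeline:

1. **Motif scanning** (`tgaredox.motif`) — find candidate windows anchored
   at the degenerate hexamer `[ACT]AGAAT` on either strand, count ungapped
   deviations from a 33-nt reference window, test for the TGACG core
   (forward or reverse-complement orientation) and classify:
   * `FULL` — core present and ≤ 7 deviations,
   * `PARTIAL` — hexamer present but FULL criteria fail; a core-less window
     with > 15 deviations is flagged as a canonical partial motif,
   * `ABSENT` — no hexamer occurrence at all.
2. **Equivalent-cysteine profiling** (`tgaredox.cysprofile`) — map
   reference cysteine positions (defaults 27, 68, 87, 114, 154, 340)
   through a protein multiple alignment, report per-homolog residues at
   those columns, and classify N-terminal extensions (length, percent
   identity to the reference N-terminus, SIGNIFICANT/LOW/ABSENT).
3. **Delta-mass modification matching** (`tgaredox.massdelta`) — in-silico
   AspN digestion (cleavage N-terminal to Asp), monoisotopic/average
   peptide masses, and assignment of observed neutral masses to cysteine
   modification hypotheses: S-glutathionylation (+305.06816 Da
   monoisotopic per site — the glutathione adduct C₁₀H₁₅N₃O₆S), intra- and
   inter-peptide disulfide bridges (−2.01565 Da — the loss of two hydrogen
   atoms).
4. **Synthetic data** (`tgaredox.synthetic`) — seeded generators for
   introns with planted motifs, designed protein families and noisy
   observed-mass lists, each with an exact truth table.
5. **Species profiling** (`tgaredox.profile_report`) — join the per-sequence
   results into per-species presence/absence profiles and render them on a
   user-supplied Newick cladogram.

## Worked example

```sh
python examples/scan_intron.py
```

plants a perfect motif copy at position 100 and a degraded, core-less copy
at 300 of a 500-nt synthetic intron, then scans it:

```
best call: FULL at 100 (0 deviations, core=True)

all candidate windows:
  FULL     start=100  strand=+ dev=0   core=True canonical_partial=False
  PARTIAL  start=300  strand=+ dev=18  core=False canonical_partial=True
  PARTIAL  start=347  strand=+ dev=22  core=False canonical_partial=True
```

The perfect copy is recovered as FULL at its planted coordinate with zero
deviations; the degraded copy (16 requested substitutions plus the
two-nucleotide core exchange = 18 deviations, no core) is a canonical
PARTIAL; the third window is a chance hexamer occurrence in the random
background. The other examples cover the remaining stages —
`profile_family.py` (equivalent-cysteine counts, e.g. a four-of-five
homolog), `match_modifications.py` (glutathionylation and disulfide
assignment within 0.5 Da) and `species_tree_report.py` (the cladogram
summary).

A thin CLI wraps the same functions:

```sh
tgaredox scan --fasta introns.fasta --out calls.tsv
tgaredox map-cys --aln family.aln.fasta --ref-id PAN --positions 27,68,87,114,154,340 --out cys.tsv
tgaredox digest-match --fasta pan.fasta --masses observed.tsv --out matches.tsv
tgaredox report --motifs calls.tsv --cys counts.tsv --tree species.nwk --species-map ids.yaml --out-prefix report
```

The shipped default reference window is synthetic (AAGAAT hexamer at offset
4, CGTCA core in reverse-complement orientation); for genomic work supply
the real element via a YAML config:

```yaml
reference:
  sequence: <the 33-bp element from the AGAMOUS second intron>
  hexamer_offset: <0-based offset of AAGAAT>
classifier:
  max_dev_full: 7
  min_dev_partial_report: 15
```

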