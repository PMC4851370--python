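# Methods

## Motif model and discrimination rule

A candidate regulatory element is modelled as a fixed-length nucleotide
window (default L = 33) containing the AAGAAT hexamer at a known offset and,
somewhere in the window, the TGACG core that is the minimal requirement for
TGA-factor binding. The first hexamer position is degenerate: A, C or T all
count as a match (`ReferenceMotif.degenerate_positions` generalizes this to
any position → allowed-set map).

Scanning anchors candidates at hexamer occurrences — the regex
`[ACT]AGAAT` on the forward strand and its reverse complement for minus-
strand hits — rather than scoring every window, which is equivalent because
every class except ABSENT requires the hexamer. Each hit is expanded to the
L-nt window that aligns its hexamer with the reference offset; windows that
would overrun the sequence are dropped. Minus-strand windows are reported
in forward coordinates with the window sequence in reference orientation
(the reverse complement of the forward slice).

Deviations are counted by ungapped Hamming comparison over the full L-nt
frame — no indels, all L positions including hexamer and core — with
degenerate positions matching their allowed set and N always counting as a
deviation. Classification is then:

* FULL — core present (TGACG, or CGTCA when both strands are allowed,
  anywhere in the window) AND deviations ≤ `max_dev_full` (default 7);
* PARTIAL — hexamer present but FULL fails. The sub-case with no core and
  more than `min_dev_partial_report` (default 15) deviations carries a
  `canonical_partial` flag. The 8–15-deviation band, which the two
  thresholds leave between them, is deliberately classified PARTIAL with
  the count reported rather than forced into either canonical case: the
  flag is descriptive, the FULL gate is the hard rule.
* ABSENT — reserved for sequences with no hexamer hit anywhere.

One best call per sequence is chosen by class (FULL > PARTIAL), then fewer
deviations, then leftmost window start, then '+' strand. The core check is
positional only in the sense of "anywhere in the window"; a central-offset
restriction was considered and rejected because window-local core position
adds no discriminating power under the deviation count, which already
penalizes displaced cores.

The shipped default reference window is synthetic: the real 33-bp element
is an experimental sequence the user must supply (config YAML), and baking
in a guessed sequence would be worse than requiring the input. The default
preserves the element's structural features — hexamer near the 5′ end, core
in reverse-complement orientation — so every test exercises the same code
paths as the real element.

## Alignment-based cysteine equivalence

Reference residue positions (1-based, default 27/68/87/114/154/340) are
mapped to alignment columns by walking the reference row's non-gap
characters; the map is strictly increasing and inverts the reference's own
ungapping. A homolog has an "equivalent" cysteine when the exact mapped
column holds C (case-insensitive); gaps and X never qualify. No ±k column
tolerance is applied by default because column identity is what a
presence/absence profile asserts; nearby cysteines that drift in the
alignment are a statement about the alignment, not the homolog, and the
module never re-aligns.

N-terminal extensions are measured against the basic (bZIP) region. The
basic-region start is either supplied per sequence or detected as the first
window of width 16 whose K/R fraction is ≥ 0.4, anchored on the window's
first basic residue (the window test alone would report up to w−1 residues
of non-basic slack). Width 16 spans a typical basic region; 0.4 is high
enough that coiled-coil heptads downstream do not fire early. Extension
length is the residue count before that start; percent identity is computed
over alignment columns N-terminal of the *reference's* basic region,
counting only columns where neither sequence is gapped. Classes:
ABSENT below a 20-residue minimum extension, SIGNIFICANT at ≥ 30% identity,
LOW otherwise. Both thresholds are explicit parameters: 30% is the
conventional twilight-zone cut for confident homology over short stretches,
and 20 residues separates a genuine extension from start-position jitter.
Homologs without a defined translation start are listed in `truncated_ids`
and reported flagged, with no extension metrics.

## Digestion and delta-mass assignment

AspN digestion cleaves immediately N-terminal to aspartate (glutamate can
be added via `cleave_before="DE"`; vendor specificities differ, and before-D
is the conservative core rule). Peptides carry parent coordinates, missed-
cleavage counts (0..max_missed, default 1) and cysteine positions; the
0-missed set concatenates exactly to the protein.

Peptide masses are sums of residue masses plus one water, with the
monoisotopic residue table derived in-source from elemental compositions
and CODATA/AME atomic masses, so digest mass conservation holds to < 1e-9 Da
and agreement with an independent elemental-composition oracle holds to
1e-6 Da on 40-mers. Average masses use the standard rounded table (4-digit)
and are intended for gel-scale comparisons such as the ~50 kDa variant
check, not for matching.

Modification hypotheses shift the predicted mass by fixed deltas:

| hypothesis | Δ monoisotopic (Da) | cysteines consumed |
|---|---|---|
| NONE | 0 | 0 |
| S-glutathionylation (per site) | +305.068156 | 1 |
| intramolecular disulfide | −2.015650 | 2 |
| interpeptide disulfide | −2.015650 | 1 per partner |

The glutathionylation delta is glutathione (C₁₀H₁₇N₃O₆S, 307.083806 Da)
minus two hydrogens for the mixed disulfide linkage — the "+306 Da"
sometimes quoted for this adduct is nominal rounding of the same chemistry.
Hypotheses stack only within a peptide's cysteine budget (a cysteine in one
bond is unavailable to another), and stacked deltas commute by
construction. Matching assigns each observed neutral mass to the candidate
with minimal |observed − predicted| within a tolerance (default 0.5 Da,
ion-trap-appropriate; ppm available), flagging masses with ≥ 2 in-tolerance
candidates as ambiguous. m/z input is converted via M = z·(m/z) − z·m_p
with the proton mass 1.00727646677 Da. Carbamidomethylation (+57.02146 Da
per free cysteine) is available as a fixed modification for
iodoacetamide-blocked samples, off by default since the baseline comparison
is against unmodified peptides. Fragment-level evidence (e.g. ETD disulfide
cleavage) is out of scope and enters only as a user-supplied annotation.

## Synthetic data: what it emulates and what it does not

`gen_intron` plants reference-window copies into an i.i.d. background
(default 500 nt at GC 0.36, approximating Arabidopsis intron composition).
Substitutions are placed only at non-hexamer, non-core, non-degenerate
positions so the requested deviation count is realized exactly; breaking
the core uses a two-nucleotide exchange inside the core (the edit size that
abolishes factor binding experimentally), adding 2 to the realized count,
which the truth table records. Each planted window is re-scored and redrawn
(bounded retries) if a substitution accidentally restores or creates a
core, keeping truth exact. The background is order-0 by design: the
classifier is window-local, so higher-order background structure cannot
change its contract, only the rate of chance hexamer hits — which the truth
table does not claim to enumerate.

`gen_protein_family` builds an alignment by construction (gaps only at the
N-terminal edge of short extensions, no internal indels), with the
reference's cysteines at the five N-terminal profiled positions plus a
universally conserved position 340. Homolog designs set extension length,
a C/X pattern over the profiled positions (X realized as serine) and a
target N-terminal identity; realized identity is recomputed after the
pattern is applied and stored in the truth table. Random residues avoid
K/R so the basic-region detector fires exactly once, at the designed
boundary.

`gen_mass_list` draws observed = predicted(hypothesis) + N(0, sd) with
sd = 0.01 Da by default — an ion-trap-scale error well inside the 0.5 Da
tolerance and far from the > 300 Da and 2 Da hypothesis separations, which
is why planted recovery is expected (and measured) at 100%.

Passing tests on these generators therefore demonstrate the pipeline's
correctness under its stated assumptions — exact truth, clean alignments,
well-separated hypotheses — not robustness to misalignment, correlated
backgrounds, or overlapping modification masses in real data.

## Species profiles

Per-species aggregation takes the best class per column (FULL > PARTIAL >
ABSENT; SIGNIFICANT > LOW > ABSENT) and the maximum equivalent-cysteine
count, preserving per-homolog sub-rows whenever a species has more than one
homolog, so no detail is lost to the summary. Trees are always user-
supplied Newick (polytomies accepted, topology never altered); leaf
matching is exact after optional case/underscore normalization. The profile
matrix TSV round-trips losslessly, with the string "NA" reserved for
missing classes.

## Problem sizes and determinism

All generators and the acceptance script are deterministic functions of a
single seed. The shipped verification runs use 1,000 seeded backgrounds for
planted-motif recovery, 100 planted masses for modification recovery, 100
random sequences (≤ 200 nt) for the brute-force scan oracle and 1,000
random peptides for the mass oracle — sizes at which the binomial noise on
a ≥ 99% recovery bound is negligible while the whole suite completes in
seconds.

## Known limitations

* The scanner reports one best call per sequence by a fixed tie-break;
  biologically co-occurring elements must be read from the all-hits table.
* No PWM or information-content scoring: the classifier is a hard-threshold
  rule by design, so near-boundary windows (7 vs 8 deviations) flip class
  with a single substitution.
* Cysteine equivalence is exact-column; alignment errors propagate directly
  into the counts.
* Mass matching is neutral-mass-level only — no isotope envelopes, adducts
  other than the modelled hypotheses, or fragment-spectrum scoring.
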