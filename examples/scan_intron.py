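"""Plant AAGAAT-element copies in a synthetic intron and classify them.

Builds a 500-nt intron with one perfect motif copy and one degraded,
core-less copy, then scans it.  The FULL call marks a window carrying the
TGACG core with at most 7 deviations from the 33-nt reference; the PARTIAL
call retains the AAGAAT hexamer but fails those criteria (with >15
deviations and no core it is a canonical partial motif).
"""

from tgaredox.motif import scan_sequence
from tgaredox.synthetic import PlantedMotif, gen_intron

(seq_id, seq), truth = gen_intron(
    [PlantedMotif(0, True, 100), PlantedMotif(16, False, 300)],
    seed=7,
)
print("planted truth:")
print(truth.to_string(index=False))

best, calls = scan_sequence(seq, seq_id=seq_id)
print(f"\nbest call: {best.motif_class} at {best.window_start} "
      f"({best.deviations} deviations, core={best.core_present})")
print("\nall candidate windows:")
for c in calls:
    print(f"  {c.motif_class:<8} start={c.window_start:<4} strand={c.strand} "
          f"dev={c.deviations:<3} core={c.core_present} "
          f"canonical_partial={c.canonical_partial}")
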