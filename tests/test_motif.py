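"""Motif scanning and full/partial classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_dna
from tgaredox.motif import (
    DEFAULT_REFERENCE,
    ClassifierParams,
    MotifCall,
    ReferenceMotif,
    classify,
    count_deviations,
    extract_window,
    find_hexamer_sites,
    has_tga_core,
    revcomp,
    scan_sequence,
)

L = DEFAULT_REFERENCE.length
OFF = DEFAULT_REFERENCE.hexamer_offset

dna = st.text(alphabet="ACGTN", min_size=0, max_size=60)


class TestRevcomp:
    @pytest.mark.parametrize(
        "seq,expected",
        [("TGACG", "CGTCA"), ("AAGAAT", "ATTCTT"), ("", ""), ("N", "N")],
    )
    def test_known_complements(self, seq, expected):
        assert revcomp(seq) == expected

    @given(dna)
    @settings(max_examples=100, deadline=None)
    def test_involution(self, seq):
        assert revcomp(revcomp(seq)) == seq

    def test_rejects_non_nucleotide(self):
        with pytest.raises(ValueError, match="'U'.*position 2"):
            revcomp("ACUG")


class TestReferenceMotif:
    def test_default_reference_is_wellformed(self, ref):
        assert ref.length == 33
        assert ref.sequence[OFF : OFF + 6] == "AAGAAT"
        # core present in reverse-complement orientation, as in the
        # Arabidopsis element
        assert "CGTCA" in ref.sequence

    def test_hexamer_must_sit_at_offset(self):
        with pytest.raises(ValueError, match="lacks AAGAAT"):
            ReferenceMotif(sequence="A" * 33, hexamer_offset=4)

    def test_degenerate_default_is_first_hexamer_position(self, ref):
        assert ref.degenerate_positions == {OFF: frozenset("ACT")}


class TestFindHexamerSites:
    def test_literal_hexamer(self, ref):
        assert find_hexamer_sites("ggAAGAATgg", ref) == [(2, "+")]

    def test_first_position_degeneracy_allows_c_and_t(self, ref):
        assert find_hexamer_sites("ggCAGAATgg", ref) == [(2, "+")]
        assert find_hexamer_sites("ggTAGAATgg", ref) == [(2, "+")]

    def test_g_not_in_allowed_set(self, ref):
        assert find_hexamer_sites("ggGAGAATgg", ref) == []

    def test_minus_strand_reported_in_forward_coordinates(self, ref):
        # ATTCTT = revcomp(AAGAAT); ATTCTG = revcomp(CAGAAT)
        assert find_hexamer_sites("ggATTCTTgg", ref) == [(2, "-")]
        assert find_hexamer_sites("ggATTCTGgg", ref) == [(2, "-")]

    def test_sorted_with_plus_before_minus_at_ties(self, ref):
        hits = find_hexamer_sites("AAGAAT" + "ATTCTT", ref)
        assert hits == [(0, "+"), (6, "-")]


class TestExtractWindow:
    def test_identity_on_reference(self, ref):
        window, start = extract_window(ref.sequence, OFF, "+", ref)
        assert window == ref.sequence and start == 0

    def test_overrun_returns_none(self, ref):
        # hexamer 2 nt from the start cannot anchor a window needing OFF=4 nt
        assert extract_window("gg" + "AAGAAT" + "g" * 40, 2, "+", ref) is None

    def test_minus_strand_window_is_revcomp_of_forward_slice(self, ref):
        seq = "T" * 10 + revcomp(ref.sequence) + "T" * 10
        (pos, strand), = find_hexamer_sites(seq, ref)
        assert strand == "-"
        window, start = extract_window(seq, pos, strand, ref)
        assert start == 10
        assert window == revcomp(seq[start : start + L]) == ref.sequence


class TestCountDeviations:
    def test_reference_has_zero(self, ref):
        assert count_deviations(ref.sequence, ref) == 0

    def test_planted_substitutions_counted_exactly(self, ref, rng):
        window = list(ref.sequence)
        free = [i for i in range(L) if i not in range(OFF, OFF + 6)]
        for i in rng.choice(free, size=3, replace=False):
            window[i] = {"A": "G", "C": "A", "G": "T", "T": "C"}[window[i]]
        assert count_deviations("".join(window), ref) == 3

    def test_degenerate_first_hexamer_position_matches(self, ref):
        window = list(ref.sequence)
        window[OFF] = "C"
        assert count_deviations("".join(window), ref) == 0
        window[OFF] = "G"
        assert count_deviations("".join(window), ref) == 1

    def test_n_always_deviates(self, ref):
        window = "N" + ref.sequence[1:]
        assert count_deviations(window, ref) == 1

    def test_length_mismatch_rejected(self, ref):
        with pytest.raises(ValueError, match="length"):
            count_deviations(ref.sequence[:-1], ref)

    def test_monotone_under_additional_substitutions(self, ref, rng):
        window = list(ref.sequence)
        free = [i for i in range(L) if i not in range(OFF, OFF + 6)]
        prev = 0
        for i in rng.permutation(free)[:10]:
            window[i] = {"A": "G", "C": "A", "G": "T", "T": "C"}[window[i]]
            now = count_deviations("".join(window), ref)
            assert now >= prev
            prev = now


class TestHasTgaCore:
    def test_forward_core(self, ref, params):
        window = "TGACG" + "A" * (L - 5)
        assert has_tga_core(window, ref, params) == (True, "+")

    def test_reverse_complement_core_only(self, ref, params):
        window = "CGTCA" + "A" * (L - 5)
        assert has_tga_core(window, ref, params) == (True, "-")

    def test_two_nucleotide_core_exchange_abolishes(self, ref, params):
        window = "TGAAT" + "A" * (L - 5)
        assert has_tga_core(window, ref, params) == (False, "none")

    def test_single_strand_policy(self, ref):
        single = ClassifierParams(core_both_strands=False)
        window = "CGTCA" + "A" * (L - 5)
        assert has_tga_core(window, ref, single) == (False, "none")


def plant_deviations(ref, k, rng, keep_core=True):
    """Reference copy with exactly k substitutions outside hexamer and core."""
    protected = set(range(OFF, OFF + 6)) | set(ref.degenerate_positions)
    for pat in (ref.core, revcomp(ref.core)):
        i = ref.sequence.find(pat)
        while i >= 0:
            protected |= set(range(i, i + 5))
            i = ref.sequence.find(pat, i + 1)
    free = sorted(set(range(L)) - protected)
    window = list(ref.sequence)
    for i in rng.choice(free, size=k, replace=False):
        window[i] = {"A": "G", "C": "A", "G": "T", "T": "C"}[window[i]]
    if not keep_core:
        i = ref.sequence.find("CGTCA")
        window[i + 1] = "A"
        window[i + 2] = "C"
    return "".join(window)


class TestClassify:
    def test_perfect_window_is_full(self, ref, params):
        call = classify(ref.sequence, ref, params)
        assert call.motif_class == "FULL" and call.deviations == 0

    def test_boundary_seven_vs_eight(self, ref, params, rng):
        assert classify(plant_deviations(ref, 7, rng), ref, params).motif_class == "FULL"
        assert classify(plant_deviations(ref, 8, rng), ref, params).motif_class == "PARTIAL"

    def test_boundary_sweep(self, ref, params, rng):
        """The largest deviation count still FULL (core intact) is 7."""
        max_free = L - len("AAGAAT") - 2 * 5  # outside hexamer and both core spans
        classes = {
            k: classify(plant_deviations(ref, k, rng), ref, params).motif_class
            for k in range(max_free + 1)
        }
        assert max(k for k, c in classes.items() if c == "FULL") == 7
        assert all(c == "PARTIAL" for k, c in classes.items() if k > 7)

    def test_high_deviation_no_core_is_canonical_partial(self, ref, params, rng):
        window = plant_deviations(ref, 16, rng, keep_core=False)
        call = classify(window, ref, params)
        assert call.motif_class == "PARTIAL"
        assert not call.core_present
        assert call.canonical_partial

    def test_low_deviation_no_core_is_plain_partial(self, ref, params, rng):
        window = plant_deviations(ref, 0, rng, keep_core=False)
        call = classify(window, ref, params)
        assert call.motif_class == "PARTIAL" and not call.canonical_partial

    def test_core_fixed_increasing_deviations_never_upgrades(self, ref, params, rng):
        # class monotonicity: PARTIAL at k implies PARTIAL at k' > k
        seen_partial = False
        for k in range(0, 14):
            cls = classify(plant_deviations(ref, k, rng), ref, params).motif_class
            if seen_partial:
                assert cls == "PARTIAL"
            seen_partial = cls == "PARTIAL"


# ---------------------------------------------------------------------------
# independent all-windows brute-force scorer used as the scan oracle


def brute_force_best(seq, ref, params):
    seq = seq.upper()
    allowed_first = ref.degenerate_positions.get(OFF, frozenset())
    candidates = []
    for s in range(len(seq) - L + 1):
        for strand in "+-":
            w = seq[s : s + L] if strand == "+" else revcomp(seq[s : s + L])
            hexa = w[OFF : OFF + 6]
            if not (hexa[1:] == "AGAAT" and hexa[0] in (allowed_first | {"A"})):
                continue
            dev = sum(
                1
                for i, (a, b) in enumerate(zip(w, ref.sequence))
                if (a not in ref.degenerate_positions.get(i, {b}))
            )
            core = ("TGACG" in w) or ("CGTCA" in w)
            cls = "FULL" if core and dev <= params.max_dev_full else "PARTIAL"
            candidates.append((0 if cls == "FULL" else 1, dev, s, strand != "+", cls))
    if not candidates:
        return None
    return min(candidates)


class TestScanSequence:
    def test_planted_motif_recovered(self, ref, params, rng):
        seq = random_dna(rng, 100) + ref.sequence + random_dna(rng, 367)
        best, _ = scan_sequence(seq, ref, params, seq_id="s")
        assert (best.motif_class, best.window_start, best.deviations) == ("FULL", 100, 0)

    def test_no_hexamer_yields_absent(self, ref, params):
        best, calls = scan_sequence("GGGGCCCCGGGGCCCC", ref, params)
        assert best.motif_class == "ABSENT" and calls == [best]

    def test_empty_sequence_rejected(self, ref, params):
        with pytest.raises(ValueError, match="empty"):
            scan_sequence("", ref, params)

    def test_tie_break_prefers_fewer_deviations(self, ref, params, rng):
        w2 = plant_deviations(ref, 2, rng)
        w5 = plant_deviations(ref, 5, rng)
        seq = "T" * 20 + w5 + "T" * 20 + w2 + "T" * 20
        best, calls = scan_sequence(seq, ref, params)
        assert best.deviations == 2 and best.window_start == 20 + L + 20
        assert len([c for c in calls if c.motif_class == "FULL"]) == 2

    def test_mirror_image_scan(self, ref, params, rng):
        seq = random_dna(rng, 80) + ref.sequence + random_dna(rng, 80)
        _, calls = scan_sequence(seq, ref, params)
        _, mirror = scan_sequence(revcomp(seq), ref, params)
        fwd = sorted((c.window_start, c.strand, c.deviations) for c in calls)
        flipped = sorted(
            (len(seq) - c.window_start - L, "+" if c.strand == "-" else "-", c.deviations)
            for c in mirror
        )
        assert fwd == flipped

    def test_agrees_with_brute_force_oracle(self, ref, params, rng):
        for _ in range(100):
            seq = random_dna(rng, int(rng.integers(40, 201)))
            expected = brute_force_best(seq, ref, params)
            best, _ = scan_sequence(seq, ref, params)
            if expected is None:
                assert best.motif_class == "ABSENT"
            else:
                _, dev, s, minus, cls = expected
                assert best.motif_class == cls
                assert best.deviations == dev
                assert best.window_start == s
                assert (best.strand != "+") == minus
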