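"""Interface positioning: landscapes, splice-site occupancy, exon definition."""

import numpy as np
import pytest

import specklesplice as ss
from specklesplice.kmer import KmerEnergyTable
from specklesplice.positioning import (
    Segment,
    TranscriptAnnotation,
    competing_site_ensemble,
    cut_energy,
    exon_definition_probability,
    interface_landscape,
    splice_site_occupancy,
)
from specklesplice.thermo import delta_g, usage_from_delta_g

SR, HN = "AAAAAA", "CCCCCC"
MOTIF_TABLE = KmerEnergyTable.from_motif_sets(6, [SR], [HN])


def random_transcript(seed, length=180):
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGU"), size=length))
    bounds = [0, *sorted(rng.choice(np.arange(10, length - 9), size=4, replace=False)), length]
    labels = ["exon", "intron"] * 3
    segments = [(a, b, lab) for a, b, lab in zip(bounds, bounds[1:], labels)]
    return TranscriptAnnotation(seq, segments)


def naive_side_energy(transcript, cut, orientation, table):
    """Brute-force window scan restricted to the speckle side."""
    seq = transcript.sequence
    k = table.k
    lo, hi = (0, cut) if orientation == "5prime" else (cut, len(seq))
    return sum(table[seq[i : i + k]] for i in range(lo, hi - k + 1))


class TestTranscriptAnnotation:
    def test_splice_site_classification(self):
        tr = TranscriptAnnotation("A" * 30, [(0, 10, "exon"), (10, 20, "intron"), (20, 30, "exon")])
        assert [(s.position, s.kind) for s in tr.splice_sites] == [(10, "5ss"), (20, "3ss")]
        assert [s.exon_segment_index for s in tr.splice_sites] == [0, 2]

    @pytest.mark.parametrize(
        "segments,message",
        [
            ([(0, 10, "exon"), (12, 30, "intron")], "without gaps"),
            ([(0, 12, "exon"), (10, 30, "intron")], "without gaps"),
            ([(0, 10, "exon"), (10, 30, "exon")], "alternate"),
            ([(5, 30, "exon")], "start at 0"),
            ([(0, 20, "exon")], "length"),
            ([], "at least one"),
        ],
    )
    def test_invalid_segmentations_rejected(self, segments, message):
        with pytest.raises(ValueError, match=message):
            TranscriptAnnotation("A" * 30, segments)

    def test_invalid_segment_label_rejected(self):
        with pytest.raises(ValueError, match="exon"):
            Segment(0, 10, "utr")


class TestCutEnergy:
    def test_zero_table_everywhere_zero(self):
        tr = random_transcript(0)
        for cut in (0, 17, len(tr)):
            assert cut_energy(tr, cut, "5prime", KmerEnergyTable.zeros(6)) == 0.0

    def test_two_occurrences_sum(self):
        # two disjoint AAAAAA windows... tiling "A"*7 gives 2 overlapping windows
        tr = TranscriptAnnotation("A" * 7 + "G" * 13, [(0, 10, "exon"), (10, 20, "intron")])
        table = KmerEnergyTable.from_dict(6, {"AAAAAA": -1.0})
        assert cut_energy(tr, 10, "5prime", table) == -2.0

    def test_cut_outside_sequence_rejected(self):
        tr = random_transcript(1)
        with pytest.raises(ValueError, match="outside"):
            cut_energy(tr, len(tr) + 1, "5prime", KmerEnergyTable.zeros(6))

    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("orientation", ["5prime", "3prime"])
    def test_matches_bruteforce_side_scan(self, seed, orientation):
        tr = random_transcript(seed)
        table = KmerEnergyTable.random(6, scale=0.5, seed=seed + 100)
        for cut in [0, 3, 40, 97, len(tr)]:
            assert cut_energy(tr, cut, orientation, table) == pytest.approx(
                naive_side_energy(tr, cut, orientation, table), abs=1e-9
            )


class TestLandscape:
    def test_zero_table_flat_profile(self):
        tr = random_transcript(2)
        assert np.all(interface_landscape(tr, KmerEnergyTable.zeros(6)) == 0.0)

    @pytest.mark.parametrize("orientation", ["5prime", "3prime"])
    def test_profile_equals_per_cut_energy(self, orientation):
        tr = random_transcript(3)
        table = KmerEnergyTable.random(6, scale=0.5, seed=11)
        profile = interface_landscape(tr, table, orientation)
        assert profile.shape == (len(tr) + 1,)
        direct = [cut_energy(tr, c, orientation, table) for c in range(len(tr) + 1)]
        assert np.allclose(profile, direct, atol=1e-9)

    def test_valley_at_composition_switch(self):
        # 5' half favors the speckle, 3' half disfavors it: the 5'-side
        # landscape decreases through the first half and rises through the second
        seq = "A" * 60 + "G" * 60
        tr = TranscriptAnnotation(seq, [(0, 60, "exon"), (60, 120, "intron")])
        table = KmerEnergyTable.from_motif_sets(6, ["AAAAAA"], ["GGGGGG"])
        profile = interface_landscape(tr, table, "5prime")
        assert profile[0] == 0.0
        first = profile[6:61]   # cuts fully inside the A-run
        second = profile[66:]   # cuts past the junction windows
        assert np.all(np.diff(first) < 0)
        assert np.all(np.diff(second) > 0)
        assert abs(profile.argmin() - 62) <= 6

    def test_both_orientations_reconstruct_span_energy(self):
        # windows fully inside [s, e): lan5[e] + lan3[s] - total
        tr = random_transcript(4)
        table = KmerEnergyTable.random(6, scale=0.5, seed=12)
        lan5 = interface_landscape(tr, table, "5prime")
        lan3 = interface_landscape(tr, table, "3prime")
        total = lan5[-1]
        for seg in tr.segments:
            expected = sum(
                table[tr.sequence[i : i + 6]] for i in range(seg.start, seg.end - 5)
            )
            assert lan5[seg.end] + lan3[seg.start] - total == pytest.approx(expected, abs=1e-9)


class TestSpliceSiteOccupancy:
    def test_zero_table_uniform_over_sites(self):
        tr = TranscriptAnnotation("A" * 30, [(0, 10, "exon"), (10, 20, "intron"), (20, 30, "exon")])
        ens = splice_site_occupancy(tr, KmerEnergyTable.zeros(6))
        assert np.allclose(ens.weights, 0.5)
        assert abs(ens.weights.sum() - 1.0) < 1e-12

    def test_normalization_with_bulk_states(self):
        tr = random_transcript(5)
        table = KmerEnergyTable.random(6, scale=0.8, seed=13)
        ens = splice_site_occupancy(tr, table, include_bulk_states=True)
        assert abs(ens.weights.sum() - 1.0) < 1e-12
        assert len(ens) == len(tr.splice_sites) + 2

    def test_no_splice_sites_is_an_error(self):
        tr = TranscriptAnnotation("A" * 20, [(0, 20, "exon")])
        with pytest.raises(ValueError, match="no annotated splice sites"):
            splice_site_occupancy(tr, KmerEnergyTable.zeros(6))

    def test_two_competing_sites_reduce_to_two_state_model(self):
        """With the speckle 3' of the cut, a two-cut ensemble whose second cut
        closes the region reproduces the two-state usage ratio exactly."""
        table = KmerEnergyTable.random(6, scale=0.4, seed=21)
        region = "ACGGAUACGGAUCCGAUAGGCAAUC"
        full = "GGCAUCGAUG" + region
        ens = competing_site_ensemble(full, [10, len(full)], table)
        ratio = ens.states[0].weight / ens.states[1].weight
        expected = usage_from_delta_g(delta_g(region, table)).ratio
        assert ratio == pytest.approx(expected, rel=1e-9)


class TestPositionDependentDuality:
    """SREs flip sign with position; SR and hnRNP words act antagonistically."""

    CUT = 40  # 5'SS of the first exon
    EXONIC, INTRONIC = 20, 50

    def occupancy(self, transcript):
        ens = splice_site_occupancy(transcript, MOTIF_TABLE, include_bulk_states=True)
        return ens.site_occupancy()[self.CUT]

    def test_sr_word_enhances_exonic_represses_intronic(self, toy_transcript_factory):
        base = self.occupancy(toy_transcript_factory())
        assert self.occupancy(toy_transcript_factory(self.EXONIC, SR)) > base
        assert self.occupancy(toy_transcript_factory(self.INTRONIC, SR)) < base

    def test_hnrnp_word_mirrors_sr_word(self, toy_transcript_factory):
        base = self.occupancy(toy_transcript_factory())
        assert self.occupancy(toy_transcript_factory(self.EXONIC, HN)) < base
        assert self.occupancy(toy_transcript_factory(self.INTRONIC, HN)) > base

    def test_equal_magnitude_words_shift_energies_antisymmetrically(
        self, toy_transcript_factory
    ):
        """The energy landscape of the SR insertion is the exact negation of
        the hnRNP insertion's (relative to baseline), by construction of the
        additive model."""
        base = toy_transcript_factory()
        with_sr = toy_transcript_factory(self.EXONIC, SR)
        with_hn = toy_transcript_factory(self.EXONIC, HN)
        e0 = interface_landscape(base, MOTIF_TABLE)
        e_sr = interface_landscape(with_sr, MOTIF_TABLE)
        e_hn = interface_landscape(with_hn, MOTIF_TABLE)
        assert np.allclose(e_sr - e0, -(e_hn - e0), atol=1e-12)


class TestExonDefinition:
    def test_zero_table_uniform_over_states(self, toy_transcript_factory):
        # 4 splice-site states + 1 U state, no bulk
        p = exon_definition_probability(toy_transcript_factory(), 1, KmerEnergyTable.zeros(6))
        assert p == pytest.approx(1 / 5)

    def test_sr_enrichment_raises_u_state_weight(self, toy_transcript_factory):
        base = exon_definition_probability(
            toy_transcript_factory(), 1, MOTIF_TABLE, include_bulk_states=True
        )
        enriched = exon_definition_probability(
            toy_transcript_factory(85, SR), 1, MOTIF_TABLE, include_bulk_states=True
        )
        assert enriched > base

    def test_hnrnp_enrichment_lowers_u_state_weight(self, toy_transcript_factory):
        base = exon_definition_probability(
            toy_transcript_factory(), 1, MOTIF_TABLE, include_bulk_states=True
        )
        depleted = exon_definition_probability(
            toy_transcript_factory(85, HN), 1, MOTIF_TABLE, include_bulk_states=True
        )
        assert depleted < base

    def test_terminal_exon_rejected(self, toy_transcript_factory):
        with pytest.raises(ValueError, match="terminal"):
            exon_definition_probability(toy_transcript_factory(), 0, MOTIF_TABLE)

    def test_unknown_exon_index_rejected(self, toy_transcript_factory):
        with pytest.raises(ValueError, match="out of range"):
            exon_definition_probability(toy_transcript_factory(), 7, MOTIF_TABLE)
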