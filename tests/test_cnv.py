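"""Copy-number discretization: thresholds, binning, per-chromosome counts."""
import numpy as np
import pytest

from nodulephylo import (CNState, SegmentCNV, SimulationConfig, ValidationError,
                         binarize_bins, call_segment_state,
                         cnv_counts_per_chromosome, simulate_patient,
                         tile_genome)
from nodulephylo.matrix import ROOT_TAXON


class TestSegmentState:
    @pytest.mark.parametrize("copy,state", [
        (2.0, CNState.NEUTRAL),
        (3.0, CNState.AMP),     # threshold inclusive
        (0.5, CNState.DEL),     # threshold inclusive
        (2.99, CNState.NEUTRAL),
        (0.51, CNState.NEUTRAL),
        (5.0, CNState.AMP),
        (0.0, CNState.DEL),
    ])
    def test_thresholds(self, copy, state):
        assert call_segment_state(copy) is state

    def test_negative_copy_rejected(self):
        with pytest.raises(ValidationError):
            call_segment_state(-0.1)


class TestTiling:
    def test_bins_tile_without_gaps_or_overlaps(self):
        bins = tile_genome([("chr1", 250_000)], 100_000)
        assert [(b.start, b.end) for b in bins] == [
            (0, 100_000), (100_000, 200_000), (200_000, 250_000)]


class TestBinarize:
    GENOME = [("chr1", 300_000)]

    def test_worked_midpoint_example(self):
        # segment [50000,250000) copy 4 covers bin midpoints 50000 and
        # 150000 but not 250000 (half-open end): exactly 2 AMP bins
        segs = {"s1": [SegmentCNV("chr1", 50_000, 250_000, 4.0)]}
        m = binarize_bins(segs, self.GENOME, encoding="ordered-ternary")
        assert m.n_characters == 2
        assert (m.row("s1") == int(CNState.AMP)).all()
        assert m.characters == ["chr1:0-100000", "chr1:100000-200000"]

    def test_no_alterations_empty_matrix(self):
        m = binarize_bins({"s1": [], "s2": []}, self.GENOME)
        assert m.n_characters == 0

    def test_neutral_segments_equal_no_segments(self):
        covered = binarize_bins(
            {"s1": [SegmentCNV("chr1", 0, 300_000, 2.0)]}, self.GENOME)
        assert covered.n_characters == 0

    def test_binary_pair_encoding(self):
        segs = {"s1": [SegmentCNV("chr1", 0, 100_000, 4.0),
                       SegmentCNV("chr1", 200_000, 300_000, 0.0)],
                "s2": []}
        m = binarize_bins(segs, self.GENOME, encoding="binary-pair")
        assert m.semantics == "binary"
        amp = m.states[:, [c.endswith(":AMP") for c in m.characters]]
        dele = m.states[:, [c.endswith(":DEL") for c in m.characters]]
        assert amp[0].sum() == 1 and dele[0].sum() == 1
        assert not m.row("s2").any()

    def test_encodings_agree_on_non_neutral_cells(self, rng):
        segs = {}
        for s in ("a", "b", "c"):
            start = int(rng.integers(0, 2)) * 100_000
            copy = float(rng.choice([0.0, 2.0, 4.0]))
            segs[s] = [SegmentCNV("chr1", start, start + 100_000, copy)]
        tern = binarize_bins(segs, self.GENOME, encoding="ordered-ternary",
                             drop_constant=False)
        pair = binarize_bins(segs, self.GENOME, encoding="binary-pair",
                             drop_constant=False)
        nn_tern = tern.states != int(CNState.NEUTRAL)
        nn_pair = (pair.states.reshape(len(segs), -1, 2).sum(axis=2)) > 0
        assert np.array_equal(nn_tern, nn_pair)

    def test_invariant_to_segment_order(self, rng):
        segs = [SegmentCNV("chr1", s, s + 50_000, c)
                for s, c in [(0, 3.0), (100_000, 0.5), (200_000, 4.0)]]
        base = binarize_bins({"s1": segs}, self.GENOME)
        for _ in range(5):
            perm = [segs[i] for i in rng.permutation(len(segs))]
            m = binarize_bins({"s1": perm}, self.GENOME)
            assert np.array_equal(m.states, base.states)
            assert m.characters == base.characters

    def test_refining_bins_never_loses_altered_bins(self):
        segs = {"s1": [SegmentCNV("chr1", 30_000, 170_000, 4.0)]}
        coarse = binarize_bins(segs, self.GENOME, bin_size=100_000,
                               encoding="ordered-ternary")
        fine = binarize_bins(segs, self.GENOME, bin_size=50_000,
                             encoding="ordered-ternary")
        assert fine.n_characters >= coarse.n_characters

    def test_root_taxon_is_all_neutral(self):
        segs = {"s1": [SegmentCNV("chr1", 0, 100_000, 4.0)], "s2": []}
        m = binarize_bins(segs, self.GENOME, encoding="ordered-ternary",
                          include_root=True)
        assert (m.row(ROOT_TAXON) == int(CNState.NEUTRAL)).all()

    def test_unknown_chromosome_rejected(self):
        segs = {"s1": [SegmentCNV("chrX", 0, 100_000, 4.0)]}
        with pytest.raises(ValidationError, match="chrX"):
            binarize_bins(segs, self.GENOME)

    def test_simulated_events_of_two_bins_always_detected(self):
        """Every injected CNV of length >= 2 bins yields >= 1 altered bin."""
        config = SimulationConfig(model="independent", n_cnv_events=5,
                                  cnv_event_length=400_000, seed=5)
        truth, _, _, samples = simulate_patient(config, 0)
        for sid, segs in truth.cnv.items():
            if not segs:
                continue
            m = binarize_bins({sid: segs}, config.genome,
                              encoding="ordered-ternary")
            altered = m.row(sid) != int(CNState.NEUTRAL)
            for seg in segs:
                if seg.length >= 200_000:
                    cols = [j for j, c in enumerate(m.characters)
                            if c.startswith(seg.chrom + ":")]
                    assert altered[cols].any()


class TestCounts:
    def test_all_neutral_zero(self):
        segs = {"s1": [SegmentCNV("chr1", 0, 100_000, 2.0)]}
        table = cnv_counts_per_chromosome(segs, ["chr1", "chr2"])
        assert table.to_numpy().sum() == 0

    def test_per_chromosome_counts(self):
        segs = {"s1": [SegmentCNV("chr1", i * 100_000, (i + 1) * 100_000, 4.0)
                       for i in range(3)]
                + [SegmentCNV("chr2", 0, 100_000, 0.0)]}
        table = cnv_counts_per_chromosome(segs, ["chr1", "chr2", "chr3"])
        assert table.loc["s1", "chr1"] == 3
        assert table.loc["s1", "chr2"] == 1
        assert table.loc["s1", "chr3"] == 0

    def test_total_count_conservation_on_simulation(self):
        """Summed per-chromosome counts equal the number of injected
        (non-neutral) events carried by each sample."""
        config = SimulationConfig(model="independent", n_cnv_events=6, seed=9)
        truth, _, segments, samples = simulate_patient(config, 0)
        table = cnv_counts_per_chromosome(segments)
        for s in samples:
            assert table.loc[s.sample_id].sum() == len(truth.cnv[s.sample_id])
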