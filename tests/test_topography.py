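"""Topography analyses: G4 scan, profiles, deciles, strand asymmetry."""

import numpy as np
import pandas as pd
import pytest

from mutascope.catalogs import MutationRecord
from mutascope.topography import (
    GenomicTrack,
    autocorrelation_peak,
    nucleosome_profile,
    profile_g4_enrichment,
    replication_asymmetry,
    scan_g4,
    simulate_matched_mutations,
    timing_deciles,
    timing_distribution,
    transcriptional_asymmetry,
)


def _rec(pos, ref="A", alt="T", chrom="chr1"):
    return MutationRecord(chrom, pos, ref, alt, 0.5, "s")


def _interval_track(rows, kind="g4", cols=("chrom", "start", "end", "name", "score", "strand")):
    return GenomicTrack(kind=kind, data=pd.DataFrame(rows, columns=list(cols)[: len(rows[0])]))


def _signal_track(rows, kind="nucleosome"):
    return GenomicTrack(kind=kind, data=pd.DataFrame(rows, columns=["chrom", "start", "end", "value"]))


class TestG4Scan:
    def test_plus_strand_motif_found(self):
        genome = {"chr1": "AA" + "GGGTGGGTGGGTGGG" + "AA"}
        track = scan_g4(genome)
        assert len(track.data) == 1
        row = track.data.iloc[0]
        assert (row.start, row.end, row.strand) == (2, 17, "+")

    def test_two_runs_do_not_match(self):
        assert scan_g4({"chr1": "AAGGGTGGGAA"}).data.empty

    def test_minus_strand_motif_found(self):
        track = scan_g4({"chr1": "TT" + "CCCACCCACCCACCC" + "TT"})
        assert list(track.data["strand"]) == ["-"]


class TestMatchedSimulation:
    GENOME = {"chr1": "TTTTTACATTTTTTTTTTACATTTTT"}  # ACA at 0-based 5 and 18

    def test_unique_alternative_is_deterministic(self):
        # C>T at 1-based 7 (context ACA); only other ACA centered at 1-based 20
        sim, skipped = simulate_matched_mutations(
            [_rec(7, "C", "T")], self.GENOME, max_dist=30, seed=0
        )
        assert skipped == 0 and sim[0].pos == 20

    def test_unique_context_skipped(self):
        genome = {"chr1": "TTTTTGCGTTTTT"}
        sim, skipped = simulate_matched_mutations(
            [_rec(7, "C", "T")], genome, max_dist=6, seed=0
        )
        assert sim == [] and skipped == 1

    def test_seed_reproducibility(self, small_study, treated_denovo):
        subs = [r for r in treated_denovo if r.is_substitution][:200]
        a, _ = simulate_matched_mutations(subs, small_study.genome, seed=3)
        b, _ = simulate_matched_mutations(subs, small_study.genome, seed=3)
        assert [r.pos for r in a] == [r.pos for r in b]


class TestG4Profile:
    def test_constant_coverage_gives_flat_unit_score(self):
        genome = {"chr1": "A" * 5000}
        track = _interval_track([("chr1", 0, 5000, "g4", 0, "+")])
        prof = profile_g4_enrichment([_rec(2500)], track, genome, window=200)
        assert np.allclose(prof.score, 1.0)

    def test_single_window_arithmetic(self):
        genome = {"chr1": "A" * 10000}
        # one G4 covering offsets +100..+120 relative to the mutation at 3000
        track = _interval_track([("chr1", 3099, 3120, "g4", 0, "+")])
        prof = profile_g4_enrichment([_rec(3000)], track, genome, window=2000)
        w1 = prof.offsets.size
        assert prof.at(110) == pytest.approx(w1 / 21)
        assert prof.at(0) == 0.0
        assert prof.score.mean() == pytest.approx(1.0, abs=1e-6)

    def test_no_overlap_rejected(self):
        genome = {"chr1": "A" * 1000}
        track = _interval_track([("chr1", 900, 950, "g4", 0, "+")])
        with pytest.raises(ValueError):
            profile_g4_enrichment([_rec(100)], track, genome, window=100)


class TestNucleosomeProfile:
    def test_constant_signal_gives_flat_profile(self):
        genome = {"chr1": "A" * 4000}
        track = _signal_track([("chr1", 0, 4000, 2.5)])
        prof = nucleosome_profile([_rec(2000), _rec(2100)], track, genome, window=1000)
        assert np.allclose(prof.score, 2.5)

    def test_single_mutation_reads_raw_signal(self):
        genome = {"chr1": "A" * 3000}
        track = _signal_track(
            [("chr1", 0, 1500, 1.0), ("chr1", 1500, 3000, 4.0)]
        )
        prof = nucleosome_profile([_rec(1500)], track, genome, window=10)
        # offsets -5..-1 fall in [0,1500) -> 1.0; 0..+5 in [1500,...) -> 4.0
        assert np.allclose(prof.score[:5], 1.0) and np.allclose(prof.score[6:], 4.0)

    def test_truncated_window_at_contig_edge(self):
        genome = {"chr1": "A" * 1000}
        track = _signal_track([("chr1", 0, 1000, 3.0)])
        with pytest.warns(UserWarning):
            prof = nucleosome_profile([_rec(5)], track, genome, window=100)
        in_range = prof.offsets >= -4
        assert np.allclose(prof.score[in_range], 3.0)
        assert np.isnan(prof.score[~in_range]).all()

    def test_periodic_signal_autocorrelation(self):
        x = 1 + np.cos(2 * np.pi * np.arange(2001) / 200)
        lag, _ = autocorrelation_peak(x, 150, 260)
        assert abs(lag - 200) <= 1  # finite-window estimator bias



class TestTimingDeciles:
    def test_linear_gradient_equal_segments(self):
        genome = {"chr1": "A" * 100_000}
        rows = [("chr1", s, s + 1000, s / 100_000) for s in range(0, 100_000, 1000)]
        edges = timing_deciles(_signal_track(rows, kind="timing"), genome)
        assert len(edges) == 11
        inner = edges[1:-1]
        assert np.all(np.diff(inner) > 0)
        assert np.allclose(inner, np.linspace(0.1, 0.9, 9), atol=0.011)

    def test_two_valued_track(self):
        genome = {"chr1": "A" * 10_000}
        rows = [("chr1", 0, 5000, 0.0), ("chr1", 5000, 10_000, 1.0)]
        edges = timing_deciles(_signal_track(rows, kind="timing"), genome)
        assert edges[5] in (0.0, 1.0) or 0.0 < edges[5] < 1.0

    def test_constant_track_rejected(self):
        genome = {"chr1": "A" * 10_000}
        with pytest.raises(ValueError):
            timing_deciles(_signal_track([("chr1", 0, 10_000, 1.0)], kind="timing"), genome)


class TestTimingDistribution:
    def _gradient(self, L):
        rows = [("chr1", s, min(s + 500, L), s / L) for s in range(0, L, 500)]
        return _signal_track(rows, kind="timing")

    def test_all_mutations_in_earliest_decile(self):
        L = 50_000
        genome = {"chr1": "A" * L}
        track = self._gradient(L)
        recs = [_rec(p) for p in range(100, 2000, 100)]
        sims = [_rec(p + 7) for p in range(100, 2000, 100)]
        dist = timing_distribution(recs, track, genome, sims, n_boot=20, seed=1)
        assert dist.observed[0] == pytest.approx(1.0)
        assert dist.observed.sum() == pytest.approx(1.0)

    def test_uniform_mutations_near_uniform_deciles(self, rng):
        L = 100_000
        genome = {"chr1": "A" * L}
        track = self._gradient(L)
        pos = rng.choice(np.arange(1000, L - 1000), size=2000, replace=False)
        recs = [_rec(int(p)) for p in pos]
        dist = timing_distribution(recs, track, genome, recs, n_boot=20, seed=2)
        se = np.sqrt(0.1 * 0.9 / 2000)
        assert np.all(np.abs(dist.observed - 0.1) <= 4 * se)
        assert dist.observed.sum() == pytest.approx(1.0)

    def test_seed_reproducibility(self):
        L = 20_000
        genome = {"chr1": "A" * L}
        track = self._gradient(L)
        recs = [_rec(p) for p in range(500, 19_000, 50)]
        a = timing_distribution(recs, track, genome, recs, n_boot=15, seed=5)
        b = timing_distribution(recs, track, genome, recs, n_boot=15, seed=5)
        assert np.array_equal(a.predicted_mean, b.predicted_mean)


class TestStrandAsymmetry:
    GENES = [("chr1", 100, 200, "g+", 0, "+"), ("chr1", 300, 400, "g-", 0, "-")]

    def test_pyrimidine_on_coding_strand_is_untranscribed(self):
        track = _interval_track(self.GENES, kind="genes")
        # T>C with ref T (pyrimidine) on plus strand, inside the + gene
        asym = transcriptional_asymmetry([_rec(150, "T", "C")], track)
        row = asym.table.set_index("class").loc["T>C"]
        assert (row["untranscribed"], row["transcribed"]) == (1, 0)

    def test_same_mutation_in_minus_gene_is_transcribed(self):
        track = _interval_track(self.GENES, kind="genes")
        asym = transcriptional_asymmetry([_rec(350, "T", "C")], track)
        row = asym.table.set_index("class").loc["T>C"]
        assert (row["untranscribed"], row["transcribed"]) == (0, 1)

    def test_outside_and_overlap_excluded(self):
        genes = self.GENES + [("chr1", 150, 250, "g2-", 0, "-")]
        track = _interval_track(genes, kind="genes")
        asym = transcriptional_asymmetry(
            [_rec(180, "T", "C"), _rec(500, "T", "C")], track
        )
        assert asym.n_assigned == 0 and asym.n_excluded == 2

    def test_complement_involution_leaves_counts_unchanged(self, rng):
        """Complementing all alleles and flipping gene strands is a no-op."""
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        recs = []
        for _ in range(200):
            ref = "ACGT"[rng.integers(4)]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            recs.append(_rec(int(rng.integers(100, 400)), ref, str(alt)))
        track = _interval_track(self.GENES, kind="genes")
        flipped_rows = [
            (c, s, e, n, sc, "-" if st == "+" else "+")
            for c, s, e, n, sc, st in self.GENES
        ]
        flipped = _interval_track(flipped_rows, kind="genes")
        comp_recs = [
            MutationRecord(r.chrom, r.pos, comp[r.ref], comp[r.alt], r.vaf, r.sample)
            for r in recs
        ]
        t1 = transcriptional_asymmetry(recs, track).table
        t2 = transcriptional_asymmetry(comp_recs, flipped).table
        pd.testing.assert_frame_equal(t1, t2)

    def test_missing_strand_rejected(self):
        track = _interval_track([("chr1", 0, 100)], cols=("chrom", "start", "end"))
        with pytest.raises(ValueError):
            transcriptional_asymmetry([_rec(50)], track)


class TestReplicationAsymmetry:
    def test_missing_track_skips_with_notice(self):
        with pytest.warns(UserWarning):
            assert replication_asymmetry([_rec(1)], None) is None

    def test_empty_overlap_gives_zero_counts(self):
        track = _interval_track(
            [("chr1", 1000, 2000, "right")], kind="repl_direction",
            cols=("chrom", "start", "end", "name"),
        )
        asym = replication_asymmetry([_rec(10, "T", "C")], track)
        assert asym.n_assigned == 0
        assert asym.table["p_value"].isna().all()

    def test_planted_leading_bias_recovered(self, rng):
        track = _interval_track(
            [("chr1", 0, 10_000, "right")], kind="repl_direction",
            cols=("chrom", "start", "end", "name"),
        )
        # pyrimidine on plus in right-replicating region => leading
        recs = [
            _rec(int(p), "T", "C") for p in rng.integers(10, 9990, size=150)
        ] + [_rec(int(p), "A", "G") for p in rng.integers(10, 9990, size=50)]
        asym = replication_asymmetry(recs, track)
        row = asym.table.set_index("class").loc["T>C"]
        assert row["leading"] == 150 and row["lagging"] == 50
        assert row["q_value"] < 0.05
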