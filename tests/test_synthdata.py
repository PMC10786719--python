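"""Synthetic-study generator: planted truth, reproducibility, emission."""

import numpy as np
import pytest

from mutascope.catalogs import (
    build_catalog,
    filter_vaf,
    flag_polyclonal,
    pair_doublets,
    read_mutations,
    subtract_parental,
)
from mutascope.synthdata import (
    StudyConfig,
    generate_genome,
    generate_study,
    generate_tracks,
    write_study,
)
from mutascope.topography import autocorrelation_peak, scan_g4, timing_deciles


def _tiny_config(**kw):
    defaults = dict(
        genome_length=120_000,
        n_genes=8,
        gene_length=1500,
        g4_density=1e-4,
        genotypes=("WT",),
        n_subclones=2,
        sbs_burden={"DMSO": 150, "CX": 1200},
        dbs_burden={"DMSO": 2, "CX": 25},
        indel_burden={"DMSO": 15, "CX": 50},
        n_parental=40,
    )
    defaults.update(kw)
    return StudyConfig(**defaults)


class TestGenome:
    def test_zero_density_means_no_g4(self):
        genome, track = generate_genome(_tiny_config(g4_density=0.0), seed=1)
        assert track.data.empty
        assert len(genome["chr1"]) == 120_000

    def test_planted_g4s_all_recovered_by_scan(self):
        genome, planted = generate_genome(_tiny_config(g4_density=2e-4), seed=2)
        scanned = scan_g4(genome)
        found = 0
        for row in planted.data.itertuples(index=False):
            hits = scanned.data[
                (scanned.data["strand"] == row.strand)
                & (scanned.data["start"] < row.end)
                & (scanned.data["end"] > row.start)
            ]
            found += not hits.empty
        assert found == len(planted.data)  # recall 1.0

    def test_seed_reproducibility(self):
        g1, t1 = generate_genome(_tiny_config(), seed=3)
        g2, t2 = generate_genome(_tiny_config(), seed=3)
        assert g1 == g2 and t1.data.equals(t2.data)

    def test_infeasible_density_rejected(self):
        with pytest.raises(ValueError):
            generate_genome(_tiny_config(g4_density=0.1), seed=1)


class TestTracks:
    def test_nucleosome_track_periodicity(self):
        cfg = _tiny_config()
        genome, _ = generate_genome(cfg, seed=4)
        tracks, _ = generate_tracks(genome, cfg, seed=4)
        sig = tracks["nucleosome"].signal_array("chr1", 20_000)
        lag, _ = autocorrelation_peak(sig, 150, 260)
        assert lag == cfg.nucleosome_period

    def test_timing_gradient_gives_contiguous_deciles(self):
        cfg = _tiny_config()
        genome, _ = generate_genome(cfg, seed=5)
        tracks, _ = generate_tracks(genome, cfg, seed=5)
        edges = timing_deciles(tracks["timing"], genome)
        assert np.all(np.diff(edges[1:-1]) > 0)

    def test_zero_genes(self):
        cfg = _tiny_config(n_genes=0)
        genome, _ = generate_genome(cfg, seed=6)
        tracks, models = generate_tracks(genome, cfg, seed=6)
        assert tracks["genes"].data.empty and models == []

    def test_infeasible_gene_count_rejected(self):
        cfg = _tiny_config(n_genes=500, gene_length=3000)
        genome, _ = generate_genome(cfg, seed=7)
        with pytest.raises(ValueError):
            generate_tracks(genome, cfg, seed=7)


class TestStudy:
    def test_roundtrip_catalogs_match_truth_exactly(self, small_study, study_catalogs):
        for name, cat in study_catalogs.items():
            truth = small_study.truth[name]
            if truth.polyclonal:
                continue  # low-VAF records are VAF-filtered by design
            assert np.array_equal(cat.sbs96, truth.sbs96), name
            assert np.array_equal(cat.dbs78, truth.dbs78), name
            assert np.array_equal(cat.indel, truth.indel), name

    def test_polyclonal_sample_flagged(self, small_study):
        for name, truth in small_study.truth.items():
            arm = ".".join(name.split(".")[:2])
            denovo = subtract_parental(
                small_study.samples[name], small_study.parental[arm]
            )
            poly, mean_vaf = flag_polyclonal(denovo)
            assert poly == truth.polyclonal
            if poly:
                assert mean_vaf < 0.4

    def test_zero_doublet_rate_gives_no_adjacent_pairs(self):
        cfg = _tiny_config(dbs_burden={"DMSO": 0, "CX": 0})
        study = generate_study(cfg, seed=8)
        for name, records in study.denovo.items():
            paired = pair_doublets([r for r in records if r.is_substitution])
            # placement keeps one free base between events: no chance pairs
            assert not paired.dbs and not paired.multi

    def test_parental_mutations_are_shared_and_subtracted(self, small_study):
        arm = "WT.CX"
        parental_keys = {r.key for r in small_study.parental[arm]}
        assert parental_keys
        for name in small_study.arm_samples("WT", "CX"):
            full_keys = {r.key for r in small_study.samples[name]}
            assert parental_keys <= full_keys
            denovo = subtract_parental(small_study.samples[name], small_study.parental[arm])
            assert not parental_keys & {r.key for r in denovo}

    def test_sibling_subtraction_equals_parental_subtraction(self, small_study):
        names = small_study.arm_samples("WT", "CX")
        for name in names:
            sibs = [small_study.samples[s] for s in names if s != name]
            via_sibs = subtract_parental(small_study.samples[name], siblings=sibs)
            via_parent = subtract_parental(
                small_study.samples[name], small_study.parental["WT.CX"]
            )
            assert {r.key for r in via_sibs} == {r.key for r in via_parent}


class TestEmission:
    def test_written_vcfs_reproduce_truth_catalogs(self, tmp_path):
        cfg = _tiny_config()
        study = generate_study(cfg, seed=9)
        write_study(study, tmp_path)
        import pyfaidx

        genome = pyfaidx.Fasta(str(tmp_path / "genome.fa"))
        name = "WT.CX.s1"
        records = read_mutations(tmp_path / f"{name}.vcf", name)
        parental = read_mutations(tmp_path / "WT.CX.parental.vcf")
        denovo = filter_vaf(subtract_parental(records, parental))
        cat = build_catalog(denovo, genome, name)
        truth = study.truth[name]
        assert np.array_equal(cat.sbs96, truth.sbs96)
        assert np.array_equal(cat.dbs78, truth.dbs78)
        assert np.array_equal(cat.indel, truth.indel)
        assert (tmp_path / "truth.json").exists()
        assert (tmp_path / "genes.gtf").exists()
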