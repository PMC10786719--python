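"""Damage potential: consequence enumeration, flat normalization, blosum62."""

import numpy as np
import pytest
from Bio.Seq import Seq

from mutascope.channels import SBS96_CHANNELS, SBS96_INDEX, classify_sbs
from mutascope.damage import (
    CONSEQUENCES,
    ConsequenceContextTable,
    GeneModel,
    blosum_scores,
    build_consequence_table,
    consequence_ratio,
    damage_report,
    normalized_ratio,
)
from mutascope.signatures import SignatureProfile


def _flat():
    return SignatureProfile.flat(SBS96_CHANNELS)


def _single_channel(channel):
    probs = np.zeros(96)
    probs[SBS96_INDEX[channel]] = 1.0
    return SignatureProfile(tuple(SBS96_CHANNELS), probs)


@pytest.fixture(scope="module")
def toy():
    """Two genes (one minus-strand, one spliced) on a 200 bp genome."""
    rng = np.random.default_rng(123)
    seq = list(rng.choice(list("ACGT"), size=200))
    # gene A: plus strand, single exon, 5 codons at 1-based 21..35
    seq[20:35] = list("ATGTGGAAACCCTAA")
    # gene B: minus strand CDS = revcomp of 1-based 61..75
    seq[60:75] = list(str(Seq("ATGCATGAATGGTAG").reverse_complement()))
    # gene C: plus strand, two exons 101..109 and 121..126 (intron 110..120)
    seq[100:109] = list("ATGAAATGG")
    seq[120:126] = list("CATTAA")
    genome = {"c1": "".join(seq)}
    models = [
        GeneModel("geneA", "c1", "+", [(21, 35)]),
        GeneModel("geneB", "c1", "-", [(61, 75)]),
        GeneModel("geneC", "c1", "+", [(101, 109), (121, 126)]),
    ]
    return genome, models


def brute_force_table(genome, models):
    """Independent enumeration: list every possible substitution directly."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    table = {c: np.zeros(96, dtype=int) for c in CONSEQUENCES}
    N = np.zeros(96, dtype=int)
    aa_subs = {}
    seq = genome["c1"]
    for m in models:
        positions = [p for s, e in m.cds_exons for p in range(s, e + 1)]
        if m.strand == "-":
            positions = positions[::-1]
        cds = "".join(
            seq[p - 1] if m.strand == "+" else comp[seq[p - 1]] for p in positions
        )
        prot = str(Seq(cds).translate())
        for ci, pos in enumerate(positions):
            codon_i, off = divmod(ci, 3)
            codon = cds[codon_i * 3 : codon_i * 3 + 3]
            for alt_coding in "ACGT":
                if alt_coding == cds[ci]:
                    continue
                new = codon[:off] + alt_coding + codon[off + 1 :]
                old_aa, new_aa = prot[codon_i], str(Seq(new).translate())
                if new_aa == old_aa:
                    cons = "synonymous"
                elif new_aa == "*":
                    cons = "stop_gain"
                else:
                    cons = "missense"
                gref = cds[ci] if m.strand == "+" else comp[cds[ci]]
                galt = alt_coding if m.strand == "+" else comp[alt_coding]
                channel = classify_sbs(gref, galt, seq[pos - 2 : pos + 1])
                k = SBS96_INDEX[channel]
                N[k] += 1
                table[cons][k] += 1
                if cons == "missense" and "*" not in (old_aa, new_aa):
                    key = (old_aa, new_aa, channel)
                    aa_subs[key] = aa_subs.get(key, 0) + 1
        for (s1, e1), (s2, _) in zip(m.cds_exons, m.cds_exons[1:]):
            for pos in (e1 + 1, e1 + 2, s2 - 2, s2 - 1):
                gref = seq[pos - 1]
                for galt in "ACGT":
                    if galt == gref:
                        continue
                    channel = classify_sbs(gref, galt, seq[pos - 2 : pos + 1])
                    k = SBS96_INDEX[channel]
                    N[k] += 1
                    table["splice_site"][k] += 1
    return N, table, aa_subs


class TestEnumeration:
    def test_genetic_code_examples(self):
        genome = {"c1": "TTTTT" + "ATGTGGTAA" + "TTTTT"}
        t = build_consequence_table([GeneModel("g", "c1", "+", [(6, 14)])], genome)
        # TGG codon: G>A at either G creates a stop (TAG / TGA)
        assert t.n["stop_gain"].sum() >= 2
        genome2 = {"c1": "TTTTT" + "ATGAAATAA" + "TTTTT"}
        t2 = build_consequence_table([GeneModel("g", "c1", "+", [(6, 14)])], genome2)
        # AAA -> AAG is Lys->Lys
        assert t2.n["synonymous"].sum() >= 1
        # 3 substitutions per coding base
        assert t2.N.sum() == 3 * 9

    def test_cds_not_multiple_of_three_skipped(self):
        genome = {"c1": "ATGAAATAAT" * 4}
        with pytest.warns(UserWarning, match="divisible"):
            t = build_consequence_table([GeneModel("g", "c1", "+", [(1, 10)])], genome)
        assert t.n_skipped_genes == 1 and t.N.sum() == 0

    def test_agrees_with_brute_force_oracle(self, toy):
        genome, models = toy
        t = build_consequence_table(models, genome)
        N, table, aa_subs = brute_force_table(genome, models)
        assert np.array_equal(t.N, N)
        for c in CONSEQUENCES:
            assert np.array_equal(t.n[c], table[c]), c
        assert t.aa_subs == aa_subs

    def test_conservation_per_channel(self, toy):
        genome, models = toy
        t = build_consequence_table(models, genome)
        total = sum(t.n.values())
        assert np.array_equal(total, t.N)


class TestRatios:
    def test_flat_signature_normalizes_to_one(self, toy):
        genome, models = toy
        t = build_consequence_table(models, genome)
        for c in CONSEQUENCES:
            if t.n[c].sum() == 0:
                continue
            assert normalized_ratio(_flat(), t, c) == pytest.approx(1.0)

    def test_single_channel_ratio(self, toy):
        genome, models = toy
        t = build_consequence_table(models, genome)
        k = int(np.argmax(t.N))
        sig = _single_channel(SBS96_CHANNELS[k])
        for c in CONSEQUENCES:
            assert consequence_ratio(sig, t, c) == pytest.approx(t.n[c][k] / t.N[k])

    def test_ratio_matches_direct_computation(self, toy):
        genome, models = toy
        t = build_consequence_table(models, genome)
        rng = np.random.default_rng(5)
        probs = rng.dirichlet(np.ones(96))
        sig = SignatureProfile(tuple(SBS96_CHANNELS), probs)
        for c in CONSEQUENCES:
            direct = (probs @ t.n[c]) / (probs @ t.N)
            assert consequence_ratio(sig, t, c) == pytest.approx(direct)

    def test_mass_on_stop_gain_channel_raises_normalized_ratio(self, toy):
        genome, models = toy
        t = build_consequence_table(models, genome)
        density = np.where(t.N > 0, t.n["stop_gain"] / np.maximum(t.N, 1), 0)
        k = int(np.argmax(density))
        flat_probs = np.full(96, 1 / 96)
        base = normalized_ratio(
            SignatureProfile(tuple(SBS96_CHANNELS), flat_probs), t, "stop_gain"
        )
        shifted = flat_probs.copy()
        shifted[k] += 0.5
        shifted /= shifted.sum()
        up = normalized_ratio(
            SignatureProfile(tuple(SBS96_CHANNELS), shifted), t, "stop_gain"
        )
        assert up > base == pytest.approx(1.0)

    def test_no_mass_on_gene_channels_rejected(self):
        t = ConsequenceContextTable()
        t.add("A[C>A]A", "missense")
        sig = _single_channel("T[T>G]T")
        with pytest.raises(ValueError):
            consequence_ratio(sig, t, "missense")


class TestBlosum:
    def test_flat_signature_normalized_to_zero(self, toy):
        genome, models = toy
        t = build_consequence_table(models, genome)
        raw, norm = blosum_scores(_flat(), t)
        assert norm == pytest.approx(0.0)

    def test_dominant_trp_to_arg_scores_minus_three(self):
        """A single W->R missense inventory gives the published blosum62 value."""
        t = ConsequenceContextTable()
        ch = "A[C>T]A"
        t.add(ch, "missense")
        t.aa_subs[("W", "R", ch)] = 1
        sig = _single_channel(ch)
        raw, _ = blosum_scores(sig, t)
        assert raw == pytest.approx(-3.0)

    def test_empty_inventory_rejected(self):
        t = ConsequenceContextTable()
        with pytest.raises(ValueError):
            blosum_scores(_flat(), t)

    def test_damage_report_keys(self, toy):
        genome, models = toy
        t = build_consequence_table(models, genome)
        report = damage_report(_flat(), t)
        assert set(CONSEQUENCES) <= set(report)
        assert report["blosum62_normalized"] == pytest.approx(0.0)
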