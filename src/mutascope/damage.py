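"""Damage-potential scoring of SBS96 signatures.

For a gene set, every possible single-base substitution in coding
sequence (and at the 2 canonical splice-site bases flanking each intron)
is enumerated and classified by consequence — stop gain, missense,
synonymous or splice site — and by SBS96 channel of its genomic
trinucleotide context. A signature's propensity for a consequence is
the signature-weighted fraction of possible substitutions with that
consequence, normalized to the same fraction under a flat (uniform)
signature; a normalized stop-gain ratio of 2 means the signature is
twice as likely as random to create stop gains in the gene set.
Missense severity is summarized as the signature-weighted mean blosum62
score, reported relative to the flat signature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Data import CodonTable

from .catalogs import fetch_seq
from .channels import SBS96_CHANNELS, SBS96_INDEX, classify_sbs, revcomp
from .signatures import SignatureProfile

CONSEQUENCES = ("stop_gain", "missense", "synonymous", "splice_site")

_CODON_TABLE = CodonTable.unambiguous_dna_by_id[1]
_CODON_TO_AA = dict(_CODON_TABLE.forward_table)
for _stop in _CODON_TABLE.stop_codons:
    _CODON_TO_AA[_stop] = "*"

BLOSUM62 = substitution_matrices.load("BLOSUM62")

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
_BASES = "ACGT"


@dataclass
class GeneModel:
    """One canonical transcript: ordered genomic CDS exons (1-based, closed)."""

    gene_id: str
    chrom: str
    strand: str
    cds_exons: list[tuple[int, int]]

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_exons)


@dataclass
class ConsequenceContextTable:
    """Counts of possible substitutions per SBS96 channel and consequence."""

    N: np.ndarray = field(default_factory=lambda: np.zeros(96, dtype=np.int64))
    n: dict[str, np.ndarray] = field(
        default_factory=lambda: {
            c: np.zeros(96, dtype=np.int64) for c in CONSEQUENCES
        }
    )
    # (from_aa, to_aa, channel) -> count, for blosum62 scoring of missense
    aa_subs: dict[tuple[str, str, str], int] = field(default_factory=dict)
    n_genes: int = 0
    n_skipped_genes: int = 0

    def add(self, channel: str, consequence: str) -> None:
        k = SBS96_INDEX[channel]
        self.N[k] += 1
        self.n[consequence][k] += 1


# ---------------------------------------------------------------------------
# Gene model reading
# ---------------------------------------------------------------------------

def read_gene_models(
    gtf_path: str | Path, gene_subset: Sequence[str] | None = None
) -> list[GeneModel]:
    """Canonical (longest-CDS) transcript per gene from a GTF."""
    import gffutils

    db = gffutils.create_db(
        str(gtf_path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique", disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    by_transcript: dict[str, list] = {}
    meta: dict[str, tuple[str, str, str]] = {}
    for cds in db.features_of_type("CDS"):
        tid = cds.attributes.get("transcript_id", [cds.id])[0]
        gid = cds.attributes.get("gene_id", [tid])[0]
        by_transcript.setdefault(tid, []).append((cds.start, cds.end))
        meta[tid] = (gid, cds.seqid, cds.strand)
    best: dict[str, GeneModel] = {}
    for tid, exons in by_transcript.items():
        gid, chrom, strand = meta[tid]
        if gene_subset is not None and gid not in set(gene_subset):
            continue
        model = GeneModel(gid, chrom, strand, sorted(exons))
        prev = best.get(gid)
        if prev is None or model.cds_length > prev.cds_length:
            best[gid] = model
    return list(best.values())


# ---------------------------------------------------------------------------
# Enumeration
# ---------------------------------------------------------------------------

def _channel_at(genome, chrom: str, pos: int, gref: str, galt: str) -> str | None:
    context = fetch_seq(genome, chrom, pos - 1, pos + 1)
    if len(context) != 3 or "N" in context or context[1] != gref:
        return None
    return classify_sbs(gref, galt, context)


def build_consequence_table(
    models: Sequence[GeneModel] | str | Path,
    genome,
    gene_subset: Sequence[str] | None = None,
) -> ConsequenceContextTable:
    """Enumerate all possible substitutions in a gene set.

    Every CDS position contributes its 3 possible substitutions
    (consequence via the standard genetic code, strand aware); the 2
    canonical splice-site bases at each intron end contribute 3
    substitutions each as splice_site. Channels use the genomic
    (plus-strand, pyrimidine-collapsed) trinucleotide context,
    independent of gene strand. Genes whose CDS length is not a
    multiple of 3 are skipped with a warning.
    """
    if not isinstance(models, (list, tuple)):
        models = read_gene_models(models, gene_subset)
    elif gene_subset is not None:
        keep = set(gene_subset)
        models = [m for m in models if m.gene_id in keep]
    table = ConsequenceContextTable()
    for model in models:
        if model.cds_length % 3 != 0:
            warnings.warn(f"gene {model.gene_id}: CDS length not divisible by 3; skipped")
            table.n_skipped_genes += 1
            continue
        _add_gene(table, model, genome)
        table.n_genes += 1
    return table


def _add_gene(table: ConsequenceContextTable, model: GeneModel, genome) -> None:
    # genomic positions of CDS bases in transcription order
    positions: list[int] = []
    for start, end in model.cds_exons:
        positions.extend(range(start, end + 1))
    if model.strand == "-":
        positions = positions[::-1]
    genomic = [fetch_seq(genome, model.chrom, p, p) for p in positions]
    coding = [
        b if model.strand == "+" else _COMP.get(b, "N") for b in genomic
    ]
    coding_seq = "".join(coding)
    for i0 in range(0, len(coding_seq) - 2, 3):
        codon = coding_seq[i0 : i0 + 3]
        if "N" in codon:
            continue
        old_aa = _CODON_TO_AA.get(codon)
        if old_aa == "*" and i0 < len(coding_seq) - 3:
            warnings.warn(f"gene {model.gene_id}: interior stop codon at {i0 // 3}")
        for j in range(3):
            ci = i0 + j
            pos = positions[ci]
            base = coding_seq[ci]
            for alt in _BASES:
                if alt == base:
                    continue
                new_codon = codon[:j] + alt + codon[j + 1 :]
                new_aa = _CODON_TO_AA.get(new_codon)
                if new_aa == old_aa:
                    consequence = "synonymous"
                elif new_aa == "*":
                    consequence = "stop_gain"
                else:
                    consequence = "missense"
                gref = base if model.strand == "+" else _COMP[base]
                galt = alt if model.strand == "+" else _COMP[alt]
                channel = _channel_at(genome, model.chrom, pos, gref, galt)
                if channel is None:
                    continue
                table.add(channel, consequence)
                if consequence == "missense" and old_aa != "*" and new_aa != "*":
                    key = (old_aa, new_aa, channel)
                    table.aa_subs[key] = table.aa_subs.get(key, 0) + 1
    _add_splice_sites(table, model, genome)


def _add_splice_sites(table: ConsequenceContextTable, model: GeneModel, genome) -> None:
    exons = model.cds_exons
    for (s1, e1), (s2, _e2) in zip(exons, exons[1:]):
        if s2 - e1 - 1 < 4:  # intron too short for two 2 bp splice sites
            continue
        splice_pos = [e1 + 1, e1 + 2, s2 - 2, s2 - 1]
        for pos in splice_pos:
            gref = fetch_seq(genome, model.chrom, pos, pos)
            if gref not in _BASES:
                continue
            for galt in _BASES:
                if galt == gref:
                    continue
                channel = _channel_at(genome, model.chrom, pos, gref, galt)
                if channel is not None:
                    table.add(channel, "splice_site")


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def consequence_ratio(
    signature: SignatureProfile, table: ConsequenceContextTable, consequence: str
) -> float:
    """Signature-weighted fraction of possible substitutions with a consequence.

    ratio = sum_k s_k * n_{k,c} / sum_k s_k * N_k
    """
    if consequence not in CONSEQUENCES:
        raise ValueError(f"unknown consequence {consequence!r}")
    s = signature.probs
    denom = float(s @ table.N)
    if denom == 0:
        raise ValueError("signature has no mass on channels present in the gene set")
    return float(s @ table.n[consequence]) / denom


def normalized_ratio(
    signature: SignatureProfile, table: ConsequenceContextTable, consequence: str
) -> float:
    """Consequence ratio normalized to a flat (uniform) signature."""
    flat = SignatureProfile.flat(SBS96_CHANNELS)
    flat_ratio = consequence_ratio(flat, table, consequence)
    if flat_ratio == 0:
        raise ValueError(f"flat signature has zero {consequence} ratio in this gene set")
    return consequence_ratio(signature, table, consequence) / flat_ratio


def blosum_scores(
    signature: SignatureProfile, table: ConsequenceContextTable
) -> tuple[float, float]:
    """(raw, normalized) signature-weighted mean blosum62 over missense.

    raw = sum over amino-acid substitutions of blosum62(from, to) *
    s_channel * count, divided by the total weight; normalized = raw
    minus the raw score of the flat signature. Lower scores mean more
    dissimilar amino acids, hence likelier detrimental effects.
    """
    if not table.aa_subs:
        raise ValueError("gene set yields no missense substitutions")

    def weighted(probs: np.ndarray) -> float:
        total_w = 0.0
        total = 0.0
        for (aa_from, aa_to, channel), count in table.aa_subs.items():
            w = probs[SBS96_INDEX[channel]] * count
            total_w += w
            total += BLOSUM62[aa_from, aa_to] * w
        if total_w == 0:
            raise ValueError("signature has no missense mass in this gene set")
        return total / total_w

    raw = weighted(signature.probs)
    flat_raw = weighted(SignatureProfile.flat(SBS96_CHANNELS).probs)
    return raw, raw - flat_raw


def damage_report(
    signature: SignatureProfile, table: ConsequenceContextTable
) -> dict[str, float]:
    """Normalized consequence ratios plus blosum62 scores for one signature."""
    out = {c: normalized_ratio(signature, table, c) for c in CONSEQUENCES}
    raw, norm = blosum_scores(signature, table)
    out["blosum62_raw"] = raw
    out["blosum62_normalized"] = norm
    return out
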