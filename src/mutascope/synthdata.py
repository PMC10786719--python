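"""Synthetic mutation-accumulation studies with a known ground truth.

Generates a complete toy study — genome, genomic tracks, clone
hierarchy and per-subclone mutation calls — in which every quantity the
pipeline estimates is planted by construction: the treatment and
background signatures over each channel set, the in-cis doublet load,
topographic biases (linker enrichment, G4 avoidance, replication-timing
trend, transcribed-strand depletion), parental-shared mutations, and
polyclonal (low-VAF) samples.

The design mirrors a drug mutagenesis experiment: isogenic genotypes are
treated or mock-treated for an equal culture period, daughter subclones
are isolated per arm, and de novo mutations are read against the
parental clone. Treated subclones accumulate the same background load
as untreated ones plus treatment-signature mutations, whose placement
is modulated by the planted topography weights (rejection sampling with
per-position weight = product of the planted bias factors, so recovery
tests have an exact generative model).

Emitted per-sample calls are reference-consistent VCFs; all placements
keep at least one untouched base between events so that catalogs built
from the emitted calls equal the planted channel draws exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalogs import MutationRecord
from .channels import (
    DBS78_CHANNELS,
    ID83_CHANNELS,
    SBS96_CHANNELS,
    classify_indel,
    revcomp,
)
from .damage import GeneModel
from .seqindex import ContextIndex, DinucIndex
from .topography import GenomicTrack


# ---------------------------------------------------------------------------
# Planted signatures
# ---------------------------------------------------------------------------

def treatment_sbs_signature() -> np.ndarray:
    """T>A / T>C dominated substitution signature peaking at ATA and ATG."""
    w = np.full(96, 0.1)
    for i, ch in enumerate(SBS96_CHANNELS):
        if "[T>A]" in ch or "[T>C]" in ch:
            w[i] = 1.0
    for peak in ("A[T>A]A", "A[T>A]G", "A[T>C]A", "A[T>C]G"):
        w[SBS96_CHANNELS.index(peak)] = 12.0
    return w / w.sum()


def background_sbs_signature() -> np.ndarray:
    """Broad culture-intrinsic background with CpG C>T elevation."""
    w = np.ones(96)
    for i, ch in enumerate(SBS96_CHANNELS):
        if "[C>T]G" in ch:
            w[i] = 3.0
    return w / w.sum()


def treatment_dbs_signature() -> np.ndarray:
    """Doublet signature on AT>CA/GA/TA and TG>AT/CT/GT."""
    w = np.zeros(78)
    for ch in ("AT>CA", "AT>GA", "AT>TA", "TG>AT", "TG>CT", "TG>GT"):
        w[DBS78_CHANNELS.index(ch)] = 1.0
    return w / w.sum()


def background_dbs_signature() -> np.ndarray:
    return np.full(78, 1.0 / 78)


def treatment_indel_signature() -> np.ndarray:
    """1 bp T indels, short tandem duplications and microhomology deletions."""
    weights = {
        "1:Del:T:1": 0.25, "1:Del:T:2": 0.15,
        "1:Ins:T:0": 0.10, "1:Ins:T:1": 0.10,
        "2:Ins:R:1": 0.10, "3:Ins:R:1": 0.05, "4:Ins:R:1": 0.05,
        "5+:Del:M:1": 0.10, "5+:Del:M:2": 0.10,
    }
    w = np.zeros(83)
    for ch, v in weights.items():
        w[ID83_CHANNELS.index(ch)] = v
    return w / w.sum()


def background_indel_signature() -> np.ndarray:
    weights = {
        "1:Del:C:1": 0.2, "1:Del:T:1": 0.2,
        "1:Ins:C:0": 0.15, "1:Ins:T:0": 0.15,
        "2:Del:R:1": 0.15, "2:Del:R:2": 0.15,
    }
    w = np.zeros(83)
    for ch, v in weights.items():
        w[ID83_CHANNELS.index(ch)] = v
    return w / w.sum()


# ---------------------------------------------------------------------------
# Configuration and truth
# ---------------------------------------------------------------------------

@dataclass
class StudyConfig:
    """Study conditions for one synthetic experiment.

    Defaults follow the toy scale of the emulated design: several
    isogenic genotypes crossed with a treatment and a vehicle control,
    2-4 daughter subclones per arm after ~equal culture time, heavy
    treatment substitution burdens versus a modest background, a
    tenfold in-cis doublet excess under treatment, and planted
    topographic biases on the treatment mutations.
    """

    genome_length: int = 10_000_000
    contig: str = "chr1"
    gc_content: float = 0.4
    g4_density: float = 1e-4  # planted motifs per bp
    nucleosome_period: int = 200
    nucleosome_core: int = 147
    core_signal: float = 1.0
    linker_signal: float = 0.1
    linker_factor: float = 3.0  # placement weight for linker positions
    g4_factor: float = 0.2  # placement weight inside G4 +/- flank (avoidance)
    g4_flank: int = 100
    timing_factor: float = 1.0  # weight = factor**timing; 1.0 = no trend
    timing_bin: int = 10_000
    strand_factor: float = 2.0  # untranscribed:transcribed for asym classes
    asym_classes: tuple[str, ...] = ("T>A", "T>C", "T>G", "C>A")
    n_genes: int = 200
    gene_length: int = 5000
    genotypes: tuple[str, ...] = ("WT", "dBRCA1", "dBRCA2")
    treatments: tuple[str, ...] = ("DMSO", "CX")
    control_treatment: str = "DMSO"
    n_subclones: int = 3
    sbs_burden: dict = field(default_factory=lambda: {"DMSO": 1500, "CX": 20000})
    dbs_burden: dict = field(default_factory=lambda: {"DMSO": 20, "CX": 200})
    indel_burden: dict = field(default_factory=lambda: {"DMSO": 100, "CX": 400})
    n_parental: int = 300
    vaf_mean: float = 0.5
    vaf_sd: float = 0.04
    polyclonal_samples: tuple[str, ...] = ()
    polyclonal_vaf: tuple[float, float] = (0.05, 0.35)
    sbs_signature: np.ndarray = field(default_factory=treatment_sbs_signature)
    sbs_background: np.ndarray = field(default_factory=background_sbs_signature)
    dbs_signature: np.ndarray = field(default_factory=treatment_dbs_signature)
    dbs_background: np.ndarray = field(default_factory=background_dbs_signature)
    indel_signature: np.ndarray = field(default_factory=treatment_indel_signature)
    indel_background: np.ndarray = field(default_factory=background_indel_signature)

    def is_treated(self, treatment: str) -> bool:
        return treatment != self.control_treatment


@dataclass
class SampleTruth:
    """Planted channel draws and mixture for one subclone's de novo set."""

    sample: str
    genotype: str
    treatment: str
    polyclonal: bool
    sbs96: np.ndarray
    dbs78: np.ndarray
    indel: np.ndarray
    n_novel_sbs: int  # treatment-signature component of the SBS draw
    n_background_sbs: int


@dataclass
class Study:
    config: StudyConfig
    genome: dict[str, str]
    g4_track: GenomicTrack
    tracks: dict[str, GenomicTrack]
    gene_models: list[GeneModel]
    samples: dict[str, list[MutationRecord]]  # full call sets (parental + de novo)
    denovo: dict[str, list[MutationRecord]]
    parental: dict[str, list[MutationRecord]]  # per arm
    sample_arm: dict[str, tuple[str, str]]  # sample -> (genotype, treatment)
    truth: dict[str, SampleTruth]

    def arm_samples(self, genotype: str, treatment: str) -> list[str]:
        return [
            s for s, (g, t) in self.sample_arm.items()
            if g == genotype and t == treatment
        ]


# ---------------------------------------------------------------------------
# Genome and tracks
# ---------------------------------------------------------------------------

def generate_genome(
    config: StudyConfig, seed: int = 0
) -> tuple[dict[str, str], GenomicTrack]:
    """Random genome with planted G4 motifs at recorded intervals."""
    if config.genome_length < 10_000:
        raise ValueError("genome length must be at least 10 kb")
    rng = np.random.default_rng(seed)
    L = config.genome_length
    gc = config.gc_content
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seq = rng.choice(list("ACGT"), size=L, p=probs)

    n_g4 = int(round(config.g4_density * L))
    rows = []
    if n_g4 > 0:
        # non-overlapping slots with clearance; error if the density is infeasible
        slot = 60
        max_slots = (L - 2000) // slot
        if n_g4 > max_slots:
            raise ValueError("G4 density too high to place without overlap")
        starts = np.sort(rng.choice(max_slots, size=n_g4, replace=False)) * slot + 1000
        for s in starts:
            strand = "+" if rng.random() < 0.5 else "-"
            motif = _g4_motif(rng)
            if strand == "-":
                motif = revcomp(motif)
            seq[s : s + len(motif)] = list(motif)
            rows.append((config.contig, int(s), int(s + len(motif)), "g4", 0, strand))
    df = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "score", "strand"]
    )
    genome = {config.contig: "".join(seq)}
    return genome, GenomicTrack(kind="g4", data=df)


def _g4_motif(rng: np.random.Generator) -> str:
    parts = []
    for i in range(4):
        parts.append("G" * int(rng.integers(3, 5)))
        if i < 3:
            loop_len = int(rng.integers(1, 8))
            parts.append("".join(rng.choice(list("ACT"), size=loop_len)))
    return "".join(parts)


def generate_tracks(
    genome: Mapping[str, str], config: StudyConfig, seed: int = 0
) -> tuple[dict[str, GenomicTrack], list[GeneModel]]:
    """Nucleosome, timing, gene and replication-direction tracks.

    The nucleosome signal is a square wave (high on cores, low on
    linkers) with the configured period; replication timing is a linear
    early-to-late gradient; genes are non-overlapping two-exon CDS
    models with random strands; replication direction alternates
    left/right between evenly spaced origins.
    """
    rng = np.random.default_rng(seed)
    chrom = config.contig
    L = len(genome[chrom])
    period, core = config.nucleosome_period, config.nucleosome_core

    rows = []
    pos = 0
    while pos < L:
        core_end = min(pos + core, L)
        rows.append((chrom, pos, core_end, config.core_signal))
        if core_end < L:
            rows.append((chrom, core_end, min(pos + period, L), config.linker_signal))
        pos += period
    nuc = GenomicTrack(
        kind="nucleosome",
        data=pd.DataFrame(rows, columns=["chrom", "start", "end", "value"]),
    )

    rows = []
    for start in range(0, L, config.timing_bin):
        end = min(start + config.timing_bin, L)
        rows.append((chrom, start, end, (start + end) / 2 / L))
    timing = GenomicTrack(
        kind="timing",
        data=pd.DataFrame(rows, columns=["chrom", "start", "end", "value"]),
    )

    glen = config.gene_length - (config.gene_length % 3)  # placed CDS multiple of 3
    spacing = L // max(config.n_genes + 1, 1)
    if config.n_genes > 0 and spacing < glen + 200:
        raise ValueError("gene count infeasible for this genome length")
    gene_rows = []
    models = []
    for i in range(config.n_genes):
        start0 = spacing * (i + 1)  # 0-based
        strand = "+" if rng.random() < 0.5 else "-"
        # two CDS exons with an intron, total CDS length = glen
        exon1 = glen // 2 - ((glen // 2) % 3)
        intron = 100
        s1, e1 = start0 + 1, start0 + exon1  # 1-based closed
        s2, e2 = e1 + intron + 1, e1 + intron + (glen - exon1)
        gene_rows.append((chrom, start0, e2, f"gene{i}", 0, strand))
        models.append(GeneModel(f"gene{i}", chrom, strand, [(s1, e1), (s2, e2)]))
    genes = GenomicTrack(
        kind="genes",
        data=pd.DataFrame(
            gene_rows, columns=["chrom", "start", "end", "name", "score", "strand"]
        ),
    )

    origin_spacing = max(L // 10, 200_000 if L >= 2_000_000 else L // 4)
    rows = []
    pos = 0
    direction = "right"
    while pos < L:
        end = min(pos + origin_spacing // 2, L)
        rows.append((chrom, pos, end, direction))
        direction = "left" if direction == "right" else "right"
        pos = end
    repl = GenomicTrack(
        kind="repl_direction",
        data=pd.DataFrame(rows, columns=["chrom", "start", "end", "name"]),
    )
    tracks = {"nucleosome": nuc, "timing": timing, "genes": genes, "repl_direction": repl}
    return tracks, models


# ---------------------------------------------------------------------------
# Mutation placement
# ---------------------------------------------------------------------------

class _Placer:
    """Rejection sampler over context-matched sites with planted weights."""

    def __init__(
        self,
        config: StudyConfig,
        genome: Mapping[str, str],
        g4_track: GenomicTrack,
        tracks: Mapping[str, GenomicTrack],
    ) -> None:
        self.config = config
        self.chrom = config.contig
        self.seq = str(genome[self.chrom]).upper()
        L = len(self.seq)
        self.ctx = ContextIndex(genome)
        self.dinuc = DinucIndex(genome)

        self.g4_zone = np.zeros(L, dtype=bool)
        for row in g4_track.data.itertuples(index=False):
            lo = max(0, int(row.start) - config.g4_flank)
            hi = min(L, int(row.end) + config.g4_flank)
            self.g4_zone[lo:hi] = True

        self.gene_strand = np.zeros(L, dtype=np.int8)  # 0 none, 1 plus, 2 minus
        genes = tracks["genes"].data
        for row in genes.itertuples(index=False):
            self.gene_strand[int(row.start) : int(row.end)] = 1 if row.strand == "+" else 2

        self.timing = np.arange(L, dtype=np.float64) / L
        phase = np.arange(L) % config.nucleosome_period
        self.in_linker = phase >= config.nucleosome_core
        self.w_max = (
            max(config.linker_factor, 1.0)
            * max(config.g4_factor, 1.0)
            * max(config.strand_factor, 1.0)
            * max(config.timing_factor, 1.0, 1.0 / max(config.timing_factor, 1e-9))
        )

    def weight(self, pos0: int, cls: str | None, pyr_plus: bool, biased: bool) -> float:
        if not biased:
            return 1.0
        c = self.config
        w = c.linker_factor if self.in_linker[pos0] else 1.0
        if self.g4_zone[pos0]:
            w *= c.g4_factor
        w *= c.timing_factor ** self.timing[pos0]
        if cls in c.asym_classes:
            gs = self.gene_strand[pos0]
            if gs:
                untx = (gs == 1) == pyr_plus
                if untx:
                    w *= c.strand_factor
        return w

    def place_sbs(
        self, channel: str, rng: np.random.Generator, blocked: set[int], biased: bool
    ) -> MutationRecord | None:
        f5, rest = channel[0], channel[2:]
        ref_p, alt_p, f3 = rest[0], rest[2], rest[4]
        ctx_pyr = f5 + ref_p + f3
        ctx_pur = revcomp(ctx_pyr)
        n_pyr, n_pur = self.ctx.count(ctx_pyr), self.ctx.count(ctx_pur)
        if n_pyr + n_pur == 0:
            return None
        cls = f"{ref_p}>{alt_p}"
        for _ in range(2000):
            pyr_plus = rng.random() < n_pyr / (n_pyr + n_pur)
            tri = ctx_pyr if pyr_plus else ctx_pur
            _, pos = self.ctx.sample(tri, rng)
            pos0 = pos - 1
            if pos in blocked:
                continue
            if rng.random() * self.w_max > self.weight(pos0, cls, pyr_plus, biased):
                continue
            ref = self.seq[pos0]
            alt = alt_p if pyr_plus else revcomp(alt_p)
            blocked.update((pos - 1, pos, pos + 1))
            return MutationRecord(self.chrom, pos, ref, alt, 0.5)
        return None

    def place_dbs(
        self, channel: str, rng: np.random.Generator, blocked: set[int], biased: bool
    ) -> MutationRecord | None:
        ref_c, alt_c = channel.split(">")
        refs = {ref_c: alt_c}
        if revcomp(ref_c) != ref_c:
            refs[revcomp(ref_c)] = revcomp(alt_c)
        else:
            # palindromic reference doublet: both orientations share the ref
            pass
        counts = {d: self.dinuc.count(d) for d in refs}
        total = sum(counts.values())
        if total == 0:
            return None
        for _ in range(2000):
            r = rng.random() * total
            acc = 0.0
            for d, cnt in counts.items():
                acc += cnt
                if r < acc:
                    dref, dalt = d, refs[d]
                    break
            _, pos = self.dinuc.sample(dref, rng)
            pos0 = pos - 1
            if pos in blocked or (pos + 1) in blocked:
                continue
            if rng.random() * self.w_max > self.weight(pos0, None, True, biased):
                continue
            if revcomp(ref_c) == ref_c and rng.random() < 0.5:
                dalt = revcomp(dalt)  # palindromic ref: random orientation
            blocked.update(range(pos - 1, pos + 3))
            return MutationRecord(self.chrom, pos, dref, dalt, 0.5)
        return None

    def place_indel(
        self, channel: str, rng: np.random.Generator, blocked: set[int]
    ) -> MutationRecord | None:
        size_s, kind, base_s, _count = channel.split(":")
        size = 5 if size_s == "5+" else int(size_s)
        is_del = kind == "Del"
        L = len(self.seq)
        for _ in range(5000):
            pos = int(rng.integers(10, L - 10 - 8 * size))  # anchor, 1-based
            pos0 = pos - 1
            anchor = self.seq[pos0]
            if is_del:
                seq = self.seq[pos0 + 1 : pos0 + 1 + size]
            elif base_s in "CT":
                seq = base_s if rng.random() < 0.5 else revcomp(base_s)
            elif _count == "0":
                # non-repeat insertion: random unit, classify-check filters
                seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=size))
            else:
                # repeat insertion: duplicate the adjacent bases
                seq = self.seq[pos0 + 1 : pos0 + 1 + size]
            if "N" in seq or anchor not in "ACGT":
                continue
            if anchor == seq[-1]:
                continue  # not left-aligned
            span = range(pos, pos + (size if is_del else 0) + 1)
            if any(p in blocked for p in span):
                continue
            up = self.seq[max(pos0 - 40, 0) : pos0 + 1]
            down_start = pos0 + 1 + (size if is_del else 0)
            down = self.seq[down_start : down_start + 40 + 6 * size]
            if classify_indel(seq, is_del, up, down) != channel:
                continue
            if is_del:
                ref, alt = anchor + seq, anchor
            else:
                ref, alt = anchor, anchor + seq
            blocked.update(range(pos - 1, pos + (size if is_del else 0) + 2))
            return MutationRecord(self.chrom, pos, ref, alt, 0.5)
        return None


# ---------------------------------------------------------------------------
# Study sampling
# ---------------------------------------------------------------------------

def _draw_counts(
    rng: np.random.Generator, n: int, probs: np.ndarray
) -> np.ndarray:
    return rng.multinomial(n, probs) if n > 0 else np.zeros(probs.size, dtype=int)


def _vaf(rng: np.random.Generator, config: StudyConfig, polyclonal: bool) -> float:
    if polyclonal:
        lo, hi = config.polyclonal_vaf
        return float(rng.uniform(lo, hi))
    v = rng.normal(config.vaf_mean, config.vaf_sd)
    return float(np.clip(v, 0.3, 0.7))


def sample_mutations(
    config: StudyConfig,
    genome: Mapping[str, str],
    g4_track: GenomicTrack,
    tracks: Mapping[str, GenomicTrack],
    seed: int = 0,
) -> tuple[
    dict[str, list[MutationRecord]],
    dict[str, list[MutationRecord]],
    dict[str, list[MutationRecord]],
    dict[str, tuple[str, str]],
    dict[str, SampleTruth],
]:
    """Draw and place all mutations for every arm and subclone.

    Returns (samples, denovo, parental, sample_arm, truth); ``samples``
    holds full per-subclone call sets (parental-shared plus de novo).
    """
    rng = np.random.default_rng(seed)
    placer = _Placer(config, genome, g4_track, tracks)
    samples: dict[str, list[MutationRecord]] = {}
    denovo: dict[str, list[MutationRecord]] = {}
    parental: dict[str, list[MutationRecord]] = {}
    sample_arm: dict[str, tuple[str, str]] = {}
    truth: dict[str, SampleTruth] = {}

    control = config.control_treatment
    for genotype in config.genotypes:
        for treatment in config.treatments:
            arm = f"{genotype}.{treatment}"
            blocked: set[int] = set()
            par_records = []
            # parental-shared mutations, background signature, clonal VAF
            par_counts = _draw_counts(rng, config.n_parental, config.sbs_background)
            for ci, cnt in enumerate(par_counts):
                for _ in range(int(cnt)):
                    rec = placer.place_sbs(SBS96_CHANNELS[ci], rng, blocked, False)
                    if rec is not None:
                        par_records.append(
                            _with(rec, vaf=_vaf(rng, config, False), sample=arm + ".parental")
                        )
            parental[arm] = sorted(par_records, key=lambda r: (r.chrom, r.pos))

            treated = config.is_treated(treatment)
            n_bg = int(config.sbs_burden[control])
            n_total = int(config.sbs_burden[treatment])
            n_novel = max(n_total - n_bg, 0) if treated else 0
            for k in range(config.n_subclones):
                name = f"{arm}.s{k + 1}"
                poly = name in config.polyclonal_samples
                recs: list[MutationRecord] = []
                sbs_counts = _draw_counts(rng, n_bg, config.sbs_background)
                novel_counts = _draw_counts(rng, n_novel, config.sbs_signature)
                for ci in range(96):
                    for _ in range(int(sbs_counts[ci])):
                        rec = placer.place_sbs(SBS96_CHANNELS[ci], rng, blocked, False)
                        if rec is None:
                            sbs_counts[ci] -= 1
                            continue
                        recs.append(rec)
                    for _ in range(int(novel_counts[ci])):
                        rec = placer.place_sbs(SBS96_CHANNELS[ci], rng, blocked, True)
                        if rec is None:
                            novel_counts[ci] -= 1
                            continue
                        recs.append(rec)

                n_dbs = int(config.dbs_burden[treatment])
                dbs_probs = config.dbs_signature if treated else config.dbs_background
                dbs_counts = _draw_counts(rng, n_dbs, dbs_probs)
                dbs_records: list[MutationRecord] = []
                for ci in range(78):
                    for _ in range(int(dbs_counts[ci])):
                        rec = placer.place_dbs(DBS78_CHANNELS[ci], rng, blocked, treated)
                        if rec is None:
                            dbs_counts[ci] -= 1
                            continue
                        dbs_records.append(rec)

                n_ind = int(config.indel_burden[treatment])
                ind_probs = config.indel_signature if treated else config.indel_background
                ind_counts = _draw_counts(rng, n_ind, ind_probs)
                indel_records: list[MutationRecord] = []
                for ci in range(83):
                    for _ in range(int(ind_counts[ci])):
                        rec = placer.place_indel(ID83_CHANNELS[ci], rng, blocked)
                        if rec is None:
                            ind_counts[ci] -= 1
                            continue
                        indel_records.append(rec)

                de_novo: list[MutationRecord] = []
                for rec in recs + indel_records:
                    de_novo.append(_with(rec, vaf=_vaf(rng, config, poly), sample=name))
                for rec in dbs_records:
                    # emit in-cis doublets as two adjacent rows with one VAF
                    v = _vaf(rng, config, poly)
                    de_novo.append(
                        MutationRecord(rec.chrom, rec.pos, rec.ref[0], rec.alt[0], v, name)
                    )
                    de_novo.append(
                        MutationRecord(rec.chrom, rec.pos + 1, rec.ref[1], rec.alt[1], v, name)
                    )
                de_novo.sort(key=lambda r: (r.chrom, r.pos))
                full = sorted(
                    de_novo + [_with(r, sample=name) for r in parental[arm]],
                    key=lambda r: (r.chrom, r.pos),
                )
                samples[name] = full
                denovo[name] = de_novo
                sample_arm[name] = (genotype, treatment)
                truth[name] = SampleTruth(
                    sample=name,
                    genotype=genotype,
                    treatment=treatment,
                    polyclonal=poly,
                    sbs96=sbs_counts + novel_counts,
                    dbs78=dbs_counts,
                    indel=ind_counts,
                    n_novel_sbs=int(novel_counts.sum()),
                    n_background_sbs=int(sbs_counts.sum()),
                )
    return samples, denovo, parental, sample_arm, truth


def _with(rec: MutationRecord, **kw) -> MutationRecord:
    from dataclasses import replace

    return replace(rec, **kw)


def generate_study(config: StudyConfig | None = None, seed: int = 0) -> Study:
    """Generate a full synthetic study (genome, tracks, clones, truth)."""
    config = config or StudyConfig()
    sub = np.random.SeedSequence(seed).spawn(3)
    genome, g4_track = generate_genome(config, seed=int(sub[0].generate_state(1)[0] % 2**31))
    tracks, models = generate_tracks(genome, config, seed=int(sub[1].generate_state(1)[0] % 2**31))
    samples, denovo, parental, sample_arm, truth = sample_mutations(
        config, genome, g4_track, tracks, seed=int(sub[2].generate_state(1)[0] % 2**31)
    )
    return Study(
        config=config,
        genome=genome,
        g4_track=g4_track,
        tracks=tracks,
        gene_models=models,
        samples=samples,
        denovo=denovo,
        parental=parental,
        sample_arm=sample_arm,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Emission of standard formats
# ---------------------------------------------------------------------------

def write_fasta(genome: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_vcf(
    records: Sequence[MutationRecord], genome: Mapping[str, str],
    path: str | Path, sample: str,
) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, seq in genome.items():
            fh.write(f"##contig=<ID={chrom},length={len(seq)}>\n")
        fh.write(
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            '##FORMAT=<ID=VAF,Number=1,Type=Float,Description='
            '"Variant allele fraction">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample + "\n"
        )
        for rec in sorted(records, key=lambda r: (r.chrom, r.pos)):
            fh.write(
                f"{rec.chrom}\t{rec.pos}\t.\t{rec.ref}\t{rec.alt}\t.\tPASS\t.\t"
                f"GT:VAF\t0/1:{rec.vaf:.4f}\n"
            )


def write_gtf(models: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in models:
            attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.gene_id}.t1";'
            for start, end in m.cds_exons:
                fh.write(
                    f"{m.chrom}\tsynth\tCDS\t{start}\t{end}\t.\t{m.strand}\t0\t{attrs}\n"
                )


def write_study(study: Study, outdir: str | Path) -> None:
    """Emit the study as FASTA/VCF/BED/bedGraph/GTF plus a truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(study.genome, outdir / "genome.fa")
    study.g4_track.data.to_csv(outdir / "g4_planted.bed", sep="\t", header=False, index=False)
    study.tracks["nucleosome"].data.to_csv(
        outdir / "nucleosome.bedgraph", sep="\t", header=False, index=False
    )
    study.tracks["timing"].data.to_csv(
        outdir / "timing.bedgraph", sep="\t", header=False, index=False
    )
    study.tracks["genes"].data.to_csv(
        outdir / "genes.bed", sep="\t", header=False, index=False
    )
    study.tracks["repl_direction"].data.to_csv(
        outdir / "repl_direction.bed", sep="\t", header=False, index=False
    )
    write_gtf(study.gene_models, outdir / "genes.gtf")
    for name, recs in study.samples.items():
        write_vcf(recs, study.genome, outdir / f"{name}.vcf", name)
    for arm, recs in study.parental.items():
        write_vcf(recs, study.genome, outdir / f"{arm}.parental.vcf", arm + ".parental")
    truth = {
        name: {
            "genotype": t.genotype,
            "treatment": t.treatment,
            "polyclonal": t.polyclonal,
            "sbs96": t.sbs96.tolist(),
            "dbs78": t.dbs78.tolist(),
            "indel": t.indel.tolist(),
            "n_novel_sbs": t.n_novel_sbs,
            "n_background_sbs": t.n_background_sbs,
        }
        for name, t in study.truth.items()
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1))
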