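"""Mutation catalog construction.

Reads somatic mutation calls (VCF or tabular), applies the clonality
filters used for mutation-accumulation subclones (VAF > 0.2 per variant;
samples with mean VAF < 0.4 flagged polyclonal), subtracts
parental/shared mutations to obtain de novo sets, pairs adjacent
substitutions into doublets, and counts mutations over the SBS96 /
DBS78 / ID83 channel sets.

Coordinates are 1-based fully closed throughout this module (VCF
convention); interval inputs elsewhere use BED half-open coordinates and
are converted at their readers.
"""

from __future__ import annotations

import json
import warnings
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .channels import (
    DBS78_CHANNELS,
    DBS78_INDEX,
    ID83_CHANNELS,
    ID83_INDEX,
    SBS96_CHANNELS,
    SBS96_INDEX,
    classify_dbs,
    classify_indel,
    classify_sbs,
    indel_motif,
)

DEFAULT_MIN_VAF = 0.2
DEFAULT_POLYCLONAL_THRESHOLD = 0.4
DEFAULT_DUPLEX_MAX_VAF = 0.01


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class MutationRecord:
    """One somatic variant.

    ``pos`` is the 1-based position of the first changed base for
    substitutions, or of the anchor base for indels (left-aligned,
    single anchor-base convention: exactly one of ref/alt has length 1).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    vaf: float
    sample: str = ""
    lineage: str | None = None

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"ref equals alt at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if len(self.ref) != len(self.alt):
            if min(len(self.ref), len(self.alt)) != 1:
                raise ValueError(
                    f"indel at {self.chrom}:{self.pos} is not in anchor-base "
                    f"form: {self.ref}>{self.alt}"
                )

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_substitution(self) -> bool:
        return len(self.ref) == len(self.alt)

    @property
    def is_indel(self) -> bool:
        return not self.is_substitution

    @property
    def is_insertion(self) -> bool:
        return len(self.alt) > len(self.ref)

    @property
    def indel_seq(self) -> str:
        """Inserted or deleted bases (without the anchor)."""
        if self.is_insertion:
            return self.alt[1:]
        return self.ref[1:]


@dataclass
class SampleCatalog:
    """Fixed-order channel count vectors for one sample."""

    sample: str
    sbs96: np.ndarray = field(default_factory=lambda: np.zeros(96, dtype=int))
    dbs78: np.ndarray = field(default_factory=lambda: np.zeros(78, dtype=int))
    indel: np.ndarray = field(default_factory=lambda: np.zeros(83, dtype=int))
    n_multi_base: int = 0
    n_skipped: int = 0
    indel_motifs: Counter = field(default_factory=Counter)

    @property
    def n_sbs(self) -> int:
        return int(self.sbs96.sum())

    @property
    def n_dbs(self) -> int:
        return int(self.dbs78.sum())

    @property
    def n_indel(self) -> int:
        return int(self.indel.sum())

    def vector(self, kind: str) -> np.ndarray:
        return {"sbs": self.sbs96, "dbs": self.dbs78, "indel": self.indel}[kind]


@dataclass(frozen=True)
class DuplexResult:
    """Duplex-sequencing mutation burden for one sample."""

    sample: str
    n_mutations: int
    informative_bases: float

    @property
    def burden(self) -> float:
        """Mutations per megabase of informative duplex bases."""
        return self.n_mutations / (self.informative_bases / 1e6)


class PairedSubstitutions(NamedTuple):
    dbs: list[MutationRecord]
    sbs: list[MutationRecord]
    multi: list[list[MutationRecord]]


# ---------------------------------------------------------------------------
# Reference-sequence access
# ---------------------------------------------------------------------------

def fetch_seq(genome, chrom: str, start: int, end: int) -> str:
    """Reference slice [start, end], 1-based inclusive, clipped to the contig.

    ``genome`` may be a ``pyfaidx.Fasta`` or a plain mapping of contig
    name to sequence string.
    """
    contig = genome[chrom]
    start = max(start, 1)
    end = min(end, len(contig))
    if start > end:
        return ""
    return str(contig[start - 1 : end]).upper()


def contig_length(genome, chrom: str) -> int:
    return len(genome[chrom])


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def _normalize_alleles(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Trim shared suffix/prefix down to anchor-base convention."""
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def _expand_mnv(rec: MutationRecord) -> list[MutationRecord]:
    """Split a length-matched multi-base substitution into per-base records."""
    out = []
    for i, (r, a) in enumerate(zip(rec.ref, rec.alt)):
        if r != a:
            out.append(replace(rec, pos=rec.pos + i, ref=r, alt=a))
    return out


def _vaf_from_vcf_record(rec, sample_index: int):
    """FORMAT VAF, then FORMAT AF, then alt/(ref+alt) from AD."""
    for tag in ("VAF", "AF"):
        if tag in rec.format:
            val = rec.samples[sample_index].get(tag)
            if val is not None:
                return float(val[0] if isinstance(val, tuple) else val)
    if "AD" in rec.format:
        ad = rec.samples[sample_index].get("AD")
        if ad is not None and ad[0] is not None:
            total = sum(x for x in ad if x is not None)
            if total > 0:
                return sum(x for x in ad[1:] if x is not None) / total
    return None


def read_mutations(path: str | Path, sample: str = "") -> list[MutationRecord]:
    """Read mutation calls from a VCF (plain or bgzipped) or a TSV.

    TSV columns: chrom, pos, ref, alt, vaf (header optional).
    Multi-allelic VCF rows are split; alleles are trimmed to the
    left-aligned anchor-base convention; length-matched multi-base
    substitutions are expanded into per-base records (adjacent ones are
    re-merged later by :func:`pair_doublets`). Records are returned
    sorted by (chrom, pos).
    """
    path = Path(path)
    if path.suffix == ".gz" or path.suffix in (".vcf", ".bcf"):
        records = _read_vcf(path, sample)
    else:
        records = _read_tsv(path, sample)
    records.sort(key=lambda r: (r.chrom, r.pos, r.ref, r.alt))
    return _dedupe(records)


def _read_vcf(path: Path, sample: str) -> list[MutationRecord]:
    import pysam

    out: list[MutationRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        names = list(vcf.header.samples)
        sidx = names.index(sample) if sample in names else 0
        label = sample or (names[sidx] if names else "")
        for rec in vcf:
            if rec.alts is None:
                continue
            for alt in rec.alts:
                if alt is None or set(alt.upper()) - set("ACGT"):
                    continue
                vaf = _vaf_from_vcf_record(rec, sidx) if names else None
                if vaf is None:
                    raise ValueError(
                        f"{path}: record {rec.chrom}:{rec.pos} has no VAF/AF/AD "
                        "field; supply a VAF source"
                    )
                pos, ref_a, alt_a = _normalize_alleles(rec.pos, rec.ref.upper(), alt.upper())
                mrec = MutationRecord(rec.chrom, pos, ref_a, alt_a, vaf, label)
                if mrec.is_substitution and len(mrec.ref) > 1:
                    out.extend(_expand_mnv(mrec))
                else:
                    out.append(mrec)
    return out


def _read_tsv(path: Path, sample: str) -> list[MutationRecord]:
    try:
        df = pd.read_csv(path, sep=None, engine="python", dtype=str, comment="#")
    except Exception as exc:
        raise ValueError(f"{path}: cannot parse mutation table: {exc}") from exc
    cols = [c.lower() for c in df.columns]
    if "pos" not in cols or not {"chrom", "ref", "alt"} <= set(cols):
        # headerless: re-read with positional names
        df = pd.read_csv(
            path, sep=None, engine="python", dtype=str, comment="#", header=None,
            names=["chrom", "pos", "ref", "alt", "vaf"],
        )
    else:
        df.columns = cols
    if "vaf" not in df.columns or df["vaf"].isna().any():
        raise ValueError(
            f"{path}: missing vaf values; supply a 'vaf' column for every row"
        )
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            pos, ref, alt = _normalize_alleles(
                int(row.pos), str(row.ref).upper(), str(row.alt).upper()
            )
            rec = MutationRecord(row.chrom, pos, ref, alt, float(row.vaf), sample)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: malformed row {i}: {exc}") from exc
        if rec.is_substitution and len(rec.ref) > 1:
            out.extend(_expand_mnv(rec))
        else:
            out.append(rec)
    return out


def _dedupe(records: list[MutationRecord]) -> list[MutationRecord]:
    """Collapse duplicate (chrom,pos,ref,alt) keys to one record (max VAF)."""
    best: dict[tuple, MutationRecord] = {}
    dups = 0
    for rec in records:
        prev = best.get(rec.key)
        if prev is None:
            best[rec.key] = rec
        else:
            dups += 1
            if rec.vaf > prev.vaf:
                best[rec.key] = rec
    if dups:
        warnings.warn(f"collapsed {dups} duplicate variant rows (kept max VAF)")
    return sorted(best.values(), key=lambda r: (r.chrom, r.pos, r.ref, r.alt))


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def filter_vaf(
    records: Sequence[MutationRecord], min_vaf: float = DEFAULT_MIN_VAF
) -> list[MutationRecord]:
    """Keep records with VAF strictly above ``min_vaf`` (order preserved)."""
    return [r for r in records if r.vaf > min_vaf]


def flag_polyclonal(
    records: Sequence[MutationRecord],
    threshold: float = DEFAULT_POLYCLONAL_THRESHOLD,
) -> tuple[bool, float]:
    """Mean-VAF clonality check for one sample.

    Returns ``(is_polyclonal, mean_vaf)``; a sample is polyclonal iff
    its mean VAF is strictly below the threshold. Polyclonal samples are
    excluded from burden and signature quantitation downstream.
    """
    if not records:
        raise ValueError("cannot assess clonality of a sample with no records")
    mean_vaf = float(np.mean([r.vaf for r in records]))
    return mean_vaf < threshold, mean_vaf


def subtract_parental(
    subclone: Sequence[MutationRecord],
    parental: Sequence[MutationRecord] | None = None,
    siblings: Sequence[Sequence[MutationRecord]] | None = None,
) -> list[MutationRecord]:
    """De novo mutations of a subclone.

    With a parental clone: subclone minus the parental key set. Without
    one: subclone minus every key seen in at least one sibling subclone.
    """
    if parental is not None:
        drop = {r.key for r in parental}
    elif siblings:
        drop = {r.key for sib in siblings for r in sib}
    else:
        raise ValueError("need a parental clone or sibling subclones to subtract")
    return [r for r in subclone if r.key not in drop]


# ---------------------------------------------------------------------------
# Doublet pairing
# ---------------------------------------------------------------------------

def pair_doublets(records: Sequence[MutationRecord]) -> PairedSubstitutions:
    """Merge adjacent single-base substitutions into dinucleotide records.

    Exactly two substitutions at (pos, pos+1) on one contig become one
    doublet; runs of three or more adjacent substitutions are set aside
    as multi-base events, contributing to neither the SBS nor the DBS
    catalog.
    """
    subs = sorted(
        (r for r in records if r.is_substitution and len(r.ref) == 1),
        key=lambda r: (r.chrom, r.pos),
    )
    dbs: list[MutationRecord] = []
    sbs: list[MutationRecord] = []
    multi: list[list[MutationRecord]] = []
    run: list[MutationRecord] = []

    def flush() -> None:
        if not run:
            return
        if len(run) == 1:
            sbs.append(run[0])
        elif len(run) == 2:
            a, b = run
            dbs.append(
                MutationRecord(
                    a.chrom, a.pos, a.ref + b.ref, a.alt + b.alt,
                    (a.vaf + b.vaf) / 2, a.sample, a.lineage,
                )
            )
        else:
            multi.append(list(run))

    for rec in subs:
        if run and rec.chrom == run[-1].chrom and rec.pos == run[-1].pos + 1:
            run.append(rec)
        else:
            flush()
            run = [rec]
    flush()
    return PairedSubstitutions(dbs=dbs, sbs=sbs, multi=multi)


# ---------------------------------------------------------------------------
# Catalog building
# ---------------------------------------------------------------------------

def build_catalog(
    records: Sequence[MutationRecord], genome, sample: str | None = None
) -> SampleCatalog:
    """Count de novo, VAF-filtered mutations over all channel sets.

    Substitutions are paired into doublets first; indels are classified
    over ID83 with an auxiliary motif tally for 1 bp T indels. Records
    whose context contains an ambiguous base are skipped and counted.
    """
    if sample is None:
        sample = records[0].sample if records else ""
    cat = SampleCatalog(sample=sample)
    subs = [r for r in records if r.is_substitution]
    indels = [r for r in records if r.is_indel]
    paired = pair_doublets(subs)
    cat.n_multi_base = sum(len(run) for run in paired.multi)

    for rec in paired.sbs:
        context = fetch_seq(genome, rec.chrom, rec.pos - 1, rec.pos + 1)
        try:
            cat.sbs96[SBS96_INDEX[classify_sbs(rec.ref, rec.alt, context)]] += 1
        except (ValueError, KeyError):
            cat.n_skipped += 1
    for rec in paired.dbs:
        cat.dbs78[DBS78_INDEX[classify_dbs(rec.ref, rec.alt)]] += 1
    for rec in indels:
        seq = rec.indel_seq
        up = fetch_seq(genome, rec.chrom, max(rec.pos - 30, 1), rec.pos)
        down_start = rec.pos + 1 if rec.is_insertion else rec.pos + 1 + len(seq)
        down = fetch_seq(genome, rec.chrom, down_start, down_start + 30 + 6 * len(seq))
        try:
            label = classify_indel(seq, not rec.is_insertion, up, down)
        except ValueError:
            cat.n_skipped += 1
            continue
        cat.indel[ID83_INDEX[label]] += 1
        motif = indel_motif(seq, not rec.is_insertion, up, down)
        if motif is not None:
            cat.indel_motifs[motif] += 1
    return cat


# ---------------------------------------------------------------------------
# Duplex sequencing burden
# ---------------------------------------------------------------------------

def duplex_burden(
    variants: pd.DataFrame | str | Path,
    informative_bases: float,
    max_vaf: float = DEFAULT_DUPLEX_MAX_VAF,
    sample: str = "",
) -> DuplexResult:
    """Duplex-sequencing mutation burden.

    Variants with VAF strictly below ``max_vaf`` are counted as
    mutagenesis-derived; the burden is mutations per megabase of
    informative duplex bases.
    """
    if informative_bases <= 0:
        raise ValueError("informative_bases must be positive")
    if not isinstance(variants, pd.DataFrame):
        variants = pd.read_csv(variants, sep="\t")
    cols = {c.lower(): c for c in variants.columns}
    if "vaf" not in cols:
        raise ValueError("duplex variant table needs a 'vaf' column")
    vafs = variants[cols["vaf"]].astype(float)
    n = int((vafs < max_vaf).sum())
    return DuplexResult(sample=sample, n_mutations=n, informative_bases=informative_bases)


# ---------------------------------------------------------------------------
# Catalog matrix I/O
# ---------------------------------------------------------------------------

_KIND_CHANNELS = {"sbs": SBS96_CHANNELS, "dbs": DBS78_CHANNELS, "indel": ID83_CHANNELS}


def catalogs_to_frame(catalogs: Sequence[SampleCatalog], kind: str) -> pd.DataFrame:
    """Channels x samples count matrix in canonical channel order."""
    channels = _KIND_CHANNELS[kind]
    data = {c.sample: c.vector(kind) for c in catalogs}
    return pd.DataFrame(data, index=pd.Index(channels, name="channel"))


def write_catalog_tsv(catalogs: Sequence[SampleCatalog], kind: str, path: str | Path) -> None:
    catalogs_to_frame(catalogs, kind).to_csv(path, sep="\t")


def read_catalog_tsv(path: str | Path, kind: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    channels = list(_KIND_CHANNELS[kind])
    missing = set(channels) - set(df.index)
    if missing:
        raise ValueError(f"{path}: missing channels: {sorted(missing)[:5]} ...")
    return df.loc[channels]


def write_filter_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2) + "\n")
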