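"""Mutation channel sets and classifiers.

Defines the canonical channel orders used throughout the package:

* ``SBS96`` — single-base substitutions, pyrimidine-centric change
  (C>A/G/T, T>A/C/G) crossed with the 5' and 3' flanking base.
* ``DBS78`` — dinucleotide substitutions collapsed by reverse complement
  onto 78 canonical doublet changes (COSMIC convention).
* ``ID83`` — insertions/deletions classified by size, base identity,
  homopolymer/repeat context and microhomology at the deletion junction.

Classifiers are pure string functions: callers supply the local reference
sequence; coordinate handling lives in :mod:`mutascope.catalogs`.
"""

from __future__ import annotations

_COMP = str.maketrans("ACGTacgt", "TGCAtgca")

PYRIMIDINES = frozenset("CT")
PURINES = frozenset("AG")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGT alphabet)."""
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# SBS96
# ---------------------------------------------------------------------------

SBS_CHANGES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = "ACGT"

#: Canonical SBS96 channel order: substitution class major, then 5' base,
#: then 3' base, each in A,C,G,T order.
SBS96_CHANNELS: tuple[str, ...] = tuple(
    f"{f5}[{chg}]{f3}" for chg in SBS_CHANGES for f5 in _BASES for f3 in _BASES
)

SBS96_INDEX = {c: i for i, c in enumerate(SBS96_CHANNELS)}


def classify_sbs(ref: str, alt: str, context: str) -> str:
    """Classify a single-base substitution into its SBS96 channel.

    Parameters
    ----------
    ref, alt : str
        Single reference and alternate bases (plus strand).
    context : str
        The reference trinucleotide centered on the mutated base
        (plus strand); ``context[1]`` must equal ``ref``.

    Purine-reference mutations are reverse complemented together with
    their context so every channel is pyrimidine-centric.
    """
    if len(ref) != 1 or len(alt) != 1:
        raise ValueError(f"not a single-base substitution: {ref}>{alt}")
    if ref == alt:
        raise ValueError(f"ref equals alt: {ref}")
    context = context.upper()
    if len(context) != 3 or context[1] != ref.upper():
        raise ValueError(f"context {context!r} does not center on ref {ref!r}")
    if "N" in context:
        raise ValueError(f"ambiguous base in context {context!r}")
    ref, alt = ref.upper(), alt.upper()
    if ref in PURINES:
        context = revcomp(context)
        ref = context[1]
        alt = revcomp(alt)
    return f"{context[0]}[{ref}>{alt}]{context[2]}"


# ---------------------------------------------------------------------------
# DBS78
# ---------------------------------------------------------------------------

# COSMIC canonical DBS78 channel list: 10 canonical reference doublets,
# each with the published set of alternate doublets.
_DBS78_SPEC = {
    "AC": ("CA", "CG", "CT", "GA", "GG", "GT", "TA", "TG", "TT"),
    "AT": ("CA", "CC", "CG", "GA", "GC", "TA"),
    "CC": ("AA", "AG", "AT", "GA", "GG", "GT", "TA", "TG", "TT"),
    "CG": ("AT", "GC", "GT", "TA", "TC", "TT"),
    "CT": ("AA", "AC", "AG", "GA", "GC", "GG", "TA", "TC", "TG"),
    "GC": ("AA", "AG", "AT", "CA", "CG", "TA"),
    "TA": ("AT", "CG", "CT", "GC", "GG", "GT"),
    "TC": ("AA", "AG", "AT", "CA", "CG", "CT", "GA", "GG", "GT"),
    "TG": ("AA", "AC", "AT", "CA", "CC", "CT", "GA", "GC", "GT"),
    "TT": ("AA", "AC", "AG", "CA", "CC", "CG", "GA", "GC", "GG"),
}

DBS78_CHANNELS: tuple[str, ...] = tuple(
    f"{ref}>{alt}" for ref, alts in _DBS78_SPEC.items() for alt in alts
)
assert len(DBS78_CHANNELS) == 78

DBS78_INDEX = {c: i for i, c in enumerate(DBS78_CHANNELS)}
_DBS78_SET = frozenset(DBS78_CHANNELS)

#: Reference doublets kept on the given strand; all others are
#: reverse complemented during canonicalization.
DBS_CANONICAL_REFS = frozenset(_DBS78_SPEC)


def classify_dbs(ref: str, alt: str) -> str:
    """Canonicalize a dinucleotide substitution into its DBS78 channel."""
    ref, alt = ref.upper(), alt.upper()
    if len(ref) != 2 or len(alt) != 2:
        raise ValueError(f"not a doublet: {ref}>{alt}")
    if ref[0] == alt[0] or ref[1] == alt[1]:
        raise ValueError(
            f"{ref}>{alt} is not a true doublet (one position unchanged)"
        )
    label = f"{ref}>{alt}"
    if label in _DBS78_SET:
        return label
    label = f"{revcomp(ref)}>{revcomp(alt)}"
    if label not in _DBS78_SET:  # pragma: no cover - exhaustive by construction
        raise ValueError(f"cannot canonicalize doublet {ref}>{alt}")
    return label


# ---------------------------------------------------------------------------
# ID83
# ---------------------------------------------------------------------------

def _id83_order() -> tuple[str, ...]:
    chans: list[str] = []
    for base in "CT":  # 1 bp deletions by homopolymer length (incl. deleted base)
        chans += [f"1:Del:{base}:{k}" for k in (1, 2, 3, 4, 5, "6+")]
    for base in "CT":  # 1 bp insertions by existing homopolymer length
        chans += [f"1:Ins:{base}:{k}" for k in (0, 1, 2, 3, 4, "5+")]
    for size in (2, 3, 4, "5+"):  # >=2 bp deletions at repeats (unit copies incl. deleted)
        chans += [f"{size}:Del:R:{k}" for k in (1, 2, 3, 4, 5, "6+")]
    for size in (2, 3, 4, "5+"):  # >=2 bp insertions at repeats (existing copies)
        chans += [f"{size}:Ins:R:{k}" for k in (0, 1, 2, 3, 4, "5+")]
    mh = {2: (1,), 3: (1, 2), 4: (1, 2, 3), "5+": (1, 2, 3, 4, "5+")}
    for size, lens in mh.items():  # deletions with microhomology at the junction
        chans += [f"{size}:Del:M:{m}" for m in lens]
    return tuple(chans)


ID83_CHANNELS: tuple[str, ...] = _id83_order()
assert len(ID83_CHANNELS) == 83
ID83_INDEX = {c: i for i, c in enumerate(ID83_CHANNELS)}


def _lead_count(seq: str, unit: str) -> int:
    """Number of complete copies of ``unit`` at the start of ``seq``."""
    n, i = 0, 0
    u = len(unit)
    while seq[i : i + u] == unit:
        n += 1
        i += u
    return n


def _trail_count(seq: str, unit: str) -> int:
    """Number of complete copies of ``unit`` at the end of ``seq``."""
    return _lead_count(seq[::-1], unit[::-1])


def _cap(value: int, top: int) -> int | str:
    return value if value < top else f"{top}+"


def classify_indel(seq: str, is_deletion: bool, upstream: str, downstream: str) -> str:
    """Classify an insertion/deletion into its ID83 channel.

    Parameters
    ----------
    seq : str
        The inserted or deleted bases (without the anchor base).
    is_deletion : bool
        True for a deletion of ``seq``, False for an insertion.
    upstream : str
        Reference sequence immediately 5' of the event (ending at the
        anchor base).
    downstream : str
        Reference sequence immediately 3' of the event (for a deletion,
        starting after the deleted bases).

    The flanks need only be long enough to resolve the repeat/homopolymer
    count caps (6 units suffice).
    """
    seq, upstream, downstream = seq.upper(), upstream.upper(), downstream.upper()
    if not seq:
        raise ValueError("empty indel sequence")
    if len(seq) == 1:
        base = seq
        run = _trail_count(upstream, base) + _lead_count(downstream, base)
        cbase = base if base in PYRIMIDINES else base.translate(_COMP)
        if is_deletion:
            return f"1:Del:{cbase}:{_cap(run + 1, 6)}"
        return f"1:Ins:{cbase}:{_cap(run, 5)}"

    size = len(seq) if len(seq) < 5 else "5+"
    copies = _trail_count(upstream, seq) + _lead_count(downstream, seq)
    if not is_deletion:
        return f"{size}:Ins:R:{_cap(copies, 5)}"
    if copies >= 1:
        return f"{size}:Del:R:{_cap(copies + 1, 6)}"
    # no full flanking copy: check for partial (microhomology) at either junction
    mh = 0
    for m in range(min(len(seq) - 1, len(downstream)), 0, -1):
        if seq[:m] == downstream[:m]:
            mh = m
            break
    for m in range(min(len(seq) - 1, len(upstream)), mh, -1):
        if seq[-m:] == upstream[-m:]:
            mh = m
            break
    if mh == 0:
        return f"{size}:Del:R:1"
    cap = {2: 1, 3: 2, 4: 3}.get(len(seq) if len(seq) < 5 else 0, 5)
    if size == "5+":
        return f"5+:Del:M:{_cap(mh, 5)}"
    return f"{size}:Del:M:{min(mh, cap)}"


def indel_motif(seq: str, is_deletion: bool, upstream: str, downstream: str) -> str | None:
    """Auxiliary motif label for 1 bp T-centric indels.

    Deletions of a T (or A, strand collapsed) are reported with their
    flanking trinucleotide class (``ATA``, ``ATG`` or ``other``);
    insertions of a T are tested against the ``[T0-1]A`` motif (inserted
    T followed by at most one further T then an A). Returns None for
    indels outside these classes.
    """
    seq, upstream, downstream = seq.upper(), upstream.upper(), downstream.upper()
    if len(seq) != 1 or seq not in "AT":
        return None
    if not upstream or not downstream:
        return None
    context = upstream[-1] + seq + downstream[0]
    if seq == "A":
        context = revcomp(context)
    if is_deletion:
        cls = context if context in ("ATA", "ATG") else "other"
        return f"del.T.{cls}"
    down = downstream if seq == "T" else revcomp(upstream[-3:])
    hit = down.startswith("A") or down.startswith("TA")
    return "ins.T.[T0-1]A" if hit else "ins.T.other"


CHANNEL_SETS = {
    "sbs": SBS96_CHANNELS,
    "dbs": DBS78_CHANNELS,
    "indel": ID83_CHANNELS,
}
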