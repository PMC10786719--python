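"""Permutation null for chance doublet substitutions.

A high single-base substitution load can produce adjacent pairs purely
by coincidence. This module re-places the observed substitutions across
the genome many times — uniformly, or restricted to positions with the
same trinucleotide context — and asks how many adjacent pairs (and what
doublet spectrum) arise by chance, yielding a p-value for the observed
doublet count and a cosine comparison of the observed versus
chance-expected doublet spectra.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .catalogs import MutationRecord, fetch_seq
from .channels import DBS78_CHANNELS, DBS78_INDEX, classify_dbs
from .seqindex import ContextIndex

DEFAULT_ALPHA = 0.01
DEFAULT_COS_THRESHOLD = 0.9


@dataclass(frozen=True)
class PermutationNull:
    n_perm: int
    seed: int
    chance_dbs_counts: np.ndarray
    chance_dbs_spectrum: np.ndarray
    observed_dbs_count: int
    p_value_count: float
    cosine_obs_vs_chance: float | None


@dataclass(frozen=True)
class DbsComparison:
    cosine: float | None
    fold_enrichment: float
    p_value: float
    legitimate: bool


def expected_adjacent_pairs(m: int, L: int) -> float:
    """Expected adjacent pairs for m uniform distinct sites on L sites.

    Each of the L-1 adjacent site pairs is jointly occupied with
    probability m(m-1)/(L(L-1)), so the expectation is m(m-1)/L.
    """
    if m > L:
        raise ValueError("cannot place more mutations than sites")
    if m < 0 or L <= 0:
        raise ValueError("m must be >= 0 and L positive")
    return m * (m - 1) / L


def _count_adjacent(chrom_idx: np.ndarray, pos: np.ndarray) -> int:
    order = np.lexsort((pos, chrom_idx))
    ci, p = chrom_idx[order], pos[order]
    return int(np.sum((np.diff(p) == 1) & (np.diff(ci) == 0)))


def _greedy_pairs(order_idx: np.ndarray, chrom_idx, pos) -> list[tuple[int, int]]:
    """Leftmost-first non-overlapping adjacent pairs (record indices)."""
    pairs = []
    i = 0
    while i < order_idx.size - 1:
        a, b = order_idx[i], order_idx[i + 1]
        if chrom_idx[a] == chrom_idx[b] and pos[b] - pos[a] == 1:
            pairs.append((a, b))
            i += 2
        else:
            i += 1
    return pairs


def permute_sbs_positions(
    records: Sequence[MutationRecord],
    genome,
    n_perm: int = 1000,
    seed: int = 0,
    context_matched: bool = True,
    observed_dbs_count: int = 0,
    observed_dbs_spectrum: np.ndarray | None = None,
) -> PermutationNull:
    """Re-place substitutions and collect the chance-doublet null.

    Each replicate independently re-places every substitution — uniformly
    over the genome, or (``context_matched``, the default) uniformly over
    positions sharing its exact trinucleotide context — with collisions
    within a replicate re-drawn. Adjacent placements are counted and
    paired into chance doublets whose DBS78 spectrum is aggregated over
    replicates.
    """
    if n_perm < 10:
        raise ValueError("need at least 10 permutation replicates")
    subs = [r for r in records if r.is_substitution and len(r.ref) == 1]
    if not subs:
        raise ValueError("no single-base substitutions to permute")
    rng = np.random.default_rng(seed)
    chroms = list(genome.keys()) if hasattr(genome, "keys") else list(genome)
    chrom_names = [str(c) for c in chroms]
    lengths = np.array([len(genome[c]) for c in chrom_names], dtype=np.int64)

    ctx_index = None
    contexts: list[str] = []
    if context_matched:
        ctx_index = ContextIndex(genome)
        kept = []
        for rec in subs:
            tri = fetch_seq(genome, rec.chrom, rec.pos - 1, rec.pos + 1)
            if len(tri) == 3 and ctx_index.count(tri) > 0:
                kept.append(rec)
                contexts.append(tri)
            else:
                warnings.warn(
                    f"no context-matched positions for {rec.chrom}:{rec.pos}; skipped"
                )
        subs = kept
        if not subs:
            raise ValueError("no substitutions with matchable contexts")

    m = len(subs)
    refs = [r.ref for r in subs]
    alts = [r.alt for r in subs]
    counts = np.zeros(n_perm, dtype=int)
    spectrum = np.zeros(len(DBS78_CHANNELS), dtype=float)

    # interior positions only (2..L-1), so every placement has a full context
    interior = np.maximum(lengths - 2, 0)
    cum = np.cumsum(interior)
    total_sites = int(cum[-1])

    for rep in range(n_perm):
        if context_matched:
            chrom_idx = np.empty(m, dtype=np.int32)
            pos = np.empty(m, dtype=np.int64)
            used: set[tuple[int, int]] = set()
            name_to_idx = {c: i for i, c in enumerate(chrom_names)}
            for i in range(m):
                for _ in range(1000):
                    c, p = ctx_index.sample(contexts[i], rng)
                    key = (name_to_idx[c], p)
                    if key not in used:
                        used.add(key)
                        chrom_idx[i], pos[i] = key
                        break
                else:  # pragma: no cover - pathological saturation
                    raise RuntimeError("could not place mutation without collision")
        else:
            flat = rng.choice(total_sites, size=m, replace=False)
            chrom_idx = np.searchsorted(cum, flat, side="right").astype(np.int32)
            offset = flat - np.concatenate(([0], cum[:-1]))[chrom_idx]
            pos = offset + 2  # 1-based interior position

        counts[rep] = _count_adjacent(chrom_idx, pos)
        order = np.lexsort((pos, chrom_idx))
        for a, b in _greedy_pairs(order, chrom_idx, pos):
            try:
                label = classify_dbs(refs[a] + refs[b], alts[a] + alts[b])
            except ValueError:
                continue
            spectrum[DBS78_INDEX[label]] += 1

    if spectrum.sum() > 0:
        spectrum /= spectrum.sum()
    p_value = float(np.mean(counts >= observed_dbs_count))
    cosine = None
    if observed_dbs_spectrum is not None and spectrum.sum() > 0:
        obs = np.asarray(observed_dbs_spectrum, dtype=float)
        if obs.sum() > 0:
            cosine = float(
                obs @ spectrum / (np.linalg.norm(obs) * np.linalg.norm(spectrum))
            )
    return PermutationNull(
        n_perm=n_perm,
        seed=seed,
        chance_dbs_counts=counts,
        chance_dbs_spectrum=spectrum,
        observed_dbs_count=observed_dbs_count,
        p_value_count=p_value,
        cosine_obs_vs_chance=cosine,
    )


def compare_dbs_patterns(
    observed: np.ndarray,
    null: PermutationNull,
    alpha: float = DEFAULT_ALPHA,
    cos_threshold: float = DEFAULT_COS_THRESHOLD,
) -> DbsComparison:
    """Observed doublets versus the chance null.

    The observed doublet load is called legitimate (a real doublet
    process, not coincidence of single substitutions) when its count is
    null-improbable (p < alpha) and its spectrum is dissimilar from the
    chance spectrum (cosine < cos_threshold).
    """
    observed = np.asarray(observed, dtype=float)
    total = observed.sum()
    if total <= 0:
        raise ValueError("no observed doublets to compare")
    mean_chance = float(null.chance_dbs_counts.mean())
    fold = math.inf if mean_chance == 0 else float(total / mean_chance)
    cosine = None
    if null.chance_dbs_spectrum.sum() > 0:
        cosine = float(
            observed
            @ null.chance_dbs_spectrum
            / (np.linalg.norm(observed) * np.linalg.norm(null.chance_dbs_spectrum))
        )
    dissimilar = cosine is None or cosine < cos_threshold
    return DbsComparison(
        cosine=cosine,
        fold_enrichment=fold,
        p_value=null.p_value_count,
        legitimate=bool(null.p_value_count < alpha and dissimilar),
    )
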