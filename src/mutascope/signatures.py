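"""Background-subtraction derivation of treatment mutational signatures.

The derivation follows the control-aware scheme used for
mutation-accumulation experiments:

1. aggregate untreated control catalogs into a background signature;
2. bootstrap control-sized samples from that background across a grid of
   mutation burdens to obtain the expected distribution of cosine
   similarities (mean +/- sd per burden);
3. declare a treatment signature present when the treated profile's
   cosine similarity to the background falls below the envelope
   (mean - k_sd * sd at the treated burden);
4. subtract the expected background mutation counts from the treated
   catalog and renormalize the residual;
5. rank the derived signature against reference signature sets by
   cosine similarity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .catalogs import SampleCatalog
from .channels import CHANNEL_SETS

DEFAULT_K_SD = 3.0
#: Logarithmic burden grid for the bootstrap envelope.
DEFAULT_BURDEN_GRID = tuple(
    int(round(b)) for b in np.geomspace(50, 50000, 12)
)
DEFAULT_N_BOOT = 1000


@dataclass(frozen=True)
class SignatureProfile:
    """Normalized probability vector over one channel set."""

    channels: tuple[str, ...]
    probs: np.ndarray
    n_source_mutations: int = 0

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        if probs.shape != (len(self.channels),):
            raise ValueError("probs length does not match channel set")
        if (probs < -1e-12).any():
            raise ValueError("signature probabilities must be non-negative")
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("signature probabilities must sum to 1")
        object.__setattr__(self, "probs", probs)

    @classmethod
    def from_counts(
        cls, counts: np.ndarray, channels: Sequence[str]
    ) -> "SignatureProfile":
        counts = np.asarray(counts, dtype=float)
        total = counts.sum()
        if total <= 0:
            raise ValueError("cannot normalize an all-zero count vector")
        return cls(tuple(channels), counts / total, int(round(total)))

    @classmethod
    def flat(cls, channels: Sequence[str]) -> "SignatureProfile":
        n = len(channels)
        return cls(tuple(channels), np.full(n, 1.0 / n))


@dataclass(frozen=True)
class BootstrapEnvelope:
    """Expected cosine similarity to the background, per mutation burden."""

    burdens: np.ndarray
    mean_cos: np.ndarray
    sd_cos: np.ndarray
    n_boot: int
    seed: int

    def at(self, burden: float) -> tuple[float, float]:
        """Mean and sd at a burden, linearly interpolated between grid points."""
        if burden <= 0:
            raise ValueError("burden must be positive")
        mean = float(np.interp(burden, self.burdens, self.mean_cos))
        sd = float(np.interp(burden, self.burdens, self.sd_cos))
        return mean, sd


@dataclass(frozen=True)
class DetectionResult:
    novel: bool
    cosine: float
    threshold: float
    burden: int


def cosine_similarity(p: np.ndarray, q: np.ndarray) -> float:
    """Cosine similarity between two count-or-probability vectors."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("vectors must share one channel set")
    np_, nq = np.linalg.norm(p), np.linalg.norm(q)
    if np_ == 0 or nq == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.dot(p, q) / (np_ * nq))


def aggregate_background(
    controls: Sequence[SampleCatalog], kind: str = "sbs"
) -> SignatureProfile:
    """Channel-wise sum of control catalogs, normalized."""
    if not controls:
        raise ValueError("need at least one control catalog")
    channels = CHANNEL_SETS[kind]
    total = np.sum([c.vector(kind) for c in controls], axis=0)
    return SignatureProfile.from_counts(total, channels)


def bootstrap_envelope(
    background: SignatureProfile,
    burden_grid: Sequence[int] = DEFAULT_BURDEN_GRID,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
) -> BootstrapEnvelope:
    """Bootstrap the cosine similarity of background-only samples.

    For each burden b, draws ``n_boot`` multinomial samples of b
    mutations from the background profile and records the mean and sd of
    their cosine similarity to the background.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be at least 2")
    burdens = np.asarray(sorted(burden_grid), dtype=int)
    if (burdens <= 0).any():
        raise ValueError("burden grid must be positive")
    rng = np.random.default_rng(seed)
    means, sds = [], []
    for b in burdens:
        draws = rng.multinomial(int(b), background.probs, size=n_boot)
        norms = np.linalg.norm(draws, axis=1)
        cosines = draws @ background.probs / (norms * np.linalg.norm(background.probs))
        means.append(float(cosines.mean()))
        sds.append(float(cosines.std(ddof=1)))
    return BootstrapEnvelope(
        burdens=burdens,
        mean_cos=np.asarray(means),
        sd_cos=np.asarray(sds),
        n_boot=n_boot,
        seed=seed,
    )


def detect_novel_signature(
    treated: SampleCatalog | np.ndarray,
    background: SignatureProfile,
    envelope: BootstrapEnvelope,
    k_sd: float = DEFAULT_K_SD,
    kind: str = "sbs",
) -> DetectionResult:
    """Decide whether a treated catalog carries a signature beyond background.

    The treated profile is declared novel iff its cosine similarity to
    the background falls below ``mean - k_sd * sd`` of the bootstrap
    envelope at the treated mutation burden.
    """
    counts = treated.vector(kind) if isinstance(treated, SampleCatalog) else np.asarray(treated)
    burden = int(counts.sum())
    if burden == 0:
        raise ValueError("treated catalog has no mutations")
    cos = cosine_similarity(counts, background.probs)
    mean, sd = envelope.at(burden)
    threshold = mean - k_sd * sd
    return DetectionResult(novel=cos < threshold, cosine=cos, threshold=threshold, burden=burden)


def subtract_background(
    treated_counts: np.ndarray,
    background: SignatureProfile,
    background_burden: float,
    kind: str = "sbs",
) -> SignatureProfile:
    """Remove the expected background counts from a treated catalog.

    ``residual_k = max(0, treated_k - background_burden * background_k)``,
    renormalized. The background burden defaults (at call sites) to the
    mean de novo burden of matched untreated subclones: equal culture
    time implies comparable background accumulation.
    """
    counts = np.asarray(treated_counts, dtype=float)
    if background_burden < 0:
        raise ValueError("background_burden must be non-negative")
    if counts.sum() <= background_burden:
        raise ValueError("treated burden must exceed the background burden")
    residual = np.maximum(0.0, counts - background_burden * background.probs)
    if residual.sum() == 0:
        raise ValueError("treatment profile indistinguishable from background")
    return SignatureProfile(
        channels=tuple(CHANNEL_SETS[kind]),
        probs=residual / residual.sum(),
        n_source_mutations=int(round(residual.sum())),
    )


def compare_to_reference(
    signature: SignatureProfile, references: pd.DataFrame
) -> list[tuple[str, float]]:
    """Rank reference signatures by cosine similarity (descending).

    ``references`` is a channels x signatures table (COSMIC layout,
    channel labels as index). Ties keep input column order; cosines are
    reported to 3 decimals.
    """
    if references.shape[1] == 0:
        raise ValueError("empty reference set")
    missing = set(signature.channels) - set(references.index)
    if missing:
        raise ValueError(f"reference set lacks channels: {sorted(missing)[:5]}")
    aligned = references.loc[list(signature.channels)]
    ranked = [
        (name, round(cosine_similarity(signature.probs, aligned[name].to_numpy()), 3))
        for name in aligned.columns
    ]
    ranked.sort(key=lambda t: -t[1])
    return ranked


def read_reference_signatures(path) -> pd.DataFrame:
    """Read a channels x signatures TSV (first column = channel labels)."""
    return pd.read_csv(path, sep="\t", index_col=0)
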