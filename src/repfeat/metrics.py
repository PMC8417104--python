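"""Repertoire-level diversity and sharing statistics.

All per-segment metrics are computed on slices downsampled (rarefied) to a
common UMI depth, so that samples of different sequencing depth are
comparable:

* **Chao1** — nonparametric richness estimate from singleton/doubleton
  counts (bias-corrected form, defined even when no doubletons exist).
* **Normalized Shannon–Wiener** — Shannon entropy of clonotype frequencies
  divided by its maximum ``ln(S_obs)`` (Pielou evenness); the complement of
  clonality.
* **Convergence** — distinct nucleotide clonotypes per distinct amino-acid
  CDR3: >1 means several rearrangements converged on the same junction
  protein sequence.
* **Publicity** — number of amino-acid CDR3 sequences shared between the
  top clonotypes of two equal-depth samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from ._seeds import derive_seed
from .types import (
    Clonotype,
    InsufficientCoverageError,
    Repertoire,
    RepertoireError,
    VSegmentSlice,
)

__all__ = [
    "downsample_umis",
    "downsample_repertoire",
    "chao1",
    "shannon_wiener_normalized",
    "convergence",
    "pairwise_publicity",
    "DiversityResult",
    "diversity_of_slice",
]


@dataclass(slots=True)
class DiversityResult:
    """Diversity metrics of one (sample, V segment) slice at fixed depth."""

    sample_id: str
    v_segment: str
    n_umi: int
    observed: int
    chao1: float
    shannon_norm: Optional[float]
    convergence: float


def _downsample_clonotypes(
    clonotypes: Sequence[Clonotype], n: int, rng: np.random.Generator
) -> list[Clonotype]:
    counts = np.array([c.umi_count for c in clonotypes], dtype=np.int64)
    new_counts = rng.multivariate_hypergeometric(counts, n)
    return [
        replace(c, umi_count=int(k), frequency=k / n)
        for c, k in zip(clonotypes, new_counts)
        if k > 0
    ]


def downsample_umis(slice_: VSegmentSlice, n: int, seed: int) -> VSegmentSlice:
    """Rarefy a V-segment slice to exactly ``n`` UMIs without replacement.

    Sampling is multivariate hypergeometric over clonotypes (equivalent to
    drawing ``n`` UMIs from the UMI multiset); clonotypes reduced to zero
    are dropped.  Deterministic given ``seed``.  A slice with fewer than
    ``n`` UMIs raises :class:`InsufficientCoverageError`, which callers
    treat as an exclusion signal for that (sample, segment).
    """
    if n < 1:
        raise ValueError("downsample depth must be positive")
    if slice_.depth < n:
        raise InsufficientCoverageError(
            slice_.sample_id, n, slice_.depth, context=f"V={slice_.v_segment}"
        )
    if slice_.depth == n:
        return replace(slice_, downsampled_to=n, seed_used=seed)
    rng = np.random.default_rng(seed)
    kept = _downsample_clonotypes(slice_.clonotypes, n, rng)
    return VSegmentSlice(
        sample_id=slice_.sample_id,
        donor_id=slice_.donor_id,
        cohort=slice_.cohort,
        subset=slice_.subset,
        v_segment=slice_.v_segment,
        clonotypes=kept,
        downsampled_to=n,
        seed_used=seed,
    )


def downsample_repertoire(repertoire: Repertoire, n: int, seed: int) -> Repertoire:
    """Rarefy a whole repertoire to ``n`` UMIs (used for publicity)."""
    if repertoire.total_umi < n:
        raise InsufficientCoverageError(repertoire.sample_id, n, repertoire.total_umi)
    if repertoire.total_umi == n:
        return repertoire
    rng = np.random.default_rng(seed)
    kept = _downsample_clonotypes(repertoire.clonotypes, n, rng)
    return Repertoire(
        sample_id=repertoire.sample_id,
        donor_id=repertoire.donor_id,
        cohort=repertoire.cohort,
        subset=repertoire.subset,
        clonotypes=kept,
    )


def chao1(counts: Sequence[int]) -> float:
    """Bias-corrected Chao1 richness: S_obs + f1(f1-1) / (2(f2+1)).

    ``f1``/``f2`` are the numbers of clonotypes seen exactly once/twice.
    The bias-corrected form stays defined when no doubletons are present.
    """
    if len(counts) == 0:
        raise ValueError("chao1: empty count vector")
    arr = np.asarray(counts)
    if np.any(arr < 1):
        raise ValueError("chao1: counts must be positive")
    s_obs = arr.size
    f1 = int(np.sum(arr == 1))
    f2 = int(np.sum(arr == 2))
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def shannon_wiener_normalized(counts: Sequence[int]) -> float:
    """Shannon entropy of clonotype frequencies divided by ln(S_obs).

    An evenness measure in (0, 1]: 1 for a perfectly even repertoire,
    approaching 0 under extreme clonal expansion.  Undefined for fewer than
    two clonotypes.
    """
    arr = np.asarray(counts, dtype=float)
    if arr.size < 2:
        raise ValueError("normalized Shannon-Wiener needs >= 2 clonotypes")
    if np.any(arr <= 0):
        raise ValueError("counts must be positive")
    p = arr / arr.sum()
    h = -np.sum(p * np.log(p))
    return float(h / math.log(arr.size))


def convergence(slice_: VSegmentSlice | Sequence[Clonotype]) -> float:
    """Distinct nucleotide variants per distinct amino-acid CDR3 (>= 1).

    Equals 1 exactly when translation is injective on the slice; higher
    values mean convergent recombination (several nucleotide rearrangements
    encoding the same CDR3 protein sequence).
    """
    clonotypes = slice_.clonotypes if isinstance(slice_, VSegmentSlice) else list(slice_)
    if not clonotypes:
        raise ValueError("convergence: empty slice")
    for c in clonotypes:
        if not c.is_functional:
            raise RepertoireError(
                "convergence requires functional clonotypes; run filter_functional first"
            )
    n_nt = len({c.cdr3_nt for c in clonotypes})
    n_aa = len({c.cdr3_aa for c in clonotypes})
    return n_nt / n_aa


def diversity_of_slice(slice_: VSegmentSlice) -> DiversityResult:
    """All diversity metrics of one (downsampled) slice."""
    counts = slice_.counts
    shannon = shannon_wiener_normalized(counts) if len(counts) >= 2 else None
    return DiversityResult(
        sample_id=slice_.sample_id,
        v_segment=slice_.v_segment,
        n_umi=slice_.depth,
        observed=len(counts),
        chao1=chao1(counts),
        shannon_norm=shannon,
        convergence=convergence(slice_),
    )


def top_public_aa_set(
    rep: Repertoire, top_n: int, equal_umi: int, seed: int
) -> set[str]:
    """Distinct amino-acid CDR3s among the top clonotypes at equal depth.

    The repertoire is downsampled to ``equal_umi`` UMIs with a seed derived
    from ``seed`` and the sample id (stable per sample), then the ``top_n``
    most abundant clonotypes (CDR3 nt tie-break) are collapsed to their
    amino-acid CDR3 set.
    """
    sub_seed = derive_seed(seed, rep.sample_id, "publicity")
    down = downsample_repertoire(rep, equal_umi, sub_seed)
    top = down.clonotypes[:top_n]  # canonical order: count desc, nt tie-break
    return {c.cdr3_aa for c in top}


def pairwise_publicity(
    rep_a: Repertoire,
    rep_b: Repertoire,
    top_n: int,
    equal_umi: int,
    seed: int,
) -> int:
    """Shared amino-acid CDR3s between the top clonotypes of two samples.

    Both repertoires are downsampled to ``equal_umi`` UMIs (per-sample
    seeds derived from ``seed`` and the sample id, so the result is
    symmetric in A and B); returns the size of the intersection of their
    top-clonotype amino-acid CDR3 sets.
    """
    set_a = top_public_aa_set(rep_a, top_n, equal_umi, seed)
    set_b = top_public_aa_set(rep_b, top_n, equal_umi, seed)
    return len(set_a & set_b)
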