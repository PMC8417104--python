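"""Core domain types for UMI-based TCR-beta clonotype repertoires.

A *clonotype* is one distinct TCR-beta rearrangement, keyed by its CDR3
nucleotide sequence together with the V and J segment calls.  Abundance is
measured in UMI counts (unique molecular identifiers), i.e. distinct cDNA
molecules, which are free of PCR amplification bias.  A *repertoire* is one
sorted-subset sample from one donor: an ordered collection of clonotypes plus
sample metadata (donor, cohort, T-cell subset).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence, Tuple

from Bio.Seq import Seq

__all__ = [
    "Clonotype",
    "Repertoire",
    "VSegmentSlice",
    "KNOWN_COHORTS",
    "KNOWN_SUBSETS",
    "STOP_CHAR",
    "FRAMESHIFT_CHAR",
    "translate_cdr3",
    "is_functional",
    "RepertoireError",
    "EmptyRepertoireError",
    "InsufficientCoverageError",
]

#: Cohort labels used in the B-cell-deficiency study design.
KNOWN_COHORTS = ("XLA", "young", "old")

#: Sorted T-cell subset labels (naive/memory CD4/CD8 and functional naive CD4 subsets).
KNOWN_SUBSETS = ("nCD4", "mCD4", "nCD8", "mCD8", "RTE", "mnCD4", "nTreg")

STOP_CHAR = "*"
FRAMESHIFT_CHAR = "_"

_AA20 = set("ACDEFGHIKLMNPQRSTVWY")
_NT = set("ACGT")


class RepertoireError(ValueError):
    """Raised when a repertoire or clonotype violates its contract."""


class EmptyRepertoireError(RepertoireError):
    """Raised when an operation would leave or receive zero clonotypes."""


class InsufficientCoverageError(RepertoireError):
    """Sample has too few UMIs for the requested downsampling depth.

    Callers treat this as an exclusion signal (the sample is left out of
    the analysis for that segment/depth, and the exclusion is logged),
    not as a fatal pipeline error.
    """

    def __init__(self, sample_id: str, needed: int, available: int, context: str = ""):
        self.sample_id = sample_id
        self.needed = needed
        self.available = available
        self.context = context
        msg = (
            f"insufficient coverage for {sample_id!r}"
            f"{' (' + context + ')' if context else ''}: "
            f"need {needed} UMIs, have {available}"
        )
        super().__init__(msg)


def translate_cdr3(cdr3_nt: str) -> str:
    """Translate a CDR3 nucleotide sequence.

    Out-of-frame sequences (length not a multiple of 3) are marked with a
    trailing ``_`` after translating complete codons, mirroring common
    clonotype-table conventions.
    """
    n = len(cdr3_nt) - len(cdr3_nt) % 3
    aa = str(Seq(cdr3_nt[:n]).translate())
    if len(cdr3_nt) % 3:
        aa += FRAMESHIFT_CHAR
    return aa


def is_functional(cdr3_nt: str, cdr3_aa: str) -> bool:
    """In-frame, stop-free CDR3: eligible for amino-acid-level analyses."""
    return (
        STOP_CHAR not in cdr3_aa
        and FRAMESHIFT_CHAR not in cdr3_aa
        and len(cdr3_nt) % 3 == 0
    )


@dataclass(frozen=True, slots=True)
class Clonotype:
    """One distinct TCR-beta rearrangement with its UMI abundance.

    Optional junction annotations locate the germline matches inside
    ``cdr3_nt``: ``v_end`` is the 0-based exclusive end of the V match,
    ``j_start`` the 0-based inclusive start of the J match, and ``d_span``
    the half-open interval of the D match.  ``true_insertions`` carries
    simulator ground truth (total non-templated nucleotides) when the
    clonotype was generated rather than sequenced.
    """

    cdr3_nt: str
    cdr3_aa: str
    v_segment: str
    j_segment: str
    umi_count: int
    frequency: float = 0.0
    v_end: Optional[int] = None
    d_span: Optional[Tuple[int, int]] = None
    j_start: Optional[int] = None
    true_insertions: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.cdr3_nt or len(self.cdr3_nt) < 9:
            raise RepertoireError(f"cdr3_nt too short: {self.cdr3_nt!r}")
        if set(self.cdr3_nt) - _NT:
            raise RepertoireError(f"cdr3_nt has non-ACGT characters: {self.cdr3_nt!r}")
        bad = set(self.cdr3_aa) - _AA20 - {STOP_CHAR, FRAMESHIFT_CHAR}
        if bad:
            raise RepertoireError(f"cdr3_aa has invalid residues {bad}: {self.cdr3_aa!r}")
        if self.umi_count < 1:
            raise RepertoireError(f"umi_count must be >= 1, got {self.umi_count}")
        if is_functional(self.cdr3_nt, self.cdr3_aa):
            if len(self.cdr3_nt) != 3 * len(self.cdr3_aa):
                raise RepertoireError(
                    f"functional clonotype with inconsistent lengths: "
                    f"{self.cdr3_nt!r} vs {self.cdr3_aa!r}"
                )
            if translate_cdr3(self.cdr3_nt) != self.cdr3_aa:
                raise RepertoireError(
                    f"cdr3_nt does not translate to cdr3_aa: {self.cdr3_nt!r}"
                )
        if self.v_end is not None and self.j_start is not None:
            if not (0 <= self.v_end <= self.j_start <= len(self.cdr3_nt)):
                raise RepertoireError(
                    f"annotation positions out of order: v_end={self.v_end}, "
                    f"j_start={self.j_start}, L={len(self.cdr3_nt)}"
                )
            if self.d_span is not None:
                d0, d1 = self.d_span
                if not (self.v_end <= d0 <= d1 <= self.j_start):
                    raise RepertoireError(
                        f"d_span {self.d_span} outside junction "
                        f"[{self.v_end}, {self.j_start}]"
                    )

    @property
    def is_functional(self) -> bool:
        return is_functional(self.cdr3_nt, self.cdr3_aa)

    def key(self) -> Tuple[str, str, str]:
        """Identity of the clonotype: (CDR3 nt, V, J)."""
        return (self.cdr3_nt, self.v_segment, self.j_segment)


def _ordered(clonotypes: Iterable[Clonotype]) -> list[Clonotype]:
    # Descending UMI count, ties broken by CDR3 nt lexicographic:
    # makes top-N selection deterministic.
    return sorted(clonotypes, key=lambda c: (-c.umi_count, c.cdr3_nt))


def _with_frequencies(clonotypes: Sequence[Clonotype]) -> list[Clonotype]:
    total = sum(c.umi_count for c in clonotypes)
    return [replace(c, frequency=c.umi_count / total) for c in clonotypes]


@dataclass(slots=True)
class Repertoire:
    """One sample's clonotype set plus metadata.

    Clonotypes are kept in canonical order (descending UMI count, CDR3 nt
    tie-break) with frequencies recomputed from counts at construction.
    """

    sample_id: str
    donor_id: str
    cohort: str
    subset: str
    clonotypes: list[Clonotype] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise RepertoireError("sample_id must be non-empty")
        if not self.cohort or not self.subset:
            raise RepertoireError("cohort and subset must be non-empty")
        keys = [c.key() for c in self.clonotypes]
        if len(set(keys)) != len(keys):
            raise RepertoireError(
                f"duplicate (cdr3_nt, V, J) clonotypes in sample {self.sample_id!r}"
            )
        if self.clonotypes:
            self.clonotypes = _with_frequencies(_ordered(self.clonotypes))
            s = sum(c.frequency for c in self.clonotypes)
            if not math.isclose(s, 1.0, abs_tol=1e-6):
                raise RepertoireError(f"frequencies sum to {s}, expected 1")

    @property
    def total_umi(self) -> int:
        return sum(c.umi_count for c in self.clonotypes)

    @property
    def n_clonotypes(self) -> int:
        return len(self.clonotypes)

    def v_segments(self) -> list[str]:
        """V segments present, ordered by summed UMI count descending."""
        totals: dict[str, int] = {}
        for c in self.clonotypes:
            totals[c.v_segment] = totals.get(c.v_segment, 0) + c.umi_count
        return sorted(totals, key=lambda v: (-totals[v], v))

    def umi_by_v(self) -> dict[str, int]:
        totals: dict[str, int] = {}
        for c in self.clonotypes:
            totals[c.v_segment] = totals.get(c.v_segment, 0) + c.umi_count
        return totals


@dataclass(slots=True)
class VSegmentSlice:
    """A repertoire restricted to one TRBV segment.

    ``downsampled_to``/``seed_used`` record whether (and how) the slice was
    rarefied to a fixed UMI depth, which is how per-segment metrics are made
    comparable across samples.
    """

    sample_id: str
    donor_id: str
    cohort: str
    subset: str
    v_segment: str
    clonotypes: list[Clonotype] = field(default_factory=list)
    downsampled_to: Optional[int] = None
    seed_used: Optional[int] = None

    def __post_init__(self) -> None:
        for c in self.clonotypes:
            if c.umi_count < 1:
                raise RepertoireError("slice clonotype with umi_count < 1")
        self.clonotypes = _ordered(self.clonotypes)
        if self.downsampled_to is not None and self.depth != self.downsampled_to:
            raise RepertoireError(
                f"slice depth {self.depth} != downsampled_to {self.downsampled_to}"
            )

    @property
    def depth(self) -> int:
        return sum(c.umi_count for c in self.clonotypes)

    @property
    def counts(self) -> list[int]:
        return [c.umi_count for c in self.clonotypes]
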