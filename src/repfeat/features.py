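"""Abundance-weighted CDR3 physicochemical and structural features.

Per-clonotype features:

* **strength** — fraction of strongly interacting (hydrophobic/aromatic)
  residues F, I, L, M, V, W, Y in the central 5-residue window of CDR3,
  the region with the highest probability of contacting the peptide–MHC
  complex;
* **volume** — mean residue volume (A^3, Zamyatnin 1972 scale) over the
  same central window;
* **charge** — fraction of charged residues D, E, K, R in the central
  window (histidine excluded: largely uncharged at physiological pH);
* **cdr3_len** — full CDR3 amino-acid length;
* **added_nt** — non-templated nucleotides inserted at the V-D and D-J
  junctions, from annotations when present, otherwise estimated by
  germline alignment.

Per-slice values are weighted by clonotype UMI abundance, and feature
matrices are Z-scored within each (subset, V segment, feature) stratum to
remove V-segment-specific baselines before group testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional

import numpy as np
import pandas as pd

from .simulate import GermlineSet
from .types import Clonotype, VSegmentSlice

__all__ = [
    "ResidueScales",
    "DEFAULT_SCALES",
    "RESIDUE_VOLUME",
    "central_region",
    "clonotype_strength",
    "clonotype_volume",
    "clonotype_charge",
    "added_nucleotides",
    "weighted_feature",
    "slice_features",
    "zscore_within_stratum",
    "aggregate_sample_features",
    "FEATURE_COLUMNS",
]

logger = logging.getLogger(__name__)

# Residue volumes in cubic angstroms (Zamyatnin, Prog Biophys Mol Biol 1972).
RESIDUE_VOLUME: dict[str, float] = {
    "A": 88.6, "R": 173.4, "N": 114.1, "D": 111.1, "C": 108.5,
    "Q": 143.8, "E": 138.4, "G": 60.1, "H": 153.2, "I": 166.7,
    "L": 166.7, "K": 168.6, "M": 162.9, "F": 189.9, "P": 112.7,
    "S": 89.0, "T": 116.1, "W": 227.8, "Y": 193.6, "V": 140.0,
}


@dataclass(frozen=True)
class ResidueScales:
    """Residue sets and scales used by the CDR3 features."""

    strong_set: frozenset[str] = frozenset("FILMVWY")
    charged_set: frozenset[str] = frozenset("DEKR")
    volume_scale: dict[str, float] = field(default_factory=lambda: dict(RESIDUE_VOLUME))

    def __post_init__(self) -> None:
        if set(self.volume_scale) != set("ACDEFGHIKLMNPQRSTVWY"):
            raise ValueError("volume_scale must cover exactly the 20 standard residues")
        if any(v <= 0 for v in self.volume_scale.values()):
            raise ValueError("volume_scale values must be positive")


DEFAULT_SCALES = ResidueScales()


class CentralRegionTooShort(ValueError):
    """CDR3 shorter than the central window; excluded from window features."""


def central_region(cdr3_aa: str, k: int = 5) -> str:
    """The ``k`` residues in the middle of CDR3.

    Window starts at offset floor((L-k)/2); for even-parity ties the window
    sits one position toward the N-terminus.
    """
    if "*" in cdr3_aa or "_" in cdr3_aa:
        raise ValueError(f"central_region on nonfunctional CDR3: {cdr3_aa!r}")
    length = len(cdr3_aa)
    if length < k:
        raise CentralRegionTooShort(f"CDR3 {cdr3_aa!r} shorter than window {k}")
    start = (length - k) // 2
    return cdr3_aa[start : start + k]


def clonotype_strength(cdr3_aa: str, scales: ResidueScales = DEFAULT_SCALES, k: int = 5) -> float:
    """Fraction of strongly interacting residues in the central window."""
    window = central_region(cdr3_aa, k)
    return sum(aa in scales.strong_set for aa in window) / len(window)


def clonotype_volume(cdr3_aa: str, scales: ResidueScales = DEFAULT_SCALES, k: int = 5) -> float:
    """Mean residue volume (A^3) over the central window."""
    window = central_region(cdr3_aa, k)
    return sum(scales.volume_scale[aa] for aa in window) / len(window)


def clonotype_charge(cdr3_aa: str, scales: ResidueScales = DEFAULT_SCALES, k: int = 5) -> float:
    """Fraction of charged residues (D, E, K, R) in the central window."""
    window = central_region(cdr3_aa, k)
    return sum(aa in scales.charged_set for aa in window) / len(window)


def _longest_common_prefix(a: str, b: str) -> int:
    n = min(len(a), len(b))
    for i in range(n):
        if a[i] != b[i]:
            return i
    return n


def _longest_common_suffix(a: str, b: str) -> int:
    n = min(len(a), len(b))
    for i in range(1, n + 1):
        if a[-i] != b[-i]:
            return i - 1
    return n


def _longest_d_match(middle: str, d_genes: Iterable[str], min_len: int = 3) -> int:
    """Longest substring of any D gene inside the junction middle; counted
    only when at least ``min_len`` nt (shorter matches are uninformative)."""
    best = 0
    for d in d_genes:
        for length in range(len(d), best, -1):
            if length > len(middle):
                continue
            found = False
            for i in range(len(d) - length + 1):
                if d[i : i + length] in middle:
                    best = length
                    found = True
                    break
            if found:
                break
    return best if best >= min_len else 0


def added_nucleotides(clonotype: Clonotype, germline: Optional[GermlineSet] = None) -> int:
    """Non-templated nucleotides in the CDR3 junctions.

    When junction annotations are present the answer is exact:
    ``(j_start - v_end) - |d_span|``.  Otherwise the germline set is
    required and the count is estimated: the V match is the longest common
    prefix of the CDR3 with the germline V tail (3' V trimming removes the
    tail's end), the J match the longest common suffix with the J head, and
    the D match the longest D-gene substring (>= 3 nt) in the remaining
    middle; negative remainders (overlapping matches) clamp to zero.
    """
    nt = clonotype.cdr3_nt
    if clonotype.v_end is not None and clonotype.j_start is not None:
        d_len = 0 if clonotype.d_span is None else clonotype.d_span[1] - clonotype.d_span[0]
        added = (clonotype.j_start - clonotype.v_end) - d_len
        if added < 0:
            logger.warning("negative annotated insertion count for %s", nt)
            return 0
        return added
    if germline is None:
        raise ValueError(
            "added_nucleotides needs junction annotations or a germline set"
        )
    if clonotype.v_segment not in germline.v_genes:
        raise KeyError(f"unknown V segment {clonotype.v_segment!r}")
    if clonotype.j_segment not in germline.j_genes:
        raise KeyError(f"unknown J segment {clonotype.j_segment!r}")
    v_match = _longest_common_prefix(nt, germline.v_genes[clonotype.v_segment])
    j_match = _longest_common_suffix(nt, germline.j_genes[clonotype.j_segment])
    middle = nt[v_match : len(nt) - j_match]
    d_match = _longest_d_match(middle, germline.d_genes.values())
    added = len(nt) - v_match - j_match - d_match
    if added < 0:
        logger.warning("overlapping germline matches for %s; clamping to 0", nt)
        return 0
    return added


def weighted_feature(
    slice_: VSegmentSlice,
    feature: Callable[[Clonotype], float],
    weighting: str = "umi",
) -> float:
    """Abundance-weighted mean of a per-clonotype feature over a slice.

    ``weighting='umi'`` weights each clonotype by its UMI count (each cDNA
    molecule counts once); ``'unweighted'`` gives each clonotype weight 1.
    Clonotypes for which the feature is undefined (e.g. CDR3 shorter than
    the central window) contribute to neither sum; if all are excluded the
    value is missing (None).
    """
    if weighting not in ("umi", "unweighted"):
        raise ValueError(f"unknown weighting {weighting!r}")
    num = 0.0
    den = 0.0
    n_excluded = 0
    for c in slice_.clonotypes:
        try:
            x = feature(c)
        except CentralRegionTooShort:
            n_excluded += 1
            continue
        w = c.umi_count if weighting == "umi" else 1.0
        num += w * x
        den += w
    if n_excluded:
        logger.debug(
            "%s/%s: %d clonotypes excluded from a window feature",
            slice_.sample_id, slice_.v_segment, n_excluded,
        )
    if den == 0:
        return None  # missing-value signal for this (sample, V, feature)
    return num / den


FEATURE_COLUMNS = [
    "sample_id", "donor_id", "cohort", "subset", "v_segment",
    "feature", "raw_value", "z_value", "n_umi_used", "n_clonotypes_used",
]

#: feature names computed per slice by :func:`slice_features`
SLICE_FEATURES = ("strength", "volume", "charge", "cdr3_len", "added_nt")


def slice_features(
    slice_: VSegmentSlice,
    scales: ResidueScales = DEFAULT_SCALES,
    germline: Optional[GermlineSet] = None,
    weighting: str = "umi",
    central_k: int = 5,
) -> list[dict]:
    """All abundance-weighted CDR3 features of one slice as tidy records.

    Central-window features (strength, volume, charge) exclude CDR3s
    shorter than the window; length and insertion counts use every
    functional clonotype.  ``added_nt`` is skipped when neither annotations
    nor a germline set are available.
    """
    funcs: dict[str, Callable[[Clonotype], float]] = {
        "strength": lambda c: clonotype_strength(c.cdr3_aa, scales, central_k),
        "volume": lambda c: clonotype_volume(c.cdr3_aa, scales, central_k),
        "charge": lambda c: clonotype_charge(c.cdr3_aa, scales, central_k),
        "cdr3_len": lambda c: float(len(c.cdr3_aa)),
    }
    annotated = all(
        c.v_end is not None and c.j_start is not None for c in slice_.clonotypes
    )
    if annotated or germline is not None:
        funcs["added_nt"] = lambda c: float(added_nucleotides(c, germline))
    records = []
    for name, fn in funcs.items():
        value = weighted_feature(slice_, fn, weighting=weighting)
        if value is None:
            continue
        records.append(
            {
                "sample_id": slice_.sample_id,
                "donor_id": slice_.donor_id,
                "cohort": slice_.cohort,
                "subset": slice_.subset,
                "v_segment": slice_.v_segment,
                "feature": name,
                "raw_value": value,
                "z_value": np.nan,
                "n_umi_used": slice_.depth,
                "n_clonotypes_used": len(slice_.clonotypes),
            }
        )
    return records


def zscore_within_stratum(records: pd.DataFrame) -> pd.DataFrame:
    """Z-score raw values within each (subset, V segment, feature) stratum.

    Uses the population standard deviation across samples; degenerate
    strata (sd = 0) map to all-zero Z-scores, and strata with a single
    sample are dropped with a warning.  Removes V-segment-specific
    baselines so features can be pooled across segments for group testing.
    """
    df = records.copy()
    keys = ["subset", "v_segment", "feature"]
    out = []
    for stratum, grp in df.groupby(keys, sort=False):
        if len(grp) < 2:
            logger.warning("dropping size-1 stratum %s", stratum)
            continue
        x = grp["raw_value"].to_numpy(dtype=float)
        sd = x.std(ddof=0)
        grp = grp.copy()
        grp["z_value"] = np.zeros_like(x) if sd == 0 else (x - x.mean()) / sd
        out.append(grp)
    if not out:
        return df.iloc[0:0]
    return pd.concat(out, ignore_index=True)


def aggregate_sample_features(records: pd.DataFrame, mode: str) -> pd.DataFrame:
    """Reduce a Z-scored feature table for downstream analyses.

    ``pooled_segments`` keeps one observation per (sample, V segment) — the
    unit used for group testing; ``mean_over_segments`` averages Z-scores
    over segments to one value per sample — the unit used for PCA.
    """
    if mode == "pooled_segments":
        return records.copy()
    if mode == "mean_over_segments":
        keys = ["sample_id", "donor_id", "cohort", "subset", "feature"]
        agg = records.groupby(keys, as_index=False, sort=False).agg(
            raw_value=("raw_value", "mean"),
            z_value=("z_value", "mean"),
            n_umi_used=("n_umi_used", "sum"),
            n_clonotypes_used=("n_clonotypes_used", "sum"),
        )
        agg["v_segment"] = "all"
        return agg[[c for c in FEATURE_COLUMNS if c in agg.columns]]
    raise ValueError(f"unknown aggregation mode {mode!r}")
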