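"""Reading and writing clonotype tables, and repertoire-level selections.

Two TSV dialects are supported:

* ``mixcr`` — MiXCR/MIGEC-style exports with columns ``cloneCount`` (or
  ``count``), ``nSeqCDR3``, ``aaSeqCDR3`` and V/J hit columns
  (``bestVHit``/``bestJHit`` or ``allVHitsWithScore``/``allJHitsWithScore``).
* ``airr`` — AIRR Rearrangement TSV with ``duplicate_count``, ``junction``,
  ``junction_aa``, ``v_call``, ``j_call``.

V/J names are normalized to the segment level: allele suffixes (``*01``) are
stripped and composite multi-hit strings are truncated at the first comma
(best hit kept), because all downstream analyses operate per V segment.

Both dialects optionally carry junction-annotation extension columns
(``v_end``, ``d_start``, ``d_end``, ``j_start``, ``true_insertions``) so that
simulator ground truth survives a round trip through disk.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .types import (
    Clonotype,
    EmptyRepertoireError,
    Repertoire,
    RepertoireError,
    VSegmentSlice,
    translate_cdr3,
)

__all__ = [
    "read_clonotype_table",
    "write_clonotype_table",
    "filter_functional",
    "select_abundant_v_segments",
    "slice_by_v",
    "StudyManifest",
    "ManifestRow",
    "read_manifest",
    "write_manifest",
    "FormatError",
]

logger = logging.getLogger(__name__)

DIALECTS = ("mixcr", "airr")

_EXT_COLS = ["v_end", "d_start", "d_end", "j_start", "true_insertions"]

_DIALECT_COLS = {
    "mixcr": {
        "count": ("cloneCount", "count"),
        "nt": ("nSeqCDR3",),
        "aa": ("aaSeqCDR3",),
        "v": ("bestVHit", "allVHitsWithScore"),
        "j": ("bestJHit", "allJHitsWithScore"),
    },
    "airr": {
        "count": ("duplicate_count",),
        "nt": ("junction",),
        "aa": ("junction_aa",),
        "v": ("v_call",),
        "j": ("j_call",),
    },
}


class FormatError(RepertoireError):
    """A clonotype table does not conform to the declared dialect."""


def normalize_segment(name: str) -> str:
    """Normalize a V/J call to segment level.

    ``"TRBV12-3*01"`` -> ``"TRBV12-3"``; composite MiXCR hit strings such as
    ``"TRBV9*00(1290.5),TRBV9-2*00(88)"`` keep the best (first) hit with any
    score parenthetical removed.
    """
    best = name.split(",")[0].strip()
    best = best.split("(")[0].strip()
    return best.split("*")[0].strip()


def _pick_column(df: pd.DataFrame, options: Sequence[str], dialect: str) -> str:
    for col in options:
        if col in df.columns:
            return col
    raise FormatError(
        f"missing required column for dialect {dialect!r}: expected one of {list(options)}"
    )


def read_clonotype_table(
    path: str | Path,
    dialect: str,
    *,
    sample_id: str,
    donor_id: str = "",
    cohort: str = "unknown",
    subset: str = "unknown",
) -> Repertoire:
    """Read one clonotype TSV into a validated :class:`Repertoire`.

    Frequencies are recomputed from UMI counts; rows with zero or missing
    counts are dropped (logged); duplicate (CDR3 nt, V, J) rows are merged by
    summing counts with a warning.  A count that is present but not a
    positive integer raises a row-level error naming the line.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = _DIALECT_COLS[dialect]
    count_col = _pick_column(df, cols["count"], dialect)
    nt_col = _pick_column(df, cols["nt"], dialect)
    aa_col = _pick_column(df, cols["aa"], dialect)
    v_col = _pick_column(df, cols["v"], dialect)
    j_col = _pick_column(df, cols["j"], dialect)

    raw_counts = df[count_col]
    numeric = pd.to_numeric(raw_counts, errors="coerce")
    bad = numeric.isna() & raw_counts.notna() & (raw_counts.astype(str).str.strip() != "")
    if bad.any():
        line_no = int(bad.idxmax()) + 2  # 1-based, after the header line
        raise FormatError(
            f"{path}: line {line_no}: count {raw_counts[bad.idxmax()]!r} is not a number"
        )
    keep = numeric.notna() & (numeric != 0)
    n_dropped = int((~keep).sum())
    df = df.loc[keep].copy()
    counts = numeric[keep]
    not_posint = (counts < 0) | (counts != counts.astype(np.int64))
    if not_posint.any():
        idx = not_posint.idxmax()
        raise FormatError(
            f"{path}: line {int(idx) + 2}: count {raw_counts[idx]!r} "
            "is not a positive integer"
        )
    df["_count"] = counts.astype(np.int64)
    df["_nt"] = df[nt_col].astype(str).str.strip().str.upper()
    aa = df[aa_col].astype(str).str.strip()
    missing_aa = aa.isin(("", "nan"))
    if missing_aa.any():
        aa = aa.mask(missing_aa, df.loc[missing_aa, "_nt"].map(translate_cdr3))
    df["_aa"] = aa
    df["_v"] = df[v_col].astype(str).map(normalize_segment)
    df["_j"] = df[j_col].astype(str).map(normalize_segment)

    merged: dict[tuple, dict] = {}
    ext_present = [c for c in _EXT_COLS if c in df.columns]
    ext_vals = {
        c: pd.to_numeric(df[c], errors="coerce").to_numpy() for c in ext_present
    }
    for pos, (nt, v, j, aa_s, cnt) in enumerate(
        zip(df["_nt"], df["_v"], df["_j"], df["_aa"], df["_count"])
    ):
        key = (nt, v, j)
        if key in merged:
            logger.warning("%s: duplicate clonotype %s, summing counts", path, key)
            merged[key]["count"] += int(cnt)
            continue
        ann = {}
        for col in ext_present:
            val = ext_vals[col][pos]
            if val == val:  # not NaN
                ann[col] = int(val)
        merged[key] = {"count": int(cnt), "aa": aa_s, "ann": ann}

    if n_dropped:
        logger.info("%s: dropped %d rows with zero/missing counts", path, n_dropped)

    clonotypes = []
    for (nt, v, j), rec in merged.items():
        ann = rec["ann"]
        d_span = None
        if "d_start" in ann and "d_end" in ann:
            d_span = (ann["d_start"], ann["d_end"])
        clonotypes.append(
            Clonotype(
                cdr3_nt=nt,
                cdr3_aa=rec["aa"],
                v_segment=v,
                j_segment=j,
                umi_count=rec["count"],
                v_end=ann.get("v_end"),
                d_span=d_span,
                j_start=ann.get("j_start"),
                true_insertions=ann.get("true_insertions"),
            )
        )
    return Repertoire(
        sample_id=sample_id,
        donor_id=donor_id,
        cohort=cohort,
        subset=subset,
        clonotypes=clonotypes,
    )


def write_clonotype_table(repertoire: Repertoire, path: str | Path, dialect: str) -> None:
    """Write a repertoire as TSV in the requested dialect.

    Output is deterministic (canonical clonotype order) so repeated writes of
    the same repertoire are byte-identical.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    rows = []
    for c in repertoire.clonotypes:
        if dialect == "mixcr":
            row = {
                "cloneCount": c.umi_count,
                "cloneFraction": c.frequency,
                "nSeqCDR3": c.cdr3_nt,
                "aaSeqCDR3": c.cdr3_aa,
                "bestVHit": c.v_segment,
                "bestJHit": c.j_segment,
            }
        else:
            row = {
                "duplicate_count": c.umi_count,
                "junction": c.cdr3_nt,
                "junction_aa": c.cdr3_aa,
                "v_call": c.v_segment,
                "j_call": c.j_segment,
            }
        row["v_end"] = "" if c.v_end is None else c.v_end
        row["d_start"] = "" if c.d_span is None else c.d_span[0]
        row["d_end"] = "" if c.d_span is None else c.d_span[1]
        row["j_start"] = "" if c.j_start is None else c.j_start
        row["true_insertions"] = "" if c.true_insertions is None else c.true_insertions
        rows.append(row)
    if rows:
        df = pd.DataFrame(rows)
    else:
        base = (
            ["cloneCount", "cloneFraction", "nSeqCDR3", "aaSeqCDR3", "bestVHit", "bestJHit"]
            if dialect == "mixcr"
            else ["duplicate_count", "junction", "junction_aa", "v_call", "j_call"]
        )
        df = pd.DataFrame(columns=base + _EXT_COLS)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def filter_functional(repertoire: Repertoire) -> Repertoire:
    """Keep only in-frame, stop-free clonotypes; renormalize frequencies.

    Amino-acid-level analyses (convergence, publicity, CDR3 features) need
    translatable junctions; for consistency the same filter is applied before
    every downstream metric.
    """
    survivors = [c for c in repertoire.clonotypes if c.is_functional]
    if not survivors:
        raise EmptyRepertoireError(
            f"no functional clonotypes left in sample {repertoire.sample_id!r}"
        )
    return Repertoire(
        sample_id=repertoire.sample_id,
        donor_id=repertoire.donor_id,
        cohort=repertoire.cohort,
        subset=repertoire.subset,
        clonotypes=survivors,
    )


def select_abundant_v_segments(
    repertoires: Sequence[Repertoire], min_umi: int
) -> list[str]:
    """V segments with summed UMI count >= ``min_umi`` in *every* repertoire.

    Restricting analyses to V segments that are well covered in all samples
    of a subset avoids biases from individual V-usage differences.  Returned
    sorted by total abundance across samples, descending.
    """
    if not repertoires:
        raise ValueError("select_abundant_v_segments: empty repertoire collection")
    subsets = {r.subset for r in repertoires}
    if len(subsets) > 1:
        raise ValueError(f"repertoires span multiple subsets: {sorted(subsets)}")
    per_sample = [r.umi_by_v() for r in repertoires]
    candidates = set(per_sample[0])
    for table in per_sample[1:]:
        candidates &= set(table)
    kept = [v for v in candidates if all(t[v] >= min_umi for t in per_sample)]
    totals = {v: sum(t[v] for t in per_sample) for v in kept}
    return sorted(kept, key=lambda v: (-totals[v], v))


def slice_by_v(repertoire: Repertoire, v: str) -> VSegmentSlice:
    """Restrict a repertoire to one TRBV segment."""
    clonotypes = [c for c in repertoire.clonotypes if c.v_segment == v]
    if not clonotypes:
        raise RepertoireError(
            f"V segment {v!r} absent from sample {repertoire.sample_id!r}"
        )
    return VSegmentSlice(
        sample_id=repertoire.sample_id,
        donor_id=repertoire.donor_id,
        cohort=repertoire.cohort,
        subset=repertoire.subset,
        v_segment=v,
        clonotypes=clonotypes,
    )


# ---------------------------------------------------------------------------
# Study manifest


@dataclass(slots=True)
class ManifestRow:
    sample_id: str
    donor_id: str
    cohort: str
    subset: str
    file_path: str
    dialect: str


@dataclass(slots=True)
class StudyManifest:
    """Table of samples: who they come from and where their clonotypes live."""

    rows: list[ManifestRow]
    base_dir: Optional[Path] = None

    def __post_init__(self) -> None:
        ids = [r.sample_id for r in self.rows]
        if len(set(ids)) != len(ids):
            raise RepertoireError("duplicate sample_id in manifest")
        for r in self.rows:
            if r.dialect not in DIALECTS:
                raise FormatError(f"manifest: unknown dialect {r.dialect!r}")

    def resolve(self, row: ManifestRow) -> Path:
        p = Path(row.file_path)
        if not p.is_absolute() and self.base_dir is not None:
            p = self.base_dir / p
        return p

    def load_repertoires(self) -> list[Repertoire]:
        reps = []
        for row in self.rows:
            path = self.resolve(row)
            if not path.exists():
                raise FileNotFoundError(f"manifest file missing: {path}")
            reps.append(
                read_clonotype_table(
                    path,
                    row.dialect,
                    sample_id=row.sample_id,
                    donor_id=row.donor_id,
                    cohort=row.cohort,
                    subset=row.subset,
                )
            )
        return reps


_MANIFEST_FIELDS = ["sample_id", "donor_id", "cohort", "subset", "file_path", "dialect"]


def read_manifest(path: str | Path) -> StudyManifest:
    """Read a study manifest from TSV or YAML (by extension)."""
    path = Path(path)
    if path.suffix in {".yaml", ".yml"}:
        with open(path) as fh:
            data = yaml.safe_load(fh)
        records = data["samples"] if isinstance(data, dict) else data
    else:
        records = pd.read_csv(path, sep="\t", dtype=str).to_dict("records")
    rows = []
    for rec in records:
        missing = [f for f in _MANIFEST_FIELDS if f not in rec or pd.isna(rec[f])]
        if missing:
            raise FormatError(f"manifest {path}: missing fields {missing}")
        rows.append(ManifestRow(**{f: str(rec[f]) for f in _MANIFEST_FIELDS}))
    return StudyManifest(rows=rows, base_dir=path.parent)


def write_manifest(manifest: StudyManifest, path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame(
        [{f: getattr(r, f) for f in _MANIFEST_FIELDS} for r in manifest.rows]
    )
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")
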