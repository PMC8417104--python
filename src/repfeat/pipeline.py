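"""End-to-end repertoire comparison pipeline.

Stages: load clonotype tables from a study manifest -> keep functional
clonotypes -> select V segments well covered in every sample of a subset ->
per-V downsampling -> diversity (Chao1, normalized Shannon-Wiener),
convergence and abundance-weighted CDR3 features -> Z-scoring within
(subset, V segment, feature) -> Kruskal-Wallis + Dunn/BH (or Wilcoxon for
two cohorts) across cohorts -> pairwise publicity -> PCA over the feature
matrix.  Fully deterministic from a master seed; every sample is accounted
for as included or excluded (with a reason) in every analysis.

Default depths mirror a UMI-based study design (1,000 UMIs per V segment
for diversity; 1,524/1,063/953 for per-segment convergence in RTE, mature
naive CD4 and naive Treg subsets; 13,000 top clonotypes at equal depths of
23,000-31,000 UMIs for publicity); all are config-overridable for
desk-scale synthetic studies.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as rio
from ._seeds import derive_seed
from .features import (
    FEATURE_COLUMNS,
    aggregate_sample_features,
    slice_features,
    zscore_within_stratum,
)
from .metrics import (
    chao1,
    convergence,
    downsample_umis,
    shannon_wiener_normalized,
    top_public_aa_set,
)
from .simulate import (
    SyntheticCohortConfig,
    default_germline_set,
    generate_cohorts,
)
from .stats import compare_groups, pca, wilcoxon_rank_sum
from .types import InsufficientCoverageError, Repertoire

__all__ = [
    "PipelineConfig",
    "RunReport",
    "run_pipeline",
    "make_fixture_study",
    "FIXTURE_PRESETS",
    "XLA_EFFECT_DIRECTIONS",
    "effect_direction_calls",
]

logger = logging.getLogger(__name__)

#: full-study defaults for per-segment convergence depths, by subset
DEFAULT_SEGMENT_DEPTHS = {"RTE": 1524, "mnCD4": 1063, "nTreg": 953}
#: full-study defaults for whole-sample publicity depths, by subset
DEFAULT_PUBLICITY_UMI = {"mnCD4": 23000, "RTE": 24000, "nTreg": 31000}


@dataclass(slots=True)
class PipelineConfig:
    """All knobs of one pipeline run."""

    manifest: str | Path
    out_dir: str | Path
    diversity_depth: int = 1000
    segment_depths: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_SEGMENT_DEPTHS)
    )
    min_umi_v: Optional[int] = None  # default: the larger of the two depths
    publicity_top_n: int = 13000
    publicity_equal_umi: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_PUBLICITY_UMI)
    )
    run_publicity: bool = True
    weighting: str = "umi"
    zscore: bool = True
    adjust_scope: str = "per_feature"  # or "study_wide"
    central_k: int = 5
    master_seed: int = 0
    germline_seed: Optional[int] = None  # for added-nt estimation on unannotated data

    def __post_init__(self) -> None:
        if self.diversity_depth < 1 or self.publicity_top_n < 1:
            raise ValueError("depths and top_n must be positive")
        if self.adjust_scope not in ("per_feature", "study_wide"):
            raise ValueError(f"unknown adjust_scope {self.adjust_scope!r}")

    def segment_depth_for(self, subset: str) -> int:
        return self.segment_depths.get(subset, self.diversity_depth)

    def publicity_umi_for(self, subset: str) -> int:
        default = max(self.publicity_equal_umi.values()) if self.publicity_equal_umi else 1
        return self.publicity_equal_umi.get(subset, default)

    def min_umi_for(self, subset: str) -> int:
        if self.min_umi_v is not None:
            return self.min_umi_v
        return max(self.diversity_depth, self.segment_depth_for(subset))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["manifest"] = str(d["manifest"])
        d["out_dir"] = str(d["out_dir"])
        return d


@dataclass(slots=True)
class RunReport:
    """Bookkeeping of one run: counts, exclusions, seeds, outputs."""

    config: dict
    stage_counts: dict = field(default_factory=dict)
    exclusions: list = field(default_factory=list)
    included: dict = field(default_factory=dict)  # analysis -> sorted sample ids
    output_files: list = field(default_factory=list)
    master_seed: int = 0
    tables: dict = field(default_factory=dict, repr=False)  # in-memory DataFrames

    def exclude(self, sample_id: str, analysis: str, reason: str, **extra) -> None:
        self.exclusions.append(
            {"sample_id": sample_id, "analysis": analysis, "reason": reason, **extra}
        )

    def to_json(self) -> str:
        payload = {
            "config": self.config,
            "master_seed": self.master_seed,
            "stage_counts": self.stage_counts,
            "included": self.included,
            "exclusions": self.exclusions,
            "output_files": self.output_files,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def _write(df: pd.DataFrame, out_dir: Path, name: str, report: RunReport) -> None:
    path = out_dir / name
    df.to_csv(path, sep="\t", index=False, lineterminator="\n", float_format="%.10g")
    report.output_files.append(name)
    report.tables[name.removesuffix(".tsv")] = df


def _metric_records(
    rep: Repertoire,
    v_segments: Sequence[str],
    config: PipelineConfig,
    report: RunReport,
) -> list[dict]:
    """Diversity (at diversity_depth) and convergence (at the subset's
    per-segment depth) for every selected V segment of one sample."""
    records = []
    for v in v_segments:
        sl = rio.slice_by_v(rep, v)
        # diversity at the common rarefaction depth
        seed_div = derive_seed(config.master_seed, rep.sample_id, v, "diversity")
        try:
            down = downsample_umis(sl, config.diversity_depth, seed_div)
        except InsufficientCoverageError:
            report.exclude(
                rep.sample_id, "diversity", "insufficient coverage",
                subset=rep.subset, v_segment=v,
            )
        else:
            counts = down.counts
            base = {
                "sample_id": rep.sample_id, "donor_id": rep.donor_id,
                "cohort": rep.cohort, "subset": rep.subset, "v_segment": v,
                "n_umi": down.depth, "seed": seed_div,
            }
            records.append({**base, "metric": "observed", "value": float(len(counts))})
            records.append({**base, "metric": "chao1", "value": chao1(counts)})
            if len(counts) >= 2:
                records.append(
                    {**base, "metric": "shannon_norm",
                     "value": shannon_wiener_normalized(counts)}
                )
        # convergence at the subset's equal-depth setting
        depth = config.segment_depth_for(rep.subset)
        seed_conv = derive_seed(config.master_seed, rep.sample_id, v, "convergence")
        try:
            down = downsample_umis(sl, depth, seed_conv)
        except InsufficientCoverageError:
            report.exclude(
                rep.sample_id, "convergence", "insufficient coverage",
                subset=rep.subset, v_segment=v,
            )
        else:
            records.append(
                {
                    "sample_id": rep.sample_id, "donor_id": rep.donor_id,
                    "cohort": rep.cohort, "subset": rep.subset, "v_segment": v,
                    "n_umi": down.depth, "seed": seed_conv,
                    "metric": "convergence", "value": convergence(down),
                }
            )
    return records


def _group_test_table(features_df: pd.DataFrame, config: PipelineConfig) -> pd.DataFrame:
    """Cohort comparison per (subset, feature) on pooled (sample, V) values."""
    value_col = "z_value" if config.zscore else "raw_value"
    rows = []
    for (subset, feat), grp in features_df.groupby(["subset", "feature"], sort=True):
        cohorts = sorted(grp["cohort"].unique())
        named = {c: grp.loc[grp["cohort"] == c, value_col].to_numpy() for c in cohorts}
        named = {c: v for c, v in named.items() if len(v) > 0}
        if len(named) < 2:
            continue
        if len(named) == 2:
            (na, va), (nb, vb) = named.items()
            w, p = wilcoxon_rank_sum(va, vb)
            rows.append(
                {
                    "subset": subset, "feature": feat, "test": "wilcoxon",
                    "group_i": na, "group_j": nb,
                    "n_i": len(va), "n_j": len(vb),
                    "statistic": w, "z": np.nan,
                    "kw_H": np.nan, "kw_p": np.nan,
                    "p_raw": p, "p_adj": p,
                    "median_diff": float(np.median(va) - np.median(vb)),
                }
            )
            continue
        res = compare_groups(feat, named)
        for gi, gj, z, p_raw, p_adj in res.pairwise:
            rows.append(
                {
                    "subset": subset, "feature": feat, "test": "kw_dunn",
                    "group_i": gi, "group_j": gj,
                    "n_i": len(named[gi]), "n_j": len(named[gj]),
                    "statistic": np.nan, "z": z,
                    "kw_H": res.kw_statistic, "kw_p": res.kw_pvalue,
                    "p_raw": p_raw, "p_adj": p_adj,
                    "median_diff": float(np.median(named[gi]) - np.median(named[gj])),
                }
            )
    df = pd.DataFrame(rows)
    if not df.empty and config.adjust_scope == "study_wide":
        from .stats import benjamini_hochberg

        df["p_adj"] = benjamini_hochberg(df["p_raw"].tolist())
    return df


def _publicity_table(
    reps: Sequence[Repertoire], config: PipelineConfig, report: RunReport
) -> pd.DataFrame:
    rows = []
    by_subset: dict[str, list[Repertoire]] = {}
    for r in reps:
        by_subset.setdefault(r.subset, []).append(r)
    for subset in sorted(by_subset):
        group = sorted(by_subset[subset], key=lambda r: r.sample_id)
        equal_umi = config.publicity_umi_for(subset)
        eligible = []
        for r in group:
            if r.total_umi < equal_umi:
                report.exclude(
                    r.sample_id, "publicity", "insufficient coverage", subset=subset
                )
            else:
                eligible.append(r)
        report.included.setdefault("publicity", []).extend(
            sorted(r.sample_id for r in eligible)
        )
        aa_sets = {
            r.sample_id: top_public_aa_set(
                r, config.publicity_top_n, equal_umi, config.master_seed
            )
            for r in eligible
        }
        for ra, rb in itertools.combinations(eligible, 2):
            shared = len(aa_sets[ra.sample_id] & aa_sets[rb.sample_id])
            rows.append(
                {
                    "subset": subset,
                    "sample_i": ra.sample_id, "sample_j": rb.sample_id,
                    "cohort_i": ra.cohort, "cohort_j": rb.cohort,
                    "equal_umi": equal_umi, "top_n": config.publicity_top_n,
                    "shared_aa_clonotypes": shared,
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the full analysis; returns the run report (tables attached)."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=config.to_dict(), master_seed=config.master_seed)

    manifest = rio.read_manifest(config.manifest)
    reps = manifest.load_repertoires()
    report.stage_counts["samples_loaded"] = len(reps)
    cohorts = {r.cohort for r in reps}
    if len(cohorts) < 2:
        raise ValueError(f"need >= 2 cohorts, manifest has {sorted(cohorts)}")

    reps = [rio.filter_functional(r) for r in reps]
    report.stage_counts["clonotypes_functional"] = int(
        sum(r.n_clonotypes for r in reps)
    )

    germline = (
        default_germline_set(config.germline_seed)
        if config.germline_seed is not None
        else None
    )

    by_subset: dict[str, list[Repertoire]] = {}
    for r in reps:
        by_subset.setdefault(r.subset, []).append(r)

    metric_rows: list[dict] = []
    feature_rows: list[dict] = []
    selected_v: dict[str, list[str]] = {}
    for subset in sorted(by_subset):
        group = sorted(by_subset[subset], key=lambda r: r.sample_id)
        v_segments = rio.select_abundant_v_segments(group, config.min_umi_for(subset))
        selected_v[subset] = v_segments
        if not v_segments:
            for r in group:
                report.exclude(r.sample_id, "per_segment", "no V segment passes min_umi",
                               subset=subset)
            continue
        for r in group:
            metric_rows.extend(_metric_records(r, v_segments, config, report))
            for v in v_segments:
                sl = rio.slice_by_v(r, v)
                feature_rows.extend(
                    slice_features(
                        sl, germline=germline,
                        weighting=config.weighting, central_k=config.central_k,
                    )
                )
            report.included.setdefault("per_segment", []).append(r.sample_id)
    report.stage_counts["v_segments_selected"] = {
        s: len(v) for s, v in selected_v.items()
    }

    metrics_df = pd.DataFrame(metric_rows)
    _write(metrics_df, out_dir, "metrics.tsv", report)

    # merge diversity metrics into the feature table so they are Z-scored
    # and group-tested alongside the CDR3 features
    if not metrics_df.empty:
        div_feats = metrics_df[
            metrics_df["metric"].isin(["chao1", "shannon_norm", "convergence"])
        ].rename(columns={"metric": "feature", "value": "raw_value",
                          "n_umi": "n_umi_used"})
        div_feats["z_value"] = np.nan
        div_feats["n_clonotypes_used"] = np.nan
        feature_rows.extend(div_feats[
            [c for c in FEATURE_COLUMNS if c in div_feats.columns]
        ].to_dict("records"))

    features_df = pd.DataFrame(feature_rows, columns=FEATURE_COLUMNS)
    if config.zscore and not features_df.empty:
        features_df = zscore_within_stratum(features_df)
    features_df = features_df.sort_values(
        ["subset", "feature", "v_segment", "sample_id"]
    ).reset_index(drop=True)
    _write(features_df, out_dir, "features.tsv", report)
    report.stage_counts["feature_records"] = int(len(features_df))

    tests_df = _group_test_table(features_df, config)
    _write(tests_df, out_dir, "tests.tsv", report)

    if config.run_publicity:
        publicity_df = _publicity_table(reps, config, report)
        _write(publicity_df, out_dir, "publicity.tsv", report)

    # PCA over per-sample feature vectors (Z-scores averaged over segments)
    if not features_df.empty:
        per_sample = aggregate_sample_features(features_df, "mean_over_segments")
        wide = per_sample.pivot_table(
            index="sample_id", columns="feature", values="z_value"
        ).dropna(axis=1)
        if wide.shape[0] >= 2 and wide.shape[1] >= 2:
            res = pca(wide.to_numpy(), list(wide.columns), list(wide.index))
            k = res.scores.shape[1]
            scores = pd.DataFrame(
                res.scores, columns=[f"PC{i+1}" for i in range(k)]
            )
            scores.insert(0, "sample_id", res.sample_ids)
            meta = per_sample.drop_duplicates("sample_id")[
                ["sample_id", "cohort", "subset"]
            ]
            scores = scores.merge(meta, on="sample_id")
            _write(scores, out_dir, "pca_scores.tsv", report)
            loadings = pd.DataFrame(
                res.loadings, columns=[f"PC{i+1}" for i in range(k)]
            )
            loadings.insert(0, "feature", res.feature_names)
            _write(loadings, out_dir, "pca_loadings.tsv", report)
            var = pd.DataFrame(
                {
                    "component": [f"PC{i+1}" for i in range(k)],
                    "explained_variance_ratio": res.explained_variance_ratio,
                }
            )
            _write(var, out_dir, "pca_variance.tsv", report)
        else:
            logger.info("PCA skipped: matrix too small after dropping missing columns")

    # per-segment inclusion bookkeeping: every loaded sample is either in
    # the included list or has an exclusion record for the analysis
    all_ids = sorted(r.sample_id for r in reps)
    for analysis in ("per_segment", "publicity" if config.run_publicity else None):
        if analysis is None:
            continue
        inc = set(report.included.get(analysis, []))
        exc = {e["sample_id"] for e in report.exclusions if e["analysis"] == analysis}
        for sid in all_ids:
            if sid not in inc and sid not in exc:
                report.exclude(sid, analysis, "not reached")
        report.included[analysis] = sorted(inc)

    (out_dir / "report.json").write_text(report.to_json() + "\n")
    report.output_files.append("report.json")
    return report


# ---------------------------------------------------------------------------
# Synthetic fixture studies

#: expected sign of the XLA-vs-young contrast for each injected effect
XLA_EFFECT_DIRECTIONS = {
    "shannon_norm": -1,   # diversity down
    "chao1": -1,          # richness down
    "convergence": +1,    # convergent recombination up
    "cdr3_len": -1,       # shorter junctions
    "added_nt": -1,       # fewer non-templated insertions
    "strength": +1,       # more strongly interacting central residues
}

FIXTURE_PRESETS = {
    "null": {"XLA": {}, "young": {}, "old": {}},
    "xla_like": {
        "XLA": {
            "n_clonotypes": 250,
            "convergence_rate": 0.15,
            "insertion_mean_vd": 2.0,
            "insertion_mean_dj": 2.0,
            "strength_bias": 3.0,
        },
        "young": {},
        "old": {},
    },
}


def make_fixture_study(
    preset: str,
    seed: int,
    out_dir: str | Path,
    *,
    n_samples: int = 8,
    subset: str = "nTreg",
) -> PipelineConfig:
    """Generate a desk-scale synthetic 3-cohort study on disk.

    ``null``: three cohorts with identical generative parameters (any
    downstream significance is a false positive).  ``xla_like``: the XLA
    cohort gets the directional alterations of a B-cell-deficient naive
    Treg repertoire — fewer clonotypes (lower diversity), raised
    convergence, shorter insertions, and a strong-residue bias.  Writes
    AIRR TSVs, a manifest, a ground-truth JSON, and returns a pipeline
    config with depths scaled to the fixture.
    """
    if preset not in FIXTURE_PRESETS:
        raise ValueError(f"unknown preset {preset!r}; options: {sorted(FIXTURE_PRESETS)}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    germline = default_germline_set(derive_seed(seed, "germline"))
    base = SyntheticCohortConfig(n_samples=n_samples, seed=seed)
    effects = FIXTURE_PRESETS[preset]
    reps = generate_cohorts(base, effects, germline, subset=subset)

    rows = []
    truth = {}
    for rep in reps:
        fname = f"{rep.sample_id}.tsv"
        rio.write_clonotype_table(rep, out_dir / fname, "airr")
        rows.append(
            rio.ManifestRow(
                sample_id=rep.sample_id, donor_id=rep.donor_id,
                cohort=rep.cohort, subset=rep.subset,
                file_path=fname, dialect="airr",
            )
        )
        cfg = replace(base, **dict(effects[rep.cohort]))
        truth[rep.sample_id] = {
            "cohort": rep.cohort,
            "n_clonotypes": cfg.n_clonotypes,
            "total_umi": cfg.total_umi,
            "convergence_rate": cfg.convergence_rate,
            "insertion_mean_vd": cfg.insertion_mean_vd,
            "insertion_mean_dj": cfg.insertion_mean_dj,
            "strength_bias": cfg.strength_bias,
        }
    manifest = rio.StudyManifest(rows=rows, base_dir=out_dir)
    rio.write_manifest(manifest, out_dir / "manifest.tsv")
    (out_dir / "ground_truth.json").write_text(
        json.dumps(truth, indent=2, sort_keys=True) + "\n"
    )
    return PipelineConfig(
        manifest=out_dir / "manifest.tsv",
        out_dir=out_dir / "results",
        diversity_depth=100,
        segment_depths={subset: 100},
        publicity_top_n=300,
        publicity_equal_umi={subset: 1500},
        master_seed=seed,
    )


def effect_direction_calls(
    tests_df: pd.DataFrame,
    pair: tuple[str, str] = ("XLA", "young"),
    alpha: float = 0.05,
) -> dict[str, dict]:
    """Per-feature significance and direction for one cohort pair.

    Direction is the sign of the Dunn z (rank-mean of ``pair[0]`` minus
    rank-mean of ``pair[1]``).  Used to check that an injected effect is
    both detected (adjusted p below ``alpha``) and in the right direction.
    """
    calls = {}
    for _, row in tests_df.iterrows():
        gi, gj = row["group_i"], row["group_j"]
        if {gi, gj} != set(pair):
            continue
        z = row["z"] if row["test"] == "kw_dunn" else row["median_diff"]
        if (gi, gj) != pair:
            z = -z
        calls[row["feature"]] = {
            "significant": bool(row["p_adj"] < alpha),
            "direction": int(np.sign(z)) if z == z else 0,
            "p_adj": float(row["p_adj"]),
        }
    return calls
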