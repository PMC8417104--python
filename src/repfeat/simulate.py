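"""Synthetic TCR-beta repertoire generator.

Emulates the statistical structure that the repertoire metrics consume:

* V(D)J recombination with geometric non-templated (N) insertions at the
  V-D and D-J junctions and uniform-bounded exonuclease trimming;
* clone-size distributions (lognormal or power law) normalized exactly to a
  fixed UMI depth;
* convergent recombination, implemented literally as synonymous recoding of
  an existing amino-acid CDR3 (same amino acids and V/J, different
  nucleotides);
* a codon-composition bias knob that favors strongly interacting residues
  (F, I, L, M, V, W, Y) in inserted nucleotides;
* a length knob shifting the insertion means.

The germline set is synthetic and ships with the package: segment sequences
are built deterministically from a seed, with every V tail starting at the
conserved-cysteine codon (TGT/TGC) and every J head ending in a
phenylalanine codon (TTT/TTC), all lengths multiples of three, so junctions
can always be framed.  No thymic selection or pMHC specificity is modelled
— only the statistics the downstream metrics measure.

Every generated clonotype carries ground-truth junction annotations
(``v_end``, ``d_span``, ``j_start``, ``true_insertions``) for
estimator-recovery tests.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

import numpy as np
from Bio.Data import CodonTable

from ._seeds import derive_seed
from .types import Clonotype, Repertoire, RepertoireError, translate_cdr3

__all__ = [
    "GermlineSet",
    "SyntheticCohortConfig",
    "default_germline_set",
    "recombine_clonotype",
    "generate_repertoire",
    "generate_cohorts",
    "GenerationError",
    "STRONG_RESIDUES",
]

STRONG_RESIDUES = frozenset("FILMVWY")

_fwd = CodonTable.unambiguous_dna_by_id[1].forward_table
#: the 61 coding (stop-free) codons, sorted for determinism
CODING_CODONS: tuple[str, ...] = tuple(sorted(_fwd))
_SYNONYMS: dict[str, tuple[str, ...]] = {
    aa: tuple(c for c in CODING_CODONS if _fwd[c] == aa) for aa in set(_fwd.values())
}
_IS_STRONG = np.array([_fwd[c] in STRONG_RESIDUES for c in CODING_CODONS])


class GenerationError(RuntimeError):
    """The generator could not satisfy its constraints (inconsistent config)."""


@dataclass(slots=True)
class GermlineSet:
    """Synthetic TRBV/TRBD/TRBJ segment sequences with usage probabilities.

    ``v_genes`` maps names to the terminal V region retained in CDR3
    (starting at the conserved Cys codon); ``j_genes`` to the leading J
    region (ending at the conserved Phe codon).
    """

    v_genes: dict[str, str]
    d_genes: dict[str, str]
    j_genes: dict[str, str]
    v_usage: dict[str, float]
    j_usage: dict[str, float]

    def __post_init__(self) -> None:
        for genes in (self.v_genes, self.d_genes, self.j_genes):
            for name, seq in genes.items():
                if set(seq) - set("ACGT"):
                    raise RepertoireError(f"non-ACGT germline sequence for {name}")
        for usage, genes in ((self.v_usage, self.v_genes), (self.j_usage, self.j_genes)):
            if set(usage) != set(genes):
                raise RepertoireError("usage vector does not match gene set")
            if abs(sum(usage.values()) - 1.0) > 1e-9:
                raise RepertoireError("usage probabilities must sum to 1")

    def with_usage(
        self,
        v_usage: Optional[Mapping[str, float]] = None,
        j_usage: Optional[Mapping[str, float]] = None,
    ) -> "GermlineSet":
        return GermlineSet(
            v_genes=dict(self.v_genes),
            d_genes=dict(self.d_genes),
            j_genes=dict(self.j_genes),
            v_usage=dict(v_usage) if v_usage is not None else dict(self.v_usage),
            j_usage=dict(j_usage) if j_usage is not None else dict(self.j_usage),
        )


def _random_codons(rng: np.random.Generator, n: int, weights: np.ndarray) -> str:
    idx = rng.choice(len(CODING_CODONS), size=n, p=weights)
    return "".join(CODING_CODONS[i] for i in idx)


def _uniform_codon_weights() -> np.ndarray:
    w = np.ones(len(CODING_CODONS))
    return w / w.sum()


def default_germline_set(seed: int) -> GermlineSet:
    """Deterministic bundled germline: 12 TRBV, 2 TRBD, 13 TRBJ.

    Uniform V/J usage by default.  All segment lengths are multiples of 3
    and every segment translates stop-free, so any untrimmed, uninserted
    V+D+J concatenation is in frame with no stop codon.
    """
    rng = np.random.default_rng(seed)
    w = _uniform_codon_weights()
    v_genes = {}
    for i in range(12):
        n_codons = int(rng.integers(5, 11))  # 15-30 nt
        start = "TGT" if i % 2 == 0 else "TGC"
        v_genes[f"TRBV{i + 1}"] = start + _random_codons(rng, n_codons - 1, w)
    d_genes = {}
    for i, n_codons in enumerate((3, 4)):  # 9 and 12 nt
        d_genes[f"TRBD{i + 1}"] = _random_codons(rng, n_codons, w)
    j_genes = {}
    for i in range(13):
        n_codons = int(rng.integers(5, 11))
        end = "TTC" if i % 2 == 0 else "TTT"
        j_genes[f"TRBJ{i + 1}"] = _random_codons(rng, n_codons - 1, w) + end
    v_usage = {name: 1.0 / len(v_genes) for name in v_genes}
    j_usage = {name: 1.0 / len(j_genes) for name in j_genes}
    return GermlineSet(v_genes, d_genes, j_genes, v_usage, j_usage)


_CLONE_SIZE_MODELS = ("lognormal", "power_law")


@dataclass(slots=True)
class SyntheticCohortConfig:
    """Generative parameters for one cohort of synthetic repertoires.

    ``insertion_mean_vd``/``insertion_mean_dj`` are the means of the
    geometric insertion-length distributions (in nucleotides);
    ``length_shift`` shifts both means (shorter or longer junctions);
    ``convergence_rate`` is the probability that a new clonotype is a
    synonymous recoding of an existing one rather than a fresh
    recombination; ``strength_bias`` is a logit shift favoring codons of
    strongly interacting residues in inserted nucleotides.
    """

    n_samples: int = 8
    n_clonotypes: int = 500
    total_umi: int = 2500
    clone_size_model: str = "lognormal"
    clone_size_sigma: float = 1.2  # lognormal sigma (log scale)
    clone_size_alpha: float = 1.5  # power-law (Pareto) shape
    insertion_mean_vd: float = 4.0
    insertion_mean_dj: float = 4.0
    v_trim_max: int = 4
    d_trim_max: int = 3
    j_trim_max: int = 4
    convergence_rate: float = 0.0
    strength_bias: float = 0.0
    length_shift: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.clone_size_model not in _CLONE_SIZE_MODELS:
            raise RepertoireError(
                f"clone_size_model must be one of {_CLONE_SIZE_MODELS}"
            )
        if not (0.0 <= self.convergence_rate < 1.0):
            raise RepertoireError("convergence_rate must lie in [0, 1)")
        if self.insertion_mean_vd < 0 or self.insertion_mean_dj < 0:
            raise RepertoireError("insertion means must be nonnegative")
        if min(self.v_trim_max, self.d_trim_max, self.j_trim_max) < 0:
            raise RepertoireError("trim bounds must be nonnegative")
        if self.n_clonotypes > self.total_umi:
            raise RepertoireError(
                f"n_clonotypes ({self.n_clonotypes}) exceeds total_umi ({self.total_umi})"
            )

    def codon_weights(self) -> np.ndarray:
        """Codon distribution for inserted nucleotides: uniform logits
        shifted by ``strength_bias`` on strong-residue codons."""
        logits = np.where(_IS_STRONG, self.strength_bias, 0.0)
        w = np.exp(logits - logits.max())
        return w / w.sum()


def _geometric(rng: np.random.Generator, mean: float) -> int:
    """Geometric draw on {0, 1, 2, ...} with the given mean."""
    if mean <= 0:
        return 0
    p = 1.0 / (1.0 + mean)
    return int(rng.geometric(p)) - 1


def recombine_clonotype(
    germline: GermlineSet,
    config: SyntheticCohortConfig,
    rng: np.random.Generator,
) -> Clonotype:
    """Draw one recombined, in-frame, stop-free clonotype.

    V, D and J are drawn from their usage distributions, trimmed uniformly
    within the configured bounds, and joined by geometric-length N-insertions
    (codon-biased by ``strength_bias``).  Out-of-frame or stop-containing
    junctions are resampled (bounded retries).  The returned clonotype has a
    placeholder UMI count of 1 and carries ground-truth annotations.
    """
    v_names = sorted(germline.v_genes)
    j_names = sorted(germline.j_genes)
    d_names = sorted(germline.d_genes)
    v_p = np.array([germline.v_usage[v] for v in v_names])
    j_p = np.array([germline.j_usage[j] for j in j_names])
    codon_w = config.codon_weights()
    mean_vd = max(0.0, config.insertion_mean_vd + config.length_shift)
    mean_dj = max(0.0, config.insertion_mean_dj + config.length_shift)

    for _ in range(1000):
        v = v_names[int(rng.choice(len(v_names), p=v_p))]
        j = j_names[int(rng.choice(len(j_names), p=j_p))]
        d = d_names[int(rng.integers(len(d_names)))]
        v_seq = germline.v_genes[v]
        d_seq = germline.d_genes[d]
        j_seq = germline.j_genes[j]

        v_trim = int(rng.integers(0, config.v_trim_max + 1))
        d_left = int(rng.integers(0, config.d_trim_max + 1))
        d_right = int(rng.integers(0, config.d_trim_max + 1))
        j_trim = int(rng.integers(0, config.j_trim_max + 1))
        v_part = v_seq[: len(v_seq) - v_trim]
        d_part = d_seq[d_left : max(d_left, len(d_seq) - d_right)]
        j_part = j_seq[j_trim:]

        n1 = _geometric(rng, mean_vd)
        n2 = _geometric(rng, mean_dj)
        ins1 = _random_codons(rng, -(-n1 // 3), codon_w)[:n1] if n1 else ""
        ins2 = _random_codons(rng, -(-n2 // 3), codon_w)[:n2] if n2 else ""

        nt = v_part + ins1 + d_part + ins2 + j_part
        if len(nt) % 3 != 0 or len(nt) < 9:
            continue
        aa = translate_cdr3(nt)
        if "*" in aa:
            continue
        v_end = len(v_part)
        j_start = len(nt) - len(j_part)
        d_span = None
        if d_part:
            d0 = v_end + n1
            d_span = (d0, d0 + len(d_part))
        return Clonotype(
            cdr3_nt=nt,
            cdr3_aa=aa,
            v_segment=v,
            j_segment=j,
            umi_count=1,
            v_end=v_end,
            d_span=d_span,
            j_start=j_start,
            true_insertions=n1 + n2,
        )
    raise GenerationError(
        "1000 consecutive out-of-frame/stop draws; check trim and insertion config"
    )


def _synonymous_recode(clonotype: Clonotype, rng: np.random.Generator) -> Optional[str]:
    """A different nucleotide sequence with the same translation, or None
    if the amino-acid sequence admits no synonymous variant."""
    codon_sets = [_SYNONYMS[aa] for aa in clonotype.cdr3_aa]
    if all(len(s) == 1 for s in codon_sets):
        return None
    for _ in range(20):
        nt = "".join(s[int(rng.integers(len(s)))] for s in codon_sets)
        if nt != clonotype.cdr3_nt:
            return nt
    return None


def _clone_sizes(
    config: SyntheticCohortConfig, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Integer clone sizes >= 1 summing exactly to total_umi.

    Weights from the configured model; every clone gets a guaranteed single
    UMI and the remaining depth is apportioned by largest-remainder
    rounding, which conserves the total exactly.
    """
    if config.clone_size_model == "lognormal":
        weights = rng.lognormal(mean=0.0, sigma=config.clone_size_sigma, size=n)
    else:
        weights = rng.pareto(config.clone_size_alpha, size=n) + 1.0
    remaining = config.total_umi - n
    quota = remaining * weights / weights.sum()
    base = np.floor(quota).astype(int)
    frac = quota - base
    short = remaining - base.sum()
    order = np.argsort(-frac, kind="stable")
    base[order[:short]] += 1
    return base + 1


def generate_repertoire(
    germline: GermlineSet,
    config: SyntheticCohortConfig,
    *,
    sample_id: str,
    donor_id: str = "",
    cohort: str = "synthetic",
    subset: str = "nTreg",
) -> Repertoire:
    """Generate one repertoire: distinct clonotypes with exact UMI depth.

    With probability ``convergence_rate`` a new clonotype synonymously
    recodes a previously generated one (same amino acids, same V/J,
    different nucleotides); otherwise a fresh recombination is drawn.
    Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    clonotypes: list[Clonotype] = []
    seen: set[tuple] = set()
    attempts = 0
    max_attempts = 200 * config.n_clonotypes + 1000
    while len(clonotypes) < config.n_clonotypes:
        attempts += 1
        if attempts > max_attempts:
            raise GenerationError(
                f"could not generate {config.n_clonotypes} distinct clonotypes"
            )
        if clonotypes and rng.random() < config.convergence_rate:
            parent = clonotypes[int(rng.integers(len(clonotypes)))]
            nt = _synonymous_recode(parent, rng)
            if nt is None:
                continue
            cand = replace(parent, cdr3_nt=nt, umi_count=1)
        else:
            cand = recombine_clonotype(germline, config, rng)
        if cand.key() in seen:
            continue
        seen.add(cand.key())
        clonotypes.append(cand)

    sizes = _clone_sizes(config, len(clonotypes), rng)
    clonotypes = [replace(c, umi_count=int(s)) for c, s in zip(clonotypes, sizes)]
    return Repertoire(
        sample_id=sample_id,
        donor_id=donor_id or sample_id,
        cohort=cohort,
        subset=subset,
        clonotypes=clonotypes,
    )


_CONFIG_FIELDS = {f.name for f in dataclasses.fields(SyntheticCohortConfig)}


def generate_cohorts(
    base: SyntheticCohortConfig,
    effects: Mapping[str, Mapping[str, object]],
    germline: GermlineSet,
    *,
    subset: str = "nTreg",
) -> list[Repertoire]:
    """Generate labeled repertoires for several cohorts.

    ``effects`` maps cohort name to config-field overrides (empty mapping =
    same parameters as ``base``).  Cohort- and sample-level seeds are
    derived deterministically from ``base.seed``, the cohort name and the
    sample index.
    """
    repertoires = []
    for cohort, overrides in effects.items():
        unknown = set(overrides) - _CONFIG_FIELDS
        if unknown:
            raise RepertoireError(f"unknown config override fields: {sorted(unknown)}")
        cfg = replace(base, **dict(overrides))
        for i in range(cfg.n_samples):
            sample_seed = derive_seed(base.seed, cohort, i, "generate")
            sample_cfg = replace(cfg, seed=sample_seed)
            repertoires.append(
                generate_repertoire(
                    germline,
                    sample_cfg,
                    sample_id=f"{cohort}_s{i:02d}",
                    donor_id=f"{cohort}_d{i:02d}",
                    cohort=cohort,
                    subset=subset,
                )
            )
    return repertoires
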