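"""Generator contracts: germline construction, recombination statistics,
clone-size conservation, convergence injection, cohort overrides."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest
from Bio.Seq import Seq

from repfeat.io import write_clonotype_table
from repfeat.metrics import convergence
from repfeat.simulate import (
    GenerationError,
    SyntheticCohortConfig,
    default_germline_set,
    generate_cohorts,
    generate_repertoire,
    recombine_clonotype,
)
from repfeat.types import RepertoireError


class TestDefaultGermlineSet:
    def test_deterministic(self):
        a, b = default_germline_set(1), default_germline_set(1)
        assert a.v_genes == b.v_genes
        assert a.d_genes == b.d_genes
        assert a.j_genes == b.j_genes

    def test_sizes_and_conserved_residues(self, germline):
        assert len(germline.v_genes) >= 12
        assert len(germline.d_genes) == 2
        assert len(germline.j_genes) >= 13
        for seq in germline.v_genes.values():
            assert "C" in str(Seq(seq).translate())
        for seq in germline.j_genes.values():
            assert "F" in str(Seq(seq).translate())

    def test_uniform_usage_exact(self, germline):
        n = len(germline.v_genes)
        assert all(p == 1.0 / n for p in germline.v_usage.values())


class TestRecombineClonotype:
    def test_degenerate_no_insertions_no_trims(self, germline):
        cfg = SyntheticCohortConfig(
            insertion_mean_vd=0, insertion_mean_dj=0,
            v_trim_max=0, d_trim_max=0, j_trim_max=0, seed=1,
        )
        rng = np.random.default_rng(5)
        for _ in range(20):
            c = recombine_clonotype(germline, cfg, rng)
            assert c.true_insertions == 0
            v_tail = germline.v_genes[c.v_segment]
            j_head = germline.j_genes[c.j_segment]
            assert c.cdr3_nt.startswith(v_tail)
            assert c.cdr3_nt.endswith(j_head)
            middle = c.cdr3_nt[len(v_tail):len(c.cdr3_nt) - len(j_head)]
            assert middle in germline.d_genes.values()

    def test_outputs_in_frame_and_stop_free(self, germline):
        cfg = SyntheticCohortConfig(seed=1)
        rng = np.random.default_rng(6)
        for _ in range(50):
            c = recombine_clonotype(germline, cfg, rng)
            assert len(c.cdr3_nt) % 3 == 0
            assert "*" not in c.cdr3_aa
            assert str(Seq(c.cdr3_nt).translate()) == c.cdr3_aa

    def test_annotations_consistent(self, germline):
        cfg = SyntheticCohortConfig(seed=1)
        rng = np.random.default_rng(7)
        for _ in range(50):
            c = recombine_clonotype(germline, cfg, rng)
            assert 0 <= c.v_end <= c.j_start <= len(c.cdr3_nt)
            d_len = 0 if c.d_span is None else c.d_span[1] - c.d_span[0]
            assert (c.j_start - c.v_end) - d_len == c.true_insertions

    def test_insertion_mean_matches_independent_oracle(self, germline):
        """Accepted-draw insertion totals follow the geometric model under
        the same in-frame/stop-free rejection, checked against a separate
        minimal implementation of that acceptance sampling."""
        cfg = SyntheticCohortConfig(
            insertion_mean_vd=4, insertion_mean_dj=4,
            v_trim_max=0, d_trim_max=0, j_trim_max=0, seed=1,
        )
        rng = np.random.default_rng(123)
        n = 10_000
        observed = np.array(
            [recombine_clonotype(germline, cfg, rng).true_insertions
             for _ in range(n)], dtype=float,
        )

        # independent oracle: same generative story, separate code
        orng = np.random.default_rng(321)
        v_list = sorted(germline.v_genes.values())
        d_list = sorted(germline.d_genes.values())
        j_list = sorted(germline.j_genes.values())
        codons = sorted(
            c for c in ("".join(t) for t in __import__("itertools").product("ACGT", repeat=3))
            if str(Seq(c).translate()) != "*"
        )
        oracle = []
        while len(oracle) < n:
            n1, n2 = orng.geometric(0.2, size=2) - 1  # mean 4 on {0,1,...}
            v = v_list[orng.integers(len(v_list))]
            d = d_list[orng.integers(len(d_list))]
            j = j_list[orng.integers(len(j_list))]
            ins1 = "".join(orng.choice(codons, size=-(-int(n1) // 3)))[: int(n1)]
            ins2 = "".join(orng.choice(codons, size=-(-int(n2) // 3)))[: int(n2)]
            seq = v + ins1 + d + ins2 + j
            if len(seq) % 3 == 0 and "*" not in str(Seq(seq).translate()):
                oracle.append(int(n1) + int(n2))
        oracle = np.array(oracle, dtype=float)
        se = np.sqrt(observed.var() / n + oracle.var() / n)
        assert abs(observed.mean() - oracle.mean()) < 3 * se

    def test_geometric_primitive_mean(self):
        from repfeat.simulate import _geometric
        rng = np.random.default_rng(9)
        draws = np.array([_geometric(rng, 4.0) for _ in range(10_000)], dtype=float)
        se = draws.std() / np.sqrt(draws.size)
        assert abs(draws.mean() - 4.0) < 3 * se

    def test_impossible_config_raises(self, germline):
        # a lone V tail of length 1 mod 3, with no trimming and no
        # insertions allowed, can never produce an in-frame junction
        cfg = SyntheticCohortConfig(
            insertion_mean_vd=0, insertion_mean_dj=0,
            v_trim_max=0, d_trim_max=0, j_trim_max=0, seed=1,
        )
        bad = replace_germline_single_v(germline)
        rng = np.random.default_rng(1)
        with pytest.raises(GenerationError):
            recombine_clonotype(bad, cfg, rng)


def replace_germline_single_v(germline):
    """Germline variant whose only V tail breaks the codon frame."""
    name = sorted(germline.v_genes)[0]
    g = germline.with_usage()
    v_seq = germline.v_genes[name] + "A"  # length = 1 mod 3
    g.v_genes.clear()
    g.v_genes[name] = v_seq
    g.v_usage.clear()
    g.v_usage[name] = 1.0
    return g


class TestGenerateRepertoire:
    def test_depth_conservation_and_determinism(self, germline, tmp_path):
        cfg = SyntheticCohortConfig(n_clonotypes=400, total_umi=2000, seed=77)
        r1 = generate_repertoire(germline, cfg, sample_id="s")
        r2 = generate_repertoire(germline, cfg, sample_id="s")
        assert r1.total_umi == 2000
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_clonotype_table(r1, p1, "airr")
        write_clonotype_table(r2, p2, "airr")
        assert p1.read_bytes() == p2.read_bytes()

    def test_no_convergence_collisions_match_birthday_oracle(self, germline):
        """With convergence_rate 0, aa richness trails nt richness only by
        chance collisions.  nt >= aa always; the mean collision count over
        seeds agrees with a birthday-problem oracle built from the
        independently sampled per-pair aa-collision probability."""
        cfg0 = SyntheticCohortConfig(convergence_rate=0.0, seed=0)
        rng = np.random.default_rng(555)
        m = 4000
        draws = [recombine_clonotype(germline, cfg0, rng).cdr3_aa for _ in range(m)]
        from collections import Counter
        counts = Counter(draws)
        p_pair = sum(k * (k - 1) for k in counts.values()) / (m * (m - 1))

        n = 500
        n_seeds = 20
        collisions = []
        for seed in range(n_seeds):
            cfg = SyntheticCohortConfig(
                n_clonotypes=n, total_umi=1000, convergence_rate=0.0, seed=seed
            )
            rep = generate_repertoire(germline, cfg, sample_id="s")
            n_nt = len({c.cdr3_nt for c in rep.clonotypes})
            n_aa = len({c.cdr3_aa for c in rep.clonotypes})
            assert n_nt >= n_aa
            collisions.append(n_nt - n_aa)
        expected = n * (n - 1) / 2 * p_pair  # per repertoire
        se = np.sqrt(max(expected, np.mean(collisions)) / n_seeds)  # Poisson-scale
        assert abs(np.mean(collisions) - expected) <= 3 * se + 0.1

    def test_sigma_zero_gives_even_clone_sizes(self, germline):
        cfg = SyntheticCohortConfig(
            n_clonotypes=100, total_umi=1000, clone_size_sigma=0.0, seed=3
        )
        rep = generate_repertoire(germline, cfg, sample_id="s")
        sizes = [c.umi_count for c in rep.clonotypes]
        assert all(abs(s - 10) <= 1 for s in sizes)
        assert sum(sizes) == 1000

    def test_too_many_clonotypes_rejected(self):
        with pytest.raises(RepertoireError):
            SyntheticCohortConfig(n_clonotypes=100, total_umi=50)

    def test_convergence_rate_raises_nt_per_aa_ratio(self, germline):
        cfg = SyntheticCohortConfig(
            n_clonotypes=800, total_umi=1600, convergence_rate=0.2, seed=5
        )
        rep = generate_repertoire(germline, cfg, sample_id="s")
        assert convergence(rep.clonotypes) > 1.1


class TestStrengthBias:
    def test_bias_increases_central_strong_fraction(self, germline):
        """Monotonicity of the codon bias: stronger logit shift, higher
        strong-residue fraction in the CDR3 center (10,000 clonotypes)."""
        from repfeat.features import clonotype_strength
        means = []
        for bias in (0.0, 1.5, 3.0):
            cfg = SyntheticCohortConfig(strength_bias=bias, seed=1)
            rng = np.random.default_rng(17)
            vals = []
            for _ in range(3400):
                c = recombine_clonotype(germline, cfg, rng)
                if len(c.cdr3_aa) >= 5:
                    vals.append(clonotype_strength(c.cdr3_aa))
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]


class TestGenerateCohorts:
    def test_unknown_override_field_rejected(self, germline):
        base = SyntheticCohortConfig(n_samples=1, seed=1)
        with pytest.raises(RepertoireError, match="unknown config override"):
            generate_cohorts(base, {"A": {"bogus_field": 1}}, germline)

    def test_labels_and_determinism(self, germline):
        base = SyntheticCohortConfig(
            n_samples=2, n_clonotypes=100, total_umi=300, seed=9
        )
        reps = generate_cohorts(base, {"A": {}, "B": {}}, germline, subset="RTE")
        assert [r.cohort for r in reps] == ["A", "A", "B", "B"]
        assert all(r.subset == "RTE" for r in reps)
        again = generate_cohorts(base, {"A": {}, "B": {}}, germline, subset="RTE")
        assert [r.clonotypes for r in reps] == [r.clonotypes for r in again]
        # different cohorts get different sub-seeds, hence different samples
        assert reps[0].clonotypes != reps[2].clonotypes

    def test_halved_clonotype_override_lowers_richness(self, germline):
        base = SyntheticCohortConfig(
            n_samples=3, n_clonotypes=400, total_umi=1200, seed=21
        )
        reps = generate_cohorts(
            base, {"A": {}, "B": {"n_clonotypes": 200}}, germline
        )
        for a, b in zip(reps[:3], reps[3:]):
            assert b.n_clonotypes < a.n_clonotypes

    def test_convergence_override_raises_statistic(self, germline):
        base = SyntheticCohortConfig(
            n_samples=3, n_clonotypes=400, total_umi=1200, seed=33
        )
        reps = generate_cohorts(
            base, {"A": {}, "B": {"convergence_rate": 0.15}}, germline
        )
        for a, b in zip(reps[:3], reps[3:]):
            assert convergence(b.clonotypes) > convergence(a.clonotypes)
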