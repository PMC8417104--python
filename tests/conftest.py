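"""Shared fixtures: codon helpers and small synthetic repertoires."""

from __future__ import annotations

import pytest
from Bio.Data import CodonTable

from repfeat.simulate import SyntheticCohortConfig, default_germline_set, generate_repertoire
from repfeat.types import Clonotype, Repertoire

# independent codon map (built here from the standard table, not taken from
# the package internals) for constructing consistent nt/aa pairs in tests
_FWD = CodonTable.unambiguous_dna_by_id[1].forward_table
AA_TO_CODON = {}
for codon in sorted(_FWD):
    AA_TO_CODON.setdefault(_FWD[codon], codon)
AA_TO_CODON["*"] = "TAA"


def nt_for(aa: str) -> str:
    """A nucleotide sequence translating to the given amino acids."""
    return "".join(AA_TO_CODON[c] for c in aa)


def make_clonotype(
    aa: str,
    count: int = 1,
    v: str = "TRBV9",
    j: str = "TRBJ1",
    nt: str | None = None,
    **kwargs,
) -> Clonotype:
    return Clonotype(
        cdr3_nt=nt if nt is not None else nt_for(aa),
        cdr3_aa=aa,
        v_segment=v,
        j_segment=j,
        umi_count=count,
        **kwargs,
    )


def make_repertoire(clonotypes, sample_id="s1", cohort="young", subset="nTreg", donor_id="d1"):
    return Repertoire(
        sample_id=sample_id,
        donor_id=donor_id,
        cohort=cohort,
        subset=subset,
        clonotypes=list(clonotypes),
    )


@pytest.fixture(scope="session")
def germline():
    return default_germline_set(11)


@pytest.fixture(scope="session")
def synthetic_repertoire(germline):
    """One moderately sized generated repertoire (deterministic)."""
    cfg = SyntheticCohortConfig(n_clonotypes=1000, total_umi=5000, seed=101)
    return generate_repertoire(germline, cfg, sample_id="syn1", cohort="young", subset="nTreg")
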