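"""Per-V-segment diversity at equal sequencing depth.

Slices one synthetic repertoire by V segment, rarefies each slice to a
common UMI depth, and prints Chao1 richness, normalized Shannon-Wiener
evenness and convergence per segment.
"""

from repfeat.io import select_abundant_v_segments, slice_by_v
from repfeat.metrics import diversity_of_slice, downsample_umis
from repfeat.simulate import SyntheticCohortConfig, default_germline_set, generate_repertoire

germline = default_germline_set(seed=1)
rep = generate_repertoire(
    germline,
    SyntheticCohortConfig(n_clonotypes=800, total_umi=4000, convergence_rate=0.1, seed=7),
    sample_id="demo", subset="nTreg",
)

depth = 150
for v in select_abundant_v_segments([rep], min_umi=depth):
    sl = downsample_umis(slice_by_v(rep, v), depth, seed=1)
    d = diversity_of_slice(sl)
    print(
        f"{v}: observed {d.observed:3d} clonotypes | Chao1 {d.chao1:6.1f} | "
        f"evenness {d.shannon_norm:.3f} | convergence {d.convergence:.3f}"
    )

# Chao1 >= observed richness always (it extrapolates unseen clonotypes from
# singletons/doubletons); evenness near 1 means little clonal expansion;
# convergence > 1 means several nucleotide variants encode one CDR3 protein.
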