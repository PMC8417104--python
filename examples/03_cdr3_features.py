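"""Abundance-weighted CDR3 physicochemical features.

Computes the central-window interaction strength, residue volume and
charge, plus CDR3 length and non-templated insertion counts, for each
abundant V segment of one synthetic repertoire.
"""

import pandas as pd

from repfeat.features import central_region, slice_features
from repfeat.io import select_abundant_v_segments, slice_by_v
from repfeat.simulate import SyntheticCohortConfig, default_germline_set, generate_repertoire

print("central 5-mer of CASSLGQAYEQYF:", central_region("CASSLGQAYEQYF"))

germline = default_germline_set(seed=1)
rep = generate_repertoire(
    germline,
    SyntheticCohortConfig(n_clonotypes=600, total_umi=3000, seed=3),
    sample_id="demo", subset="nTreg",
)

records = []
for v in select_abundant_v_segments([rep], min_umi=100):
    records.extend(slice_features(slice_by_v(rep, v)))
df = pd.DataFrame(records).pivot_table(
    index="v_segment", columns="feature", values="raw_value"
)
print(df.round(3).to_string())

# strength/charge are fractions of the central 5 residues (strongly
# interacting F/I/L/M/V/W/Y, charged D/E/K/R); volume is the mean residue
# volume in cubic angstroms; cdr3_len in residues; added_nt counts the
# non-templated nucleotides at the V-D and D-J junctions.  All values are
# weighted by clonotype UMI abundance.
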