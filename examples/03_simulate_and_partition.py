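"""Simulate a clone survey and recover its clades from K2P distances.

The generator produces clones from 18 individuals in four taxa, with two
ancient numt lineages (translocated before the taxa split, evolving at
0.1x the mitochondrial rate, lacking the R2 array) plus heteroplasmy and
polymerase errors.  Average-linkage clustering of K2P distances on the
masked alignment should recover exactly three clades.
"""

from collections import Counter

from numtscan import SimulationConfig, simulate_dataset, k2p_matrix, partition_clades

ds = simulate_dataset(SimulationConfig(seed=1))
print(f"simulated {len(ds.clones)} clones from "
      f"{ds.truth_individuals.shape[0]} individuals")
print("true origins:", {k: int(v) for k, v in ds.truth_sequences["origin"].value_counts().items()})

dm = k2p_matrix(ds.aligned)  # R2 block masked, pairwise deletion
part = partition_clades(dm)
print(f"\nrecovered {part.n_clades} clades (cut height {part.cut_height:.3f})")
origin = ds.origin_of()
for cid, members in sorted(part.groups().items()):
    counts = Counter(origin[m] for m in members)
    print(f"  clade {cid}: {len(members)} clones, true origins {dict(counts)}")
# Each recovered clade maps one-to-one onto a true origin (mtDNA, numt-1,
# numt-2): the ~10-30% between-clade divergence dwarfs within-clade noise.
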