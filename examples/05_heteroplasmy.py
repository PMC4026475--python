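"""Call per-individual heteroplasmy, discounting polymerase error.

Sequence heteroplasmy: a second core haplotype whose variant sites recur
in at least two clones (a polymerase error is private to one clone).
Length heteroplasmy: more than one R2 array-length class among an
individual's clones.  Calls are compared against the simulator's truth.
"""

from numtscan import (
    ErrorModel, SimulationConfig, simulate_dataset, call_heteroplasmy, decompose,
)

ds = simulate_dataset(SimulationConfig(seed=1))
core = ds.aligned.core_sequences()
decs = {r.id: decompose(r.sequence) for r in ds.clones}
em = ErrorModel(rate=7.2e-5, length=int(ds.aligned.column_keep().sum()), cycles=34)

mt = ds.truth_sequences.query("origin == 'mtDNA'")
truth = ds.truth_individuals.set_index("individual")
hits = total = 0
print("individual  taxon            seq-het  len-het  haplotypes  size-classes  truth")
for ind, group in mt.groupby("individual", sort=False):
    ids = list(group["id"])
    call = call_heteroplasmy(ind, {i: core[i] for i in ids},
                             {i: decs[i] for i in ids}, em)
    t = bool(truth.loc[ind, "sequence_het"])
    total += t
    hits += t and call.sequence_het
    print(f"{ind:10s}  {group['taxon'].iloc[0]:15s}  {str(call.sequence_het):7s}  "
          f"{str(call.length_het):7s}  {call.n_core_haplotypes:^10d}  "
          f"{call.n_size_classes:^12d}  {t}")
print(f"\nsequence-heteroplasmy detected in {hits}/{total} truly heteroplasmic individuals")
# East/Hainan individuals carry a planted minor haplotype (2 core sites);
# Central/septentrionalis do not — matching the published phylogeographic
# pattern where only the former taxa show core-sequence heteroplasmy.
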