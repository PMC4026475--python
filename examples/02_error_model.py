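"""Expected polymerase errors per cloned sequence.

Each cloned molecule accumulates Taq misincorporations over the PCR, so
per-clone error counts follow Poisson(rate x length x cycles).  With the
standard Taq rate, a 724-bp amplicon and 34 cycles this predicts ~1.77
errors per clone — enough to create apparent "haplotypes" that are
artefacts, which is why heteroplasmy calling must discount them.
"""

from numtscan import ErrorModel

em = ErrorModel(rate=7.2e-5, length=724, cycles=34)
print(f"lambda = {em.lam:.2f} expected errors per clone")
for k in (2, 3, 4):
    print(f"  P(> {k} errors) = {em.tail_fraction(k):.0%}")
print(f"  expected error-free clones: {em.error_free_fraction():.0%}")
# Prints lambda = 1.77 with tails 26%, 10%, 3%: a quarter of clones are
# expected to carry more than two artefactual substitutions.
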