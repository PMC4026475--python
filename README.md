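# numtscan

Numt detection and heteroplasmy calling from cloned mitochondrial
control-region sequences.

## The problem

When the mitochondrial control region is PCR-amplified and cloned, the
clone library mixes three kinds of molecules: authentic mtDNA haplotypes
(possibly several per individual — heteroplasmy), nuclear copies of
mitochondrial DNA (numts) that co-amplify with the same primers, and
polymerase artefacts introduced during amplification.  Mistaking any one
for another corrupts phylogenetic and phylogeographic inference.
`numtscan` implements the analysis that separates them, built around the
mitochondrial control region of the Chinese horseshoe bat *Rhinolophus
sinicus* (four taxa: East, Hainan, Central *sinicus* and
*septentrionalis*), whose CSB domain carries the R2 tandem array of 11-bp
repeat motifs.

## What it computes

* **R2 repeat decomposition** — finds the tandem array, infers the unit
  period, assigns every unit to a motif class (A–E built in; classes
  differ by 1–2 substitutions; tolerance: edit distance ≤ 2) and emits
  the run-length structure `(A)4(B)1…`, full-unit count *N* and array
  length, with partial units kept inline as literals.
* **K2P distances and Nei net divergence** — on a gapped alignment with
  the unalignable R2 block masked, with pairwise deletion:
  *d* = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q), and
  *d*<sub>net</sub>(X,Y) = mean d(x,y) − ½(mean d within X + mean d within Y).
* **Clade partition** — average-linkage clustering cut at the largest
  relative merge-height gap, accepted only when mean between-clade /
  within-clade distance ≥ 5.
* **Numt calls** — a clade is a numt when ≥ 90 % of its members lack the
  R2 array and it contains no anchor (independently verified mtDNA)
  sequence; mean internal mutational steps corroborate (numts evolve
  slower after translocation).
* **Haplotype networks** — minimum spanning networks (all co-minimal
  edges kept) weighted by mutational steps; an indel run counts as one
  step.
* **Heteroplasmy calls** — per individual: sequence heteroplasmy when a
  second core haplotype survives error discounting (variant sites must
  recur in ≥ 2 clones), length heteroplasmy when clones span ≥ 2 R2
  array-length classes.
* **Polymerase error model** — per-clone errors ~ Poisson(rate × length ×
  cycles); tail fractions and re-cloning summaries quantify expected
  artefacts.
* **Simulator** — generates clone sets with the full causal structure
  (taxon divergence, ancient translocations, heteroplasmy, slippage,
  Taq errors) plus ground-truth tables, so the whole pipeline is testable
  without external data.

## Worked example

```python
from numtscan import decompose, reconstruct_from_structure, ErrorModel

seq = reconstruct_from_structure("(C)1AACGC(D)6(C)1(D)1(C)3(D)2(C)1(D)1(C)3")
dec = decompose(seq)
print(dec.structure, dec.n_units, dec.array_length)
# (C)1AACGC(D)6(C)1(D)1(C)3(D)2(C)1(D)1(C)3 19 214

em = ErrorModel(rate=7.2e-5, length=724, cycles=34)
print(f"{em.lam:.2f}", f"{em.tail_fraction(2):.0%}")
# 1.77 26%
```

The decomposition recovers the published structure of a Hainan
individual's array — 19 full units plus a 5-bp truncated unit, 214 bp —
and the error model says a typical 724-bp clone carries 1.77 polymerase
errors on average, with 26 % of clones exceeding two.

The `examples/` directory has one short script per capability
(decomposition, error model, simulation + clade recovery, numt calls +
networks, heteroplasmy); each prints the numbers it computes and what
they mean.  A thin CLI wraps the same functions:

```bash
numtscan errors --rate 7.2e-5 --length 724 --cycles 34
numtscan run --seed 1 --out myrun        # simulate -> decompose -> classify
```

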