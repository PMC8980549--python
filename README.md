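# founderage

Founder-mutation haplotype analysis and allele-age estimation from
carrier SNP haplotypes.

When one pathogenic variant is found in many apparently unrelated
families on the same surrounding SNP haplotype, the parsimonious
explanation is a single founder event. The variant's age can then be
read from how far recombination has eroded the ancestral haplotype
around it. `founderage` implements that analysis end to end for
autozygous carriers — the motivating data set, shipped with the
package, is the CLCC1 c.75C>A (chr1:108,950,376 G>T, GRCh38) retinitis
pigmentosa mutation carried by 9 consanguineous families of Pakistani
origin (18 carrier chromosomes, 99 markers spanning ~3.5 Mb).

It is a library first: import it, or run the short scripts in
`examples/`. A thin `founderage` CLI wraps the main entry points.

## What it computes

**Haplotype structure** (`founderage.haplotype`)

* the fully shared autozygous core around the mutation;
* the founder haplotype, by outward extension: at each marker the
  founder allele is the plurality allele among chromosomes still
  consistent with the founder on that side;
* recombination-free blocks, each labeled by its marker nearest the
  mutation, with recombination fraction θ = Δbp × (cM/Mb) × 10⁻⁸ to
  the label marker and a sharing count of chromosomes conserving the
  founder haplotype out through the block;
* per-family recombination events (at most one breakpoint per side)
  and shared-recombinant-ancestor groups;
* one-sided conserved segment lengths with censoring at the map edge.

**Haplotype frequencies** (`founderage.frequency`) — multilocus EM and
composite (equal-weight) counting from unphased control genotypes,
supplying the control frequency P_N of the founder block haplotype.

**Age estimators** (`founderage.age`) — with P_D the founder-haplotype
frequency on carrier chromosomes, P_N its control frequency and
δ = (P_D − P_N)/(1 − P_N):

* closed-form decay: g = ln δ / ln(1 − θ);
* iterative transition-matrix: the state (ancestral, non-ancestral)
  starts at (1, 0) and is multiplied each generation by
  K = cR + μM + (1 − c − μ)I until the ancestral frequency reaches
  P_D (equals the closed form when μ = 0);
* segment-length (Gamma): one-sided conserved segments are
  Exponential(g) in Morgans; with S their sum and m the uncensored
  count, ĝ = (m − 1)/S with Gamma-quantile confidence limits, under
  independent or correlated genealogies;
* parametric bootstrap CIs (binomial resampling of carrier sharing).

**Simulation** (`founderage.simulate`) — forward simulation of founder
descent (Haldane recombination, per-site mutation, background haplotype
pool) with a ground-truth record, plus Hardy–Weinberg control
diplotypes, so every estimator is testable against known truth.

## Worked example

```sh
founderage reproduce-paper
```

prints, from the packaged carrier table and per-block inputs:

```
Founder-mutation haplotype analysis
  shared core: rs10857972..rs570812 (9 markers)
  families: 9, max recombination events 2

           block n_snps    theta shared  age EM  age CHM
      rs12403629     10  0.01242      4     123      123
        rs345292     13  0.01068      6     104      104
      rs17020437      6  0.01009      8      99       89
      rs12034547      8  0.00858     10      88       79
       rs1333130     24  0.00130     14     196      196
  CLCC1-MUTATION      9  0.00000     18
        rs587727      2  0.00192     16     159      136
      rs17014495     17  0.00221     12     185      185
      rs12239350      4  0.00828      6     135      134
      rs11102121      2  0.01522      2

age range: 79-196 generations (~1975-4900 years)
gamma (independent): 94.7 (66.1-136.0); (correlated): 74.5 (38.3-146.8)
```

Reading it: all 18 carrier chromosomes are identical over a 9-marker
core around the mutation — the autozygous footprint of the founder
chromosome. Moving outward, the count of chromosomes still carrying
the founder haplotype (`shared`) decays from 18 to 4 (left) and 2
(right); each block's decay, paired with the control-panel frequency of
its haplotype (EM or composite estimate), converts into an age in
generations via the decay formula. Blocks whose haplotype is common in
controls (e.g. rs11102121, δ < 0) carry no decay signal and are left
blank. Across estimable blocks the age spans 79–196 generations —
roughly 2,000–4,900 years at 25 years per generation — and the
segment-length (Gamma) estimates fall in the same range without using
any control panel. Python equivalents with commentary are in
`examples/`.

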