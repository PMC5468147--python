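# mitoselect

Tools for asking how efficiently purifying selection scrubs deleterious
amino acid variants from mitochondrial protein-coding (OXPHOS) genes, aimed
at population geneticists comparing habitats or demographic groups within a
species — the motivating system being nine-spined stickleback mitogenomes
pooled from freshwater and brackish-water habitats, with three-spined
stickleback as the outgroup.

## What it computes

Given a multiple alignment of complete mitogenomes with gene annotations,
pool (habitat) labels and an outgroup, the package:

- classifies every segregating coding site as synonymous or nonsynonymous
  under the **vertebrate mitochondrial genetic code** (translation table 2:
  TGA→Trp, ATA→Met, AGA/AGG→stop), with Nei–Gojobori stop-avoiding pathway
  averaging for multi-hit codons, and polarizes derived alleles by the
  minor-allele rule with outgroup tie-breaking;
- estimates the fraction of nonsynonymous polymorphisms that are weakly or
  moderately deleterious in the McDonald–Kreitman framework,

      δ = 1 − (Dn·Ps)/(Ds·Pn),

  where (Pn, Ps) count nonsynonymous/synonymous polymorphisms within the
  pool and (Dn, Ds) count fixed differences to the outgroup species, with a
  10,000-replicate percentile bootstrap CI (class-label resampling);
- contrasts habitats by Fisher's exact test on the (Pn, Ps) table and by a
  one-sided downsampling permutation test of the Pn/Ps ratio;
- computes NG86 dN/dS with Jukes–Cantor correction, per-genome mutation
  load (δ × mean derived nonsynonymous alleles per genome), and
  Mann–Whitney / variance-F / Spearman tests for score comparisons;
- joins externally produced pathogenicity scores (MutPred-style on [0,1],
  SNAP2-style on [−100,100]) to observed and all-potential amino acid
  variants and fits the exponential **selection function**
  y = a·exp(−b·x) to the binned ratio of observed to potential score
  distributions (larger b = steeper purifying selection);
- summarizes diversity: S, haplotype number and diversity
  h = n/(n−1)(1−Σp²), π, Watterson's θ, and microsatellite HE/HO/NA/AR/FIS
  plus the heterozygosity-loss coefficient F = (HE_src − HE_der)/HE_src;
- generates **synthetic studies with planted truth**: alignments carrying
  exact (Pn, Ps, Dn, Ds) targets, score tables with a controllable
  observed-vs-potential shift, and bottleneck-drifted microsatellites.

## Worked example

```sh
mitoselect simulate --seed 3 --out run        # synthetic two-habitat study
mitoselect classify --data run                # variants + (Pn,Ps,Dn,Ds)
mitoselect mkdelta  --data run --seed 3 --reps 2000
cat run/mkdelta_report.txt
```

```
seed	3
reps	2000
freshwater.Pn	28
freshwater.Ps	51
freshwater.PnPs	0.549
freshwater.delta	0.8359
freshwater.delta_ci95	(0.7218, 0.8990)
brackish.Pn	41
brackish.Ps	145
brackish.PnPs	0.283
brackish.delta	0.6814
brackish.delta_ci95	(0.5170, 0.7777)
fisher_PnPs.p	0.03163
downsampling_brackish_to_freshwater.p	0.0004998
```

Reading this: the simulator planted 28 nonsynonymous and 51 synonymous
polymorphisms in the freshwater pool (41/145 brackish) and 141/1565 fixed
differences on the outgroup branch; the classifier recovered them exactly.
The freshwater δ of 0.836 says an estimated 84% of freshwater
nonsynonymous polymorphisms are weakly or moderately deleterious (95% CI
roughly 72–90%), versus 68% in brackish water; Fisher's p = 0.032 marks
the habitat difference in Pn/Ps as significant, and the downsampling test
shows it is not an artifact of the smaller freshwater site count.
`mitoselect scores` and `mitoselect diversity` add the selection-function
fits and the Table-style diversity summaries; `mitoselect report` collates
everything.

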