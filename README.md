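# grapekin

Pedigree reconstruction for clonally propagated germplasm collections —
grapevine varietal panels being the motivating case. Old cultivar assortments
are tangled webs of parent–offspring links, full sibs, recurrent founders,
synonyms and somatic variants; `grapekin` re-implements, as a tested and
reusable pipeline, the marker-based workflow used to unravel them:

1. **SSR exclusion search** — multiallelic nuclear microsatellite profiles
   propose candidate duos (parent–offspring) and trios
   (parent–parent–offspring) by allele-sharing exclusion.
2. **SNP curation** — array genotypes are filtered (MAF > 0.05, no-calls
   < 5%, call quality > 0.54) and classified into reliability classes
   (Robust, one-homozygote-rare with/without Hardy–Weinberg support,
   distorted/null-allele-like) from genotype counts.
3. **Method-of-moments IBD** — for each pair, the probabilities of sharing
   0/1/2 alleles identical by descent (Z0, Z1, Z2) and
   PI-HAT = Z2 + Z1/2 are estimated from observed identity-by-state counts
   at cohort allele frequencies. Reference points: parent–offspring
   (0, 1, 0), full sibs (0.25, 0.5, 0.25), half sibs (0.5, 0.5, 0),
   unrelated (1, 0, 0); PI-HAT ≈ 0.5 for first-degree pairs, ≈ 1 for clones.
4. **Mendelian-inconsistency (MI) testing** — opposite-homozygote conflicts
   for duos, transmission-impossible genotypes for trios, stratified by SNP
   reliability class; accept/reject thresholds are *calibrated on reference
   pedigrees* present in the panel (lowest reference Z1, highest reference
   MI rate).
5. **Sibship & missing parents** — pairwise relationship labelling, full-sib
   grouping, and constraint-based reconstruction of an absent parent's SSR
   genotype, re-matched against the profile database.
6. **Chlorotypes** — 8-locus chloroplast SSR haplotypes identify the
   maternal parent of each trio (strict maternal inheritance).
7. **Clustering** — Kimura 2-parameter distances on genotype
   pseudo-sequences, UPGMA dendrogram, 500-replicate locus bootstrap,
   Newick export.

A seeded pedigree simulator generates panels with known ground truth
(recurrent founders, FS/HS pairs, reference trios, a clone pair, genotyping
error and missingness), so every stage is testable without external data.

## Worked example

```python
from grapekin import (SimulationConfig, simulate_study,
                      estimate_ibd, duo_mi_snp)

cfg = SimulationConfig(n_founders=10, snp_loci=12000,
                       error_rate=0.0, missing_rate=0.0, seed=1)
study, truth = simulate_study(cfg)          # founder-star pedigree

r = estimate_ibd(study.snp, ("C01", "F001"))   # a true parent-offspring pair
m = duo_mi_snp(study.snp, "C01", "F001")
print(f"Z0={r.Z0:.4f} Z1={r.Z1:.4f} Z2={r.Z2:.4f} "
      f"PI_HAT={r.PI_HAT:.4f} loci={r.n_loci}")
print(f"MI={m.mi_total} mi_rate={m.mi_rate:.4f}")

u = estimate_ibd(study.snp, ("F009", "F010"))  # two unrelated founders
print(f"unrelated: Z0={u.Z0:.4f} Z1={u.Z1:.4f} PI_HAT={u.PI_HAT:.4f}")
```

prints

```
Z0=0.0000 Z1=1.0000 Z2=0.0000 PI_HAT=0.5000 loci=11595
MI=0 mi_rate=0.0000
unrelated: Z0=0.9259 Z1=0.0741 PI_HAT=0.0370
```

The parent–offspring pair sits exactly on the (0, 1, 0) reference point with
zero Mendelian conflicts over ~11.6k informative loci; the unrelated pair is
near (1, 0, 0) with PI-HAT ≈ 0.04 and hundreds of opposite-homozygote
conflicts. Those two signatures — IBD vector plus MI rate against calibrated
reference ceilings — are what the verdict engine turns into
SUPPORTED / POSSIBLE / REJECTED parentage calls.

The same flow runs end to end from a YAML config:

```bash
grapekin simulate --seed 7 --out demo/           # writes CSV + truth tables
grapekin ibd  --snp demo/snp_genotypes.csv --out demo/ibd.csv
grapekin tree --snp demo/snp_genotypes.csv --reps 100 --out demo/tree.nwk
grapekin run  --config pipeline.yaml             # QC -> IBD -> MI -> verdicts
```

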