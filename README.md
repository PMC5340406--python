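# autozyg

Autozygosity mapping and recessive disease-variant discovery for inbred
populations, built for the classic veterinary/medical genetics study design:
a handful of affected relatives genotyped on a SNP array, one or a few
affected genomes sequenced, and a panel of unrelated control genomes.

The package implements the full analysis as a reusable Python library:

1. **ROH mapping** — array QC (marker call rate > 95%, sample call rate
   > 95%, MAF > 0.05), per-sample runs of homozygosity by a 50-SNP sliding
   window that tolerates bounded heterozygous/missing calls, and
   intersection of the affected individuals' runs into shared regions that
   additionally require identical homozygous alleles in every case.
2. **Recessive filtering funnel** — keep variants homozygous-alternate in
   every case and absent from the control panel, then exonic, then inside
   the shared homozygous regions, then protein-changing
   (missense/nonsense/frameshift), with a non-increasing count ledger.
3. **Consequence annotation** — strand-aware projection onto transcript
   models with simplified HGVS-style notation (`c.31C>T`, `p.R11*`,
   `p.A78fs`) and truncation statistics for nonsense variants.
4. **Segregation & association** — recessive pedigree consistency (cases
   homozygous, obligate carriers heterozygous, healthy sibs het or
   wild-type), carrier-frequency screening, and the 2×2 allelic Pearson
   chi-square (df = 1, no continuity correction) with an
   extreme-tail-safe p-value: for the allele table
   $\chi^2 = \sum (O - E)^2 / E$ and
   $P(X > \chi^2) = \operatorname{erfc}\!\left(\sqrt{\chi^2 / 2}\right)$,
   exact far below where `1 − CDF` underflows.
5. **Synthetic cohort generator** — a reduced-scale genome (3 × 10 Mb,
   3,000 array SNPs per contig) with study-scale cohorts (7 cases, 5 close
   relatives, 176 population dogs with 3 carriers, a 136-genome panel), a
   planted 2 Mb shared homozygous interval, a planted causal nonsense
   variant (C>T at spliced CDS position 31 of a 1121-residue product,
   codon 11 CGA→TGA) and one decoy variant per funnel failure mode, so the
   whole pipeline is testable end to end without external data.

## Worked example

```python
from autozyg import SimConfig, simulate_bundle, qc_filter, detect_roh, \
    shared_regions, run_funnel
from autozyg.pipeline import run_discovery

bundle = simulate_bundle(SimConfig(seed=1))
result = run_discovery(bundle)
for label, n in result.funnel.stages:
    print(f"{label}: {n}")
print("carrier:", result.carrier.frequency_pct, "%")
print("p =", result.association.p_value)
```

prints

```
Total number of variants: 6014
Variants that segregate under recessive mode of inheritance: 4
Variants in the exonic regions: 3
Variants in the identified regions of homozygosity: 2
Non-synonymous, frameshift and nonsense variants in the regions of homozygosity: 1
carrier: 1.7 %
p = 3.075391922264901e-58
```

The funnel ends at a single candidate — the planted causal nonsense
variant. It fully segregates (7 homozygous cases, heterozygous parent and
grandparent, healthy siblings het or wild-type), the population screen
finds 3 carriers among 176 dogs (1.7%), and the allelic chi-square on the
case/control allele table (14/0 vs 6/356) gives p ≈ 3.08 × 10⁻⁵⁸.
Annotating the candidate yields `c.31C>T` / `p.R11*`, a premature stop in
codon 11 that truncates the 1121-residue product after its first ten
residues.

The `examples/` directory holds one short script per capability
(simulation and fixture writing, ROH mapping, annotation, the funnel,
segregation/association); each prints the numbers it computes and what
they mean.

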