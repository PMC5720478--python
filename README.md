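# hlaloh

Allele-specific copy number and loss of heterozygosity (LOH) calling for
the class I HLA genes (HLA-A/B/C) from paired tumor/germline short-read
sequencing.

HLA LOH is a recurrent immune-evasion event in cancer: losing one
parental HLA haplotype removes the ability to present the neoantigens
restricted to that haplotype. The HLA region is too polymorphic for
reference-based copy-number tools, so `hlaloh` re-aligns the reads of a
tumor/germline pair to the patient's own HLA allele sequences, finds the
positions where the two homologs of each gene differ, and infers each
homolog's copy number from binned coverage ratios (logR) and site-level
allele fractions (BAF) under the standard purity/ploidy mixture model:

    n₁ = (ρ − 1 + BAF · 2^logR · (2(1 − ρ) + ρψ)) / ρ
    n₂ = (ρ − 1 − (BAF − 1) · 2^logR · (2(1 − ρ) + ρψ)) / ρ

with tumor purity ρ and ploidy ψ supplied by an external tool (e.g.
ASCAT). A gene is called LOH when the smaller homolog copy number falls
below 0.5 and a paired t-test on per-site homolog coverage differences
rejects at p < 0.01. Companion modules place LOH events on clone
phylogenies by constrained least squares, classify copy-number segments
as focal vs arm-level (75%-of-arm rule), test cohort-level enrichment of
locus LOH by permutation, and generate fully synthetic patients — allele
pairs, reads, BAMs, truth records — so the whole system is testable
without any external data. See `docs/methods.md` for the model and the
design decisions.

## Worked example

Simulate a patient whose tumor (purity 0.6, ploidy 2) has lost the first
homolog of every class I gene, then call it:

```bash
hlaloh simulate --seed 17 --out-dir fx --rho 0.6 --cn 0 2 --depth 50 --n-sites 15
hlaloh call --tumor fx/tumor.bam --germline fx/germline.bam \
    --hla-fasta fx/alleles.fasta --hla-calls fx/hla_calls.tsv \
    --rho 0.6 --psi 2.0 --out-dir calls
```

which prints one line per gene:

```
A	loh_allele1_lost	cn1=-0.11372693788514093	cn2=1.8013436575106356	p=1.2327324839676351e-05
B	loh_allele1_lost	cn1=0.00754791791300701	cn2=2.212031056429777	p=7.868761205701126e-08
C	loh_allele1_lost	cn1=-0.08346497234843309	cn2=1.9784864781159044	p=1.6277767686165406e-11
```

The planted state was (0, 2): each gene's first homolog is estimated at
≈ 0 copies, the second at ≈ 2, and the imbalance p-values are far below
the 0.01 gate, so all three genes are called `loh_allele1_lost` — the
correct verdict. `calls/hla_loss_calls.tsv` holds the same table with
fixed columns, and `calls/hla_baf_sites.tsv` the per-site evidence.

The other subcommands are `tree-map` (place a multi-region LOH event on
a clone tree), `enrich` (permutation test of locus-LOH enrichment), and
`fisher` (2×2 exact test for cohort contingency tables). The Python API
(`hlaloh.call_gene`, `hlaloh.map_loss_to_clone`, …) exposes the same
functionality programmatically.

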