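# graftscope

Toolkit for two-genotype variant surveys and graft-mobile mRNA detection.

It covers a complete desk-scale pipeline:

1. **io_formats** — VCF 4.x, GFF3 (+FASTA), and samtools-mpileup text
   readers/writers with 1-based inclusive coordinates throughout.
2. **variant_filtering** — post-calling filters: quality (QUAL < 30
   removed), relative coverage (depth within [0.5×, 2×] of the mean), and
   SNP density (any 10 nt window with more than 3 SNPs is purged).
3. **variant_annotation** — a SnpEff-style consequence engine: region
   (CDS/UTR/intron/intergenic), codon-level effect (synonymous, missense,
   nonsense, start/stop loss, frameshift, in-frame InDel), impact tier
   (high/moderate/low/modifier), and functional class
   (missense/nonsense/silent).
4. **comparison_summary** — specific/common partition of two variant sets,
   zygosity and Ts/Tv summaries, per-chromosome densities, InDel length
   spectra, and inclusion–exclusion set arithmetic for directional gene
   sets.
5. **mobile_detection** — the mobility algorithm: replicate merging,
   homozygous consensus genotyping (≥5 reads, dominant-allele frequency
   > 95%), diagnostic-locus identification between graft partners,
   donor-allele detection in the receptor (> 5% of reads, exactly two
   alleles, conflict-free vs the pre-graft control), and gene-level
   aggregation with direction (scion→rootstock, rootstock→scion,
   bidirectional).
6. **synthetic_data** — a seeded generator producing a reference genome
   with valid multi-exon gene models, two genotypes with asymmetric SNP
   density/heterozygosity, and graft RNA pileups with a planted
   mobility truth table for end-to-end validation.

## Tests

```bash
python -m pytest -q tests/
```

The suite includes unit tests per module, property/oracle tests (exhaustive
sliding-window filter oracle, all 576 single-base codon substitutions vs a
frozen translation table, strand symmetry), and `tests/test_acceptance.py`
with the end-to-end recovery criteria on the default synthetic dataset.

## CLI

```bash
graftscope simulate --seed 0 --outdir sim/          # ref.fa, genes.gff3, VCFs, pileups, truth.json
graftscope convert-pileup sim/pileups/leaf_scion_rep1.pileup counts.tsv
graftscope filter --vcf sim/rootstock.vcf --out filtered.vcf
graftscope annotate --vcf sim/rootstock.vcf --gff sim/genes.gff3 --fasta sim/ref.fa --out annotated.tsv
graftscope compare --vcf-a sim/scion.vcf --vcf-b sim/rootstock.vcf \
    --gff sim/genes.gff3 --fasta sim/ref.fa --out summary.json
graftscope mobility \
    --scion-pileups sim/pileups/leaf_scion_rep1.pileup,sim/pileups/leaf_scion_rep2.pileup,sim/pileups/leaf_scion_rep3.pileup \
    --rootstock-pileups sim/pileups/leaf_rootstock_rep1.pileup,sim/pileups/leaf_rootstock_rep2.pileup,sim/pileups/leaf_rootstock_rep3.pileup \
    --scion-control-pileups sim/pileups/control_scion_rep1.pileup,sim/pileups/control_scion_rep2.pileup,sim/pileups/control_scion_rep3.pileup \
    --rootstock-control-pileups sim/pileups/control_rootstock_rep1.pileup,sim/pileups/control_rootstock_rep2.pileup,sim/pileups/control_rootstock_rep3.pileup \
    --gff sim/genes.gff3 --fasta sim/ref.fa --tissue leaf --out mobile.tsv
```

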