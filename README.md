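# translomap

Breakpoint mapping toolkit for reciprocal translocations, built around a
fully worked desk-scale study: a reciprocal t(3;4) exchange segregating in a
pig line, characterized from cytogenetic resolution down to the base pair.

Balanced reciprocal translocations are the most common constitutional
structural rearrangement in mammals and a recurrent cause of reproductive
failure in livestock. Mapping a breakpoint precisely takes two complementary
routes, both implemented here as reusable, tested components:

1. **Positional cloning in somatic cell hybrids.** Pig–hamster hybrid clones
   from a homozygous carrier randomly retain derivative chromosomes; scoring
   PCR markers across clones yields retention patterns that localize each
   breakpoint between the last positive and first negative marker. Iterative
   STS selection ("chromosome walking") then shrinks the interval — each
   round places k markers at the (i·W)/(k+1) points of the current interval
   and keeps the span between the last amplifying and first non-amplifying
   STS — until cross-junction PCR and sequencing call the junction at
   base-pair resolution, including the microdeletion lost during rejoining.
2. **Discordant mate-pair screening.** A long-insert (6 kb) mate-pair
   library over a pool of genomes containing one heterozygous carrier yields
   inter-chromosomal read pairs spanning both junctions. Clustering pairs by
   chromosome pair and strand signature, requiring support > 10, pairing
   complementary clusters into balanced calls, and removing calls recurring
   in a control pool isolates the translocation from heavy chimeric-pair
   background noise.

Every stage runs on a deterministic synthetic scenario (`feve_toy`) whose
coordinates echo the real study at 1/1000 scale: a 50 kb chromosome A broken
at 23,800 bp and a 150 kb chromosome B broken at 107,800 bp, joined
fold-back (der(4) carries both proximal segments), with a 5 bp `TACAC`
microdeletion at the der(3) junction and a 19-exon gene whose last four
exons are lost on the derivative. The package also ships the study's printed
12-clone × 37-microsatellite retention table as a fixture and reanalyzes it
exactly.

## Worked example

```bash
translomap simulate --outdir demo --seed 20171109 --coverage 17.5
```

writes the toy genome (normal and derivative chromosomes), the marker map,
a simulated hybrid panel, and case/control mate-pair tables. The retention
panel localizes the breakpoints:

```text
$ translomap hybrid interval --retention table1_retention.tsv \
      --markers table1_markers.tsv --clone Hb1.8 --chrom SSC3
SSC3  21948000  31261000  width=9313000bp (9.313 Mb)  flanks=SW2527,SW487  order=genetic
```

The interval runs from the last amplifying marker to the first silent one;
SW2527 has no assembly position, so its genetically adjacent mapped
neighbour (SW251, 21.948 Mb) substitutes — giving the 9.313 Mb initial
interval (13.998 Mb on the other chromosome, via the same rule). The walk
then refines the scaled interval with sequence-derived STSs:

```text
$ translomap walk --scenario demo --chrom SSC3 --start 21948 --end 31261 --target-bp 1000
REACHED_TARGET  SSC3:23485-24119  width=634bp  rounds=3
```

Cross-primer PCR across the junction and comparison of both derivative
junction sequences to the references call the breakpoint exactly and
recover the microdeletion:

```text
$ translomap junction call --scenario demo
der4  SSC3:23799  SSC4:107801  mh=1
der3  SSC3:23805  SSC4:107800  mh=1
deletion  5bp  TACAC
```

(each junction carries 1 bp of incidental microhomology, so its breakend is
reported left-aligned with a 1 bp confidence interval; reconciling the two
junctions on a common chromosome-B breakpoint recovers the 5 bp `TACAC`
loss). The three-primer genotyping assay separates all genotypes by product
length — 346 bp from the normal chromosome, 277 bp across the junction:

```text
$ translomap junction genotype --scenario demo
N/N  products=346      called=N/N
N/T  products=277,346  called=N/T
T/T  products=277      called=T/T
```

Finally the pooled mate-pair screen, after case/control differential
filtering at support > 10, leaves a single reciprocal call whose breakend
intervals bracket both true breakpoints; the three recurrent artifact loci
are flagged as present in the control pool:

```text
$ translomap svscan --case demo/case_pairs.tsv --control demo/control_pairs.tsv \
      -o demo/calls.vcf --fasta demo/genome.fasta
PASS        SSC3:21507-24536  SSC4:107016-109084  support=33  reciprocal=True
IN_CONTROL  SSC3:14069-23089  SSC4:69583-76513    support=19  reciprocal=False
IN_CONTROL  SSC3:6901-15596   SSC4:28788-36692    support=14  reciprocal=False
IN_CONTROL  SSC3:37574-48037  SSC4:129278-139302  support=13  reciprocal=False
...
```

`calls.vcf` holds the candidates as VCF 4.2 breakend (BND) records with
`MATEID`, `CIPOS` and `SUPPORT` annotations.

The same functionality is available as a library; see the module docstrings
in `translomap.scenario`, `translomap.hybrid_panel`, `translomap.walk`,
`translomap.junction` and `translomap.matepair_sv`.

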