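# lodn

Somatic single-nucleotide variants are mutations present in a tumor but
absent from the patient's germline. Callers that genotype the tumor and the
matched normal *independently* (GATK-style) find many variants but litter
the somatic list with germline polymorphisms that were simply missed in the
normal sample — low coverage or an unlucky allele draw is enough. Callers
that model both samples *jointly* (MuTect-style) are precise but
conservative. `lodn` implements the bridge between the two: a Bayesian
log-odds (LOD) classifier, applied downstream of independent calling, that
re-examines every candidate against the raw tumor and normal pileups and
keeps only candidates whose normal sample is confidently clean. The package
also ships the full benchmarking toolkit for characterising such a filter:
artificial-tumor spike-ins at chosen allele fractions, coverage
downsampling, split-sample specificity runs, and confusion-count scoring.

It is aimed at people building or evaluating tumor/normal small-variant
pipelines who want the classification stage as an inspectable, testable
library rather than a black box inside a larger caller.

## The model

Each read base *b* observed at a candidate site contributes

```
P(b | f) = f · P(b | alt) + (1 − f) · P(b | ref),
P(b | a) = 1 − e  if b = a,  else  e/3,       e = 10^(−q/10)
```

where *f* is the variant allele fraction, *q* the phred base quality, and
*e* is clamped at 0.75 so a miscall never outweighs a correct call. Reads
are independent, so the site log-likelihood is the sum of per-read log10
terms. Two statistics follow:

* **LOD_T** (tumor): `ℓ(f̂) − ℓ(0)` with `f̂` the maximum-likelihood allele
  fraction — evidence that the variant is *present* in the tumor.
* **LOD_N** (normal): `ℓ(0) − ℓ(0.5)` — evidence that the normal sample is
  reference-only rather than a germline heterozygote.

A candidate is called **somatic** when the pileups pass the depth gates
(normal ≥ 8, tumor ≥ 14 reads), `LOD_T ≥ Θ_T` (default 6.5), and
`LOD_N ≥ Θ_N` (default 2.2; 5.5 at known dbSNP-like sites, where germline
prior odds are higher). All comparisons are inclusive. A relaxed preset
(`Θ_T = 4.5`, `Θ_N|dbSNP = 3`) trades precision for sensitivity; its output
is always a superset of the default's.

The full pipeline (`run_pipeline` / `lodn merge`) takes tumor-sample calls,
normal-sample calls and joint-caller calls: candidates are the
tumor-minus-normal set difference, the LOD stage filters them, the result
is unioned with the joint caller's calls, and functional-class
(non-synonymous / stop gain / stop loss) and population-frequency
(MAF > 0.05) filters produce the final list.

## Worked example

```python
from lodn import Pileup, ReadObservation, ThresholdConfig, classify_somatic

# tumor: 40 alt + 40 ref reads at q30; normal: 30 clean reference reads
tumor = Pileup("A", tuple(ReadObservation("C", 30) for _ in range(40))
                    + tuple(ReadObservation("A", 30) for _ in range(40)))
normal = Pileup("A", tuple(ReadObservation("A", 30) for _ in range(30)))

result = classify_somatic(tumor, normal, alt="C", cfg=ThresholdConfig())
print(result.verdict)
s = result.scores
print(f"f_hat={s.f_hat:.2f}  LOD_T={s.lod_t:.1f}  LOD_N={s.lod_n:.2f}  "
      f"depths={s.tumor_depth}/{s.normal_depth}")

het_normal = Pileup("A", tuple(ReadObservation(b, 30) for b in "A" * 15 + "C" * 15))
print(classify_somatic(tumor, het_normal, alt="C").verdict)
```

prints

```
somatic
f_hat=0.50  LOD_T=115.0  LOD_N=9.03  depths=80/30
germline
```

The balanced tumor pileup puts the MLE allele fraction at 0.50 with
overwhelming detection evidence (LOD_T ≈ 115 ≫ 6.5). Thirty clean normal
reads give LOD_N ≈ 9.0 (each error-free reference read contributes
log10 2 ≈ 0.30 toward "no germline variant"), clearing the 2.2 threshold:
somatic. Swap in a heterozygous normal (15 of 30 reads alt) and LOD_N
collapses to ≈ −43: the same tumor evidence is reclassified as germline.

The same stage runs from the shell on standard formats:

```
lodn filter --candidates candidates.vcf --tumor tumor.sam --normal normal.sam \
            --known-sites dbsnp.vcf --out somatic.vcf
lodn sim synth --length 30000 --depth 80 --seed 1 \
               --truth src/lodn/data/artificial_tumors.tsv --column intermediate \
               --out-sam tumor.sam --out-vcf truth.vcf --out-fasta ref.fa
lodn eval score --calls somatic.vcf --truth src/lodn/data/artificial_tumors.tsv \
                --column intermediate
```

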