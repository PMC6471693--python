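# gaphase

Genetic-algorithm solver for the weighted Minimum Error Correction (wMEC)
formulation of single-individual haplotype assembly. Aligned sequencing
reads restricted to heterozygous SNP positions form a ternary fragment
matrix; `gaphase` partitions the reads into two sets, infers one haplotype
per set by confidence-weighted column majority, and minimizes the number
of allele corrections needed for consistency.

Large instances are handled with a divide-and-conquer strategy: haplotype
blocks (connected components of read/column co-coverage) are detected
first, each block is split into chunks of `gamma` reads (`gamma` = the
block's rounded mean coverage), every chunk's sub-problem is solved by an
independent GA (tournament selection, single-point crossover, bit-flip and
circular burst mutation, elitism), and the per-chunk haplotype pairs are
oriented and merged. Positions covered by reads of only one side of the
final bipartition are masked with `X`. Sub-problems can run on a process
pool; results are identical for any worker count at a fixed seed.

## Layout

| module | contents |
| --- | --- |
| `gaphase.core` | fragment matrix, haplotypes, extended Hamming distance, weighted-majority inference, wMEC cost |
| `gaphase.ga` | GA operators and the evolutionary loop (`run_ga`) |
| `gaphase.assembly` | block detection, chunking, parallel solving, orientation/merge, homozygous correction, masking |
| `gaphase.io_wif` | WIF fragment reader/writer, truth files, block-structured haplotype output |
| `gaphase.simulate` | planted-haplotype read simulator (Roche/454-like and PacBio-like profiles) |
| `gaphase.evaluate` | haplotype error rate (HE), block agreement, average-best-fitness curves |

## CLI

Simulate an instance, assemble it, evaluate against the planted truth:

```bash
gaphase simulate --profile roche454 --n-snps 500 --f-snps 100 --cov 30 \
    --seed 1 --out-prefix scratch/demo
gaphase run --input scratch/demo.wif --output scratch/demo --seed 1 --workers 1
gaphase evaluate --pred scratch/demo.haplotypes.txt \
    --truth scratch/demo.truth.txt --report scratch/demo.eval.json
```

`gaphase run` writes a block-structured haplotype file (one stanza per
block: `BLOCK <first> <last> <n> <cost>`, two `{0,1,X}` lines, a positions
line) plus a JSON run report. Defaults follow the selected GA setting:
population 100, crossover rate 0.9, mutation rate 0.05, tournament size
10, at most 100 iterations with a 25-iteration stall cutoff.

Input is a WIF fragment file, one read per line, each covered SNP as a
`position base allele phred` field, fields separated by `:`, with a
trailing `# <score> : <name>` comment. Conversion from BAM+VCF to WIF is
out of scope; use the WhatsHap toolchain to produce WIF.

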