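# conshmm

Annotate a reference genome into **conservation states** at single-nucleotide
resolution from a multiple-species DNA sequence alignment.

Constraint scores and constrained-element calls compress cross-species
conservation into a single dimension. A conservation state instead captures
*which* species align to and match the reference at each base: deep
conservation through all vertebrates, alignment restricted to mammals or
primates only, alignment without matching, or artifact-like patterns all
receive distinct labels. The package also ships the surrounding analysis
machinery: base-resolution fold enrichment for external annotations,
positional enrichment around anchor points, state clustering, and
precision-recall evaluation against target annotations — plus a synthetic
alignment generator with known ground truth so every stage is testable
without external downloads.

## The model

For each reference base *i* and non-reference species *j*, the alignment is
encoded as one of three observations: aligns with a matching nucleotide,
aligns with a non-matching nucleotide, or contributes no nucleotide. A
*K*-state hidden Markov model with initial probabilities *a*, transitions
*b*, and per-state, per-species multinomial emissions

> p<sub>k,j,1</sub> = f<sub>k,j</sub>·g<sub>k,j</sub>,&nbsp;
> p<sub>k,j,2</sub> = f<sub>k,j</sub>·(1−g<sub>k,j</sub>),&nbsp;
> p<sub>k,j,3</sub> = 1−f<sub>k,j</sub>

is fit by Baum–Welch, where f<sub>k,j</sub> is the probability that species
*j* aligns in state *k* and g<sub>k,j</sub> the probability that it matches
given that it aligns. Emissions factor over species, so the likelihood of an
observation vector is a product of multinomials. The match flag is missing
data wherever the species does not align, and *g* is re-estimated only from
aligned positions. Genomes are tiled into 200 kb slices; each EM iteration
trains on a random subset of slices (150 by default) for a fixed number of
iterations (200 by default) with no likelihood-based stopping. After
training, every base is assigned the state with maximum posterior
probability and per-slice decodings are merged into a genome-wide BED
segmentation.

## Worked example

```bash
conshmm simulate --species 8 --states 4 --length 100000 \
    --slice-length 20000 --seed 13 --out-dir sim/
conshmm encode --maf sim/alignment.maf --reference ref \
    --species-list sim/species.txt --slice-length 20000 --out-dir bin/
conshmm learn --binarized-dir bin/ --states 4 --iterations 100 \
    --segments-per-iter 3 --seed 1 --out model.tsv
conshmm segment --model model.tsv --binarized-dir bin/ --out seg.bed
conshmm enrich overlap --seg seg.bed --ann sim/truth.bed
```

The same pipeline from Python (`examples/02_train_and_segment.py`) prints:

```
max |error| after state matching: f 0.0027, g 0.0254, b 0.0007
2013 segments over 200,000 bases (mean length 99 b)
per-state mean assigned posterior: [1. 1. 1. 1.]
```

The first line scores the fitted emission and transition parameters against
the generating model after optimally matching state labels (EM does not
identify label order); errors of a few thousandths mean the parameters are
recovered essentially exactly. The segment count reflects the sticky
transitions of the generating model, and the mean assigned posterior near 1
says the decoding is confident at nearly every base.

`examples/` contains one short script per capability: simulation and
encoding round trip, training and segmentation, overlap and positional
enrichment, precision-recall evaluation, and state clustering.

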