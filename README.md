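# neocistrome

Reusable building blocks for analyzing how a nuclear-receptor cistrome is
reprogrammed in tumors: chimeric composite-motif construction with
mismatch-thresholded scanning, hypergeometric motif enrichment against
GC-matched backgrounds, cistrome overlap classification, ROSE-style
super-enhancer calling, and pooled CRISPR reporter-screen ranking — all
exercised end-to-end on synthetic data with known ground truth.

## Scientific problem

In prostate tumors the androgen receptor (AR) is redistributed away from
canonical androgen response elements (AREs) toward *neo-enhancers*: sites
where a single hexameric AR half-site (`AGAACA`) sits next to a partner
transcription factor's element, forming a chimeric composite motif. This
package implements the computational procedures needed to detect and
quantify that redistribution:

1. **Motif engine** — turn IUPAC consensus strings into
   probability/log-odds profiles whose acceptance threshold admits exactly
   the sequences within *k* mismatches of the consensus; assemble full
   palindromic AREs (half-site + spacer + inverted half-site) and chimeric
   composites (two elements, variable spacer 0–8 nt, both orders); scan
   sequences or peak sets on both strands.
2. **Enrichment** — per-peak motif presence in a target cistrome versus a
   (supplied or GC-matched sampled) background, scored by the
   hypergeometric tail over the pooled population, plus proximity
   co-occurrence of an anchor hit with a partner motif within a fixed
   edge-to-edge window (default 25 bp).
3. **Interval toolkit** — BED-convention (0-based, half-open) peak
   merging (gap ≤ 500 bp by default), Venn-style overlap classification
   of two cistromes, promoter/exon/intron/intergenic annotation
   (TSS ± 1 kb), and reference-point signal matrices from bedGraph
   coverage.
4. **Super-enhancers** — stitch peaks within 12.5 kb, rank domains by
   aggregate signal, normalize both axes, and call every domain strictly
   above the first point where the local slope of the rank-signal curve
   reaches 1; compare wild-type and knockout calls to measure
   super-enhancer loss.
5. **Screen ranking** — CPM-normalize sorted-reporter sgRNA counts, rank
   guides by the LOW/HIGH log2 ratio, aggregate to genes, and score drug
   synergy by Bliss excess.
6. **Simulators** — genomes, peak sets with motifs planted at controlled
   frequencies, signal tracks with amplified enhancer clusters, and
   negative-binomial screen counts, each returning a ground-truth table.

## Worked example

```python
from neocistrome import (
    ConsensusMotif, assemble_palindrome, assemble_chimeras,
    build_profile, scan, simulate_genome,
)

half = ConsensusMotif("AR_half", "AGAACA")

# Full palindromic ARE: 15 bp, its own reverse complement
are = assemble_palindrome(half, 3)
print(are.iupac)            # AGAACANNNTGTTCT

# Chimeric composites with a FOX partner element: 9 spacers x 2 orders
chimeras = assemble_chimeras(half, ConsensusMotif("FKH", "TGTTTAC"), (0, 8))
print(len(chimeras))        # 18
print(chimeras[0].iupac)    # AGAACATGTTTAC

# k = 2 mismatch threshold: accepts exactly the 154 hexamers within
# Hamming distance 2 of AGAACA (1 + 18 + 135 of the 4096 possible)
profile = build_profile(half, 2)
print(round(profile.consensus_score, 3), round(profile.threshold, 3))
# 10.593 2.418

hits = scan(profile, {"chr1": simulate_genome(100_000, 0.5, 1)})
print(len(hits))            # 7445 (a permissive short motif, as expected)
```

The same operations are available from the command line; the umbrella
command runs every stage on synthetic data and writes all artifacts,
ground truth included, to one directory:

```bash
neocistrome run --outdir demo_run --seed 1
```

Individual stages: `neocistrome simulate|motif|scan|enrich|overlap|annotate|matrix|rose|screen|synergy`.

## Layout

```
src/neocistrome/
  motifs.py          consensus -> profile, assembly, scanning
  enrichment.py      hypergeometric enrichment, backgrounds, proximity
  intervals.py       peaks, merging, overlap, annotation, coverage
  superenhancer.py   stitching, rank curve, super calls, WT/KO compare
  screen.py          guide ratios, gene scores, Bliss synergy
  simulate.py        genomes, planted peaks, signal tracks, screen counts
  pipeline.py        staged end-to-end run with YAML config
  io.py              FASTA/BED/bedGraph/TSV/motif-file readers and writers
  cli.py             click-based command-line interface
```

See `docs/methods.md` for the model, parameter defaults and numerical
choices.
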