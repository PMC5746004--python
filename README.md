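# tumap

Mapping the vegetative transcriptional landscape of a high-GC bacterium from
dual-platform expression signals.

During exponential growth, a bacterial chromosome is transcribed as a set of
**transcriptional units (TUs)** — promoter-driven transcripts covering one or
more genes plus untranslated 5′ and 3′ ends. `tumap` reconstructs these units
from the two signal types such a study produces:

- **strand-specific tiling-array measurements** — two channels per 60-mer
  probe (22 nt tiling step): a genomic-DNA baseline and an mRNA channel whose
  ratio (fold-change, FC) measures transcription;
- **strand-specific RNA-seq coverage** — per-base read depth, with the 5′-end
  truncation and positional unevenness typical of the platform.

On top of the reconstructed units it performs the regulatory annotation a
microbial transcriptomics group would want:

- **TSS/TTS mapping** — probe-level significance calling (robust one-sided
  z-test on log₂ ratios, Benjamini–Hochberg FDR ≤ 10⁻⁴), segmentation, and
  cross-platform TSS refinement; expression classes high (FC > 10), medium
  (3 ≤ FC ≤ 10), low (FC < 3); RPKM = numReads/((L/1000)·(N/10⁶)) with a
  150-RPKM expression call;
- **σ⁷⁰ promoter discovery** — a two-box model (consensus TTGACA and TATAAT,
  14–20 bp spacer with a 17 bp optimum) learned by constrained
  expectation-maximization from upstream windows of strongly transcribed
  units, then scanned over every TU;
- **rho-independent terminator detection** — GC-rich stem-loops followed by a
  polyT run, with leading-polyA (bidirectional) variants and per-TU
  termination-strategy classes (rho-independent, stem-loop-only, convergent
  3′-UTR overlap);
- **intergenic sRNA candidates** — expressed segments outside annotated genes
  (housekeeping sRNAs, riboswitch leaders);
- **promoter feature ranking** — a random-forest on the 62-bp promoter
  feature set (24 bp upstream of the −35 + hexamers + spacer + 9 bp
  downstream of the −10, plus spacer/leader lengths and block AT fractions)
  against expression classes and intergenic negative k-mers.

A seeded synthetic-genome generator plants all of this structure with known
ground truth, so every stage is validated by parameter recovery.

## Worked example

```python
from tumap import RunConfig, run

res = run(RunConfig(outdir="out", seed=1, profile="desk"))
s = res["summary"]
print(s["tu_class_counts"])
print(s["promoter_model"])
print(s["termination"]["rho_independent_pct"])
print(s["tss_concordance"]["median"], s["tss_concordance"]["frac_25_50"])
```

On the desk profile (200 kb synthetic chromosome, 60 planted TUs plus two
sRNA-like transcripts, default noise) this prints:

```
{'medium': 29, 'high': 22, 'low': 94}
{'consensus35': 'TTGACA', 'consensus10': 'TATAAT', 'spacer_mode': 17,
 'information_bits': 2.215, 'low_information': False}
56
40.0 0.594
```

Reading it: the array recovers every strongly transcribed unit but shatters
weak ones into short segments (hence many low-class fragments — weak signals
sit close to the hybridization baseline); the promoter model relearns the
planted TTGACA/TATAAT consensus with its 17 bp spacer optimum from the data
alone; 56% of gene-bearing units terminate at a detected hairpin+polyT; and
the RNA-seq start predictions trail the array predictions by a median 40 bp
(59% of discrepancies in the 25–50 bp band), because RNA-seq coverage misses
the first ~20 transcribed bases while an array segment overhangs the true
start by up to one probe.

The same stages are available from the shell:

```bash
tumap simulate --seed 1 --outdir sim          # genome, truth, probe table, coverage
tumap array --probes sim/probes.tsv           # probe calls + transcribed segments
tumap coverage --plus sim/coverage_plus.bedgraph --minus sim/coverage_minus.bedgraph \
      --length 200000 --counts sim/counts.tsv
tumap all --seed 1 --outdir out               # full pipeline + summary.json
```

All tables and GFF3/BED/bedGraph outputs state their coordinate convention in
their headers; internal arithmetic is 1-based inclusive throughout
(length = end − start + 1).

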