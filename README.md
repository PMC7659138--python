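# lrmeta

Linked-read metagenome simulation and profiling toolkit.

Linked-read (10x-style) sequencing attaches a shared barcode to the short
reads coming from one long DNA fragment (10–100 kb), restoring long-range
information to cheap, accurate short reads — which is particularly useful
for assembling microbial communities where most members cannot be
cultured.  How well that works depends on a small parameter vector:

* `C_R` — average read depth sequenced per fragment (typically 0.1–0.4X),
* `C_F` — physical depth of the genome in long fragments,
* `N_F/P` — mean number of fragments sharing one barcode partition,
* `μ_FL` / `Wμ_FL` — unweighted and length-weighted mean fragment length,

linked by the identity `C = C_R · C_F` for total read depth `C`.

`lrmeta` provides the tooling to study this parameter space at desk scale:

* **simulate** — generate barcoded paired-end FASTQ from a community of
  reference genomes with uneven abundance (per-genome depth
  `C_Fi = C_F · A_i · G` for relative abundances `A_i`), plus full ground
  truth and a manifest of realised parameter values;
* **reconstruct** — rebuild long fragments from co-barcoded alignments
  (SAM/BAM `BX` tags or a plain TSV) by greedy gap clustering: extend
  while the next co-barcoded read is within 50 kb, keep fragments with
  ≥ 2 read pairs spanning ≥ 2 kb;
* **stats** — estimate `C, C_R, C_F, μ_FL, Wμ_FL, N_F/P` from truth or
  reconstructed fragments;
* **subsample** — thin a library by read pairs (scales `C_R`) or by whole
  barcodes (scales `C_F`) to generate depth-titration series;
* **binqc** — classify assembly bins into high / medium / low / other
  draft-genome quality tiers (completeness, contamination, 5S/16S/23S
  rRNA presence, ≥ 18 tRNAs) and summarise draft-genome proportions;
* **demo** — run the whole loop on a generated three-genome community.

See `docs/methods.md` for the model, estimators, and design decisions.

## Worked example

```bash
lrmeta demo --out demo_out --seed 1
```

runs community generation → simulation → reconstruction → estimation →
bin triage and prints:

```
recall=0.924 precision=0.946 length_bias=0.931
```

92.4 % of the ~1,100 simulated fragments are recovered at 0.8 reciprocal
overlap, and recovered fragments average 93 % of their true length
(reconstruction reaches only to the outermost sequenced reads).
`demo_out/report.json` holds the estimated parameter vectors; the
truth-side estimates for this seed are

```json
{"c": 14.2, "c_r": 0.76, "c_f": 18.7, "mu_fl": 10051.4, "w_mu_fl": 10450.4, "n_fp": 1.57}
```

— the configured `C_R = 0.77` and `μ_FL = 10 kb` are recovered, `C_F`
reflects the staggered abundances (the high-abundance genome is covered
~47X, the low-abundance one ~1.6X), and `c ≈ c_r_weighted · c_f` holds
exactly.  The toy bin table classifies into 1 high / 2 medium / 1 low /
1 other, an 80 % draft-genome proportion.

The same stages are available individually, e.g.:

```bash
lrmeta simulate --community community.tsv --out sim --c 10 --c-f 28 --seed 1
# implied C_R = 0.36X
lrmeta reconstruct --alignments aln.tsv --dialect tsv --out fragments.tsv
lrmeta stats --fragments fragments.tsv --genome-size 600000
lrmeta subsample --in1 sim/reads_R1.fastq.gz --in2 sim/reads_R2.fastq.gz \
    --out1 half_R1.fastq.gz --out2 half_R2.fastq.gz --mode barcodes --fraction 0.5
lrmeta binqc --bins bins.tsv --out summary.tsv
```

The community TSV has columns `genome_id, fasta_path, molarity`; a genome's
size is the sum of its FASTA record lengths.

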