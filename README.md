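# tagedit

Decoding CRISPR–Cas9 multiplex editing outcomes in tandemly arrayed gene
(TAG) families.

A single guide RNA that matches a consensus site in every member of a
tandem array creates many simultaneous double-strand breaks, and the
repair outcomes go far beyond small indels: large genomic dropouts that
fuse the 5' portion of one paralog to the 3' portion of another,
inversions (including nested, sequential ones), translocations to related
loci on other contigs, and three-way fusions carrying a short sequence
block copied from a third paralog. Because the paralogs are nearly
identical, every standard readout is compromised: short reads map
ambiguously, fusion alleles masquerade as natives, and "no amplification"
can mean a lost gene or just a lost primer site.

`tagedit` is a library (plus a thin CLI) that implements the full
decoding loop on synthetic data with ground truth:

* **Forward model** (`tagedit.model`) — segment-level allele
  architectures; apply dropouts, inversions, translocations,
  templated-insert fusions and indels; render sequences; enumerate
  junctions with productive/opposing orientation and reading-frame class.
* **Synthetic data** (`tagedit.simulate`) — a hemizygous ~100 kb array of
  7 near-identical paralogs (1% divergence, shared guide site in exon 2)
  plus pseudogene loci; seeded mutant populations with per-gene truth;
  error-free PE150 amplicon and capture reads (~550 bp fragments).
* **Fusion-aware amplicon genotyping** (`tagedit.targets`,
  `tagedit.amplicon`) — native + all hypothetical fusion targets
  (n + n(n−1)), exact-match classification (0% mismatch, ≤ 1 contiguous
  indel), noise-thresholded allele calls with a built-in nontarget
  control, population summaries.
* **In-silico PCR** (`tagedit.pcr`) — mismatch-tolerant primer binding
  (≤ 2 mismatches, exact 3' terminus), product and banding prediction,
  NA-allele logic.
* **Capture analysis** (`tagedit.capture`) — a deterministic first-best
  k-mer mapper (k = 15), coverage dropout detection, discordant-pair
  clusters, and junction recovery by read segmentation and greedy
  exact-overlap assembly, hardened against paralog ambiguity.
* **Reconstruction** (`tagedit.reconstruct`) — parsimony search over
  ordered event sequences (≤ 3 events) whose forward-simulated junction
  sets explain the evidence, scored as
  `|predicted Δ observed| + 0.5·events`, with ties reported; a
  reconciliation layer that arbitrates amplicon/PCR/capture conflicts with
  explicit codes (e.g. `AMPLICON_BLINDSPOT`, `PRIMER_SITE_LOST`).

## Worked example

A line carrying a 5'-g7/3'-g2 fusion with a −2 joint indel (losing
g3–g6), genotyped from simulated 200× amplicon reads
(`examples/03_amplicon_genotyping.py`):

```
targets: 50 records (49 before dedupe)
simulated 600 read pairs from 3 products
control locus amplified: True
  g1: native                         reads=200
  g2: fusion  g7-g2 (-2, frameshift) reads=200
  g3: na                             reads=0
  g4: na                             reads=0
  g5: na                             reads=0
  g6: na                             reads=0
  g7: fusion  g7-g2 (-2, frameshift) reads=200
site percentages: {'native': 14, 'fusion': 29, 'na': 57, 'indel': 0, 'no_call': 0}
```

The 49 targets are the 7 native amplicons plus all 42 ordered fusion
hypotheses; the fusion product matches the enumerated `g7-g2` target with
a single −2 indel at the joint and is tabulated in both partner cells as a
linked pair; the four intervening genes are NA because their amplicons no
longer exist — the amplified nontarget control shows the PCR itself
worked. The other example scripts walk through guide validation,
population simulation, PCR banding, capture evidence with translocation
reconstruction, and a nested double inversion recovered from junction
evidence alone (`examples/01…06`).

The same stages run from the shell:

```bash
tagedit all --outdir run1 --seed 7 --n-lines 10
```

which writes the array model, per-line FASTQs, truth tables, allele
matrix, banding, capture evidence, and per-line reconstruction reports
under `run1/`.

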