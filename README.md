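# satkit

Satellitome analysis toolkit: annotate satellite-DNA (satDNA) monomers and
arrays on genome assemblies, profile their divergence landscapes, inspect the
conserved context flanking short arrays, quantify satDNA transcription from
RNA-seq reads, build monomer phylogenies, and estimate each family's minimal
evolutionary age from its taxonomic distribution on a dated tree.

It is written for repeat biologists working on satellitomes — the complete
satDNA complement of a genome — in insects and other taxa where families
range from megabase pericentromeric blocks to a dozen short arrays on a
single chromosome. Every stage is exercisable on synthetic data with known
truth via the built-in simulators, so the pipeline's behavior is testable
without downloading assemblies.

## What it computes

* **Annotation** — all copies of a consensus monomer (any rotation, either
  strand) at ≤ 45% divergence, merged into arrays; per-family monomer counts,
  chromosome distribution classes and genome fractions.
* **Divergence landscapes** — per-monomer Kimura 2-parameter distance to the
  consensus, d = −½ ln[(1 − 2P − Q)√(1 − 2Q)], binned at 1%; peaks are bins
  (or series of bins) standing 50% above their flanking bins; landscapes are
  classified as unimodal (low/shifted), bimodal or multimodal. Low-divergence
  peaks signal recent amplification or homogenization; high-divergence peaks,
  aged variant sets.
* **Flanks** — 1,000-bp upstream/downstream extractions per array,
  strand-aware; per-position conservation against a reference flank, the
  length of the conserved block from the array boundary, and outliers with a
  classified cause (insertion / truncation / early similarity loss).
* **Transcription** — reads counted against each family's head-to-tail dimer
  (so junction-spanning reads align) at ≤ 1 mismatch, FPKM-normalized:
  FPKM = C·10⁹/(L·N). Valid longitudinally (one family across stages and
  sexes), never for ranking families against each other.
* **Phylogeny & age** — 100-monomer subsampling, K2P distance matrices,
  neighbor-joining trees with column-bootstrap supports; presence filtered at
  query coverage strictly > 50%; a family's minimal age is the age of the
  MRCA of the taxa that carry it on a time-calibrated tree.

See `docs/methods.md` for the models, defaults, and known limitations.

## Worked example

Simulate a two-family satellitome, annotate it, and profile divergence:

```yaml
# spec.yaml
seed: 11
chromosomes: {chr1: 600000, chr2: 600000, chr3: 600000}
families:
  - family_id: DemoSat01          # 143-bp monomer, two age cohorts
    consensus: "TGCATTCGACCTAGGATTCATGACC..."   # full sequence in the file
    placement_mode: interspersed
    n_arrays: 150
    array_length_range: [4, 12]
    divergence_mixture: [[0.6, 0.04, 0.01], [0.4, 0.2, 0.02]]
  - family_id: DemoSat02          # 124-bp monomer, chromosome-restricted
    consensus: "ACCGTTAGCATGGACCTTAGC..."
    placement_mode: restricted_chromosome
    n_arrays: 12
    array_length_range: [2, 9]
    divergence_mixture: [[1.0, 0.05, 0.02]]
```

```console
$ satkit simulate --spec spec.yaml --out sim
wrote sim/genome.fasta and truth tables
$ satkit annotate --genome sim/genome.fasta --consensus cons.fasta --out ann
DemoSat01: 1264 monomers in 150 arrays
DemoSat02: 60 monomers in 12 arrays
$ satkit landscape --genome sim/genome.fasta --consensus cons.fasta --out ls
DemoSat01: 2 peaks, shape bimodal
DemoSat02: 2 peaks, shape bimodal
```

The annotator recovers exactly the planted 150 and 12 arrays (the truth
tables are in `sim/truth_*.tsv`). DemoSat01's landscape is called bimodal
with peaks at the 4% and 20% divergence classes — the two planted age
cohorts. DemoSat02 was planted unimodal; its spurious second peak
illustrates a caveat documented in the methods note: with only 60 monomers,
bin-level sampling noise makes shape labels unstable — landscapes are meant
to be read at thousands of monomers.

Minimal ages from taxonomic presence, on the bundled insect-order time tree:

```console
$ cat hits.tsv
taxon        family    query_coverage
Coleoptera   TmSat01   1.0
Blattodea    TmSat01   0.8
Coleoptera   TmSat11   1.0
$ satkit age --presence hits.tsv --focal Coleoptera --clade-bound 165 --out age
 family  n_qualifying  minimal_age  upper_bound                                              mrca
TmSat01             2        380.0          NaN Blattodea,Coleoptera,Diptera,Hemiptera,Hymenoptera,Lepidoptera
TmSat11             1          0.0        165.0                                              None
```

A family shared by Coleoptera and Blattodea must predate their split
(380 MY); a family seen only in the focal species is younger than the
emergence of its family-level clade (here bounded at 165 MY).

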