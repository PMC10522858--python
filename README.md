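# vnarpan

Deep-sequencing analysis of single-domain-antibody (VNAR) display-library
biopanning, plus a synthetic biopanning simulator for end-to-end testing.

The pipeline takes per-round FASTA/FASTQ amplicon reads (one file per
library × biopanning round), and produces:

- **CDR3 extraction** — six-frame scan for configurable framework anchor
  motifs (defaults: 5′ `[YF][YF]C`, 3′ `[DN]G[AG]GT`), excising the CDR3
  amino-acid and coding-nucleotide sequences; reads shorter than 400 bp are
  dropped first (strictly `> 400` by default).
- **Clonotype tables** — per-round counts keyed by exact CDR3 amino-acid
  sequence, with a majority-vote representative coding sequence per
  clonotype; abundance (% of CDR3 reads), top-N rankings, enrichment
  trajectories, unique-sequence length histograms.
- **Cross-library comparison** — Pearson correlation of abundances over
  clonotypes shared between two libraries.
- **Homology clustering** — Needleman–Wunsch identity distances
  (match +1 / mismatch 0 / gap −1), neighbor-joining trees (newick), and
  single-linkage threshold clusters over top clonotypes.
- **Codon-usage scoring** — rare / intermediate / common classification by
  relative adaptiveness *w* (cutoffs 1/3 and 2/3, configurable) against
  bundled *E. coli* K-12 and *S. cerevisiae* usage tables; per-sequence and
  top-N cohort rare-codon percentages.
- **Simulator** — clone populations with a multimodal CDR3 length
  distribution, log-uniform affinities, and capture–wash–amplify rounds
  where capture probability combines antigen occupancy, display valence
  (phage default 5, yeast 1) and an optional rare-codon display penalty
  (`q = exp(-λ·r/100) · (1 − (1 − b)^valence)`, `b = C/(C+Kd)`). Paired mode
  runs phage and yeast campaigns from the same library. Output is per-round
  FASTQ plus a ground-truth TSV, byte-reproducible from the seed.

## Test

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (simulation-based
headline reproduction, parameter recovery, alignment/NJ oracle equivalence,
invariant suites, exact worked values); the whole suite runs in a few
minutes on one CPU.

## CLI

```sh
vnarpan simulate --mode paired --seed 1 --out simdata/     # synthetic campaign
vnarpan filter reads.fastq kept.fastq --min-len 400        # length filter
vnarpan extract kept.fastq annot.tsv                       # per-read CDR3s
vnarpan tally reads.fastq round0.tsv                       # clonotype table
vnarpan compare phage_R0.tsv yeast_R0.tsv cmp.json         # shared-abundance r
vnarpan cluster round4.tsv tree.nwk --top 100 --threshold 0.5
vnarpan codon round4.tsv codon.tsv --organism bacteria --top 10
vnarpan run --config run.json                              # full pipeline
```

`run.json` example:

```json
{
  "inputs": {"phage": ["phage_R0.fastq", "phage_R1.fastq"],
             "yeast": ["yeast_R0.fastq", "yeast_R1.fastq"]},
  "organisms": {"phage": "bacteria", "yeast": "yeast"},
  "out_dir": "results",
  "top_n_cluster": 100,
  "top_n_codon": 10
}
```

The pipeline writes per-round tables, trajectories, newick trees, cluster
assignments, codon reports, cross-library comparisons, and a `manifest.json`
that fully records the configuration and all outputs.

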