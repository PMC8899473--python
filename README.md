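# turriphylo

Venom-peptide libraries in a phylogenetic framework. The package builds a
housekeeping-gene (HKG) panel from per-sample transcriptome annotations,
infers per-gene distance trees and a consensus tree whose node values are
the fraction of gene trees supporting each node, classifies turripeptide
mature peptides by cysteine framework and clade, normalizes toxin expression
against the mean HKG expression of the same transcriptome, and tests whether
peptide clades are exclusive to a single genus with a permutation test.

A 32-sequence reference table of predicted mature P-like turripeptides
(species, toxin name, clade, sequence) is packaged under
`src/turriphylo/data/`, and a synthetic-data module generates species trees,
discordant gene trees, Jukes–Cantor alignments, toxin precursor repertoires,
annotation tables and TPM expression tables, so the entire pipeline is
testable offline.

## Layout

| module        | contents |
|---------------|----------|
| `io_formats`  | FASTA/newick/TSV readers and writers, residue sanitization, the 70 bp / 5% N read filter |
| `trees`       | tree structure and newick parsing/serialization |
| `phylo`       | p-distance, Jukes–Cantor correction, neighbor joining, midpoint rooting, bipartitions, consensus with support fractions, Robinson–Foulds |
| `simulate`    | Yule species trees, NNI-perturbed gene trees, sequence evolution, precursor repertoires, annotation and expression tables |
| `hkg`         | e-value filtering, shared-gene panel construction, per-gene FASTA export |
| `peptides`    | framework extraction, census, consensus motifs, nomenclature, deduplication, peptide tree and clade partition |
| `expression`  | TPM from counts, log2 fold change vs the HKG mean, ranked expression reports |
| `congruence`  | clade/genus composition, mixed-clade statistic, permutation test |
| `config`, `pipeline`, `cli` | run configuration, stage orchestration, command line |

## Command line

```sh
turriphylo simulate --n-species 13 --n-genes 66 --seed 1 --out sim/
turriphylo filter-reads reads.fasta kept.fasta --min-len 70 --max-n-fraction 0.05
turriphylo hkg-panel sim/annotations.tsv --e-threshold 1e-4 --out panel.tsv
turriphylo gene-trees aln/*.fasta --out gene_trees.nwk
turriphylo consensus gene_trees.nwk --min-frequency 0.5 --out consensus.nwk
turriphylo peptides --out peptide_report/            # packaged reference table
turriphylo expression expr.tsv --panel panel.tsv --out report.tsv
turriphylo congruence --n-permutations 10000 --seed 1
turriphylo all --mode fixture --seed 1 --out run/    # full pipeline
```

Exit codes: 0 success, 2 validation error, 3 stage failure. `all` writes a
deterministic run directory (`trees/`, `tables/`, `report.txt`); rerunning
with the same config reproduces it byte for byte.

## Method notes

* Per-gene maximum-likelihood inference and quartet-based consensus are
  replaced by in-repo neighbor joining over Jukes–Cantor distances plus
  bipartition-frequency consensus. Node supports are computed literally as
  the fraction of gene trees containing each bipartition, which is the
  semantics the consensus stage is meant to reproduce; ML optimization
  itself is out of scope.
* Gene-tree discordance is simulated by re-resolving each internal edge
  uniformly among its three local topologies with a configurable
  probability — the simplest mechanism with a tunable concordance level,
  not a coalescent model.
* "More than 5% ambiguous bases" and "e < 1e-4" are read as strict
  inequalities; reads at exactly 5% N are kept and hits at exactly 1e-4 are
  discarded.
* The congruence report treats absence of a genus from a clade in the input
  table as absence in the data only; undetected peptides cannot be ruled
  out, and the textual report carries that caveat.
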