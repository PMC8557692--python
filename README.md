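# cbscan

Annotation of compositionally-biased (CB) regions in protein and DNA
sequences by binomial tail-probability minimisation.

A CB region is a tract enriched for a subset of residue types — anything from
a concentrated "low-complexity" run to a long, mild compositional skew. For
each residue type, `cbscan` slides fixed-length windows along a sequence,
keeps windows whose residue count is improbable under a background
composition (the binomial null), exhaustively minimises the tail probability
over subintervals of the kept contigs, trims non-contributing ends off
minimum-length regions, and merges overlapping single-residue biases into
multiple-residue regions with pooled counts. Regions are reported with a
curly-bracket **bias signature** (biasing residues in precedence order, e.g.
`{PYQ}`), a physico-chemical **bias class** (protein: smallest containing
class of a Taylor-Venn-derived table; DNA: one of the eight strand-paired
classes such as `{AC}-{GT}`), and an **enrichment** ratio (biasing fraction
of the region over the summed background frequency of the biasing residues).

## Command line

Three entry points are installed.

### `cbscan` — the scanner

```sh
cbscan [options] input.fasta
```

| flag | meaning | default |
|------|---------|---------|
| `-t` | output P-value threshold | `1e-3` |
| `-m` / `-M` | minimum / maximum window length | 15 / 500 |
| `-z` | precision: `fast` (baseline 0.001, step 3), `medium` (0.01, 2), `thorough` (0.1, 1) | `fast` |
| `-n` | input is DNA (uniform 0.25 background by default) | protein |
| `-r` | restriction list: only these residues may bias, e.g. `-r FYW` | all |
| `-c` | background composition file | packaged default |
| `-D` | report filtered-domain positions (remap excised coordinates) | off |
| `-k` | ignore unknown residues (X/N) in calculations | off |
| `-d` | '#'-prefixed header and footer lines | off |
| `-o` | output style: `long`, `short`, `oneline` | `long` |
| `-O` | prefix for a unique, parameter-stamped output file | stdout |
| `-v` | verbose progress on stderr | off |

Examples:

```sh
# short low-complexity regions
cbscan -t1e-5 -m5 -M25 -o long yeast.fasta
# longer, milder skews
cbscan -z thorough -t0.001 -M 1000 yeast.fasta
# restrict to six-membered aromatics under the input's own background
CompositionMaker yeast.fasta        # writes yeast.fasta.COMPOSITION
cbscan -dv -ooneline -c yeast.fasta.COMPOSITION -r FYW yeast.fasta
# DNA with headers/footers
cbscan -dn DNA.example.fasta
```

Long output is tab-separated, one region per row:
`seq_id  index  kind  start  end  count  p_value  signature  bias_class
enrichment  excluded` (coordinates 1-based inclusive; `p_value` is the
binomial tail at 2 significant digits; `excluded` lists excised spans inside
a discontinuous region, or `-`). `short` keeps only the best region per
overlapping footprint; `oneline` prints one summary row per sequence
(`none` when nothing is found). `cbscan.cli.read_long_output` re-ingests
long output.

### `CompositionMaker` — background compositions

```sh
CompositionMaker [-n] [-k] input.fasta   # writes input.fasta.COMPOSITION
```

The composition file format is one `LETTER FREQUENCY` pair per line with
`#` comments; supply it to the scanner with `-c`.

### `DomainFilter` — domain excision / masking

```sh
DomainFilter -D excised -a domains.tsv input.fasta > input.Dexcised.fasta
```

`domains.tsv` is tab-separated `seq_id  start  end  [domain_id]` (1-based
inclusive). `excised` deletes the spans (shorter output sequences);
`masked` replaces them with X/N (length preserved). Filtered spans are
recorded on the FASTA name line as `#FILTERED start-end id[,...]#` in
original coordinates, so a later `cbscan -D` run can remap regions found on
the filtered sequence back to original coordinates, reporting regions that
span an excision as discontinuous (outer extent plus excluded spans).

## Library

```python
from cbscan import PROTEIN, ScanParams, annotate, default_composition, read_fasta

records = read_fasta("input.fasta", PROTEIN)
comp = default_composition(PROTEIN)
regions = annotate(records[0], comp, ScanParams(PROTEIN, precision="thorough"))
```

Modules: `seqio` (FASTA + name-line dialect), `composition` (backgrounds),
`binom` (log10 binomial tails), `scanner` (quick scan / minimise / merge /
trim), `bias_typing` (signatures, classes, enrichment), `domain_filter`
(excise/mask + coordinate remapping), `cli` (commands and formats),
`fixtures` (synthetic sequences with implanted tracts, reciprocal-overlap
scoring). The protein bias-class table and default composition live in
`src/cbscan/data/` and are user-replaceable.

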