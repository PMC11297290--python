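# isoflat

Characterization of long-read transcript isoforms against flattened
reference gene models.

Deep targeted long-read sequencing (PacBio Iso-Seq, Oxford Nanopore)
resolves a gene into hundreds or thousands of full-length transcript
models. Making biological sense of that catalog requires (i) a stable
coordinate frame per gene, (ii) a systematic call of every
alternative-splicing event in every isoform, and (iii) usage-level
statistics that work on full-length read counts. `isoflat` provides all
three as a Python library with a thin command-line interface, aimed at
people analysing targeted long-read panels or collapse-tool output
(isoform GTFs with per-sample full-length read counts).

## What it computes

**Flattened gene model.** All reference transcripts of a gene are merged
into a single set of non-overlapping, numbered "known exons" (exon 1 =
transcription 5'-most). Overlapping annotated exons with different
boundaries become one flat exon whose distinct (start, end) pairs are
kept as *variants*. The model also catalogs every known donor, acceptor,
junction, transcription start (TSS) and end (TTS).

**Event calling.** Each isoform exon is matched to the flat exons; from
the matches the caller labels, per isoform:

- **A5 / A3** — an internal exon edge whose distance to every annotated
  same-side boundary exceeds the splice tolerance τ (default 10 bp,
  strict: an 11 bp offset is an event, 10 bp is not),
- **ES** — a flat exon strictly inside the isoform's matched span with no
  overlapping isoform exon (one event per skipped exon),
- **IR** — a single isoform exon spanning ≥ 2 flat exons and the introns
  between them (the record carries the number of exons spanned),
- **CE / NE** — a cryptic exon wholly inside a reference intron / a novel
  exon outside the gene span,
- **AF / AL** — first (last) exon that is never first (last) in any
  reference transcript,
- **AP / AT** — TSS (TTS) farther than *w* (default 50 bp) from every
  annotated one.

**Structural categories.** Independently of event labels, each isoform is
assigned FSM (junction chain equals a reference transcript's), ISM
(contiguous sub-chain), NIC (all splice sites known, combination novel)
or NNC (≥ 1 novel splice site), by exact coordinate comparison.

**Quantification.** Rare-transcript filtering (retain when the five
highest per-sample full-length read counts sum to ≥ 10), CPM and
median-of-ratios normalization, isoform fractions IF (isoform reads over
gene total), dominant/major isoform calls (major: IF relative to the
dominant > 0.5, strict), a minor-isoform pre-filter, and differential
transcript usage (DTU): total change = 100 · ½ Σᵢ |IF̄ᵢ(A) − IF̄ᵢ(B)|,
podium change = a switch of the dominant isoform, with a seeded
label-permutation p-value and BH correction.

**ORF / NMD.** Spliced transcript sequences from a genome FASTA, longest
ATG-initiated ORF, nonsense-mediated-decay candidates (stop codon > 50 nt
upstream of the last exon–exon junction), cryptic-exon frame effects, and
collapsing of transcripts producing identical proteins (representative =
most abundant member).

**Synthetic panels.** `isoflat.synthetic` generates reference genes,
isoform catalogs with implanted events and a ground-truth ledger, plus
negative-binomial count matrices with group effects, so the whole tool is
testable without external data.

## Worked example

```sh
isoflat simulate --outdir panel --n-genes 4 --seed 7
isoflat characterize --reference panel/reference.gtf --isoforms panel/isoforms.gtf \
    --counts panel/counts.tsv --genome panel/genome.fa --outdir char
isoflat quantify --counts panel/counts.tsv --metadata panel/samples.tsv \
    --gene-map panel/gene_map.tsv --outdir quant
isoflat report --characterize-dir char --outdir report
```

`characterize` prints `characterized 32 isoforms across 4 genes -> char`
and writes `gene_summary.tsv`:

```
gene   n_isoforms n_known n_novel n_coding n_noncoding A5A3_isoforms A5A3_events A5A3_pct ES_isoforms ES_events ES_pct IR_isoforms IR_events IR_pct
GSYN1  8          0       8       8        0           4             6           50.0     4           7         50.0   1           1         12.5
GSYN2  8          0       8       8        0           6             6           75.0     6           9         75.0   1           1         12.5
```

Read: gene GSYN1 carries 8 isoforms, none a full splice match to a
reference transcript; 4 isoforms carry a total of 6 alternative splice
sites (50.0% of isoforms), 4 carry 7 exon-skipping events, 1 retains
introns. `isoform_events.tsv` holds the per-isoform calls,
`exon_matrix.<gene>.tsv` the clustered isoform × known-exon presence
matrix (1 present, 2 skipped, 3 retained-intron, 0 outside the isoform
span), and `orf_nmd.tsv` the ORF and decay predictions, e.g.

```
transcript  orf_start orf_end protein_length has_stop nmd_candidate coding_call
GSYN1.iso1  453       660     68             True     True          coding
```

`quantify` prints `quantified 32 isoforms (0.0% removed as rare) -> quant`
and writes isoform fractions, size factors and `dtu_results.tsv` with the
total-change, podium-change and permutation-p columns per gene.

## Layout

- `src/isoflat/annotation_io.py` — GTF/BED12/counts/metadata readers and
  writers, shared `Config`
- `src/isoflat/gene_model.py` — flattening, numbered exons, site catalogs
- `src/isoflat/event_caller.py` — exon matching, event calls, structural
  categories, gene summaries, exon-presence matrices
- `src/isoflat/quantify.py` — filtering, normalization, isoform
  fractions, DTU, burden statistics
- `src/isoflat/orf_nmd.py` — spliced sequences, ORF/NMD, protein groups
- `src/isoflat/synthetic.py` — fixture generator with ground truth
- `src/isoflat/cli.py` — `isoflat` subcommands

See `docs/methods.md` for the model conventions, parameter defaults and
known limitations.
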