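# Methods

This note records the conventions, parameter defaults and design choices
behind `isoflat`, and what the synthetic fixtures do and do not establish
about real data.

## Coordinates and gene flattening

All interval math runs on 0-based half-open coordinates; GTF is read and
written 1-based inclusive and BED 0-based half-open, their native
conventions. A transcript's gene assignment is taken from the GTF
attributes written by the upstream collapse/annotation step and is never
re-derived by overlap.

A gene's reference transcripts are flattened by merging every overlapping
annotated exon into one *flat exon*; the union interval defines the exon,
and each distinct annotated (start, end) pair is kept as a *variant*.
Alternative-splice-site offsets are measured against variant boundaries,
not the union, so an isoform matching any annotated boundary is never
mislabeled. Flat exons are numbered in transcription order (exon 1 =
5'-most; on the minus strand exon 1 has the largest coordinates).
Whether partially overlapping annotated exons should count as one or two
"known exons" is a genuine convention choice; we merge and expose
`n_variants` per exon so either view can be reported. Reference
transcripts occupying disjoint loci under one gene id are flattened
jointly with a logged warning.

## Event calling

Events are always called against the flattened model, independent of
structural category — a full-splice-match isoform whose reference
transcript skips a flat exon therefore carries an ES label, which is what
gene-level event accounting needs.

- **A5/A3.** A5 is an alternative donor-side edge (the transcription-3'
  edge of an exon), A3 an alternative acceptor-side edge; the labels are
  stated explicitly because usage in the field varies. Only internal
  splice edges are eligible: the isoform's transcription-start edge
  belongs to AP, its end edge to AT. An edge is an event iff its distance
  to every same-side variant boundary of its matched exon *and* to every
  known donor/acceptor of the gene strictly exceeds the tolerance τ
  (default 10 bp): offset 10 matches, offset 11 is an event. Edges of
  exons that span several flat exons (retained introns) are flanking
  known boundaries in the data this models; they are not separately
  A5/A3-labeled.
- **ES** is counted per skipped exon (not per skipped block): a flat exon
  strictly between the isoform's 5'-most and 3'-most matched flat exons,
  overlapped by no isoform exon and not inside a retained-intron span.
  Exons outside the matched span belong to AF/AL, never ES.
- **IR**: each isoform exon overlapping ≥ 2 flat exons yields one event
  recording the spanned range; separate spanning exons are separate
  events.
- **CE** requires zero overlap with any flat exon and containment in one
  reference intron; an exon overlapping a flat exon by even 1 bp follows
  the alternative-boundary path instead. **NE** is an exon wholly outside
  the flattened span, labeled upstream/downstream in transcription
  orientation.
- **AF** uses the transcription-5'-most flat exon matched by the
  isoform's first exon (the biologically relevant first-exon identity
  when the first exon spans several flat exons); AL mirrors with the
  3'-most. A cryptic or novel first/last exon is always AF/AL. **AP/AT**
  compare the isoform's TSS/TTS against every annotated one with window
  *w* = 50 bp (inclusive: offset 50 is still "known").

## Structural categories

FSM/ISM/NIC/NNC follow the standard junction-chain definitions and use
exact coordinates — τ applies only to event labels, so a 5 bp offset is
inside event tolerance yet still a novel site (NNC). ISM means a
contiguous sub-chain of one reference transcript's chain. Mono-exonic
isoforms are matched by containment (FSM within a mono-exonic reference
transcript's exon, ISM within any reference exon, else NIC) and flagged
`mono_exon`, since junction chains are undefined for them. The
known/novel split in gene summaries counts FSM only as "known" by
default — the conservative reading — with an `{FSM, ISM}` switch.

## Quantification

Full-length read counts proxy transcript abundance directly. The
rare-transcript filter retains an isoform when the sum of its five
largest per-sample counts reaches 10 (defaults `rare_n_samples` = 5,
`rare_min_reads` = 10); a stricter per-sample semantics (≥ 5 samples each
at ≥ 10 reads) is available behind a flag, since the phrase "count ≥ 10
across any five samples" supports both readings. Gene-level counts
aggregate *before* filtering. Median-of-ratios size factors are estimated
on rows with no zero count; CPM is provided as the simple alternative.

Isoform fractions are per sample; samples where the gene has zero reads
give undefined fractions that are excluded from group means. Dominant =
largest mean IF (ties to the lexicographically first id, logged); major
isoforms exceed half the dominant's share, strictly. The DTU *total
change* is the half-L1 distance between group-mean IF vectors × 100 — a
documented stand-in with the right invariances (symmetric in groups,
bounded by 100, zero iff identical means), not a replication of any
external tool's internal metric. Significance comes from label
permutation with the +1-corrected p-value, BH-adjusted across genes.
Event-burden fold changes use a pseudocount of 1. Reported percentages
round to one decimal and fold changes to two.

## ORF and NMD

The ORF is the longest ATG-initiated reading frame ending at an in-frame
stop (ties to the 5'-most start; with no in-frame stop the frame runs
open-ended and is flagged). Coding status is ORF-with-stop by default;
when an external coding-potential score table is supplied, coding ⇔
score > 0.44 instead. NMD candidates have a stop codon more than
`nmd_distance_nt` = 50 nt upstream of the last exon–exon junction — the
canonical 50-nt rule, exposed as a parameter; mono-exonic transcripts are
never NMD. Cryptic-exon frame effects: length ≢ 0 (mod 3) is a
frameshift; otherwise the ORF frame is translated across the exon to
detect introduced stops; cryptic exons outside the translated region are
labeled UTR. Transcripts with identical predicted proteins collapse into
one group represented by the most abundant member; transcripts without a
stop codon are excluded from collapsing and reported separately.

## Synthetic fixtures

The generator emulates a deeply sequenced targeted panel: multi-exon
genes (default 8 exons of 80–200 bp, introns 100–300 bp), a full-length
reference transcript plus variants dropping single internal exons, and
isoform catalogs with independently implanted events. Default per-isoform
probabilities — A5 0.4, A3 0.4, ES 0.5, IR 0.05, CE 0.05, NE 0.05,
5'-truncation 0.3, 3'-truncation 0.1 — mirror the observed event mix in
such panels, where alternative splice sites and exon skipping dominate,
retained introns and cryptic exons are rare, and 5'-degraded
(incomplete-splice-match) artifacts are a sizeable minority. Implant
geometry (offsets drawn from 11–30 bp, cryptic exons with 20 bp intronic
margins, one event type per exon) guarantees the truth labels are exactly
what a correct caller must return; minus-strand genes are produced by
coordinate reflection, which preserves all transcription-order labels.
Counts are negative-binomial with overdispersion α (variance μ + αμ²,
default α = 0.1; α = 0 degenerates to Poisson) and multiplicative group
effects.

What passing these fixtures does *not* show: robustness to alignment
artifacts, wobbly splice sites near repeats, reference exons with many
overlapping variants interacting with implanted offsets, or genes where
several events collide on one exon — real catalogs contain all of these,
and the caller's behavior there follows the documented rules rather than
a validated ground truth.

## Numerical and reporting choices

Exon-matrix clustering uses average linkage on a Jaccard-style distance
over ternary exon states (present / skipped / retained treated as
distinct), rows pre-sorted by isoform id so dendrogram order is
deterministic; identical isoforms land adjacently. Permutation tests are
seeded; all CLI runs are byte-reproducible given fixed inputs and seed.
The acceptance script scales its recovery suites to 1000 synthetic genes,
100 detection replicates and 500 null simulations — sizes chosen so the
whole script completes in well under a minute while keeping Monte-Carlo
error far below the decision margins. Median-of-ratios normalization
mildly attenuates implanted fold changes when a large minority of
features carry the effect (the estimator assumes most features are
unchanged); the recovery checks account for this with a ±0.3 log2 margin.

## Known limitations

- Events on exons spanning several flat exons are summarized as IR only;
  shifted outer edges of such exons are not additionally A5/A3-labeled.
- The total-change metric is this package's own definition (above);
  values are comparable within a dataset, not across tools.
- No coding-potential model is included; external scores are ingested.
- Junction support annotation consumes a short-read junction table but no
  per-base coverage; TSS-evidence peaks are used only as a proximity flag.
- Mono-exonic genes are accepted, but junction-based event calls are
  undefined for them and flagged rather than guessed.
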