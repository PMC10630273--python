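# Methods

This note documents the models, rules and numerical conventions behind
`lyticmine`, the parameters that matter, what the synthetic generator does
and does not emulate, and the design choices made where several reasonable
options existed.

## Coordinate model and input formats

GenBank flat files are parsed with Biopython; the 1-based inclusive
feature coordinates become 0-based half-open intervals at the boundary and
never reappear internally. `complement(...)` features carry strand `-`;
joined multi-interval CDS are concatenated in feature order with the
strand applied to the whole feature. A CDS without a `/translation`
qualifier is translated from the nucleotide sequence with translation
table 11 (the bacterial/phage standard); if the record has no sequence
either, the CDS is kept with an empty translation and flagged, so the
pipeline can run on feature-table-only records and fails loudly only where
nucleotides are actually needed. A simple (non-joined) CDS whose length is
not a multiple of three is flagged, never silently fixed.

Protein coordinates (domain hits, linker calls, segmentations) stay
1-based inclusive, matching InterProScan output. The domain-scan reader
accepts both the full InterProScan TSV dialect (protein id, md5, length,
database, accession, description, start, stop, …) and a compact
six-column form; rows from databases other than Pfam (configurable) are
dropped and counted, and hits whose protein id matches no genome are
reported as orphans rather than discarded.

## Lytic-role annotation

Two evidence streams are combined:

* **Keywords** — case-insensitive substring match on the `product`
  qualifier; endolysin keywords (`n-acetylmuramoyl-l-alanine amidase`,
  `endolysin`, `phage lysin`, `lysin`) are checked before the holin
  keyword (`holin`), and no match yields `unknown`. The classifier is
  total: it never raises.
* **Domains** — signature accessions mapped through a controlled
  vocabulary of 7 holin families, XhlA (hemolysin-like holin companion),
  6 catalytic families and 4 CWB families; version suffixes are stripped;
  the vocabulary is extensible via a two-column override file (for
  entries without stable Pfam accessions, such as endopeptidase-like CATH
  superfamilies).

Role precedence is: holin-family domain > XhlA > catalytic domain >
CWB-only > keyword > unknown. Domain evidence outranks keywords because
keyword annotations in public records are frequently wrong in exactly the
cases that matter (XhlA genes labelled "tail fiber protein" or
"hypothetical protein"); the `evidence` field records which pathway fired.
Overlapping hits of the same domain merge to their envelope interval while
distinct or non-overlapping repeats (e.g. tandem LysM copies) are kept,
and the assigned role is invariant under permutation of the input hits.

## Cassette mining and tabulation

Every holin or endolysin seeds a cassette; the neighborhood extends over
adjacent genes of any lytic role on either strand, tolerating at most
`max_gap_genes` (default 2) consecutive unknown-role genes inside and
trimming unknown-role genes from the ends. Gene-count gaps were chosen
over base-pair distances because they are robust to annotation density.
By default each genome contributes its primary cassette (most members,
ties to the leftmost) so that n genomes yield n counting units;
`--all-cassettes` disables this.

Genomes are stratified into five half-open, lower-inclusive size groups —
[0, 20), [20, 50), [50, 65), [65, 100), [100, ∞) kbp — so a genome of
exactly 20,000 bp is Group 2. Combination tables count one unit per
endolysin per cassette along the requested axes (catalytic×CWB, or
holin×catalytic×CWB with fixed holin display aliases such as `PH_1`);
endolysins with no CWB-category hit are labelled `Unknown`, multiple CWB
domains join N→C with `" + "`. Percentages are `100·count/total` rounded
half-away-from-zero to two decimals — the convention that reproduces every
printed value of the published 171-cassette census. The size histogram
uses left-closed bins from zero.

## Alignment and identities

All comparisons use global Needleman–Wunsch alignment with BLOSUM62 and
affine gaps (open −10, extend −0.5 per additional gap position), via
Biopython's `PairwiseAligner`. Identity is matched columns divided by the
**full alignment length**, so gaps count against identity; length
differences between endolysin variants are treated as evidence, which is
deliberate. Inputs are aligned in a canonical pair order, making identity
exactly symmetric; non-standard residues score as `X`. Optimal scores are
verified in the tests against an exhaustive maximisation over all gapped
alignments for short sequences. Among co-optimal alignments the library's
deterministic traceback is used; only the reported aligned strings, never
the score or any identity threshold decision at the margins tested, depend
on that choice.

## Linker detection and endolysin segmentation

The interdomain linker is searched downstream of the catalytic domain
(window starts within `linker_search_span` = 80 residues) under two
criteria:

* **composition** — the best window of length 12–16 with P+K fraction ≥
  0.5, then extended maximally over P/K residues (extension that can only
  keep or raise the fraction; a greedy ≥ 0.5 extension would dilute a pure
  P/K window below fraction 1.0);
* **motif** — the best substring within edit distance ≤ 3 of the consensus
  `KPTKPPSKPPPKP`, found with a semi-global edit-distance DP (free
  start/end in the text, leftmost tie-break).

The higher-scoring criterion wins (motif score `1 − d/13` vs composition
score = P/K fraction; ties favour the motif). An exact planted consensus
is therefore always reported at its exact coordinates with distance 0.

Segmentation takes the first catalytic-domain span as the catalytic
region and searches the linker from its end. The CWB region is the
annotated CWB span when one exists; otherwise the stretch from linker end
to C terminus becomes a putative UCWB candidate when it is at least
`min_ucwb_len` = 40 residues (shorter tails are left unlabelled). When a
known CWB domain starts ≥ 40 residues after the linker, the gap is emitted
as an additional pre-CWB candidate — the "extra domain between linker and
SH3_5" pattern. An endolysin with neither a catalytic domain nor a
detectable linker gets a `failed` marker instead of an exception. UCWB
candidates from the whole dataset are clustered by single linkage at
identity ≥ 0.8 and labelled `UCWB-1`, `UCWB-2`, … by descending cluster
size then smallest member id; all UCWB calls are putative by construction
(sequence composition stands in for structure prediction, which is out of
scope). The 0.8 threshold sits between the within-family (≥ 0.9) and
between-family (≤ 0.5) identity regimes the swap rules assume.

## Shuffling calls

For every pair of segmented endolysins with both regions available, the
catalytic regions and the **post-linker regions** (everything C-terminal
of the linker end, or of the catalytic end when no linker exists — the
shuffling breakpoint sits at the conserved linker) are aligned:

* catalytic identity ≥ `high_id` (0.9) and CWB identity ≤ `low_id` (0.5)
  ⇒ CWB-domain swap;
* catalytic identity ≤ 0.5 and CWB identity ≥ 0.9 ⇒ catalytic-domain swap.

Both identities travel with the event as evidence. The thresholds
formalise "almost identical" vs "different" conservatively: raising
`high_id` or lowering `low_id` can only reduce the number of calls
(monotonicity is property-tested).

Gene (holin) swaps: cassettes are clustered by full-length identity of
their first endolysin (single linkage, ≥ `endolysin_cluster_id` = 0.9);
within each cluster of ≥ 3 cassettes with a unique modal holin signature,
every cassette with a different holin yields a `gene_holin_swap` naming
the minority and modal holins. Clusters with tied modes are skipped —
with no majority there is no direction to call. No randomness is used
anywhere in the analysis; every output is a pure function of inputs and
configuration.

## Synthetic populations and what they show

The generator emulates the study conditions end to end. A seeded block
library draws one archetype per family — catalytic blocks of 120–160 aa,
CWB blocks of 50–120 aa (including three UCWB families with no Pfam rows),
holins of 70–100 aa, an XhlA block, and linker blocks including the exact
consensus — redrawing any block whose global identity to an accepted block
of the same set exceeds 0.3. Each size group has one cassette template
(holin family, catalytic+linker+CWB recipe, XhlA flag) with deliberately
distinct catalytic families across groups, so the no-swap population
contains no cross-group signal by construction. Genomes sample a length
inside their group's range, receive filler CDS with neutral decoy products
("hypothetical protein", "tail fiber protein", "terminase large subunit",
…) and one planted cassette; nucleotide sequences are reverse-translated
with uniform codon choice (table 11) with random intergenic filler.
Domain-scan rows are emitted for every planted block with correct
coordinates, plus occasional non-Pfam decoy rows the reader must skip.
The XhlA gene is always written with the product "tail fiber protein" to
exercise the domain-rescue path.

Copies diverge by **substitutions only**, applied per block at the exact
count `round(rate × block length)` at distinct sites, never inside the
linker (mirroring the observed conservation of interdomain linkers). The
deterministic count makes every identity the detector relies on
structurally bounded: at the default divergence 0.03, within-family
regions stay ≥ 0.90 identity and between-family regions stay well below
0.5 for every copy pair on every seed, so perfect recovery is a property
of the construction, not a lucky draw. Defaults are 30 genomes (6 per
group) and 3 planted swaps per event class, assigned round-robin to
groups; generation fails loudly when a group is too small to keep a gene
swap detectable.

The truth ledger derives its domain events from the planted block labels:
every endolysin pair with equal catalytic family and different CWB family
is a CWB-swap truth event (symmetrically for catalytic swaps), which is
exactly the pair set a threshold detector should call — one planted swap
therefore implies one truth event per co-template member. Gene-swap truth
lists the minority cassettes per group among domain-swap-free genomes.
`score_recovery` matches events on class plus unordered participant set
and reports precision/recall overall and per class (empty truth and empty
calls score 1.0 by convention).

What passing these tests does **not** show: real phage genomes have
correlated gene content, indels, partial domains, annotation errors
beyond the simulated decoys, and cassettes that deviate from a
one-holin-one-endolysin template; the generator's substitution-only model
(an `--indels`-style extension is left to future work) and its clean
domain coordinates are easier than real InterProScan output. The
generator validates the machinery, not the biology of any particular
dataset.

## Problem sizes and runtime

The default test and acceptance conditions — 30 genomes per population,
20 seeds for recovery plus 20 null populations, 200 alignment-oracle
pairs of length ≤ 8, 100 linker trials, 10,000 size-group draws — were
chosen so a full run completes in about a minute on one core while still
exercising every decision path several times per seed. Alignment results
are memoised per process; all randomness flows through
`numpy.random.default_rng` seeds, so every reported number is exactly
reproducible.

## Known limitations

* Cassette mining assumes reasonably complete CDS annotation; genomes
  annotated without products *and* without domain scans yield no seeds.
* The one-primary-cassette default can hide a genuine second cassette;
  use `--all-cassettes` when that matters.
* UCWB calls are sequence-level hypotheses; without structural evidence a
  C-terminal region of unknown function is only *putatively* a CWB
  domain.
* Identity thresholds are global; a dataset with unusually high
  background relatedness may need a higher `endolysin_cluster_id` to keep
  clusters meaningful.
* The holin-swap rule needs clusters of ≥ 3 cassettes and a unique modal
  holin; sparser datasets produce no gene-swap calls rather than guesses.
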