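# Methods

## Breakend model and orientation algebra

All structural variants are reduced to breakpoints: pairs of breakends
joined at a junction on the derivative chromosome. Coordinates are 1-based
inclusive throughout the model (the VCF convention); BEDPE's 0-based
half-open intervals are shifted at the I/O boundary (`lo = start + 1`,
`hi = end`).

Orientation `+` means the retained segment extends toward lower coordinates
(junction 3' of the base), `-` toward higher coordinates. The symbolic
alleles decompose as, for POS = p and END = e:

* `<DEL>`: `(p,+) <-> (e+1,-)` — the junction joins the last retained base
  to the first base after the deleted segment;
* `<DUP>`: `(p+1,-) <-> (e,+)` — the tandem copy joins base e back to base
  p+1;
* `<INS>` at p: `(p,+) <-> (p+1,-)` carrying the inserted sequence;
* `<INV>`: two breakpoints `(p,+)<->(e,+)` and `(p+1,-)<->(e+1,-)`.

The four bracketed BND ALT forms map to (local, mate) orientations
`t[p[ -> (+,-)`, `t]p] -> (+,+)`, `]p]t -> (-,+)`, `[p[t -> (-,-)`; the
parser and renderer are mutually inverse and byte-exact, which the suite
checks exhaustively. Single-breakend ALTs `.s` / `s.` are `-` / `+`
breakends whose unanchored bases become the stored insert.

### Location intervals, precision and homology

A breakend lives on an interval `[lo, hi]` with a nominal (caller-reported)
position inside it. Two sources of width are distinguished by the
`precise` flag: an imprecise call (IMPRECISE flag set; interval = confidence
interval) and a precise call with breakpoint microhomology (interval = the
homologous range over which the junction can be placed equivalently). The
model enforces that a precise breakend's homology length covers its
interval width; when a caller reports a precise record whose CIPOS is wider
than its HOMLEN, the homology length is raised to the width, since for a
precise call the interval has no other reading. CIEND absent on a symbolic
record falls back to CIPOS (symmetric uncertainty as the least-surprising
default).

### Pair conventions

Partner links are an involution (mirroring MATEID reciprocity) and are
validated at set construction, as are id uniqueness and insert-sequence
agreement between mates. Inserted sequence is stored identically on both
mates, read along the derivative in canonical pair order; the VCF writer
re-derives the per-mate ALT representation (reverse complement when the two
mates share an orientation sign, i.e. inversion-type junctions). Canonical
pair order is the total order (contig rank, nominal, orientation, id) with
contig rank taken from the source header, unknown contigs sorting after it
lexicographically — deterministic without a reference genome.

## VCF ingest and dialects

`breakpoint_ranges` composes dialect normalization, per-notation conversion
and uncertainty attachment. Non-compliant conventions handled: `SVTYPE=TRA`
/`CTX` with `CHR2`/`END` becomes a reciprocal BND pair, orientations taken
from DELLY `CT` (`3 -> +`, `5 -> -`) or LUMPY `STRANDS`, defaulting to
`(+,-)` when neither is present; Pindel `RPL` becomes a deletion carrying
the replacement sequence as junction insert; `INV3`/`INV5` restrict an
inversion to its `(+,+)` or `(-,-)` breakpoint. `UNK` and `IMPRECISE_DIR`
constructs are recognized and skipped with a warning — their semantics are
caller-private. `CILEN`/`HOMPOSINFO` keys are retained in the record's info
map but unused, as no public specification defines them.

Direct-sequence records are trimmed (common prefix including the anchor
base, then common suffix) and classified as net deletion, net insertion or
replacement; records with a length difference below `min_sv_size`
(default 50 bp, the field's customary SV floor) are skipped and counted.
Symbolic `<INS>` takes its sequence from the Manta-style `SVINSSEQ` key
when present and otherwise N-pads to SVLEN so length-based comparisons
still work. Unmated BND records are downgraded to single breakends by
default (`drop` is available), preserving evidence.

The writer emits every pair as two reciprocal BND records (CIPOS from the
interval, HOMLEN, IMPRECISE, EVENT for provenance) and singles in
single-breakend notation, sorted by contig order then position; re-ingest
is the identity on all model fields. One practical note: htslib only
preserves `END` on records whose header declares it as an Integer INFO
field, so dialect files must carry the usual declarations (real callers
do; the package's own writers always declare every key they use).

## Matching

Two pairs match when some assignment of query to subject breakends (both
assignments are tried, covering interchromosomal and inverted pairs whose
canonical order differs) aligns breakends on the same contig with equal
orientation and intersecting intervals after each is widened by `maxgap`.
An uncertain position therefore matches exactly anywhere inside its
interval, and `maxgap=0` is exact matching. Event size is defined only for
intrachromosomal pairs as `|nominal2 - nominal1|` (deletion/duplication
length up to ±1) and is used only in the relative test
`|span_q - span_s| / max <= size_margin`.
`restrict_margin_to_size_multiple` caps the effective gap at a multiple of
the smaller event size and is applied conjunctively with `size_margin`
(their composition is otherwise unspecified; conjunction is the
conservative choice). All ties are reported; `best_hits` implements the
deterministic one-to-one selection (total gap, then size difference, then
subject id) separately so counts stay unambiguous.

The production matcher uses a per-contig interval index over subject
breakends; its contract is exact equality with the brute-force all-pairs
reference (`find_breakpoint_overlaps_naive`), which the suite verifies on
500×500-pair sets across gap and margin settings.

## Duplication/insertion equivalence

A pair is duplication-like iff intrachromosomal with signature `(-,+)` in
coordinate order; insertion-like iff `(+,-)` with breakends at most 1 bp
apart (widened by their intervals) and non-empty insert. A duplication of
length `L = nominal2 - nominal1 + 1` matches an insertion of ℓ bases when
the insertion site lies within `maxgap` (default 16) of either duplication
boundary and `|L - l| / max(L, l) <= size_margin` (default 0.25). An
insertion reaching both boundaries of a short duplication yields one hit
flagged `both`. Equivalence is positional and length-based only — insert
content is never compared to the reference, both because callers emit
placeholder or N-padded sequence and because no FASTA dependency is wanted.
No hard 50–1000 bp length gate is imposed: that range describes where the
discordance is prevalent, not a filter.

## Transitive calls

The search treats every pair as a candidate. From a junction whose breakend
matches the candidate's near side (interval-exact, same rule as exact
matching), it crosses to the partner and walks into the retained flank —
rightward for a `-` breakend, leftward for `+` — collecting junctions that
face back toward it within `max_segment_bp` (default 1000; observed
intervening segments are usually far shorter, but the bound is a parameter,
not a claim). Distances are nominal-position differences widened by the
breakend intervals and clamped to `[0, max_segment_bp]`. A path closes the
first time its exit breakend matches the candidate's far side; chains need
≥ 2 constituents, never reuse a junction (preventing loops on fold-back
structures) and never include the candidate itself. Searching from one side
suffices — the link geometry is symmetric under reversal — so a chain may
be reported in either direction.

Acceptance: a precise candidate with m inserted bases requires the total
traversed distance — reference segments plus the constituents' own insert
lengths, since those bases are present on the derivative — to satisfy
`|total - m| <= insert_tolerance_bp` (default 25). Imprecise candidates are
accepted structurally (both transitive sources occur in practice, so
`allow_imprecise` defaults on); an optional `bound_by_interval` constraint
additionally caps their traversal by the candidate's own interval widths
and is off by default. Identified calls are only reported, never filtered
out — filtering policy belongs to the user. A two-set mode takes candidates
and constituents from different call sets (the motivating short- vs
long-read comparison). `find_transitive_calls_bruteforce` re-derives the
same answer by exhaustive enumeration of ordered junction sequences and
serves as the reference on small sets.

## Simulator

The simulator is the package's test surface: three synthetic 10 Mbp contigs
(no FASTA; no routine reads reference bases), events placed without overlap
with a 2 kb separation margin, kinds drawn from a configurable mix (default
DEL/DUP/INS/INV/translocation/single-breakend at 22/18/18/16/14/12 %),
spans uniform in 50–10 000 bp (50–1000 bp in the dup/ins profile, the range
where the notational discordance concentrates). Per event, precision is
drawn 70 % precise, 15 % imprecise (CIPOS/CIEND half-widths 3–50 bp), 15 %
precise-with-homology (1–20 bp); quality values are integral so VCF round
trips compare exactly. Renderings: `symbolic`, `bnd`, `direct` (DEL/INS
only), extended `bedpe`, plus `dup-as-ins` and `ins-as-dup` for the
equivalence scenarios. Interchromosomal and single-breakend events are
emitted as BND records in every VCF notation, as they must be.

Transitive planting reserves chain anchors with a 5 kb margin so chains
cannot interact, draws segment gaps from 10–300 bp and junction inserts
from 0–10 bp, and gives the candidate an insert of exactly the intervening
derivative length. Negative controls either offset that insert by 500 bp
(far beyond the 25 bp tolerance) or inflate one segment gap to 1200–2000 bp
(beyond `max_segment_bp`). Decoy insertions for the equivalence scenario
are placed outside 200 bp exclusion zones around every duplication
boundary, which is what makes them decoys rather than accidental
equivalents.

What the simulator does not emulate: read-level evidence and its error
modes, sequence context at junctions (breakpoints do not sit in repeats or
homopolymers unless homology is planted), reference-genome sequence, and
caller-specific biases beyond the notation itself. Passing tests therefore
demonstrate correctness of representation, conversion and comparison logic
under known geometry — not robustness to the noise of real callers on real
genomes.

## Problem sizes and numerical choices

The end-to-end suite runs at the scales the properties are stated for: 200
mixed events for notation invariance and round-trip identity, 500×500 pairs
for matcher/oracle parity (maxgap 0/10/100 × size margin off/0.25), 100
duplications plus 100 decoys for reconciliation, 70 planted chains plus 50
negatives for transitive recovery, and 100 inversions for decomposition —
sizes at which every check completes in seconds on one CPU. Ties anywhere
in the toolkit break deterministically (by id after position), all
randomness flows from explicit seeds, and degenerate inputs (empty sets,
empty files, zero-length inserts) are exercised in the unit tests.

## Known limitations

* FORMAT/genotype fields are not carried through; QUAL/FILTER pass through
  unreconciled between mates (the specification of BND pairs does not say
  whether they may disagree).
* Only a representative dialect subset is normalized (DELLY-style TRA/CT,
  LUMPY STRANDS, Pindel RPL, INV3/INV5, generic CHR2/END); other caller
  quirks pass through or are skipped with warnings.
* Dispersed (non-tandem) duplication vs insertion equivalence is out of
  scope, as is verifying duplicated content against a reference.
* The transitive search explains calls; it does not reconstruct derivative
  chromosomes or classify complex events.
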