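# svbreaks

A caller-agnostic toolkit for structural variant (SV) breakpoints. It
decouples downstream SV analysis from the quirks of individual variant
callers by converting every representation a caller may emit — direct
REF/ALT sequence, symbolic alleles (`<DEL>`, `<DUP>`, `<INS>`, `<INV>`),
paired BND records with bracketed ALTs and MATEID links, single-breakend
ALTs, BEDPE rows, and common non-compliant dialects (`SVTYPE=TRA/CTX` with
`CHR2`/`END`, DELLY `CT` connection types, Pindel `RPL`, `INV3`/`INV5`
half-inversions) — into one paired-breakend model, and building call-set
comparison on top of that model.

It is aimed at people who benchmark or integrate SV call sets: anyone who
has tried to compare a short-read caller against a long-read caller and
found that identical rearrangements "mismatch" because they were written in
different VCF notations.

## The model

Every variant is decomposed into **breakpoints**: novel adjacencies on the
derivative chromosome. A breakpoint is a pair of **breakends**, each a
located, oriented position on a contig:

* orientation `+`: the retained (joined) segment extends toward lower
  coordinates — the junction is immediately 3' of the base;
* orientation `-`: the retained segment extends toward higher coordinates.

Under this convention, with positions ordered along the contig:

| event              | breakpoint signature                    |
|--------------------|-----------------------------------------|
| deletion           | `(+,-)`                                  |
| tandem duplication | `(-,+)`                                  |
| inversion          | two breakpoints: `(+,+)` and `(-,-)`     |
| insertion          | adjacent `(+,-)` carrying inserted bases |

A breakend is located on an interval `[lo, hi]`, not a point: the caller's
confidence interval (CIPOS/CIEND) for imprecise calls, or the microhomology
range (HOMLEN) for precise calls that can be placed at several equivalent
positions. Single breakends — junctions whose far side could not be placed —
are breakends with no partner, carrying their unanchored assembled sequence.

Matching is purely positional and orientational (no prior typing into
DEL/DUP/INV classes), so call sets match regardless of the notation they
were written in. Two further routines handle equivalences that even a
common notation cannot see:

* **duplication vs insertion** (`find_ins_dup_overlaps`): a tandem
  duplication of length *L* and an insertion of ℓ ≈ *L* bases at one of its
  boundaries describe the same rearrangement; long-read callers typically
  report the insertion form, short-read callers the duplication form.
* **transitive breakpoints** (`find_transitive_calls`): a single reported
  junction that actually spans a path through ≥ 2 real junctions separated
  by short derivative-chromosome segments; the search explains such calls
  and reports the underlying junction chain.

A seeded simulator plants ground-truth rearrangements (including transitive
chains and deliberately discordant renderings), so every routine is testable
end-to-end without external data.

## Worked example

Simulate eight tandem duplications and render them the way a short-read
caller would (`<DUP>` records) and the way a long-read caller would
(insertions at the duplication boundary):

```sh
svbreaks simulate --n 8 --seed 42 --mix "DUP=1.0" --size-range 50,1000 \
    --notation symbolic  --out short_read
svbreaks simulate --n 8 --seed 42 --mix "DUP=1.0" --size-range 50,1000 \
    --notation dup-as-ins --out long_read

svbreaks match --truth short_read.vcf --calls long_read.vcf
```

Plain exact matching sees two disjoint call sets — the duplication pairs
are `(-,+)`, the insertion pairs `(+,-)`:

```
# TP=0
# FP=8
# FN=8
pair_id	role	status	match_type
ev0006_bp1_1	call	FP	.
...
```

Adding duplication/insertion reconciliation recovers every one:

```sh
svbreaks match --truth short_read.vcf --calls long_read.vcf --reconcile-dupins
```

```
# TP=8
# FP=0
# FN=0
pair_id	role	status	match_type
ev0006_bp1_1	call	TP	dupins
...
```

`TP`/`FP`/`FN` count call pairs matched to truth, call pairs unmatched, and
truth pairs left unfound; `match_type` records whether the match came from
plain breakpoint overlap (`breakpoint`), dup/ins equivalence (`dupins`) or a
transitive-chain explanation (`transitive`).

The same operations are available as a library:

```python
from svbreaks import breakpoint_ranges, count_breakpoint_overlaps

truth = breakpoint_ranges("truth.vcf")
calls = breakpoint_ranges("caller.vcf")
tp = {pair: n > 0 for pair, n in
      count_breakpoint_overlaps(calls, truth).items()}
```

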