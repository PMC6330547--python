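# Methods

## Search model

A *spacer site* is a 20-nt protospacer with a 3-nt PAM immediately 3' of it
on the same strand; NGG sites are guide candidates and off-target loci, NAG
sites are off-target loci only. Off-target search asks: for a query spacer
q, which sites admit an alignment with at most `max_mismatches` mismatches
**and** at most `max_gaps` single-base bulges? The two budgets are enforced
separately (defaults 4 and 2), mirroring the hardest planted benchmark
cases (four mismatches; two gaps); both are exposed as parameters because
the appropriate budget is a user-level risk decision.

Candidate windows are anchored at the PAM-proximal end and range over
lengths 20 − `max_gaps` … 20 + `max_gaps`, so length changes from bulges
are absorbed at the PAM-distal side, where Cas9 tolerance is highest.
Alignment costs are unit: one per mismatch, one per bulged base.
"Differences" everywhere means mismatches + gap bases.

Bulges are modelled as isolated unpaired bases: two gap columns are never
adjacent in an alignment. A two-base insertion would be a multi-base bulge
(a different lesion, outside the model), and an insertion adjacent to a
deletion is equivalent to a mismatch and would otherwise let a two-gap
budget smuggle in mismatches.

### Position numbering and seeds

Spacer positions are numbered 1..20 from the PAM-proximal end. `seed10` and
`seed15` count differences at positions ≤ 10 / ≤ 15, the two seed-region
lengths used by the classifier. An RNA bulge (unpaired query base) is
counted at that base's position; a DNA bulge (unpaired window base) falling
between query positions p and p+1 is assigned p+1, i.e. pushed toward the
seed. Assignments are deliberately conservative: they can only understate a
site's seed disruption, never overstate it.

### Tie-breaking

Among alignments with minimal total differences the engine prefers fewer
gaps, then fewest seed10 differences, then fewest seed15. The classifier
must assume the most threatening (least seed-disrupted) reading of every
off-target, so ties resolve toward the seed-intact interpretation. Within
the dynamic program this is a lexicographic cost (mismatches, seed10,
seed15) per exact-gap-count layer; across window lengths, remaining ties go
to the length closest to 20, then the shorter one.

### Global vs local alignment

The global aligner produces one full-length result per window, which is
what makes gapped sites detectable as single hits. The local aligner is
ungapped (match +1, mismatch −2) and therefore splits a bulged site into
sub-segments — the failure mode of local tools on gapped off-targets, kept
as an explicit, testable behaviour. Reported hits always carry the global
profile: a local detection is re-scored globally before reporting, so the
exhaustive hit set is exactly the set of sites whose *global* alignment
fits the budget (the global DP is optimal under the difference metric, so
combining modes cannot add hits).

### Exhaustive and seeded modes

Exhaustive mode runs the alignment against every candidate site; nothing
within budget can be missed. The engine encodes all candidate windows once
(PAM-proximal-first integer codes; out-of-bounds and N cells marked
unalignable) and runs the banded DP over (query position, window offset,
gap count, trailing-gap flag) vectorized across all sites with numpy,
then recomputes exact profiles in Python only for feasible sites. Seeded
mode first requires the raw candidate window (with its PAM-distal
extension) to share at least one exact, ungapped substring of the query of
length `word_size` — the k-mer heuristic of conventional aligners, included
so its blind spots can be measured rather than suffered.

### N handling and degenerate inputs

Genomes may contain N, but any window containing N is skipped: an N can
neither confirm nor deny a difference, and a conservative pipeline should
not report sites it cannot evaluate. This includes a literal N at the PAM's
"N" position. Lowercase (soft-masked) sequence is uppercased and treated
identically; masking policy is left to the user as a pre-filter. Only the
query's exact locus (interval + strand) is excluded from its own search:
identical sequences elsewhere are genuine 0-difference off-targets, which
is what makes multi-copy spacers self-rejecting.

## The independent oracle

`brute_force_oracle` re-derives hit sets without sharing code with the
engine: it slides over every position of the forward and
reverse-complemented sequence, checks PAM adjacency by string comparison,
prescreens each window with edlib's unconstrained edit distance (a lower
bound on any gap-limited alignment cost, so the prescreen can only discard
true negatives), and runs a textbook full-matrix DP that tracks exact gap
counts and the trailing-gap flag. Engine and oracle are compared as sets of
(site, total differences) on seeded random genomes with planted variants;
the acceptance script reports the agreement fraction over 20 genomes of
50 kb. The oracle returns lightweight records (site identity plus
mismatch/gap/total counts) rather than full alignments — it exists to
certify hit sets, not to produce reports.

## Classification

Group assignment follows universal criteria over the NGG hit list:

* **A** — every NGG hit has ≥ 1 difference in the 10-nt seed;
* **B** — every NGG hit has ≥ 1 difference in the 15-nt seed and ≥ 3
  differences in total;
* otherwise the spacer is **rejected** (written to a separate report, not
  dropped).

A spacer meeting A is labelled A even if it also meets B (the 10-nt-seed
rule is the more conservative criterion and ranks first). The criteria are
universal, so a mixed hit list — one hit protected only by a seed
difference, another only by the B criterion — is rejected; every emitted
spacer therefore literally satisfies "all NGG hits have seed10 ≥ 1, or all
have seed15 ≥ 1 and total ≥ 3".

The NAG subclass grades residual risk at NAG sites: 0 if every NAG hit
passes the A-style criterion (vacuously true with no NAG hits), 0.1 if
every hit passes the B-style criterion, 1 if every hit still has ≥ 2
differences anywhere, else 2 (some NAG site within one difference). The
1-vs-2 boundary is a documented interpretation — the class definitions fix
the order and the 0/0.1 criteria but not the lower boundary — and mirrors
the NGG logic while grading by the worst NAG site; it is deliberately kept
in one small function so alternative boundaries are a trivial override.

Targetability of an annotation is the fraction of transcription units whose
interval entirely contains the 20-nt protospacer of ≥ 1 admitted spacer on
either strand; the PAM may fall outside because the cut site lies within
the protospacer. The feature type collected from GFF3 is a parameter
(default `gene`), since annotations differ in which tier represents a
transcription unit.

## Synthetic benchmark

`build_benchmark` emulates a planted-off-target experiment on a synthetic
background:

* **Background** — i.i.d. random sequence, default 100 kb at GC 0.44
  (rice-like). A real plant chromosome would add repeat families and
  compositional heterogeneity; the planted-variant logic being tested does
  not depend on those, but absolute accidental-hit rates on real genomes
  will differ, so passing the benchmark says nothing about genome-scale
  hit counts in real annotation work.
* **Variants** — the target spacer plus one variant per kind: mm0–mm4
  (0–4 substitutions) and gap1–gap2 (1–2 deletions, i.e. RNA-bulge sites);
  insertion (DNA-bulge) variants ins1–ins2 are available on request since
  bulges occur in both directions. Differences are placed at
  `equally_spaced_positions`, the placement minimizing the longest intact
  run (lexicographically smallest minimizer, so truth sets are
  deterministic) — the adversarial case for seeded detection.
* **Planting** — each sequence plus a random NGG PAM overwrites the
  background at loci ≥ 100 nt from the ends and ~equally spread (≥ 100 nt
  apart), avoiding window overlap between truth intervals.
* **Verification and rejection sampling** — a construction is accepted only
  if every variant's edlib edit distance to the spacer equals its expected
  total, an exhaustive default-budget search finds every planted site with
  its expected mismatch/gap split, and no background window outside the
  planted inserts is as close to the spacer as any planted variant
  (total ≤ 4, the largest planted total). Overlapping-PAM views of planted
  material ("satellites") are planted sequence, not background, and are
  tolerated, as are background windows at the far edge of the search budget
  (totals 5–6): measured on random 100-kb backgrounds, totals ≤ 4 occur
  essentially never (0 in 500 kb) while totals 5–6 occur ~9 times per
  100 kb, so demanding a background empty to the full 4 + 2 budget would
  reject virtually every 100-kb draw without making the truth set any more
  exact. Construction is bit-reproducible from `rng_seed`.

`max_guaranteed_wordsize(L, d)` returns ⌈(L−d)/(d+1)⌉, the largest word
size detecting every placement of d differences; `verify=True` checks the
closed form against enumeration of all C(L, d) placements (used in tests
and the acceptance script; enumeration is exponential in d, so it is opt-in
rather than the default on every call).

## Problem sizes and defaults

| Parameter | Default | Meaning |
|---|---|---|
| `spacer_len` | 20 nt | SpCas9 spacer length; scanning and search are parameterized but all shipped analyses use 20 |
| `max_mismatches` | 4 | per-alignment mismatch budget |
| `max_gaps` | 2 | per-alignment single-base bulge budget |
| `word_size` | 5 | seeded mode; 5 is the largest size guaranteed for ≤ 3 differences in a 20-mer |
| `gc_content` | 0.44 | benchmark background composition |
| `background_length` | 100 kb | benchmark scale; the acceptance script uses 100 kb for detection and 20 × 50 kb for oracle agreement, sizes at which the full analysis completes in seconds per genome |

## Known limitations

* No cleavage-activity scoring (CFD/MIT-style) and no chromatin context:
  classes rank sequence specificity only.
* Only 3'-side 3-nt PAMs (NGG/NAG) are scanned; the engine is
  parameterized by PAM class but no 5'-PAM (Cas12a-style) support exists.
* Ambiguity codes other than N are rejected rather than expanded.
* Whole-genome classification is quadratic-ish (every NGG spacer searched
  against every site) and is intended for the toy-to-megabase scale; the
  per-query engine itself is linear in candidate sites and comfortably
  handles chromosome-scale site lists.
* The local aligner is intentionally ungapped; it exists to characterize
  segment-splitting behaviour, not as a detection path of its own.
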