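# Methods

## The problem

Short-read assemblers produce contigs: gap-free sequences that are far shorter
than chromosomes. Two further sources of information can organize them. Read
pairs (paired-end, mate-pair and BAC-end libraries) whose mates land on two
different contigs are *local* evidence that the contigs are near one another —
how near, and in which mutual orientation, is constrained by the library's
insert-size distribution. A genetic map provides *broad-scale* evidence: the
order of markers along linkage groups. `baylink` fuses the two: a Bayesian
model scores candidate contig joins from paired alignments, a greedy merger
builds superscaffolds, and map anchoring orders and orients the scaffolds into
chromosome-scale pseudomolecules with chimera surgery and colinearity QC.

## The link model

Every read pair whose mates map to different contigs implies one join
hypothesis: an ordered pair of contig ends plus a relative orientation (four
classes). For a mate at position `p` with aligned length `l` on a contig of
length `L`, the mate "points" toward the contig tail if its strand matches the
library's expected inward orientation, contributing flank `L − p` to the
implied span; otherwise toward the head, contributing `p + l`. The pair's
summed flank `s_i` relates to the outer insert span via `d_i = s_i + g`, where
`g` is the unknown gap between the two contig ends.

Each pair is modelled as a two-component mixture. With probability

    c_i = (1 − 10^(−q1/10)) · (1 − 10^(−q2/10))

(the product of the two mates' MAPQ-derived correctness probabilities) the
pair is a correctly mapped fragment whose span follows the library's
`Normal(μ, σ²)`; with probability `1 − c_i` it is mapping noise whose implied
span is uniform over a window `W = μ + 3σ`. The per-pair Bayes factor in
favour of the join being real is therefore

    f_i = c_i · N(d_i; μ, σ²) · W + (1 − c_i)

and the bundle's posterior combines the cumulative Bayes factor
`B = ∏ f_i` with a prior `π` on any candidate adjacency being real:

    posterior = πB / (πB + 1 − π).

`B` is accumulated in log space; the posterior is evaluated on the log-odds
scale (`logit⁻¹(logit(π) + log B)`) so extreme evidence cannot overflow. A
bundle with no pairs carries `B = 1` and returns the prior exactly.

`d_i` is evaluated at the bundle's own gap estimate — an empirical-Bayes
plug-in rather than an integral over `g`. The plug-in has a closed form, is
directly testable against a grid search, and is standard practice in
scaffolders; integrating over the gap would change posteriors only marginally
because the per-bundle gap standard error (`σ/√k`) is small at the pair counts
that matter.

### Insert-size estimation

Each library's declared `(μ, σ)` is replaced by a robust fit whenever at least
`min_fit_pairs` (default 50) same-contig, orientation-consistent pairs are
available: `μ = median(spans)`, `σ = 1.4826 × MAD` floored at 1. Sparse
long-insert libraries (BAC ends rarely fit inside a contig) simply keep their
declared profile — in simulation that profile is exact, and on real data BAC
insert declarations are typically vector-derived and reliable.

### Bundling, filtering, fusion

Cross-contig pairs are grouped by (unordered contig pair, end/end combination,
library). A pair whose flank sum cannot be reconciled with any gap
`≥ −max_overlap` (i.e. `s_i > μ + 4σ + max_overlap`) is discarded as
inconsistent before grouping. Bundles with fewer than `min_pairs` (default 2;
1 for BAC-end libraries, which are genome-wide sparse by construction) are
dropped. Per-library bundles for the same end pair are fused by multiplying
Bayes factors — the prior is applied once — and gap estimates combine by
inverse-variance weighting, which is the joint Normal MLE. This is how
evidence from heterogeneous platforms (short-insert, mate-pair, BAC ends)
merges into a single posterior per candidate join.

### Gap estimation

Maximizing `Σ_i log N(s_i + g; μ, σ²)` gives `ĝ = μ − mean(s_i)`, clipped at
`−max_overlap` (default: the library's read length, the most overlap a join
could hide without the mates themselves overlapping the junction);
`sd(ĝ) = σ/√k`.

## Scaffolding

Repeat-like contigs are masked before merging: coverage above
`repeat_cov_factor` (default 2.5) times the median, or a contig end carrying
more than `max_degree` (default 3) *confident* bundles (posterior at or above
the acceptance threshold). Only confident bundles count toward the degree:
long-insert libraries legitimately produce lower-evidence bundles between
non-adjacent contigs two slots apart, and sub-threshold noise bundles are
common at permissive `min_pairs`; counting those would mask perfectly unique
contigs.

Accepted joins are chosen greedily: bundles sorted by (posterior desc, pair
count desc, total correctness mass desc, lexicographic ids) are taken iff the
posterior clears `posterior_threshold` (default 0.99), neither contig is
masked, both implicated ends are free, and a disjoint-set check shows the join
would not close a cycle. Greedy best-first matches the accept/reject structure
a posterior threshold implies, and is deterministic. The pair-count tie-break
does real work: with deep data many true joins saturate the posterior at 1.0
in double precision, and adjacent joins (supported by mate pairs *and* BAC
ends) then outrank long-range BAC-only "skip" links that would otherwise
compete for the same contig ends.

A layout and its mirror (reversed order, flipped orientations) describe the
same molecule. The canonical representative prefers the one whose first contig
is `+`; when both or neither qualify (e.g. `[A−, B+]` versus its mirror
`[B−, A+]`, neither of which starts `+`), the one whose first terminal contig
id sorts lower wins. Negative gap estimates (possible overlaps) never trigger
contig merging; they are floored to the 13-base AGP minimum informative gap at
write time, with the estimate preserved in the layout.

## Anchoring

Sequence markers are located by exact match against both strands of every
scaffold: one hit places the marker, several make it ambiguous (excluded from
anchoring), none leaves it unplaced. Coordinate markers lift through their
contig's slot: a marker at contig offset `o` on a `−`-oriented contig of
length `L` starting at scaffold offset `t` maps to `t + L − 1 − o`.

A scaffold is chimeric when its placed markers span two linkage groups, or
when same-group markers regress by more than `chimera_cm_window` (default
20 cM) against the scaffold's dominant cM direction (detected via the sign of
the position–cM rank correlation, with a running-extremum scan). The 20 cM
default is deliberately wide: recombination-suppressed pericentromeres make
long runs of nearly equal cM positions normal, so only large discordances
should trigger surgery. The scaffold is split at the lowest-posterior accepted
join lying strictly between the offending marker positions, repeatedly until
no conflict remains; breaking removes a gap, never sequence. A conflict with
no intervening join (both markers inside one contig) is flagged unresolvable
and the scaffold is excluded from anchoring rather than broken arbitrarily.

Within each linkage group, scaffolds are ordered by the mean cM of their
placed markers (mean, not median: markers per scaffold are few, and the mean
uses all of them; ties go to the longer scaffold, then the lower id).
Orientation is the sign of the cM-versus-position slope over markers with at
least two distinct cM values; single-marker or equal-cM scaffolds get `+` with
confidence `single_marker`, recorded so downstream consumers know the
orientation is arbitrary. Pseudomolecules are emitted with a fixed 10 kb
inter-scaffold gap (AGP `contig`/`no`/`map` evidence), distinct from the
estimated paired-read gaps inside scaffolds (`scaffold`/`yes`/
`paired-ends;map`).

Colinearity QC computes Spearman's rho (midrank ties) between physical
position and cM per chromosome, defined only with ≥3 placed markers; a marker
whose removal raises rho by more than `discord_eps` (default 0.01) is listed
as discordant. Held-out markers — markers never used for anchoring — are
evaluated through exactly the same code path and reported separately, which is
the standard independent check that the anchoring is not merely self-
consistent.

## The simulator

The generator emulates the conditions the pipeline is designed for:

- **Genome**: i.i.d. bases at a configurable GC (default 0.36, a typical
  crucifer value), optionally with a central block of 99 %-identical tandem
  repeat copies emulating a pericentromere.
- **Contigs**: left-to-right tiling with sampled inter-contig gaps (default
  100–300 bp), a fraction (default 0.3) stored reverse-complemented to
  exercise orientation logic. Concatenating truth-ordered, truth-oriented
  contigs plus gaps reconstructs the genome exactly.
- **Read pairs**: uniform fragment midpoints, Normal outer spans, mates
  projected into contig coordinates through the truth and emitted *as
  alignments* — downstream code never sees the truth, and no external mapper
  enters the test loop (a FASTQ emitter exists for end-to-end demos). With
  probability `mismap_rate` one mate teleports to a uniform random contig
  position with MAPQ ≤ 3; correct mates carry MAPQ 40.
- **Genetic map**: uniform marker positions; cM accumulates at `cm_per_mb`
  (default 4) outside a suppressed interval (default the central 20 % of each
  chromosome, rate ×0.01), giving the flat pericentromeric cM profiles real
  maps show. Markers carry their 31-mer so sequence placement works.

The standard study conditions (used by the truth-recovery check and the
acceptance script) are: 2 chromosomes × 500 kb, 20 contigs each, a 3000 ± 300
mate-pair library at 20× sequence coverage, a 30 000 ± 3 000 BAC-end-like
library at 0.5×, 15 anchoring plus 3 held-out markers per chromosome, 2 %
mismapping, read length 100. The robustness check runs a reduced scenario
(2 × 150 kb, 10 contigs each) over five seeds and mismap rates {0, 0.05, 0.2}.
All randomness flows from one integer seed through a named generator per
sub-stage, so every stage is independently reproducible.

### What the simulator does not emulate

Base-calling errors, chimeric PCR fragments, optical duplicates, heterozygous
or polyploid genomes, GC-coverage bias, and genuinely nested or dispersed
repeat families. Passing tests therefore demonstrate the correctness of the
inference machinery under its own model assumptions — clean Normal inserts,
honest MAPQ values, uniform coverage — not performance on arbitrary real
libraries, where insert distributions are skewed and MAPQ calibration varies
by mapper.

## Numerical and degenerate-input choices

- Likelihoods in log space; posteriors via the log-odds scale.
- Per-pair Bayes factor floored at 1e−300 before taking logs.
- Zero MAD floors the fitted sigma at 1.0; an underpowered fit keeps declared
  library values with a logged warning.
- Ties in greedy acceptance broken by pair count, then total correctness
  mass, then lexicographic contig ids — the output is byte-identical across
  runs for identical input.
- Empty linkage groups yield empty pseudomolecules with a warning; fewer than
  three markers leave rho reported as undefined rather than numeric.
- "No joins" precision is reported as 1.0 with an explicit flag (a fragmented
  but join-free result is not a precision failure; 0/0 would poison summary
  statistics).

## Known limitations

- Single-pass scaffolding: reads are not re-mapped to superscaffolds for a
  second linking round.
- No gap filling and no split-read evidence; misassembly detection uses the
  map only.
- Greedy merging is not a global optimum over the link graph; with deep,
  consistent data this does not matter in practice, and it keeps accept /
  reject decisions individually explainable.
- The repeat mask is coarse (coverage plus link degree); dispersed repeat
  families shorter than a contig are handled only insofar as they inflate
  coverage or degree.
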