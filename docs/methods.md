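# Methods

`spacernet` infers putative interactions between bacterial hosts and mobile
genetic elements (MGEs: phages and plasmids) from the genetic memory stored
in CRISPR arrays. A CRISPR array is a locus of near-identical repeats
(typically 23–55 bp) separated by variable spacers (18–72 bp); each spacer
is usually a copy of a segment (the protospacer) of a past invader's genome.
Matching spacers against an MGE sequence collection therefore links hosts to
the elements that invaded them. The pipeline runs in four stages: array
detection, spacer deduplication, protospacer search with statistical
filtering, and greedy network summarisation.

## CRISPR array detection

**De novo mode** finds arrays purely from the repeat–spacer repetitive
structure. Exact k-mer seeds (k = 13) whose occurrences on a contig recur
with a period compatible with one repeat plus one spacer
(41–127 bp by default) are chained, and the repeat around each seed is grown
by *maximal unanimous extension*: a column is added to the repeat while every
occurrence carries the same base, stopping at the contig bounds, the maximum
repeat length, or where further growth would squeeze a spacer below its
minimum length. Candidate arrays from different seeds of the same repeat
converge to identical boundaries and are deduplicated; overlapping
candidates are resolved in favour of more repeats. An array needs at least
3 repeats (`min_repeats`). This is the classical strategy of repeat-finding
CRISPR detectors, specialised to exact repeats with a mismatch-tolerant
guided mode alongside.

A detected boundary is only well defined when the column just outside the
repeat is not unanimous across units: if every spacer began with the same
base, a description with a one-base-longer repeat and one-base-shorter
spacers would be equally valid. The synthetic generator therefore resamples
the flanking base adjacent to each planted array when it would create such
an ambiguity, which makes "exact boundary recovery" a well-posed target. On
real data the ambiguity is inherent and affects at most a base or two of
spacer ends; downstream matching is insensitive to it because the coverage
filter (below) tolerates a one-base-trimmed spacer.

**Guided mode** scans both strands for windows within `max_repeat_mismatch`
(default 3) substitutions of a known repeat — a Hamming scan rather than
gapped alignment, appropriate because usable guide repeats are identical or
nearly identical to the array's repeats. Matches separated by valid spacer
gaps are chained; the array inherits the repeat's CRISPR-Cas type label
(e.g. I-C, II-C, V-A), which later lets modules be broken down by the
system type that acquired each spacer. Minus-strand arrays are reported
with spacers reverse-complemented and ordered along the repeat orientation.

**Artifact filtering.** Tandem repeats and other repetitive loci can mimic
the repeat–spacer structure. Genuine spacers are independent segments of
(usually different) invader genomes, so they should look mutually random:
an array is discarded when the mean pairwise spacer identity exceeds 0.60,
or when spacers resemble the consensus repeat above the same threshold.
Identity here is ungapped positional identity (matching positions divided by
the longer length): random same-length DNA scores ≈ 0.25 under this measure,
giving a wide margin to the 0.60 cutoff, whereas gapped/LCS-style identity
of random 4-letter strings is ≈ 0.65 and could not separate the two cases.

**Deduplication.** Spacers are collapsed into 100%-identity clusters
(byte-identical after uppercasing; an `exact_rc` mode additionally merges
reverse complements, keeping the lexicographically smaller orientation as
representative). Substring containment is deliberately not collapsed: two
spacers of different lengths are different sampling events, and keeping them
separate preserves per-cluster host provenance. All unique spacers — not a
per-host subset — are searched, which maximises sensitivity.

## Protospacer search and filtering

The built-in search is a seed-and-extend aligner specialised for short,
near-exact nucleotide queries. Exact `word_size`-mer matches (default 7, the
short-query BLASTN convention) between a spacer cluster representative and
an MGE sequence, on both strands, nominate diagonals; each diagonal is
extended **ungapped** across the full query span, clipped only at subject
edges. Overlapping alignments for the same (cluster, MGE, strand) are merged
keeping the best score. Hits are retained when

- identity (matches / alignment length) **> 0.90**,
- per-HSP query coverage **> 0.80**, and
- e-value **< 10⁻³**

with all three inequalities strict. For a 32-bp spacer this admits up to 3
substitutions (29/32 = 0.906) and rejects 4 (28/32 = 0.875) — enough slack
for mutation and sequencing error without admitting chance matches.

Two numerical choices deserve comment:

*Word size 7.* By pigeonhole, any ≥ 18-bp spacer whose best locus passes the
identity filter retains an exact 7-mer; seeding is therefore lossless for
reportable hits. With word size 11 an evenly spread 3-substitution pattern
on a 32-bp spacer leaves no exact seed and the locus would be silently
missed.

*Ungapped extension.* A score-optimal gapped extension can realign two
adjacent substitutions that form a transposition (e.g. `CT → TC`) as a
spurious 1-bp indel: 30 identities over 33 columns (0.909) out-scores the
honest 28/32 (0.875) ungapped reading and crosses the 90% threshold. Since
spacer/protospacer divergence is substitution-dominated and the steep gap
penalties make gaps useless for genuine hits, the engine is ungapped, which
preserves the exact mismatch-count semantics of the identity filter. The
gap penalties in `SearchParams` describe the scoring scheme of ingested
external tabular hits (12-column alignment format), which the pipeline
accepts as a drop-in replacement for the built-in search.

**Significance.** E-values follow Karlin–Altschul statistics for ungapped
alignments under uniform base composition: λ is the unique positive root of
¼·e^{λ·match} + ¾·e^{λ·mismatch} = 1 (solved numerically; λ ≈ 1.3327 for
+1/−2), E = K·m·n·e^{−λS} with m the spacer length and n the total database
length, and bitscore = (λS − ln K)/ln 2. K is a configurable constant
(default 0.46, the tabulated ungapped value for this scheme); computing K
exactly would change e-values by far less than the three-order-of-magnitude
margin typical passing hits enjoy against the 10⁻³ cutoff. No edge-effect
or composition correction is applied, for the same reason.

## Greedy covering selection and networks

Public MGE collections are highly redundant, so a network containing every
MGE with a matching protospacer would be unreadable. Instead a greedy
set-cover heuristic selects a small explanatory set: repeatedly pick the
MGE covering the largest number of not-yet-covered matched spacer clusters
until every matched cluster is covered, breaking ties by lexicographically
smallest identifier for reproducibility. The same rule selects a minimal
host set (a host covers the matched clusters to which it contributes a
member spacer). The greedy rule carries the classical (1 + ln d)
approximation guarantee, which the test suite verifies against exhaustive
optima on small instances.

The cover universe is the set of *matched spacer clusters*, not individual
protospacer loci: a cluster is "explained" once one selected MGE contains a
matching segment, which is the semantics the networks need. Hosts whose
spacers match nothing cannot enter the network (every node has degree ≥ 1).
Phages and plasmids compete in one selection pool.

Two bipartite networks are emitted. In the **spacer–MGE network**, nodes
are matched spacer clusters and selected MGEs; an edge means the MGE
carries a protospacer for the cluster, weighted by the number of matched
loci (`n_matches`). In the **host–MGE network**, an edge joins a selected
host and selected MGE when the pair shares at least one matching
spacer/protospacer, weighted by distinct (cluster, locus) pairs. Connected
components ("modules") are numbered by decreasing size with lexicographic
tie-breaks, and per-module reports count spacers by CRISPR type and MGEs by
class — e.g. to ask whether one CRISPR-Cas system dominates the response to
a group of phages. Networks are written as GML (lossless round trip) and as
node/edge TSV tables for Cytoscape.

## Synthetic data generator

The generator emulates exactly the statistical structure the method relies
on — spacers are near-exact copies of invader segments — without any claim
to phage biology. MGEs are i.i.d. uniform DNA (default 50 real elements of
2–4 kb plus 10 decoys that are never sampled); each of 20 hosts carries one
CRISPR array whose 3–8 spacers (32 bp) are segments drawn uniformly from
random real MGEs on either strand, substituted per base at `sub_rate`
(default 0, i.e. exact copies), with 10% random decoy spacers. Repeats come
from a generated 3-entry library labelled I-C / II-C / V-A. A ground-truth
table records every implanted (host, MGE, locus, strand, substitutions)
tuple. Everything derives from a single seed; identical seeds give
byte-identical files.

The mutation model has no indels (the identity filter's mismatch semantics
are exercised exactly by Hamming mutations), decoys are uniform random DNA
rather than shuffled genomes, and array geometry is regular. Passing the
end-to-end tests therefore demonstrates correctness of the machinery —
detection, dedup, search, filters, selection, network assembly — under the
model's assumptions, not robustness to real phage genome architecture,
PAMs, repeat degeneracy, or assembly artifacts.

## Determinism and degenerate inputs

Every stage is deterministic: candidate and hit orderings are fully
specified, greedy ties are lexicographic, and output files are written in
sorted order, so identical inputs give byte-identical artifacts. Empty
intermediate results (no arrays, no matches) propagate as empty-but-valid
files and zero counts rather than errors; spacers shorter than the seed
word are skipped with a warning; malformed tabular hit lines and unknown
query identifiers are reported with file and line number.

## Problem sizes

The bundled tests and the reproduction script run entirely on synthetic
communities of 20 hosts and 50 + 10 MGEs (≈ 100 kb of host sequence, ≈ 180 kb
of database per replicate), 100-contig detection panels, 200-replicate
filter-boundary experiments, and 200 random cover instances — sizes chosen
so the whole suite completes in well under a minute per component on one
CPU while still exercising every code path at the scale the guarantees are
stated for. Real deployments substitute multi-FASTA genome collections and
MGE databases of arbitrary size; stages stream one contig/MGE at a time and
memory stays proportional to the largest single sequence plus the hit list.

## Known limitations

- No cas-gene annotation or CRISPR-Cas subtype calling: type labels are
  metadata supplied by the repeat library (or absent).
- De novo detection targets arrays with (near-)identical repeats; heavily
  degenerated repeats are better served by guided mode.
- The search is ungapped by design; protospacers that diverged by indels
  are only found via externally supplied gapped tabular hits.
- Greedy selection deliberately discards redundant MGEs; interactions
  involving unselected MGEs remain available in the filtered-hits table.
- E-value calibration (K, edge effects) is approximate, which is
  immaterial at the coarse 10⁻³ threshold but makes reported e-values
  indicative rather than exact.
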