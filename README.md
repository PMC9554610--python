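# spacernet

Inference of bacteria–MGE (phage/plasmid) interaction networks from CRISPR
spacers.

Bacteria record past invasions in their CRISPR arrays: each spacer between
two repeats is typically a copy of a segment — the *protospacer* — of an
invading mobile genetic element (MGE). Given host genomes, MAGs or
metagenome assemblies plus an MGE sequence collection, `spacernet` detects
CRISPR arrays, extracts and deduplicates spacers, matches them against the
MGEs, and summarises the matches into two bipartite interaction networks
whose modules group co-interacting hosts, spacers and invaders. It is aimed
at microbiome researchers studying phage–host interactions who want a
self-contained, reproducible pipeline from FASTA to Cytoscape-ready
networks.

## Method in brief

1. **Array detection** — de novo from the repeat–spacer repetitive
   structure (k-mer seeds recurring with a repeat+spacer period, grown by
   unanimous extension), or guided by a library of known repeats (Hamming
   scan, ≤ 3 substitutions, both strands) that also supplies CRISPR-Cas
   type labels. Tandem-repeat artifacts are removed by spacer-similarity
   rules.
2. **Deduplication** — spacers collapse into 100%-identity clusters; all
   unique spacers are searched.
3. **Protospacer search** — seed-and-extend (exact 7-mers, ungapped
   full-query extension, both strands). A hit is retained when identity
   > 90%, per-HSP query coverage > 80% and Karlin–Altschul e-value < 10⁻³
   (λ the positive root of ¼e^{λm} + ¾e^{λs} = 1; E = K·m·n·e^{−λS}). For
   a 32-bp spacer this admits ≤ 3 substitutions and rejects ≥ 4.
   Precomputed 12-column tabular hits are accepted in place of the
   built-in search.
4. **Greedy selection and networks** — a greedy set cover picks the
   minimum-redundancy MGE set explaining every matched spacer cluster
   (repeatedly take the MGE covering the most uncovered clusters;
   lexicographic ties), and likewise a minimal host set. Spacer–MGE and
   host–MGE networks are emitted as GML and TSV with per-module summaries
   (connected components, spacer counts by CRISPR type, MGEs by class).

A seeded synthetic-community generator (hosts whose arrays carry mutated
copies of MGE segments, plus decoy MGEs and decoy spacers, with a
ground-truth table) makes every stage testable without downloading any
reference database. See `docs/methods.md` for assumptions, parameters and
limitations.

## Worked example

Simulate a 20-host community (50 real MGEs + 10 decoys, exact 32-bp
spacers) and run the full pipeline with repeat-guided detection:

```sh
spacernet simulate --seed 7 -o sim
spacernet run --genomes sim/hosts.fasta --mge-fasta sim/mges.fasta \
    --mge-metadata sim/mge_metadata.tsv --repeats sim/repeats.fasta \
    --mode guided -o out
```

which prints the run manifest:

```json
{
  "dedup_mode": "exact",
  "detection_mode": "guided",
  "n_arrays": 20,
  "n_clusters": 128,
  "n_components_host_mge": 1,
  "n_components_spacer_mge": 45,
  "n_contigs": 20,
  "n_matched_clusters": 119,
  "n_passing_hits": 119,
  "n_selected_hosts": 20,
  "n_selected_mges": 45,
  "n_selected_mges_by_class": {
    "phage": 29,
    "plasmid": 16
  },
  "n_spacers": 128
}
```

All 20 hosts carry one array; their 128 spacers are all unique (128
clusters), 119 of them match an implanted protospacer (the other 9 are the
simulation's random decoy spacers, which correctly match nothing), and the
greedy cover explains those 119 clusters with 45 of the 50 real MGEs — no
decoy MGE is ever selected. `out/` then contains `arrays.tsv`/`arrays.gff`,
`spacers.fasta`, `filtered_hits.tsv`, `spacer_mge.gml`, `host_mge.gml`,
`components.tsv`, `selected_mges.fasta`, and `manifest.json`. The first
line of `components.tsv`,

```
component_id  n_nodes  n_hosts  n_spacers  n_mges  n_phages  n_plasmids
C1            65       20       0          45      29        16
```

shows a single host–MGE module connecting all 20 hosts to the 45 selected
MGEs. Stages can also be run separately (`spacernet detect`, `search`,
`network`), and the same functionality is available as a library
(`import spacernet`).

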