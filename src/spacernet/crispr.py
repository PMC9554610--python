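"""CRISPR array detection, artifact filtering, and spacer extraction.

Two detection modes are provided. De novo detection finds arrays purely from
the repeat--spacer repetitive structure: exact k-mer seeds that recur with a
period compatible with one repeat plus one spacer are chained, and the repeat
is grown around each seed by maximal unanimous extension across all
occurrences. Guided detection scans the contig (both strands) for windows
within a small Hamming distance of a known repeat and chains the matches; it
yields precise spacer boundaries and inherits the repeat's CRISPR type label.

Artifact filtering removes repeat-like false positives (tandem repeats) using
two similarity rules on the putative spacers. Deduplication collapses spacers
into exact-sequence clusters (optionally merging reverse complements).
"""

from __future__ import annotations

import itertools
from collections import defaultdict
from dataclasses import dataclass

import numpy as np

from .records import (
    CRISPRArray,
    RepeatEntry,
    SequenceRecord,
    Spacer,
    SpacerCluster,
    revcomp,
)


@dataclass
class DetectionParams:
    """Tunable parameters for CRISPR array detection.

    Defaults reflect canonical CRISPR geometry: repeats of 23-55 bp, spacers
    of 18-72 bp, at least 3 repeats per array.
    """

    min_repeat_len: int = 23
    max_repeat_len: int = 55
    min_spacer_len: int = 18
    max_spacer_len: int = 72
    min_repeats: int = 3
    seed_k: int = 13
    max_repeat_mismatch: int = 3
    spacer_sim_cutoff: float = 0.60
    repeat_spacer_sim_cutoff: float = 0.60

    @property
    def min_period(self) -> int:
        return self.min_repeat_len + self.min_spacer_len

    @property
    def max_period(self) -> int:
        return self.max_repeat_len + self.max_spacer_len


def _unanimous(seq: str, cols: list[int]) -> bool:
    first = seq[cols[0]]
    return all(seq[c] == first for c in cols[1:])


def _extend_chain(
    seq: str, pos: list[int], k: int, params: DetectionParams
) -> tuple[int, list[int]] | None:
    """Grow a seed chain into (repeat_length, repeat_starts) or None.

    Extension adds a column while every occurrence carries the same base,
    stopping at the sequence bounds, the maximum repeat length, or the point
    where further growth would squeeze a spacer below its minimum length.
    """
    gmin = min(b - a for a, b in zip(pos, pos[1:]))
    cap = min(params.max_repeat_len, gmin - params.min_spacer_len)
    if cap < k:
        return None
    off_l = 0
    while (
        k + off_l < cap
        and pos[0] - off_l - 1 >= 0
        and _unanimous(seq, [p - off_l - 1 for p in pos])
    ):
        off_l += 1
    off_r = 0
    while (
        k + off_l + off_r < cap
        and pos[-1] + k + off_r < len(seq)
        and _unanimous(seq, [p + k + off_r for p in pos])
    ):
        off_r += 1
    rep_len = k + off_l + off_r
    if rep_len < params.min_repeat_len:
        return None
    return rep_len, [p - off_l for p in pos]


def find_denovo_arrays(
    contig: SequenceRecord,
    params: DetectionParams | None = None,
    host_id: str | None = None,
) -> list[CRISPRArray]:
    """Detect CRISPR arrays from the repeat--spacer structure alone.

    Returns non-overlapping arrays left-to-right; no arrays is an empty list.
    """
    params = params or DetectionParams()
    host_id = host_id if host_id is not None else contig.id
    seq = contig.seq
    n = len(seq)
    if n < 2 * params.min_repeat_len + params.min_spacer_len:
        return []

    k = params.seed_k
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(n - k + 1):
        word = seq[i : i + k]
        if "N" not in word:
            index[word].append(i)

    # Chain seed occurrences whose consecutive gaps look like one
    # repeat+spacer period, then grow each chain into a full repeat.
    candidates: dict[tuple[int, int, tuple[int, ...]], None] = {}
    for word, pos in index.items():
        if len(pos) < params.min_repeats:
            continue
        chain = [pos[0]]
        chains = []
        for p in pos[1:]:
            if params.min_period <= p - chain[-1] <= params.max_period:
                chain.append(p)
            else:
                chains.append(chain)
                chain = [p]
        chains.append(chain)
        for ch in chains:
            if len(ch) < params.min_repeats:
                continue
            grown = _extend_chain(seq, ch, k, params)
            if grown is None:
                continue
            rep_len, starts = grown
            candidates[(rep_len, starts[0], tuple(starts))] = None

    arrays: list[CRISPRArray] = []
    # Prefer candidates with more repeats; keep non-overlapping ones.
    ranked = sorted(
        candidates, key=lambda c: (-len(c[2]), c[1], c[0])
    )
    taken: list[tuple[int, int]] = []
    for rep_len, _, starts in ranked:
        a_start, a_end = starts[0], starts[-1] + rep_len
        if any(a_start < e and s < a_end for s, e in taken):
            continue
        spacers = []
        ok = True
        for a, b in zip(starts, starts[1:]):
            s0, s1 = a + rep_len, b
            if not (params.min_spacer_len <= s1 - s0 <= params.max_spacer_len):
                ok = False
                break
            spacers.append((s0, seq[s0:s1]))
        if not ok:
            continue
        taken.append((a_start, a_end))
        arrays.append(
            CRISPRArray(
                array_id="",
                host_id=host_id,
                contig_id=contig.id,
                start=a_start,
                end=a_end,
                repeats=[(s, seq[s : s + rep_len]) for s in starts],
                spacers=spacers,
                consensus_repeat=seq[starts[0] : starts[0] + rep_len],
                mode="denovo",
            )
        )

    arrays.sort(key=lambda a: a.start)
    for i, arr in enumerate(arrays):
        arr.array_id = f"{contig.id}|arr{i + 1}"
        arr.validate()
    return arrays


def _hamming_scan(seq_arr: np.ndarray, pattern: str) -> np.ndarray:
    """Mismatch count of ``pattern`` against every window of ``seq_arr``."""
    L = len(pattern)
    n_win = len(seq_arr) - L + 1
    if n_win <= 0:
        return np.empty(0, dtype=np.int32)
    pat = np.frombuffer(pattern.encode(), dtype=np.uint8)
    mism = np.zeros(n_win, dtype=np.int32)
    for j in range(L):
        mism += seq_arr[j : j + n_win] != pat[j]
    return mism


def find_guided_arrays(
    contig: SequenceRecord,
    library: list[RepeatEntry],
    params: DetectionParams | None = None,
    host_id: str | None = None,
) -> list[CRISPRArray]:
    """Detect arrays whose repeats match a known-repeat library.

    Every repeat of a returned array lies within ``max_repeat_mismatch``
    substitutions of a library entry on one strand; the array inherits that
    entry's CRISPR type. Minus-strand arrays are reported with spacers
    reverse-complemented and ordered along the repeat orientation.
    """
    params = params or DetectionParams()
    host_id = host_id if host_id is not None else contig.id
    if not library:
        raise ValueError("guided detection requires a non-empty repeat library")
    for entry in library:
        if len(entry.seq) < RepeatEntry.MIN_LEN:
            raise ValueError(f"repeat {entry.id!r} shorter than 16 bp")

    seq = contig.seq
    seq_arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    candidates: list[tuple[int, CRISPRArray]] = []

    for entry in library:
        for strand in "+-":
            pattern = entry.seq if strand == "+" else revcomp(entry.seq)
            L = len(pattern)
            mism = _hamming_scan(seq_arr, pattern)
            hit_pos = np.nonzero(mism <= params.max_repeat_mismatch)[0]
            if hit_pos.size < params.min_repeats:
                continue
            # Collapse clusters of near-identical positions (keep best).
            merged: list[int] = []
            for p in hit_pos.tolist():
                if merged and p - merged[-1] < L:
                    if mism[p] < mism[merged[-1]]:
                        merged[-1] = p
                else:
                    merged.append(p)
            # Chain matches separated by a valid spacer gap.
            chain = [merged[0]]
            chains = []
            for p in merged[1:]:
                gap = p - (chain[-1] + L)
                if params.min_spacer_len <= gap <= params.max_spacer_len:
                    chain.append(p)
                else:
                    chains.append(chain)
                    chain = [p]
            chains.append(chain)
            for ch in chains:
                if len(ch) < params.min_repeats:
                    continue
                total_mm = int(sum(mism[p] for p in ch))
                arr = _guided_array(
                    contig, host_id, seq, ch, L, entry, strand, params
                )
                candidates.append((total_mm, arr))

    # Resolve overlaps across entries/strands: more repeats, then fewer
    # total mismatches, then leftmost.
    candidates.sort(key=lambda t: (-t[1].n_repeats, t[0], t[1].start))
    arrays: list[CRISPRArray] = []
    taken: list[tuple[int, int]] = []
    for _, arr in candidates:
        if any(arr.start < e and s < arr.end for s, e in taken):
            continue
        taken.append((arr.start, arr.end))
        arrays.append(arr)
    arrays.sort(key=lambda a: a.start)
    for i, arr in enumerate(arrays):
        arr.array_id = f"{contig.id}|arr{i + 1}"
        arr.validate()
    return arrays


def _guided_array(
    contig: SequenceRecord,
    host_id: str,
    seq: str,
    repeat_starts: list[int],
    rep_len: int,
    entry: RepeatEntry,
    strand: str,
    params: DetectionParams,
) -> CRISPRArray:
    repeats_fw = [(p, seq[p : p + rep_len]) for p in repeat_starts]
    spacers_fw = []
    for a, b in zip(repeat_starts, repeat_starts[1:]):
        s0, s1 = a + rep_len, b
        spacers_fw.append((s0, seq[s0:s1]))
    if strand == "+":
        repeats, spacers = repeats_fw, spacers_fw
    else:
        repeats = [(p, revcomp(s)) for p, s in reversed(repeats_fw)]
        spacers = [(p, revcomp(s)) for p, s in reversed(spacers_fw)]
    return CRISPRArray(
        array_id="",
        host_id=host_id,
        contig_id=contig.id,
        start=repeat_starts[0],
        end=repeat_starts[-1] + rep_len,
        repeats=repeats,
        spacers=spacers,
        consensus_repeat=entry.seq,
        crispr_type=entry.crispr_type,
        mode="guided",
        strand=strand,
    )


def _positional_identity(a: str, b: str) -> float:
    """Ungapped identity: matching positions at offset 0 over the longer length."""
    if not a or not b:
        return 0.0
    matches = sum(x == y for x, y in zip(a, b))
    return matches / max(len(a), len(b))


def filter_artifacts(
    arrays: list[CRISPRArray], params: DetectionParams | None = None
) -> list[CRISPRArray]:
    """Drop repeat-like false positives (e.g. tandem repeats).

    An array is removed when its putative spacers are too similar to each
    other (mean pairwise identity > ``spacer_sim_cutoff``) or too similar to
    the consensus repeat (mean identity > ``repeat_spacer_sim_cutoff``):
    genuine spacers are independent invader-derived segments and should look
    mutually random. Retained arrays are passed through unchanged.
    """
    params = params or DetectionParams()
    kept = []
    for arr in arrays:
        spacer_seqs = [s for _, s in arr.spacers]
        if len(spacer_seqs) >= 2:
            pair_ids = [
                _positional_identity(a, b)
                for a, b in itertools.combinations(spacer_seqs, 2)
            ]
            if sum(pair_ids) / len(pair_ids) > params.spacer_sim_cutoff:
                continue
        if spacer_seqs:
            rep_ids = [
                _positional_identity(s, arr.consensus_repeat)
                for s in spacer_seqs
            ]
            if sum(rep_ids) / len(rep_ids) > params.repeat_spacer_sim_cutoff:
                continue
        kept.append(arr)
    return kept


def extract_spacers(arrays: list[CRISPRArray]) -> list[Spacer]:
    """One Spacer per spacer slot, inheriting host/array/type metadata."""
    spacers = []
    for arr in arrays:
        for i, (_, seq) in enumerate(arr.spacers):
            spacers.append(
                Spacer(
                    spacer_id=f"{arr.array_id}|sp{i}",
                    seq=seq,
                    host_id=arr.host_id,
                    array_id=arr.array_id,
                    index_in_array=i,
                    crispr_type=arr.crispr_type,
                )
            )
    return spacers


def deduplicate_spacers(
    spacers: list[Spacer], mode: str = "exact"
) -> list[SpacerCluster]:
    """Collapse spacers into 100%-identity clusters.

    mode="exact": byte-identical after uppercasing. mode="exact_rc": also
    merge reverse complements; the representative is the lexicographically
    smaller orientation. Output is ordered by representative sequence.
    """
    if mode not in ("exact", "exact_rc"):
        raise ValueError(f"unknown dedup mode {mode!r}")
    groups: dict[str, list[Spacer]] = defaultdict(list)
    for sp in spacers:
        key = sp.seq.upper()
        if mode == "exact_rc":
            key = min(key, revcomp(key))
        groups[key].append(sp)
    clusters = []
    for i, rep in enumerate(sorted(groups)):
        members = groups[rep]
        clusters.append(
            SpacerCluster(
                cluster_id=f"SC{i + 1:06d}",
                rep_seq=rep,
                members=[sp.spacer_id for sp in members],
                crispr_types={
                    sp.crispr_type for sp in members if sp.crispr_type
                },
            )
        )
    return clusters


def cluster_hosts_map(
    clusters: list[SpacerCluster], spacers: list[Spacer]
) -> dict[str, set[str]]:
    """Map cluster_id -> set of host ids contributing a member spacer."""
    by_id = {sp.spacer_id: sp for sp in spacers}
    return {
        c.cluster_id: {by_id[m].host_id for m in c.members} for c in clusters
    }
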