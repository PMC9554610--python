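"""Shared fixtures and independent oracles for the test suite.

The oracles here re-derive expected results by brute force (all-offsets
Hamming scans, bisection root-finding, BFS) and deliberately share no code
with the package paths they check.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

COMPLEMENT = str.maketrans("ACGT", "TGCA")


def rc(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


# ---------------------------------------------------------------- oracles


def bisect_lambda(match: int, mismatch: int, iters: int = 200) -> float:
    """Karlin-Altschul lambda by plain bisection (independent of scipy)."""

    def f(lam: float) -> float:
        return (
            0.25 * math.exp(lam * match)
            + 0.75 * math.exp(lam * mismatch)
            - 1.0
        )

    lo, hi = 1e-9, 16.0
    while f(hi) < 0:
        hi *= 2
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def hamming_mismatch_profile(query: str, subject: str) -> np.ndarray:
    """Mismatch count of ``query`` against every full window of ``subject``."""
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    s = np.frombuffer(subject.encode(), dtype=np.uint8)
    n_win = len(s) - len(q) + 1
    if n_win <= 0:
        return np.empty(0, dtype=int)
    windows = np.lib.stride_tricks.sliding_window_view(s, len(q))
    return (windows != q).sum(axis=1)


def oracle_passing_loci(
    spacers: dict[str, str],
    mges: dict[str, str],
    min_identity: float = 0.90,
    max_evalue: float = 1e-3,
    k_const: float = 0.46,
    match: int = 1,
    mismatch: int = -2,
) -> dict[tuple[str, str, str, int], float]:
    """Brute-force all-offsets Hamming scan of every spacer against every
    MGE on both strands.

    Returns {(spacer_id, mge_id, strand, s_min_1based): identity} for loci
    with identity strictly above ``min_identity`` (full query coverage) and
    e-value strictly below ``max_evalue``.
    """
    lam = bisect_lambda(match, mismatch)
    db_total = sum(len(s) for s in mges.values())
    out: dict[tuple[str, str, str, int], float] = {}
    for sid, spacer in spacers.items():
        L = len(spacer)
        for mid, subject in mges.items():
            for strand in "+-":
                q = spacer if strand == "+" else rc(spacer)
                mism = hamming_mismatch_profile(q, subject)
                for off in np.nonzero(mism / L < (1 - min_identity))[0]:
                    m = int(mism[off])
                    score = (L - m) * match + m * mismatch
                    ev = k_const * L * db_total * math.exp(-lam * score)
                    if ev < max_evalue:
                        out[(sid, mid, strand, int(off) + 1)] = (L - m) / L
    return out


def bfs_components(nodes: list, edges: list[tuple]) -> list[frozenset]:
    """Connected components by explicit BFS from every node."""
    adj: dict = {n: set() for n in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    seen: set = set()
    comps = []
    for n in nodes:
        if n in seen:
            continue
        queue, comp = [n], {n}
        seen.add(n)
        while queue:
            cur = queue.pop()
            for nb in adj[cur]:
                if nb not in seen:
                    seen.add(nb)
                    comp.add(nb)
                    queue.append(nb)
        comps.append(frozenset(comp))
    return comps


def exhaustive_min_cover(universe: set, candidates: dict) -> int:
    """Size of an optimal set cover by exhaustive subset enumeration."""
    from itertools import combinations

    ids = sorted(candidates)
    for size in range(1, len(ids) + 1):
        for combo in combinations(ids, size):
            covered = set()
            for cid in combo:
                covered |= candidates[cid]
            if covered >= universe:
                return size
    raise AssertionError("universe not coverable")


# ---------------------------------------------------------------- fixtures


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def plant_protospacers(
    rng: np.random.Generator,
    n_spacers: int,
    n_mges: int,
    mge_len: int,
    spacer_len: int = 32,
    n_subs: int = 0,
    decoy_frac: float = 0.0,
):
    """Build (spacers, mges, truth) with each non-decoy spacer copied from a
    random MGE segment with exactly ``n_subs`` substitutions."""
    from spacernet.simulate import mutate_exact

    mges = {
        f"M{i + 1:03d}": random_dna(rng, mge_len) for i in range(n_mges)
    }
    mge_ids = sorted(mges)
    spacers = {}
    truth = {}
    for j in range(n_spacers):
        sid = f"S{j + 1:03d}"
        if rng.random() < decoy_frac:
            spacers[sid] = random_dna(rng, spacer_len)
            truth[sid] = None
            continue
        mid = mge_ids[int(rng.integers(n_mges))]
        off = int(rng.integers(mge_len - spacer_len + 1))
        segment = mges[mid][off : off + spacer_len]
        strand = "+" if rng.random() < 0.5 else "-"
        proto = segment if strand == "+" else rc(segment)
        seq, _ = mutate_exact(proto, n_subs, rng)
        spacers[sid] = seq
        truth[sid] = (mid, strand, off + 1)
    return spacers, mges, truth
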