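"""Spacer-vs-MGE protospacer search, alignment statistics, and hit filters.

The search is a seed-and-extend nucleotide aligner specialised for short,
near-exact queries (CRISPR spacers against a phage/plasmid database). Exact
``word_size``-mer seeds on both strands nominate candidate diagonals; each
diagonal is extended ungapped across the full query span (clipped only at
subject edges), so every query position -- including terminal substitutions
-- counts toward identity and coverage. The engine is deliberately ungapped:
spacer/protospacer divergence is substitution-dominated, and a score-optimal
gapped extension can realign adjacent substitutions as a spurious 1-bp indel
and inflate identity past the retention threshold, blurring the exact
mismatch-count semantics of the filters. Significance uses Karlin-Altschul
statistics with a numerically derived lambda for the configured
match/mismatch scores.

Hits are retained when identity > 90%, per-HSP query coverage > 80% and
e-value < 0.001 (all strict); for a 32-bp spacer this admits up to 3
substitutions (29/32 = 0.906) and rejects 4 (28/32 = 0.875), tolerating
mutation and sequencing error while excluding chance matches.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache

from scipy.optimize import brentq

from .records import MGERecord, SpacerCluster, SpacerHit, revcomp

logger = logging.getLogger(__name__)


@dataclass
class SearchParams:
    """Alignment scoring, seeding, and retention thresholds.

    ``word_size`` defaults to 7 (the short-query BLASTN convention): by the
    pigeonhole principle any spacer of >= 18 bp whose best locus passes the
    90% identity filter is guaranteed to retain an exact 7-mer seed, so
    seeding never loses a reportable hit. A word size of 11 would miss some
    32-bp protospacers carrying 3 substitutions (three evenly spread
    substitutions leave no exact 11-mer).
    """

    min_identity: float = 0.90
    min_qcov: float = 0.80
    max_evalue: float = 1e-3
    word_size: int = 7
    match_score: int = 1
    mismatch_score: int = -2
    # Gap penalties describe the scoring scheme of ingested external
    # (gapped) tabular hits; the built-in engine itself is ungapped.
    gap_open: int = -5
    gap_extend: int = -2
    k_const: float = 0.46
    db_length_total: int | None = None

    def __post_init__(self) -> None:
        if not (0 < self.min_identity <= 1 and 0 < self.min_qcov <= 1):
            raise ValueError("identity/coverage thresholds must be in (0, 1]")
        if self.max_evalue <= 0:
            raise ValueError("max_evalue must be positive")


@lru_cache(maxsize=None)
def karlin_lambda(match_score: int, mismatch_score: int) -> float:
    """Positive root of (1/4)e^(lambda*match) + (3/4)e^(lambda*mismatch) = 1.

    This is the Karlin-Altschul lambda for an ungapped scoring scheme under
    uniform base composition, where a random aligned pair matches with
    probability 1/4.
    """
    if match_score <= 0 or mismatch_score >= 0:
        raise ValueError("need match_score > 0 and mismatch_score < 0")

    def f(lam: float) -> float:
        return (
            0.25 * math.exp(lam * match_score)
            + 0.75 * math.exp(lam * mismatch_score)
            - 1.0
        )

    # f(0)=0 is the trivial root; bracket the positive one.
    lo = 1e-9
    while f(lo) >= 0:  # pragma: no cover - defensive for odd schemes
        lo /= 10
    hi = 1.0
    while f(hi) < 0:
        hi *= 2
    return float(brentq(f, lo, hi, xtol=1e-12))


def compute_evalue(
    score_raw: float,
    query_len: int,
    db_len_total: int,
    params: SearchParams | None = None,
) -> tuple[float, float]:
    """(bitscore, evalue) for a raw alignment score.

    E = K * m * n * exp(-lambda * S) with m the query length and n the total
    database length; bitscore = (lambda*S - ln K) / ln 2.
    """
    params = params or SearchParams()
    if query_len <= 0 or db_len_total <= 0:
        raise ValueError("query and database lengths must be positive")
    lam = karlin_lambda(params.match_score, params.mismatch_score)
    bitscore = (lam * score_raw - math.log(params.k_const)) / math.log(2.0)
    evalue = (
        params.k_const * query_len * db_len_total * math.exp(-lam * score_raw)
    )
    return bitscore, evalue


def _seed_diagonals(query: str, index: dict[str, list[int]], w: int) -> set[int]:
    diags: set[int] = set()
    for i in range(len(query) - w + 1):
        word = query[i : i + w]
        for s in index.get(word, ()):
            diags.add(s - i)
    return diags


def _ungapped_stats(
    query: str, subject: str, diag: int, params: SearchParams
) -> tuple[float, int, int, int, int, int, int, int] | None:
    """Ungapped extension of one seed diagonal across the full query span.

    The alignment is clipped only where the query runs past a subject edge.
    Returns (score, identities, mismatches, aln_len, gap_openings, qa, sa,
    sb) with qa the query start offset and sa/sb the subject span (0-based,
    half-open), or None when fewer than ``word_size`` positions overlap.
    """
    L = len(query)
    q_lo = max(0, -diag)
    q_hi = min(L, len(subject) - diag)
    if q_hi - q_lo < params.word_size:
        return None
    window = subject[diag + q_lo : diag + q_hi]
    mism = sum(a != b for a, b in zip(query[q_lo:q_hi], window))
    ident = (q_hi - q_lo) - mism
    score = float(ident * params.match_score + mism * params.mismatch_score)
    return (score, ident, mism, q_hi - q_lo, 0, q_lo, diag + q_lo, diag + q_hi)


def search_spacers(
    clusters: list[SpacerCluster],
    db: list[MGERecord],
    params: SearchParams | None = None,
) -> list[SpacerHit]:
    """All seed-supported spacer/MGE local alignments, unfiltered.

    One hit per (cluster, MGE, locus, strand): overlapping alignments on the
    same subject strand are merged keeping the best-scoring one. Spacers
    shorter than the seed word size are skipped with a warning.
    """
    params = params or SearchParams()
    if not clusters:
        raise ValueError("no spacer clusters to search")
    if not db:
        raise ValueError("empty MGE database")
    w = params.word_size
    db_total = params.db_length_total or sum(len(m.seq) for m in db)

    hits: list[SpacerHit] = []
    for mge in db:
        subject = mge.seq
        index: dict[str, list[int]] = {}
        for i in range(len(subject) - w + 1):
            word = subject[i : i + w]
            if "N" not in word:
                index.setdefault(word, []).append(i)
        for cluster in clusters:
            qseq = cluster.rep_seq
            qlen = len(qseq)
            if qlen < w:
                logger.warning(
                    "spacer cluster %s (%d bp) shorter than word size %d; "
                    "skipped",
                    cluster.cluster_id,
                    qlen,
                    w,
                )
                continue
            for strand in "+-":
                query = qseq if strand == "+" else revcomp(qseq)
                diags = _seed_diagonals(query, index, w)
                if not diags:
                    continue
                raw: list[tuple] = []
                for d in sorted(diags):
                    res = _ungapped_stats(query, subject, d, params)
                    if res is not None:
                        raw.append(res)
                for res in _merge_loci(raw):
                    hits.append(
                        _to_hit(
                            res, cluster, mge, strand, qlen, db_total, params
                        )
                    )
    hits.sort(
        key=lambda h: (h.cluster_id, h.mge_id, h.strand, *h.subject_interval())
    )
    return hits


def _merge_loci(raw: list[tuple]) -> list[tuple]:
    """Keep the best-scoring alignment among overlapping subject spans."""
    raw = sorted(raw, key=lambda r: (r[6], r[7], -r[0]))
    kept: list[tuple] = []
    for res in raw:
        sa, sb = res[6], res[7]
        merged = False
        for i, prev in enumerate(kept):
            if sa < prev[7] and prev[6] < sb:  # overlap
                if res[0] > prev[0]:
                    kept[i] = res
                merged = True
                break
        if not merged:
            kept.append(res)
    return kept


def _to_hit(
    res: tuple,
    cluster: SpacerCluster,
    mge: MGERecord,
    strand: str,
    qlen: int,
    db_total: int,
    params: SearchParams,
) -> SpacerHit:
    score, identities, mismatches, aln_len, gap_openings, qa, sa, sb = res
    bitscore, evalue = compute_evalue(score, qlen, db_total, params)
    qb = qa + (sb - sa)  # ungapped: query span equals subject span
    if strand == "+":
        q_start, q_end = qa + 1, qb
        s_start, s_end = sa + 1, sb
    else:
        # query was reverse-complemented for the scan; report original
        # query orientation with descending subject coordinates
        q_start, q_end = qlen - qb + 1, qlen - qa
        s_start, s_end = sb, sa + 1
    return SpacerHit(
        cluster_id=cluster.cluster_id,
        mge_id=mge.mge_id,
        identity=identities / aln_len,
        aln_len=aln_len,
        mismatches=mismatches,
        gap_openings=gap_openings,
        q_start=q_start,
        q_end=q_end,
        s_start=s_start,
        s_end=s_end,
        evalue=evalue,
        bitscore=bitscore,
        qcov=(q_end - q_start + 1) / qlen,
        strand=strand,
    )


def filter_hits(
    hits: list[SpacerHit], params: SearchParams | None = None
) -> list[SpacerHit]:
    """Retain hits passing all three thresholds (strict inequalities)."""
    params = params or SearchParams()
    return [
        h
        for h in hits
        if h.identity > params.min_identity
        and h.qcov > params.min_qcov
        and h.evalue < params.max_evalue
    ]


def read_tabular_hits(
    path: str, spacer_lengths: dict[str, int]
) -> list[SpacerHit]:
    """Ingest 12-column tabular alignment output (BLAST outfmt-6 layout).

    Columns: query, subject, %identity, aln_len, mismatches, gap_openings,
    q_start, q_end, s_start, s_end, evalue, bitscore. Query coverage is
    recomputed from the query span and the known spacer length; the strand
    follows from s_start vs s_end. Files written by :func:`write_hits_tsv`
    (the same 12 columns plus qcov and strand) are accepted too; the two
    appended columns are ignored and recomputed.
    """
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) not in (12, 14):
                raise ValueError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, "
                    f"got {len(fields)}"
                )
            (
                qid,
                sid,
                pident,
                aln_len,
                mism,
                gapo,
                qs,
                qe,
                ss,
                se,
                ev,
                bits,
            ) = fields[:12]
            if qid not in spacer_lengths:
                raise KeyError(
                    f"{path}:{lineno}: unknown query id {qid!r} "
                    "(no spacer length available)"
                )
            try:
                hit = SpacerHit(
                    cluster_id=qid,
                    mge_id=sid,
                    identity=float(pident) / 100.0,
                    aln_len=int(aln_len),
                    mismatches=int(mism),
                    gap_openings=int(gapo),
                    q_start=int(qs),
                    q_end=int(qe),
                    s_start=int(ss),
                    s_end=int(se),
                    evalue=float(ev),
                    bitscore=float(bits),
                    qcov=(int(qe) - int(qs) + 1) / spacer_lengths[qid],
                    strand="+" if int(ss) <= int(se) else "-",
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed line: {exc}")
            hits.append(hit)
    return hits


def write_hits_tsv(hits: list[SpacerHit], path: str) -> None:
    """Write hits in the 12-column layout plus qcov and strand columns."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    [
                        h.cluster_id,
                        h.mge_id,
                        f"{h.identity * 100:.2f}",
                        str(h.aln_len),
                        str(h.mismatches),
                        str(h.gap_openings),
                        str(h.q_start),
                        str(h.q_end),
                        str(h.s_start),
                        str(h.s_end),
                        f"{h.evalue:.3g}",
                        f"{h.bitscore:.1f}",
                        f"{h.qcov:.4f}",
                        h.strand,
                    ]
                )
                + "\n"
            )
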