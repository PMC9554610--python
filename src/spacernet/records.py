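"""Core domain records shared across the pipeline.

The records mirror the objects a CRISPR-based host--MGE interaction analysis
passes between its stages: input sequences, repeat library entries, detected
CRISPR arrays, extracted spacers, deduplicated spacer clusters, mobile genetic
element (MGE) records, and individual spacer-vs-MGE alignment hits.

Coordinates are 0-based half-open internally; 1-based inclusive coordinates
appear only in human-readable outputs and in the tabular hit format.
"""

from __future__ import annotations

from dataclasses import dataclass, field

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

VALID_BASES = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def validate_dna(seq: str, *, what: str = "sequence") -> str:
    """Uppercase and validate a DNA string; raise ValueError on bad input."""
    if not seq:
        raise ValueError(f"empty {what}")
    up = seq.upper()
    bad = set(up) - VALID_BASES
    if bad:
        raise ValueError(f"invalid characters in {what}: {sorted(bad)}")
    return up


@dataclass
class SequenceRecord:
    """A named DNA sequence (genome, contig, or MGE)."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        self.seq = validate_dna(self.seq, what=f"sequence {self.id!r}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class RepeatEntry:
    """A known CRISPR repeat used to guide array discovery.

    ``crispr_type`` carries an optional CRISPR-Cas type label (e.g. "I-C",
    "II-C", "V-A") which is inherited by arrays detected with this repeat.
    """

    id: str
    seq: str
    crispr_type: str | None = None

    MIN_LEN = 16

    def __post_init__(self) -> None:
        self.seq = validate_dna(self.seq, what=f"repeat {self.id!r}")
        if len(self.seq) < self.MIN_LEN:
            raise ValueError(
                f"repeat {self.id!r} is {len(self.seq)} bp; "
                f"minimum is {self.MIN_LEN} bp"
            )


@dataclass
class CRISPRArray:
    """A detected repeat--spacer structure on a host contig.

    ``repeats`` and ``spacers`` are ordered lists of ``(start_bp, seq)`` in
    array orientation; for minus-strand (guided) arrays the order runs
    right-to-left on the contig and sequences are reverse-complemented, so
    spacer order always follows the repeat orientation.
    """

    array_id: str
    host_id: str
    contig_id: str
    start: int
    end: int
    repeats: list[tuple[int, str]]
    spacers: list[tuple[int, str]]
    consensus_repeat: str
    crispr_type: str | None = None
    mode: str = "denovo"  # "denovo" | "guided"
    strand: str = "+"

    @property
    def n_repeats(self) -> int:
        return len(self.repeats)

    def validate(self) -> None:
        if len(self.spacers) != len(self.repeats) - 1:
            raise ValueError(
                f"{self.array_id}: {len(self.spacers)} spacers for "
                f"{len(self.repeats)} repeats"
            )
        if self.strand not in "+-":
            raise ValueError(f"{self.array_id}: bad strand {self.strand!r}")
        for pos, seq in self.repeats + self.spacers:
            if not (self.start <= pos and pos + len(seq) <= self.end):
                raise ValueError(
                    f"{self.array_id}: feature at {pos} outside "
                    f"[{self.start},{self.end})"
                )


@dataclass
class Spacer:
    """One spacer occurrence extracted from a CRISPR array."""

    spacer_id: str
    seq: str
    host_id: str
    array_id: str
    index_in_array: int
    crispr_type: str | None = None


@dataclass
class SpacerCluster:
    """A deduplicated spacer sequence with its member occurrences."""

    cluster_id: str
    rep_seq: str
    members: list[str] = field(default_factory=list)
    crispr_types: set[str] = field(default_factory=set)

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class MGERecord:
    """One phage or plasmid sequence with its metadata."""

    mge_id: str
    seq: str
    mge_class: str = "phage"  # "phage" | "plasmid"
    source_db: str = ""
    known_host: str | None = None

    def __post_init__(self) -> None:
        if not self.mge_id:
            raise ValueError("mge_id must be non-empty")
        if self.mge_class not in ("phage", "plasmid"):
            raise ValueError(
                f"{self.mge_id}: mge_class must be 'phage' or 'plasmid', "
                f"got {self.mge_class!r}"
            )
        self.seq = validate_dna(self.seq, what=f"MGE {self.mge_id!r}")


@dataclass
class SpacerHit:
    """One alignment (HSP) between a spacer cluster and an MGE.

    Coordinates follow the 12-column tabular alignment convention: 1-based
    inclusive, with ``s_start > s_end`` on the minus strand. ``identity`` is
    matches / alignment length (gap columns included); ``qcov`` is the HSP's
    query span over the spacer length.
    """

    cluster_id: str
    mge_id: str
    identity: float
    aln_len: int
    mismatches: int
    gap_openings: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float
    qcov: float
    strand: str

    def subject_interval(self) -> tuple[int, int]:
        """Subject span as a 0-based half-open interval on the plus strand."""
        lo, hi = sorted((self.s_start, self.s_end))
        return lo - 1, hi
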