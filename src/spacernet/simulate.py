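"""Seeded synthetic hosts, MGEs and ground truth for pipeline testing.

The generator emulates the statistical structure the analysis relies on:
CRISPR spacers are near-exact copies of segments of invader (MGE) genomes.
It writes a host multi-FASTA whose contigs carry planted CRISPR arrays, an
MGE multi-FASTA with metadata, the repeat library used to build the arrays,
and a ground-truth table linking each implanted spacer to its source MGE
locus. Decoy MGEs (never sampled) and decoy spacers (uniform random DNA)
provide negative controls. Everything is reproducible from a single seed.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field

import numpy as np

from .records import MGERecord, RepeatEntry, SequenceRecord, revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def mutate_sequence(
    seq: str, rate: float, rng: np.random.Generator
) -> tuple[str, int]:
    """Substitute each base independently with probability ``rate``.

    A substituted base is drawn uniformly from the three other bases, so
    rate=1 changes every position. Length is preserved (no indels).
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    flip = rng.random(len(arr)) < rate
    n_sub = int(flip.sum())
    if n_sub:
        idx = np.nonzero(flip)[0]
        # shift by 1..3 positions in the base alphabet => always different
        base_idx = np.searchsorted(_BASES, arr[idx])
        new_idx = (base_idx + rng.integers(1, 4, size=n_sub)) % 4
        arr[idx] = _BASES[new_idx]
    return arr.tobytes().decode(), n_sub


def mutate_exact(
    seq: str, n_subs: int, rng: np.random.Generator
) -> tuple[str, int]:
    """Substitute exactly ``n_subs`` distinct positions (uniformly chosen)."""
    if n_subs > len(seq):
        raise ValueError("more substitutions than positions")
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    idx = rng.choice(len(arr), size=n_subs, replace=False)
    base_idx = np.searchsorted(_BASES, arr[idx])
    new_idx = (base_idx + rng.integers(1, 4, size=n_subs)) % 4
    arr[idx] = _BASES[new_idx]
    return arr.tobytes().decode(), n_subs


@dataclass
class SimConfig:
    """Parameters of the synthetic community.

    Defaults describe a small but fully exercising community: 20 hosts with
    one CRISPR array each (3-8 spacers of 32 bp), 50 real MGEs of 2-4 kb
    plus 10 decoys, spacers copied exactly (substitution rate 0) with a 10%
    decoy-spacer fraction.
    """

    n_hosts: int = 20
    n_mges: int = 50
    n_decoy_mges: int = 10
    mge_len_range: tuple[int, int] = (2000, 4000)
    arrays_per_host: int = 1
    spacers_per_array_range: tuple[int, int] = (3, 8)
    spacer_len: int = 32
    sub_rate: float = 0.0
    decoy_spacer_frac: float = 0.1
    plasmid_frac: float = 0.2
    repeat_len: int = 30
    n_repeat_types: int = 3
    flank_len: int = 400
    seed: int = 0
    repeats: list[RepeatEntry] = field(default_factory=list)

    def validate(self) -> None:
        for name in (
            "n_hosts",
            "n_mges",
            "n_decoy_mges",
            "arrays_per_host",
            "spacer_len",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("sub_rate", "decoy_spacer_frac", "plasmid_frac"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_mges and self.spacer_len > self.mge_len_range[0]:
            raise ValueError("spacer_len exceeds the minimum MGE length")


_TYPE_LABELS = ["I-C", "II-C", "V-A"]


@dataclass
class SimResult:
    hosts: list[SequenceRecord]
    mges: list[MGERecord]
    repeats: list[RepeatEntry]
    ground_truth: list[dict]
    decoy_mge_ids: set[str]

    def true_host_mge_pairs(self) -> set[tuple[str, str]]:
        return {
            (row["host_id"], row["mge_id"])
            for row in self.ground_truth
            if row["mge_id"] != "NA"
        }


def _sample_spacer(
    rng: np.random.Generator,
    mges: list[MGERecord],
    cfg: SimConfig,
) -> dict:
    """Draw one spacer: either a mutated MGE segment or a random decoy."""
    if rng.random() < cfg.decoy_spacer_frac or not mges:
        return {
            "seq": _random_dna(rng, cfg.spacer_len),
            "mge_id": "NA",
            "s_start": 0,
            "s_end": 0,
            "strand": ".",
            "n_substitutions": 0,
        }
    mge = mges[int(rng.integers(len(mges)))]
    start = int(rng.integers(len(mge.seq) - cfg.spacer_len + 1))
    segment = mge.seq[start : start + cfg.spacer_len]
    strand = "+" if rng.random() < 0.5 else "-"
    proto = segment if strand == "+" else revcomp(segment)
    seq, n_sub = mutate_sequence(proto, cfg.sub_rate, rng)
    return {
        "seq": seq,
        "mge_id": mge.mge_id,
        "s_start": start + 1,
        "s_end": start + cfg.spacer_len,
        "strand": strand,
        "n_substitutions": n_sub,
    }


def build_array_contig(
    rng: np.random.Generator,
    repeat: str,
    spacers: list[str],
    flank_len: int,
) -> tuple[str, int]:
    """Assemble flank + repeat/spacer alternation + flank.

    The single flanking column on each side of the array is resampled until
    it breaks unanimity with the adjacent spacer boundary columns, keeping
    the repeat extent identifiable: otherwise an equally valid description
    with a longer repeat and shorter spacers would exist and exact boundary
    recovery would be ill-posed.

    Returns (contig_sequence, array_start).
    """
    left = _random_dna(rng, flank_len)
    right = _random_dna(rng, flank_len)
    body = repeat + "".join(s + repeat for s in spacers)

    # columns immediately right of each repeat: first bases of spacers,
    # then the first base of the right flank
    right_cols = [s[0] for s in spacers]
    if right and right_cols and all(c == right_cols[0] for c in right_cols):
        while right[0] == right_cols[0]:
            right = _random_dna(rng, 1) + right[1:]
    left_cols = [s[-1] for s in spacers]
    if left and left_cols and all(c == left_cols[0] for c in left_cols):
        while left[-1] == left_cols[0]:
            left = left[:-1] + _random_dna(rng, 1)
    return left + body + right, len(left)


def simulate(config: SimConfig) -> SimResult:
    """Generate the synthetic community in memory."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    repeats = list(config.repeats)
    if not repeats:
        for i in range(config.n_repeat_types):
            repeats.append(
                RepeatEntry(
                    id=f"rep{i + 1}",
                    seq=_random_dna(rng, config.repeat_len),
                    crispr_type=_TYPE_LABELS[i % len(_TYPE_LABELS)],
                )
            )

    mges: list[MGERecord] = []
    decoy_ids: set[str] = set()
    total = config.n_mges + config.n_decoy_mges
    for i in range(total):
        length = int(rng.integers(*config.mge_len_range, endpoint=True))
        is_decoy = i >= config.n_mges
        mge_id = f"mge{i + 1:04d}"
        mges.append(
            MGERecord(
                mge_id=mge_id,
                seq=_random_dna(rng, length),
                mge_class=(
                    "plasmid" if rng.random() < config.plasmid_frac else "phage"
                ),
                source_db="sim_decoy" if is_decoy else "sim",
            )
        )
        if is_decoy:
            decoy_ids.add(mge_id)
    real_mges = mges[: config.n_mges]

    hosts: list[SequenceRecord] = []
    truth: list[dict] = []
    for h in range(config.n_hosts):
        host_id = f"host{h + 1:04d}"
        parts = []
        for _ in range(config.arrays_per_host):
            entry = repeats[int(rng.integers(len(repeats)))]
            n_sp = int(rng.integers(*config.spacers_per_array_range, endpoint=True))
            draws = [_sample_spacer(rng, real_mges, config) for _ in range(n_sp)]
            contig_part, _ = build_array_contig(
                rng, entry.seq, [d["seq"] for d in draws], config.flank_len
            )
            parts.append(contig_part)
            for d in draws:
                truth.append(
                    {
                        "host_id": host_id,
                        "mge_id": d["mge_id"],
                        "spacer_seq": d["seq"],
                        "s_start": d["s_start"],
                        "s_end": d["s_end"],
                        "strand": d["strand"],
                        "n_substitutions": d["n_substitutions"],
                    }
                )
        hosts.append(SequenceRecord(id=host_id, seq="".join(parts)))

    return SimResult(
        hosts=hosts,
        mges=mges,
        repeats=repeats,
        ground_truth=truth,
        decoy_mge_ids=decoy_ids,
    )


def write_simulation(result: SimResult, outdir: str) -> dict[str, str]:
    """Write the five simulation files; returns a name->path mapping."""
    from . import io as snio

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "hosts": os.path.join(outdir, "hosts.fasta"),
        "mges": os.path.join(outdir, "mges.fasta"),
        "mge_metadata": os.path.join(outdir, "mge_metadata.tsv"),
        "repeats": os.path.join(outdir, "repeats.fasta"),
        "ground_truth": os.path.join(outdir, "ground_truth.tsv"),
    }
    snio.write_fasta(result.hosts, paths["hosts"])
    snio.write_fasta(
        [SequenceRecord(id=m.mge_id, seq=m.seq) for m in result.mges],
        paths["mges"],
    )
    snio.write_mge_metadata(result.mges, paths["mge_metadata"])
    snio.write_repeat_library(result.repeats, paths["repeats"])
    cols = [
        "host_id",
        "mge_id",
        "spacer_seq",
        "s_start",
        "s_end",
        "strand",
        "n_substitutions",
    ]
    with open(paths["ground_truth"], "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in result.ground_truth:
            fh.write("\t".join(str(row[c]) for c in cols) + "\n")
    return paths


def config_from_dict(d: dict) -> SimConfig:
    """Build a SimConfig from a flat dict (e.g. parsed YAML), ignoring
    unknown keys."""
    names = {f.name for f in dataclasses.fields(SimConfig)}
    kwargs = {k: v for k, v in d.items() if k in names}
    for key in ("mge_len_range", "spacers_per_array_range"):
        if key in kwargs and isinstance(kwargs[key], list):
            kwargs[key] = tuple(kwargs[key])
    return SimConfig(**kwargs)
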