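"""File interfaces: FASTA, repeat libraries, MGE metadata, array tables.

Spacer FASTA headers carry the occurrence metadata needed downstream:
``<cluster_id>|host=<host_id>|array=<array_id>|idx=<i>|type=<label>``.
Array tables use 1-based inclusive coordinates (human-readable convention);
the in-memory records remain 0-based half-open.
"""

from __future__ import annotations

import csv

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .records import (
    CRISPRArray,
    MGERecord,
    RepeatEntry,
    SequenceRecord,
    Spacer,
    SpacerCluster,
)


def read_fasta(path: str) -> list[SequenceRecord]:
    records = [
        SequenceRecord(id=r.id, seq=str(r.seq), description=r.description)
        for r in SeqIO.parse(path, "fasta")
    ]
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"{path}: duplicate sequence ids: {dupes[:5]}")
    return records


def write_fasta(records: list[SequenceRecord], path: str) -> None:
    SeqIO.write(
        (
            BioSeqRecord(Seq(r.seq), id=r.id, description=r.description)
            for r in records
        ),
        path,
        "fasta",
    )


def read_repeat_library(path: str) -> list[RepeatEntry]:
    """Repeat FASTA; an optional ``type=<label>`` token in the description
    line supplies the CRISPR type."""
    entries = []
    for r in SeqIO.parse(path, "fasta"):
        crispr_type = None
        for token in r.description.split():
            if token.startswith("type="):
                crispr_type = token[len("type=") :]
        entries.append(
            RepeatEntry(id=r.id, seq=str(r.seq), crispr_type=crispr_type)
        )
    if not entries:
        raise ValueError(f"{path}: empty repeat library")
    return entries


def write_repeat_library(entries: list[RepeatEntry], path: str) -> None:
    with open(path, "w") as fh:
        for e in entries:
            desc = f" type={e.crispr_type}" if e.crispr_type else ""
            fh.write(f">{e.id}{desc}\n{e.seq}\n")


def read_mge_database(
    fasta_path: str, metadata_path: str | None = None
) -> list[MGERecord]:
    """MGE multi-FASTA plus optional metadata TSV.

    Metadata columns: mge_id, class (phage|plasmid), source_db, known_host
    (optional). Sequences without a metadata row default to class "phage".
    """
    meta: dict[str, dict] = {}
    if metadata_path:
        with open(metadata_path) as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            for row in reader:
                meta[row["mge_id"]] = row
    records = []
    for r in SeqIO.parse(fasta_path, "fasta"):
        m = meta.get(r.id, {})
        known_host = m.get("known_host") or None
        records.append(
            MGERecord(
                mge_id=r.id,
                seq=str(r.seq),
                mge_class=m.get("class", "phage"),
                source_db=m.get("source_db", ""),
                known_host=known_host,
            )
        )
    return records


def write_mge_metadata(mges: list[MGERecord], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("mge_id\tclass\tsource_db\tknown_host\n")
        for m in mges:
            fh.write(
                f"{m.mge_id}\t{m.mge_class}\t{m.source_db}\t"
                f"{m.known_host or ''}\n"
            )


def write_arrays_tsv(arrays: list[CRISPRArray], path: str) -> None:
    """Array summary table; coordinates are 1-based inclusive."""
    with open(path, "w") as fh:
        fh.write(
            "array_id\thost\tcontig\tstart\tend\tn_repeats\t"
            "consensus_repeat\ttype\tmode\tstrand\n"
        )
        for a in arrays:
            fh.write(
                "\t".join(
                    [
                        a.array_id,
                        a.host_id,
                        a.contig_id,
                        str(a.start + 1),
                        str(a.end),
                        str(a.n_repeats),
                        a.consensus_repeat,
                        a.crispr_type or "",
                        a.mode,
                        a.strand,
                    ]
                )
                + "\n"
            )


def write_arrays_gff(arrays: list[CRISPRArray], path: str) -> None:
    """GFF3-style feature lines for arrays and their repeats/spacers."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for a in arrays:
            strand = a.strand
            fh.write(
                f"{a.contig_id}\tspacernet\tCRISPR_array\t{a.start + 1}\t"
                f"{a.end}\t.\t{strand}\t.\tID={a.array_id};mode={a.mode}"
                + (f";crispr_type={a.crispr_type}" if a.crispr_type else "")
                + "\n"
            )
            for kind, feats in (("repeat", a.repeats), ("spacer", a.spacers)):
                for i, (pos, seq) in enumerate(feats):
                    fh.write(
                        f"{a.contig_id}\tspacernet\tCRISPR_{kind}\t{pos + 1}\t"
                        f"{pos + len(seq)}\t.\t{strand}\t.\t"
                        f"ID={a.array_id}|{kind}{i};Parent={a.array_id}\n"
                    )


def write_spacer_fasta(
    clusters: list[SpacerCluster], spacers: list[Spacer], path: str
) -> None:
    """One record per spacer occurrence, grouped by cluster."""
    by_id = {sp.spacer_id: sp for sp in spacers}
    with open(path, "w") as fh:
        for c in clusters:
            for member in c.members:
                sp = by_id[member]
                fh.write(
                    f">{c.cluster_id}|host={sp.host_id}|array={sp.array_id}"
                    f"|idx={sp.index_in_array}|type={sp.crispr_type or ''}\n"
                    f"{sp.seq}\n"
                )


def read_spacer_fasta(
    path: str,
) -> tuple[list[SpacerCluster], dict[str, set[str]]]:
    """Recover clusters and the cluster->hosts mapping from a spacer FASTA."""
    clusters: dict[str, SpacerCluster] = {}
    cluster_hosts: dict[str, set[str]] = {}
    for r in SeqIO.parse(path, "fasta"):
        fields = r.description.split("|")
        cluster_id = fields[0].split()[0]
        meta = {}
        for f in fields[1:]:
            if "=" in f:
                k, v = f.split("=", 1)
                meta[k] = v
        host = meta.get("host", "")
        array = meta.get("array", "")
        idx = meta.get("idx", "0")
        ctype = meta.get("type") or None
        spacer_id = f"{array}|sp{idx}"
        c = clusters.setdefault(
            cluster_id,
            SpacerCluster(cluster_id=cluster_id, rep_seq=str(r.seq).upper()),
        )
        c.members.append(spacer_id)
        if ctype:
            c.crispr_types.add(ctype)
        cluster_hosts.setdefault(cluster_id, set()).add(host)
    return sorted(clusters.values(), key=lambda c: c.cluster_id), cluster_hosts


def write_selected_mges_fasta(
    mges: list[MGERecord], selected: list[str], path: str
) -> None:
    """FASTA of the greedily selected MGEs with their source annotations."""
    by_id = {m.mge_id: m for m in mges}
    with open(path, "w") as fh:
        for mid in selected:
            m = by_id[mid]
            desc = f"class={m.mge_class} source={m.source_db}"
            if m.known_host:
                desc += f" known_host={m.known_host}"
            fh.write(f">{m.mge_id} {desc}\n{m.seq}\n")
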