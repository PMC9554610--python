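"""End-to-end orchestration: detect -> dedup -> search -> filter -> networks.

Each stage writes plain files into the working directory so stages can be
re-run independently; a JSON manifest records the counts at every stage.
Re-running on identical inputs reproduces identical artifacts byte for byte.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

from . import io as snio
from .crispr import (
    DetectionParams,
    cluster_hosts_map,
    deduplicate_spacers,
    extract_spacers,
    filter_artifacts,
    find_denovo_arrays,
    find_guided_arrays,
)
from .network import (
    build_host_mge_network,
    build_spacer_mge_network,
    connected_components,
    select_hosts,
    select_mges,
    validate_network,
    write_components_tsv,
    write_network,
)
from .search import SearchParams, filter_hits, read_tabular_hits, search_spacers

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Inputs, working directory and stage parameters for one run."""

    genomes: str = ""
    mge_fasta: str = ""
    mge_metadata: str | None = None
    repeat_library: str | None = None
    workdir: str = "spacernet_out"
    mode: str = "denovo"  # denovo | guided | both
    dedup_mode: str = "exact"
    external_hits: str | None = None
    host_map: str | None = None
    detection: DetectionParams = field(default_factory=DetectionParams)
    search: SearchParams = field(default_factory=SearchParams)
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.mode not in ("denovo", "guided", "both"):
            raise ValueError(f"unknown detection mode {self.mode!r}")
        for label, path in (
            ("genomes", self.genomes),
            ("mge_fasta", self.mge_fasta),
        ):
            if not path or not os.path.exists(path):
                raise FileNotFoundError(f"{label} input not found: {path!r}")
        if self.mode in ("guided", "both") and not self.repeat_library:
            raise ValueError("guided detection requires a repeat library")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _read_host_map(path: str | None) -> dict[str, str]:
    if not path:
        return {}
    mapping = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            contig, host = line.split("\t")[:2]
            mapping[contig] = host
    return mapping


def _detect_stage(config: PipelineConfig):
    contigs = snio.read_fasta(config.genomes)
    host_map = _read_host_map(config.host_map)
    library = (
        snio.read_repeat_library(config.repeat_library)
        if config.repeat_library
        else None
    )
    arrays = []
    for contig in contigs:
        host_id = host_map.get(contig.id, contig.id)
        found = []
        if config.mode in ("guided", "both"):
            found.extend(
                find_guided_arrays(
                    contig, library, config.detection, host_id=host_id
                )
            )
        if config.mode in ("denovo", "both"):
            denovo = find_denovo_arrays(
                contig, config.detection, host_id=host_id
            )
            taken = [(a.start, a.end) for a in found]
            found.extend(
                a
                for a in denovo
                if not any(a.start < e and s < a.end for s, e in taken)
            )
        found.sort(key=lambda a: a.start)
        for i, arr in enumerate(found):
            arr.array_id = f"{contig.id}|arr{i + 1}"
        arrays.extend(found)
    return contigs, filter_artifacts(arrays, config.detection)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages and return the manifest (also written as JSON)."""
    config.validate()
    os.makedirs(config.workdir, exist_ok=True)
    log_path = os.path.join(config.workdir, "run.log")
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("spacernet")
    root.addHandler(handler)
    root.setLevel(getattr(logging, config.log_level.upper(), logging.INFO))
    try:
        return _run(config)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run(config: PipelineConfig) -> dict:
    wd = config.workdir

    try:
        contigs, arrays = _detect_stage(config)
    except Exception as exc:
        raise StageError("detect", exc)
    logger.info("detected %d arrays on %d contigs", len(arrays), len(contigs))

    try:
        spacers = extract_spacers(arrays)
        clusters = deduplicate_spacers(spacers, mode=config.dedup_mode)
        cluster_hosts = cluster_hosts_map(clusters, spacers)
        snio.write_arrays_tsv(arrays, os.path.join(wd, "arrays.tsv"))
        snio.write_arrays_gff(arrays, os.path.join(wd, "arrays.gff"))
        snio.write_spacer_fasta(
            clusters, spacers, os.path.join(wd, "spacers.fasta")
        )
    except Exception as exc:
        raise StageError("extract", exc)

    try:
        mges = snio.read_mge_database(config.mge_fasta, config.mge_metadata)
        mge_meta = {m.mge_id: m for m in mges}
        if config.external_hits:
            lengths = {c.cluster_id: len(c.rep_seq) for c in clusters}
            hits = read_tabular_hits(config.external_hits, lengths)
        elif clusters and mges:
            hits = search_spacers(clusters, mges, config.search)
        else:
            hits = []
        passing = filter_hits(hits, config.search)
        from .search import write_hits_tsv

        write_hits_tsv(passing, os.path.join(wd, "filtered_hits.tsv"))
    except StageError:
        raise
    except Exception as exc:
        raise StageError("search", exc)
    logger.info("%d hits pass filters (%d raw)", len(passing), len(hits))

    try:
        selected_mges = select_mges(passing)
        selected_hosts = select_hosts(passing, cluster_hosts)
        sm_net = build_spacer_mge_network(
            passing, selected_mges, clusters, mge_meta
        )
        hm_net = build_host_mge_network(
            passing, selected_hosts, selected_mges, cluster_hosts, mge_meta
        )
        validate_network(sm_net)
        validate_network(hm_net)
        write_network(sm_net, os.path.join(wd, "spacer_mge.gml"))
        write_network(hm_net, os.path.join(wd, "host_mge.gml"))
        components = connected_components(hm_net)
        write_components_tsv(components, os.path.join(wd, "components.tsv"))
        snio.write_selected_mges_fasta(
            mges, selected_mges, os.path.join(wd, "selected_mges.fasta")
        )
    except Exception as exc:
        raise StageError("network", exc)

    by_class = {"phage": 0, "plasmid": 0}
    for mid in selected_mges:
        by_class[mge_meta[mid].mge_class] += 1
    manifest = {
        "n_contigs": len(contigs),
        "n_arrays": len(arrays),
        "n_spacers": len(spacers),
        "n_clusters": len(clusters),
        "n_matched_clusters": len({h.cluster_id for h in passing}),
        "n_passing_hits": len(passing),
        "n_selected_mges": len(selected_mges),
        "n_selected_mges_by_class": by_class,
        "n_selected_hosts": len(selected_hosts),
        "n_components_host_mge": len(components),
        "n_components_spacer_mge": len(
            connected_components(sm_net)
        ),
        "detection_mode": config.mode,
        "dedup_mode": config.dedup_mode,
    }
    with open(os.path.join(wd, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
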