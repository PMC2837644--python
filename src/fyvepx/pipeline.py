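"""End-to-end orchestration: dereplicate -> annotate -> classify -> analyse.

The pipeline consumes the three input tables (FASTA, domain annotation,
lineage), removes redundancy, builds architectures, and computes every
downstream product: selectivity summaries, presence maps and Venn
partitions per anchor, association tables, functional category roll-ups,
the streptophyte FYVE-RCC1-DZC correlation, and FYVE binding-site calls.
A manifest (input hashes, parameters, package version) makes reruns
auditable; identical inputs and parameters yield byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from fyvepx import __version__
from fyvepx.annotation import (
    ANCHORS,
    Architecture,
    architectures_to_frame,
    build_architectures,
    fraction_multidomain,
)
from fyvepx.analysis import (
    AssociationTable,
    PresenceMap,
    VennPartition,
    association_scores,
    exclusivity_percent,
    fyve_rcc1_dzc_correlation,
    presence_map,
    rank_for_plot,
    selectivity,
    venn_partition,
)
from fyvepx.function_map import category_summary, load_function_map
from fyvepx.io import DomainHit, LineageRow, ProteinRecord, _write_json
from fyvepx.motif import call_binding_sites, calls_to_frame, class_architecture_table
from fyvepx.redundancy import clusters_to_frame, dereplicate
from fyvepx.taxonomy import build_assignments

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """Everything one analysis run produces, in memory."""

    architectures: list[Architecture]
    assignments: dict[str, LineageRow]
    selectivity: list
    presence: dict[str, PresenceMap]
    venn: dict[str, VennPartition]
    association: dict[str, AssociationTable]
    multidomain_percent: dict[str, int]
    exclusivity: dict[str, int]
    correlation_pairs: pd.DataFrame
    correlation_r: float | None
    binding_calls: list
    n_input: int
    n_retained: int
    clusters_frame: pd.DataFrame = field(repr=False, default=None)


def run(
    records: list[ProteinRecord],
    hits: list[DomainHit],
    lineage: list[LineageRow],
    e_cutoff: float = 0.1,
    identity: float = 95.0,
    skip_dereplication: bool = False,
) -> PipelineResult:
    """Run the full analysis on in-memory inputs."""
    logger.info("input: %d records, %d raw hits", len(records), len(hits))
    if skip_dereplication:
        retained, clusters_frame = records, pd.DataFrame()
    else:
        retained, clusters = dereplicate(records, identity)
        clusters_frame = clusters_to_frame(clusters, records)
    logger.info("dereplication: %d of %d records retained", len(retained), len(records))

    architectures = build_architectures(retained, hits, e_cutoff)
    logger.info("architectures: %d anchor proteins", len(architectures))

    assignments = build_assignments([r.species for r in retained], lineage)
    sel = selectivity(architectures, assignments)

    presence: dict[str, PresenceMap] = {}
    venn: dict[str, VennPartition] = {}
    association: dict[str, AssociationTable] = {}
    multidomain: dict[str, int] = {}
    exclusivity: dict[str, int] = {}
    for anchor in ANCHORS:
        presence[anchor] = presence_map(architectures, assignments, anchor)
        venn[anchor] = venn_partition(presence[anchor])
        association[anchor] = association_scores(architectures, anchor)
        try:
            multidomain[anchor] = fraction_multidomain(architectures, anchor)
        except ValueError:
            pass
        if venn[anchor].total:
            exclusivity[anchor] = exclusivity_percent(venn[anchor])

    pairs, r = fyve_rcc1_dzc_correlation(architectures, assignments)
    calls = call_binding_sites(retained, hits, e_cutoff)

    return PipelineResult(
        architectures=architectures,
        assignments=assignments,
        selectivity=sel,
        presence=presence,
        venn=venn,
        association=association,
        multidomain_percent=multidomain,
        exclusivity=exclusivity,
        correlation_pairs=pairs,
        correlation_r=r,
        binding_calls=calls,
        n_input=len(records),
        n_retained=len(retained),
        clusters_frame=clusters_frame,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_outputs(
    result: PipelineResult,
    out_dir: str | Path,
    inputs: dict[str, Path] | None = None,
    params: dict | None = None,
    function_map_path: str | Path | None = None,
) -> dict[str, Path]:
    """Write the report bundle: TSV/JSON products plus a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    def tsv(name: str, frame: pd.DataFrame) -> None:
        path = out / name
        frame.to_csv(path, sep="\t", index=False)
        written[name] = path

    tsv("selectivity.tsv", pd.DataFrame([s.to_row() for s in result.selectivity]))
    tsv("architectures.tsv", architectures_to_frame(result.architectures))
    if result.clusters_frame is not None and len(result.clusters_frame):
        tsv("clusters.tsv", result.clusters_frame)

    fmap = load_function_map(function_map_path)
    for anchor in ANCHORS:
        tsv(f"presence_{anchor}.tsv", result.presence[anchor].to_frame())
        tsv(
            f"association_scores_{anchor}.tsv",
            result.association[anchor].to_frame(),
        )
        tsv(
            f"association_ranked_{anchor}.tsv",
            rank_for_plot(result.association[anchor], result.venn[anchor]),
        )
        if result.association[anchor].counts:
            tsv(
                f"function_categories_{anchor}.tsv",
                category_summary(result.association[anchor], fmap),
            )
        path = out / f"venn_{anchor}.json"
        _write_json(result.venn[anchor].to_dict(), path)
        written[f"venn_{anchor}.json"] = path

    tsv("binding_sites.tsv", calls_to_frame(result.binding_calls, result.architectures))
    tsv(
        "site_class_architecture.tsv",
        class_architecture_table(result.binding_calls, result.architectures),
    )

    summary = {
        "n_input": result.n_input,
        "n_retained": result.n_retained,
        "multidomain_percent": result.multidomain_percent,
        "exclusivity_percent": result.exclusivity,
        "correlation": {
            "method": "pearson",
            "r": result.correlation_r,
            "pairs": result.correlation_pairs.to_dict(orient="records"),
        },
    }
    _write_json(summary, out / "summary.json")
    written["summary.json"] = out / "summary.json"

    manifest = {
        "version": __version__,
        "parameters": params or {},
        "inputs": {
            name: _sha256(Path(p)) for name, p in (inputs or {}).items()
        },
        "outputs": sorted(written),
    }
    _write_json(manifest, out / "manifest.json")
    written["manifest.json"] = out / "manifest.json"
    return written
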