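"""End-to-end orchestration: structure -> indels -> ancestral -> statistics.

The pipeline composes the analysis modules over a directory of annotated
genomes, an alignment, and a rooted time tree, and writes one JSON report
plus per-stage TSVs. Stages are individually skippable so the statistics
stage can run on packaged size/node tables alone. Per-genome failures
(e.g., one genome without a detectable IR) are logged and skipped; the run
continues.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import __version__
from .ancestral import scp_reconstruct
from .indels import (
    Alignment,
    alignment_column_map,
    call_gap_patterns,
    classify_region,
    events_table,
    node_counts,
    polarize_and_place,
    windowed_divergence,
)
from .ir import NoQuadripartiteError, detect_quadripartite, ir_size_table, junction_report
from .plastome import read_genbank, size_partition, write_size_table, read_size_table
from .stats import clade_summary, divergence_correlations, kruskal_wallis
from .trees import PhyloTree

logger = logging.getLogger(__name__)


class PipelineError(ValueError):
    pass


@dataclass
class PipelineConfig:
    out_dir: Path
    genbank_dir: Optional[Path] = None
    alignment: Optional[Path] = None
    tree: Optional[Path] = None
    clade_map: Optional[Path] = None      # TSV: species<TAB>clade
    node_ages: Optional[Path] = None      # TSV: node<TAB>age
    sizes_table: Optional[Path] = None    # precomputed size table (stats-only runs)
    nodes_table: Optional[Path] = None    # precomputed node table (stats-only runs)
    outgroup: Optional[str] = None
    reference: Optional[str] = None       # reference taxon for region classes
    min_ir_len: int = 1000
    window: int = 600
    step: int = 200
    seed: int = 0
    stages: tuple[str, ...] = ("sizes", "structure", "indels", "ancestral", "stats")

    def config_hash(self) -> str:
        payload = {
            k: str(v) for k, v in dataclasses.asdict(self).items()
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def _load_clade_map(path: Optional[Path]) -> dict[str, str]:
    if path is None:
        return {}
    out = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("species"):
            continue
        sp, clade = line.split("\t")[:2]
        out[sp] = clade
    return out


def run(cfg: PipelineConfig) -> dict:
    """Execute the configured stages and write the analysis report.

    Returns the report dict; files go under ``cfg.out_dir``.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "provenance": {
            "version": __version__,
            "config_hash": cfg.config_hash(),
            "seed": cfg.seed,
        }
    }
    stages = set(cfg.stages)

    needs_seq = stages & {"sizes", "structure", "indels"}
    plastomes = {}
    if needs_seq:
        if cfg.genbank_dir is None:
            raise PipelineError("sequence stages requested but no genbank_dir")
        paths = sorted(Path(cfg.genbank_dir).glob("*.gb")) + sorted(
            Path(cfg.genbank_dir).glob("*.gbk")
        )
        if not paths:
            raise PipelineError(f"no GenBank files in {cfg.genbank_dir}")
        for p in paths:
            plastome = read_genbank(p)
            plastomes[plastome.id] = plastome
        logger.info("loaded %d genomes", len(plastomes))

    clade_map = _load_clade_map(cfg.clade_map)
    sizes = None
    if "sizes" in stages:
        sizes = [
            size_partition(p, clade_map.get(label, "outgroup"))
            for label, p in plastomes.items()
        ]
        write_size_table(sizes, out / "sizes.tsv")
        report["sizes"] = {"n_genomes": len(sizes)}
        logger.info("sizes: %d rows", len(sizes))
    elif cfg.sizes_table is not None:
        sizes = read_size_table(cfg.sizes_table)

    quads = {}
    if "structure" in stages:
        for label, p in plastomes.items():
            try:
                quads[label] = detect_quadripartite(p, min_ir_len=cfg.min_ir_len)
            except NoQuadripartiteError as exc:
                logger.warning("structure: %s", exc)
        table = ir_size_table(plastomes.values(), min_ir_len=cfg.min_ir_len)
        table.to_csv(out / "ir_sizes.tsv", sep="\t", index=False)
        junctions = {}
        for label, q in quads.items():
            rep = junction_report(plastomes[label], q)
            junctions[label] = {
                j: {
                    "position": r.position,
                    "nearest_upstream": r.upstream.name if r.upstream else None,
                    "upstream_distance": r.upstream.distance if r.upstream else None,
                    "nearest_downstream": r.downstream.name if r.downstream else None,
                    "downstream_distance": (
                        r.downstream.distance if r.downstream else None
                    ),
                    "spanning": r.spanning.name if r.spanning else None,
                }
                for j, r in rep.items()
            }
        report["structure"] = {
            "n_detected": len(quads),
            "ir_len_range": (
                [int(table.ir_len.min()), int(table.ir_len.max())]
                if len(table)
                else None
            ),
            "junctions": junctions,
        }
        logger.info("structure: %d/%d genomes", len(quads), len(plastomes))

    tree = None
    if cfg.tree is not None:
        tree = PhyloTree.from_newick(Path(cfg.tree))
        try:
            tree.assign_ages_from_lengths()
        except Exception:
            logger.info("tree not ultrametric; node ages left unset")

    events = []
    nodes_df = None
    if "indels" in stages:
        if cfg.alignment is None or tree is None or cfg.outgroup is None:
            raise PipelineError("indels stage needs alignment, tree, outgroup")
        aln = Alignment.from_fasta(cfg.alignment)
        mismatched = set(aln.taxa) ^ set(tree.tip_labels)
        if mismatched:
            raise PipelineError(
                f"alignment/tree taxon mismatch: {sorted(mismatched)}"
            )
        raw = call_gap_patterns(aln)
        ref_taxon = cfg.reference or aln.taxa[0]
        colmap = alignment_column_map(aln, ref_taxon)
        ref = plastomes.get(ref_taxon)
        q = quads.get(ref_taxon)
        for e in raw:
            e = polarize_and_place(e, tree, cfg.outgroup)
            if ref is not None and q is not None:
                e = classify_region(e, ref.rotated(q.rotation), q, colmap)
            events.append(e)
        events_table(events).to_csv(out / "indel_events.tsv", sep="\t", index=False)

        sizes_by_node = None
        if sizes is not None:
            tip_vals = {
                r.species: float(r.total_bp)
                for r in sizes
                if r.species in set(tree.tip_labels)
            }
            if set(tip_vals) == set(tree.tip_labels):
                rec = scp_reconstruct(tree, tip_vals, weighted=True)
                sizes_by_node = {**rec.node_values}
        nodes_df = node_counts(events, tree, sizes=sizes_by_node)
        nodes_df.to_csv(out / "node_indels.tsv", sep="\t", index=False)
        div = windowed_divergence(aln, window=cfg.window, step=cfg.step)
        div.to_csv(out / "divergence_profile.tsv", sep="\t", index=False)
        report["indels"] = {
            "n_events": len(events),
            "n_deletions": sum(1 for e in events if e.polarity == "deletion"),
            "n_insertions": sum(1 for e in events if e.polarity == "insertion"),
        }
        logger.info("indels: %d events", len(events))

    if "ancestral" in stages and tree is not None and sizes is not None:
        from .ancestral import reconstruct_report

        ingroup_tips = set(tree.tip_labels)
        usable = [r for r in sizes if r.species in ingroup_tips]
        if {r.species for r in usable} == ingroup_tips:
            anc = reconstruct_report(tree, usable)
            anc.to_csv(out / "ancestral_sizes.tsv", sep="\t", index=False)
            root_total = anc[
                (anc.node == tree.root.id) & (anc.character == "total")
            ].value.iloc[0]
            report["ancestral"] = {"root_total_bp": float(root_total)}
        else:
            logger.warning("ancestral: size records incomplete; stage skipped")

    if "stats" in stages:
        if nodes_df is None and cfg.nodes_table is not None:
            import pandas as pd

            nodes_df = pd.read_csv(cfg.nodes_table, sep="\t")
        stats_block: dict = {}
        if nodes_df is not None and {"divergence_time", "indel_count"} <= set(
            nodes_df.columns
        ):
            corr = divergence_correlations(nodes_df)
            stats_block["correlations"] = {
                name: {"R": round(c.rho, 2), "rho": c.rho, "n": c.n, "p": c.p}
                for name, c in corr.items()
            }
        if sizes is not None:
            ingroup = [r for r in sizes if r.clade in ("I", "II", "III", "IV")]
            if ingroup:
                for field_name in ("total", "coding", "noncoding"):
                    stats_block[f"clade_means_{field_name}"] = {
                        s.clade: s.mean_bp
                        for s in clade_summary(ingroup, field_name)
                    }
                groups = {}
                for r in ingroup:
                    groups.setdefault(r.clade, []).append(r.total_bp)
                labels = sorted(groups)
                kw = kruskal_wallis([groups[c] for c in labels], labels)
                stats_block["kruskal_wallis_total"] = {
                    "H": kw.H,
                    "df": kw.df,
                    "p": kw.p,
                    "significant": kw.significant,
                }
        report["stats"] = stats_block

    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report
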