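"""End-to-end orchestration: dedup -> bin -> orthology -> contamination ->
min-taxa filter -> selection -> supermatrix (-> tree support), with a run
manifest recording stage-wise counts.

The contamination screen is advisory: it reports suspected pairs but never
drops taxa on its own.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .contamination import ScreenParams, screen_cross_contamination
from .locus_selection import (
    TreelikenessParams,
    filter_min_taxa,
    select_informative,
    treelikeness,
)
from .orthology import predict_frame, reciprocal_best_hit
from .read_curation import (
    BaitIndex,
    DedupParams,
    MatchParams,
    assign_to_bins,
    deduplicate_pairs,
)
from .seqio_core import (
    LocusAlignment,
    TaxonGroups,
    alignment_from_fasta,
    read_fasta,
    read_fastq_pairs,
    read_newick,
    write_phylip_relaxed,
)
from .supermatrix import concatenate, matrix_stats, write_partition_file
from .treesupport import internode_certainty

__all__ = ["RunManifest", "run_pipeline", "apply_locus_exclusions"]


@dataclass
class RunManifest:
    config: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)
    stats: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)
    started: float = 0.0
    finished: float = 0.0
    version: str = __version__
    failed_stage: str | None = None

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1, default=str)


def apply_locus_exclusions(
    loci: list[LocusAlignment],
    orthology_flagged: set[str],
    min_taxa: int = 4,
) -> tuple[list[LocusAlignment], list[LocusAlignment], list[LocusAlignment]]:
    """Drop orthology-flagged loci, then loci below the taxon minimum.

    Returns ``(analysed, excluded_orthology, excluded_min_taxa)``.
    """
    excluded_orth = [a for a in loci if a.locus_id in orthology_flagged]
    remaining = [a for a in loci if a.locus_id not in orthology_flagged]
    kept, excluded_min = filter_min_taxa(remaining, min_taxa)
    return kept, excluded_orth, excluded_min


def run_pipeline(config: dict) -> RunManifest:
    """Run the stage sequence described by a config mapping (see README
    for the schema); every stage report lands in ``out_dir``."""
    manifest = RunManifest(config=dict(config), started=time.time())
    out_dir = Path(config.get("out_dir", "capcure_run"))
    out_dir.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        match_params = MatchParams(**config.get("match", {}))

        if "reads_dir" in config:
            stage = "dedup"
            dedup_params = DedupParams(**config.get("dedup", {}))
            kept_total = removed_total = 0
            reads_dir = Path(config["reads_dir"])
            for r1 in sorted(reads_dir.glob("*_R1.fastq")):
                r2 = Path(str(r1).replace("_R1.fastq", "_R2.fastq"))
                pairs = read_fastq_pairs(r1, r2)
                kept, removed = deduplicate_pairs(pairs, dedup_params)
                kept_total += len(kept)
                removed_total += len(removed)
            manifest.counts["read_pairs_kept"] = kept_total
            manifest.counts["read_pairs_removed"] = removed_total

        orthology_flagged_loci: set[str] = set()
        if "contigs" in config:
            stage = "bin"
            exons = read_fasta(config["exons"])
            contigs = read_fasta(config["contigs"])
            bins, unassigned = assign_to_bins(contigs, exons, match_params)
            manifest.counts["contigs_binned"] = sum(len(b.members) for b in bins)
            manifest.counts["contigs_unassigned"] = len(unassigned)

            stage = "orthology"
            index = BaitIndex(exons, match_params)
            n_paralogs = 0
            with open(out_dir / "orthology.tsv", "w") as fh:
                fh.write("contig_id\tlocus\treverse_best\tstatus\tframe\tn_stops\n")
                for bin_ in bins:
                    for member in bin_.members:
                        verdict = reciprocal_best_hit(member, bin_.locus_id, index)
                        frame = predict_frame(member)
                        if verdict.status == "paralog_flagged":
                            n_paralogs += 1
                        fh.write(
                            f"{verdict.contig_id}\t{verdict.assigned_locus}"
                            f"\t{verdict.reverse_best_locus}\t{verdict.status}"
                            f"\t{frame.strand}{frame.offset}"
                            f"\t{frame.n_internal_stops_before_trim}\n"
                        )
            manifest.counts["contigs_paralog_flagged"] = n_paralogs

        stage = "load_loci"
        loci_dir = Path(config["loci_dir"])
        loci = [
            alignment_from_fasta(p) for p in sorted(loci_dir.glob("*.fasta"))
        ]
        manifest.counts["loci_input"] = len(loci)

        stage = "contamination"
        if "groups" in config:
            groups = TaxonGroups.from_tsv(config["groups"])
            screen = ScreenParams(**config.get("contamination", {}))
            report = screen_cross_contamination(loci, groups, screen)
            report.to_tsv(out_dir / "contamination.tsv")
            manifest.counts["contamination_suspected_pairs"] = len(
                report.suspected_pairs
            )
            manifest.stats["contamination_max_percentage"] = report.max_percentage

        stage = "min_taxa_filter"
        sel_cfg = dict(config.get("selection", {}))
        min_taxa = sel_cfg.pop("min_taxa", 4)
        n_target = sel_cfg.pop("n_target", None)
        kept, excluded = filter_min_taxa(loci, min_taxa)
        manifest.counts["loci_excluded_min_taxa"] = len(excluded)

        stage = "selection"
        params = TreelikenessParams(**sel_cfg)
        manifest.seeds["treelikeness"] = params.rng_seed
        scores = [treelikeness(aln, params) for aln in kept]
        presence = {a.locus_id: set(a.rows) for a in kept}
        if n_target is None:
            n_target = len(scores)
        n_target = min(n_target, len(scores))
        selected_ids = select_informative(scores, presence, n_target)
        manifest.counts["loci_scored"] = len(scores)
        manifest.counts["loci_selected"] = len(selected_ids)
        with open(out_dir / "scores.tsv", "w") as fh:
            fh.write("locus\tn_taxa\ttreelikeness\tn_quartets\tselected\n")
            chosen = set(selected_ids)
            for s in scores:
                fh.write(
                    f"{s.locus_id}\t{s.n_taxa}\t{s.treelikeness:.6f}"
                    f"\t{s.n_quartets_evaluated}\t{int(s.locus_id in chosen)}\n"
                )

        stage = "supermatrix"
        by_id = {a.locus_id: a for a in kept}
        selected = [by_id[i] for i in selected_ids]
        sm = concatenate(selected)
        stats = matrix_stats(sm)
        write_phylip_relaxed(sm, out_dir / "super.phy")
        write_partition_file(sm, config.get("datatype", "DNA"), out_dir / "super.part")
        manifest.stats["supermatrix"] = {
            "n_taxa": stats.n_taxa,
            "n_sites": stats.n_sites,
            "n_distinct_patterns": stats.n_distinct_patterns,
            "prop_gap_undetermined": stats.prop_gap_undetermined,
        }

        if "reference_tree" in config and "gene_trees" in config:
            stage = "support"
            reference = read_newick(config["reference_tree"])[0]
            gene_trees = read_newick(config["gene_trees"])
            certainty = internode_certainty(reference, gene_trees)
            certainty.to_tsv(out_dir / "ic.tsv")
            manifest.stats["tc"] = certainty.tc
            manifest.stats["relative_tc"] = certainty.relative_tc
    except Exception:
        manifest.failed_stage = stage
        manifest.finished = time.time()
        manifest.write(out_dir / "manifest.json")
        raise
    manifest.finished = time.time()
    manifest.write(out_dir / "manifest.json")
    return manifest
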