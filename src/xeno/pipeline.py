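"""End-to-end orchestration: screen -> triage -> presence/absence -> dating
-> Ka/Ks -> codon usage -> expression, with per-stage structured logging.

The pipeline runs either on a synthetic bundle (the default demo: no inputs
needed) or on user-provided FASTA/FASTQ/Newick inputs whose records carry
``taxon=`` header fields.  All stochastic stages draw from the single
configured seed, so identical configurations produce byte-identical
reports.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

from . import io as xio
from .config import RunConfig
from .dating import (
    build_presence_matrix,
    design_cross_species_primers,
    donor_divergence_constraint,
    infer_transfer_window,
    insilico_pcr,
)
from .expression import expression_rows, expression_table
from .molevol import (
    clade_nesting_check,
    codon_usage_profile,
    group_kaks,
    nei_gojobori,
    nj_tree,
    p_distance_matrix,
)
from .records import ReadSet, SequenceRecord, translate_cds
from .screen import (
    Panels,
    candidate_summary,
    classify_hits,
    collapse_unique_reads,
    hits_to_outfmt6,
    local_search,
)
from .simulate import (
    CLAVICEPS_TIPS,
    EPICHLOE_TIPS,
    OUTGROUP_TIPS,
    simulate_bundle,
)
from .tree import CalibratedTree

logger = logging.getLogger("xeno")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineData:
    host_genes: dict[str, dict[str, SequenceRecord]]
    donor_genes: dict[str, dict[str, SequenceRecord]]
    host_tree: CalibratedTree
    donor_tree: CalibratedTree
    libraries: list[ReadSet]
    focal_host: str
    focal_donor: str
    outgroup_taxa: list[str]
    donor_crown_taxa: list[str]
    truth: object | None = None


def _group_by_taxon(records: list[SequenceRecord]) -> dict[str, dict[str, SequenceRecord]]:
    out: dict[str, dict[str, SequenceRecord]] = {}
    for rec in records:
        gene = rec.id.split("|")[0]
        out.setdefault(rec.taxon, {})[gene] = rec
    return out


def load_pipeline_data(config: RunConfig) -> PipelineData:
    """Assemble pipeline inputs: external files where given, synthetic else."""
    if config.host_fasta and config.donor_fasta:
        host_records = xio.read_fasta(config.host_fasta, moltype="dna_cds")
        donor_records = xio.read_fasta(config.donor_fasta, moltype="dna_cds")
        host_genes = _group_by_taxon(host_records)
        donor_genes = _group_by_taxon(donor_records)
        host_tree = xio.read_newick(config.host_tree) if config.host_tree else None
        donor_tree = xio.read_newick(config.donor_tree) if config.donor_tree else None
        libraries = [xio.read_fastq(p) for p in config.reads_fastq]
        sim = config.simulation
        outgroups = [t for t in OUTGROUP_TIPS if t in host_genes]
        crown = [t for t in EPICHLOE_TIPS if t in donor_genes] or sorted(donor_genes)
        if host_tree is None or donor_tree is None:
            raise ValueError("external inputs require host_tree and donor_tree Newick files")
        return PipelineData(
            host_genes=host_genes, donor_genes=donor_genes,
            host_tree=host_tree, donor_tree=donor_tree, libraries=libraries,
            focal_host=sim.focal_host, focal_donor=sim.focal_donor,
            outgroup_taxa=outgroups, donor_crown_taxa=crown,
        )
    bundle = simulate_bundle(config.simulation)
    return PipelineData(
        host_genes=bundle.host_genes, donor_genes=bundle.donor_genes,
        host_tree=bundle.host_tree, donor_tree=bundle.donor_tree,
        libraries=bundle.read_libraries,
        focal_host=config.simulation.focal_host,
        focal_donor=config.simulation.focal_donor,
        outgroup_taxa=list(OUTGROUP_TIPS),
        donor_crown_taxa=list(EPICHLOE_TIPS),
        truth=bundle.truth,
    )


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the aggregated report (JSON-serialisable).

    On stage failure, partial outputs are flushed to the output directory and
    a StageError naming the stage is raised.
    """
    os.makedirs(config.output_dir, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": {}, "log": []}

    def log(stage: str, **fields) -> None:
        entry = {"stage": stage, **fields}
        report["log"].append(entry)
        logger.info("%s", json.dumps(entry, sort_keys=True, default=str))

    def flush() -> None:
        xio.write_json(report, os.path.join(config.output_dir, "report.json"))

    stage = "load"
    try:
        data = load_pipeline_data(config)
        log("load", host_taxa=len(data.host_genes), donor_taxa=len(data.donor_genes),
            libraries=len(data.libraries))

        # ---- screen ----------------------------------------------------
        stage = "screen"
        focal_transcripts = sorted(
            data.host_genes.get(data.focal_host, {}).values(), key=lambda r: r.id
        )
        all_reads = [r for lib in data.libraries for r in lib]
        merged = ReadSet(reads=all_reads, library_size=len(all_reads), library_id="merged")
        unique = collapse_unique_reads(merged) if len(merged) else None
        read_queries = (
            [
                SequenceRecord(id=uid, seq=seq, taxon=data.focal_host)
                for uid, seq in zip(unique.ids, unique.sequences)
            ]
            if unique
            else []
        )
        queries = focal_transcripts + read_queries
        subjects = sorted(
            data.donor_genes.get(data.focal_donor, {}).values(), key=lambda r: r.id
        )
        hits = local_search(queries, subjects, config.screen)
        panels = Panels(
            outgroup_plant=[
                rec for taxon in data.outgroup_taxa
                for rec in data.host_genes.get(taxon, {}).values()
            ],
            host_assembly=focal_transcripts,
            donor=subjects,
        )
        classifications, counts = classify_hits(
            hits, queries, panels, config.triage, config.screen
        )
        candidates = candidate_summary(classifications)
        log("screen", reads_total=len(merged), unique_reads=len(unique) if unique else 0,
            hits_total=len(hits), excluded_low_similarity=counts["low_similarity"],
            excluded_conserved=counts["conserved_eukaryote"],
            excluded_microbiome=counts["microbiome"],
            candidates=counts["hgt_candidate"])
        report["stages"]["screen"] = {
            "reads_total": len(merged),
            "unique_reads": len(unique) if unique else 0,
            "hits_total": len(hits),
            "counts": counts,
            "candidate_genes": sorted(
                {g.split("|")[0] for g in candidates["subject_gene"]}
            ) if len(candidates) else [],
            "candidate_table": candidates.to_dict(orient="records"),
        }
        cols = ("qseqid sseqid pident length mismatch gapopen qstart qend "
                "sstart send evalue bitscore").split()
        xio.write_tsv(
            [dict(zip(cols, line.split("\t"))) for line in hits_to_outfmt6(hits)],
            os.path.join(config.output_dir, "hits.tsv"),
            columns=cols,
        )

        candidate_genes = report["stages"]["screen"]["candidate_genes"]

        # ---- presence/absence + dating ---------------------------------
        stage = "presence_dating"
        presence_report = {}
        dating_report = {}
        taxa = sorted(data.host_genes)
        for gene in candidate_genes:
            host_copy = data.host_genes.get(data.focal_host, {}).get(gene)
            if host_copy is None:
                continue
            in_silico = {}
            for taxon in taxa:
                templates = sorted(data.host_genes[taxon].values(), key=lambda r: r.id)
                found = bool(local_search([host_copy], templates, config.cross_species))
                in_silico[(taxon, gene)] = found
            carrier_seqs = [
                data.host_genes[t][gene].seq
                for t in taxa
                if gene in data.host_genes[t] and in_silico.get((t, gene))
            ]
            primers = design_cross_species_primers(
                carrier_seqs, name=f"{gene}_assay", max_product_len=config.max_amplicon_len
            )
            pcr = {}
            if primers is not None:
                for taxon in taxa:
                    templates = sorted(data.host_genes[taxon].values(), key=lambda r: r.id)
                    amps = insilico_pcr(primers, templates, config.max_amplicon_len)
                    pcr[(taxon, gene)] = any(a.amplified for a in amps)
            matrix = build_presence_matrix(in_silico, pcr, taxa, [gene])
            presence_report[gene] = {
                "matrix": matrix.to_rows(),
                "conflicts": [list(c) for c in matrix.conflicts],
                "primers": (
                    {"forward": primers.forward, "reverse": primers.reverse}
                    if primers else None
                ),
            }
            # donor-side placement from the gene phylogram
            placement, constraint = None, None
            alignment = {}
            for t in taxa:
                if gene in data.host_genes[t] and matrix.call(t, gene) == "present":
                    alignment[f"host__{t}"] = translate_cds(data.host_genes[t][gene].seq)
            for t in sorted(data.donor_genes):
                if gene in data.donor_genes[t]:
                    alignment[f"donor__{t}"] = translate_cds(data.donor_genes[t][gene].seq)
            focal_ids = [k for k in alignment if k.startswith("host__")]
            crown_ids = [f"donor__{t}" for t in data.donor_crown_taxa
                         if f"donor__{t}" in alignment]
            out_ids = [f"donor__{t}" for t in CLAVICEPS_TIPS if f"donor__{t}" in alignment]
            if len(alignment) >= 3 and focal_ids and crown_ids and out_ids:
                tree = nj_tree(p_distance_matrix(alignment))
                placement = clade_nesting_check(tree, focal_ids, crown_ids, out_ids)
                if placement in ("nested_in_crown", "sister_to_crown"):
                    constraint = donor_divergence_constraint(
                        data.donor_tree, placement, data.donor_crown_taxa
                    )
            try:
                window = infer_transfer_window(
                    matrix, data.host_tree, gene, constraint,
                    loss_policy=config.loss_policy,
                )
                dating_report[gene] = {
                    "lower_mya": window.lower_mya, "upper_mya": window.upper_mya,
                    "host_constraint": list(window.host_constraint),
                    "donor_placement": placement,
                    "donor_constraint_mya": constraint,
                    "implied_losses": window.implied_losses,
                }
            except ValueError as exc:
                dating_report[gene] = {"error": str(exc)}
            log("dating", gene=gene, **{
                k: v for k, v in dating_report[gene].items() if k != "implied_losses"
            })
        report["stages"]["presence"] = presence_report
        report["stages"]["dating"] = dating_report

        # ---- Ka/Ks groups ----------------------------------------------
        stage = "kaks"
        kaks_report = {}
        host_ages = {  # divergence ages between host groups, from the tree
            "triticeae_poeae": data.host_tree.node("TriticeaePoeae").age
            if "TriticeaePoeae" in data.host_tree._index else None,
        }
        for gene in candidate_genes:
            groups = []
            host_carriers = [t for t in taxa if gene in data.host_genes[t]
                             and data.host_genes[t][gene] is not None]
            donor_taxa = [t for t in sorted(data.donor_genes)
                          if gene in data.donor_genes[t]]
            crown = [t for t in donor_taxa if t in data.donor_crown_taxa]
            claviceps = [t for t in donor_taxa if t in CLAVICEPS_TIPS]

            def aligned(a, b):
                return nei_gojobori(a.seq, b.seq, id_a=a.taxon, id_b=b.taxon)

            def add_group(pairs, T, label):
                # groups whose pairs all sit past JC saturation are reported
                # as skipped rather than aborting the stage
                try:
                    groups.append(group_kaks(pairs, T, label=label,
                                             ratio_mode=config.ratio_mode))
                except ValueError as exc:
                    log("kaks_skipped", gene=gene, group=label, reason=str(exc))

            # plants split across the Triticeae-Poeae divergence
            if host_ages["triticeae_poeae"]:
                node = data.host_tree.node("TriticeaePoeae")
                sides = [data.host_tree.tip_set(c) for c in node.children]
                if len(sides) == 2:
                    left = [t for t in host_carriers if t in sides[0]]
                    right = [t for t in host_carriers if t in sides[1]]
                    pairs = [
                        aligned(data.host_genes[a][gene], data.host_genes[b][gene])
                        for a in left for b in right
                    ]
                    if pairs:
                        add_group(pairs, host_ages["triticeae_poeae"], "Triticeae-Poeae")
            # within-donor combinations
            crown_age = data.donor_tree.mrca(data.donor_crown_taxa).age if crown else None
            if len(crown) >= 2 and "Epichloe_gansuensis" in crown:
                others = [t for t in crown if t != "Epichloe_gansuensis"]
                pairs = [
                    aligned(data.donor_genes["Epichloe_gansuensis"][gene],
                            data.donor_genes[t][gene])
                    for t in others
                ]
                add_group(pairs, crown_age, "E._gansuensis-other_Epichloe")
            if claviceps and crown:
                stem_age = data.donor_tree.root_age
                pairs = [
                    aligned(data.donor_genes[c][gene], data.donor_genes[t][gene])
                    for c in claviceps for t in crown
                ]
                add_group(pairs, stem_age, "Claviceps-Epichloe")
                host_pairs = [
                    aligned(data.donor_genes[c][gene], data.host_genes[t][gene])
                    for c in claviceps for t in host_carriers
                ]
                if host_pairs:
                    add_group(host_pairs, stem_age, "Claviceps-plants")
            kaks_report[gene] = [
                {k: getattr(g, k) for k in ("label", "T", "n_pairs", "Ks_avg", "Ks_sdv",
                                            "Ks_rate", "Ka_avg", "Ka_sdv", "Ka_rate",
                                            "ratio")}
                for g in groups
            ]
            log("kaks", gene=gene, groups=len(groups))
        report["stages"]["kaks"] = kaks_report

        # ---- codon usage -----------------------------------------------
        stage = "codon_usage"
        usage_report = {}
        for gene in candidate_genes:
            plant = [data.host_genes[t][gene].seq for t in taxa
                     if gene in data.host_genes[t]]
            fungal = [data.donor_genes[t][gene].seq
                      for t in sorted(data.donor_genes)
                      if gene in data.donor_genes[t] and t in data.donor_crown_taxa]
            entry = {}
            if plant:
                entry["plant_termination"] = codon_usage_profile(plant).ratios.get("*", {})
            if fungal:
                entry["donor_termination"] = codon_usage_profile(fungal).ratios.get("*", {})
            usage_report[gene] = entry
        report["stages"]["codon_usage"] = usage_report
        log("codon_usage", genes=len(usage_report))

        # ---- expression -------------------------------------------------
        stage = "expression"
        expr_genes = [
            data.host_genes[data.focal_host][g]
            for g in candidate_genes
            if g in data.host_genes.get(data.focal_host, {})
        ]
        records = expression_table(expr_genes, data.libraries, config.min_perfect_match)
        report["stages"]["expression"] = expression_rows(records)
        log("expression", genes=len(expr_genes), libraries=len(data.libraries),
            records=len(records))

        flush()
        return report
    except StageError:
        flush()
        raise
    except Exception as exc:  # noqa: BLE001 - annotate failing stage
        flush()
        raise StageError(stage, exc) from exc
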