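"""End-to-end pipeline: filter -> panel -> gene trees -> consensus ->
peptide analysis -> expression -> congruence, with a deterministic run
directory (trees/, tables/, report.txt)."""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from . import expression as expr
from . import hkg, peptides, phylo, simulate
from .config import RunConfig
from .io_formats import write_newick_file
from .trees import write_newick

logger = logging.getLogger("turriphylo.pipeline")


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def _log(stage: str, message: str) -> None:
    logger.info("[%s] %s", stage, message)


def run_pipeline(config: RunConfig, out_dir) -> Path:
    out_dir = Path(out_dir)
    trees_dir = out_dir / "trees"
    tables_dir = out_dir / "tables"
    trees_dir.mkdir(parents=True, exist_ok=True)
    tables_dir.mkdir(parents=True, exist_ok=True)

    report: list[str] = [f"mode: {config.mode}", f"seed: {config.seed}"]

    if config.mode == "simulate":
        _run_simulate(config, trees_dir, tables_dir, report)
    else:
        _run_fixture(config, trees_dir, tables_dir, report)

    report_path = out_dir / "report.txt"
    report_path.write_text("\n".join(report) + "\n", encoding="utf-8")
    _log("report", f"wrote {len(report)} lines")
    return out_dir


def _run_simulate(config: RunConfig, trees_dir, tables_dir, report) -> None:
    sim = config.simulation

    try:
        species_tree = simulate.simulate_species_tree(sim.n_species, seed=sim.seed)
        gene_trees = simulate.simulate_gene_trees(
            species_tree,
            sim.n_genes,
            sim.discordance_rate,
            seed=sim.seed + 1,
            branch_jitter_sd=sim.branch_jitter_sd,
        )
    except Exception as exc:
        raise StageError("simulate-trees", str(exc)) from exc
    (trees_dir / "species_tree.nwk").write_text(
        write_newick(species_tree) + "\n", encoding="utf-8"
    )
    write_newick_file(gene_trees, trees_dir / "gene_trees.nwk")
    _log("simulate-trees", f"{sim.n_species} species, {len(gene_trees)} gene trees")
    report.append(f"species: {sim.n_species}")
    report.append(f"gene trees: {len(gene_trees)}")

    samples = species_tree.leaf_names()

    if config.run_panel:
        try:
            annotations = simulate.simulate_annotation_table(
                samples, n_shared=sim.n_genes, n_private=sim.n_private_genes,
                seed=sim.seed + 2,
            )
            annotations.to_csv(tables_dir / "annotations.tsv", sep="\t", index=False)
            kept = hkg.filter_hits(annotations, e_threshold=config.e_threshold)
            panel = hkg.build_panel(kept)
            panel.to_table().to_csv(tables_dir / "hkg_panel.tsv", sep="\t", index=False)
        except Exception as exc:
            raise StageError("hkg-panel", str(exc)) from exc
        _log("hkg-panel", f"{len(annotations)} annotation rows -> panel of {panel.size}")
        report.append(f"hkg panel size: {panel.size}")
    else:
        panel = None

    if config.run_consensus:
        try:
            result = phylo.consensus_with_support(
                gene_trees, min_frequency=config.min_frequency
            )
            rf = phylo.robinson_foulds(result.tree, species_tree)
        except Exception as exc:
            raise StageError("consensus", str(exc)) from exc
        (trees_dir / "consensus.nwk").write_text(
            write_newick(result.tree, support_digits=2) + "\n", encoding="utf-8"
        )
        supports = sorted(result.support_values())
        mean_support = sum(supports) / len(supports) if supports else float("nan")
        _log("consensus", f"RF to species tree = {rf}")
        report.append(f"consensus RF to species tree: {rf}")
        report.append(f"mean consensus support: {mean_support:.4f}")

    if config.run_peptides:
        try:
            precursors = simulate.simulate_toxin_precursors(samples, sim)
            prec_df = pd.DataFrame(
                {
                    "species": [p.species for p in precursors],
                    "precursor_id": [p.precursor_id for p in precursors],
                    "superfamily": [p.superfamily for p in precursors],
                    "signal": [p.signal for p in precursors],
                    "pro": [p.pro for p in precursors],
                    "mature": [p.mature for p in precursors],
                }
            )
            prec_df.to_csv(tables_dir / "precursors.tsv", sep="\t", index=False)
            profiles = [peptides.extract_framework(p.mature) for p in precursors]
            n_cys_values = sorted({pr.n_cys for pr in profiles})
        except Exception as exc:
            raise StageError("peptides", str(exc)) from exc
        _log("peptides", f"{len(precursors)} precursors, n_cys values {n_cys_values}")
        report.append(f"precursors: {len(precursors)}")
        report.append(f"cysteine counts observed: {n_cys_values}")

    if config.run_expression and panel is not None:
        try:
            contig_rows = []
            for (sample, gene), contig in sorted(panel.representatives.items()):
                contig_rows.append((sample, contig, "hkg"))
            toxin_ids = []
            for sample in samples:
                tox = f"{sample}_toxA"
                toxin_ids.append(tox)
                contig_rows.append((sample, tox, "toxin"))
            planted = {(samples[0], f"{samples[0]}_toxA"): 8.0}
            table = simulate.simulate_expression(
                contig_rows, sim, seed=sim.seed + 3, planted=planted
            )
            table.to_csv(tables_dir / "expression.tsv", sep="\t", index=False)
            rep = expr.expression_report(table, panel, toxin_ids)
            rep.to_csv(tables_dir / "expression_report.tsv", sep="\t", index=False)
        except Exception as exc:
            raise StageError("expression", str(exc)) from exc
        top = rep[rep["is_top"]]
        _log("expression", f"{len(rep)} report rows")
        report.append(f"expression rows: {len(rep)}")
        lead = top[top["sample_id"] == samples[0]]
        if not lead.empty:
            report.append(
                "planted lead fold change: "
                f"{float(lead.iloc[0]['log2_fold_vs_hkg']):.4f}"
            )


def _run_fixture(config: RunConfig, trees_dir, tables_dir, report) -> None:
    from . import congruence as cong

    try:
        records = peptides.load_reference_peptides()
    except Exception as exc:
        raise StageError("fixture-load", str(exc)) from exc
    report.append(f"fixture records: {len(records)}")
    report.append(f"clade labels: {sorted({r.clade for r in records})}")

    try:
        census = peptides.framework_census(records)
    except Exception as exc:
        raise StageError("census", str(exc)) from exc
    census.to_table().to_csv(tables_dir / "framework_census.tsv", sep="\t", index=False)
    report.append(f"modal cysteine count: {census.modal_n_cys}")
    for clade in sorted(census.clade_loop1):
        report.append(f"clade {clade} loop1 lengths: {census.clade_loop1[clade]}")
    report.append(
        "framework outliers: "
        + (", ".join(r.toxin_name for r in census.outliers) or "none")
    )

    try:
        clade12 = [r for r in records if r.clade in ("I", "II")]
        motif = peptides.consensus_motif(
            clade12,
            loop_index=1,
            include_threshold=config.motif_include_threshold,
            dominance_threshold=config.motif_dominance_threshold,
        )
    except Exception as exc:
        raise StageError("motif", str(exc)) from exc
    report.append(f"clade I+II loop1 motif: {motif}")

    groups = peptides.deduplicate(records)
    n_dupe = sum(1 for g in groups if len(g.records) > 1)
    report.append(f"duplicate mature-sequence groups: {n_dupe}")

    if config.run_congruence:
        try:
            comp = cong.genus_composition(records)
            comp.to_table().to_csv(
                tables_dir / "clade_composition.tsv", sep="\t", index=False
            )
            result = cong.exclusivity_permutation_test(
                records, n_permutations=config.n_permutations, seed=config.seed
            )
        except Exception as exc:
            raise StageError("congruence", str(exc)) from exc
        report.append(f"mixed clades: {result.observed}")
        report.append(f"exclusivity p-value: {result.p_value:.6g}")
        report.append(cong.CAVEAT)

    if config.run_peptides:
        try:
            tree = peptides.build_peptide_tree(records)
            partition = peptides.clade_partition(tree)
            table = peptides.partition_concordance(partition, records)
        except Exception as exc:
            raise StageError("peptide-tree", str(exc)) from exc
        (trees_dir / "peptide_tree.nwk").write_text(
            write_newick(tree) + "\n", encoding="utf-8"
        )
        table.to_csv(tables_dir / "clade_concordance.tsv", sep="\t")
        agree = 0
        total = 0
        by_name = {r.toxin_name: r for r in records}
        # majority mapping between de novo labels and published clades
        mapping = {}
        for label in partition.labels:
            members = [l for l, lab in partition.assignment.items() if lab == label]
            published = [by_name[m].clade for m in members if m in by_name]
            if published:
                mapping[label] = max(set(published), key=published.count)
        for leaf, label in partition.assignment.items():
            rec = by_name.get(leaf)
            if rec is None:
                continue
            total += 1
            if mapping.get(label) == rec.clade:
                agree += 1
        report.append(
            f"peptide-tree clade concordance: {agree}/{total} records "
            f"(degenerate={partition.degenerate})"
        )
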