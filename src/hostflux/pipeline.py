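"""End-to-end pipeline orchestration.

``run_pipeline`` executes the stages in dependency order on a synthetic
dataset (or on user-supplied inputs via the CLI subcommands), writes each
stage's outputs under the run directory, and produces a deterministic JSON
summary: identical config (including seed) ⇒ byte-identical summary.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from hostflux import adhesion as adhesion_mod
from hostflux import io as hio
from hostflux import ordination as ord_mod
from hostflux import pangenome as pan_mod
from hostflux import pangwas as gwas_mod
from hostflux import gene_flux as flux_mod
from hostflux import host_evolution as host_mod
from hostflux import phylostructure as struct_mod
from hostflux import prophage as prophage_mod
from hostflux import simulate as sim_mod
from hostflux.errors import ConfigurationError, InputError

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Pipeline defaults follow the source analysis: core threshold 0.95,
    PHI 100 permutations, alpha 0.05, sensitivity/specificity 70%, GWAS
    1000 permutations, prophage fragment floor 5000 bp."""

    seed: int = 0
    core_threshold: float = 0.95
    phi_permutations: int = 100
    phi_window: int = 100
    phi_alpha: float = 0.05
    gwas_alpha: float = 0.05
    sens_min: float = 70.0
    spec_min: float = 70.0
    gwas_adjust: str = "bh"
    gwas_permutations: int = 1000
    prophage_min_fragment: int = 5000
    tree_method: str = "upgma"
    n_bootstrap: int = 0
    n_content_groups: int = 4
    anosim_permutations: int = 999
    nmds_restarts: int = 8
    simulation: sim_mod.SimulationConfig = field(default_factory=sim_mod.SimulationConfig)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        sim_raw = raw.pop("simulation", {})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        sim_known = {f.name for f in dataclasses.fields(sim_mod.SimulationConfig)}
        sim_unknown = set(sim_raw) - sim_known
        if sim_unknown:
            raise ConfigurationError(f"unknown simulation config keys: {sorted(sim_unknown)}")
        if "host_labels" in sim_raw:
            sim_raw["host_labels"] = tuple(sim_raw["host_labels"])
        sim = sim_mod.SimulationConfig(**sim_raw)
        cfg = cls(simulation=sim, **raw)
        if "seed" in raw and "seed" not in sim_raw:
            cfg.simulation = sim.replace(seed=cfg.seed)
        return cfg

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["simulation"]["host_labels"] = list(out["simulation"]["host_labels"])
        return out


def run_pipeline(config: PipelineConfig, outdir: Path) -> dict:
    """Run all nine stages on a fresh simulation; returns the summary dict
    (also written to ``summary.json``)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    hio.write_json(outdir / "effective_config.json", config.to_dict())
    sim = config.simulation
    summary: dict = {}

    # -------------------------------------------------- simulate
    tree, truth_tree = sim_mod.simulate_host_phylogeny(sim)
    genomes, families, values, truth_content = sim_mod.simulate_gene_content(tree, sim)
    gene_seqs, truth_rec = sim_mod.simulate_core_alignment(tree, sim)
    lineage_map = truth_tree.lineages
    prophage_sets, truth_phage = sim_mod.simulate_prophage_repertoires(tree, lineage_map, sim)

    hio.write_newick(outdir / "true_tree.nwk", tree)
    hio.write_presence_tsv(outdir / "presence_absence.tsv", genomes, families,
                           np.asarray(values))
    meta = pd.DataFrame({
        "genome": genomes,
        "host": [tree.find(g).host for g in genomes],
        "lineage": [lineage_map[g] for g in genomes],
    })
    meta.to_csv(outdir / "metadata.csv", index=False)
    aln_dir = outdir / "core_genes"
    aln_dir.mkdir(exist_ok=True)
    for gene, seqs in gene_seqs.items():
        hio.write_fasta(aln_dir / f"{gene}.fasta", seqs)
    truth = sim_mod.TruthLog(
        lineages=lineage_map,
        host_switches=truth_tree.host_switches,
        gene_events=truth_content.gene_events,
        root_families=truth_content.root_families,
        recombination=truth_rec.recombination,
        prophage_transfers=truth_phage.prophage_transfers,
    )
    hio.write_json(outdir / "truth_log.json", truth.to_dict())
    summary["simulate"] = {
        "n_genomes": len(genomes),
        "n_families": len(families),
        "n_core_genes": len(gene_seqs),
        "n_host_switches": len(truth_tree.host_switches),
        "n_prophage_transfers": len(truth_phage.prophage_transfers),
    }

    # -------------------------------------------------- pangenome
    matrix = pan_mod.PresenceAbsenceMatrix(genomes, families, values,
                                           provenance="simulation")
    partition = pan_mod.partition_core_accessory(matrix, config.core_threshold)
    heaps = pan_mod.pan_accumulation(matrix, seed=config.seed)
    basis = partition.accessory if partition.accessory else None
    jac_labels, jac = pan_mod.jaccard_distances(matrix, basis=basis)
    hio.write_distance_tsv(outdir / "jaccard.tsv", jac_labels, jac)
    summary["pangenome"] = {
        "core": len(partition.core),
        "accessory": len(partition.accessory),
        "singleton": len(partition.singleton),
        "heaps_gamma": round(heaps["gamma"], 6),
        "open": heaps["open"],
    }

    # -------------------------------------------------- structure
    gene_alignments = {g: struct_mod.Alignment.from_dict(s, partition=g)
                       for g, s in gene_seqs.items()}
    phi = {g: struct_mod.phi_recombination_test(
        a, window=config.phi_window, n_permutations=config.phi_permutations,
        seed=config.seed) for g, a in gene_alignments.items()}
    concat = struct_mod.concatenate_recombination_free(gene_alignments, phi,
                                                       alpha=config.phi_alpha)
    snp_labels, snp = struct_mod.snp_distances(concat)
    ani_labels, ani, _ = struct_mod.core_identity(concat)
    hio.write_distance_tsv(outdir / "snp_distances.tsv", snp_labels, snp)
    hio.write_distance_tsv(outdir / "core_identity.tsv", ani_labels, ani)
    core_tree = struct_mod.distance_tree(snp_labels, snp, method=config.tree_method,
                                         bootstrap_alignment=concat if config.n_bootstrap else None,
                                         n_bootstrap=config.n_bootstrap,
                                         seed=config.seed)
    hio.write_newick(outdir / "core_tree.nwk", core_tree)
    lineages_called, threshold = struct_mod.delineate_lineages(snp_labels, snp)
    pd.DataFrame({"genome": list(lineages_called),
                  "lineage": [lineages_called[g] for g in lineages_called]}
                 ).to_csv(outdir / "lineages.csv", index=False)
    summary["structure"] = {
        "n_genes_pass_phi": sum(1 for r in phi.values() if r.p_value >= config.phi_alpha),
        "n_genes_total": len(phi),
        "alignment_length": concat.length,
        "snp_threshold": round(threshold, 6),
        "n_lineages_called": len({v for v in lineages_called.values() if v != "unassigned"}),
    }

    # -------------------------------------------------- ordination
    content_tree = struct_mod.distance_tree(jac_labels, jac, method="upgma")
    hio.write_newick(outdir / "content_tree.nwk", content_tree)
    nmds = ord_mod.nmds_embed(jac_labels, jac, n_restarts=config.nmds_restarts,
                              seed=config.seed)
    groups = ord_mod.cut_tree_groups(content_tree, config.n_content_groups)
    # ANOSIM over delineated lineages, excluding unassigned genomes and
    # groups too small to contribute within-group pairs
    from collections import Counter
    sizes = Counter(lineages_called[g] for g in jac_labels)
    keep = [g for g in jac_labels
            if lineages_called[g] != "unassigned" and sizes[lineages_called[g]] >= 2]
    keep_idx = [jac_labels.index(g) for g in keep]
    anosim_lineage = None
    if len({lineages_called[g] for g in keep}) >= 2:
        anosim_lineage = ord_mod.anosim(keep, jac[np.ix_(keep_idx, keep_idx)],
                                        {g: lineages_called[g] for g in keep},
                                        n_permutations=config.anosim_permutations,
                                        seed=config.seed)
    topo = ord_mod.compare_trees(core_tree, content_tree)
    coords = pd.DataFrame(nmds.coordinates, columns=["nmds1", "nmds2"])
    coords.insert(0, "genome", nmds.labels)
    coords.to_csv(outdir / "nmds_coordinates.tsv", sep="\t", index=False)
    summary["ordination"] = {
        "stress": round(nmds.stress, 6),
        "anosim_r": (round(anosim_lineage.statistic, 6)
                     if anosim_lineage is not None else None),
        "anosim_p": (round(anosim_lineage.p_value, 6)
                     if anosim_lineage is not None else None),
        "rf_core_vs_content": topo["rf"],
        "n_content_groups": len(set(groups.values())),
    }

    # -------------------------------------------------- gwas
    accessory_matrix = (matrix.subset_families(partition.accessory)
                        if partition.accessory else matrix)
    specific: dict[str, list[str]] = {}
    gwas_rows = []
    lineage_names = sorted({v for v in lineage_map.values()})
    for lineage in lineage_names:
        trait = {g: int(lineage_map[g] == lineage) for g in genomes}
        if sum(trait.values()) in (0, len(genomes)):
            continue
        results = gwas_mod.select_specific_genes(
            accessory_matrix, trait, sens_min=config.sens_min,
            spec_min=config.spec_min, alpha=config.gwas_alpha,
            adjust=config.gwas_adjust, n_permutations=config.gwas_permutations,
            seed=config.seed)
        specific[lineage] = [r.family for r in results if r.specific]
        for r in results:
            if r.specific:
                gwas_rows.append({"trait": lineage, "family": r.family,
                                  "sensitivity": r.sensitivity,
                                  "specificity": r.specificity,
                                  "p_naive": r.p_naive, "p_bh": r.p_bh,
                                  "p_bonferroni": r.p_bonferroni,
                                  "p_empirical": r.p_empirical})
    pd.DataFrame(gwas_rows).to_csv(outdir / "specific_genes.tsv", sep="\t", index=False)
    summary["gwas"] = {lin: len(specific.get(lin, [])) for lin in lineage_names}

    # -------------------------------------------------- flux
    flux = flux_mod.ml_gain_loss_fit(tree, genomes, families, values,
                                     seed=config.seed)
    content = flux_mod.ancestral_content(flux, tree)
    origins = flux_mod.classify_specific_origins(specific, flux, tree, lineage_map)
    hio.write_json(outdir / "flux_report.json", flux.to_dict())
    gained = sum(t[flux_mod.OriginClassification.GAINED] for t in origins.tallies.values())
    total_specific = sum(len(v) for v in specific.values())
    summary["flux"] = {
        "gain_rate": round(flux.rates["background"][0], 6),
        "loss_rate": round(flux.rates["background"][1], 6),
        "root_count": content["root_count"],
        "mean_tip_count": round(content["mean_tip_count"], 3),
        "expansion": content["expansion"],
        "specific_gained": gained,
        "specific_total": total_specific,
    }

    # -------------------------------------------------- hosts
    dated = host_mod.strict_clock_date(core_tree, root_age=1.0)
    host_labels = {g: tree.find(g).host for g in genomes}
    history = host_mod.ancestral_hosts(dated.tree, host_labels,
                                       model="ctmc_asymmetric", seed=config.seed)
    switches = host_mod.enumerate_host_switches(history, dated.tree)
    hio.write_newick(outdir / "dated_tree.nwk", dated.tree)
    pd.DataFrame(switches).to_csv(outdir / "host_switches.tsv", sep="\t", index=False)
    root_name = dated.tree.root.name
    summary["hosts"] = {
        "clock_rate": round(dated.rate, 8),
        "root_host": history.modal[root_name],
        "n_switches": len(switches),
    }

    # -------------------------------------------------- prophage
    exchange = prophage_mod.exchange_summary(prophage_sets, lineage_map,
                                             min_fragment=config.prophage_min_fragment)
    hio.write_distance_tsv(outdir / "prophage_exchange.tsv", exchange.lineages,
                           np.nan_to_num(exchange.percentages, nan=-1.0))
    ratio = exchange.intra_inter_ratio
    summary["prophage"] = {
        "intra_inter_ratio": ("inf" if np.isinf(ratio) else
                              "nan" if np.isnan(ratio) else round(ratio, 4)),
        "retained": exchange.retained_counts,
    }

    # -------------------------------------------------- adhesion
    host_frac = {}
    for group in set(groups.values()):
        members = [g for g, gr in groups.items() if gr == group]
        host_frac[group] = np.mean([host_labels[g] == sim.root_host for g in members])
    rodent_group = max(sorted(host_frac), key=lambda g: host_frac[g])
    assay = sim_mod.simulate_adhesion_assay(genomes, groups, rodent_group, sim)
    classified = adhesion_mod.classify_table(assay)
    classified.to_csv(outdir / "adhesion_classified.csv", index=False)
    n_effective = int((classified["adhesion_class"] == "effective").sum())
    summary["adhesion"] = {
        "rodent_group": rodent_group,
        "n_effective": n_effective,
        "n_ineffective": int((classified["adhesion_class"] == "ineffective").sum()),
        "n_intermediate": int((classified["adhesion_class"] == "intermediate").sum()),
    }

    hio.write_json(outdir / "summary.json", summary)
    return summary
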