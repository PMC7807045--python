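"""End-to-end orchestration of the accelerated-aging analysis.

This driver wires the stages together the way the striatal study does:
island calling on bulk H3K27ac tracks per sample, high-confidence lists per
condition merged into one region universe, background-equalized size
factors, genotype and age differential contrasts, the NeuN+/NeuN- enhancer
catalogue, cell-type attribution of differential regions, the age-by-
genotype concordance statistics, RNA differential expression with k-means
epigenetic clustering, cluster and cell-type enrichment of the top
dysregulated genes.

It operates on the synthetic-data generator's output, so every summary
number it returns can be checked against the planted ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .core import GenomicInterval, merge_intervals
from .differential import (
    RegionCountMatrix,
    build_enhancer_catalogue,
    compute_size_factors,
    count_matrix_from_tracks,
    differential_table,
    differential_test,
    sample_background_regions,
)
from .integrate import (
    attribute_regions,
    celltype_specificity_enrichment,
    cluster_enrichment,
    cluster_gene_profiles,
    concordance_analysis,
    gene_profile_matrix,
    top_ranked_genes,
)
from .islands import IslandParams, call_islands, high_confidence_islands
from .simulate import (
    SimulationConfig,
    TrackKey,
    simulate_chip_tracks,
    simulate_genome_and_annotation,
    simulate_rnaseq,
)


@dataclass
class StudyResult:
    """Headline numbers plus the intermediate objects they came from."""

    summary: dict[str, Any]
    universe: list[GenomicInterval] = field(default_factory=list)
    genotype_diff: list = field(default_factory=list)
    age_diff: list = field(default_factory=list)
    catalogue: Any = None
    concordance: Any = None
    de_table: pd.DataFrame | None = None
    clusters: Any = None
    cluster_table: pd.DataFrame | None = None


def _de_dataframe(results, gene_ids, chroms) -> pd.DataFrame:
    tab = differential_table(results)
    tab.insert(0, "gene_id", gene_ids)
    tab["chromosome"] = chroms
    return tab


def accelerated_aging_study(
    cfg: SimulationConfig | None = None,
    seed: int = 0,
    island_params: IslandParams | None = None,
    attribution_alpha: float = 0.05,
    top_n: int = 60,
    k: int = 7,
) -> StudyResult:
    """Run the full synthetic study and return its summary statistics.

    ``attribution_alpha`` selects differential regions (BH-adjusted) for the
    cell-type attribution counts; the concordance filter stays at raw
    p < 0.05 on both contrasts.  ``top_n`` is the size of the top
    dysregulated gene set used in the enrichment tests (scaled to the
    synthetic gene count; the full-scale analysis uses 300).
    """
    cfg = cfg or SimulationConfig(seed=seed)
    island_params = island_params or IslandParams.for_mark("H3K27ac")

    _, genes, truth = simulate_genome_and_annotation(cfg, with_sequence=False)
    tracks = simulate_chip_tracks(cfg, truth)

    # --- islands per bulk sample, high-confidence per condition, merged ----
    bulk_keys = [k_ for k_ in tracks if k_.fraction == "bulk"]
    per_condition: dict[tuple[str, str], list] = {}
    for key in bulk_keys:
        isl = call_islands(tracks[key], island_params, seed=seed)
        per_condition.setdefault((key.genotype, key.age), []).append(isl)
    condition_sets = [
        high_confidence_islands(lists) for lists in per_condition.values()
    ]
    universe = merge_intervals([iv for s in condition_sets for iv in s])

    # --- counts + background-equalized size factors ------------------------
    background = sample_background_regions(
        cfg.genome, universe, n=300, width=2000, seed=seed
    )
    all_regions = universe + background
    bulk_names = {
        f"{key.genotype}_{key.age}_rep{key.replicate}": tracks[key]
        for key in bulk_keys
    }
    bulk_meta = pd.DataFrame(
        [
            {"genotype": key.genotype, "age": key.age, "replicate": key.replicate}
            for key in bulk_keys
        ],
        index=list(bulk_names),
    )
    rcm = count_matrix_from_tracks(all_regions, bulk_names, bulk_meta)
    rcm.size_factors = compute_size_factors(rcm, background)
    n_uni = len(universe)
    rcm_universe = RegionCountMatrix(
        universe, rcm.counts[:n_uni], rcm.samples, rcm.size_factors
    )

    # --- differential contrasts -------------------------------------------
    mask_2mo = (rcm_universe.samples["age"] == "2mo").to_numpy()
    genotype_diff = differential_test(
        rcm_universe.subset_samples(mask_2mo), ("WT", "Q140")
    )
    mask_wt = (rcm_universe.samples["genotype"] == "WT").to_numpy()
    age_diff = differential_test(
        rcm_universe.subset_samples(mask_wt), ("2mo", "6mo"), condition_col="age"
    )

    # --- NeuN catalogue over the same universe -----------------------------
    def fraction_matrix(fraction: str) -> RegionCountMatrix:
        keys = [
            k_
            for k_ in tracks
            if k_.fraction == fraction and k_.mark == "H3K27ac"
        ]
        names = {f"{fraction}_rep{k_.replicate}": tracks[k_] for k_ in keys}
        meta = pd.DataFrame(
            [{"replicate": k_.replicate} for k_ in keys], index=list(names)
        )
        return count_matrix_from_tracks(universe, names, meta)

    catalogue = build_enhancer_catalogue(
        fraction_matrix("NeuN+"), fraction_matrix("NeuN-")
    )

    # --- attribution of significant genotype regions -----------------------
    sig_regions = [r for r in genotype_diff if r.adj_p < attribution_alpha]
    _, att_counts = attribute_regions(sig_regions, catalogue)
    piv = att_counts.pivot(index="direction", columns="label", values="count")

    def frac(direction: str, label: str) -> float:
        row = piv.loc[direction] if direction in piv.index else None
        if row is None or row.sum() == 0:
            return float("nan")
        return float(row.get(label, 0) / row.sum())

    # --- concordance -------------------------------------------------------
    conc = concordance_analysis(genotype_diff, age_diff, catalogue)

    # --- RNA + clustering --------------------------------------------------
    rna = simulate_rnaseq(cfg, truth)
    gene_ivs = [g.interval for g in genes]
    rna_meta = pd.DataFrame(rna.samples, index=[f"r{i}" for i in range(len(rna.samples))])
    rna_rcm = RegionCountMatrix(
        gene_ivs,
        rna.counts[:, :],
        rna_meta,
        size_factors=np.ones(len(rna.samples)),
    )
    rna_2mo = rna_rcm.subset_samples((rna_meta["age"] == "2mo").to_numpy())
    de_res = differential_test(rna_2mo, ("WT", "Q140"))
    de_table = _de_dataframe(
        de_res, [g.gene_id for g in genes], [g.interval.chrom for g in genes]
    )

    ct_meta = pd.DataFrame(
        rna.celltype_samples, index=[f"c{i}" for i in range(len(rna.celltype_samples))]
    )
    ct_rcm = RegionCountMatrix(
        gene_ivs, rna.celltype_counts, ct_meta, size_factors=np.ones(len(ct_meta))
    )
    ct_res = differential_test(ct_rcm, ("glia", "neuron"), condition_col="celltype")
    ct_table = _de_dataframe(
        ct_res, [g.gene_id for g in genes], [g.interval.chrom for g in genes]
    )

    neun_tracks = {
        f"{k_.mark}_{k_.fraction}": tracks[k_]
        for k_ in tracks
        if k_.fraction in ("NeuN+", "NeuN-") and k_.replicate == 1
    }
    profiles = gene_profile_matrix(neun_tracks, genes)
    clusters = cluster_gene_profiles(profiles, k=k, seed=seed)

    # the neuronal-archetype cluster: plurality of true neuronal genes
    neuronal_ids = {
        g.annotation.gene_id for g in truth.genes if g.gene_class == "neuronal"
    }
    shares = {
        c: sum(1 for g in clusters.members(c) if g in neuronal_ids)
        for c in range(k)
    }
    neuronal_cluster = max(shares, key=lambda c: (shares[c], -c))

    cluster_table = cluster_enrichment(
        de_table, clusters, top_n=top_n, rank_key="raw_p", direction="down"
    )
    neuronal_cluster_p = float(
        cluster_table.loc[cluster_table["cluster"] == neuronal_cluster, "adj_p"].iloc[0]
    )

    top_down = top_ranked_genes(de_table, top_n, "raw_p", "down")
    top_up = top_ranked_genes(de_table, top_n, "raw_p", "up")
    spec_down = celltype_specificity_enrichment(top_down, ct_table)
    spec_up = celltype_specificity_enrichment(top_up, ct_table)

    summary = {
        "n_universe_regions": len(universe),
        "n_catalogue_neuronal": len(catalogue.neuronal),
        "n_catalogue_glial": len(catalogue.glial),
        "n_significant_genotype_regions": len(sig_regions),
        "frac_down_neuronal": frac("down", "Neuronal"),
        "frac_up_glial": frac("up", "Glial"),
        "concordance": conc.concordance,
        "spearman_rho": conc.spearman_rho,
        "spearman_p": conc.spearman_p,
        "neuronal_cluster": neuronal_cluster,
        "neuronal_cluster_adj_p": neuronal_cluster_p,
        "top_down_neuronal_specific": spec_down.n_neuronal,
        "top_down_glial_specific": spec_down.n_glial,
        "top_down_specificity_p": spec_down.p_value,
        "top_up_neuronal_specific": spec_up.n_neuronal,
        "top_up_glial_specific": spec_up.n_glial,
        "top_up_specificity_p": spec_up.p_value,
    }
    return StudyResult(
        summary=summary,
        universe=universe,
        genotype_diff=genotype_diff,
        age_diff=age_diff,
        catalogue=catalogue,
        concordance=conc,
        de_table=de_table,
        clusters=clusters,
        cluster_table=cluster_table,
    )
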