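"""Integrative statistics over the differential and catalogue outputs.

This module carries the study's cross-cutting analyses: attributing
differential regions to neuronal/glial/non-specific enhancer classes,
metaprofiles over regions or scaled gene bodies, k-means clustering of gene
epigenetic profiles with enrichment tests of dysregulated genes, linear
ChIP-RNA regression, age-by-genotype concordance (sign concordance,
Spearman correlation, hierarchically ordered z-score heatmaps), per-
chromosome enrichment of differentially expressed genes, group-wise z-score
comparisons (Kruskal-Wallis), and the nuclear-sorting percentage
bookkeeping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from sklearn.cluster import KMeans

from .core import (
    GeneAnnotation,
    GenomicInterval,
    SignalTrack,
    adjust_pvalues,
    binomial_enrichment,
    intersect,
    zscore_matrix,
)
from .differential import DifferentialRegion, EnhancerCatalogue

CELLTYPE_LABELS = ("Neuronal", "Glial", "Non-specific")


# ---------------------------------------------------------------------------
# cell-type attribution
# ---------------------------------------------------------------------------


@dataclass
class AttributedRegion:
    region: DifferentialRegion
    label: str

    def __post_init__(self) -> None:
        if self.label not in CELLTYPE_LABELS:
            raise ValueError(f"unknown label {self.label!r}")


def attribute_regions(
    diff: Sequence[DifferentialRegion],
    catalogue: EnhancerCatalogue,
    min_overlap_bp: int = 1,
) -> tuple[list[AttributedRegion], pd.DataFrame]:
    """Label each differential region by catalogue overlap.

    A region overlapping only neuronal catalogue entries is Neuronal, only
    glial entries Glial, neither or both Non-specific (the ambiguity rule).
    Also returns the direction x label contingency counts; the three labels
    partition the input.
    """
    ivs = [r.interval for r in diff]
    neuronal_hits = {a for a, _, _ in intersect(ivs, catalogue.neuronal, min_overlap_bp)}
    glial_hits = {a for a, _, _ in intersect(ivs, catalogue.glial, min_overlap_bp)}
    out: list[AttributedRegion] = []
    counts = {
        (d, lab): 0 for d in ("up", "down") for lab in CELLTYPE_LABELS
    }
    for r in diff:
        in_n = r.interval in neuronal_hits
        in_g = r.interval in glial_hits
        if in_n and not in_g:
            label = "Neuronal"
        elif in_g and not in_n:
            label = "Glial"
        else:
            label = "Non-specific"
        out.append(AttributedRegion(r, label))
        counts[(r.direction, label)] += 1
    table = pd.DataFrame(
        [
            {"direction": d, "label": lab, "count": c}
            for (d, lab), c in sorted(counts.items())
        ]
    )
    return out, table


# ---------------------------------------------------------------------------
# metaprofiles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegionScheme:
    """Fixed-width windows centred on region midpoints."""

    half_width: int = 2000
    bin_bp: int = 100

    @property
    def n_bins(self) -> int:
        return 2 * self.half_width // self.bin_bp


@dataclass(frozen=True)
class GeneScheme:
    """Fixed flanks plus a length-scaled gene body (strand-flipped so bin 0
    is always 5')."""

    flank_bp: int = 2000
    flank_bin_bp: int = 100
    body_bins: int = 100

    @property
    def flank_bins(self) -> int:
        return self.flank_bp // self.flank_bin_bp

    @property
    def n_bins(self) -> int:
        return 2 * self.flank_bins + self.body_bins


@dataclass
class Metaprofile:
    mean_profile: np.ndarray
    per_feature_density: np.ndarray  # mean density per feature (for boxplots)
    profiles: np.ndarray  # features x bins


def _bin_edges_for_gene(gene: GeneAnnotation, scheme: GeneScheme) -> np.ndarray:
    iv = gene.interval
    up = np.linspace(iv.start - scheme.flank_bp, iv.start, scheme.flank_bins + 1)
    body = np.linspace(iv.start, iv.end, scheme.body_bins + 1)
    down = np.linspace(iv.end, iv.end + scheme.flank_bp, scheme.flank_bins + 1)
    return np.concatenate((up[:-1], body[:-1], down))


def metaprofile(
    track: SignalTrack,
    features: Sequence[GenomicInterval | GeneAnnotation],
    scheme: RegionScheme | GeneScheme | None = None,
) -> Metaprofile:
    """Resample coverage onto a fixed bin scheme per feature and average.

    The track should be normalized to 1x genome coverage so a featureless
    profile sits at 1.0.  Gene features use the scaled-body scheme and are
    strand-flipped; interval features use midpoint-centred fixed windows.
    Features reaching past a chromosome end are clipped (coverage outside
    counts as zero) with a warning.
    """
    if track.normalization_state != "rpgc_1x":
        warnings.warn(
            "metaprofile expects a 1x-normalized track "
            f"(state={track.normalization_state})",
            RuntimeWarning,
        )
    if scheme is None:
        scheme = (
            GeneScheme() if isinstance(features[0], GeneAnnotation) else RegionScheme()
        )
    rows = []
    clipped = 0
    for feat in features:
        if isinstance(feat, GeneAnnotation):
            if not isinstance(scheme, GeneScheme):
                raise ValueError("gene features require a GeneScheme")
            edges = _bin_edges_for_gene(feat, scheme)
            chrom = feat.interval.chrom
            flip = feat.interval.strand == "-"
        else:
            if not isinstance(scheme, RegionScheme):
                raise ValueError("interval features require a RegionScheme")
            mid = feat.midpoint
            edges = np.linspace(
                mid - scheme.half_width, mid + scheme.half_width, scheme.n_bins + 1
            )
            chrom = feat.chrom
            flip = feat.strand == "-"
        length = track.chrom_length(chrom)
        if edges[0] < 0 or edges[-1] > length:
            clipped += 1
        vals = np.array(
            [
                track.mean_coverage(chrom, a, b) if b > 0 and a < length else 0.0
                for a, b in zip(edges[:-1], edges[1:])
            ]
        )
        if flip:
            vals = vals[::-1]
        rows.append(vals)
    if clipped:
        warnings.warn(f"{clipped} feature(s) clipped at chromosome bounds", RuntimeWarning)
    profiles = np.vstack(rows)
    return Metaprofile(
        mean_profile=profiles.mean(axis=0),
        per_feature_density=profiles.mean(axis=1),
        profiles=profiles,
    )


def gene_profile_matrix(
    tracks: dict[str, SignalTrack],
    genes: Sequence[GeneAnnotation],
    scheme: GeneScheme | None = None,
) -> pd.DataFrame:
    """Genes x (track x bin) profile matrix for epigenetic clustering.

    Tracks (one per mark x fraction) are concatenated along columns in
    sorted key order; each track is 1x-normalized first if still raw.
    """
    scheme = scheme or GeneScheme()
    blocks = []
    cols = []
    for key in sorted(tracks):
        track = tracks[key]
        if track.normalization_state == "raw":
            track = track.to_rpgc()
        mp = metaprofile(track, list(genes), scheme)
        blocks.append(mp.profiles)
        cols.extend(f"{key}:{i}" for i in range(scheme.n_bins))
    return pd.DataFrame(
        np.hstack(blocks), index=[g.gene_id for g in genes], columns=cols
    )


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------


@dataclass
class ClusterAssignment:
    labels: pd.Series  # gene_id -> cluster id (0..k-1)
    centroids: np.ndarray
    inertia: float
    k: int

    def members(self, cluster: int) -> list[str]:
        return list(self.labels.index[self.labels == cluster])

    def sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()


def cluster_gene_profiles(
    profiles: pd.DataFrame,
    k: int = 7,
    seed: int = 0,
    restarts: int = 10,
) -> ClusterAssignment:
    """Seeded k-means (k-means++ init, best of ``restarts`` runs by inertia).

    Deterministic under a fixed seed.  Default k=7 mirrors the seven
    epigenetic profile archetypes the striatal gene clustering resolves.
    """
    if k > len(profiles):
        raise ValueError(f"k={k} exceeds the number of genes {len(profiles)}")
    X = profiles.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("profile matrix contains non-finite values")
    km = KMeans(n_clusters=k, init="k-means++", n_init=restarts, random_state=seed)
    lab = km.fit_predict(X)
    return ClusterAssignment(
        labels=pd.Series(lab, index=profiles.index),
        centroids=km.cluster_centers_,
        inertia=float(km.inertia_),
        k=k,
    )


def top_ranked_genes(
    de: pd.DataFrame,
    top_n: int,
    rank_key: str = "raw_p",
    direction: str = "down",
) -> list[str]:
    """Top-N genes of one direction ranked by p-value (ties broken by
    gene_id for determinism)."""
    if direction == "down":
        sub = de[de["log2fc"] < 0]
    elif direction == "up":
        sub = de[de["log2fc"] > 0]
    else:
        raise ValueError("direction must be 'up' or 'down'")
    if top_n > len(sub):
        raise ValueError(f"top_n={top_n} exceeds ranked list length {len(sub)}")
    sub = sub.sort_values([rank_key, "gene_id"], kind="stable")
    return list(sub["gene_id"].head(top_n))


def cluster_enrichment(
    de: pd.DataFrame,
    assignment: ClusterAssignment,
    top_n: int = 300,
    rank_key: str = "raw_p",
    direction: str = "down",
) -> pd.DataFrame:
    """Two-sided binomial enrichment of top dysregulated genes per cluster.

    The expected proportion of each cluster is its share of the clustered
    universe; observed is the number of top-N genes (of the requested
    direction, ranked by ``rank_key``) landing in the cluster.  Bonferroni
    family size = k.
    """
    universe = set(assignment.labels.index)
    de_cl = de[de["gene_id"].isin(universe)]
    top = top_ranked_genes(de_cl, top_n, rank_key, direction)
    sizes = assignment.sizes()
    n_universe = len(assignment.labels)
    rows = []
    for cluster in range(assignment.k):
        p0 = sizes.get(cluster, 0) / n_universe
        observed = sum(1 for g in top if assignment.labels.get(g) == cluster)
        expected = top_n * p0
        if 0 < p0 < 1:
            p = binomial_enrichment(observed, top_n, p0)
        else:
            p = 1.0
        rows.append(
            {
                "cluster": cluster,
                "observed": observed,
                "expected": expected,
                "raw_p": p,
            }
        )
    table = pd.DataFrame(rows)
    table["adj_p"] = adjust_pvalues(table["raw_p"], "bonferroni", m=assignment.k)
    return table


# ---------------------------------------------------------------------------
# cell-type specificity of dysregulated genes
# ---------------------------------------------------------------------------


@dataclass
class SpecificityEnrichment:
    n_neuronal: int
    n_glial: int
    null_proportion: float
    p_value: float


def celltype_specificity_enrichment(
    top_genes: Sequence[str],
    celltype_de: pd.DataFrame,
    alpha: float = 0.05,
) -> SpecificityEnrichment:
    """Enrichment of neuronal- vs glial-specific genes in a top gene set.

    Specificity calls come from the neurons-vs-glia table: adj_p < alpha and
    log2fc > 0 is neuronal-specific, < 0 glial-specific.  The null
    proportion is the neuronal share among all specific genes in the table;
    the test is the two-sided exact binomial on the top set's specific
    members.
    """
    spec = celltype_de[celltype_de["adj_p"] < alpha]
    spec_n = set(spec.loc[spec["log2fc"] > 0, "gene_id"])
    spec_g = set(spec.loc[spec["log2fc"] < 0, "gene_id"])
    if not spec_n and not spec_g:
        raise ValueError("no cell-type-specific genes in the table")
    p0 = len(spec_n) / (len(spec_n) + len(spec_g))
    n_n = sum(1 for g in top_genes if g in spec_n)
    n_g = sum(1 for g in top_genes if g in spec_g)
    total = n_n + n_g
    if total == 0 or not (0 < p0 < 1):
        p = 1.0
    else:
        p = binomial_enrichment(n_n, total, p0)
    return SpecificityEnrichment(n_n, n_g, p0, p)


# ---------------------------------------------------------------------------
# ChIP-RNA regression
# ---------------------------------------------------------------------------


def chip_rna_regression(
    table: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """OLS of RNA log2FC on ChIP (H3K27ac) log2FC per significance stratum.

    ``table`` columns: gene_id, chip_log2fc, rna_log2fc, rna_adj_p.  Strata:
    all genes; significantly down (rna log2fc < 0, adj_p < alpha);
    significantly up; non-significant.  Reports slope, Pearson r and the
    regression p per stratum.
    """
    for col in ("chip_log2fc", "rna_log2fc", "rna_adj_p"):
        if col not in table:
            raise ValueError(f"missing column {col!r}")
    sig = table["rna_adj_p"] < alpha
    strata = {
        "all": np.ones(len(table), dtype=bool),
        "down": sig & (table["rna_log2fc"] < 0),
        "up": sig & (table["rna_log2fc"] > 0),
        "ns": ~sig,
    }
    rows = []
    for name, mask in strata.items():
        sub = table[mask]
        if len(sub) < 3:
            continue
        x = sub["chip_log2fc"].to_numpy(dtype=float)
        y = sub["rna_log2fc"].to_numpy(dtype=float)
        if np.std(x) == 0:
            raise ValueError(f"constant ChIP predictor in stratum {name!r}")
        fit = stats.linregress(x, y)
        rows.append(
            {
                "stratum": name,
                "n": len(sub),
                "slope": fit.slope,
                "intercept": fit.intercept,
                "pearson_r": fit.rvalue,
                "p_value": fit.pvalue,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# age x genotype concordance
# ---------------------------------------------------------------------------


@dataclass
class ConcordanceResult:
    table: pd.DataFrame  # region, log2fc_genotype, log2fc_age, label
    per_label: pd.DataFrame  # label, n, mean FCs, concordance
    concordance: float
    spearman_rho: float
    spearman_p: float
    zmatrix: np.ndarray | None = None
    row_order: np.ndarray | None = None


def concordance_analysis(
    genotype_diff: Sequence[DifferentialRegion],
    age_diff: Sequence[DifferentialRegion],
    catalogue: EnhancerCatalogue,
    p_cutoff: float = 0.05,
    signal: pd.DataFrame | None = None,
) -> ConcordanceResult:
    """Joint analysis of genotype and age effects over one region universe.

    Regions passing raw p < ``p_cutoff`` in *both* contrasts are retained,
    attributed to Neuronal / Glial / Non-specific, and summarized: per-label
    mean log2FCs and sign-concordance fraction, the overall concordance, and
    Spearman's rho between the two fold-change vectors.  When a region x
    condition ``signal`` matrix is provided, its retained rows are z-scored
    and ordered by average-linkage Euclidean hierarchical clustering for the
    heatmap output.
    """
    key = lambda r: (r.interval.chrom, r.interval.start, r.interval.end)
    g_map = {key(r): r for r in genotype_diff}
    a_map = {key(r): r for r in age_diff}
    if set(g_map) != set(a_map):
        raise ValueError("the two contrasts cover different region universes")
    retained = [
        (g_map[k], a_map[k])
        for k in g_map
        if g_map[k].raw_p < p_cutoff and a_map[k].raw_p < p_cutoff
    ]
    if not retained:
        n_g = sum(1 for r in genotype_diff if r.raw_p < p_cutoff)
        n_a = sum(1 for r in age_diff if r.raw_p < p_cutoff)
        raise ValueError(
            f"no regions pass p<{p_cutoff} in both contrasts "
            f"(genotype: {n_g}, age: {n_a}, joint: 0)"
        )
    attributed, _ = attribute_regions([g for g, _ in retained], catalogue)
    rows = []
    for (g, a), att in zip(retained, attributed):
        rows.append(
            {
                "chrom": g.interval.chrom,
                "start": g.interval.start,
                "end": g.interval.end,
                "log2fc_genotype": g.log2fc,
                "log2fc_age": a.log2fc,
                "label": att.label,
            }
        )
    table = pd.DataFrame(rows).sort_values(["chrom", "start"]).reset_index(drop=True)
    conc = (
        np.sign(table["log2fc_genotype"]) == np.sign(table["log2fc_age"])
    ).to_numpy()
    per_label = (
        table.assign(concordant=conc)
        .groupby("label")
        .agg(
            n=("label", "size"),
            mean_log2fc_genotype=("log2fc_genotype", "mean"),
            mean_log2fc_age=("log2fc_age", "mean"),
            concordance=("concordant", "mean"),
        )
        .reset_index()
    )
    rho, rho_p = stats.spearmanr(table["log2fc_genotype"], table["log2fc_age"])

    zmat = order = None
    if signal is not None:
        keys = list(zip(table["chrom"], table["start"], table["end"]))
        sig_rows = signal.loc[[f"{c}:{s}-{e}" for c, s, e in keys]]
        zmat = zscore_matrix(sig_rows.to_numpy(dtype=float))
        link = hierarchy.linkage(zmat, method="average", metric="euclidean")
        order = np.asarray(hierarchy.leaves_list(link))
    return ConcordanceResult(
        table=table,
        per_label=per_label,
        concordance=float(conc.mean()),
        spearman_rho=float(rho),
        spearman_p=float(rho_p),
        zmatrix=zmat,
        row_order=order,
    )


# ---------------------------------------------------------------------------
# chromosome enrichment of DEGs
# ---------------------------------------------------------------------------


def chromosome_enrichment(
    de: pd.DataFrame,
    universe: Sequence[GeneAnnotation] | pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-chromosome two-sided binomial enrichment of DE genes.

    Expected proportions come from the annotated universe; DE genes are the
    table rows with adj_p < alpha.  Reports observed/expected counts, the
    percentage of DEGs per chromosome, and Bonferroni-adjusted p-values.
    """
    if isinstance(universe, pd.DataFrame):
        uni = universe[["gene_id", "chromosome"]]
    else:
        uni = pd.DataFrame(
            {
                "gene_id": [g.gene_id for g in universe],
                "chromosome": [g.interval.chrom for g in universe],
            }
        )
    chrom_sizes = uni.groupby("chromosome").size()
    degs = de[de["adj_p"] < alpha]
    unknown = set(degs["chromosome"]) - set(chrom_sizes.index)
    if unknown:
        raise ValueError(f"chromosome(s) absent from universe: {sorted(unknown)}")
    n_deg = len(degs)
    n_uni = len(uni)
    rows = []
    for chrom, size in chrom_sizes.items():
        p0 = size / n_uni
        observed = int((degs["chromosome"] == chrom).sum())
        p = binomial_enrichment(observed, n_deg, p0) if (n_deg and 0 < p0 < 1) else 1.0
        rows.append(
            {
                "chromosome": chrom,
                "observed": observed,
                "expected": n_deg * p0,
                "pct_of_degs": 100.0 * observed / n_deg if n_deg else 0.0,
                "raw_p": p,
            }
        )
    table = pd.DataFrame(rows)
    table["adj_p"] = adjust_pvalues(table["raw_p"], "bonferroni")
    return table


# ---------------------------------------------------------------------------
# group-wise z-score comparisons
# ---------------------------------------------------------------------------


@dataclass
class GroupZScoreResult:
    pooled: dict[str, np.ndarray]  # group -> pooled z-scores
    h_stat: float
    p_value: float
    pairwise: pd.DataFrame  # group1, group2, H, raw_p, adj_p (BH)


def groupwise_zscore_test(
    expr: pd.DataFrame,
    gene_set: Sequence[str],
    groups: pd.Series,
) -> GroupZScoreResult:
    """Kruskal-Wallis on pooled gene-wise z-scores across sample groups.

    Expression rows are z-scored per gene across all samples, restricted to
    ``gene_set``, and pooled per group (all gene x sample values).  The
    omnibus KW test (tie-corrected) is followed by pairwise two-group tests
    BH-adjusted across comparisons.
    """
    missing = [g for g in gene_set if g not in expr.index]
    if missing:
        raise ValueError(f"genes absent from expression matrix: {missing[:5]}")
    sub = expr.loc[list(gene_set)]
    z = zscore_matrix(sub.to_numpy(dtype=float))
    zdf = pd.DataFrame(z, index=sub.index, columns=sub.columns)
    pooled: dict[str, np.ndarray] = {}
    for group in pd.unique(groups):
        cols = groups.index[groups == group]
        if len(cols) < 2:
            raise ValueError(f"group {group!r} has fewer than 2 samples")
        pooled[group] = zdf[cols].to_numpy().ravel()
    if len(pooled) < 2:
        raise ValueError("need >= 2 groups")
    h, p = stats.kruskal(*pooled.values())
    names = list(pooled)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            hij, pij = stats.kruskal(pooled[names[i]], pooled[names[j]])
            rows.append(
                {"group1": names[i], "group2": names[j], "H": hij, "raw_p": pij}
            )
    pairwise = pd.DataFrame(rows)
    if len(pairwise):
        pairwise["adj_p"] = adjust_pvalues(pairwise["raw_p"], "BH")
    return GroupZScoreResult(pooled, float(h), float(p), pairwise)


# ---------------------------------------------------------------------------
# FANS bookkeeping
# ---------------------------------------------------------------------------

MIN_SINGLET_EVENTS = 30_000


def nuclear_fractions(neun_pos_events: int, neun_neg_events: int) -> tuple[float, float]:
    """NeuN+ and NeuN- percentages of total sorted nuclei.

    NeuN+ % = NeuN+ / (NeuN+ + NeuN-) x 100 (and complementarily for
    NeuN-).  Totals below the 30,000 singlet-gated-event quality threshold
    trigger a warning.
    """
    if neun_pos_events < 0 or neun_neg_events < 0:
        raise ValueError("event counts must be non-negative")
    total = neun_pos_events + neun_neg_events
    if total == 0:
        raise ValueError("no events recorded")
    if total < MIN_SINGLET_EVENTS:
        warnings.warn(
            f"only {total} events (< {MIN_SINGLET_EVENTS} singlet gated events)",
            RuntimeWarning,
        )
    pos = 100.0 * neun_pos_events / total
    return pos, 100.0 - pos
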