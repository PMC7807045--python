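"""Synthetic data with planted ground truth.

Every downstream stage of the pipeline is exercised against data generated
here: a small two-chromosome genome with non-overlapping genes and enhancers,
cell-type-structured ChIP coverage tracks (NeuN+ neuronal and NeuN- glial
nuclear fractions plus bulk mixtures), RNA-seq counts coupled to enhancer
effects, and multi-bait 4C fragment profiles generated from a known 3D bead
geometry.  The generator's defaults emulate the study design the pipeline
re-implements: two genotypes (WT and the CAG-knockin line Q140), two ages,
neuronal enhancers losing H3K27ac under the mutation, glial enhancers gaining
it, and an age effect of the same sign structure whose amplitude the mutation
exceeds at the later age (the "accelerated aging" configuration).

All randomness flows through :func:`numpy.random.default_rng` seeded from the
configuration, with child streams spawned via ``SeedSequence`` so each product
is independently reproducible.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .core import GeneAnnotation, GenomicInterval, SignalTrack

ENHANCER_CLASSES = ("neuronal", "glial", "shared")
GENE_CLASSES = ("neuronal", "glial", "other")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class EnhancerPlan:
    """Counts and width (bp) of planted enhancers per cell-type class."""

    n_neuronal: int = 100
    n_glial: int = 100
    n_shared: int = 100
    width: int = 2000

    def counts(self) -> dict[str, int]:
        return {
            "neuronal": self.n_neuronal,
            "glial": self.n_glial,
            "shared": self.n_shared,
        }


def _default_geno_age1() -> dict[str, float]:
    return {"neuronal": -1.0, "glial": 1.0, "shared": 0.0}


def _default_geno_age2() -> dict[str, float]:
    return {"neuronal": -1.5, "glial": 1.5, "shared": 0.0}


def _default_age() -> dict[str, float]:
    return {"neuronal": -0.8, "glial": 0.8, "shared": 0.0}


@dataclass
class EffectPlan:
    """Planted log2 effects per enhancer class.

    Neuronal-class genotype effects must be <= 0 and glial-class >= 0
    (mutant neuronal enhancers are depleted in H3K27ac, glial enriched),
    and the genotype amplitude at the later age must be at least that at the
    earlier age (progressive effect).
    """

    genotype_age1: dict[str, float] = field(default_factory=_default_geno_age1)
    genotype_age2: dict[str, float] = field(default_factory=_default_geno_age2)
    age: dict[str, float] = field(default_factory=_default_age)

    def validate(self) -> None:
        for plan in (self.genotype_age1, self.genotype_age2):
            if plan["neuronal"] > 0:
                raise ValueError("neuronal genotype effect must be <= 0")
            if plan["glial"] < 0:
                raise ValueError("glial genotype effect must be >= 0")
        for cls in ENHANCER_CLASSES:
            if abs(self.genotype_age2[cls]) < abs(self.genotype_age1[cls]):
                raise ValueError(
                    f"|genotype effect| must not shrink with age ({cls})"
                )


@dataclass
class NoisePlan:
    """Count-noise model: 'none' (expected values), 'poisson', or 'nb'
    (gamma-Poisson with the given dispersion)."""

    model: str = "nb"
    dispersion: float = 0.05
    library_scale_range: tuple[float, float] = (1.0, 1.0)

    def validate(self) -> None:
        if self.model not in ("none", "poisson", "nb"):
            raise ValueError(f"unknown noise model {self.model!r}")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")


@dataclass
class SimulationConfig:
    seed: int = 0
    genome: tuple[tuple[str, int], ...] = (("chr1", 5_000_000), ("chr2", 5_000_000))
    bin_size: int = 200
    n_genes: int = 300
    gene_length: int = 6000
    enhancer_plan: EnhancerPlan = field(default_factory=EnhancerPlan)
    effect_plan: EffectPlan = field(default_factory=EffectPlan)
    noise: NoisePlan = field(default_factory=NoisePlan)
    #: NeuN+ (neuronal) fraction of bulk tissue; identical across genotypes
    mixture: float = 0.6
    n_replicates: int = 2
    # per-bin expected reads
    enhancer_mean: float = 20.0
    class_separation: float = 4.0  # active vs inactive fraction, fold
    background_mean: float = 2.0
    gene_body_on: float = 10.0
    gene_body_off: float = 2.0
    # restriction-site planting for 4C fragment maps (mean spacing, bp)
    first_site_spacing: int = 400
    second_site_spacing: int = 1200

    def __post_init__(self) -> None:
        if not (0.0 < self.mixture < 1.0):
            raise ValueError("mixture must lie in (0, 1)")
        if self.n_replicates < 2:
            raise ValueError("need >= 2 replicates per condition")
        self.effect_plan.validate()
        self.noise.validate()

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        """Load a configuration from YAML; nested plans are plain mappings."""
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "genome" in raw:
            raw["genome"] = tuple((c, int(l)) for c, l in raw["genome"])
        for key, klass in (
            ("enhancer_plan", EnhancerPlan),
            ("effect_plan", EffectPlan),
            ("noise", NoisePlan),
        ):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = klass(**raw[key])
        return cls(**raw)

    def rng_for(self, stream: str) -> np.random.Generator:
        """An independent, reproducible generator for a named product.

        Stream identity is hashed with CRC-32 (stable across processes,
        unlike Python's builtin string hash) and mixed with the config seed.
        """
        h = zlib.crc32(stream.encode())
        return np.random.default_rng(
            np.random.SeedSequence(entropy=(self.seed, h))
        )


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------


@dataclass
class EnhancerTruth:
    interval: GenomicInterval
    label: str  # neuronal / glial / shared
    effects: dict[str, float]  # contrast -> planted log2 effect


@dataclass
class GeneTruth:
    annotation: GeneAnnotation
    gene_class: str  # neuronal / glial / other
    linked_enhancer: int | None = None  # index into GroundTruth.enhancers
    rna_log2fc: dict[str, float] = field(default_factory=dict)
    celltype_log2fc: float = 0.0  # neurons vs glia


@dataclass
class GroundTruth:
    """Every simulated signal feature traces to one record here."""

    enhancers: list[EnhancerTruth] = field(default_factory=list)
    genes: list[GeneTruth] = field(default_factory=list)
    mixture: float = 0.5
    bead_coords: np.ndarray | None = None
    tad_boundary: int | None = None
    bait_beads: list[int] | None = None

    def enhancer_intervals(self, label: str | None = None) -> list[GenomicInterval]:
        return [
            e.interval for e in self.enhancers if label is None or e.label == label
        ]

    def to_json(self, path) -> None:
        payload = {
            "mixture": self.mixture,
            "enhancers": [
                {
                    "chrom": e.interval.chrom,
                    "start": e.interval.start,
                    "end": e.interval.end,
                    "label": e.label,
                    "effects": e.effects,
                }
                for e in self.enhancers
            ],
            "genes": [
                {
                    "gene_id": g.annotation.gene_id,
                    "chrom": g.annotation.interval.chrom,
                    "start": g.annotation.interval.start,
                    "end": g.annotation.interval.end,
                    "strand": g.annotation.interval.strand,
                    "class": g.gene_class,
                    "linked_enhancer": g.linked_enhancer,
                    "rna_log2fc": g.rna_log2fc,
                    "celltype_log2fc": g.celltype_log2fc,
                }
                for g in self.genes
            ],
            "tad_boundary": self.tad_boundary,
            "bait_beads": self.bait_beads,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# genome + annotation
# ---------------------------------------------------------------------------


def _place_non_overlapping(
    widths: Sequence[int], length: int, rng: np.random.Generator
) -> list[int]:
    """Uniformly random non-overlapping starts for elements of the given
    widths on [0, length).  Exact gap-allocation construction: no retries."""
    total = int(np.sum(widths))
    slack = length - total
    if slack < 0:
        raise ValueError(
            f"cannot place {total} bp of features on a {length} bp chromosome"
        )
    n = len(widths)
    if n == 0:
        return []
    cuts = np.sort(rng.integers(0, slack + 1, size=n))
    starts = cuts + np.concatenate(([0], np.cumsum(widths)[:-1]))
    return [int(s) for s in starts]


def simulate_genome_and_annotation(
    cfg: SimulationConfig, with_sequence: bool = True
) -> tuple[dict[str, str], list[GeneAnnotation], GroundTruth]:
    """Place genes and enhancers uniformly at random without overlap and
    (optionally) synthesize chromosome sequences with planted restriction
    sites for 4C fragment maps.

    Returns ``(sequences, genes, truth)``; ``sequences`` is empty when
    ``with_sequence`` is false.  Deterministic for a fixed config seed.
    """
    rng = cfg.rng_for("genome")
    plan = cfg.enhancer_plan.counts()
    largest = max(cfg.gene_length, cfg.enhancer_plan.width)
    for chrom, length in cfg.genome:
        if length < 10 * largest:
            raise ValueError(
                f"{chrom}: genome length {length} < 10x largest feature {largest}"
            )

    # element list: (kind, class) with widths; shuffle, split across chroms
    elements: list[tuple[str, str]] = []
    gene_classes = [GENE_CLASSES[i % 3] for i in range(cfg.n_genes)]
    elements += [("gene", c) for c in gene_classes]
    for label in ENHANCER_CLASSES:
        elements += [("enhancer", label)] * plan[label]
    order = rng.permutation(len(elements))
    elements = [elements[i] for i in order]

    lengths = np.array([L for _, L in cfg.genome], dtype=float)
    probs = lengths / lengths.sum()
    chrom_of = rng.choice(len(cfg.genome), size=len(elements), p=probs)

    truth = GroundTruth(mixture=cfg.mixture)
    genes: list[GeneAnnotation] = []
    gene_count = 0
    enhancer_by_class: dict[str, list[int]] = {c: [] for c in ENHANCER_CLASSES}
    pending_genes: list[tuple[GeneAnnotation, str]] = []
    for ci, (chrom, length) in enumerate(cfg.genome):
        idx = [i for i in range(len(elements)) if chrom_of[i] == ci]
        widths = [
            cfg.gene_length if elements[i][0] == "gene" else cfg.enhancer_plan.width
            for i in idx
        ]
        starts = _place_non_overlapping(widths, length, rng)
        for i, start, width in zip(idx, starts, widths):
            kind, label = elements[i]
            if kind == "gene":
                strand = "+" if rng.random() < 0.5 else "-"
                iv = GenomicInterval(chrom, start, start + width, strand)
                ann = GeneAnnotation.from_interval(f"gene{gene_count:04d}", iv)
                genes.append(ann)
                pending_genes.append((ann, label))
                gene_count += 1
            else:
                iv = GenomicInterval(chrom, start, start + width)
                effects = {
                    "genotype_age1": cfg.effect_plan.genotype_age1[label],
                    "genotype_age2": cfg.effect_plan.genotype_age2[label],
                    "age": cfg.effect_plan.age[label],
                }
                enhancer_by_class[label].append(len(truth.enhancers))
                truth.enhancers.append(EnhancerTruth(iv, label, effects))

    # couple each neuronal/glial gene to an enhancer of its class (round-robin)
    counters = {c: 0 for c in ENHANCER_CLASSES}
    for ann, gclass in pending_genes:
        linked = None
        if gclass in ("neuronal", "glial") and enhancer_by_class[gclass]:
            pool = enhancer_by_class[gclass]
            linked = pool[counters[gclass] % len(pool)]
            counters[gclass] += 1
        truth.genes.append(GeneTruth(ann, gclass, linked_enhancer=linked))

    sequences: dict[str, str] = {}
    if with_sequence:
        for chrom, length in cfg.genome:
            sequences[chrom] = _synthesize_sequence(
                length,
                rng,
                cfg.first_site_spacing,
                cfg.second_site_spacing,
            )
    return sequences, genes, truth


_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _synthesize_sequence(
    length: int,
    rng: np.random.Generator,
    first_spacing: int,
    second_spacing: int,
    first_site: str = "GATC",
    second_site: str = "GTAC",
) -> str:
    """Random sequence with first/second-cutter sites planted at the given
    mean spacings (on top of chance occurrences)."""
    arr = _BASES[rng.integers(0, 4, size=length)].copy()
    for site, spacing in ((first_site, first_spacing), (second_site, second_spacing)):
        n = max(1, int(length / spacing))
        pos = np.sort(rng.integers(0, max(length - len(site), 1), size=n))
        raw = np.frombuffer(site.encode(), dtype="S1")
        for p in pos:
            arr[p : p + len(site)] = raw
    return arr.tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# ChIP tracks
# ---------------------------------------------------------------------------


class TrackKey(NamedTuple):
    mark: str
    fraction: str  # "NeuN+", "NeuN-", "bulk"
    genotype: str  # "WT", "Q140"
    age: str  # "2mo", "6mo"
    replicate: int


def _expected_fraction_means(
    cfg: SimulationConfig, truth: GroundTruth, mark: str, fraction: str,
    genotype: str, age: str,
) -> dict[str, np.ndarray]:
    """Expected per-bin signal for one sorted nuclear fraction."""
    bs = cfg.bin_size
    mu = {
        chrom: np.full(length // bs, cfg.background_mean, dtype=float)
        for chrom, length in cfg.genome
    }
    sep = cfg.class_separation

    if mark == "H3K27ac":
        for e in truth.enhancers:
            if e.label == "shared":
                base = cfg.enhancer_mean
            elif (e.label == "neuronal") == (fraction == "NeuN+"):
                base = cfg.enhancer_mean
            else:
                base = cfg.enhancer_mean / sep
            # genotype / age multipliers act on the affected class only
            mult = 1.0
            if age == "6mo":
                mult *= 2.0 ** e.effects["age"]
            if genotype == "Q140":
                key = "genotype_age2" if age == "6mo" else "genotype_age1"
                mult *= 2.0 ** e.effects[key]
            iv = e.interval
            b0, b1 = iv.start // bs, iv.end // bs
            mu[iv.chrom][b0:b1] = base * mult

    # gene-body archetypes (drive the k-means epigenetic clustering)
    for g in truth.genes:
        iv = g.annotation.interval
        active_in_fraction = (
            g.gene_class == "neuronal" and fraction == "NeuN+"
        ) or (g.gene_class == "glial" and fraction == "NeuN-")
        if mark == "H3K27ac":
            level = cfg.gene_body_on if active_in_fraction else cfg.gene_body_off
        else:  # H3K27me3: Polycomb-repressed in the opposite fraction
            if g.gene_class == "other":
                level = cfg.gene_body_off
            else:
                level = cfg.gene_body_off if active_in_fraction else cfg.gene_body_on
        b0, b1 = iv.start // bs, iv.end // bs
        mu[iv.chrom][b0:b1] = level
    return mu


def _sample_counts(
    mu: dict[str, np.ndarray], noise: NoisePlan, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    lo, hi = noise.library_scale_range
    scale = rng.uniform(lo, hi) if hi > lo else lo
    out = {}
    for chrom, m in mu.items():
        lam = m * scale
        if noise.model == "none":
            out[chrom] = lam.copy()
        elif noise.model == "poisson" or noise.dispersion == 0:
            out[chrom] = rng.poisson(lam).astype(float)
        else:
            r = 1.0 / noise.dispersion
            lam_nb = rng.gamma(r, lam / r)
            out[chrom] = rng.poisson(lam_nb).astype(float)
    return out


def simulate_chip_tracks(
    cfg: SimulationConfig,
    truth: GroundTruth,
    marks: Sequence[str] = ("H3K27ac", "H3K27me3"),
) -> dict[TrackKey, SignalTrack]:
    """Simulate the full track panel.

    Sorted fractions (NeuN+/NeuN-) are generated for WT at the first age for
    both marks; bulk striatum H3K27ac is generated for every genotype x age.
    Bulk expectation is the mixture-weighted sum of the two fraction
    expectations.  Counts follow the configured noise model.
    """
    tracks: dict[TrackKey, SignalTrack] = {}
    for mark in marks:
        for rep in range(1, cfg.n_replicates + 1):
            for fraction in ("NeuN+", "NeuN-"):
                mu = _expected_fraction_means(cfg, truth, mark, fraction, "WT", "2mo")
                rng = cfg.rng_for(f"chip/{mark}/{fraction}/WT/2mo/{rep}")
                data = _sample_counts(mu, cfg.noise, rng)
                key = TrackKey(mark, fraction, "WT", "2mo", rep)
                tracks[key] = SignalTrack(
                    cfg.bin_size, data, library_size=int(sum(v.sum() for v in data.values()))
                )
    for genotype in ("WT", "Q140"):
        for age in ("2mo", "6mo"):
            for rep in range(1, cfg.n_replicates + 1):
                mu_pos = _expected_fraction_means(
                    cfg, truth, "H3K27ac", "NeuN+", genotype, age
                )
                mu_neg = _expected_fraction_means(
                    cfg, truth, "H3K27ac", "NeuN-", genotype, age
                )
                mu_bulk = {
                    c: cfg.mixture * mu_pos[c] + (1 - cfg.mixture) * mu_neg[c]
                    for c in mu_pos
                }
                rng = cfg.rng_for(f"chip/H3K27ac/bulk/{genotype}/{age}/{rep}")
                data = _sample_counts(mu_bulk, cfg.noise, rng)
                key = TrackKey("H3K27ac", "bulk", genotype, age, rep)
                tracks[key] = SignalTrack(
                    cfg.bin_size, data, library_size=int(sum(v.sum() for v in data.values()))
                )
    return tracks


def simulate_poisson_null_track(
    genome: Sequence[tuple[str, int]],
    bin_size: int,
    lam: float,
    seed: int,
) -> SignalTrack:
    """A pure Poisson background track (no planted features) for null tests."""
    rng = np.random.default_rng(seed)
    data = {
        chrom: rng.poisson(lam, size=length // bin_size).astype(float)
        for chrom, length in genome
    }
    return SignalTrack(bin_size, data, library_size=int(sum(v.sum() for v in data.values())))


# ---------------------------------------------------------------------------
# RNA-seq
# ---------------------------------------------------------------------------


@dataclass
class RnaSim:
    counts: "np.ndarray"  # genes x samples
    gene_ids: list[str]
    samples: list[dict]  # genotype / age / replicate per column
    celltype_counts: np.ndarray  # genes x (neuron reps + glia reps)
    celltype_samples: list[dict]
    true_lfc: dict[str, np.ndarray]  # contrast -> per-gene planted log2FC


def simulate_rnaseq(
    cfg: SimulationConfig,
    truth: GroundTruth,
    coupling: float = 0.8,
    n_rna_replicates: int = 4,
    base_expression: float = 200.0,
    lfc_noise_sd: float = 0.4,
    celltype_lfc: float = 2.0,
) -> RnaSim:
    """RNA counts whose genotype/age log2 fold-changes are coupled (with
    coefficient ``coupling`` in [0, 1]) to the planted effect of each gene's
    linked enhancer, plus a neurons-vs-glia table driven by gene class."""
    if not truth.genes:
        raise ValueError("no genes in ground truth")
    rng = cfg.rng_for("rnaseq")
    n = len(truth.genes)
    base = base_expression * rng.lognormal(0.0, 0.8, size=n)

    def enhancer_effect(g: GeneTruth, contrast: str) -> float:
        if g.linked_enhancer is None:
            return 0.0
        return truth.enhancers[g.linked_enhancer].effects[contrast]

    resid_sd = lfc_noise_sd * np.sqrt(max(0.0, 1.0 - coupling**2))
    true_lfc: dict[str, np.ndarray] = {}
    for contrast in ("genotype_age1", "genotype_age2", "age"):
        eff = np.array([enhancer_effect(g, contrast) for g in truth.genes])
        noise = rng.normal(0.0, resid_sd, size=n) if resid_sd > 0 else 0.0
        lfc = coupling * eff + noise
        true_lfc[contrast] = lfc
        for g, v in zip(truth.genes, lfc):
            g.rna_log2fc[contrast] = float(v)

    ct = np.zeros(n)
    for i, g in enumerate(truth.genes):
        if g.gene_class == "neuronal":
            ct[i] = celltype_lfc
        elif g.gene_class == "glial":
            ct[i] = -celltype_lfc
    ct = ct + rng.normal(0.0, 0.3, size=n)
    for g, v in zip(truth.genes, ct):
        g.celltype_log2fc = float(v)

    lo, hi = cfg.noise.library_scale_range

    def draw(mean: np.ndarray, stream_rng: np.random.Generator) -> np.ndarray:
        scale = stream_rng.uniform(lo, hi) if hi > lo else lo
        lam = mean * scale
        if cfg.noise.model == "none":
            return lam
        if cfg.noise.model == "poisson" or cfg.noise.dispersion == 0:
            return stream_rng.poisson(lam).astype(float)
        r = 1.0 / cfg.noise.dispersion
        return stream_rng.poisson(stream_rng.gamma(r, lam / r)).astype(float)

    samples, cols = [], []
    for genotype in ("WT", "Q140"):
        for age in ("2mo", "6mo"):
            mult = np.ones(n)
            if age == "6mo":
                mult = mult * 2.0 ** true_lfc["age"]
            if genotype == "Q140":
                key = "genotype_age2" if age == "6mo" else "genotype_age1"
                mult = mult * 2.0 ** true_lfc[key]
            for rep in range(1, n_rna_replicates + 1):
                srng = cfg.rng_for(f"rna/{genotype}/{age}/{rep}")
                cols.append(draw(base * mult, srng))
                samples.append({"genotype": genotype, "age": age, "replicate": rep})
    counts = np.column_stack(cols)

    ct_cols, ct_samples = [], []
    for celltype, sign in (("neuron", 0.5), ("glia", -0.5)):
        for rep in range(1, n_rna_replicates + 1):
            srng = cfg.rng_for(f"rna_ct/{celltype}/{rep}")
            mean = base * 2.0 ** (sign * ct)
            ct_cols.append(draw(mean, srng))
            ct_samples.append({"celltype": celltype, "replicate": rep})
    celltype_counts = np.column_stack(ct_cols)

    return RnaSim(
        counts=counts,
        gene_ids=[g.annotation.gene_id for g in truth.genes],
        samples=samples,
        celltype_counts=celltype_counts,
        celltype_samples=ct_samples,
        true_lfc=true_lfc,
    )


# ---------------------------------------------------------------------------
# 4C profiles from a bead geometry
# ---------------------------------------------------------------------------


def simulate_fourc(
    truth_beads: np.ndarray,
    baits: Sequence[int],
    frag_per_bead: int = 25,
    noise_sigma: float = 0.2,
    alpha: float = 1.0,
    amplitude: float = 1000.0,
    seed: int = 0,
) -> list["FourCProfile"]:
    """Per-bait 4C fragment profiles from known bead coordinates.

    Expected fragment signal decays with bait-bead Euclidean distance as
    ``A * d**(-alpha)``; each fragment then receives independent
    multiplicative log-normal noise (sigma on the natural-log scale) and the
    result is rounded to integer counts.  The bait's own bead is assigned the
    maximum off-bait signal (it is excluded from scoring downstream anyway).
    """
    from .fourc import FourCProfile  # local import to avoid a cycle

    coords = np.asarray(truth_beads, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("truth_beads must be an (n, 3) coordinate array")
    n_beads = coords.shape[0]
    if len(baits) < 4:
        raise ValueError("need >= 4 bait viewpoints for 3D modelling")
    for b in baits:
        if not (0 <= b < n_beads):
            raise ValueError(f"bait bead index {b} out of range")
    rng = np.random.default_rng(seed)
    profiles = []
    for b in baits:
        d = np.linalg.norm(coords - coords[b], axis=1)
        with np.errstate(divide="ignore"):
            s = amplitude * np.where(d > 0, d, np.inf) ** (-alpha)
        if alpha == 0:
            s = np.full(n_beads, amplitude)
        s[b] = s[np.arange(n_beads) != b].max() if n_beads > 1 else amplitude
        frag_expected = np.repeat(s, frag_per_bead)
        if noise_sigma > 0:
            frag_expected = frag_expected * rng.lognormal(
                0.0, noise_sigma, size=frag_expected.size
            )
        counts = np.round(frag_expected).astype(int)
        bait_frag = b * frag_per_bead + frag_per_bead // 2
        profiles.append(
            FourCProfile(
                bait_fragment=bait_frag,
                counts=counts.astype(float),
                metadata={"bait_bead": int(b)},
            )
        )
    return profiles


def two_tad_geometry(
    n_beads: int,
    boundary: int,
    intra_radius: float = 2.0,
    separation: float = 10.0,
    seed: int = 0,
) -> np.ndarray:
    """A planted two-domain bead geometry: beads [0, boundary) cluster around
    one centre and [boundary, n) around another, ``separation`` model units
    apart; within-domain positions are uniform in a ball of ``intra_radius``."""
    if not (1 < boundary < n_beads - 1):
        raise ValueError("boundary must be interior to the chain")
    rng = np.random.default_rng(seed)
    centres = np.array([[0.0, 0.0, 0.0], [separation, 0.0, 0.0]])
    coords = np.empty((n_beads, 3))
    for i in range(n_beads):
        c = centres[0] if i < boundary else centres[1]
        # uniform in ball
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        r = intra_radius * rng.random() ** (1 / 3)
        coords[i] = c + r * v
    return coords


# ---------------------------------------------------------------------------
# on-disk export (same formats the real pipeline reads)
# ---------------------------------------------------------------------------


def write_simulation(out_dir, cfg: SimulationConfig, with_sequence: bool = False) -> dict:
    """Run the generator and write genome, annotation, truth and tracks to
    ``out_dir`` in the pipeline's input formats.  Returns a manifest dict."""
    import os

    from .core import write_gene_annotation, write_bed
    from dataclasses import replace as dc_replace

    os.makedirs(out_dir, exist_ok=True)
    sequences, genes, truth = simulate_genome_and_annotation(
        cfg, with_sequence=with_sequence
    )
    manifest: dict = {"seed": cfg.seed, "tracks": []}
    if with_sequence:
        fasta = os.path.join(out_dir, "genome.fa")
        with open(fasta, "w") as fh:
            for chrom, seq in sequences.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
        manifest["genome"] = "genome.fa"
    write_gene_annotation(os.path.join(out_dir, "genes.bed"), genes)
    write_bed(
        os.path.join(out_dir, "enhancers_truth.bed"),
        [dc_replace(e.interval, name=e.label) for e in truth.enhancers],
    )
    truth.to_json(os.path.join(out_dir, "ground_truth.json"))
    tracks = simulate_chip_tracks(cfg, truth)
    for key, track in sorted(tracks.items()):
        name = f"{key.mark}_{key.fraction.replace('+', 'pos').replace('-', 'neg')}_{key.genotype}_{key.age}_rep{key.replicate}.bedgraph"
        track.to_bedgraph(os.path.join(out_dir, name))
        manifest["tracks"].append(name)
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
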