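"""Synthetic-data generators with machine-readable ground truth.

Every downstream stage of the pipeline (quantification, differential
abundance, DMR calling, overlap statistics, phenotype statistics) is
testable against the truths emitted here, without any sequencing download.
The generators emulate:

- a small TAIR10-like genome with non-overlapping gene and TE annotation,
  TE family/superfamily labels, and dense cytosine positions in the three
  contexts (CG/CHG/CHH);
- per-cytosine bisulfite reports with Poisson coverage and binomial
  methylation, with planted hypomethylated regions (methylated TE-like
  islands that lose methylation in the test condition);
- length-structured (18-30 nt) collapsed small-RNA reads, multimapping by
  literal repeated placement at a family's genomic copies so that the hit
  count is exact by construction, with group-specific depletion;
- negative-binomial count matrices with known fold changes and dispersion;
- per-plant collapsed-seed counts with genotype effects and optional
  beta-binomial overdispersion.

Each generator is deterministic under a fixed master seed; streams are keyed
by (seed, generator name) so stage-level reproducibility does not depend on
call order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import stage_rng
from .core import CONTEXTS, AlignedSmallRead, GenomicInterval

#: TE family -> superfamily labels in TAIR10 nomenclature.
DEFAULT_TE_CATALOG: dict[str, str] = {
    "ATGP1": "LTR/Gypsy",
    "ATGP2N": "LTR/Gypsy",
    "ATHILA4": "LTR/Gypsy",
    "ATHILA4A": "LTR/Gypsy",
    "ATCOPIA93": "LTR/Copia",
    "ATCOPIA28": "LTR/Copia",
    "VANDAL21": "DNA/MuDR",
    "ATENSPM3": "DNA/En-Spm",
    "ATREP3": "RC/Helitron",
    "TA11": "LINE/L1",
}

#: cytosines per 100-bp bin per context; CHH sites dominate, as in the
#: A/C/T-rich Arabidopsis genome.
DEFAULT_CYTOSINES_PER_BIN: dict[str, int] = {"CG": 3, "CHG": 3, "CHH": 10}

#: read-length distributions: genes carry mostly 21/22-nt siRNAs, TEs mostly
#: 24-nt heterochromatic siRNAs.
GENE_LENGTH_DIST: dict[int, float] = {21: 0.45, 22: 0.35, 24: 0.10, 20: 0.05, 23: 0.05}
TE_LENGTH_DIST: dict[int, float] = {24: 0.70, 23: 0.10, 21: 0.10, 22: 0.10}


@dataclass
class SimGenome:
    """A simulated genome: chromosome sizes, annotation, cytosine positions."""

    chrom_lengths: dict[str, int]
    features: list[GenomicInterval]
    cytosines: pd.DataFrame  # columns chrom, pos, strand, context

    def features_of_class(self, fclass: str) -> list[GenomicInterval]:
        return [f for f in self.features if f.feature_class == fclass]

    def te_copies_by_family(self) -> dict[str, list[GenomicInterval]]:
        out: dict[str, list[GenomicInterval]] = {}
        for f in self.features:
            if f.feature_class == "TE" and f.family:
                out.setdefault(f.family, []).append(f)
        return out


@dataclass
class PlantedRegion:
    """A planted differential-methylation region.

    ``ref_level`` is the methylation level of the reference condition inside
    the region (defaults to the context baseline); the test condition has
    ``ref_level + delta``.  A methylated island losing methylation is
    expressed as e.g. ref_level 0.4, delta -0.3 on a 0.1 CHH background.
    """

    interval: GenomicInterval
    context: str
    delta: float
    ref_level: float | None = None


@dataclass
class MethylationTruth:
    baseline_level: dict[str, float] = field(
        default_factory=lambda: {"CG": 0.85, "CHG": 0.35, "CHH": 0.10}
    )
    planted_regions: list[PlantedRegion] = field(default_factory=list)
    coverage_mean: float = 20.0

    def validate(self) -> None:
        for ctx, level in self.baseline_level.items():
            if ctx not in CONTEXTS or not (0 <= level <= 1):
                raise ValueError(f"invalid baseline for {ctx!r}: {level}")
        if self.coverage_mean < 0:
            raise ValueError("coverage_mean must be non-negative")
        for pr in self.planted_regions:
            base = pr.ref_level if pr.ref_level is not None else self.baseline_level[pr.context]
            if not (0 <= base <= 1 and 0 <= base + pr.delta <= 1):
                raise ValueError(
                    f"planted region {pr.interval.chrom}:{pr.interval.start}-"
                    f"{pr.interval.end}: level {base}+{pr.delta} outside [0, 1]"
                )

    def regions_table(self) -> pd.DataFrame:
        rows = [
            (
                pr.interval.chrom,
                pr.interval.start,
                pr.interval.end,
                pr.context,
                pr.delta,
                pr.ref_level if pr.ref_level is not None else self.baseline_level[pr.context],
            )
            for pr in self.planted_regions
        ]
        return pd.DataFrame(
            rows, columns=["chrom", "start", "end", "context", "delta", "ref_level"]
        )


@dataclass
class ExpressionTruth:
    """Per-feature NB expression truth: means, dispersion, planted log2 fold
    changes (group B relative to A) and per-sample size factors."""

    mean: dict[str, float]
    dispersion: float | dict[str, float] = 0.1
    group_log2fc: dict[str, float] = field(default_factory=dict)
    size_factors: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        if any(m <= 0 for m in self.mean.values()):
            raise ValueError("feature means must be positive")
        disps = (
            self.dispersion.values()
            if isinstance(self.dispersion, dict)
            else [self.dispersion]
        )
        if any(d < 0 for d in disps):
            raise ValueError("dispersion must be non-negative")


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def simulate_genome(
    seed: int,
    n_chrom: int = 2,
    chrom_length: int = 50_000,
    n_genes: int = 15,
    n_tes: int = 25,
    te_family_catalog: dict[str, str] | None = None,
    cytosines_per_bin: dict[str, int] | None = None,
    gene_length: tuple[int, int] = (800, 2500),
    te_length: tuple[int, int] = (300, 1200),
) -> SimGenome:
    """Simulate a genome with non-overlapping gene/TE annotation.

    TE copies of the same family are given identical lengths so that a
    family's reads can be placed at the same offset in every copy.
    Raises if the requested features cannot be placed.
    """
    catalog = te_family_catalog if te_family_catalog is not None else DEFAULT_TE_CATALOG
    per_bin = cytosines_per_bin or DEFAULT_CYTOSINES_PER_BIN
    if n_tes > 0 and not catalog:
        raise ValueError("n_tes > 0 requires a non-empty TE family catalog")
    rng = stage_rng(seed, "genome")
    chroms = {f"Chr{i + 1}": chrom_length for i in range(n_chrom)}

    min_total = n_genes * gene_length[0] + n_tes * te_length[0]
    if min_total > 0.8 * n_chrom * chrom_length:
        raise ValueError(
            f"cannot fit {n_genes} genes + {n_tes} TEs of minimum size into "
            f"{n_chrom} x {chrom_length} bp"
        )

    families = sorted(catalog)
    fam_lengths = {
        fam: int(rng.integers(te_length[0], te_length[1] + 1)) for fam in families
    }
    specs: list[tuple[str, int, str | None]] = []
    for _ in range(n_genes):
        specs.append(("gene", int(rng.integers(gene_length[0], gene_length[1] + 1)), None))
    for i in range(n_tes):
        fam = families[i % len(families)]
        specs.append(("TE", fam_lengths[fam], fam))
    # place longest first to keep rejection sampling cheap
    order = sorted(range(len(specs)), key=lambda i: -specs[i][1])

    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    features: list[GenomicInterval] = []
    gene_idx = 0
    for idx in order:
        fclass, length, fam = specs[idx]
        ok = False
        for _ in range(2000):
            chrom = f"Chr{int(rng.integers(n_chrom)) + 1}"
            start = int(rng.integers(0, chrom_length - length))
            if all(start >= e or start + length <= s for s, e in placed[chrom]):
                placed[chrom].append((start, start + length))
                strand = "+" if rng.random() < 0.5 else "-"
                if fclass == "gene":
                    name_fam = None
                    superfam = None
                else:
                    name_fam = fam
                    superfam = catalog[fam]
                features.append(
                    GenomicInterval(
                        chrom=chrom,
                        start=start,
                        end=start + length,
                        strand=strand,
                        feature_class=fclass,
                        family=name_fam,
                        superfamily=superfam,
                    )
                )
                ok = True
                break
        if not ok:
            raise ValueError("could not place all requested features; genome too dense")
        if fclass == "gene":
            gene_idx += 1
    features.sort(key=lambda f: (f.chrom, f.start))

    rows = []
    bin_size = 100
    for chrom, length in chroms.items():
        for bstart in range(0, length, bin_size):
            width = min(bin_size, length - bstart)
            n_sites = sum(per_bin.values())
            if n_sites > width:
                raise ValueError("cytosine density exceeds one site per bp")
            offs = rng.choice(width, size=n_sites, replace=False)
            offs.sort()
            ctxs = [c for c in CONTEXTS for _ in range(per_bin.get(c, 0))]
            ctx_arr = np.array(ctxs)
            rng.shuffle(ctx_arr)
            for off, ctx in zip(offs, ctx_arr):
                strand = "+" if rng.random() < 0.5 else "-"
                rows.append((chrom, bstart + int(off), strand, ctx))
    cytosines = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "context"])
    return SimGenome(chrom_lengths=chroms, features=features, cytosines=cytosines)


# ---------------------------------------------------------------------------
# methylome
# ---------------------------------------------------------------------------

def simulate_methylome(
    genome: SimGenome,
    truth: MethylationTruth,
    n_replicates: int = 1,
    seed: int = 0,
    conditions: tuple[str, str] = ("test", "reference"),
) -> dict[tuple[str, int], pd.DataFrame]:
    """Simulate per-cytosine bisulfite reports for two conditions.

    Coverage is Poisson(coverage_mean) per cytosine; methylated counts are
    Binomial(coverage, level).  Inside a planted region (matching context)
    the reference condition is at the region's reference level and the test
    condition at reference level + delta; elsewhere both are at the context
    baseline.  Returns one cytosine table per (condition, replicate).
    """
    truth.validate()
    rng = stage_rng(seed, "methylome")
    cyt = genome.cytosines
    level_ref = np.array([truth.baseline_level[c] for c in cyt["context"]], dtype=float)
    level_test = level_ref.copy()
    chrom_arr = cyt["chrom"].to_numpy()
    pos_arr = cyt["pos"].to_numpy()
    ctx_arr = cyt["context"].to_numpy()
    for pr in truth.planted_regions:
        base = pr.ref_level if pr.ref_level is not None else truth.baseline_level[pr.context]
        mask = (
            (chrom_arr == pr.interval.chrom)
            & (pos_arr >= pr.interval.start)
            & (pos_arr < pr.interval.end)
            & (ctx_arr == pr.context)
        )
        level_ref[mask] = base
        level_test[mask] = base + pr.delta

    levels = {conditions[0]: level_test, conditions[1]: level_ref}
    out: dict[tuple[str, int], pd.DataFrame] = {}
    for cond in conditions:
        for rep in range(1, n_replicates + 1):
            cov = rng.poisson(truth.coverage_mean, size=len(cyt))
            meth = rng.binomial(cov, levels[cond])
            df = cyt.copy()
            df["meth"] = meth
            df["unmeth"] = cov - meth
            out[(cond, rep)] = df
    return out


# ---------------------------------------------------------------------------
# small-RNA reads
# ---------------------------------------------------------------------------

def simulate_smallrna_reads(
    genome: SimGenome,
    expression: ExpressionTruth,
    seed: int = 0,
    condition: str = "A",
    replicate: int = 1,
    gene_length_dist: dict[int, float] | None = None,
    te_length_dist: dict[int, float] | None = None,
    mean_multiplicity: float = 3.0,
    contaminant_rate: float = 0.02,
    imperfect_rate: float = 0.02,
) -> list[AlignedSmallRead]:
    """Simulate collapsed small-RNA reads for one sample.

    Expression truth keys are feature ids: ``gene:<i>`` for the i-th gene
    locus and ``TE:<family>`` for a TE family.  A TE family's reads are
    placed at the same offset in every genomic copy of the family, so their
    hit count equals the copy number by construction; gene reads map
    uniquely.  ``group_log2fc`` applies only when ``condition == "B"``.
    Contaminant reads (length outside 18-30) and imperfect-match reads are
    planted at low rates as negative controls for the downstream filter.
    """
    expression.validate()
    gene_dist = GENE_LENGTH_DIST if gene_length_dist is None else gene_length_dist
    te_dist = TE_LENGTH_DIST if te_length_dist is None else te_length_dist
    if not gene_dist or not te_dist:
        raise ValueError("length distributions must be non-empty")
    rng = stage_rng(seed, f"smallrna:{condition}:{replicate}")
    genes = genome.features_of_class("gene")
    fams = genome.te_copies_by_family()
    sf = expression.size_factors.get(f"{condition}{replicate}", 1.0)

    reads: list[AlignedSmallRead] = []
    serial = 0
    for feat_id, mean in expression.mean.items():
        if feat_id.startswith("gene:"):
            gi = int(feat_id.split(":", 1)[1])
            if gi >= len(genes):
                raise ValueError(f"{feat_id}: genome has only {len(genes)} genes")
            loci = [genes[gi]]
            dist = gene_dist
        elif feat_id.startswith("TE:"):
            fam = feat_id.split(":", 1)[1]
            if fam not in fams:
                raise ValueError(f"{feat_id}: family not present in genome")
            loci = fams[fam]
            dist = te_dist
        else:
            raise ValueError(f"unknown feature id {feat_id!r}")
        lfc = expression.group_log2fc.get(feat_id, 0.0) if condition == "B" else 0.0
        mu = mean * (2.0**lfc) * sf
        n_distinct = int(rng.poisson(mu / mean_multiplicity))
        lengths = np.array(sorted(dist), dtype=int)
        probs = np.array([dist[ln] for ln in lengths], dtype=float)
        probs = probs / probs.sum()
        min_locus = min(len(l) for l in loci)
        for _ in range(n_distinct):
            length = int(rng.choice(lengths, p=probs))
            length = min(length, min_locus)
            count = 1 + int(rng.poisson(mean_multiplicity - 1.0))
            offset = int(rng.integers(0, min_locus - length + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            serial += 1
            rid = f"{condition}{replicate}:{feat_id}:{serial}_x{count}"
            placements = [
                (
                    GenomicInterval(l.chrom, l.start + offset, l.start + offset + length),
                    strand,
                )
                for l in loci
            ]
            reads.append(
                AlignedSmallRead(
                    read_id=rid,
                    length=length,
                    n_hits=len(placements),
                    perfect_match=rng.random() >= imperfect_rate,
                    count=count,
                    placements=placements,
                )
            )

    # planted negative controls: out-of-window lengths at random positions
    n_contam = int(rng.poisson(contaminant_rate * max(1, len(reads))))
    chroms = sorted(genome.chrom_lengths)
    for i in range(n_contam):
        length = int(rng.choice([16, 17, 31, 32, 35]))
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, genome.chrom_lengths[chrom] - length))
        serial += 1
        rid = f"{condition}{replicate}:contaminant:{serial}_x1"
        reads.append(
            AlignedSmallRead(
                read_id=rid,
                length=length,
                n_hits=1,
                perfect_match=True,
                count=1,
                placements=[(GenomicInterval(chrom, start, start + length), "+")],
            )
        )
    for r in reads:
        r.validate()
    return reads


def expected_weighted_count(
    expression: ExpressionTruth, feat_id: str, condition: str = "A"
) -> float:
    """Expected total weighted count for a feature in one sample (truth)."""
    lfc = expression.group_log2fc.get(feat_id, 0.0) if condition == "B" else 0.0
    return expression.mean[feat_id] * (2.0**lfc)


# ---------------------------------------------------------------------------
# NB count matrices
# ---------------------------------------------------------------------------

def simulate_count_matrix(
    expression: ExpressionTruth,
    n_per_group: tuple[int, int] = (2, 2),
    seed: int = 0,
) -> tuple[pd.DataFrame, list[str]]:
    """Simulate a features x samples NB count matrix for a two-group design.

    Returns the raw count matrix and the per-sample group labels (A/B).
    Counts for feature f in sample j are NB with mean
    ``size_factor_j * mean_f * 2**(log2fc_f if group B)`` and dispersion
    alpha (variance mu + alpha mu^2); alpha = 0 degenerates to Poisson.
    """
    expression.validate()
    rng = stage_rng(seed, "counts")
    features = sorted(expression.mean)
    samples = [f"A{i + 1}" for i in range(n_per_group[0])] + [
        f"B{i + 1}" for i in range(n_per_group[1])
    ]
    groups = ["A"] * n_per_group[0] + ["B"] * n_per_group[1]
    sfs = np.array([expression.size_factors.get(s, 1.0) for s in samples])
    mat = np.zeros((len(features), len(samples)), dtype=np.int64)
    for i, feat in enumerate(features):
        alpha = (
            expression.dispersion[feat]
            if isinstance(expression.dispersion, dict)
            else expression.dispersion
        )
        base = expression.mean[feat]
        lfc = expression.group_log2fc.get(feat, 0.0)
        mus = sfs * base * np.where(np.array(groups) == "B", 2.0**lfc, 1.0)
        if alpha <= 0:
            mat[i] = rng.poisson(mus)
        else:
            # NB as gamma-Poisson: shape 1/alpha, scale alpha*mu
            lam = rng.gamma(1.0 / alpha, alpha * mus)
            mat[i] = rng.poisson(lam)
    df = pd.DataFrame(mat, index=features, columns=samples)
    return df, groups


# ---------------------------------------------------------------------------
# seed counts
# ---------------------------------------------------------------------------

def simulate_seed_counts(
    genotype_effects: dict[str, float],
    n_plants: int = 15,
    seeds_per_plant: int = 300,
    rho: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate per-plant normal/collapsed seed counts.

    Collapsed counts are beta-binomial(seeds_per_plant, p_genotype, rho);
    rho = 0 degenerates to binomial.  One row per plant.
    """
    if not (0 <= rho < 1):
        raise ValueError("rho must be in [0, 1)")
    for g, p in genotype_effects.items():
        if not (0 <= p <= 1):
            raise ValueError(f"collapse probability for {g!r} outside [0, 1]")
    rng = stage_rng(seed, "seeds")
    rows = []
    for genotype in sorted(genotype_effects):
        p = genotype_effects[genotype]
        for i in range(n_plants):
            if rho > 0 and 0 < p < 1:
                a = p * (1 - rho) / rho
                b = (1 - p) * (1 - rho) / rho
                pi = rng.beta(a, b)
            else:
                pi = p
            collapsed = int(rng.binomial(seeds_per_plant, pi))
            rows.append((genotype, f"{genotype}_p{i + 1}", seeds_per_plant - collapsed, collapsed))
    return pd.DataFrame(rows, columns=["genotype", "plant_id", "normal", "collapsed"])
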