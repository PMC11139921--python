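"""Small-RNA filtering, multimapper weighting, and per-locus quantification.

The quantification rule: collapse identical sequences, keep the multiplicity
(the non-redundant read count), divide the multiplicity by the read's number
of genomic hits, and give each placement that weight.  Summed over the
genome, placement weights therefore conserve the total filtered read count
exactly.  Per-locus counts use an any-overlap rule (strand-agnostic by
default); library-size normalization is reads per million of filtered,
perfectly mapped reads.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .config import FilterConfig
from .core import AlignedSmallRead, GenomicInterval

logger = logging.getLogger(__name__)

PLACEMENT_COLUMNS = ["read_id", "length", "chrom", "start", "end", "strand", "weight"]


def filter_reads(
    reads: Iterable[AlignedSmallRead], cfg: FilterConfig | None = None
) -> list[AlignedSmallRead]:
    """Keep reads inside the length window (18-30 nt by default) and, when
    required, with perfect genomic matches.  Removal counts are logged by
    reason."""
    cfg = cfg or FilterConfig()
    cfg.validate()
    kept: list[AlignedSmallRead] = []
    removed = {"too_short": 0, "too_long": 0, "imperfect": 0}
    for read in reads:
        if read.length < cfg.min_len:
            removed["too_short"] += 1
        elif read.length > cfg.max_len:
            removed["too_long"] += 1
        elif cfg.require_perfect and not read.perfect_match:
            removed["imperfect"] += 1
        else:
            kept.append(read)
    if any(removed.values()):
        logger.info("filter_reads removed %s", removed)
    return kept


def weight_multimappers(reads: Sequence[AlignedSmallRead]) -> pd.DataFrame:
    """Expand reads into per-placement rows with weight count / n_hits.

    The sum of all weights equals the sum of distinct-read counts exactly.
    """
    rows = []
    for read in reads:
        if read.n_hits <= 0:
            raise ValueError(f"read {read.read_id}: n_hits must be positive")
        w = read.count / read.n_hits
        for iv, strand in read.placements:
            rows.append((read.read_id, read.length, iv.chrom, iv.start, iv.end, strand, w))
    return pd.DataFrame(rows, columns=PLACEMENT_COLUMNS)


def total_weight(placements: pd.DataFrame) -> float:
    return float(placements["weight"].sum())


def _locus_trees(loci: Sequence[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for i, locus in enumerate(loci):
        trees.setdefault(locus.chrom, IntervalTree()).addi(locus.start, locus.end, i)
    return trees


def locus_id(locus: GenomicInterval, index: int | None = None) -> str:
    label = locus.family or locus.feature_class
    return f"{label}:{locus.chrom}:{locus.start}-{locus.end}"


def count_by_locus(
    placements: pd.DataFrame,
    loci: Sequence[GenomicInterval],
    sample_id: str = "sample",
    strand_aware: bool = False,
) -> pd.DataFrame:
    """Sum placement weights per locus (one-column count matrix).

    A placement contributes its full weight to every locus it overlaps
    (any-overlap; the 1/n_hits weighting already accounts for genomic
    multiplicity, so no additional split across overlapping annotation).
    """
    ids = [locus_id(l, i) for i, l in enumerate(loci)]
    counts = np.zeros(len(loci), dtype=float)
    if len(loci) and len(placements):
        trees = _locus_trees(loci)
        for row in placements.itertuples(index=False):
            tree = trees.get(row.chrom)
            if tree is None:
                continue
            for hit in tree.overlap(row.start, row.end):
                if strand_aware and loci[hit.data].strand not in (".", row.strand):
                    continue
                counts[hit.data] += row.weight
    return pd.DataFrame({sample_id: counts}, index=pd.Index(ids, name="feature"))


def quantify_sample(
    reads: Iterable[AlignedSmallRead],
    loci: Sequence[GenomicInterval],
    cfg: FilterConfig | None = None,
    sample_id: str = "sample",
    strand_aware: bool = False,
) -> tuple[pd.DataFrame, float]:
    """filter -> weight -> count for one sample; returns (column, library size).

    Library size is the total weighted filtered mapped read count, the RPM
    denominator.
    """
    filtered = filter_reads(reads, cfg)
    placements = weight_multimappers(filtered)
    col = count_by_locus(placements, loci, sample_id=sample_id, strand_aware=strand_aware)
    return col, total_weight(placements)


def rpm_normalize(matrix: pd.DataFrame, library_sizes: dict[str, float]) -> pd.DataFrame:
    """Reads-per-million normalization against per-sample library sizes."""
    out = matrix.astype(float).copy()
    for sample in out.columns:
        if sample not in library_sizes:
            raise ValueError(f"no library size for sample {sample!r}")
        size = library_sizes[sample]
        if size <= 0:
            raise ValueError(f"library size for sample {sample!r} is not positive")
        out[sample] = out[sample] / size * 1e6
    return out


def size_class_profile(
    reads: Iterable[AlignedSmallRead],
    loci: Sequence[GenomicInterval],
    cfg: FilterConfig | None = None,
) -> pd.DataFrame:
    """Per-locus weighted fraction of each siRNA size class.

    Rows are loci, columns size classes; fractions sum to 1 where the locus
    has positive weight and are NaN for loci with no assigned weight.
    """
    cfg = cfg or FilterConfig()
    placements = weight_multimappers(list(reads))
    if len(placements):
        placements = placements.assign(
            size_class=[cfg.size_class(ln) for ln in placements["length"]]
        )
    classes = list(cfg.sirna_classes) + ["other"]
    cols = {}
    for cls in classes:
        sub = placements[placements["size_class"] == cls] if len(placements) else placements
        cols[cls] = count_by_locus(sub, loci, sample_id=cls)[cls]
    prof = pd.DataFrame(cols)
    totals = prof.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = prof.div(totals, axis=0)
    frac[totals == 0] = np.nan
    return frac
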