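"""Binned, context-specific DMR caller.

Definition: the genome is tiled into fixed 100-bp bins anchored at
coordinate 0.  A cytosine is differentially methylated when both conditions
cover it with at least ``min_coverage`` reads and the absolute level
difference reaches the context-specific threshold (0.4 for CG, 0.2 for CHG,
0.1 for CHH).  A bin is a candidate DMR for a (context, direction) when it
holds at least 4 (CG), 5 (CHG) or 6 (CHH) such cytosines of that direction;
candidate bins whose gap is at most 200 bp merge transitively into one DMR.
"hypo" means the test condition (A) is less methylated than the reference
(B).  Replicates are pooled by summing counts before comparison.
"""

from __future__ import annotations

import logging
from collections.abc import Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .config import DmrConfig
from .core import CONTEXTS, CytosineRecord, Dmr, GenomicInterval

logger = logging.getLogger(__name__)

CYTOSINE_KEY = ["chrom", "pos", "strand", "context"]

BIN_COLUMNS = [
    "chrom",
    "start",
    "end",
    "context",
    "direction",
    "n_support",
    "mean_level_a",
    "mean_level_b",
]


def pool_replicates(reports: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Sum methylation counts per cytosine across replicate reports.

    A cytosine present in only some replicates is kept with the available
    counts (and logged); the cytosine identity is (chrom, pos, strand,
    context).
    """
    if not reports:
        raise ValueError("no replicate reports to pool")
    if len(reports) == 1:
        return reports[0].copy()
    cat = pd.concat(reports, ignore_index=True)
    pooled = cat.groupby(CYTOSINE_KEY, as_index=False, sort=True)[["meth", "unmeth"]].sum()
    counts = cat.groupby(CYTOSINE_KEY, sort=True).size()
    n_partial = int((counts < len(reports)).sum())
    if n_partial:
        logger.info("%d cytosines missing from some replicates; pooled available counts", n_partial)
    return pooled


def per_cytosine_diff(a: CytosineRecord, b: CytosineRecord, cfg: DmrConfig | None = None) -> str:
    """Classify one cytosine: hypo / hyper / not_differential / insufficient.

    A is the test sample and B the reference; "hypo" means A is less
    methylated than B.  Coverage below ``min_coverage`` in either sample
    gives "insufficient"; otherwise the status is differential when the
    absolute level difference reaches the context threshold.
    """
    cfg = cfg or DmrConfig()
    cfg.validate()
    if (a.chrom, a.position, a.context) != (b.chrom, b.position, b.context):
        raise ValueError("cytosine records disagree on position or context")
    if a.coverage < cfg.min_coverage or b.coverage < cfg.min_coverage:
        return "insufficient"
    diff = a.level - b.level
    if abs(diff) >= cfg.min_abs_diff[a.context] - 1e-12:
        if cfg.diff_method == "fisher" and not _fisher_significant(a, b, cfg.fisher_alpha):
            return "not_differential"
        return "hypo" if diff < 0 else "hyper"
    return "not_differential"


def _fisher_significant(a: CytosineRecord, b: CytosineRecord, alpha: float) -> bool:
    from scipy.stats import fisher_exact

    _odds, p = fisher_exact(
        [[a.meth_count, a.unmeth_count], [b.meth_count, b.unmeth_count]]
    )
    return p < alpha


def _join_conditions(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    joined = a.merge(b, on=CYTOSINE_KEY, how="inner", suffixes=("_a", "_b"))
    return joined


def _classify(joined: pd.DataFrame, cfg: DmrConfig) -> pd.DataFrame:
    cov_a = joined["meth_a"] + joined["unmeth_a"]
    cov_b = joined["meth_b"] + joined["unmeth_b"]
    ok = (cov_a >= cfg.min_coverage) & (cov_b >= cfg.min_coverage)
    with np.errstate(invalid="ignore", divide="ignore"):
        level_a = joined["meth_a"] / cov_a
        level_b = joined["meth_b"] / cov_b
    diff = level_a - level_b
    thr = joined["context"].map(cfg.min_abs_diff).to_numpy(dtype=float)
    differential = ok & (np.abs(diff) >= thr - 1e-12)
    if cfg.diff_method == "fisher":
        from scipy.stats import fisher_exact

        for idx in np.flatnonzero(differential.to_numpy()):
            row = joined.iloc[idx]
            _odds, p = fisher_exact(
                [[row["meth_a"], row["unmeth_a"]], [row["meth_b"], row["unmeth_b"]]]
            )
            if p >= cfg.fisher_alpha:
                differential.iloc[idx] = False
    status = np.where(
        ~ok,
        "insufficient",
        np.where(differential, np.where(diff < 0, "hypo", "hyper"), "not_differential"),
    )
    out = joined[CYTOSINE_KEY].copy()
    out["level_a"] = level_a
    out["level_b"] = level_b
    out["covered"] = ok
    out["status"] = status
    return out


def bin_scan(a: pd.DataFrame, b: pd.DataFrame, cfg: DmrConfig | None = None) -> pd.DataFrame:
    """Scan fixed genome bins for candidate DMRs per context and direction.

    Inputs are pooled per-condition cytosine tables (columns chrom, pos,
    strand, context, meth, unmeth).  Returns one row per candidate
    (bin, context, direction) with the supporting-cytosine count and the
    mean levels of the supporting cytosines in each condition.
    """
    cfg = cfg or DmrConfig()
    cfg.validate()
    classified = _classify(_join_conditions(a, b), cfg)
    diff = classified[classified["status"].isin(["hypo", "hyper"])].copy()
    rows: list[tuple] = []
    if len(diff):
        diff["bin"] = diff["pos"] // cfg.bin_size
        grouped = diff.groupby(["chrom", "bin", "context", "status"], sort=True)
        for (chrom, b_idx, context, direction), sub in grouped:
            if len(sub) < cfg.min_diff_cytosines[context]:
                continue
            start = int(b_idx) * cfg.bin_size
            if cfg.require_bin_mean_diff and not _bin_mean_passes(
                classified, chrom, start, cfg, context
            ):
                continue
            rows.append(
                (
                    chrom,
                    start,
                    start + cfg.bin_size,
                    context,
                    direction,
                    int(len(sub)),
                    float(sub["level_a"].mean()),
                    float(sub["level_b"].mean()),
                )
            )
    return pd.DataFrame(rows, columns=BIN_COLUMNS)


def _bin_mean_passes(
    classified: pd.DataFrame, chrom: str, start: int, cfg: DmrConfig, context: str
) -> bool:
    sub = classified[
        (classified["chrom"] == chrom)
        & (classified["context"] == context)
        & (classified["covered"])
        & (classified["pos"] >= start)
        & (classified["pos"] < start + cfg.bin_size)
    ]
    if not len(sub):
        return False
    return abs(sub["level_a"].mean() - sub["level_b"].mean()) >= cfg.min_abs_diff[context] - 1e-12


def merge_bins(candidates: pd.DataFrame, cfg: DmrConfig | None = None) -> list[Dmr]:
    """Merge candidate bins within ``merge_distance`` bp into DMRs.

    Merging is transitive within one chromosome, context and direction; a
    gap (start of next bin minus end of previous run) of exactly the merge
    distance still merges ("within 200 bp" read inclusively).  Mean levels
    are supporting-cytosine-weighted over the merged bins.
    """
    cfg = cfg or DmrConfig()
    cfg.validate()
    dmrs: list[Dmr] = []
    if not len(candidates):
        return dmrs
    for (chrom, context, direction), sub in candidates.groupby(
        ["chrom", "context", "direction"], sort=True
    ):
        sub = sub.sort_values("start")
        run: list[pd.Series] = []
        for _, row in sub.iterrows():
            if run and row["start"] - run[-1]["end"] > cfg.merge_distance:
                dmrs.append(_finish_run(run, chrom, context, direction))
                run = []
            run.append(row)
        if run:
            dmrs.append(_finish_run(run, chrom, context, direction))
    dmrs.sort(key=lambda d: (d.chrom, d.start, d.context, d.direction))
    return dmrs


def _finish_run(run: list[pd.Series], chrom: str, context: str, direction: str) -> Dmr:
    n = int(sum(r["n_support"] for r in run))
    wa = sum(r["mean_level_a"] * r["n_support"] for r in run) / n
    wb = sum(r["mean_level_b"] * r["n_support"] for r in run) / n
    return Dmr(
        chrom=chrom,
        start=int(run[0]["start"]),
        end=int(run[-1]["end"]),
        context=context,
        direction=direction,
        n_supporting_cytosines=n,
        mean_level_a=float(wa),
        mean_level_b=float(wb),
        source_bins=tuple((int(r["start"]), int(r["end"])) for r in run),
    )


def annotate_dmrs(dmrs: Sequence[Dmr], annotation: Sequence[GenomicInterval]) -> list[Dmr]:
    """Label each DMR TE / gene / intergenic (TE has priority over gene).

    The family and superfamily of the first overlapping TE (leftmost) are
    recorded on TE-labeled DMRs.
    """
    trees: dict[str, IntervalTree] = {}
    for i, iv in enumerate(annotation):
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, i)
    out: list[Dmr] = []
    for d in dmrs:
        hits = sorted(
            (annotation[h.data] for h in trees.get(d.chrom, IntervalTree()).overlap(d.start, d.end)),
            key=lambda iv: iv.start,
        )
        te_hits = [h for h in hits if h.feature_class == "TE"]
        gene_hits = [h for h in hits if h.feature_class == "gene"]
        if te_hits:
            fclass, family, superfamily = "TE", te_hits[0].family, te_hits[0].superfamily
        elif gene_hits:
            fclass, family, superfamily = "gene", None, None
        else:
            fclass, family, superfamily = "intergenic", None, None
        out.append(
            Dmr(
                chrom=d.chrom,
                start=d.start,
                end=d.end,
                context=d.context,
                direction=d.direction,
                n_supporting_cytosines=d.n_supporting_cytosines,
                mean_level_a=d.mean_level_a,
                mean_level_b=d.mean_level_b,
                source_bins=d.source_bins,
                feature_class=fclass,
                family=family,
                superfamily=superfamily,
            )
        )
    return out


def call_dmrs(
    a_reports: Sequence[pd.DataFrame],
    b_reports: Sequence[pd.DataFrame],
    cfg: DmrConfig | None = None,
    annotation: Sequence[GenomicInterval] | None = None,
) -> list[Dmr]:
    """Full caller: pool replicates, scan bins, merge, annotate.

    A is the test condition, B the reference.
    """
    cfg = cfg or DmrConfig()
    a = pool_replicates(list(a_reports))
    b = pool_replicates(list(b_reports))
    candidates = bin_scan(a, b, cfg)
    dmrs = merge_bins(candidates, cfg)
    if annotation is not None:
        dmrs = annotate_dmrs(dmrs, annotation)
    return dmrs
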