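"""Readers and writers for every external format the pipeline touches.

Formats
-------
- bismark-style cytosine reports (TSV, 1-based positions; CX flavor with a
  context column, or the 6-column coverage flavor)
- BED6 / GFF3 annotation and DMR intervals
- SAM (NH tag) or tabular small-RNA alignments, with collapsed-read
  multiplicities encoded as a ``_xN`` read-name suffix (SAM) or an explicit
  ``count`` column (TSV)
- TSV count matrices (first column feature id, header row of sample ids)
- CSV seed-count tables

Everything in memory is 0-based half-open; all conversion happens here.
"""

from __future__ import annotations

import logging
import re
from collections.abc import Iterable, Iterator
from pathlib import Path

import pandas as pd
import pysam

from .core import CONTEXTS, AlignedSmallRead, CytosineRecord, Dmr, GenomicInterval, SeedCountRecord

logger = logging.getLogger(__name__)

CYTOSINE_COLUMNS = ["chrom", "pos", "strand", "context", "meth", "unmeth"]


class ParseError(ValueError):
    """Malformed line in an input file; carries file and line context."""


def provenance_header(seed: int | None = None, config_hash: str | None = None) -> str:
    from . import __version__

    parts = [f"pollenpipe v{__version__}"]
    if config_hash is not None:
        parts.append(f"config={config_hash}")
    if seed is not None:
        parts.append(f"seed={seed}")
    return "# " + "; ".join(parts)


# ---------------------------------------------------------------------------
# cytosine reports
# ---------------------------------------------------------------------------

def read_cytosine_report(
    path: str | Path, flavor: str = "auto", default_context: str | None = None
) -> Iterator[CytosineRecord]:
    """Stream CytosineRecords from a bismark-style cytosine report.

    The CX flavor has columns chrom, pos (1-based), strand, count_methylated,
    count_unmethylated, context[, trinucleotide].  The coverage flavor has
    chrom, pos, pos, percent, count_methylated, count_unmethylated and no
    context column; reading it requires ``default_context``.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            use_flavor = flavor
            if use_flavor == "auto":
                use_flavor = _sniff_cytosine_flavor(fields)
            try:
                if use_flavor == "cx":
                    chrom, pos, strand, meth, unmeth, context = fields[:6]
                elif use_flavor == "coverage":
                    if default_context is None:
                        raise ValueError(
                            "coverage-flavor report has no context column; "
                            "pass default_context"
                        )
                    chrom, pos, _end, _pct, meth, unmeth = fields[:6]
                    strand, context = ".", default_context
                else:
                    raise ValueError(f"unknown flavor {use_flavor!r}")
                if context not in CONTEXTS:
                    raise ValueError(f"unknown context token {context!r}")
                yield CytosineRecord(
                    chrom=chrom,
                    position=int(pos) - 1,
                    strand=strand,
                    context=context,
                    meth_count=int(meth),
                    unmeth_count=int(unmeth),
                )
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc} in line {line!r}") from exc


def _sniff_cytosine_flavor(fields: list[str]) -> str:
    # CX: column 3 is a strand symbol; coverage: column 3 is an end position
    if len(fields) >= 6 and fields[2] in ("+", "-", "."):
        return "cx"
    if len(fields) >= 6:
        return "coverage"
    raise ValueError(f"expected >= 6 tab-separated columns, got {len(fields)}")


def read_cytosine_table(path: str | Path, **kwargs) -> pd.DataFrame:
    """Read a cytosine report into a DataFrame with internal 0-based positions."""
    recs = read_cytosine_report(path, **kwargs)
    rows = [
        (r.chrom, r.position, r.strand, r.context, r.meth_count, r.unmeth_count)
        for r in recs
    ]
    return pd.DataFrame(rows, columns=CYTOSINE_COLUMNS)


def write_cytosine_report(
    records: Iterable[CytosineRecord] | pd.DataFrame,
    path: str | Path,
    header: str | None = None,
) -> None:
    """Write a CX-flavor cytosine report (1-based positions)."""
    with open(path, "w") as fh:
        if header:
            fh.write(header.rstrip("\n") + "\n")
        if isinstance(records, pd.DataFrame):
            it = (
                CytosineRecord(r.chrom, int(r.pos), r.strand, r.context, int(r.meth), int(r.unmeth))
                for r in records.itertuples(index=False)
            )
        else:
            it = iter(records)
        for rec in it:
            tri = {"CG": "CGN", "CHG": "CAG", "CHH": "CAT"}[rec.context]
            fh.write(
                f"{rec.chrom}\t{rec.position + 1}\t{rec.strand}\t"
                f"{rec.meth_count}\t{rec.unmeth_count}\t{rec.context}\t{tri}\n"
            )


# ---------------------------------------------------------------------------
# annotation intervals
# ---------------------------------------------------------------------------

_GFF_TE_TYPES = {
    "transposable_element",
    "transposable_element_gene",
    "transposon_fragment",
}
_GFF_GENE_TYPES = {"gene", "mRNA", "protein_coding_gene"}


def format_interval_name(iv: GenomicInterval) -> str:
    return f"{iv.feature_class}|{iv.family or ''}|{iv.superfamily or ''}"


def _parse_interval_name(name: str, default_class: str) -> tuple[str, str | None, str | None]:
    parts = name.split("|")
    if len(parts) == 3 and parts[0] in ("gene", "TE", "intergenic"):
        return parts[0], parts[1] or None, parts[2] or None
    return default_class, None, None


def read_annotation(
    path: str | Path, dialect: str = "auto", default_class: str = "gene"
) -> list[GenomicInterval]:
    """Read BED6 (0-based half-open) or GFF3 (1-based inclusive) annotation.

    Feature class/family/superfamily are taken from structured BED names
    (``TE|ATGP1|LTR/Gypsy``) or GFF3 types and attributes; unstructured names
    fall back to ``default_class``.
    """
    path = Path(path)
    if dialect == "auto":
        dialect = "GFF3" if path.suffix.lower() in (".gff", ".gff3") else "BED"
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = re.split(r"\t| +", line) if dialect == "BED" else line.split("\t")
            try:
                if dialect == "BED":
                    chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                    name = fields[3] if len(fields) > 3 else ""
                    strand = fields[5] if len(fields) > 5 else "."
                    fclass, family, superfamily = _parse_interval_name(name, default_class)
                elif dialect == "GFF3":
                    chrom = fields[0]
                    ftype = fields[2]
                    start, end = int(fields[3]) - 1, int(fields[4])
                    strand = fields[6] if fields[6] in ("+", "-") else "."
                    attrs = _parse_gff_attributes(fields[8] if len(fields) > 8 else "")
                    if ftype in _GFF_TE_TYPES:
                        fclass = "TE"
                    elif ftype in _GFF_GENE_TYPES:
                        fclass = "gene"
                    else:
                        fclass = default_class
                    family = attrs.get("Family") or attrs.get("family")
                    superfamily = attrs.get("Superfamily") or attrs.get("superfamily")
                else:
                    raise ValueError(f"unknown dialect {dialect!r}")
                if start >= end:
                    raise ValueError(f"empty interval after normalization: {start} >= {end}")
                out.append(
                    GenomicInterval(
                        chrom=chrom,
                        start=start,
                        end=end,
                        strand=strand,
                        feature_class=fclass,
                        family=family,
                        superfamily=superfamily,
                    )
                )
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc} in line {line!r}") from exc
    return out


def _parse_gff_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in text.split(";"):
        if "=" in chunk:
            k, v = chunk.split("=", 1)
            attrs[k.strip()] = v.strip()
    return attrs


def write_annotation_bed(
    intervals: Iterable[GenomicInterval], path: str | Path, header: str | None = None
) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(header.rstrip("\n") + "\n")
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t"
                f"{format_interval_name(iv)}\t0\t{iv.strand}\n"
            )


# ---------------------------------------------------------------------------
# small-RNA alignments
# ---------------------------------------------------------------------------

ALIGNMENT_COLUMNS = [
    "read_id",
    "count",
    "length",
    "n_hits",
    "chrom",
    "start",
    "strand",
    "mismatches",
]

_COLLAPSED_SUFFIX = re.compile(r"_x(\d+)$")


def _read_count_from_id(read_id: str) -> int:
    m = _COLLAPSED_SUFFIX.search(read_id)
    return int(m.group(1)) if m else 1


def read_alignments(path: str | Path) -> list[AlignedSmallRead]:
    """Read small-RNA alignments, grouped per distinct read.

    SAM input (``.sam``) requires the NH tag; perfect match means NM == 0
    when the NM tag is present.  Tabular input carries the columns
    ``read_id, count, length, n_hits, chrom, start, strand, mismatches``.
    Unmapped records are skipped and counted in a log summary; an n_hits
    value inconsistent with the number of alignment records is an error.
    """
    path = Path(path)
    if path.suffix.lower() == ".sam":
        grouped = _read_alignments_sam(path)
    else:
        grouped = _read_alignments_tsv(path)
    reads = list(grouped.values())
    for read in reads:
        read.validate()
    return reads


def _read_alignments_sam(path: Path) -> dict[str, AlignedSmallRead]:
    grouped: dict[str, AlignedSmallRead] = {}
    n_unmapped = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped:
                n_unmapped += 1
                continue
            if not aln.has_tag("NH"):
                raise ParseError(f"read {aln.query_name}: NH tag absent")
            n_hits = aln.get_tag("NH")
            nm = aln.get_tag("NM") if aln.has_tag("NM") else 0
            length = aln.query_length or aln.infer_query_length() or 0
            placement = (
                GenomicInterval(aln.reference_name, aln.reference_start, aln.reference_end),
                "-" if aln.is_reverse else "+",
            )
            read = grouped.get(aln.query_name)
            if read is None:
                grouped[aln.query_name] = read = AlignedSmallRead(
                    read_id=aln.query_name,
                    length=length,
                    n_hits=int(n_hits),
                    perfect_match=(nm == 0),
                    count=_read_count_from_id(aln.query_name),
                )
            read.perfect_match = read.perfect_match and nm == 0
            read.placements.append(placement)
    if n_unmapped:
        logger.info("skipped %d unmapped records in %s", n_unmapped, path)
    return grouped


def _read_alignments_tsv(path: Path) -> dict[str, AlignedSmallRead]:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(ALIGNMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing alignment columns {sorted(missing)}")
    grouped: dict[str, AlignedSmallRead] = {}
    for row in df.itertuples(index=False):
        read = grouped.get(row.read_id)
        if read is None:
            grouped[row.read_id] = read = AlignedSmallRead(
                read_id=row.read_id,
                length=int(row.length),
                n_hits=int(row.n_hits),
                perfect_match=(int(row.mismatches) == 0),
                count=int(row.count),
            )
        read.perfect_match = read.perfect_match and int(row.mismatches) == 0
        start = int(row.start)
        read.placements.append(
            (GenomicInterval(row.chrom, start, start + int(row.length)), row.strand)
        )
    return grouped


def write_alignments_tsv(
    reads: Iterable[AlignedSmallRead], path: str | Path, header: str | None = None
) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(header.rstrip("\n") + "\n")
        fh.write("\t".join(ALIGNMENT_COLUMNS) + "\n")
        for read in reads:
            mism = 0 if read.perfect_match else 1
            for iv, strand in read.placements:
                fh.write(
                    f"{read.read_id}\t{read.count}\t{read.length}\t{read.n_hits}\t"
                    f"{iv.chrom}\t{iv.start}\t{strand}\t{mism}\n"
                )


def write_alignments_sam(
    reads: Iterable[AlignedSmallRead],
    path: str | Path,
    chrom_lengths: dict[str, int],
) -> None:
    """Write alignments as headered SAM with NH/NM tags (collapsed-read ids)."""
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": c, "LN": ln} for c, ln in chrom_lengths.items()],
    }
    ref_ids = {c: i for i, c in enumerate(chrom_lengths)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for read in reads:
            for iv, strand in read.placements:
                a = pysam.AlignedSegment(out.header)
                a.query_name = read.read_id
                a.query_sequence = "N" * read.length
                a.reference_id = ref_ids[iv.chrom]
                a.reference_start = iv.start
                a.cigarstring = f"{read.length}M"
                a.mapping_quality = 255
                a.flag = 16 if strand == "-" else 0
                a.set_tag("NH", read.n_hits)
                a.set_tag("NM", 0 if read.perfect_match else 1)
                out.write(a)


# ---------------------------------------------------------------------------
# count matrices
# ---------------------------------------------------------------------------

def read_count_matrix(path: str | Path) -> pd.DataFrame:
    """Read a features x samples TSV count matrix (first column feature ids)."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if (df.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative entries in count matrix")
    return df


def write_count_matrix(
    matrix: pd.DataFrame, path: str | Path, header: str | None = None
) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(header.rstrip("\n") + "\n")
        matrix.to_csv(fh, sep="\t", index_label="feature")


# ---------------------------------------------------------------------------
# DMR BED
# ---------------------------------------------------------------------------

def write_dmr_bed(dmrs: Iterable[Dmr], path: str | Path, header: str | None = None) -> None:
    """BED6+ DMR output: name=context:direction, score=supporting cytosines,
    extra columns mean levels and feature annotation."""
    with open(path, "w") as fh:
        if header:
            fh.write(header.rstrip("\n") + "\n")
        for d in dmrs:
            fh.write(
                f"{d.chrom}\t{d.start}\t{d.end}\t{d.context}:{d.direction}\t"
                f"{d.n_supporting_cytosines}\t.\t{d.mean_level_a:.4f}\t"
                f"{d.mean_level_b:.4f}\t{d.feature_class or '.'}\t"
                f"{d.family or '.'}\t{d.superfamily or '.'}\n"
            )


def read_dmr_bed(path: str | Path) -> list[Dmr]:
    out: list[Dmr] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            try:
                context, direction = f[3].split(":")
                out.append(
                    Dmr(
                        chrom=f[0],
                        start=int(f[1]),
                        end=int(f[2]),
                        context=context,
                        direction=direction,
                        n_supporting_cytosines=int(f[4]),
                        mean_level_a=float(f[6]) if len(f) > 6 else float("nan"),
                        mean_level_b=float(f[7]) if len(f) > 7 else float("nan"),
                        source_bins=(),
                        feature_class=None if len(f) <= 8 or f[8] == "." else f[8],
                        family=None if len(f) <= 9 or f[9] == "." else f[9],
                        superfamily=None if len(f) <= 10 or f[10] == "." else f[10],
                    )
                )
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc} in line {line!r}") from exc
    return out


# ---------------------------------------------------------------------------
# seed-count tables
# ---------------------------------------------------------------------------

def read_seed_counts(path: str | Path) -> list[SeedCountRecord]:
    df = pd.read_csv(path, comment="#")
    required = {"genotype", "plant_id", "normal", "collapsed"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing seed-count columns {sorted(missing)}")
    return [
        SeedCountRecord(
            genotype=str(r.genotype),
            plant_id=str(r.plant_id),
            n_normal=int(r.normal),
            n_collapsed=int(r.collapsed),
        )
        for r in df.itertuples(index=False)
    ]


def write_seed_counts(
    records: Iterable[SeedCountRecord], path: str | Path, header: str | None = None
) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(header.rstrip("\n") + "\n")
        fh.write("genotype,plant_id,normal,collapsed\n")
        for r in records:
            fh.write(f"{r.genotype},{r.plant_id},{r.n_normal},{r.n_collapsed}\n")
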