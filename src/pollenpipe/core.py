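"""Core domain types shared across the pipeline.

All genomic coordinates held in memory are 0-based, half-open ``[start, end)``.
Conversion to and from 1-based external formats (bismark cytosine reports,
GFF3, SAM) happens only inside :mod:`pollenpipe.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Cytosine sequence contexts (H = A, C or T).
CONTEXTS = ("CG", "CHG", "CHH")

STRANDS = ("+", "-", ".")

FEATURE_CLASSES = ("gene", "TE", "intergenic")


@dataclass(frozen=True)
class GenomicInterval:
    """A genomic interval with optional annotation labels.

    ``start``/``end`` are 0-based half-open.  ``feature_class`` classifies the
    interval as a protein-coding gene, a transposable element, or intergenic
    space; TE intervals may additionally carry ``family`` (e.g. ``ATGP1``) and
    ``superfamily`` (e.g. ``LTR/Gypsy``) labels.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    feature_class: str = "intergenic"
    family: str | None = None
    superfamily: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.feature_class not in FEATURE_CLASSES:
            raise ValueError(f"invalid feature_class {self.feature_class!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class CytosineRecord:
    """One cytosine's methylation evidence in one sample.

    ``position`` is the internal 0-based coordinate.  ``level`` is defined
    only when coverage is positive.
    """

    chrom: str
    position: int
    strand: str
    context: str
    meth_count: int
    unmeth_count: int

    def __post_init__(self) -> None:
        if self.context not in CONTEXTS:
            raise ValueError(f"unknown context {self.context!r}")
        if self.meth_count < 0 or self.unmeth_count < 0:
            raise ValueError("negative methylation counts")

    @property
    def coverage(self) -> int:
        return self.meth_count + self.unmeth_count

    @property
    def level(self) -> float:
        cov = self.coverage
        if cov == 0:
            raise ValueError("methylation level undefined at zero coverage")
        return self.meth_count / cov


@dataclass
class AlignedSmallRead:
    """One distinct (collapsed) small-RNA sequence and all its placements.

    ``count`` is the multiplicity of the distinct sequence in the library
    (the "non-redundant read count"); ``n_hits`` is its number of genomic
    hits and must equal ``len(placements)``.
    """

    read_id: str
    length: int
    n_hits: int
    perfect_match: bool = True
    count: int = 1
    placements: list[tuple[GenomicInterval, str]] = field(default_factory=list)

    def validate(self) -> None:
        if self.length <= 0:
            raise ValueError(f"read {self.read_id}: non-positive length")
        if self.n_hits != len(self.placements):
            raise ValueError(
                f"read {self.read_id}: NH={self.n_hits} but "
                f"{len(self.placements)} alignment records present"
            )
        if self.n_hits <= 0:
            raise ValueError(f"read {self.read_id}: n_hits must be positive")


@dataclass(frozen=True)
class Dmr:
    """A merged differentially methylated region.

    ``direction`` is ``hypo`` when the test condition (A) is less methylated
    than the reference (B).  ``n_supporting_cytosines`` counts differential
    cytosines of the region's context/direction over the merged span.
    """

    chrom: str
    start: int
    end: int
    context: str
    direction: str
    n_supporting_cytosines: int
    mean_level_a: float
    mean_level_b: float
    source_bins: tuple[tuple[int, int], ...]
    feature_class: str | None = None
    family: str | None = None
    superfamily: str | None = None

    def __post_init__(self) -> None:
        if self.direction not in ("hypo", "hyper"):
            raise ValueError(f"invalid direction {self.direction!r}")
        if self.context not in CONTEXTS:
            raise ValueError(f"unknown context {self.context!r}")

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)


@dataclass(frozen=True)
class SeedCountRecord:
    """Normal and collapsed seed counts from six siliques of one plant."""

    genotype: str
    plant_id: str
    n_normal: int
    n_collapsed: int

    def __post_init__(self) -> None:
        if self.n_normal < 0 or self.n_collapsed < 0:
            raise ValueError("negative seed counts")

    @property
    def total(self) -> int:
        return self.n_normal + self.n_collapsed
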