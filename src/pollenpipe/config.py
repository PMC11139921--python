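"""Pipeline configuration objects, YAML round-trip, and seed plumbing."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .core import CONTEXTS


@dataclass
class FilterConfig:
    """Small-RNA read filter: length window and perfect-match requirement.

    Defaults implement the standard pollen siRNA filter: keep 18-30 nt
    perfectly matched reads.  ``sirna_classes`` partitions kept lengths into
    the biologically meaningful size classes (21/22-nt post-transcriptional
    siRNAs, 24-nt heterochromatic siRNAs, everything else).
    """

    min_len: int = 18
    max_len: int = 30
    require_perfect: bool = True
    sirna_classes: dict[str, tuple[int, ...]] = field(
        default_factory=lambda: {"21/22-nt": (21, 22), "24-nt": (24,)}
    )

    def validate(self) -> None:
        if self.min_len > self.max_len:
            raise ValueError("min_len must be <= max_len")
        if self.min_len <= 0:
            raise ValueError("min_len must be positive")
        seen: set[int] = set()
        for lengths in self.sirna_classes.values():
            for ln in lengths:
                if ln in seen:
                    raise ValueError(f"length {ln} assigned to two siRNA classes")
                seen.add(ln)

    def size_class(self, length: int) -> str:
        for name, lengths in self.sirna_classes.items():
            if length in lengths:
                return name
        return "other"


@dataclass
class DmrConfig:
    """Binned DMR-caller parameters.

    A 100-bp bin is a candidate DMR when it contains at least
    ``min_diff_cytosines[context]`` cytosines whose methylation difference
    (at per-sample coverage >= ``min_coverage``) exceeds
    ``min_abs_diff[context]`` in the same direction; candidate bins within
    ``merge_distance`` bp of each other are merged.
    """

    bin_size: int = 100
    min_diff_cytosines: dict[str, int] = field(
        default_factory=lambda: {"CG": 4, "CHG": 5, "CHH": 6}
    )
    min_abs_diff: dict[str, float] = field(
        default_factory=lambda: {"CG": 0.4, "CHG": 0.2, "CHH": 0.1}
    )
    merge_distance: int = 200
    min_coverage: int = 4
    # when True, additionally require the bin-average level difference of the
    # supporting cytosines to pass min_abs_diff (stricter reading)
    require_bin_mean_diff: bool = False
    # per-cytosine differential criterion: "level-threshold" (default) or
    # "fisher" (two-sided Fisher exact p < fisher_alpha on the count table,
    # in addition to the level-difference threshold)
    diff_method: str = "level-threshold"
    fisher_alpha: float = 0.05

    def validate(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if self.merge_distance < 0:
            raise ValueError("merge_distance must be non-negative")
        if self.min_coverage < 0:
            raise ValueError("min_coverage must be non-negative")
        for ctx in CONTEXTS:
            if self.min_diff_cytosines.get(ctx, 0) <= 0:
                raise ValueError(f"min_diff_cytosines[{ctx}] must be positive")
            if not (0 < self.min_abs_diff.get(ctx, 0) <= 1):
                raise ValueError(f"min_abs_diff[{ctx}] must be in (0, 1]")
        if self.diff_method not in ("level-threshold", "fisher"):
            raise ValueError(f"unknown diff_method {self.diff_method!r}")
        if not (0 < self.fisher_alpha < 1):
            raise ValueError("fisher_alpha must be in (0, 1)")


@dataclass
class DeConfig:
    """Differential-abundance settings: BH FDR level, dispersion handling,
    and the pseudo-count of the log2 variance-stabilizing fallback."""

    alpha_fdr: float = 0.05
    dispersion_mode: str = "common"  # or "per-feature-moments-with-shrinkage"
    pseudo_count: float = 1.0
    dispersion_floor: float = 1e-8

    def validate(self) -> None:
        if not (0 < self.alpha_fdr < 1):
            raise ValueError("alpha_fdr must be in (0, 1)")
        if self.dispersion_mode not in (
            "common",
            "per-feature-moments-with-shrinkage",
        ):
            raise ValueError(f"unknown dispersion_mode {self.dispersion_mode!r}")
        if self.pseudo_count < 0:
            raise ValueError("pseudo_count must be non-negative")


@dataclass
class PipelineConfig:
    rng_seed: int = 0
    filter: FilterConfig = field(default_factory=FilterConfig)
    dmr: DmrConfig = field(default_factory=DmrConfig)
    de: DeConfig = field(default_factory=DeConfig)
    output_dir: str = "pollenpipe_out"

    def validate(self) -> None:
        self.filter.validate()
        self.dmr.validate()
        self.de.validate()

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kwargs = dict(d)
        if "filter" in kwargs:
            kwargs["filter"] = _filter_from_dict(kwargs["filter"])
        if "dmr" in kwargs:
            kwargs["dmr"] = DmrConfig(**kwargs["dmr"])
        if "de" in kwargs:
            kwargs["de"] = DeConfig(**kwargs["de"])
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    def save_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        """Short stable hash of the full configuration, for output headers."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _filter_from_dict(d: dict) -> FilterConfig:
    kwargs = dict(d)
    if "sirna_classes" in kwargs:
        kwargs["sirna_classes"] = {
            k: tuple(v) for k, v in kwargs["sirna_classes"].items()
        }
    return FilterConfig(**kwargs)


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """RNG stream keyed by (master seed, stage name).

    Each pipeline stage gets its own reproducible stream so that results do
    not depend on the order in which stages consume randomness.
    """
    key = zlib.crc32(stage.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))
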