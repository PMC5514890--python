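"""Domain types for per-site read evidence.

Coordinates are 1-based inclusive throughout the package; interval files
are ingested as standard 0-based half-open BED and converted on read.
Only biallelic SNVs are modelled: a site carries a single reference base
and (once chosen) a single alternative base.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Iterable, Sequence

BASES = ("A", "C", "G", "T")
#: canonical base order used for every tie-break in the package
BASE_ORDER = {b: i for i, b in enumerate(BASES)}

FORWARD = "+"
REVERSE = "-"


class ContractViolation(ValueError):
    """A documented precondition or invariant was violated by the caller."""


class UnknownChromosome(ContractViolation):
    """A site references a chromosome absent from the evidence source."""


@dataclass(frozen=True, order=True)
class GenomicSite:
    """One genomic position, optionally with a chosen alternative base.

    ``alt`` may be unset (None) during traversal, before the most frequent
    non-reference base has been chosen.
    """

    chrom: str
    pos: int
    ref: str
    alt: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ContractViolation(f"pos must be >= 1, got {self.pos}")
        if self.ref not in BASES:
            raise ContractViolation(f"ref must be one of {BASES}, got {self.ref!r}")
        if self.alt is not None:
            if self.alt not in BASES:
                raise ContractViolation(f"alt must be one of {BASES}, got {self.alt!r}")
            if self.alt == self.ref:
                raise ContractViolation(f"alt must differ from ref ({self.ref!r})")

    @property
    def key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)

    def with_alt(self, alt: str) -> "GenomicSite":
        return replace(self, alt=alt)

    def label(self) -> str:
        alt = self.alt if self.alt is not None else "?"
        return f"{self.chrom}:{self.pos} {self.ref}>{alt}"


@dataclass(frozen=True, slots=True)
class ReadEvidence:
    """One read's observation of one genomic site.

    ``read_position`` is the 1-based offset of the site within the read
    counted from the read's 5' end in *sequencing order*, regardless of the
    strand the read aligned to: artifact chemistry tracks the physical read
    ends, not reference orientation.  ``fragment_id`` is shared by both
    mates of a pair so that overlapping mates can be collapsed to one
    molecule.
    """

    site: GenomicSite
    base: str
    base_quality: int
    mapping_quality: int
    strand: str
    read_position: int
    read_length: int
    fragment_id: str
    read_id: str = ""

    def __post_init__(self) -> None:
        if self.base not in BASES and self.base != "N":
            raise ContractViolation(f"base must be A/C/G/T/N, got {self.base!r}")
        if not (1 <= self.read_position <= self.read_length):
            raise ContractViolation(
                f"read_position {self.read_position} outside 1..{self.read_length}"
            )
        if self.base_quality < 0 or self.mapping_quality < 0:
            raise ContractViolation("qualities must be non-negative")
        if self.strand not in (FORWARD, REVERSE):
            raise ContractViolation(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def is_forward(self) -> bool:
        return self.strand == FORWARD


@dataclass
class SiteObservation:
    """The filtered read stack and allele counts for one sample at one site."""

    site: GenomicSite
    sample_id: str
    reads: list[ReadEvidence]
    alt_count: int
    total_count: int

    @classmethod
    def from_reads(
        cls, site: GenomicSite, sample_id: str, reads: Sequence[ReadEvidence]
    ) -> "SiteObservation":
        reads = list(reads)
        alt = sum(1 for r in reads if site.alt is not None and r.base == site.alt)
        return cls(site=site, sample_id=sample_id, reads=reads,
                   alt_count=alt, total_count=len(reads))

    @property
    def allelic_fraction(self) -> float | None:
        """alt_count / total_count; None (undefined) at zero coverage."""
        if self.total_count == 0:
            return None
        return self.alt_count / self.total_count


@dataclass
class FilterConfig:
    """Thresholds of the read/site filters and of the statistical stage.

    Defaults are the whole-exome defaults: Phred 30 base/mapping quality
    cut-offs, a 5-bp read-end exclusion window, at most 1 altered read
    tolerated in the matched normal, a 10% control allelic-fraction trigger
    for germline clustering, germline recurrence at 2 carriers, family-wise
    alpha 0.05, and an 80%-power coverage requirement to detect a 30% AF
    mutation in the tumor and a 50% AF mutation in the matched normal.
    """

    min_base_quality: int = 30
    min_mapping_quality: int = 30
    end_window: int = 5
    max_normal_alt: int = 1
    germline_af_threshold: float = 0.10
    min_germline_recurrence: int = 2
    alpha: float = 0.05
    power_threshold: float = 0.80
    tumor_detect_af: float = 0.30
    normal_detect_af: float = 0.50
    # soft floor: warn (never fail) when fewer controls cover a site
    min_covered_controls_warn: int = 10

    def __post_init__(self) -> None:
        if self.min_base_quality < 0 or self.min_mapping_quality < 0:
            raise ContractViolation("quality thresholds must be non-negative")
        if self.end_window < 0:
            raise ContractViolation("end_window must be non-negative")
        if self.max_normal_alt < 0:
            raise ContractViolation("max_normal_alt must be non-negative")
        for name in ("germline_af_threshold", "alpha", "power_threshold",
                     "tumor_detect_af", "normal_detect_af"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ContractViolation(f"{name} must be in [0,1], got {v}")
        if self.min_germline_recurrence < 1:
            raise ContractViolation("min_germline_recurrence must be >= 1")

    def replace(self, **overrides) -> "FilterConfig":
        known = {f.name for f in fields(self)}
        bad = set(overrides) - known
        if bad:
            raise ContractViolation(f"unknown FilterConfig fields: {sorted(bad)}")
        merged = {f.name: getattr(self, f.name) for f in fields(self)}
        merged.update(overrides)
        return FilterConfig(**merged)


def allelic_fraction(alt: int, total: int) -> float | None:
    """Fraction of reads supporting the alternative base.

    Returns None (undefined, to be flagged by the caller) when ``total`` is
    zero.  Raises on the impossible ``alt > total``.
    """
    if alt < 0 or total < 0:
        raise ContractViolation("counts must be non-negative")
    if alt > total:
        raise ContractViolation(f"alt count {alt} exceeds total {total}")
    if total == 0:
        return None
    return alt / total


def sort_sites(sites: Iterable[GenomicSite]) -> list[GenomicSite]:
    return sorted(sites, key=lambda s: (s.chrom, s.pos))
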