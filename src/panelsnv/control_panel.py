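"""Step 2: tally filtered read evidence across the control panel.

For every candidate site from Step 1, each control sample's reads are
counted under exactly the same read filters as the tumor (base quality,
mapping quality, overlapping-mate collapse); the site filters are *not*
applied to controls.  Per-control allelic fractions feed the Step 3
germline/error separation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .model import (
    ContractViolation,
    FilterConfig,
    GenomicSite,
    SiteObservation,
    UnknownChromosome,
)
from .pileup import extract_site_evidence, open_source
from .raw_caller import RawCandidate, deduplicate_overlapping_mates, filter_reads

log = logging.getLogger(__name__)


@dataclass
class ControlObservation:
    """Post-filter allele counts for one control sample at one site."""

    sample_id: str
    site: GenomicSite
    alt_count: int
    total_count: int

    @property
    def allelic_fraction(self) -> float | None:
        if self.total_count == 0:
            return None
        return self.alt_count / self.total_count

    @property
    def covered(self) -> bool:
        return self.total_count > 0


@dataclass
class ControlTable:
    """All panel observations at one candidate site, in panel order."""

    site: GenomicSite
    observations: list[ControlObservation]

    @property
    def covered_count(self) -> int:
        return sum(1 for o in self.observations if o.covered)

    @property
    def covered(self) -> list[ControlObservation]:
        return [o for o in self.observations if o.covered]


def tally_control_site(
    control, site: GenomicSite, cfg: FilterConfig
) -> ControlObservation:
    """Count one control's reads at a site under the Step 1 read filters."""
    if site.alt is None:
        raise ContractViolation("site must have alt set before control tallying")
    try:
        reads = extract_site_evidence(control, site)
    except UnknownChromosome:
        log.warning(
            "site %s outside reference of control %s; counting zero coverage",
            site.label(), getattr(control, "sample_id", "?"),
        )
        reads = []
    kept = deduplicate_overlapping_mates(filter_reads(reads, cfg))
    obs = SiteObservation.from_reads(site, getattr(control, "sample_id", "?"), kept)
    return ControlObservation(
        sample_id=obs.sample_id, site=site,
        alt_count=obs.alt_count, total_count=obs.total_count,
    )


def build_control_table(
    panel: Sequence,
    candidates: Sequence[RawCandidate | GenomicSite],
    cfg: FilterConfig | None = None,
    n_workers: int = 1,
) -> list[ControlTable]:
    """One ControlTable per candidate, panel order preserved.

    Work is partitioned by candidate site; the result is identical for any
    partitioning (no shared mutable state), so parallel workers are safe.
    """
    cfg = cfg or FilterConfig()
    if not panel:
        raise ContractViolation(
            "control panel is empty: site-specific error rates require at "
            "least one control sample; with only a matched normal the "
            "background error model cannot be estimated"
        )
    sites = [c.site if isinstance(c, RawCandidate) else c for c in candidates]

    def tally_one(site: GenomicSite) -> ControlTable:
        table = ControlTable(
            site=site,
            observations=[tally_control_site(ctrl, site, cfg) for ctrl in panel],
        )
        if table.covered_count < cfg.min_covered_controls_warn:
            log.warning(
                "site %s covered by only %d/%d controls; the error rate "
                "estimate will be weakly supported",
                site.label(), table.covered_count, len(panel),
            )
        return table

    if n_workers > 1 and len(sites) > 1:
        from concurrent.futures import ThreadPoolExecutor

        with ThreadPoolExecutor(max_workers=n_workers) as pool:
            return list(pool.map(tally_one, sites))
    return [tally_one(s) for s in sites]


def read_panel_manifest(path: str | Path) -> list[str]:
    """Read a panel manifest: one control source path per line.

    Blank lines and ``#`` comments are allowed; anything else must be an
    existing path (reported with its line number otherwise).
    """
    paths: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            entry = line.strip()
            if not entry or entry.startswith("#"):
                continue
            if "\t" in entry or " " in entry:
                raise ContractViolation(
                    f"{path}: malformed manifest line {lineno}: {line.rstrip()!r} "
                    "(expected exactly one path per line)"
                )
            paths.append(entry)
    if not paths:
        raise ContractViolation(f"{path}: manifest lists no control samples")
    return paths


def open_panel(manifest: str | Path, reference: str | Path | None = None) -> list:
    sources = []
    for p in read_panel_manifest(manifest):
        if not Path(p).exists():
            raise ContractViolation(f"control sample file not found: {p}")
        sources.append(open_source(p, reference=reference))
    return sources
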