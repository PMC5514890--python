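"""Step 1: raw somatic candidate calling from tumor and matched normal.

Filters are applied in a fixed order and recorded in an auditable trace:

1. base quality   (read filter, drop Phred < threshold)
2. mapping quality (read filter, drop Phred < threshold)
3. overlapping read pairs (read filter: both mates of a fragment covering
   the site represent one sequenced molecule and are counted once)
4. tumor support  (site filter: >= 2 post-filter alternative reads from
   >= 2 distinct fragments — a variant supported only by the two mates of
   a single pair is not trusted)
5. position in read (site filter: fail when, on some strand with
   alternative reads, *all* of them sit within the first or last
   ``end_window`` bases of their read — the classic end-of-read artifact
   signature)
6. variant in matched normal (site filter: >= 2 post-filter altered reads
   in the matched normal disqualifies the site as somatic)

A candidate is emitted only when every filter passed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .model import (
    ContractViolation,
    FilterConfig,
    GenomicSite,
    ReadEvidence,
    SiteObservation,
)
from .pileup import Regions, discover_candidate_sites, extract_site_evidence

FILTER_NAMES = (
    "base_quality",
    "mapping_quality",
    "overlapping_read_pairs",
    "tumor_support",
    "position_in_read",
    "variant_in_matched_normal",
)


@dataclass
class RawCandidate:
    """One candidate somatic site with its post-filter observations."""

    site: GenomicSite
    tumor: SiteObservation
    normal: SiteObservation
    filter_trace: list[tuple[str, bool, str]] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return all(ok for _, ok, _ in self.filter_trace)


def filter_reads(reads: Sequence[ReadEvidence], cfg: FilterConfig) -> list[ReadEvidence]:
    """Drop reads below the base-quality or mapping-quality thresholds.

    The thresholds are removals at "< threshold": a read scoring exactly at
    the threshold is kept.  Input order is preserved.
    """
    return [
        r for r in reads
        if r.base_quality >= cfg.min_base_quality
        and r.mapping_quality >= cfg.min_mapping_quality
    ]


def deduplicate_overlapping_mates(reads: Sequence[ReadEvidence]) -> list[ReadEvidence]:
    """Collapse overlapping mate pairs to one observation per fragment.

    When both mates of a fragment cover the site, they sequenced the same
    molecule; the retained mate is the one with higher base quality
    (tie: the forward-strand mate; further tie: first in input order).
    Output follows input order of the retained reads.  Idempotent.
    """
    best: dict[str, tuple[int, ReadEvidence]] = {}
    for idx, r in enumerate(reads):
        prev = best.get(r.fragment_id)
        if prev is None:
            best[r.fragment_id] = (idx, r)
            continue
        _, p = prev
        if r.base_quality > p.base_quality or (
            r.base_quality == p.base_quality and r.is_forward and not p.is_forward
        ):
            best[r.fragment_id] = (prev[0], r)  # keep original slot for order
    return [r for _, r in sorted(best.values(), key=lambda t: t[0])]


def _end_positioned(r: ReadEvidence, end_window: int) -> bool:
    return (
        r.read_position <= end_window
        or r.read_position > r.read_length - end_window
    )


def position_in_read_filter(
    alt_reads: Sequence[ReadEvidence], cfg: FilterConfig
) -> bool:
    """True (pass) unless some strand's alternative reads are all end-positioned.

    Evaluated per strand over the post-dedup alternative reads: if, on
    either strand carrying at least one alternative read, every such read
    lies within the first or last ``end_window`` positions of its read,
    the site fails.
    """
    if not alt_reads:
        raise ContractViolation("position_in_read_filter requires >= 1 alt read")
    for strand in ("+", "-"):
        on_strand = [r for r in alt_reads if r.strand == strand]
        if on_strand and all(_end_positioned(r, cfg.end_window) for r in on_strand):
            return False
    return True


def matched_normal_filter(normal: SiteObservation, cfg: FilterConfig) -> bool:
    """True (pass) unless the matched normal shows too many altered reads.

    Counts are post-quality-filter, post-dedup; the default tolerates a
    single altered read (fails at >= 2).
    """
    return normal.alt_count <= cfg.max_normal_alt


def _observe(site: GenomicSite, sample_id: str,
             reads: Sequence[ReadEvidence], cfg: FilterConfig
             ) -> tuple[SiteObservation, int, int, int]:
    """Apply read filters; return observation and per-stage removal counts."""
    bq_kept = [r for r in reads if r.base_quality >= cfg.min_base_quality]
    n_bq = len(reads) - len(bq_kept)
    mq_kept = [r for r in bq_kept if r.mapping_quality >= cfg.min_mapping_quality]
    n_mq = len(bq_kept) - len(mq_kept)
    deduped = deduplicate_overlapping_mates(mq_kept)
    n_dup = len(mq_kept) - len(deduped)
    return SiteObservation.from_reads(site, sample_id, deduped), n_bq, n_mq, n_dup


def evaluate_candidate(
    site: GenomicSite,
    tumor_reads: Sequence[ReadEvidence],
    normal_reads: Sequence[ReadEvidence],
    cfg: FilterConfig,
    tumor_id: str = "tumor",
    normal_id: str = "normal",
) -> RawCandidate:
    """Apply the full filter cascade at one site and record the trace."""
    t_obs, t_bq, t_mq, t_dup = _observe(site, tumor_id, tumor_reads, cfg)
    n_obs, n_bq, n_mq, n_dup = _observe(site, normal_id, normal_reads, cfg)

    trace: list[tuple[str, bool, str]] = [
        ("base_quality", True, f"removed tumor={t_bq} normal={n_bq}"),
        ("mapping_quality", True, f"removed tumor={t_mq} normal={n_mq}"),
        ("overlapping_read_pairs", True,
         f"collapsed tumor={t_dup} normal={n_dup}"),
    ]

    alt_reads = [r for r in t_obs.reads if r.base == site.alt]
    alt_fragments = {r.fragment_id for r in alt_reads}
    support_ok = t_obs.alt_count >= 2 and len(alt_fragments) >= 2
    trace.append((
        "tumor_support", support_ok,
        f"alt_reads={t_obs.alt_count} alt_fragments={len(alt_fragments)}",
    ))

    if alt_reads:
        pos_ok = position_in_read_filter(alt_reads, cfg)
        detail = f"end_window={cfg.end_window}"
    else:
        pos_ok = False
        detail = "no alt reads after filtering"
    trace.append(("position_in_read", pos_ok, detail))

    normal_ok = matched_normal_filter(n_obs, cfg)
    trace.append((
        "variant_in_matched_normal", normal_ok,
        f"normal_alt={n_obs.alt_count} (max {cfg.max_normal_alt})",
    ))

    return RawCandidate(site=site, tumor=t_obs, normal=n_obs, filter_trace=trace)


def call_raw_variants(
    tumor,
    normal,
    regions: Regions | None = None,
    cfg: FilterConfig | None = None,
    keep_rejected: bool = False,
) -> list[RawCandidate]:
    """Discover candidate sites in the tumor and run the filter cascade.

    Returns all-pass candidates in (chrom, pos) order; with
    ``keep_rejected`` the failing candidates are returned too (their
    ``passed`` attribute is False) so rejected sites remain auditable.
    """
    cfg = cfg or FilterConfig()
    out: list[RawCandidate] = []
    for site in discover_candidate_sites(tumor, regions):
        t_reads = extract_site_evidence(tumor, site)
        n_reads = extract_site_evidence(normal, site)
        cand = evaluate_candidate(
            site, t_reads, n_reads, cfg,
            tumor_id=getattr(tumor, "sample_id", "tumor"),
            normal_id=getattr(normal, "sample_id", "normal"),
        )
        if cand.passed or keep_rejected:
            out.append(cand)
    return out
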