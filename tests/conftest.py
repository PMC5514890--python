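"""Shared fixture builders: hand-written read stacks and tiny pileup tables."""

from __future__ import annotations

import itertools

import pytest

from panelsnv import GenomicSite, PileupTable, ReadEvidence
from panelsnv.pileup import NO_FLAGS, PILEUP_COLUMNS

_counter = itertools.count()


def make_read(
    site: GenomicSite,
    base: str | None = None,
    baseq: int = 35,
    mapq: int = 60,
    strand: str = "+",
    read_pos: int = 50,
    read_len: int = 100,
    fragment: str | None = None,
) -> ReadEvidence:
    """A single ReadEvidence with sensible defaults (mid-read, high quality)."""
    n = next(_counter)
    frag = fragment if fragment is not None else f"frag{n}"
    return ReadEvidence(
        site=site,
        base=base if base is not None else site.ref,
        base_quality=baseq,
        mapping_quality=mapq,
        strand=strand,
        read_position=read_pos,
        read_length=read_len,
        fragment_id=frag,
        read_id=f"{frag}/r{n}",
    )


def pileup_row(
    chrom="chr1", pos=100, ref="C", sample="s1", base=None, baseq=35, mapq=60,
    strand="+", read_pos=50, read_len=100, flags=NO_FLAGS, fragment=None,
) -> dict:
    n = next(_counter)
    frag = fragment if fragment is not None else f"frag{n}"
    return {
        "chrom": chrom, "pos": pos, "ref": ref, "sample": sample,
        "read_id": f"{frag}/r{n}", "fragment_id": frag,
        "base": base if base is not None else ref,
        "baseq": baseq, "mapq": mapq, "strand": strand,
        "read_pos": read_pos, "read_len": read_len, "flags": flags,
    }


def table_from_rows(rows, sample_id=None) -> PileupTable:
    return PileupTable.from_rows(rows, sample_id=sample_id)


@pytest.fixture
def site_c_a() -> GenomicSite:
    return GenomicSite("chr1", 100, "C", "A")


def stack_table(sample: str, site: GenomicSite, n_ref: int, n_alt: int,
                **row_kw) -> PileupTable:
    """A clean high-quality stack: n_ref reference + n_alt alternative reads."""
    rows = []
    for _ in range(n_ref):
        rows.append(pileup_row(chrom=site.chrom, pos=site.pos, ref=site.ref,
                               sample=sample, base=site.ref, **row_kw))
    for _ in range(n_alt):
        rows.append(pileup_row(chrom=site.chrom, pos=site.pos, ref=site.ref,
                               sample=sample, base=site.alt, **row_kw))
    return table_from_rows(rows, sample_id=sample)
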