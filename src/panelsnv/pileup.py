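"""Read-evidence sources: plain-text pileup tables and alignment files.

Two interchangeable backends provide per-site read stacks:

* :class:`PileupTable` — a plain-text TSV with one row per read-site
  observation (the fixture format; bit-exact round-trip, used by the
  synthetic generator and the test suite).
* :class:`BamSource` — coordinate-sorted indexed BAM/CRAM via pysam, with
  reference bases from an indexed FASTA.

Both expose ``reads_at(site)`` and ``iter_pileups(regions)``; everything
downstream is backend-agnostic.  Reads flagged as duplicates or QC-fail by
the upstream pipeline, and reads whose base call at the site is N (which
support neither allele), are dropped at extraction.  No quality filtering
happens here.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd

from .model import (
    BASE_ORDER,
    BASES,
    FORWARD,
    REVERSE,
    ContractViolation,
    GenomicSite,
    ReadEvidence,
    UnknownChromosome,
    sort_sites,
)

PILEUP_COLUMNS = [
    "chrom", "pos", "ref", "sample", "read_id", "fragment_id",
    "base", "baseq", "mapq", "strand", "read_pos", "read_len", "flags",
]

#: flag tokens understood in the fixture format
FLAG_DUP = "dup"
FLAG_QCFAIL = "qcfail"
NO_FLAGS = "."


class Regions:
    """Genomic intervals, stored half-open 0-based as in BED."""

    def __init__(self, intervals: Iterable[tuple[str, int, int]] = ()):
        self._by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in intervals:
            if end < start or start < 0:
                raise ContractViolation(f"bad interval {chrom}:{start}-{end}")
            self._by_chrom.setdefault(chrom, []).append((start, end))
        for ivs in self._by_chrom.values():
            ivs.sort()

    @classmethod
    def from_bed(cls, path: str | Path) -> "Regions":
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ContractViolation(f"malformed BED line: {line!r}")
                rows.append((parts[0], int(parts[1]), int(parts[2])))
        return cls(rows)

    def __bool__(self) -> bool:
        return bool(self._by_chrom)

    def contains(self, chrom: str, pos: int) -> bool:
        """pos is 1-based; interval [start, end) covers it iff start < pos <= end."""
        for start, end in self._by_chrom.get(chrom, ()):
            if start < pos <= end:
                return True
        return False

    def chroms(self) -> list[str]:
        return sorted(self._by_chrom)

    def intervals(self, chrom: str) -> list[tuple[int, int]]:
        return list(self._by_chrom.get(chrom, ()))


class PileupTable:
    """Plain-text per-read pileup for one sample (the fixture format).

    TSV columns: ``chrom pos ref sample read_id fragment_id base baseq mapq
    strand read_pos read_len flags`` with 1-based positions; ``flags`` is a
    comma-separated subset of {dup, qcfail}, ``.`` when empty.
    """

    def __init__(self, df: pd.DataFrame, sample_id: str | None = None):
        missing = [c for c in PILEUP_COLUMNS if c not in df.columns]
        if missing:
            raise ContractViolation(f"pileup table missing columns: {missing}")
        self.df = df.reset_index(drop=True)
        samples = self.df["sample"].unique().tolist()
        if sample_id is None:
            if len(samples) != 1:
                raise ContractViolation(
                    "sample_id required for multi-sample pileup table"
                )
            sample_id = samples[0]
        self.sample_id = str(sample_id)
        # column caches: row access through pandas is too slow for deep stacks
        self._col = {
            c: self.df[c].to_numpy() for c in PILEUP_COLUMNS
        }
        self._chroms = {str(c) for c in self._col["chrom"]}
        # row indices per (chrom, pos), preserving file order
        self._index: dict[tuple[str, int], list[int]] = {}
        samples = self._col["sample"]
        for i, (chrom, pos) in enumerate(zip(self._col["chrom"], self._col["pos"])):
            if str(samples[i]) != self.sample_id:
                continue
            self._index.setdefault((str(chrom), int(pos)), []).append(i)

    # -- construction / io -------------------------------------------------

    @classmethod
    def from_tsv(cls, path: str | Path, sample_id: str | None = None) -> "PileupTable":
        df = pd.read_csv(
            path, sep="\t",
            dtype={"chrom": str, "sample": str, "read_id": str,
                   "fragment_id": str, "base": str, "strand": str, "flags": str},
        )
        return cls(df, sample_id=sample_id)

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_rows(cls, rows: Sequence[dict], sample_id: str | None = None) -> "PileupTable":
        df = pd.DataFrame(list(rows), columns=PILEUP_COLUMNS)
        return cls(df, sample_id=sample_id)

    # -- evidence access ---------------------------------------------------

    def reads_at(self, site: GenomicSite) -> list[ReadEvidence]:
        if site.chrom not in self._chroms:
            raise UnknownChromosome(
                f"chromosome {site.chrom!r} not present in pileup for "
                f"sample {self.sample_id!r}"
            )
        c = self._col
        out: list[ReadEvidence] = []
        for i in self._index.get((site.chrom, site.pos), ()):
            flags = str(c["flags"][i])
            if FLAG_DUP in flags or FLAG_QCFAIL in flags:
                continue
            base = str(c["base"][i])
            if base == "N":
                continue
            out.append(ReadEvidence(
                site=site,
                base=base,
                base_quality=int(c["baseq"][i]),
                mapping_quality=int(c["mapq"][i]),
                strand=str(c["strand"][i]),
                read_position=int(c["read_pos"][i]),
                read_length=int(c["read_len"][i]),
                fragment_id=str(c["fragment_id"][i]),
                read_id=str(c["read_id"][i]),
            ))
        return out

    def iter_pileups(
        self, regions: Regions | None = None
    ) -> Iterator[tuple[GenomicSite, list[ReadEvidence]]]:
        """Yield (altless site, extracted reads) in (chrom, pos) order."""
        keys = sorted(self._index)
        for chrom, pos in keys:
            if regions and not regions.contains(chrom, pos):
                continue
            i0 = self._index[(chrom, pos)][0]
            ref = str(self._col["ref"][i0])
            if ref not in BASES:
                continue
            site = GenomicSite(chrom, pos, ref)
            reads = self.reads_at(site)
            if reads:
                yield site, reads


class BamSource:
    """Indexed BAM/CRAM backend (pysam), reference bases from indexed FASTA."""

    def __init__(self, path: str | Path, reference: str | Path | None = None,
                 sample_id: str | None = None):
        import pysam

        self.path = str(path)
        self._af = pysam.AlignmentFile(self.path)
        self.sample_id = sample_id or Path(self.path).stem
        self._fasta = None
        if reference is not None:
            from pyfaidx import Fasta

            self._fasta = Fasta(str(reference))
        self._chroms = set(self._af.references)

    def _reads_in_column(self, col, site: GenomicSite) -> list[ReadEvidence]:
        import pysam

        out: list[ReadEvidence] = []
        for pr in col.pileups:
            if pr.is_del or pr.is_refskip or pr.query_position is None:
                continue
            aln = pr.alignment
            if aln.is_duplicate or aln.is_qcfail or aln.is_secondary or aln.is_supplementary:
                continue
            base = aln.query_sequence[pr.query_position].upper()
            if base == "N" or base not in BASES:
                continue
            qpos = pr.query_position
            rlen = aln.query_length
            read_pos = rlen - qpos if aln.is_reverse else qpos + 1
            out.append(ReadEvidence(
                site=site,
                base=base,
                base_quality=int(aln.query_qualities[qpos]),
                mapping_quality=int(aln.mapping_quality),
                strand=REVERSE if aln.is_reverse else FORWARD,
                read_position=read_pos,
                read_length=rlen,
                fragment_id=aln.query_name,
                read_id=f"{aln.query_name}/{2 if aln.is_read2 else 1}",
            ))
        return out

    def _columns(self, chrom: str, start0: int, end0: int):
        return self._af.pileup(
            chrom, start0, end0, truncate=True, max_depth=100000,
            min_base_quality=0, ignore_overlaps=False, ignore_orphans=False,
        )

    def reads_at(self, site: GenomicSite) -> list[ReadEvidence]:
        if site.chrom not in self._chroms:
            raise UnknownChromosome(
                f"chromosome {site.chrom!r} not present in {self.path}"
            )
        for col in self._columns(site.chrom, site.pos - 1, site.pos):
            if col.reference_pos == site.pos - 1:
                return self._reads_in_column(col, site)
        return []

    def iter_pileups(
        self, regions: Regions | None = None
    ) -> Iterator[tuple[GenomicSite, list[ReadEvidence]]]:
        if self._fasta is None:
            raise ContractViolation(
                "a reference FASTA is required to traverse an alignment file"
            )
        if regions:
            spans = [(c, s, e) for c in regions.chroms()
                     for s, e in regions.intervals(c)]
        else:
            spans = [(c, 0, self._af.get_reference_length(c))
                     for c in self._af.references]
        for chrom, start0, end0 in spans:
            if chrom not in self._chroms:
                raise UnknownChromosome(
                    f"chromosome {chrom!r} not present in {self.path}"
                )
            for col in self._columns(chrom, start0, end0):
                pos = col.reference_pos + 1
                ref = str(self._fasta[chrom][col.reference_pos]).upper()
                if ref not in BASES:
                    continue
                site = GenomicSite(chrom, pos, ref)
                reads = self._reads_in_column(col, site)
                if reads:
                    yield site, reads


def open_source(path: str | Path, reference: str | Path | None = None,
                sample_id: str | None = None):
    """Open a pileup TSV or an alignment file, dispatching on extension."""
    p = str(path)
    if p.endswith((".bam", ".cram", ".sam")):
        return BamSource(p, reference=reference, sample_id=sample_id)
    return PileupTable.from_tsv(p, sample_id=sample_id)


# -- traversal primitives ----------------------------------------------------

def extract_site_evidence(source, site: GenomicSite) -> list[ReadEvidence]:
    """All non-duplicate, non-QC-fail reads with a base call at ``site``.

    Deterministic and order-stable for a fixed source; no quality
    filtering is applied here.
    """
    return source.reads_at(site)


def choose_alt(reads: Sequence[ReadEvidence], ref: str) -> str | None:
    """Most frequent non-reference base; ties broken by fixed A<C<G<T order."""
    counts = {b: 0 for b in BASES}
    for r in reads:
        if r.base != ref and r.base in counts:
            counts[r.base] += 1
    best = None
    for b in BASES:  # fixed order ensures the tie-break
        if counts[b] > 0 and (best is None or counts[b] > counts[best]):
            best = b
    return best


def discover_candidate_sites(
    tumor, regions: Regions | None = None
) -> Iterator[GenomicSite]:
    """Sites where at least one tumor read carries a non-reference base.

    Yields sites in (chrom, pos) order, duplicate-free, with ``alt`` set to
    the most frequent non-reference base (A<C<G<T tie-break).
    """
    for site, reads in tumor.iter_pileups(regions):
        alt = choose_alt(reads, site.ref)
        if alt is not None:
            yield site.with_alt(alt)
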