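"""Format plumbing and the three-step pipeline glue.

Intermediate products are plain TSV so each step can be run, inspected and
resumed independently: Step 1 candidates, Step 2 per-control tallies, and
the final per-site calls (optionally also a minimal VCF).  All coordinates
are 1-based in these files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

from .control_panel import ControlObservation, ControlTable, build_control_table
from .model import ContractViolation, FilterConfig, GenomicSite, SiteObservation
from .pileup import Regions
from .raw_caller import RawCandidate, call_raw_variants
from .stats import VariantCall, judge_variants

CANDIDATE_HEADER = [
    "chrom", "pos", "ref", "alt", "tumor_alt", "tumor_total", "tumor_af",
    "normal_alt", "normal_total", "filter_trace",
]
CONTROL_HEADER = ["chrom", "pos", "ref", "alt", "sample", "alt_count",
                  "total_count", "af"]
CALL_HEADER = [
    "chrom", "pos", "ref", "alt", "tumor_alt", "tumor_total", "af",
    "normal_alt", "normal_total", "error_rate", "covered_controls",
    "germline_controls", "p_value", "p_adjusted", "judgement", "id",
]


def _fmt_af(af: float | None, digits: int = 2) -> str:
    return "." if af is None else f"{af:.{digits}f}"


def _fmt_trace(trace) -> str:
    return ";".join(
        f"{name}={'PASS' if ok else 'FAIL'}({detail})" for name, ok, detail in trace
    )


def write_candidates(path: str | Path, candidates: Sequence[RawCandidate]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(CANDIDATE_HEADER) + "\n")
        for c in candidates:
            fh.write("\t".join([
                c.site.chrom, str(c.site.pos), c.site.ref, c.site.alt,
                str(c.tumor.alt_count), str(c.tumor.total_count),
                _fmt_af(c.tumor.allelic_fraction, 4),
                str(c.normal.alt_count), str(c.normal.total_count),
                _fmt_trace(c.filter_trace),
            ]) + "\n")


def _parse_trace(text: str):
    trace = []
    if not text or text == ".":
        return trace
    for tok in text.split(";"):
        name, rest = tok.split("=", 1)
        ok = rest.startswith("PASS")
        detail = rest[rest.index("(") + 1:-1] if "(" in rest else ""
        trace.append((name, ok, detail))
    return trace


def read_candidates(path: str | Path) -> list[RawCandidate]:
    """Reload Step 1 output; read stacks are not retained across the TSV."""
    out: list[RawCandidate] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != CANDIDATE_HEADER:
            raise ContractViolation(f"{path}: unexpected candidate header {header}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            site = GenomicSite(f[0], int(f[1]), f[2], f[3])
            tumor = SiteObservation(site, "tumor", [], int(f[4]), int(f[5]))
            normal = SiteObservation(site, "normal", [], int(f[7]), int(f[8]))
            out.append(RawCandidate(site=site, tumor=tumor, normal=normal,
                                    filter_trace=_parse_trace(f[9])))
    return out


def write_control_tables(path: str | Path, tables: Sequence[ControlTable]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(CONTROL_HEADER) + "\n")
        for t in tables:
            for o in t.observations:
                af = o.allelic_fraction
                fh.write("\t".join([
                    t.site.chrom, str(t.site.pos), t.site.ref, t.site.alt,
                    o.sample_id, str(o.alt_count), str(o.total_count),
                    "." if af is None else f"{af:.6g}",
                ]) + "\n")


def read_control_tables(path: str | Path) -> list[ControlTable]:
    tables: dict[tuple, ControlTable] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != CONTROL_HEADER:
            raise ContractViolation(f"{path}: unexpected control header {header}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            site = GenomicSite(f[0], int(f[1]), f[2], f[3])
            key = (site.chrom, site.pos, site.ref, site.alt)
            if key not in tables:
                tables[key] = ControlTable(site=site, observations=[])
            tables[key].observations.append(ControlObservation(
                sample_id=f[4], site=site,
                alt_count=int(f[5]), total_count=int(f[6]),
            ))
    return sorted(tables.values(), key=lambda t: (t.site.chrom, t.site.pos))


def write_calls(path: str | Path, calls: Sequence[VariantCall]) -> None:
    """Final per-site report, judged sites and rejected sites alike.

    Allelic fractions print at 2 decimals; error rates and p-values in
    scientific notation with 3 significant digits.
    """
    with open(path, "w") as fh:
        fh.write("\t".join(CALL_HEADER) + "\n")
        for c in calls:
            er = c.error_model.error_rate
            fh.write("\t".join([
                c.site.chrom, str(c.site.pos), c.site.ref, c.site.alt,
                str(c.tumor_alt), str(c.tumor_total),
                _fmt_af(c.tumor_af),
                str(c.normal_alt), str(c.normal_total),
                "." if er is None else f"{er:.2e}",
                str(c.error_model.covered_count),
                str(len(c.error_model.germline_samples)),
                "." if c.test is None else f"{c.test.p_value:.2e}",
                "." if c.test is None else f"{c.test.p_adjusted:.2e}",
                c.judgement,
                c.variant_id,
            ]) + "\n")


def write_vcf(path: str | Path, calls: Sequence[VariantCall],
              sample: str = "TUMOR") -> None:
    """Minimal SNV-only VCF; the judgement is carried in FILTER."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=panelsnv\n")
        fh.write('##INFO=<ID=ER,Number=1,Type=Float,'
                 'Description="Site-specific background error rate">\n')
        fh.write('##INFO=<ID=PV,Number=1,Type=Float,'
                 'Description="Binomial upper-tail p-value">\n')
        fh.write('##INFO=<ID=PADJ,Number=1,Type=Float,'
                 'Description="Bonferroni-adjusted p-value">\n')
        fh.write('##INFO=<ID=TAF,Number=1,Type=Float,'
                 'Description="Tumor allelic fraction">\n')
        for judgement in ("reject", "germline", "low_power"):
            fh.write(f'##FILTER=<ID={judgement},Description='
                     f'"Judged {judgement} by the panel error model">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in calls:
            er = c.error_model.error_rate
            info = [
                f"ER={er:.3g}" if er is not None else "ER=.",
                f"PV={c.test.p_value:.3g}" if c.test else "PV=.",
                f"PADJ={c.test.p_adjusted:.3g}" if c.test else "PADJ=.",
                f"TAF={c.tumor_af:.3g}" if c.tumor_af is not None else "TAF=.",
            ]
            filt = "PASS" if c.judgement == "real" else c.judgement
            fh.write("\t".join([
                c.site.chrom, str(c.site.pos), c.variant_id, c.site.ref,
                c.site.alt, ".", filt, ";".join(info),
            ]) + "\n")


def write_summary(path: str | Path, calls: Sequence[VariantCall],
                  extra: dict | None = None) -> None:
    """Machine-readable run summary: JSON lines of per-judgement counts."""
    counts: dict[str, int] = {}
    for c in calls:
        counts[c.judgement] = counts.get(c.judgement, 0) + 1
    with open(path, "w") as fh:
        record = {"type": "judgement_counts", **counts}
        fh.write(json.dumps(record) + "\n")
        if extra:
            fh.write(json.dumps({"type": "run_parameters", **extra}) + "\n")


def run_pipeline(
    tumor,
    normal,
    panel: Sequence,
    regions: Regions | None = None,
    cfg: FilterConfig | None = None,
    n_workers: int = 1,
    keep_rejected: bool = True,
) -> list[VariantCall]:
    """Steps 1-3 in sequence, in memory; returns the final calls."""
    cfg = cfg or FilterConfig()
    candidates = call_raw_variants(tumor, normal, regions, cfg)
    if not candidates:
        return []
    tables = build_control_table(panel, candidates, cfg, n_workers=n_workers)
    calls = judge_variants(candidates, tables, cfg)
    if not keep_rejected:
        calls = [c for c in calls if c.judgement == "real"]
    return calls
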