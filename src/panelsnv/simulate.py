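"""Synthetic read-stack generator with known truth.

Emulates the per-site pileups the caller consumes — tumor, matched normal
and a control panel — without simulating sequences or alignment.  Each
sequenced *molecule* (fragment) at a site is assigned a base: the
designated alternative base for planted germline carriers and somatic
variants, an error base at the site's (possibly elevated, possibly
transition-biased) error rate, or the reference.  Fragments then emit one
read, or two overlapping mates sharing a fragment_id, with base/mapping
qualities, strand and in-read position drawn from a configurable profile.

The formalin-fixation artifact spectrum is modelled by multiplying the
per-base error rate of the C>T and G>A transitions by
``ffpe_transition_bias``: at a C or G reference the total error rate
becomes e*(2 + bias)/3 and the expected fraction of errors that are
transitions is bias/(bias + 2).

Everything is a deterministic function of the seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .model import BASES, ContractViolation, GenomicSite, sort_sites
from .pileup import NO_FLAGS, PILEUP_COLUMNS, PileupTable


@dataclass
class QualityProfile:
    """Discrete per-read quality distributions.

    Defaults put 5% of base qualities and 3% of mapping qualities below the
    Phred-30 filter thresholds, so the expected read-filter removal rate of
    a simulated stack is known in closed form.
    """

    baseq_values: tuple[int, ...] = (20, 33, 37, 41)
    baseq_probs: tuple[float, ...] = (0.05, 0.25, 0.35, 0.35)
    mapq_values: tuple[int, ...] = (20, 60)
    mapq_probs: tuple[float, ...] = (0.03, 0.97)
    read_length: int = 100

    def __post_init__(self) -> None:
        for probs in (self.baseq_probs, self.mapq_probs):
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ContractViolation("quality probabilities must sum to 1")

    @property
    def pass_rate(self) -> float:
        """Probability a read survives both quality filters at Phred 30."""
        bq = sum(p for v, p in zip(self.baseq_values, self.baseq_probs) if v >= 30)
        mq = sum(p for v, p in zip(self.mapq_values, self.mapq_probs) if v >= 30)
        return bq * mq


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    ``sites`` lists background positions (reference base only); planted
    features carry their own sites, which must have ``alt`` set.  Depth is
    the expected number of *fragments* covering a site, drawn from a
    negative-binomial with the given dispersion (size) parameter;
    ``depth_dispersion=inf`` recovers Poisson counts for analytic checks.
    """

    sites: list[GenomicSite] = field(default_factory=list)
    n_controls: int = 100
    depth_mean: float = 100.0
    normal_depth_mean: float | None = None
    depth_dispersion: float = 50.0
    base_error_rate: float = 1e-3
    artifact_sites: list[tuple[GenomicSite, float]] = field(default_factory=list)
    germline_sites: list[tuple[GenomicSite, int, float]] = field(default_factory=list)
    true_somatic: list[tuple[GenomicSite, float]] = field(default_factory=list)
    ffpe_transition_bias: float = 1.0
    overlap_fraction: float = 0.2
    quality_profile: QualityProfile = field(default_factory=QualityProfile)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_controls < 0 or self.depth_mean < 0:
            raise ContractViolation("n_controls and depth_mean must be non-negative")
        for rate in (self.base_error_rate, self.overlap_fraction):
            if not (0.0 <= rate <= 1.0):
                raise ContractViolation("rates must lie in [0, 1]")
        if self.ffpe_transition_bias < 0:
            raise ContractViolation("ffpe_transition_bias must be non-negative")
        for site, rate in self.artifact_sites:
            if site.alt is None:
                raise ContractViolation(f"artifact site {site.label()} needs alt set")
            if not (0.0 <= rate <= 1.0):
                raise ContractViolation("artifact error rate must lie in [0, 1]")
        for site, carriers, het_af in self.germline_sites:
            if site.alt is None:
                raise ContractViolation(f"germline site {site.label()} needs alt set")
            if carriers > self.n_controls:
                raise ContractViolation(
                    f"{carriers} carriers exceed panel size {self.n_controls}"
                )
            if not (0.0 <= het_af <= 1.0):
                raise ContractViolation("het_af_mean must lie in [0, 1]")
        for site, af in self.true_somatic:
            if site.alt is None:
                raise ContractViolation(f"somatic site {site.label()} needs alt set")
            if not (0.0 <= af <= 1.0):
                raise ContractViolation("tumor_af must lie in [0, 1]")
            if af <= self.base_error_rate:
                warnings.warn(
                    f"planted variant at {site.label()} has AF {af} at or below "
                    f"the background error rate {self.base_error_rate}; it is "
                    "undetectable by design",
                    stacklevel=2,
                )

    def all_sites(self) -> list[GenomicSite]:
        """Every simulated site (planted sites carry their alt), sorted."""
        by_key: dict[tuple[str, int], GenomicSite] = {}
        for s in self.sites:
            by_key[s.key] = s
        for s, _ in self.artifact_sites:
            by_key[s.key] = s
        for s, _, _ in self.germline_sites:
            by_key[s.key] = s
        for s, _ in self.true_somatic:
            by_key[s.key] = s
        return sort_sites(by_key.values())


_TRANSITION_TARGET = {"C": "T", "G": "A"}


def _error_base_rates(site: GenomicSite, base_rate: float, bias: float
                      ) -> list[tuple[str, float]]:
    """Per-base molecule error rates at a site (transition-biased)."""
    out = []
    for b in BASES:
        if b == site.ref:
            continue
        mult = bias if _TRANSITION_TARGET.get(site.ref) == b else 1.0
        out.append((b, base_rate / 3.0 * mult))
    return out


class _Generator:
    def __init__(self, cfg: SimulationConfig):
        self.cfg = cfg
        self.rng = np.random.default_rng(cfg.seed)
        self.qp = cfg.quality_profile
        self._artifact = {s.key: (s, r) for s, r in cfg.artifact_sites}
        self._germline = {s.key: (s, c, af) for s, c, af in cfg.germline_sites}
        self._somatic = {s.key: (s, af) for s, af in cfg.true_somatic}

    def _draw_depth(self, mean: float | None = None) -> int:
        if mean is None:
            mean = self.cfg.depth_mean
        disp = self.cfg.depth_dispersion
        if mean == 0:
            return 0
        if np.isinf(disp):
            return int(self.rng.poisson(mean))
        return int(self.rng.negative_binomial(disp, disp / (disp + mean)))

    def _molecule_outcomes(self, site: GenomicSite, signal_af: float
                           ) -> list[tuple[str, float]]:
        """Non-reference molecule outcomes as (base, probability)."""
        key = site.key
        outcomes: dict[str, float] = {}
        if signal_af > 0.0:
            outcomes[site.alt] = signal_af
        if key in self._artifact and signal_af == 0.0:
            art_site, rate = self._artifact[key]
            outcomes[art_site.alt] = outcomes.get(art_site.alt, 0.0) + rate
            for b, r in _error_base_rates(site, self.cfg.base_error_rate,
                                          self.cfg.ffpe_transition_bias):
                if b != art_site.alt:
                    outcomes[b] = outcomes.get(b, 0.0) + r
        elif signal_af == 0.0:
            for b, r in _error_base_rates(site, self.cfg.base_error_rate,
                                          self.cfg.ffpe_transition_bias):
                outcomes[b] = outcomes.get(b, 0.0) + r
        total = sum(outcomes.values())
        if total > 1.0:
            raise ContractViolation(f"outcome probabilities exceed 1 at {site.label()}")
        return sorted(outcomes.items())

    def site_rows(self, sample: str, site: GenomicSite, signal_af: float,
                  sink: dict[str, list], depth_mean: float | None = None
                  ) -> tuple[int, int]:
        """Append one sample's reads at one site; return (n_frag, n_alt_mol)."""
        rng, qp, cfg = self.rng, self.qp, self.cfg
        n_frag = self._draw_depth(depth_mean)
        if n_frag == 0:
            return 0, 0
        outcomes = self._molecule_outcomes(site, signal_af)
        bases = np.full(n_frag, site.ref, dtype=object)
        if outcomes:
            cum = np.cumsum([p for _, p in outcomes])
            u = rng.random(n_frag)
            idx = np.searchsorted(cum, u)
            labels = [b for b, _ in outcomes]
            hit = idx < len(labels)
            bases[hit] = [labels[i] for i in idx[hit]]
        paired = rng.random(n_frag) < cfg.overlap_fraction
        first_strand = np.where(rng.random(n_frag) < 0.5, "+", "-")

        frag_idx = np.concatenate([np.arange(n_frag), np.nonzero(paired)[0]])
        mate_no = np.concatenate([
            np.ones(n_frag, dtype=int), np.full(int(paired.sum()), 2, dtype=int)
        ])
        n_reads = frag_idx.size
        strands = np.where(
            mate_no == 1, first_strand[frag_idx],
            np.where(first_strand[frag_idx] == "+", "-", "+"),
        )
        baseq = rng.choice(qp.baseq_values, size=n_reads, p=qp.baseq_probs)
        mapq = rng.choice(qp.mapq_values, size=n_reads, p=qp.mapq_probs)
        read_pos = rng.integers(1, qp.read_length + 1, size=n_reads)

        frag_ids = [f"{sample}|{site.chrom}:{site.pos}|{i}" for i in frag_idx]
        sink["chrom"].extend([site.chrom] * n_reads)
        sink["pos"].extend([site.pos] * n_reads)
        sink["ref"].extend([site.ref] * n_reads)
        sink["sample"].extend([sample] * n_reads)
        sink["read_id"].extend(f"{f}/{m}" for f, m in zip(frag_ids, mate_no))
        sink["fragment_id"].extend(frag_ids)
        sink["base"].extend(bases[frag_idx])
        sink["baseq"].extend(int(q) for q in baseq)
        sink["mapq"].extend(int(q) for q in mapq)
        sink["strand"].extend(strands)
        sink["read_pos"].extend(int(p) for p in read_pos)
        sink["read_len"].extend([qp.read_length] * n_reads)
        sink["flags"].extend([NO_FLAGS] * n_reads)
        n_alt_mol = int(sum(1 for b in bases if site.alt is not None and b == site.alt))
        return n_frag, n_alt_mol

    def sample_table(self, sample: str, signal_by_site: dict[tuple[str, int], float],
                     depth_mean: float | None = None
                     ) -> tuple[PileupTable, list[dict]]:
        sink: dict[str, list] = {c: [] for c in PILEUP_COLUMNS}
        stats = []
        for site in self.cfg.all_sites():
            af = signal_by_site.get(site.key, 0.0)
            n_frag, n_alt = self.site_rows(sample, site, af, sink, depth_mean)
            stats.append({
                "sample": sample, "chrom": site.chrom, "pos": site.pos,
                "fragments": n_frag, "alt_molecules": n_alt,
            })
        df = pd.DataFrame(sink, columns=PILEUP_COLUMNS)
        return PileupTable(df, sample_id=sample), stats


def _truth_rows(cfg: SimulationConfig, carriers: dict[tuple[str, int], list[str]]
                ) -> list[dict]:
    rows = []
    planted = set()
    for site, rate in cfg.artifact_sites:
        rows.append({"chrom": site.chrom, "pos": site.pos, "ref": site.ref,
                     "alt": site.alt, "kind": "artifact", "param": rate,
                     "carriers": "."})
        planted.add(site.key)
    for site, count, het_af in cfg.germline_sites:
        rows.append({"chrom": site.chrom, "pos": site.pos, "ref": site.ref,
                     "alt": site.alt, "kind": "germline", "param": het_af,
                     "carriers": ";".join(carriers.get(site.key, [])) or "."})
        planted.add(site.key)
    for site, af in cfg.true_somatic:
        rows.append({"chrom": site.chrom, "pos": site.pos, "ref": site.ref,
                     "alt": site.alt, "kind": "somatic", "param": af,
                     "carriers": "."})
        planted.add(site.key)
    for site in cfg.all_sites():
        if site.key not in planted:
            rows.append({"chrom": site.chrom, "pos": site.pos, "ref": site.ref,
                         "alt": ".", "kind": "background",
                         "param": cfg.base_error_rate, "carriers": "."})
    rows.sort(key=lambda r: (r["chrom"], r["pos"]))
    return rows


def simulate_panel(cfg: SimulationConfig) -> tuple[list[PileupTable], pd.DataFrame]:
    """Simulate the control panel; returns (per-control pileups, truth table).

    Germline carriers are drawn without replacement per germline site;
    carriers emit the alternative base at ``het_af_mean`` per molecule,
    everyone else at the site's (possibly elevated) error rate.
    """
    gen = _Generator(cfg)
    names = [f"control_{i:03d}" for i in range(cfg.n_controls)]
    carriers: dict[tuple[str, int], list[str]] = {}
    for site, count, het_af in cfg.germline_sites:
        chosen = gen.rng.choice(cfg.n_controls, size=count, replace=False)
        carriers[site.key] = [names[i] for i in sorted(int(i) for i in chosen)]

    tables = []
    for name in names:
        signal = {
            site.key: het_af
            for site, _, het_af in cfg.germline_sites
            if name in carriers[site.key]
        }
        table, _ = gen.sample_table(name, signal)
        tables.append(table)
    truth = pd.DataFrame(_truth_rows(cfg, carriers))
    return tables, truth


def simulate_tumor_normal(
    cfg: SimulationConfig,
) -> tuple[PileupTable, PileupTable, pd.DataFrame]:
    """Simulate the tumor and its matched normal; returns both plus truth.

    The tumor carries the planted somatic variants at their stated allelic
    fractions plus background errors; artifact error rates elevate the
    tumor only (a tumor-batch artifact the matched normal cannot catch).
    Germline sites make *both* samples heterozygous carriers.  The drawn
    alternative molecule count of each somatic site is recorded in the
    truth table (``drawn_alt``/``drawn_fragments``).
    """
    gen = _Generator(cfg)
    germline_signal = {s.key: het_af for s, _, het_af in cfg.germline_sites}
    tumor_signal = dict(germline_signal)
    tumor_signal.update({s.key: af for s, af in cfg.true_somatic})

    tumor, t_stats = gen.sample_table("tumor", tumor_signal)

    # the normal must not see tumor-batch artifacts: rebuild a generator view
    # without artifact elevation for the normal draw, same RNG stream
    artifact_backup = gen._artifact
    gen._artifact = {}
    normal, _ = gen.sample_table("normal", germline_signal,
                                 depth_mean=cfg.normal_depth_mean)
    gen._artifact = artifact_backup

    carriers = {s.key: ["tumor", "normal"] for s, _, _ in cfg.germline_sites}
    truth = pd.DataFrame(_truth_rows(cfg, carriers))
    drawn = {(r["chrom"], r["pos"]): r for r in t_stats}
    truth["drawn_alt"] = [
        drawn[(c, p)]["alt_molecules"] if (c, p) in drawn else 0
        for c, p in zip(truth["chrom"], truth["pos"])
    ]
    truth["drawn_fragments"] = [
        drawn[(c, p)]["fragments"] if (c, p) in drawn else 0
        for c, p in zip(truth["chrom"], truth["pos"])
    ]
    return tumor, normal, truth
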