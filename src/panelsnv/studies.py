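"""Canonical synthetic studies exercising the full caller.

Each function builds a seeded cohort with the generator, runs the caller,
and scores the result against the planted truth.  These studies define
fixed, documented conditions (depths, error rates, panel sizes) so that
the same experiment is reproducible from tests, example scripts and the
reproduction script.

Conditions common to the specificity studies: 100-control panel at mean
400x per control, tumor at mean 300x, matched normal at mean 40x,
negative-binomial dispersion 100, background error 1e-3 per molecule.
The panel is deep enough that a 5%-error artifact site's per-control
allelic fraction essentially never crosses the 10% germline-clustering
trigger, and the shallow normal rarely accumulates two background error
reads, so planted truths map onto unambiguous expected judgements.
Artifact sites carry a 5% panel-wide error rate and a 3.5% rate in the
tumor (artifact intensity varies between samples in practice).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .control_panel import build_control_table
from .model import FilterConfig, GenomicSite
from .simulate import SimulationConfig, simulate_panel, simulate_tumor_normal
from .stats import (
    estimate_error_rate,
    flag_recurrent_germline,
    judge_variants,
    split_controls,
)
from .raw_caller import call_raw_variants

_TRANSITIONS = {("C", "T"), ("G", "A")}


@dataclass
class GermlineClusterResult:
    germline_size: int
    error_size: int
    germline_mean_af: float
    error_mean_af: float
    flagged_recurrent: bool


def germline_cluster_study(
    seed: int,
    n_controls: int = 135,
    carrier_count: int = 5,
    het_af_mean: float = 0.35,
    error_rate: float = 0.02,
    depth_mean: float = 100.0,
    cfg: FilterConfig | None = None,
) -> GermlineClusterResult:
    """One SNP-vs-artifact panel: a handful of het carriers over a noisy floor.

    Emulates the canonical situation where a known polymorphism appears in a
    few panel members around the (capture-biased) het fraction while every
    other control shows a low-level recurrent artifact, and the per-site
    clustering must separate the two.
    """
    cfg = cfg or FilterConfig()
    site = GenomicSite("chr7", 55249071, "C", "T")
    sim = SimulationConfig(
        sites=[], n_controls=n_controls, depth_mean=depth_mean,
        base_error_rate=1e-3,
        artifact_sites=[(site, error_rate)],
        germline_sites=[(site, carrier_count, het_af_mean)],
        seed=seed,
    )
    panel, _ = simulate_panel(sim)
    (table,) = build_control_table(panel, [site], cfg)
    model = split_controls(table, cfg)
    obs = {o.sample_id: o for o in table.covered}
    g_afs = [obs[s].allelic_fraction for s in model.germline_samples]
    e_afs = [obs[s].allelic_fraction for s in model.error_samples]
    return GermlineClusterResult(
        germline_size=len(model.germline_samples),
        error_size=len(model.error_samples),
        germline_mean_af=sum(g_afs) / len(g_afs) if g_afs else float("nan"),
        error_mean_af=sum(e_afs) / len(e_afs) if e_afs else float("nan"),
        flagged_recurrent=flag_recurrent_germline(model, cfg),
    )


@dataclass
class EndToEndResult:
    """Scored judgements of one synthetic tumor/normal/panel replicate."""

    true_sites: dict[tuple[str, int], str]
    artifact_sites: dict[tuple[str, int], str]
    error_rate_background: float | None
    judgement_counts: dict[str, int] = field(default_factory=dict)

    @property
    def all_true_real(self) -> bool:
        return all(j == "real" for j in self.true_sites.values())

    @property
    def all_artifacts_rejected(self) -> bool:
        return all(j == "reject" for j in self.artifact_sites.values())


def end_to_end_study(
    seed: int,
    somatic_afs: tuple[float, ...] = (0.05, 0.10, 0.15),
    n_controls: int = 100,
    panel_depth: float = 400.0,
    tumor_depth: float = 300.0,
    normal_depth: float = 40.0,
    base_error_rate: float = 1e-3,
    panel_artifact_rate: float = 0.05,
    tumor_artifact_rate: float = 0.035,
    n_background: int = 10,
    cfg: FilterConfig | None = None,
) -> EndToEndResult:
    """Plant low-AF truths and batch artifacts; run the three-step caller.

    Returns the judgement of every planted site (missing from the output
    counts as its own pseudo-judgement ``absent``) plus the pooled error
    rate the panel estimated at the first somatic site.
    """
    cfg = cfg or FilterConfig()
    somatic = [
        (GenomicSite("chr1", 1_000_000 + i, "A", "G"), af)
        for i, af in enumerate(somatic_afs)
    ]
    artifacts = [GenomicSite("chr2", 2_000_000 + i, "C", "T") for i in range(2)]
    background = [GenomicSite("chr3", 3_000_000 + i, "T") for i in range(n_background)]

    panel_cfg = SimulationConfig(
        sites=background + [GenomicSite(s.chrom, s.pos, s.ref) for s, _ in somatic],
        n_controls=n_controls, depth_mean=panel_depth, depth_dispersion=100,
        base_error_rate=base_error_rate,
        artifact_sites=[(s, panel_artifact_rate) for s in artifacts],
        seed=2 * seed + 1,
    )
    tn_cfg = SimulationConfig(
        sites=background, n_controls=0,
        depth_mean=tumor_depth, normal_depth_mean=normal_depth,
        depth_dispersion=100, base_error_rate=base_error_rate,
        artifact_sites=[(s, tumor_artifact_rate) for s in artifacts],
        true_somatic=somatic,
        seed=2 * seed,
    )
    panel, _ = simulate_panel(panel_cfg)
    tumor, normal, _ = simulate_tumor_normal(tn_cfg)

    candidates = call_raw_variants(tumor, normal, cfg=cfg)
    tables = build_control_table(panel, candidates, cfg)
    calls = judge_variants(candidates, tables, cfg)

    judged = {c.site.key: c.judgement for c in calls}
    counts: dict[str, int] = {}
    for j in judged.values():
        counts[j] = counts.get(j, 0) + 1

    rate = None
    somatic_keys = {s.key for s, _ in somatic}
    for cand, table in zip(candidates, tables):
        if cand.site.key in somatic_keys:
            rate = estimate_error_rate(split_controls(table, cfg))
            break

    return EndToEndResult(
        true_sites={s.key: judged.get(s.key, "absent") for s, _ in somatic},
        artifact_sites={s.key: judged.get(s.key, "absent") for s in artifacts},
        error_rate_background=rate,
        judgement_counts=counts,
    )


@dataclass
class FfpeStudyResult:
    transition_fraction_rejected: float
    transition_fraction_called: float
    n_rejected: int
    n_called: int


def ffpe_artifact_study(seed: int, cfg: FilterConfig | None = None) -> FfpeStudyResult:
    """A formalin-damaged cohort: C>T/G>A artifact burden vs real variants.

    Plants 16 transition artifact sites and 4 transversion artifact sites
    (panel-wide 5%, tumor 3.5%) alongside 4 true somatic variants of which
    one is itself a transition, then measures the fraction of C>T/G>A
    changes among rejected vs retained calls.  In formalin-fixed samples
    the rejected set should be transition-dominated.
    """
    cfg = cfg or FilterConfig()
    transitions = [GenomicSite("chr5", 5_000_000 + i, "C", "T") for i in range(8)]
    transitions += [GenomicSite("chr5", 5_100_000 + i, "G", "A") for i in range(8)]
    transversions = [GenomicSite("chr6", 6_000_000 + i, "A", "C") for i in range(4)]
    somatic = [
        (GenomicSite("chr8", 8_000_000, "A", "G"), 0.15),
        (GenomicSite("chr8", 8_000_001, "T", "A"), 0.20),
        (GenomicSite("chr8", 8_000_002, "G", "C"), 0.10),
        (GenomicSite("chr8", 8_000_003, "C", "T"), 0.15),  # a real transition
    ]
    artifacts = transitions + transversions

    panel_cfg = SimulationConfig(
        sites=[GenomicSite(s.chrom, s.pos, s.ref) for s, _ in somatic],
        n_controls=100, depth_mean=400, depth_dispersion=100,
        base_error_rate=1e-3,
        artifact_sites=[(s, 0.05) for s in artifacts],
        seed=2 * seed + 1,
    )
    tn_cfg = SimulationConfig(
        sites=[], n_controls=0, depth_mean=300, normal_depth_mean=40,
        depth_dispersion=100, base_error_rate=1e-3,
        artifact_sites=[(s, 0.035) for s in artifacts],
        true_somatic=somatic,
        seed=2 * seed,
    )
    panel, _ = simulate_panel(panel_cfg)
    tumor, normal, _ = simulate_tumor_normal(tn_cfg)
    candidates = call_raw_variants(tumor, normal, cfg=cfg)
    tables = build_control_table(panel, candidates, cfg)
    calls = judge_variants(candidates, tables, cfg)

    def is_transition(c):
        return (c.site.ref, c.site.alt) in _TRANSITIONS

    rejected = [c for c in calls if c.judgement == "reject"]
    called = [c for c in calls if c.judgement == "real"]
    return FfpeStudyResult(
        transition_fraction_rejected=(
            sum(map(is_transition, rejected)) / len(rejected) if rejected else 0.0
        ),
        transition_fraction_called=(
            sum(map(is_transition, called)) / len(called) if called else 0.0
        ),
        n_rejected=len(rejected),
        n_called=len(called),
    )
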