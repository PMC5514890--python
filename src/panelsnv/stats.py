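"""Step 3: site-specific error model, binomial test, power-based coverage filter.

Per candidate site the control panel is split into germline carriers and
error-bearing samples.  When no control shows the variant above the
germline allelic-fraction trigger (default 10%), every covered control is
treated as error-bearing.  Above the trigger, a one-dimensional two-means
clustering of the control allelic fractions separates the cluster with the
larger mean (germline carriers of an inherited variant) from the cluster
with the smaller mean (low-fraction artifacts).  Variants recurrently seen
as germline in the panel are flagged and excluded from somatic testing.

Reads from the error-bearing controls are merged into a site-specific
error rate

    p = (sum of alternative reads over error controls)
        / (sum of total reads over error controls)

and the tumor's alternative read count X out of n total reads is tested
against X ~ Binom(n, p) (upper tail), Bonferroni-corrected across the
tested sites at family-wise alpha 0.05.  Sites whose coverage gives less
than 80% power to detect a 30% AF mutation in the tumor or a 50% AF
mutation in the matched normal are set aside as low-power rather than
trusted as negative.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import binom

from .control_panel import ControlTable
from .model import ContractViolation, FilterConfig, GenomicSite, allelic_fraction
from .raw_caller import RawCandidate

log = logging.getLogger(__name__)

JUDGEMENTS = ("real", "reject", "germline", "low_power")


# -- exact 1-D two-means -----------------------------------------------------

@dataclass
class KMeansPartition:
    """Globally optimal 2-means partition of 1-D values.

    ``lower``/``upper`` hold indices into the input (upper = larger mean).
    """

    lower: list[int]
    upper: list[int]
    lower_mean: float
    upper_mean: float
    within_ss: float


def kmeans_1d_two_clusters(
    values: Sequence[float], seed: int | None = None
) -> KMeansPartition:
    """Exact two-cluster K-means in one dimension.

    In 1-D the optimal 2-means clusters are contiguous in sorted order, so
    the global optimum is found by enumerating the n-1 split points of the
    sorted values and minimizing the within-cluster sum of squares.  The
    result is therefore deterministic; ``seed`` is accepted for interface
    stability but unused.
    """
    vals = np.asarray(values, dtype=float)
    n = vals.size
    if n < 2:
        raise ContractViolation("two-means clustering requires >= 2 values")
    if np.all(vals == vals[0]):
        raise ContractViolation("two-means clustering requires non-identical values")
    order = np.argsort(vals, kind="stable")
    s = vals[order]
    csum = np.cumsum(s)
    total = csum[-1]
    ks = np.arange(1, n)                      # lower-cluster sizes
    mean_lo = csum[:-1] / ks
    mean_hi = (total - csum[:-1]) / (n - ks)
    csq = np.cumsum(s * s)
    ss_lo = csq[:-1] - ks * mean_lo**2
    ss_hi = (csq[-1] - csq[:-1]) - (n - ks) * mean_hi**2
    wss = ss_lo + ss_hi
    k = int(ks[np.argmin(wss)])               # first optimum on ties
    lower_idx = sorted(int(i) for i in order[:k])
    upper_idx = sorted(int(i) for i in order[k:])
    return KMeansPartition(
        lower=lower_idx,
        upper=upper_idx,
        lower_mean=float(mean_lo[k - 1]),
        upper_mean=float(mean_hi[k - 1]),
        within_ss=float(wss[k - 1]),
    )


# -- site error model --------------------------------------------------------

@dataclass
class SiteErrorModel:
    """Germline/error partition of the panel and the pooled error rate."""

    site: GenomicSite
    germline_samples: list[str]
    error_samples: list[str]
    pooled_alt: int
    pooled_total: int
    clustering_triggered: bool
    covered_count: int = 0

    @property
    def error_rate(self) -> float | None:
        """Raw pooled ratio; None (undefined) with an empty error pool."""
        if self.pooled_total == 0:
            return None
        return self.pooled_alt / self.pooled_total


def split_controls(table: ControlTable, cfg: FilterConfig) -> SiteErrorModel:
    """Partition covered controls into germline carriers and the error pool.

    Clustering is triggered iff some covered control's allelic fraction
    exceeds ``cfg.germline_af_threshold``.  With fewer than two covered
    controls, or identical fractions, the exact clustering is degenerate
    and the partition falls back to the threshold itself.
    """
    covered = table.covered
    afs = [o.allelic_fraction for o in covered]
    triggered = any(af > cfg.germline_af_threshold for af in afs)

    if not triggered:
        germline: list[int] = []
        error = list(range(len(covered)))
    elif len(covered) >= 2 and len(set(afs)) > 1:
        part = kmeans_1d_two_clusters(afs)
        germline = part.upper
        error = part.lower
    else:
        germline = [i for i, af in enumerate(afs) if af > cfg.germline_af_threshold]
        error = [i for i, af in enumerate(afs) if af <= cfg.germline_af_threshold]

    pooled_alt = sum(covered[i].alt_count for i in error)
    pooled_total = sum(covered[i].total_count for i in error)
    return SiteErrorModel(
        site=table.site,
        germline_samples=[covered[i].sample_id for i in germline],
        error_samples=[covered[i].sample_id for i in error],
        pooled_alt=pooled_alt,
        pooled_total=pooled_total,
        clustering_triggered=triggered,
        covered_count=len(covered),
    )


def flag_recurrent_germline(model: SiteErrorModel, cfg: FilterConfig) -> bool:
    """True when the germline cluster is populous enough to flag the site.

    A variant recurrently carried in the control panel is an inherited
    polymorphism, not a somatic event, and is excluded from testing.
    """
    return (
        model.clustering_triggered
        and len(model.germline_samples) >= cfg.min_germline_recurrence
    )


def estimate_error_rate(model: SiteErrorModel) -> float | None:
    """Error rate used in testing: pooled ratio, floored when the pool is clean.

    With zero pooled alternative reads the raw ratio is 0 and any tumor
    support would give p-value 0 regardless of pooled depth; the rate is
    floored at 1/(pooled_total + 1) so confidence scales with how deeply
    the panel covered the site.  Undefined (None) with an empty pool.
    """
    if model.pooled_total == 0:
        return None
    if model.pooled_alt == 0:
        return 1.0 / (model.pooled_total + 1)
    return model.pooled_alt / model.pooled_total


# -- binomial machinery ------------------------------------------------------

def binomial_pvalue(X: int, n: int, p: float) -> float:
    """Upper-tail probability P[Binom(n, p) >= X]."""
    if not (0 <= X <= n):
        raise ContractViolation(f"need 0 <= X <= n, got X={X}, n={n}")
    if not (0.0 < p <= 1.0):
        raise ContractViolation(
            f"need 0 < p <= 1, got p={p} (apply the zero-pool floor first)"
        )
    if X == 0:
        return 1.0
    return float(binom.sf(X - 1, n, p))


def bonferroni(
    p_values: Sequence[float], alpha: float, m: int | None = None
) -> tuple[list[float], list[bool]]:
    """Family-wise correction: adjusted_i = min(1, m * p_i); significant iff < alpha."""
    if m is None:
        m = len(p_values)
    adjusted = [min(1.0, m * p) for p in p_values]
    return adjusted, [a < alpha for a in adjusted]


def rejection_threshold(n: int, p_err: float, alpha_site: float) -> int:
    """Smallest alt count k* with P[Binom(n, p_err) >= k*] < alpha_site."""
    k = np.arange(0, n + 2)
    sf = binom.sf(k - 1, n, p_err)  # P[X >= k]
    hits = np.nonzero(sf < alpha_site)[0]
    return int(k[hits[0]]) if hits.size else n + 1


def binomial_power(
    n: int, p_err: float, detect_af: float, alpha_site: float
) -> float:
    """Power of the site's binomial test against a true allelic fraction.

    k* is the site's rejection threshold under the error rate; power is the
    probability a variant at ``detect_af`` produces at least k* alternative
    reads.  Zero coverage has zero power.
    """
    if n < 0:
        raise ContractViolation("n must be non-negative")
    if not (0.0 < p_err < detect_af <= 1.0):
        raise ContractViolation(
            f"need 0 < p_err < detect_af <= 1, got p_err={p_err}, detect_af={detect_af}"
        )
    if n == 0:
        return 0.0
    k_star = rejection_threshold(n, p_err, alpha_site)
    if k_star > n:
        return 0.0
    return float(binom.sf(k_star - 1, n, detect_af))


def power_filter(
    tumor_n: int,
    normal_n: int,
    model: SiteErrorModel,
    cfg: FilterConfig,
    alpha_site: float,
) -> bool:
    """Pass iff both samples are covered deeply enough to trust a negative.

    Requires >= ``cfg.power_threshold`` power to detect a mutation at
    ``cfg.tumor_detect_af`` in the tumor and ``cfg.normal_detect_af`` in
    the matched normal, at the per-site significance level.
    """
    p = estimate_error_rate(model)
    if p is None:
        return False
    if p >= cfg.tumor_detect_af or p >= cfg.normal_detect_af:
        # error rate swamps the detectable signal; the test is powerless
        return False
    pw_t = binomial_power(tumor_n, p, cfg.tumor_detect_af, alpha_site)
    pw_n = binomial_power(normal_n, p, cfg.normal_detect_af, alpha_site)
    return pw_t >= cfg.power_threshold and pw_n >= cfg.power_threshold


# -- final judgement ---------------------------------------------------------

@dataclass
class BinomialTestResult:
    X: int
    n: int
    p: float
    p_value: float
    p_adjusted: float
    significant: bool


@dataclass
class VariantCall:
    """Final per-site record: counts, error model summary, test, judgement."""

    site: GenomicSite
    tumor_alt: int
    tumor_total: int
    normal_alt: int
    normal_total: int
    error_model: SiteErrorModel
    test: BinomialTestResult | None
    judgement: str
    variant_id: str = "."

    @property
    def tumor_af(self) -> float | None:
        return allelic_fraction(self.tumor_alt, self.tumor_total)


def judge_variants(
    candidates: Sequence[RawCandidate],
    tables: Sequence[ControlTable],
    cfg: FilterConfig | None = None,
    ids: dict[tuple[str, int], str] | None = None,
) -> list[VariantCall]:
    """Run the Step 3 cascade over aligned candidates and control tables.

    Per site: recurrent-germline flag -> ``germline``; empty error pool or
    insufficient detection power -> ``low_power``; otherwise the binomial
    test is run, Bonferroni-corrected over the m tested sites: significant
    -> ``real``, else ``reject``.  The per-site alpha used for the power
    computation is alpha divided by the number of candidates that reach the
    power stage.  Output is sorted by (chrom, pos).
    """
    cfg = cfg or FilterConfig()
    if len(candidates) != len(tables):
        raise ContractViolation(
            f"{len(candidates)} candidates vs {len(tables)} control tables"
        )
    pairs = sorted(
        zip(candidates, tables), key=lambda ct: (ct[0].site.chrom, ct[0].site.pos)
    )
    for cand, table in pairs:
        if cand.site.key != table.site.key:
            raise ContractViolation(
                f"candidate {cand.site.label()} misaligned with "
                f"control table {table.site.label()}"
            )

    models = [split_controls(t, cfg) for _, t in pairs]
    germ = [flag_recurrent_germline(m, cfg) for m in models]
    rates = [estimate_error_rate(m) for m in models]

    stage2 = [
        i for i in range(len(pairs)) if not germ[i] and rates[i] is not None
    ]
    alpha_site = cfg.alpha / len(stage2) if stage2 else cfg.alpha

    tested: list[int] = []
    judgements: dict[int, str] = {}
    for i in range(len(pairs)):
        if germ[i]:
            judgements[i] = "germline"
        elif i not in stage2:
            judgements[i] = "low_power"
        else:
            cand = pairs[i][0]
            ok = power_filter(
                cand.tumor.total_count, cand.normal.total_count,
                models[i], cfg, alpha_site,
            )
            if ok:
                tested.append(i)
            else:
                judgements[i] = "low_power"

    m = len(tested)
    pvals = [
        binomial_pvalue(pairs[i][0].tumor.alt_count,
                        pairs[i][0].tumor.total_count, rates[i])
        for i in tested
    ]
    adjusted, signif = bonferroni(pvals, cfg.alpha, m=m)
    log.info("binomial testing: m=%d alpha=%g per-site alpha=%g",
             m, cfg.alpha, alpha_site)

    tests: dict[int, BinomialTestResult] = {}
    for j, i in enumerate(tested):
        cand = pairs[i][0]
        tests[i] = BinomialTestResult(
            X=cand.tumor.alt_count, n=cand.tumor.total_count, p=rates[i],
            p_value=pvals[j], p_adjusted=adjusted[j], significant=signif[j],
        )
        judgements[i] = "real" if signif[j] else "reject"

    calls: list[VariantCall] = []
    for i, (cand, _) in enumerate(pairs):
        key = cand.site.key
        calls.append(VariantCall(
            site=cand.site,
            tumor_alt=cand.tumor.alt_count,
            tumor_total=cand.tumor.total_count,
            normal_alt=cand.normal.alt_count,
            normal_total=cand.normal.total_count,
            error_model=models[i],
            test=tests.get(i),
            judgement=judgements[i],
            variant_id=(ids or {}).get(key, "."),
        ))
    return calls
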