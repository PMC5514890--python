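"""Step 1 on a tiny synthetic tumor/normal pair.

Builds a 150x tumor carrying one 20%-AF somatic SNV over a 60x matched
normal, runs the raw caller, and prints each candidate with its filter
trace.  Every filter of the cascade appears in the trace, in order, so a
rejected site is always explainable.
"""

from panelsnv import FilterConfig, GenomicSite, SimulationConfig, simulate_tumor_normal
from panelsnv.raw_caller import call_raw_variants

cfg = SimulationConfig(
    sites=[GenomicSite("chr1", 100 + i, "C") for i in range(5)],
    n_controls=0,
    depth_mean=150,
    normal_depth_mean=60,
    true_somatic=[(GenomicSite("chr1", 500, "A", "G"), 0.20)],
    seed=7,
)
tumor, normal, truth = simulate_tumor_normal(cfg)

candidates = call_raw_variants(tumor, normal, cfg=FilterConfig())
print(f"{len(candidates)} candidate site(s)\n")
for cand in candidates:
    af = cand.tumor.allelic_fraction
    print(f"{cand.site.label()}  tumor {cand.tumor.alt_count}/"
          f"{cand.tumor.total_count} (AF {af:.2f}), "
          f"normal {cand.normal.alt_count}/{cand.normal.total_count}")
    for name, ok, detail in cand.filter_trace:
        print(f"    {name:<26} {'PASS' if ok else 'FAIL'}  {detail}")

print("\nThe planted chr1:500 A>G variant survives every read and site "
      "filter; background error sites lack 2-fragment alt support and are "
      "never emitted.")
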