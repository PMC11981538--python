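"""Generate a disturbance pair of synthetic webs and compare them.

The baseline is a niche-model web; the disturbed variant re-draws the
whole basal set (a regime switch to cyanobacteria-like producers) plus 20%
of consumers, then the full pipeline compares topology, trophic levels of
shared nodes, and flux diversity.
"""

from trophoweb import (
    Perturbation,
    SyntheticWebSpec,
    compare_webs,
    compute_fluxes,
    flux_summaries,
    generate_disturbance_pair,
    global_metrics,
    symmetrize,
    trophic_levels,
)

spec = SyntheticWebSpec(n_nodes=23, connectance=0.217, seed=7)
baseline, disturbed = generate_disturbance_pair(
    spec, Perturbation(basal_replacement=1.0, consumer_turnover=0.2)
)

report = compare_webs(
    baseline,
    disturbed,
    global_metrics(symmetrize(baseline)),
    global_metrics(symmetrize(disturbed)),
    trophic_levels(baseline),
    trophic_levels(disturbed),
    {
        "pre": flux_summaries(compute_fluxes(baseline)[0]),
        "post": flux_summaries(compute_fluxes(disturbed)[0]),
    },
)
print(report.to_text())
print("Shared nodes keep their identity across the disturbance; their TL")
print("shifts (classified at 2 dp) show food-chain shortening or lengthening.")
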