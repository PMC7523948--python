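"""Convert body measurements to joules and summarize univariate metrics.

Each measured invertebrate is converted to dry mass (DM = a * L^b, mg) and
then to energy (J) with taxon-specific coefficients resolved by taxonomic
fallback.  Per-sample metrics are then averaged per section x period group,
and the headline percent decline is computed from the group means.
"""

import foodwebkit as fwk

params = fwk.SimParams(samples_per_cell=8, seasons=("summer",),
                       sections=("LE", "TR"))
catalog, community, truth = fwk.simulate_community(params, seed=11)
conversions = fwk.make_conversion_table(catalog, seed=11)
annotated = fwk.annotate_energy(community, catalog, conversions)

table = fwk.sample_metrics_table(annotated, catalog)
summary = fwk.group_summary(table, "numeric_density").set_index(
    ["section", "season", "period"])
print(summary.round(2).to_string())

pre = summary.loc[("LE", "summer", "Pre"), "mean"]
during = summary.loc[("LE", "summer", "2013"), "mean"]
print(f"\nLE numeric density decline Pre -> 2013: "
      f"{fwk.percent_change(pre, during, digits=0):.0f}%")
# With the default imposed factor of 0.04 on aquatic taxa (plus enriched
# terrestrials), the recovered decline sits close to the imposed truth;
# the TR reference rows stay flat.
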