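"""Map a field trial onto the hierarchy and filter streams by metadata.

Builds a wheat trial: one research group (user), one experiment, eight
~2 m x 6 m plots (nodes) split between irrigated and rainfed treatment,
each with a canopy-temperature and a soil-moisture stream, then selects
streams by treatment metadata and by measurement unit.
"""

from fieldstore import SensorStore

store = SensorStore()
store.create_entity("user", "csiro-hb", attrs={"description": "field phenomics group"})
store.create_entity("experiment", "yanco-2013", "csiro-hb")
store.tree.set_metadata("csiro-hb~yanco-2013", "sowing-date", "2013-05-21")
store.tree.set_metadata("csiro-hb~yanco-2013", "site", "Yanco NSW")

for row in (1, 2):
    for col in (1, 2, 3, 4):
        node = f"plot-R{row}C{col}"
        store.create_entity(
            "node", node, "csiro-hb~yanco-2013",
            attrs={"latitude": -34.62, "longitude": 146.43},
        )
        treatment = "irrigated" if row == 1 else "rainfed"
        store.tree.set_metadata(f"csiro-hb~yanco-2013~{node}", "treatment", treatment)
        store.create_entity(
            "stream", "canopy-temp", f"csiro-hb~yanco-2013~{node}", attrs={"unit": "degC"}
        )
        store.create_entity(
            "stream", "soil-moisture-30cm", f"csiro-hb~yanco-2013~{node}",
            attrs={"unit": "%vol"},
        )

all_streams = store.tree.filter_streams("csiro-hb")
print(f"streams in trial: {len(all_streams)}")

irrigated = store.tree.filter_streams(
    "csiro-hb", metadata_predicates=[("node", "treatment", "irrigated")]
)
print(f"streams under irrigated plots: {len(irrigated)}")

moisture = store.tree.filter_streams("csiro-hb", unit_pattern="%vol")
print(f"soil-moisture streams (by unit): {len(moisture)}")

both = store.tree.filter_streams(
    "csiro-hb",
    unit_pattern="%vol",
    metadata_predicates=[("node", "treatment", "irrigated")],
)
print("irrigated soil-moisture streams:")
for s in both:
    print(f"  {s.path}")

# 16 streams total; 8 under the 4 irrigated plots; the conjunction returns
# the 4 moisture streams of those plots, in deterministic name order.
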