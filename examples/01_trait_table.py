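"""Build a coded species trait table from raw database-style entries.

Raw trait records (one per database entry, with replication counts) are
coded per the standard grassland response-trait scheme — categorical
attributes to [0, 1] scores, height and leaf size natural-logged — and
averaged per species with replication weights.
"""

from grazefd.traits import DEFAULT_SCHEMES, RawTraitEntry, build_trait_table

entries = [
    # Festuca-like tussock grass: two LDMC entries with different replication
    RawTraitEntry("festuca", "ldmc_mg_per_g", 310.0, replication=12),
    RawTraitEntry("festuca", "ldmc_mg_per_g", 290.0, replication=4),
    RawTraitEntry("festuca", "sla_mm2_per_mg", 11.0, replication=8),
    RawTraitEntry("festuca", "canopy_height_m", 0.25),
    RawTraitEntry("festuca", "leaf_size_mm2", 120.0),
    RawTraitEntry("festuca", "flowering_start_month", 6),
    RawTraitEntry("festuca", "life_form", "Hemicryptophyte"),
    RawTraitEntry("festuca", "canopy_structure", "Erosulate"),
    RawTraitEntry("festuca", "leafing_period", "Evergreen"),
    RawTraitEntry("festuca", "life_span", "Perennial"),
    RawTraitEntry("festuca", "veg_spread_rhizome", "Not rhizomatous"),
    RawTraitEntry("festuca", "veg_spread_stolon", "Not stoloniferous"),
    # Trifolium-like legume: soft leaves, stoloniferous
    RawTraitEntry("trifolium", "ldmc_mg_per_g", 180.0, replication=9),
    RawTraitEntry("trifolium", "sla_mm2_per_mg", 28.0, replication=6),
    RawTraitEntry("trifolium", "canopy_height_m", 0.15),
    RawTraitEntry("trifolium", "leaf_size_mm2", 350.0),
    RawTraitEntry("trifolium", "flowering_start_month", 5),
    RawTraitEntry("trifolium", "life_form", "Hemicryptophyte"),
    RawTraitEntry("trifolium", "canopy_structure", "Hemirosette"),
    RawTraitEntry("trifolium", "leafing_period", "Summer green"),
    RawTraitEntry("trifolium", "life_span", "Perennial"),
    RawTraitEntry("trifolium", "veg_spread_rhizome", "Not rhizomatous"),
    RawTraitEntry("trifolium", "veg_spread_stolon", "Stoloniferous"),
]

table = build_trait_table(entries, DEFAULT_SCHEMES)
print(table.data.round(3).T)
print()
# festuca's LDMC is the replication-weighted mean (310*12 + 290*4)/16 = 305;
# canopy height is stored as its natural log; coded traits lie in [0, 1].
print("festuca LDMC (weighted mean):", table.data.at["festuca", "ldmc_mg_per_g"])
print("trait weights:", table.weights())
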