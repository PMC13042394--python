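"""Place every spot on the spot allocation plot (SAP).

SAP X = distance to the nearest enterocyte spot; SAP Y = distance to the
nearest smooth-muscle spot. Crypt spots sit near the muscle band (small Y)
and away from the villus epithelium (larger X), so the crypt occupies a
distinct corner of the SAP plane.
"""

import villustat as vs

spots, _, _ = vs.simulate_section(vs.wt_like_tissue(seed=0))
sap = vs.compute_sap(spots).merge(spots, on="spot_id")

for comp in ("smooth_muscle", "crypt", "lamina_propria", "enterocyte"):
    sub = sap[sap["compartment"] == comp]
    print(f"{comp:>15}: mean d_ent = {sub.d_ent.mean():6.1f} um, "
          f"mean d_sm = {sub.d_sm.mean():6.1f} um  (n={len(sub)})")

regions = vs.define_crypt_regions(spots, pitch=2.0)
print(f"\ncrypt regions found: {len(regions)} "
      f"(sizes: {[len(r) for r in regions]})")
# Each region is one connected block of crypt spots; immune spots within
# 3 spot-pitches of a region are attributed to it for proximity analysis.
region_map = vs.assign_spots_to_regions(spots, regions, radius_um=6.0)
print(f"immune spots assigned to a crypt region: {int(region_map.notna().sum())} "
      f"of {len(region_map)}")
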