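"""Chromosome-wide LRLD scan on a synthetic three-population panel.

Generates 500 diploids x 300 common variants per population, plants five
D' = 1 pairs >= 5 Mb apart (two shared by all populations, three specific to
EAS), scans all long-range pairs with the chi-square test under per-chromosome
BH-FDR, and summarizes recovery, population intersections and hotspots.
"""

import lrldscan as L

spec = L.PanelSpec(seed=42)
panels = L.generate_panel(spec)
pos = next(iter(panels.values())).variants["pos"].to_numpy()

plants = [
    L.PlantedLRLD(int(pos[0]), int(pos[150]), 1.0, ("AFR", "EUR", "EAS"), (0.3, 0.3)),
    L.PlantedLRLD(int(pos[1]), int(pos[151]), 1.0, ("AFR", "EUR", "EAS"), (0.3, 0.3)),
    L.PlantedLRLD(int(pos[2]), int(pos[152]), 1.0, ("EAS",), (0.3, 0.3)),
    L.PlantedLRLD(int(pos[3]), int(pos[153]), 1.0, ("EAS",), (0.3, 0.3)),
    L.PlantedLRLD(int(pos[4]), int(pos[154]), 1.0, ("EAS",), (0.3, 0.3)),
]
planted = L.plant_lrld(panels, plants, seed=43)

result = L.scan_pairs(planted, L.ScanConfig())
print(f"tested long-range pairs per population: {int(result.tested_pairs.sum())}")
print(f"FDR-significant records (pair x population): {len(result.records)}")

summary = L.population_intersections(result.records, result.tested_pairs)
counts = summary.counts["total"].loc["Sum"]
print("\nsignificant pair counts by population subset:")
print(counts.to_string())
print("\nexpected pairwise/triple intersections if populations were independent:")
print(summary.expected["total"].loc["Sum"].round(4).to_string())
print(
    "\nEAS exceeds AFR/EUR by the three EAS-specific plants; the shared plants "
    "drive the observed intersections far above their independence expectation."
)
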