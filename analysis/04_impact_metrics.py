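#!/usr/bin/env python
"""Impact metrics of the simulated delousing plume.

Reduces the dispersal run to the exposure quantities that matter for
northern shrimp: area and maximum reach of water that exceeded the lethal
2 ng/L threshold, the worst-cell accumulated exposure time, and the
contour polygons of the 2 and 200 ng/L levels.  Writes
results/impact_summary.json, results/plume_contours.geojson and a
maximum-concentration map figure.
"""

import importlib.util
import json
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results"
OUT.mkdir(exist_ok=True)

_spec = importlib.util.spec_from_file_location("sim", ROOT / "analysis" / "03_simulate_dispersal.py")
sim = importlib.util.module_from_spec(_spec)
_spec.loader.exec_module(sim)

from deltarisk.dispersal import max_map, time_above  # noqa: E402
from deltarisk.impact import (  # noqa: E402
    ThresholdSet,
    area_above,
    contour_polygons,
    contours_to_geojson,
    max_duration,
    max_extent,
)


def main(seed: int = 1) -> None:
    history, centre = sim.run(seed)
    grid = history.grid
    thresholds = ThresholdSet()
    mm = max_map(history)
    summary = []
    for thr in (thresholds.lethal_water, thresholds.contour_high):
        ta = time_above(history, thr)
        rec = {
            "threshold_ng_per_L": thr,
            "area_km2": area_above(mm, thr, grid.cell_area),
            "max_extent_km": max_extent(mm, thr, centre, grid),
            "max_duration_h": max_duration(ta),
        }
        summary.append(rec)
        print(f"> {thr:g} ng/L: {rec['area_km2']:.2f} km2 touched, up to "
              f"{rec['max_extent_km']:.1f} km from the pens, lethal for up to "
              f"{rec['max_duration_h']:.0f} h in the worst cell")

    polys = contour_polygons(mm, thresholds.lethal_water, grid)
    contours_to_geojson(polys, thresholds.lethal_water, OUT / "plume_contours.geojson")
    json.dump(summary, open(OUT / "impact_summary.json", "w"), indent=2)

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import LogNorm

    fig, ax = plt.subplots(figsize=(7, 6))
    masked = mm.copy()
    masked[masked < 0.01] = 0.01
    im = ax.pcolormesh(grid.x / 1000, grid.y / 1000, masked,
                       norm=LogNorm(vmin=0.1, vmax=2000), cmap="viridis")
    for level, style in ((2.0, "k-"), (200.0, "k--")):
        for p in contour_polygons(mm, level, grid):
            xs, ys = p.exterior.xy
            ax.plot([x / 1000 for x in xs], [y / 1000 for y in ys], style, lw=1)
    ax.plot(centre[0] / 1000, centre[1] / 1000, "r^", label="pens")
    ax.set_xlabel("km")
    ax.set_ylabel("km")
    ax.set_title("maximum concentration over 7 days (ng/L)")
    ax.set_xticks(range(0, 13))
    ax.set_yticks(range(0, 13))
    ax.grid(color="gray", lw=0.3)
    fig.colorbar(im, ax=ax)
    ax.legend()
    fig.savefig(OUT / "max_concentration_map.png", dpi=130)
    print(f"wrote {OUT / 'impact_summary.json'}, plume_contours.geojson, "
          f"max_concentration_map.png")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
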