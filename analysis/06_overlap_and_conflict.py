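"""Overlap analysis: turbine impact table, conflict maps, roost buffers.

Assigns every turbine the habitat class of its cell per season (the impact
table), intersects high-siting ground with seasonal habitat classes into
minimum/low/high potential-conflict maps, and counts turbines and
high-siting area within 100 km of each roost.
"""

import shutil

from common import RESULTS, WORKSPACE, ensure_dirs, study_config

from batwind.pipeline import stage_conflict, stage_overlap, stage_report


def main() -> None:
    ensure_dirs()
    cfg = study_config()
    impact = stage_overlap(cfg, WORKSPACE)
    print(f"turbine impact table ({impact['n_turbines']} turbines):")
    for season, row in impact["counts"].items():
        pct = impact["percentages"][season]
        print(f"  {season:>6}: unlikely {row['unlikely']:>3} ({pct['unlikely']:.1f}%)"
              f"  moderate {row['moderate']:>3} ({pct['moderate']:.1f}%)"
              f"  high {row['high']:>3} ({pct['high']:.1f}%)"
              f"  off-map {row['off_map']}")
    conflict_counts = stage_conflict(cfg, WORKSPACE)
    print("conflict cells on high-siting ground (minimum/low/high):")
    for season, c in conflict_counts.items():
        print(f"  {season:>6}: {c['minimum']:>5} / {c['low']:>5} / {c['high']:>5}")
    report = stage_report(cfg, WORKSPACE)
    print(f"turbines within {report['buffer_km']:.0f} km of any roost: "
          f"{report['pooled_turbines']}")
    for rel, dst in (("conflict/impact_table.csv", "06_impact_table.csv"),
                     ("conflict/impact_table.json", "06_impact_table.json"),
                     ("conflict/conflict_cell_counts.json",
                      "06_conflict_cell_counts.json"),
                     ("conflict/roost_report.json", "06_roost_report.json")):
        shutil.copy(WORKSPACE / rel, RESULTS / dst)


if __name__ == "__main__":
    main()
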