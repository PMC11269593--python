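"""Build the multi-criteria turbine-siting suitability map.

Reclassifies the six criteria to 0-4 scores, sums them under weights
{wind power class 3, roads 2, transmission 2, land cover 2, slope 2,
population 1} into the 0-48 composite, masks exclusions (military,
protected, 1-km airport buffers), cuts the low/moderate/high classes at
16/32, and checks where the existing turbines sit on that score scale.
"""

import shutil

from common import RESULTS, WORKSPACE, ensure_dirs, study_config

from batwind.pipeline import stage_build_siting


def main() -> None:
    ensure_dirs()
    info = stage_build_siting(study_config(), WORKSPACE)
    print(f"turbines kept after capacity/rotor filters: {info['n_turbines_kept']}")
    print(f"composite score range on valid ground: "
          f"{info['score_min']}..{info['score_max']} (bound 0..48)")
    print(f"fraction of turbines with score < {info['cutoff']}: "
          f"{info['fraction_below']:.3f}  ({info['n_nodata']} on excluded ground)")
    shutil.copy(WORKSPACE / "siting" / "turbine_quantile.json",
                RESULTS / "05_siting_summary.json")


if __name__ == "__main__":
    main()
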