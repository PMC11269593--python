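"""Generate the synthetic study scene.

Writes per-season environmental stacks (five continuous climate layers plus
land cover on a 100x100 1-km grid), the known-truth suitability surfaces,
raw occurrence records with realistic contamination, siting criteria on a
300-m grid, turbines biased toward high wind classes, and roosts.
"""

import json

from common import RESULTS, WORKSPACE, ensure_dirs, study_config

from batwind.pipeline import stage_simulate


def main() -> None:
    ensure_dirs()
    cfg = study_config()
    info = stage_simulate(cfg, WORKSPACE)
    print(f"scene written to {WORKSPACE / 'scene'}")
    print(f"  raw occurrence records : {info['n_raw_occurrences']}")
    print(f"  turbines placed        : {info['n_turbines']}")
    print(f"  variables per season   : {', '.join(info['variables'])}")
    (RESULTS / "01_scene_summary.json").write_text(
        json.dumps(info, indent=1, sort_keys=True))


if __name__ == "__main__":
    main()
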