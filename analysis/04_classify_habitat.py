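"""Reclassify seasonal suitability into three habitat classes.

The boundaries come from the training presences themselves: the suitability
value at the 10% training omission rate separates unsuitable from
low-to-moderate habitat, and the 50% value separates low-to-moderate from
high habitat.
"""

import json

from common import RESULTS, WORKSPACE, ensure_dirs, study_config

from batwind.pipeline import stage_classify_habitat


def main() -> None:
    ensure_dirs()
    info = stage_classify_habitat(study_config(), WORKSPACE)
    for season, t in info.items():
        print(f"{season:>6}: t_low = {t['t_low']:.4f}  t_high = {t['t_high']:.4f}"
              f"  (m = {t['m']} training presences)")
    (RESULTS / "04_habitat_thresholds.json").write_text(
        json.dumps(info, indent=1, sort_keys=True))


if __name__ == "__main__":
    main()
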