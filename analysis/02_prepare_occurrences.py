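"""Clean the raw occurrence records.

Keeps preserved specimens from the configured year window, splits records by
meteorological season, removes exact coordinate duplicates within season, and
rarefies each season with the 10-km window so no two retained records are
closer than the window. Prints the funnel of record counts.
"""

import shutil

from common import RESULTS, WORKSPACE, ensure_dirs, study_config

from batwind.pipeline import stage_prep_occ


def main() -> None:
    ensure_dirs()
    funnel = stage_prep_occ(study_config(), WORKSPACE)
    print(f"raw records: {funnel['raw']}  ->  after filters: {funnel['filtered']}")
    for season in ("spring", "summer", "fall", "winter"):
        f = funnel[season]
        print(f"  {season:>6}: split {f['split']:>4}  deduped {f['deduped']:>4}"
              f"  thinned {f['thinned']:>4}")
    shutil.copy(WORKSPACE / "occurrences" / "funnel.json",
                RESULTS / "02_occurrence_funnel.json")


if __name__ == "__main__":
    main()
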