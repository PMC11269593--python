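"""Shared setup for the numbered analysis drivers.

The full workspace (including rasters) lives under scratch/pipeline; the
small summary tables each driver reports land under results/.
"""

from pathlib import Path

from batwind.pipeline import PipelineConfig

ROOT = Path(__file__).resolve().parent.parent
WORKSPACE = ROOT / "scratch" / "pipeline"
RESULTS = ROOT / "results"


def study_config() -> PipelineConfig:
    """The documented study conditions: 100x100 1-km habitat grid, 4 seasons,
    ~150 raw records/season, 10,000 background points, 0.5-step rm grid."""
    return PipelineConfig()


def ensure_dirs() -> None:
    WORKSPACE.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)
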