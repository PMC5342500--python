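"""Shared configuration and paths for the numbered analysis scripts.

Every script reconstructs what it needs from this one seeded config, so
the whole analysis is reproducible end to end; heavier artifacts are
passed between scripts as TSV/CSV files under results/.
"""

from pathlib import Path

from anchornet.pipeline import PipelineConfig

CONFIG = PipelineConfig(seed=1)

ROOT = Path(__file__).resolve().parent.parent
DATA = ROOT / "results" / "data"
TABLES = ROOT / "results" / "tables"

for _d in (DATA, TABLES):
    _d.mkdir(parents=True, exist_ok=True)
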