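"""CSV readers/writers and the run manifest.

All tables are RFC-4180 CSV with a header row, UTF-8, '.' decimal
separator; clock times are HH:MM 24 h strings; missing values are empty
strings.  Floats are written with a fixed repr-stable format so that
rerunning with identical config and seeds yields byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

FLOAT_FORMAT = "%.10g"


def write_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT, na_rep="")
    return path


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, keep_default_na=True, na_values=[""])


def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(out_dir, config_dict: dict, seeds: dict, tables: list[str]) -> Path:
    """Record versions, seeds, config hash and output digests for a run."""
    out_dir = Path(out_dir)
    cfg_text = json.dumps(config_dict, sort_keys=True, default=str)
    manifest = {
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "seeds": seeds,
        "outputs": {
            name: file_digest(out_dir / name)
            for name in tables
            if (out_dir / name).exists()
        },
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path
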