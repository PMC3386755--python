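"""File formats: voltammogram CSV, manifests, config and stable JSON output.

Voltammogram CSV layout: header ``potential_mV,current_nA,segment`` with one
sample per row.  Floats are serialised with 6 significant digits everywhere,
which makes writer output byte-stable and write/read round trips exact.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError
from .geometry import Nanotube, ProteinPrism
from .voltammetry import Voltammogram

CSV_COLUMNS = ("potential_mV", "current_nA", "segment")
FLOAT_FORMAT = "%.6g"


def write_voltammogram_csv(v: Voltammogram, path: str | Path) -> None:
    df = pd.DataFrame(
        {"potential_mV": v.potential, "current_nA": v.current, "segment": v.segment}
    )
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_voltammogram_csv(path: str | Path) -> Voltammogram:
    """Parse a voltammogram CSV; validates columns and sweep invariants."""
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")
    return Voltammogram(
        potential=df["potential_mV"].to_numpy(dtype=float),
        current=df["current_nA"].to_numpy(dtype=float),
        segment=df["segment"].to_numpy(dtype=str),
    )


def _round_floats(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {k: _round_floats(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v) for v in obj]
    if isinstance(obj, (float, np.floating)):
        return float(f"{float(obj):.6g}")
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def write_json(data: dict, path: str | Path) -> None:
    """Byte-stable JSON: sorted keys, 6-significant-digit floats."""
    Path(path).write_text(json.dumps(_round_floats(data), sort_keys=True, indent=1) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def config_hash(config: dict) -> str:
    """Short stable fingerprint of a configuration dict."""
    canon = json.dumps(_round_floats(config), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def load_geometry_config(path: str | Path) -> tuple[ProteinPrism, Nanotube, float]:
    """Load ``{protein: {...}, tube: {...}, cutoff}`` from YAML or JSON."""
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: expected a mapping at top level")
    from .geometry import DEFAULT_CONTACT_CUTOFF

    protein = ProteinPrism(**cfg.get("protein", {}))
    tube = Nanotube(**cfg.get("tube", {}))
    cutoff = float(cfg.get("cutoff", DEFAULT_CONTACT_CUTOFF))
    return protein, tube, cutoff
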