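"""Stable JSON serialization for solutions and reports.

Output is byte-reproducible: keys are sorted and every float is reduced to six
significant digits before encoding, so identical runs write identical bytes.
"""

from __future__ import annotations

import json
import math
from typing import Any


def round_sig(x: float, sig: int = 6) -> float:
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, sig - 1 - int(math.floor(math.log10(abs(x)))))


def _normalize(obj: Any) -> Any:
    if isinstance(obj, float):
        if math.isinf(obj):
            return "inf" if obj > 0 else "-inf"
        return round_sig(obj)
    if isinstance(obj, dict):
        return {k: _normalize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_normalize(v) for v in obj]
    return obj


def stable_json(obj: Any) -> str:
    """Deterministic JSON text (sorted keys, 6-significant-digit floats)."""
    return json.dumps(_normalize(obj), sort_keys=True, indent=1)


def write_stable_json(obj: Any, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(stable_json(obj))
        fh.write("\n")
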