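"""Small shared helpers: display rounding and provenance records."""

from __future__ import annotations

import hashlib
import json
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero, as printed tables do (3.5 -> 4, not 4 -> banker's).

    Computation elsewhere always uses unrounded values; this is display-only.
    """
    q = Decimal(1).scaleb(-ndigits)
    v = float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
    return int(v) if ndigits <= 0 else v


def display_percent(x: float) -> float:
    """Percentage display at two significant figures, half-up.

    Matches the printed-table convention (43, 4.6, 0.23, 0.038, ...):
    integers at or above 10, finer precision as the value shrinks.
    """
    if x == 0:
        return 0.0
    import math

    ndigits = 1 - math.floor(math.log10(abs(x)))
    return round_half_up(x, max(ndigits, 0))


def content_hash(obj) -> str:
    """Stable sha256 of a DataFrame / array / string, for provenance records."""
    if hasattr(obj, "to_csv"):
        payload = obj.to_csv(sep="\t").encode()
    elif isinstance(obj, (bytes, bytearray)):
        payload = bytes(obj)
    else:
        payload = str(obj).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def write_provenance(path, operation: str, params: dict, input_hash: str | None = None) -> None:
    record = {"operation": operation, "params": params}
    if input_hash is not None:
        record["input_hash"] = input_hash
    Path(path).write_text(json.dumps(record, indent=2, default=str) + "\n")
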