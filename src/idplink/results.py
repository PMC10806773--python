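"""Common machinery for fit-result objects.

Every analysis stage returns a frozen dataclass deriving from
:class:`FitResult`.  Results serialize to flat JSON records (numpy arrays as
lists, nested results recursively) and deserialize bit-exactly for finite
doubles, so written records double as machine-readable provenance.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Any, ClassVar

import numpy as np

__all__ = ["FitResult", "result_to_dict", "result_from_dict"]

_REGISTRY: dict[str, type] = {}


def _encode(value: Any) -> Any:
    if isinstance(value, FitResult):
        return result_to_dict(value)
    if isinstance(value, np.ndarray):
        return {"__ndarray__": value.tolist()}
    if isinstance(value, (np.floating, np.integer)):
        return value.item()
    if isinstance(value, dict):
        return {str(k): _encode(v) for k, v in value.items()}
    if isinstance(value, (list, tuple)):
        return [_encode(v) for v in value]
    return value


def _decode(value: Any) -> Any:
    if isinstance(value, dict):
        if "__ndarray__" in value:
            return np.asarray(value["__ndarray__"], dtype=float)
        if "__result__" in value:
            return result_from_dict(value)
        return {k: _decode(v) for k, v in value.items()}
    if isinstance(value, list):
        return [_decode(v) for v in value]
    return value


def result_to_dict(result: "FitResult") -> dict:
    payload = {
        f.name: _encode(getattr(result, f.name))
        for f in dataclasses.fields(result)
    }
    return {"__result__": type(result).__name__, "fields": payload}


def result_from_dict(record: dict) -> "FitResult":
    cls = _REGISTRY.get(record["__result__"])
    if cls is None:
        raise KeyError(f"unknown result type {record['__result__']!r}")
    fields = {k: _decode(v) for k, v in record["fields"].items()}
    return cls(**fields)


class FitResult:
    """Base class: registration, JSON round-trip, and a plain-text summary."""

    _summary_title: ClassVar[str] = "Fit result"

    def __init_subclass__(cls, **kwargs):
        super().__init_subclass__(**kwargs)
        _REGISTRY[cls.__name__] = cls

    def to_dict(self) -> dict:
        return result_to_dict(self)

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def summary(self) -> str:
        """Human-readable parameter table."""
        lines = [self._summary_title, "=" * len(self._summary_title)]
        for f in dataclasses.fields(self):
            value = getattr(self, f.name)
            if isinstance(value, np.ndarray):
                desc = f"array(n={value.size})"
            elif isinstance(value, FitResult):
                desc = type(value).__name__
            elif isinstance(value, float):
                desc = f"{value:.6g}"
            else:
                desc = repr(value)
            lines.append(f"{f.name:>24s}  {desc}")
        return "\n".join(lines)
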