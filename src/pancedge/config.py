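"""Run configuration: every knob that influences a score, in one place.

Configs round-trip through a flat, comment-friendly ``key = value`` text
format. Seeds are always explicit — no wall-clock randomness anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

from .edgecore import CannyParams
from .errors import PancedgeError
from .pmscore import DEFAULT_THRESHOLD_PX, params_fingerprint

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Configuration for scoring and simulation runs."""

    canny_sigma: float = 1.0
    canny_high_quantile: float = 0.90
    canny_low_fraction: float = 0.4
    knot_spacing: float | None = None  # None -> ROI width / 4
    roi_height: int = 40
    roi_width: int = 40
    threshold: float = DEFAULT_THRESHOLD_PX
    subpixel: bool = False
    seed: int = 0
    log_level: str = "INFO"

    def canny(self) -> CannyParams:
        return CannyParams(
            sigma=self.canny_sigma,
            high_quantile=self.canny_high_quantile,
            low_fraction=self.canny_low_fraction,
        )

    def effective_knot_spacing(self, roi_width: int | None = None) -> float:
        if self.knot_spacing is not None:
            return self.knot_spacing
        return (roi_width if roi_width is not None else self.roi_width) / 4.0

    def fingerprint(self, roi_width: int | None = None) -> str:
        return params_fingerprint(
            self.canny(), self.effective_knot_spacing(roi_width), self.subpixel
        )

    def to_file(self, path) -> Path:
        path = Path(path)
        lines = ["# pancedge run configuration"]
        for f in fields(self):
            value = getattr(self, f.name)
            lines.append(f"{f.name} = {'' if value is None else value}")
        path.write_text("\n".join(lines) + "\n")
        return path

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise PancedgeError(f"config file not found: {path}")
        known = {f.name: f for f in fields(cls)}
        kwargs = {}
        for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise PancedgeError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
            key, value = (part.strip() for part in line.split("=", 1))
            if key not in known:
                raise PancedgeError(f"{path}:{lineno}: unknown config key {key!r}")
            kwargs[key] = _parse(key, value)
        return cls(**kwargs)


def _parse(key: str, value: str):
    if value == "":
        return None
    if key in ("roi_height", "roi_width", "seed"):
        return int(value)
    if key == "subpixel":
        return value.lower() in ("1", "true", "yes", "on")
    if key == "log_level":
        return value
    return float(value)
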