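"""Analysis configuration: explicit defaults, YAML round-trip."""

from __future__ import annotations

from dataclasses import asdict, dataclass

import yaml

from vesselmetrics.images import ParameterError


@dataclass
class AnalysisConfig:
    """All tunable knobs of the analysis pipeline.

    Every run should write its resolved config next to its results so the
    numbers are reproducible without guessing defaults.
    """

    threshold_window_px: int = 51
    threshold_offset: float = 10.0
    tile_um: float = 100.0
    separation_mode: str = "auto"  # "auto" or "manual"
    z_ranges: list[tuple[int, int]] | None = None  # inclusive slice ranges, manual mode
    smooth_window: int = 3  # slices, moving average for auto plexus separation
    deviation_decimals: int = 2
    change_decimals: int = 1

    def __post_init__(self) -> None:
        if self.threshold_window_px < 3 or self.threshold_window_px % 2 == 0:
            raise ParameterError("threshold_window_px must be odd and >= 3")
        if self.separation_mode not in ("auto", "manual"):
            raise ParameterError(f"unknown separation_mode {self.separation_mode!r}")
        if self.separation_mode == "manual" and not self.z_ranges:
            raise ParameterError("manual separation requires z_ranges")
        if self.z_ranges is not None:
            self.z_ranges = [tuple(int(v) for v in r) for r in self.z_ranges]
            if len(self.z_ranges) != 3:
                raise ParameterError("z_ranges must list exactly three (start, stop) pairs")
            for a, b in self.z_ranges:
                if b < a:
                    raise ParameterError(f"z-range {a}:{b} is reversed")
            for (_, b), (a2, _) in zip(self.z_ranges, self.z_ranges[1:]):
                if a2 <= b:
                    raise ParameterError("z_ranges must be increasing and non-overlapping")
        if self.smooth_window < 1 or self.smooth_window % 2 == 0:
            raise ParameterError("smooth_window must be odd and >= 1")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
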