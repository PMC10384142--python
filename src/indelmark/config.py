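"""Run configuration for the InDel marker pipeline.

The defaults encode the screening protocol used throughout the package:
per-genotype minimum depth 10 and genotype quality 30, at most 20% missing
calls per locus, the balanced '303' polymorphic type as the marker target,
a 15-100 bp size-difference window for gel-resolvable fragments, a >200 bp
contig-edge clearance for primer design, and a 30 bp threshold above which
an unexpected fragment is scored as a novel (C/D) allele.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path


@dataclass(frozen=True)
class RunConfig:
    min_depth: int = 10
    min_gq: int = 30
    max_missing_fraction: float = 0.2
    target_code: str = "303"
    min_size_diff: int = 15
    max_size_diff: int = 100
    min_edge_distance: int = 200
    novel_allele_threshold: int = 30
    fragment_tolerance: int = 5
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.min_size_diff > self.max_size_diff:
            raise ValueError(
                f"min_size_diff ({self.min_size_diff}) exceeds "
                f"max_size_diff ({self.max_size_diff})"
            )
        for name in (
            "min_depth",
            "min_gq",
            "min_size_diff",
            "max_size_diff",
            "min_edge_distance",
            "novel_allele_threshold",
            "fragment_tolerance",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.max_missing_fraction <= 1.0:
            raise ValueError("max_missing_fraction must lie in [0, 1]")
        if not (len(self.target_code) == 3 and self.target_code.isdigit()):
            raise ValueError("target_code must be a three-digit string like '303'")


def load_config(path: str | Path) -> RunConfig:
    """Read a RunConfig from a flat ``key = value`` text file.

    Lines starting with ``#`` and blank lines are ignored; unknown keys are
    rejected so typos do not silently fall back to defaults.
    """
    kwargs: dict[str, object] = {}
    field_types = {f.name: f.type for f in fields(RunConfig)}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        if key not in field_types:
            raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
        if key == "target_code":
            kwargs[key] = value.strip("'\"")
        elif key == "max_missing_fraction":
            kwargs[key] = float(value)
        else:
            kwargs[key] = int(value)
    return RunConfig(**kwargs)  # type: ignore[arg-type]
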