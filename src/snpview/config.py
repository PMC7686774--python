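"""Dataset registry configuration.

A YAML file names the VCF datasets available to the CLI and sets display
defaults. Comparisons are only valid within one dataset (one reference
assembly), so each dataset is a self-contained unit::

    datasets:
      - name: soy_demo
        vcf: /data/soy_demo.vcf.gz
        display_name: Soy demo panel
    defaults:
      bin_size: 500000
      ruler_interval: 5000000
      palette: ["#cc0000", "#008800", "#0044cc"]
      output_dir: out

Validation reports every problem at once rather than stopping at the first.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import yaml

PathLike = Union[str, Path]

DEFAULT_BIN_SIZE = 500_000  # 500 kb
DEFAULT_RULER_INTERVAL = 5_000_000
DEFAULT_PALETTE = [
    "#cc0000", "#008800", "#0044cc", "#e69f00",
    "#56b4e9", "#cc79a7", "#999999", "#7b3294",
]


@dataclass
class DatasetEntry:
    name: str
    vcf: str
    display_name: Optional[str] = None


@dataclass
class Config:
    datasets: list[DatasetEntry] = field(default_factory=list)
    bin_size: int = DEFAULT_BIN_SIZE
    ruler_interval: int = DEFAULT_RULER_INTERVAL
    palette: list[str] = field(default_factory=lambda: list(DEFAULT_PALETTE))
    output_dir: str = "."

    def dataset(self, name: str) -> DatasetEntry:
        for d in self.datasets:
            if d.name == name:
                return d
        raise KeyError(
            f"unknown dataset {name!r}; configured: "
            f"{', '.join(d.name for d in self.datasets) or '(none)'}"
        )


def load_config(path: PathLike) -> Config:
    """Parse and validate a configuration file, filling defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    problems: list[str] = []

    entries: list[DatasetEntry] = []
    seen: set[str] = set()
    for i, item in enumerate(raw.get("datasets", []) or []):
        name = item.get("name")
        vcf = item.get("vcf")
        if not name:
            problems.append(f"datasets[{i}]: missing 'name'")
            continue
        if name in seen:
            problems.append(f"datasets[{i}]: duplicate dataset name {name!r}")
            continue
        seen.add(name)
        if not vcf:
            problems.append(f"dataset {name!r}: missing 'vcf' path")
            continue
        if not Path(vcf).exists():
            problems.append(f"dataset {name!r}: VCF path {vcf!r} does not exist")
            continue
        entries.append(DatasetEntry(name=name, vcf=str(vcf),
                                    display_name=item.get("display_name")))

    defaults = raw.get("defaults", {}) or {}
    bin_size = int(defaults.get("bin_size", DEFAULT_BIN_SIZE))
    ruler_interval = int(defaults.get("ruler_interval", DEFAULT_RULER_INTERVAL))
    palette = list(defaults.get("palette", DEFAULT_PALETTE))
    if bin_size < 1:
        problems.append(f"defaults.bin_size must be >= 1, got {bin_size}")
    if not palette:
        problems.append("defaults.palette must not be empty")

    if problems:
        raise ValueError(
            f"{path}: invalid configuration:\n  - " + "\n  - ".join(problems)
        )
    return Config(
        datasets=entries,
        bin_size=bin_size,
        ruler_interval=ruler_interval,
        palette=palette,
        output_dir=str(defaults.get("output_dir", ".")),
    )
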