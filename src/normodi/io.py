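"""Reading and writing the pipeline's tab-separated formats.

The canonical table dialect is UTF-8 TSV with a header row, samples as rows
and a leading identifier column.  Empty cells and ``NA`` are read as missing
measurements; they are flagged (NaN), never silently zeroed.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import AbundanceTable, SampleMetadata

__all__ = [
    "read_abundance_table",
    "write_abundance_table",
    "read_metadata",
    "write_metadata",
    "PipelineConfig",
    "read_config",
]

log = logging.getLogger("normodi")

_MISSING_MARKERS = ["", "NA"]

_TRANSFORMS = ("relative", "clr", "log-relative")


def read_abundance_table(
    path: str | Path,
    orientation: str = "samples-as-rows",
    state: str = "raw",
) -> AbundanceTable:
    """Read a TSV abundance table.

    Parameters
    ----------
    path
        File with a header row; the first column holds identifiers.
    orientation
        ``samples-as-rows`` (canonical) or ``features-as-rows`` (the table is
        transposed after reading).
    state
        State to stamp on the resulting table (``raw`` unless the file is
        known to hold relative or transformed values).
    """
    if orientation not in ("samples-as-rows", "features-as-rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        frame = pd.read_csv(
            path,
            sep="\t",
            index_col=0,
            na_values=_MISSING_MARKERS,
            keep_default_na=False,
            float_precision="round_trip",
        )
    except pd.errors.ParserError as exc:  # ragged rows and friends
        raise ValueError(f"{path}: malformed table ({exc})") from exc
    if orientation == "features-as-rows":
        frame = frame.T
    for axis, kind in ((frame.index, "sample"), (frame.columns, "feature")):
        if axis.has_duplicates:
            dups = axis[axis.duplicated()].unique().tolist()
            raise ValueError(f"{path}: duplicate {kind} identifiers: {dups}")
    # any column left non-numeric holds an unparsable cell: name it
    for col in frame.columns:
        if frame[col].dtype == object:
            for sample, value in frame[col].items():
                if pd.isna(value):
                    continue
                try:
                    float(value)
                except (TypeError, ValueError):
                    raise ValueError(
                        f"{path}: cell (sample {sample!r}, feature {col!r}) "
                        f"value {value!r} is not a non-negative real"
                    ) from None
            frame[col] = frame[col].astype(float)
    values = frame.to_numpy(dtype=float)
    neg = np.argwhere(values < 0)
    if neg.size:
        r, c = neg[0]
        raise ValueError(
            f"{path}: negative value {values[r, c]} at "
            f"(sample {frame.index[r]!r}, feature {frame.columns[c]!r})"
        )
    table = AbundanceTable(frame.astype(float), state=state)
    log.info("read %s: %d samples x %d features", path, *table.shape)
    return table


def write_abundance_table(table: AbundanceTable, path: str | Path) -> None:
    """Write a table to TSV at full (round-tripping) precision."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = table.data.copy()
    out.index.name = out.index.name or "sample_id"
    out.to_csv(path, sep="\t", na_rep="NA", float_format="%.17g")


def read_metadata(path: str | Path) -> SampleMetadata:
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    frame.index.name = "sample_id"
    return SampleMetadata(frame)


def write_metadata(metadata: SampleMetadata, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    metadata.frame.to_csv(path, sep="\t")


@dataclass
class PipelineConfig:
    """Pipeline-wide tunables with bounds enforced at construction.

    ``lda_threshold`` and ``kw_alpha`` hold the discriminatory-feature gate
    (log10 LDA score > 2 and Kruskal-Wallis p < 0.05 by default).
    """

    pseudocount: float | None = None  # None -> half the smallest nonzero value
    variance_target: float = 0.90
    alpha: float = 0.05
    lda_threshold: float = 2.0
    kw_alpha: float = 0.05
    seed: int = 0
    transform: str = "clr"

    def __post_init__(self) -> None:
        if self.pseudocount is not None and not self.pseudocount > 0:
            raise ValueError(f"pseudocount must be positive, got {self.pseudocount}")
        if not 0 < self.variance_target <= 1:
            raise ValueError(f"variance_target must be in (0,1], got {self.variance_target}")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")
        if not 0 < self.kw_alpha < 1:
            raise ValueError(f"kw_alpha must be in (0,1), got {self.kw_alpha}")
        if not (isinstance(self.seed, (int, np.integer)) and self.seed >= 0):
            raise ValueError(f"seed must be a non-negative integer, got {self.seed!r}")
        if self.transform not in _TRANSFORMS:
            raise ValueError(f"transform must be one of {_TRANSFORMS}, got {self.transform!r}")

    def replace(self, **overrides) -> "PipelineConfig":
        """New config with ``overrides`` applied (None values ignored)."""
        clean = {k: v for k, v in overrides.items() if v is not None}
        return dataclasses.replace(self, **clean)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


_CONFIG_CASTS = {
    "pseudocount": float,
    "variance_target": float,
    "alpha": float,
    "lda_threshold": float,
    "kw_alpha": float,
    "seed": int,
    "transform": str,
}


def read_config(path: str | Path) -> PipelineConfig:
    """Load a flat ``key = value`` (or ``key\\tvalue``) config file."""
    values: dict = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" in line:
            key, _, val = line.partition("=")
        elif "\t" in line:
            key, _, val = line.partition("\t")
        else:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, val = key.strip(), val.strip()
        if key not in _CONFIG_CASTS:
            raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
        values[key] = _CONFIG_CASTS[key](val)
    return PipelineConfig(**values)
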