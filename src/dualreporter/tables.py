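"""Reading, validating and summarising per-cell measurement tables.

Tables are plain CSV with a header row, one row per measured cell:
``experiment_id, animal_id, ring, cell_id, nucleus_count`` followed by one
mean-intensity column per channel (canonically ``ch_green``, ``ch_red``,
``ch_blue``).  Intensities are in arbitrary units; binucleate cells store
the two-nucleus average, flagged by ``nucleus_count == 2``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import pandas as pd
import yaml

KEY_COLUMNS = ("experiment_id", "animal_id", "ring", "cell_id")
MANDATORY_COLUMNS = KEY_COLUMNS
CHANNEL_PREFIX = "ch_"
MIN_RING, MAX_RING = 1, 9


@dataclass
class ParseReport:
    """Outcome of reading a cells CSV: row counts and per-row rejections."""
    rows_read: int = 0
    rows_kept: int = 0
    rejected: List[Tuple[int, str]] = field(default_factory=list)

    @property
    def rows_rejected(self) -> int:
        return len(self.rejected)


def detect_channels(columns: Sequence[str]) -> List[str]:
    return [c for c in columns if c.startswith(CHANNEL_PREFIX)]


def read_cells(path, config: Mapping | None = None
               ) -> Tuple[pd.DataFrame, ParseReport]:
    """Read and validate a per-cell CSV.

    ``config`` may provide ``columns`` (role -> CSV column name, for exports
    with tool-specific headers) and ``channels`` (channel name -> column).
    Without it, canonical names are assumed and every ``ch_*`` column is a
    channel.  Rows with non-numeric/negative intensities, rings outside 1-9
    or bad nucleus counts are rejected individually (with CSV line numbers
    in the report); a missing mandatory column or duplicate cell key is an
    error for the whole file.
    """
    raw = pd.read_csv(path)
    rename: Dict[str, str] = {}
    channels: List[str]
    if config:
        for role, col in (config.get("columns") or {}).items():
            rename[col] = role
        channel_map = config.get("channels") or {}
        for name, col in channel_map.items():
            rename[col] = name
        channels = list(channel_map) or detect_channels(
            [rename.get(c, c) for c in raw.columns])
    else:
        channels = detect_channels(raw.columns)
    if rename:
        raw = raw.rename(columns=rename)

    for col in MANDATORY_COLUMNS:
        if col not in raw.columns:
            raise ValueError(f"missing column: {col}")
    if not channels:
        raise ValueError("no channel columns found (expected columns named "
                         f"'{CHANNEL_PREFIX}*' or a channels config block)")
    if "nucleus_count" not in raw.columns:
        raw["nucleus_count"] = 1

    report = ParseReport(rows_read=len(raw))
    ring = pd.to_numeric(raw["ring"], errors="coerce")
    nuc = pd.to_numeric(raw["nucleus_count"], errors="coerce")
    intens = {ch: pd.to_numeric(raw[ch], errors="coerce") for ch in channels}

    reasons = pd.Series("", index=raw.index)
    bad_ring = ring.isna() | (ring != ring.round()) | \
        (ring < MIN_RING) | (ring > MAX_RING)
    reasons[bad_ring & (reasons == "")] = "invalid ring (must be integer 1-9)"
    bad_nuc = nuc.isna() | ~nuc.isin([1, 2])
    reasons[bad_nuc & (reasons == "")] = "invalid nucleus_count (must be 1 or 2)"
    for ch, vals in intens.items():
        bad = vals.isna()
        reasons[bad & (reasons == "")] = f"non-numeric intensity in {ch}"
        neg = vals < 0
        reasons[neg & (reasons == "")] = f"negative intensity in {ch}"

    for idx in raw.index[reasons != ""]:
        # +2: header line plus 1-based numbering
        report.rejected.append((int(idx) + 2, reasons[idx]))

    keep = reasons == ""
    out = raw.loc[keep, list(MANDATORY_COLUMNS) + ["nucleus_count"]].copy()
    out["ring"] = ring[keep].astype(int)
    out["nucleus_count"] = nuc[keep].astype(int)
    for ch in channels:
        out[ch] = intens[ch][keep].astype(float)
    out = out.reset_index(drop=True)

    dup = out.duplicated(subset=list(KEY_COLUMNS))
    if dup.any():
        first = out.loc[dup.idxmax(), list(KEY_COLUMNS)].tolist()
        raise ValueError(f"duplicate cell key: {tuple(first)}")
    report.rows_kept = len(out)
    return out, report


def write_cells(cells: pd.DataFrame, path) -> None:
    cells.to_csv(path, index=False)


def summarize_per_animal(cells: pd.DataFrame,
                         channels: Sequence[str] | None = None
                         ) -> pd.DataFrame:
    """Per-animal, per-channel unweighted mean over that animal's cells.

    Mirrors the whole-intestine summaries used for animal-resolution
    correlations: each animal contributes the plain average of its measured
    cells, with the contributing cell count recorded as ``n_cells``.
    """
    if channels is None:
        channels = detect_channels(cells.columns)
    if cells.empty:
        warnings.warn("summarize_per_animal: empty input table",
                      stacklevel=2)
        return pd.DataFrame(
            columns=["experiment_id", "animal_id", *channels, "n_cells"])
    grouped = cells.groupby(["experiment_id", "animal_id"], sort=True)
    out = grouped[list(channels)].mean()
    out["n_cells"] = grouped.size()
    return out.reset_index()


def load_config(path) -> dict:
    """Load a YAML run/analysis config (channels, pair, grouping, options)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg
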