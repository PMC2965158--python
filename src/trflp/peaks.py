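"""Chromatogram peak matching, multi-enzyme consensus, and taxon tallies.

Observed T-RFLP peaks come from fragment-analysis software as tables of
fragment size (often fractional, from interpolation against the size
standard) with peak height and area.  Because measured sizes drift from
true nucleotide counts, predictions are matched to peaks within a size
tolerance (default +/- 2 nt).  Because unrelated taxa can share a T-RF
under one enzyme, robust labels require a sequence's predictions to
match observed peaks under two or more enzymes ("consensus").

Peaks may be matched by multiple predictions (many-to-one): distinct
taxa sharing a fragment size is precisely the ambiguity the consensus
step quantifies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .trf_core import TRFPrediction, truncate_lineage

logger = logging.getLogger(__name__)

DEFAULT_TOLERANCE = 2.0


@dataclass(frozen=True)
class Peak:
    size: float
    height: float | None = None
    area: float | None = None


@dataclass(frozen=True)
class PeakTable:
    """Observed peaks for one enzyme, sorted by fragment size."""

    enzyme: str
    peaks: tuple[Peak, ...]

    def __post_init__(self) -> None:
        sizes = [p.size for p in self.peaks]
        if any(s < 0 for s in sizes):
            raise ValueError("peak sizes must be >= 0")
        if sizes != sorted(sizes):
            object.__setattr__(
                self, "peaks", tuple(sorted(self.peaks, key=lambda p: p.size))
            )

    @property
    def sizes(self) -> list[float]:
        return [p.size for p in self.peaks]

    @property
    def has_areas(self) -> bool:
        return bool(self.peaks) and all(p.area is not None for p in self.peaks)


@dataclass(frozen=True)
class PeakMatch:
    """A prediction matched to its nearest observed peak within tolerance."""

    sample_id: str
    enzyme: str
    peak_size: float
    predicted: float
    delta: float
    lineage: str | None
    rank: int | None = None


def load_peak_table(path: str | Path, enzyme: str) -> PeakTable:
    """Read a peak CSV with columns ``size[,height][,area]``.

    Rows with unparsable or negative sizes are rejected with a
    diagnostic; a file with no parsable rows is an error.
    """
    df = pd.read_csv(path)
    cols = {c.lower().strip(): c for c in df.columns}
    if "size" not in cols:
        raise ValueError(f"{path}: peak CSV needs a 'size' column, found {list(df.columns)}")
    peaks: list[Peak] = []
    for idx, row in df.iterrows():
        try:
            size = float(row[cols["size"]])
        except (TypeError, ValueError):
            logger.warning("%s: row %d has unparsable size %r; rejected",
                           path, idx, row[cols["size"]])
            continue
        if not np.isfinite(size) or size < 0:
            logger.warning("%s: row %d has invalid size %r; rejected", path, idx, size)
            continue
        height = _opt_float(row, cols.get("height"))
        area = _opt_float(row, cols.get("area"))
        peaks.append(Peak(size=size, height=height, area=area))
    if not peaks:
        raise ValueError(f"{path}: no parsable peak rows")
    table = PeakTable(enzyme=enzyme, peaks=tuple(peaks))
    if not table.has_areas:
        logger.warning("%s: peak areas missing; relative-abundance output disabled", path)
    return table


def _opt_float(row, col) -> float | None:
    if col is None:
        return None
    val = row[col]
    try:
        f = float(val)
    except (TypeError, ValueError):
        return None
    return f if np.isfinite(f) else None


def write_peak_table(table: PeakTable, path: str | Path) -> None:
    pd.DataFrame(
        {
            "size": [p.size for p in table.peaks],
            "height": [p.height for p in table.peaks],
            "area": [p.area for p in table.peaks],
        }
    ).to_csv(path, index=False)


def match_to_peaks(
    predictions: list[TRFPrediction],
    table: PeakTable,
    tolerance: float = DEFAULT_TOLERANCE,
) -> list[PeakMatch]:
    """Match each prediction to the nearest observed peak within tolerance.

    Ties in distance go to the smaller peak size.  Predictions lacking
    an estimated length, or without a peak in range, are unmatched and
    simply omitted.  Matching is independent per prediction, so many
    predictions may share one peak.
    """
    matches: list[PeakMatch] = []
    sizes = table.sizes
    for pred in predictions:
        if pred.enzyme != table.enzyme:
            raise ValueError(
                f"prediction enzyme {pred.enzyme!r} does not match table "
                f"enzyme {table.enzyme!r}"
            )
        if pred.est_fragment_length is None:
            continue
        best: float | None = None
        for size in sizes:
            d = abs(size - pred.est_fragment_length)
            if d > tolerance:
                continue
            if best is None or d < abs(best - pred.est_fragment_length):
                best = size
            # equal distance: sizes are scanned ascending, keep the smaller
        if best is not None:
            matches.append(PeakMatch(
                sample_id=pred.sample_id, enzyme=pred.enzyme,
                peak_size=best, predicted=float(pred.est_fragment_length),
                delta=best - pred.est_fragment_length,
                lineage=pred.lineage, rank=pred.rank,
            ))
    return matches


def multi_enzyme_consensus(
    matches_by_enzyme: dict[str, list[PeakMatch]],
    required: int = 2,
) -> set[str]:
    """Sample ids whose predictions hit observed peaks under >= ``required`` enzymes.

    With ``required`` equal to the number of enzymes this is the strict
    intersection that yields the most robust taxon labels.
    """
    if required < 1:
        raise ValueError("required must be >= 1")
    if required > len(matches_by_enzyme):
        raise ValueError(
            f"required={required} exceeds the {len(matches_by_enzyme)} enzyme tables given"
        )
    support: dict[str, int] = {}
    for matches in matches_by_enzyme.values():
        for sid in {m.sample_id for m in matches}:
            support[sid] = support.get(sid, 0) + 1
    return {sid for sid, n in support.items() if n >= required}


def tally_taxa(
    consensus_ids: set[str],
    predictions: list[TRFPrediction],
    rank: int = 4,
) -> dict[str, int]:
    """Count consensus samples per (rank-truncated) taxon.

    Each sample contributes once, via the lineage of its best (rank-1)
    prediction.  Returns counts in descending order plus a ``Total``
    entry equal to the consensus size.
    """
    lineage_of: dict[str, str] = {}
    for pred in predictions:
        if pred.sample_id in consensus_ids and pred.lineage is not None:
            if pred.sample_id not in lineage_of or (pred.rank or 1) == 1:
                lineage_of[pred.sample_id] = truncate_lineage(pred.lineage, rank)
    missing = consensus_ids - set(lineage_of)
    if missing:
        raise ValueError(f"no lineage available for consensus ids: {sorted(missing)[:5]}")
    counts: dict[str, int] = {}
    for taxon in lineage_of.values():
        counts[taxon] = counts.get(taxon, 0) + 1
    ordered = dict(sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])))
    ordered["Total"] = len(consensus_ids)
    return ordered


def relative_abundance(table: PeakTable) -> dict[float, float]:
    """Per-peak fraction of total peak area (a proxy for T-RF abundance)."""
    if not table.has_areas:
        raise ValueError(f"peak table for {table.enzyme} has no areas")
    total = sum(p.area for p in table.peaks)  # type: ignore[misc]
    if total <= 0:
        raise ValueError("total peak area is zero")
    return {p.size: p.area / total for p in table.peaks}  # type: ignore[operator]


def fit_size_drift(anchors: list[tuple[float, float]]) -> tuple[float, float]:
    """Fit observed = a + b * predicted on user-supplied anchor pairs.

    Optional preprocessing for systematic electrophoretic drift; apply
    with :func:`correct_predicted_sizes`.  Off by default.
    """
    if len(anchors) < 2:
        raise ValueError("need at least 2 anchor pairs")
    pred = np.array([p for p, _ in anchors], dtype=float)
    obs = np.array([o for _, o in anchors], dtype=float)
    b, a = np.polyfit(pred, obs, 1)
    return float(a), float(b)


def correct_predicted_sizes(predicted: list[float], drift: tuple[float, float]) -> list[float]:
    a, b = drift
    return [a + b * p for p in predicted]
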