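"""Apply a calibration table to depth data.

Per-base sensitivity tracks, aggregation over arbitrary labeled regions
(exon, gene, exome, ...), total (depth-distribution-weighted) sensitivity,
required-mean-depth estimation from a down-sampling series, and the tile
easy/difficult coverage analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
from scipy.optimize import isotonic_regression

from .calibration import GENOTYPES, CalibrationTable
from .errors import ContractViolation, ParameterError
from .intervals_io import DepthProfile, GenomicInterval, TargetSet, Tile

WELL_COVERED_DEPTH = 10     # a base is well-covered at depth >= 10
WELL_COVERED_FRACTION = 0.9  # a tile is well-covered if >= 90% of bases are

TILE_DIFFICULT = "difficult"
TILE_EASY = "easy"
TILE_INTERMEDIATE = "intermediate"


@dataclass
class SensitivityTrack:
    """Per-base sensitivity over a target set, one array per genotype
    class, in the target's global-index order."""

    target: TargetSet
    values: Dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for g, arr in self.values.items():
            if arr.shape != (self.target.total_length,):
                raise ContractViolation(f"track length mismatch for {g}")


@dataclass
class RegionReport:
    label: str
    length: int  # number of track positions covered
    mean: Dict[str, float]
    minimum: Dict[str, float]
    fraction_below: Dict[str, float]
    missed_fraction: Dict[str, float]  # 1 - mean sensitivity
    defined: bool = True


@dataclass
class TileClassification:
    tile: Tile
    label: str  # difficult | easy | intermediate
    well_covered: bool  # in the full alignment
    gc: Optional[float] = None

    def __post_init__(self) -> None:
        if self.label == TILE_DIFFICULT and self.well_covered:
            raise ContractViolation("difficult tile cannot be well-covered")


def _lookup(profile: DepthProfile, table_values: np.ndarray) -> np.ndarray:
    depth = np.clip(profile.values, 0, len(table_values) - 1)
    out = table_values[depth]
    if np.isnan(out).any():
        missing = sorted(set(depth[np.isnan(out)].tolist()))
        raise ParameterError(
            f"calibration table undefined at occurring depths {missing}; "
            "fill or re-estimate the table"
        )
    return out


def per_base_sensitivity(
    profile: DepthProfile, table: CalibrationTable
) -> SensitivityTrack:
    """track(p) = table[genotype][clamp(depth(p))]; depth 0 maps to 0."""
    values = {g: _lookup(profile, table.sens[g]) for g in GENOTYPES}
    return SensitivityTrack(target=profile.target, values=values)


def aggregate_regions(
    track: SensitivityTrack,
    regions: Sequence[Tuple[str, GenomicInterval]],
    sens_threshold: float = 0.95,
) -> List[RegionReport]:
    """Per-region mean/min sensitivity and fraction of bases below
    ``sens_threshold``.  Regions are clipped to the track's target; a
    region with no targeted overlap is reported flagged-undefined."""
    reports: List[RegionReport] = []
    target = track.target
    for label, region in regions:
        idx_parts: List[Tuple[int, int]] = []
        tindex = target._index.get(region.chrom)
        if tindex is not None:
            starts, ends, offsets = tindex
            i0 = int(np.searchsorted(ends, region.start, side="right"))
            for i in range(i0, len(starts)):
                if starts[i] >= region.end:
                    break
                lo = max(int(starts[i]), region.start)
                hi = min(int(ends[i]), region.end)
                off = int(offsets[i])
                idx_parts.append((off + lo - int(starts[i]), off + hi - int(starts[i])))
        length = sum(hi - lo for lo, hi in idx_parts)
        if length == 0:
            nanmap = {g: float("nan") for g in GENOTYPES}
            reports.append(RegionReport(label, 0, dict(nanmap), dict(nanmap),
                                        dict(nanmap), dict(nanmap), defined=False))
            continue
        mean, minimum, frac_below, missed = {}, {}, {}, {}
        for g in GENOTYPES:
            vals = np.concatenate(
                [track.values[g][lo:hi] for lo, hi in idx_parts]
            )
            mean[g] = float(vals.mean())
            minimum[g] = float(vals.min())
            frac_below[g] = float((vals < sens_threshold).mean())
            missed[g] = 1.0 - mean[g]
        reports.append(RegionReport(label, length, mean, minimum, frac_below, missed))
    return reports


def total_sensitivity(
    profile: DepthProfile, table: CalibrationTable
) -> Dict[str, float]:
    """Depth-distribution-weighted mean sensitivity over the whole target:
    the mean over targeted positions of table[genotype][depth(p)]."""
    if profile.values.size == 0:
        raise ParameterError("total_sensitivity undefined for an empty target")
    return {g: float(_lookup(profile, table.sens[g]).mean()) for g in GENOTYPES}


def required_mean_depth(
    samples: Sequence[Tuple[float, float]],
    levels: Sequence[float] = (0.80, 0.90, 0.95),
) -> Dict[float, Optional[float]]:
    """Mean on-target depth needed to reach each total-sensitivity level.

    Points (mean_depth, total_sensitivity) from a down-sampling series are
    made monotone by isotonic regression, then each level's first crossing
    is located by piecewise-linear interpolation.  Levels above the maximum
    achieved sensitivity map to None (unattained); levels at or below the
    lowest point map to the lowest sampled depth (an upper bound).
    """
    pts = sorted(samples)
    if len(pts) < 2:
        raise ParameterError("required_mean_depth needs at least 2 points")
    depths = np.array([d for d, _ in pts], dtype=float)
    sens = np.array([s for _, s in pts], dtype=float)
    iso = isotonic_regression(sens).x
    out: Dict[float, Optional[float]] = {}
    for level in levels:
        if level > iso[-1]:
            out[level] = None
        elif level <= iso[0]:
            out[level] = float(depths[0])
        else:
            i = int(np.searchsorted(iso, level, side="left"))
            d0, d1 = depths[i - 1], depths[i]
            s0, s1 = iso[i - 1], iso[i]
            if s1 == s0:
                out[level] = float(d1)
            else:
                out[level] = float(d0 + (level - s0) * (d1 - d0) / (s1 - s0))
    return out


def _tile_depths(profile: DepthProfile, tile: Tile) -> np.ndarray:
    lo, hi = profile.target.interval_slice(tile.interval)
    return profile.values[lo:hi]


def tile_well_covered(depths: np.ndarray) -> bool:
    """At least 90% of bases well-covered (>= 10 reads); the base count
    threshold is the ceiling of 0.9 * tile length."""
    need = math.ceil(WELL_COVERED_FRACTION * len(depths))
    return int((depths >= WELL_COVERED_DEPTH).sum()) >= need


def classify_tiles(
    full_profile: DepthProfile,
    p01_profile: DepthProfile,
    tiles: Sequence[Tile],
    reference: Optional[Mapping[str, str]] = None,
) -> List[TileClassification]:
    """Difficult: no well-covered base in the full alignment.  Easy:
    well-covered in the p=0.1 down-sampled alignment.  Otherwise
    intermediate.  ``well_covered`` reports the full-alignment rule."""
    out: List[TileClassification] = []
    for tile in tiles:
        full_d = _tile_depths(full_profile, tile)
        p01_d = _tile_depths(p01_profile, tile)
        wc_full = tile_well_covered(full_d)
        if int((full_d >= WELL_COVERED_DEPTH).sum()) == 0:
            label = TILE_DIFFICULT
        elif tile_well_covered(p01_d):
            label = TILE_EASY
        else:
            label = TILE_INTERMEDIATE
        gc = tile_gc(tile, reference) if reference is not None else None
        out.append(TileClassification(tile, label, wc_full, gc))
    return out


def tile_gc(tile: Tile, reference: Mapping[str, str]) -> float:
    """(#G + #C) / (#A + #C + #G + #T) over the tile; ambiguous bases are
    excluded from both numerator and denominator (NaN if none remain)."""
    seq = reference[tile.interval.chrom][tile.interval.start : tile.interval.end]
    n_gc = seq.count("G") + seq.count("C")
    n_at = seq.count("A") + seq.count("T")
    return n_gc / (n_gc + n_at) if n_gc + n_at else float("nan")


def _tile_key(tc: TileClassification) -> Tuple[str, int, int]:
    iv = tc.tile.interval
    return (iv.chrom, iv.start, iv.end)


def tile_sharing(
    classifications_by_sample: Mapping[str, Sequence[TileClassification]],
    class_label: str,
) -> Tuple[Dict[Tuple[str, str], float], float, float]:
    """Pairwise shared fraction |class_a & class_b| / |class_a| over all
    ordered sample pairs, plus mean +- sd over pairs.  Pairs whose first
    sample has no tiles in the class are skipped."""
    sets = {
        sample: {_tile_key(tc) for tc in tcs if tc.label == class_label}
        for sample, tcs in classifications_by_sample.items()
    }
    if len(sets) < 2:
        raise ParameterError("tile_sharing needs >= 2 samples")
    matrix: Dict[Tuple[str, str], float] = {}
    for a in sets:
        for b in sets:
            if a == b:
                continue
            if not sets[a]:
                continue
            matrix[(a, b)] = len(sets[a] & sets[b]) / len(sets[a])
    fractions = np.array(list(matrix.values()), dtype=float)
    mean = float(fractions.mean()) if fractions.size else float("nan")
    sd = float(fractions.std(ddof=1)) if fractions.size > 1 else float("nan")
    return matrix, mean, sd


def covered_target_sets(
    tile_cover: Mapping[str, Mapping[str, Iterable[Tuple[str, int, int]]]],
) -> Tuple[Dict[str, Set[Tuple[str, int, int]]], Set[Tuple[str, int, int]]]:
    """Per capture method: the union over its samples of tiles covered by
    at least one read; plus the across-method intersection."""
    per_method: Dict[str, Set[Tuple[str, int, int]]] = {}
    for method, samples in tile_cover.items():
        if not samples:
            raise ParameterError(f"method {method!r} has no samples")
        union: Set[Tuple[str, int, int]] = set()
        for covered in samples.values():
            union |= set(covered)
        per_method[method] = union
    intersection = set.intersection(*per_method.values()) if per_method else set()
    return per_method, intersection


def flag_capture_failures(
    well_covered_counts: Mapping[str, int], k_mad: float = 3.0
) -> List[str]:
    """Flag samples whose well-covered tile count falls below
    median - k_mad * MAD of the cohort (partial capture failure)."""
    if len(well_covered_counts) < 3:
        raise ParameterError("flag_capture_failures needs >= 3 samples")
    counts = np.array(list(well_covered_counts.values()), dtype=float)
    med = float(np.median(counts))
    mad = float(np.median(np.abs(counts - med)))
    threshold = med - k_mad * mad
    if math.isnan(threshold):  # k_mad = inf with MAD = 0
        threshold = -math.inf
    return [s for s, c in well_covered_counts.items() if c < threshold]
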