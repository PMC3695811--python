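"""Gold-standard construction, call classification, sensitivity-by-depth
curves, the naive binomial comparison, and genotype concordance.

A call from a down-sampled alignment is classified against the truth set
(full-alignment calls cross-referenced to a known-site panel by position
and alleles) as TP (matching genotype), PTP (matching site, mismatching
genotype, with the direction recorded) or FN; sensitivity for a genotype
class at depth d is TP / (TP + PTP + FN) over observations binned either
cumulatively (depth <= d) or at exact depth d.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import binom

from .caller import (
    CallerParams,
    PileupColumn,
    VariantCall,
    _decide,
    call_variants,
    downsample_reads,
)
from .errors import ContractViolation, FormatError, ParameterError
from .intervals_io import (
    AlignedRead,
    DepthProfile,
    KnownSite,
    TargetSet,
    compute_depth_profile,
)

GENOTYPES = ("het", "hom")
OUTCOME_TP = "TP"
OUTCOME_PTP_HET_CALLED_HOM = "PTP_het_called_hom"
OUTCOME_PTP_HOM_CALLED_HET = "PTP_hom_called_het"
OUTCOME_FN = "FN"

DEFAULT_MAX_DEPTH = 100  # table rows cover read depths up to 100X


@dataclass
class TruthSet:
    """Full-alignment calls matched (position + alleles) to the known-site
    panel and restricted to the target set."""

    sample: str
    records: List[Tuple[VariantCall, KnownSite]]
    n_allele_mismatch: int = 0
    n_off_target: int = 0

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class Classification:
    chrom: str
    pos: int
    true_genotype: str
    outcome: str
    depth_at_site: int
    downsample_p: float
    replicate_id: str = ""


@dataclass(frozen=True)
class CurveRow:
    n_tp: int
    n_ptp: int
    n_fn: int

    @property
    def n(self) -> int:
        return self.n_tp + self.n_ptp + self.n_fn

    @property
    def sensitivity(self) -> Optional[float]:
        return self.n_tp / self.n if self.n else None


@dataclass
class SensitivityCurve:
    genotype: str
    mode: str  # 'cumulative_le_d' | 'exact_d'
    rows: Dict[int, CurveRow]

    def sensitivity(self, depth: int) -> Optional[float]:
        row = self.rows.get(depth)
        return row.sensitivity if row else None


def build_truth_set(
    full_calls: Sequence[VariantCall],
    panel: Sequence[KnownSite],
    target: TargetSet,
    qual_filter: Optional[float] = None,
    sample: str = "",
) -> TruthSet:
    """Intersect full-alignment calls with the panel on (chrom, pos, ref,
    alt), restricted to the target; optional Phred quality filter."""
    panel_by_key = {s.key: s for s in panel}
    panel_by_pos = {(s.chrom, s.pos) for s in panel}
    records: List[Tuple[VariantCall, KnownSite]] = []
    n_mismatch = 0
    n_off = 0
    for call in full_calls:
        if qual_filter is not None and call.qual < qual_filter:
            continue
        site = panel_by_key.get(call.key)
        if site is None:
            if (call.chrom, call.pos) in panel_by_pos:
                n_mismatch += 1
            continue
        if not target.contains(call.chrom, call.pos):
            n_off += 1
            continue
        records.append((call, site))
    return TruthSet(sample=sample, records=records,
                    n_allele_mismatch=n_mismatch, n_off_target=n_off)


def classify_downsampled(
    truth: TruthSet,
    ds_calls: Sequence[VariantCall],
    ds_depth: DepthProfile,
    p: float,
    replicate_id: str = "",
) -> List[Classification]:
    """One Classification per truth record against a down-sampled call set.

    FN depth is read from the down-sampled alignment's depth profile at the
    truth position (calls carry their own DP, which is used for TP/PTP).
    """
    calls_by_key = {c.key: c for c in ds_calls}
    out: List[Classification] = []
    for full_call, site in truth.records:
        ds_call = calls_by_key.get(full_call.key)
        depth = ds_depth.depth_at(full_call.chrom, full_call.pos)  # ContractViolation if absent
        if ds_call is None:
            outcome = OUTCOME_FN
        elif ds_call.genotype == full_call.genotype:
            outcome = OUTCOME_TP
            depth = ds_call.depth_at_site
        elif full_call.genotype == "het":
            outcome = OUTCOME_PTP_HET_CALLED_HOM
            depth = ds_call.depth_at_site
        else:
            outcome = OUTCOME_PTP_HOM_CALLED_HET
            depth = ds_call.depth_at_site
        out.append(
            Classification(
                chrom=full_call.chrom,
                pos=full_call.pos,
                true_genotype=full_call.genotype,
                outcome=outcome,
                depth_at_site=depth,
                downsample_p=p,
                replicate_id=replicate_id,
            )
        )
    return out


def sensitivity_curve(
    classifications: Sequence[Classification],
    genotype: str,
    mode: str = "exact_d",
    max_depth: int = DEFAULT_MAX_DEPTH,
) -> SensitivityCurve:
    """Tally TP/PTP/FN by depth for one genotype class.

    Depths above ``max_depth`` are clamped to the top row.  Rows with an
    empty denominator have ``sensitivity is None`` (undefined, not 0).
    """
    if genotype not in GENOTYPES:
        raise ParameterError(f"unknown genotype {genotype!r}")
    if mode not in ("exact_d", "cumulative_le_d"):
        raise ParameterError(f"unknown mode {mode!r}")
    tp = np.zeros(max_depth + 1, dtype=np.int64)
    ptp = np.zeros(max_depth + 1, dtype=np.int64)
    fn = np.zeros(max_depth + 1, dtype=np.int64)
    for c in classifications:
        if c.true_genotype != genotype:
            continue
        d = min(max(c.depth_at_site, 0), max_depth)
        if c.outcome == OUTCOME_TP:
            tp[d] += 1
        elif c.outcome == OUTCOME_FN:
            fn[d] += 1
        else:
            ptp[d] += 1
    if mode == "cumulative_le_d":
        tp, ptp, fn = np.cumsum(tp), np.cumsum(ptp), np.cumsum(fn)
    rows = {
        d: CurveRow(int(tp[d]), int(ptp[d]), int(fn[d]))
        for d in range(max_depth + 1)
    }
    return SensitivityCurve(genotype=genotype, mode=mode, rows=rows)


def binomial_expectation(
    d: int,
    genotype: str,
    caller_params: CallerParams = CallerParams(),
    q: int = 30,
) -> float:
    """Idealized sensitivity at depth ``d`` assuming alt reads sampled from
    Binomial(d, 1/2) for a het (all d alt for a hom), uniform base quality
    ``q`` and no sequencing error: the probability that the caller both
    emits a call and assigns the correct genotype.
    """
    if genotype not in GENOTYPES:
        raise ParameterError(f"unknown genotype {genotype!r}")
    if d < 0:
        raise ParameterError("depth must be >= 0")
    if d == 0:
        return 0.0

    def success(k: int) -> bool:
        obs = [("T", q)] * k + [("A", q)] * (d - k)
        col = PileupColumn("chrN", 0, "A", obs)
        decision = _decide(col, "T", caller_params) if k > 0 else None
        return decision is not None and decision[0] == genotype

    if genotype == "hom":
        return float(success(d))
    total = 0.0
    for k in range(d + 1):
        if success(k):
            total += float(binom.pmf(k, d, 0.5))
    return total


@dataclass
class ConcordanceResult:
    het_concordance: Optional[float]
    hom_concordance: Optional[float]
    n_het: int
    n_hom: int
    n_only_a: int
    n_only_b: int


def genotype_concordance(
    calls_a: Sequence[VariantCall], calls_b: Sequence[VariantCall]
) -> ConcordanceResult:
    """Fraction of allele-matched shared sites with identical genotype,
    reported separately for het and hom as classified by set A.  Sites
    called in only one set are counted separately, not in the denominator.
    """
    by_key_b = {c.key: c for c in calls_b}
    keys_a = {c.key for c in calls_a}
    n = {"het": 0, "hom": 0}
    agree = {"het": 0, "hom": 0}
    n_only_a = 0
    for a in calls_a:
        b = by_key_b.get(a.key)
        if b is None:
            n_only_a += 1
            continue
        n[a.genotype] += 1
        if a.genotype == b.genotype:
            agree[a.genotype] += 1
    n_only_b = sum(1 for k in by_key_b if k not in keys_a)
    return ConcordanceResult(
        het_concordance=agree["het"] / n["het"] if n["het"] else None,
        hom_concordance=agree["hom"] / n["hom"] if n["hom"] else None,
        n_het=n["het"],
        n_hom=n["hom"],
        n_only_a=n_only_a,
        n_only_b=n_only_b,
    )


# ---------------------------------------------------------------------------
# calibration table (recall-table dialect)
# ---------------------------------------------------------------------------


class CalibrationTable:
    """Sensitivity-by-depth lookup for both genotype classes.

    ``sens[g][d]`` is the sensitivity at depth d (index 0..max_depth);
    depth 0 is always 0 (no call is possible with no reads) and undefined
    rows are NaN.
    """

    def __init__(self, sens: Mapping[str, np.ndarray],
                 counts: Optional[Mapping[str, Mapping[str, np.ndarray]]] = None):
        self.sens = {g: np.asarray(sens[g], dtype=float) for g in GENOTYPES}
        lengths = {len(v) for v in self.sens.values()}
        if len(lengths) != 1:
            raise ParameterError("het/hom sensitivity arrays differ in length")
        self.max_depth = lengths.pop() - 1
        for g in GENOTYPES:
            self.sens[g][0] = 0.0
        self.counts = counts

    @classmethod
    def from_curves(cls, curves: Mapping[str, SensitivityCurve]) -> "CalibrationTable":
        max_depth = max(max(c.rows) for c in curves.values())
        sens = {}
        counts = {}
        for g in GENOTYPES:
            curve = curves[g]
            arr = np.full(max_depth + 1, np.nan)
            cnt = {k: np.zeros(max_depth + 1, dtype=np.int64)
                   for k in ("n_tp", "n_ptp", "n_fn")}
            for d, row in curve.rows.items():
                s = row.sensitivity
                arr[d] = np.nan if s is None else s
                cnt["n_tp"][d] = row.n_tp
                cnt["n_ptp"][d] = row.n_ptp
                cnt["n_fn"][d] = row.n_fn
            sens[g] = arr
            counts[g] = cnt
        return cls(sens, counts)

    def fill_gaps(self) -> "CalibrationTable":
        """Return a copy with NaN rows filled by linear interpolation
        between defined depths (flat extrapolation at the ends)."""
        sens = {}
        for g in GENOTYPES:
            arr = self.sens[g].copy()
            idx = np.arange(len(arr))
            ok = ~np.isnan(arr)
            if ok.sum() == 0:
                raise ParameterError(f"no defined rows for genotype {g}")
            arr[~ok] = np.interp(idx[~ok], idx[ok], arr[ok])
            sens[g] = arr
        return CalibrationTable(sens, self.counts)

    def to_tsv(self, path) -> None:
        """Write the full dialect: depth, genotype, n_tp, n_ptp, n_fn,
        sensitivity; one row per (depth 1..max_depth, genotype)."""
        rows = []
        for g in GENOTYPES:
            cnt = (self.counts or {}).get(g)
            for d in range(1, self.max_depth + 1):
                s = self.sens[g][d]
                rows.append({
                    "depth": d,
                    "genotype": g,
                    "n_tp": int(cnt["n_tp"][d]) if cnt is not None else 0,
                    "n_ptp": int(cnt["n_ptp"][d]) if cnt is not None else 0,
                    "n_fn": int(cnt["n_fn"][d]) if cnt is not None else 0,
                    "sensitivity": "NA" if math.isnan(s) else f"{s:.10g}",
                })
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "CalibrationTable":
        """Read either the full dialect or the minimal 3-column dialect
        (depth, het_sensitivity, hom_sensitivity)."""
        try:
            df = pd.read_csv(path, sep="\t")
        except (ValueError, OSError) as exc:
            raise FormatError(f"cannot parse calibration table {path}: {exc}") from exc
        cols = set(df.columns)
        if {"depth", "genotype", "sensitivity"} <= cols:
            max_depth = int(df["depth"].max())
            sens = {g: np.full(max_depth + 1, np.nan) for g in GENOTYPES}
            counts = {g: {k: np.zeros(max_depth + 1, dtype=np.int64)
                          for k in ("n_tp", "n_ptp", "n_fn")} for g in GENOTYPES}
            has_counts = {"n_tp", "n_ptp", "n_fn"} <= cols
            for _, row in df.iterrows():
                g, d = row["genotype"], int(row["depth"])
                if g not in GENOTYPES:
                    raise FormatError(f"unknown genotype {g!r} in {path}")
                val = row["sensitivity"]
                sens[g][d] = np.nan if (isinstance(val, str) and val == "NA") \
                    else float(val)
                if has_counts:
                    for k in ("n_tp", "n_ptp", "n_fn"):
                        counts[g][k][d] = int(row[k])
            return cls(sens, counts if has_counts else None)
        if {"depth", "het_sensitivity", "hom_sensitivity"} <= cols:
            max_depth = int(df["depth"].max())
            sens = {g: np.full(max_depth + 1, np.nan) for g in GENOTYPES}
            for _, row in df.iterrows():
                d = int(row["depth"])
                sens["het"][d] = float(row["het_sensitivity"])
                sens["hom"][d] = float(row["hom_sensitivity"])
            return cls(sens)
        raise FormatError(
            f"unrecognised calibration table header in {path}: {sorted(cols)}"
        )


# ---------------------------------------------------------------------------
# end-to-end calibration pipeline
# ---------------------------------------------------------------------------

DEFAULT_PROBABILITIES = tuple(round(0.1 * i, 1) for i in range(1, 10))


@dataclass
class CalibrationResult:
    truth: TruthSet
    classifications: List[Classification]
    curves: Dict[str, SensitivityCurve]
    table: CalibrationTable
    full_profile: DepthProfile


def run_calibration(
    reads: Sequence[AlignedRead],
    panel: Sequence[KnownSite],
    target: TargetSet,
    reference: Mapping[str, str],
    seed: int = 0,
    probabilities: Sequence[float] = DEFAULT_PROBABILITIES,
    caller_params: CallerParams = CallerParams(),
    mode: str = "exact_d",
    max_depth: int = DEFAULT_MAX_DEPTH,
    qual_filter: Optional[float] = None,
    sample: str = "",
) -> CalibrationResult:
    """Full alignment calls -> truth set -> per-probability down-sampled
    calls -> pooled classifications -> sensitivity curves and table.

    Calling is restricted to the panel positions (classification only ever
    consults calls at truth sites, which are a subset of the panel).
    """
    for p in probabilities:
        if not 0.0 < p < 1.0:
            raise ParameterError("down-sampling probabilities must be in (0, 1)")
    positions: Dict[str, List[int]] = {}
    for s in panel:
        positions.setdefault(s.chrom, []).append(s.pos)

    full_profile = compute_depth_profile(reads, target)
    full_calls = call_variants(
        reads, target, reference, caller_params,
        depth_profile=full_profile, positions=positions,
    )
    truth = build_truth_set(full_calls, panel, target,
                            qual_filter=qual_filter, sample=sample)

    classifications: List[Classification] = []
    for p in probabilities:
        ds_reads = downsample_reads(reads, p, seed)
        ds_profile = compute_depth_profile(ds_reads, target)
        ds_calls = call_variants(
            ds_reads, target, reference, caller_params,
            depth_profile=ds_profile, positions=positions,
        )
        classifications.extend(
            classify_downsampled(truth, ds_calls, ds_profile, p, replicate_id=sample)
        )

    curves = {
        g: sensitivity_curve(classifications, g, mode=mode, max_depth=max_depth)
        for g in GENOTYPES
    }
    return CalibrationResult(
        truth=truth,
        classifications=classifications,
        curves=curves,
        table=CalibrationTable.from_curves(curves),
        full_profile=full_profile,
    )
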