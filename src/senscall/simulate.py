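"""Synthetic exome-capture experiments.

Generates a reference with locally varying G+C, merged target intervals,
planted diploid SNV truth genotypes, and reads with heterogeneous per-tile
capture efficiency (lognormal noise plus an optional G+C-linked component)
and an optional bias toward fragments carrying the reference allele.

Reads are emitted pre-aligned at their true coordinates; no aligner is in
the loop, so mapping losses are folded into capture efficiency.  All
randomness derives from ``params.seed`` via independent numpy Generator
streams, so outputs are byte-identical across runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import ParameterError
from .intervals_io import (
    AlignedRead,
    GenomicInterval,
    TargetSet,
    Tile,
    merge_intervals,
    tile_targets,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i

# stream ids for the per-purpose RNGs (all spawned from params.seed)
_STREAM_LAYOUT, _STREAM_REFERENCE, _STREAM_TRUTH, _STREAM_READS = range(4)


@dataclass(frozen=True)
class SimulationParams:
    seed: int = 0
    n_targets: int = 50
    target_len_range: Tuple[int, int] = (400, 2000)
    mean_depth: float = 30.0
    read_len: int = 50
    paired: bool = True
    fragment_len_mean: float = 300.0
    fragment_len_sd: float = 25.0
    error_rate: float = 0.001
    het_site_rate: float = 0.001
    hom_site_rate: float = 0.0005
    capture_cv: float = 0.3
    gc_bias_slope: float = 0.0
    ref_bias: float = 1.0
    gc_mean: float = 0.45
    gc_sd: float = 0.12
    gc_window: int = 100
    gap_range: Tuple[int, int] = (400, 900)
    chrom_name: str = "chr1"
    sample_name: str = "sim"

    def __post_init__(self) -> None:
        for name in ("error_rate", "het_site_rate", "hom_site_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1], got {v}")
        if self.mean_depth <= 0:
            raise ParameterError("mean_depth must be > 0")
        if self.capture_cv < 0:
            raise ParameterError("capture_cv must be >= 0")
        if not 0.0 < self.ref_bias <= 1.0:
            raise ParameterError("ref_bias must be in (0, 1]")
        if self.read_len < 1 or self.n_targets < 1:
            raise ParameterError("read_len and n_targets must be >= 1")
        lo, hi = self.target_len_range
        if lo < 1 or hi < lo:
            raise ParameterError("bad target_len_range")
        if self.paired and self.fragment_len_mean < 2 * self.read_len:
            raise ParameterError("fragment_len_mean must be >= 2 * read_len when paired")
        if not 0.0 < self.gc_mean < 1.0:
            raise ParameterError("gc_mean must be in (0, 1)")

    @property
    def base_quality(self) -> int:
        """Uniform Phred quality corresponding to error_rate (capped at 60)."""
        if self.error_rate <= 0:
            return 60
        return min(60, int(round(-10.0 * math.log10(self.error_rate))))

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


@dataclass(frozen=True)
class TruthRecord:
    """A planted biallelic SNV with its diploid genotype."""

    site: GenomicInterval
    ref_allele: str
    alt_allele: str
    genotype: str  # 'het' | 'hom'

    def __post_init__(self) -> None:
        if self.site.length != 1:
            raise ParameterError("truth site must span exactly one base")
        if self.ref_allele == self.alt_allele:
            raise ParameterError("ref == alt in truth record")
        if self.genotype not in ("het", "hom"):
            raise ParameterError(f"bad genotype {self.genotype!r}")

    # VCF-writer duck-typing (see intervals_io.write_vcf)
    @property
    def chrom(self) -> str:
        return self.site.chrom

    @property
    def pos(self) -> int:
        return self.site.start


def simulate_targets(params: SimulationParams) -> TargetSet:
    """Deterministic target layout: n_targets intervals with lengths from
    target_len_range separated by gaps from gap_range, one chromosome."""
    rng = params._rng(_STREAM_LAYOUT)
    lo, hi = params.target_len_range
    glo, ghi = params.gap_range
    intervals: List[GenomicInterval] = []
    pos = int(rng.integers(glo, ghi + 1))
    for _ in range(params.n_targets):
        length = int(rng.integers(lo, hi + 1))
        intervals.append(GenomicInterval(params.chrom_name, pos, pos + length))
        pos += length + int(rng.integers(glo, ghi + 1))
    return merge_intervals(intervals, label="simulated")


def _chrom_length(params: SimulationParams, target: TargetSet) -> int:
    margin = int(params.fragment_len_mean + 6 * params.fragment_len_sd) + params.read_len
    return target.intervals[-1].end + margin


def simulate_reference(params: SimulationParams) -> Dict[str, str]:
    """Reference with per-window G+C drawn around gc_mean so that the
    G+C-linked capture bias has something to act on."""
    target = simulate_targets(params)
    rng = params._rng(_STREAM_REFERENCE)
    n = _chrom_length(params, target)
    w = params.gc_window
    n_windows = (n + w - 1) // w
    gc = np.clip(rng.normal(params.gc_mean, params.gc_sd, size=n_windows), 0.05, 0.95)
    p_gc = np.repeat(gc, w)[:n]
    u_class = rng.random(n)
    u_base = rng.random(n)
    codes = np.where(
        u_class < p_gc,
        np.where(u_base < 0.5, ord("G"), ord("C")),
        np.where(u_base < 0.5, ord("A"), ord("T")),
    ).astype(np.uint8)
    return {params.chrom_name: codes.tobytes().decode("ascii")}


def simulate_truth(
    reference: Dict[str, str], target: TargetSet, params: SimulationParams
) -> List[TruthRecord]:
    """Plant Bernoulli het/hom SNVs per targeted base; alt drawn uniformly
    from the three non-reference bases."""
    rng = params._rng(_STREAM_TRUTH)
    records: List[TruthRecord] = []
    for iv in target:
        seq = reference[iv.chrom]
        u = rng.random(iv.length)
        hits = np.nonzero(u < params.het_site_rate + params.hom_site_rate)[0]
        for off in hits:
            pos = iv.start + int(off)
            ref_base = seq[pos]
            if ref_base not in "ACGT":  # pragma: no cover - reference is ACGT-only
                continue
            genotype = "het" if u[off] < params.het_site_rate else "hom"
            shift = int(rng.integers(1, 4))
            alt_base = "ACGT"[(int(_BASE_INDEX[ord(ref_base)]) + shift) % 4]
            records.append(
                TruthRecord(
                    GenomicInterval(iv.chrom, pos, pos + 1), ref_base, alt_base, genotype
                )
            )
    return records


def _build_haplotypes(
    reference: Dict[str, str], truth: Sequence[TruthRecord], rng: np.random.Generator
) -> Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]]:
    """Per chrom: (hap0, hap1) byte arrays plus, per haplotype, the sorted
    positions where it differs from the reference."""
    out = {}
    diffs: Dict[str, Tuple[List[int], List[int]]] = {}
    haps: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    for chrom, seq in reference.items():
        ref_codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
        haps[chrom] = (ref_codes.copy(), ref_codes.copy())
        diffs[chrom] = ([], [])
    for rec in truth:
        h0, h1 = haps[rec.site.chrom]
        d0, d1 = diffs[rec.site.chrom]
        alt = ord(rec.alt_allele)
        if rec.genotype == "hom":
            h0[rec.site.start] = alt
            h1[rec.site.start] = alt
            d0.append(rec.site.start)
            d1.append(rec.site.start)
        else:
            phase = int(rng.integers(2))
            (h0 if phase == 0 else h1)[rec.site.start] = alt
            (d0 if phase == 0 else d1).append(rec.site.start)
    for chrom in haps:
        h0, h1 = haps[chrom]
        d0, d1 = diffs[chrom]
        out[chrom] = (
            h0,
            h1,
            np.asarray(sorted(d0), dtype=np.int64),
            np.asarray(sorted(d1), dtype=np.int64),
        )
    return out


def _gc_fraction(seq: str, start: int, end: int) -> float:
    window = seq[start:end]
    n_gc = window.count("G") + window.count("C")
    n_at = window.count("A") + window.count("T")
    return n_gc / (n_gc + n_at) if n_gc + n_at else float("nan")


def simulate_reads(
    reference: Dict[str, str],
    target: TargetSet,
    truth: Sequence[TruthRecord],
    params: SimulationParams,
) -> List[AlignedRead]:
    """Emit pre-aligned reads with per-tile capture heterogeneity.

    Per <=100 bp tile the efficiency multiplier is
    ``lognormal(mean 1, cv=capture_cv) * (1 + gc_bias_slope*(gc - 0.5))``
    truncated at 0; fragment starts are Poisson-placed at a per-base rate
    of ``mean_depth * e / read_bases_per_fragment``.  The start window of
    the first tile of each target interval is extended upstream by the
    maximum fragment reach, which makes the expected depth uniform at
    ``mean_depth * e`` across the whole interval (no edge ramp) at the
    price of some off-target reads, as in a real capture experiment.

    Each fragment copies one haplotype.  If it carries any non-reference
    allele it is accepted with probability ``ref_bias``, otherwise the
    haplotype is re-drawn (renormalized sampling odds: an isolated het site
    shows the alt allele with probability ref_bias / (1 + ref_bias)).
    """
    rng = params._rng(_STREAM_READS)
    haps = _build_haplotypes(reference, truth, rng)
    rl = params.read_len
    n_mates = 2 if params.paired else 1
    frag_bases = rl * n_mates

    if params.capture_cv > 0:
        sigma = math.sqrt(math.log(1.0 + params.capture_cv**2))
        mu = -0.5 * sigma**2
    else:
        sigma = mu = 0.0

    # collect fragments as (chrom-local) arrays, then materialize reads
    frag_chrom: List[str] = []
    frag_start: List[np.ndarray] = []
    frag_len: List[np.ndarray] = []
    hap_stacks = {c: np.stack([h[0], h[1]]) for c, h in haps.items()}

    # upstream extension covering the reach of (almost) any fragment
    if params.paired:
        ext = int(params.fragment_len_mean + 4 * params.fragment_len_sd)
    else:
        ext = rl - 1

    tiles = tile_targets(target)
    for tile in tiles:
        chrom = tile.interval.chrom
        seq = reference[chrom]
        gc = _gc_fraction(seq, tile.interval.start, tile.interval.end)
        e = 1.0 if sigma == 0.0 else float(rng.lognormal(mu, sigma))
        if params.gc_bias_slope and not math.isnan(gc):
            e *= 1.0 + params.gc_bias_slope * (gc - 0.5)
        e = max(e, 0.0)
        tile_ext = ext if tile.index == 0 else 0
        window_lo = max(tile.interval.start - tile_ext, 0)
        lam = (
            params.mean_depth * e / frag_bases
            * (tile.interval.end - window_lo)
        )
        n_frag = int(rng.poisson(lam))
        if n_frag == 0:
            continue
        starts = rng.integers(window_lo, tile.interval.end, size=n_frag)
        if params.paired:
            lens = np.rint(
                rng.normal(params.fragment_len_mean, params.fragment_len_sd, size=n_frag)
            ).astype(np.int64)
            lens = np.maximum(lens, 2 * rl)  # mates never overlap
        else:
            lens = np.full(n_frag, rl, dtype=np.int64)
        # fragments running off the chromosome end are re-positioned
        chrom_len = len(seq)
        over = starts + lens > chrom_len
        if over.any():
            starts = np.where(over, np.maximum(chrom_len - lens, 0), starts)
        frag_chrom.append(chrom)
        frag_start.append(starts.astype(np.int64))
        frag_len.append(lens)

    reads: List[AlignedRead] = []
    quals_cache = (params.base_quality,) * rl  # shared tuple: uniform quality
    cigar_cache = (("M", rl),)
    frag_counter = 0
    for chrom, starts, lens in zip(frag_chrom, frag_start, frag_len):
        h0, h1, d0, d1 = haps[chrom]
        diff_pos = (d0, d1)
        n = len(starts)
        hap_sel = rng.integers(2, size=n)
        if params.ref_bias < 1.0 and (len(d0) or len(d1)):
            accept_u = rng.random(n)
            for i in range(n):
                s, e = int(starts[i]), int(starts[i] + lens[i])
                h = int(hap_sel[i])
                tries = 0
                while True:
                    dp = diff_pos[h]
                    lo = int(np.searchsorted(dp, s))
                    carries_alt = lo < len(dp) and dp[lo] < e
                    if not carries_alt:
                        break
                    u = accept_u[i] if tries == 0 else float(rng.random())
                    if u < params.ref_bias:
                        break
                    h = int(rng.integers(2))
                    tries += 1
                    if tries > 1000:  # pragma: no cover - ref_bias > 0 terminates a.s.
                        break
                hap_sel[i] = h
        hap_stack = hap_stacks[chrom]

        # gather read base codes for both mates at once
        ends = starts + lens
        read_starts = [starts]
        firsts = [True]
        if params.paired:
            read_starts.append(ends - rl)
            firsts.append(False)
        mate_codes = []
        for rs in read_starts:
            idx = rs[:, None] + np.arange(rl)[None, :]
            codes = hap_stack[hap_sel[:, None], idx]
            mate_codes.append(codes)
        all_codes = np.concatenate(mate_codes, axis=0)
        if params.error_rate > 0:
            err_mask = rng.random(all_codes.shape) < params.error_rate
            n_err = int(err_mask.sum())
            if n_err:
                shifts = rng.integers(1, 4, size=n_err)
                old_idx = _BASE_INDEX[all_codes[err_mask]].astype(np.int64)
                all_codes[err_mask] = _BASES[(old_idx + shifts) % 4]
        n_per_mate = n
        blob = all_codes.tobytes()
        for mate_i, (rs, first) in enumerate(zip(read_starts, firsts)):
            base_off = mate_i * n_per_mate * rl
            for i in range(n):
                b0 = base_off + i * rl
                reads.append(
                    AlignedRead(
                        name=f"frag{frag_counter + i:09d}",
                        chrom=chrom,
                        pos=int(rs[i]),
                        cigar=cigar_cache,
                        bases=blob[b0 : b0 + rl].decode("ascii"),
                        quals=quals_cache,
                        is_paired=params.paired,
                        is_first=first,
                        sample=params.sample_name,
                    )
                )
        frag_counter += n

    reads.sort(key=lambda r: (r.chrom, r.pos, r.name, not r.is_first))
    return reads


@dataclass
class SimulatedExperiment:
    params: SimulationParams
    reference: Dict[str, str]
    target: TargetSet
    truth: List[TruthRecord]
    reads: List[AlignedRead]

    @property
    def reference_lengths(self) -> Dict[str, int]:
        return {c: len(s) for c, s in self.reference.items()}


def simulate_experiment(params: SimulationParams) -> SimulatedExperiment:
    """Run the full generator chain (targets, reference, truth, reads)."""
    reference = simulate_reference(params)
    target = simulate_targets(params)
    truth = simulate_truth(reference, target, params)
    reads = simulate_reads(reference, target, truth, params)
    return SimulatedExperiment(params, reference, target, truth, reads)
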