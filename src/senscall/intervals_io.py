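"""Interval algebra, read-depth computation and text-format I/O.

All internal coordinates are 0-based half-open.  Conversion to the 1-based
convention of VCF happens only at the format boundary; BED shares the
internal convention.

The SAM and VCF readers/writers delegate parsing to :mod:`pysam` behind a
thin conversion layer so the rest of the package only ever sees the
lightweight domain types defined here.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ContractViolation, FormatError, ParameterError

log = logging.getLogger(__name__)

# cigar ops that consume reference / read sequence
_REF_OPS = frozenset("MD")
_READ_OPS = frozenset("MIS")
_CIGAR_OPS = frozenset("MIDS")

# pysam numeric cigar codes for the subset we model; 7 (=) and 8 (X) are
# sequence-match refinements of M and are folded into it.
_PYSAM_TO_OP = {0: "M", 1: "I", 2: "D", 4: "S", 7: "M", 8: "M"}
_OP_TO_PYSAM = {"M": 0, "I": 1, "D": 2, "S": 4}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval [start, end) on ``chrom``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise FormatError("interval chrom must be non-empty")
        if self.start < 0 or self.start >= self.end:
            raise FormatError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(require 0 <= start < end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end

    def __str__(self) -> str:  # pragma: no cover - repr convenience
        return f"{self.chrom}:{self.start}-{self.end}"


class TargetSet:
    """Sorted, merged (non-overlapping, non-abutting) intervals.

    Every targeted position is represented exactly once; positions carry a
    stable global index (concatenation order of the sorted intervals) used
    by :class:`DepthProfile` and sensitivity tracks.
    """

    def __init__(self, intervals: Sequence[GenomicInterval], label: str = "target"):
        ivs = list(intervals)
        for prev, cur in zip(ivs, ivs[1:]):
            if (prev.chrom, prev.start) > (cur.chrom, cur.start):
                raise FormatError("TargetSet intervals must be sorted by (chrom, start)")
            if prev.chrom == cur.chrom and cur.start <= prev.end:
                raise FormatError(
                    f"TargetSet intervals overlap or abut: {prev} / {cur}; "
                    "merge them first"
                )
        self.intervals: Tuple[GenomicInterval, ...] = tuple(ivs)
        self.label = label
        # per-chrom lookup arrays: starts, ends, global offset of each interval
        self._index: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        offset = 0
        by_chrom: Dict[str, List[Tuple[int, int, int]]] = {}
        for iv in self.intervals:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, offset))
            offset += iv.length
        self._total_length = offset
        for chrom, rows in by_chrom.items():
            arr = np.asarray(rows, dtype=np.int64).reshape(-1, 3)
            self._index[chrom] = (arr[:, 0], arr[:, 1], arr[:, 2])

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, TargetSet) and self.intervals == other.intervals

    @property
    def total_length(self) -> int:
        return self._total_length

    @property
    def chroms(self) -> List[str]:
        return list(self._index)

    def contains(self, chrom: str, pos: int) -> bool:
        return self.position_index(chrom, pos) is not None

    def position_index(self, chrom: str, pos: int) -> Optional[int]:
        """Global index of a targeted position, or None if off-target."""
        idx = self._index.get(chrom)
        if idx is None:
            return None
        starts, ends, offsets = idx
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i >= 0 and pos < ends[i]:
            return int(offsets[i] + (pos - starts[i]))
        return None

    def positions(self) -> Iterator[Tuple[str, int]]:
        """Iterate every targeted (chrom, pos) in global-index order."""
        for iv in self.intervals:
            for pos in range(iv.start, iv.end):
                yield iv.chrom, pos

    def interval_slice(self, iv: GenomicInterval) -> Tuple[int, int]:
        """Global-index slice [lo, hi) of an interval fully inside one
        target interval; raises ContractViolation otherwise."""
        lo = self.position_index(iv.chrom, iv.start)
        hi = self.position_index(iv.chrom, iv.end - 1)
        if lo is None or hi is None or hi - lo != iv.length - 1:
            raise ContractViolation(f"interval {iv} not contained in target set")
        return lo, hi + 1


def merge_intervals(
    raw: Iterable[GenomicInterval], label: str = "target"
) -> TargetSet:
    """Merge possibly overlapping/abutting/unsorted intervals into the
    minimal sorted non-overlapping cover of their union."""
    ivs = sorted(raw, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: List[GenomicInterval] = []
    for iv in ivs:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(iv)
    return TargetSet(merged, label=label)


@dataclass(frozen=True)
class Tile:
    """A <=100 bp (``max_len``) piece of a target interval."""

    interval: GenomicInterval
    parent: GenomicInterval
    index: int

    def __post_init__(self) -> None:
        iv, parent = self.interval, self.parent
        if iv.chrom != parent.chrom or iv.start < parent.start or iv.end > parent.end:
            raise ContractViolation(f"tile {iv} outside parent {parent}")


def tile_targets(target: TargetSet, max_len: int = 100) -> List[Tile]:
    """Split each target interval into non-overlapping tiles of ``max_len``
    with the (smaller) remainder tile at the right edge."""
    if max_len < 1:
        raise ParameterError("max_len must be >= 1")
    tiles: List[Tile] = []
    for parent in target:
        idx = 0
        for start in range(parent.start, parent.end, max_len):
            end = min(start + max_len, parent.end)
            tiles.append(Tile(GenomicInterval(parent.chrom, start, end), parent, idx))
            idx += 1
    return tiles


@dataclass(slots=True)
class AlignedRead:
    """Minimal alignment record sufficient for depth and pileup.

    ``cigar`` is restricted to M/I/D/S; bases and quals cover the read
    sequence (M+I+S); the aligned reference span is M+D.
    """

    name: str
    chrom: str
    pos: int
    cigar: Tuple[Tuple[str, int], ...]
    bases: str
    quals: Tuple[int, ...]
    is_paired: bool = False
    is_first: bool = True
    sample: str = ""

    def __post_init__(self) -> None:
        read_len = 0
        for op, n in self.cigar:
            if op not in _CIGAR_OPS or n < 1:
                raise FormatError(f"unsupported cigar element {op}{n} in read {self.name}")
            if op in _READ_OPS:
                read_len += n
        if read_len != len(self.bases) or read_len != len(self.quals):
            raise FormatError(
                f"read {self.name}: cigar read length {read_len} != "
                f"{len(self.bases)} bases / {len(self.quals)} quals"
            )

    @property
    def ref_span(self) -> int:
        return sum(n for op, n in self.cigar if op in _REF_OPS)

    @property
    def end(self) -> int:
        """One past the last reference position the alignment covers."""
        return self.pos + self.ref_span

    @property
    def mate_name_key(self) -> str:
        return self.name

    def aligned_observations(self) -> Iterator[Tuple[int, str, int]]:
        """Yield (ref_pos, base, qual) for every M-aligned base."""
        rpos, qpos = self.pos, 0
        for op, n in self.cigar:
            if op == "M":
                for k in range(n):
                    yield rpos + k, self.bases[qpos + k], self.quals[qpos + k]
                rpos += n
                qpos += n
            elif op == "D":
                rpos += n
            else:  # I or S consume read only
                qpos += n


class DepthProfile:
    """Per-base read depth over every position of a TargetSet.

    Values are stored as one int array in the target's global-index order.
    """

    def __init__(self, target: TargetSet, values: np.ndarray, n_skipped: int = 0):
        values = np.asarray(values, dtype=np.int64)
        if values.shape != (target.total_length,):
            raise ContractViolation(
                f"depth profile length {values.shape} != target length "
                f"{target.total_length}"
            )
        if values.size and values.min() < 0:
            raise ContractViolation("negative depth")
        self.target = target
        self.values = values
        self.n_skipped = n_skipped

    def depth_at(self, chrom: str, pos: int) -> int:
        i = self.target.position_index(chrom, pos)
        if i is None:
            raise ContractViolation(f"position {chrom}:{pos} not in target")
        return int(self.values[i])

    def __add__(self, other: "DepthProfile") -> "DepthProfile":
        if self.target != other.target:
            raise ContractViolation("cannot add profiles over different targets")
        return DepthProfile(self.target, self.values + other.values,
                            self.n_skipped + other.n_skipped)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, DepthProfile)
            and self.target == other.target
            and bool(np.array_equal(self.values, other.values))
        )


def compute_depth_profile(
    reads: Iterable[AlignedRead], target: TargetSet
) -> DepthProfile:
    """Depth = number of reads whose aligned span (M+D ops) covers the
    position; reads aligned with a deletion across a position still count.
    Order-independent. Reads on chroms absent from the target are skipped
    (counted in ``n_skipped``)."""
    spans: Dict[str, List[Tuple[int, int]]] = {c: [] for c in target.chroms}
    n_skipped = 0
    for r in reads:
        lst = spans.get(r.chrom)
        if lst is None:
            n_skipped += 1
            continue
        lst.append((r.pos, r.end))
    if n_skipped:
        log.debug("compute_depth_profile: skipped %d off-target-chrom reads", n_skipped)
    values = np.zeros(target.total_length, dtype=np.int64)
    for chrom, lst in spans.items():
        starts, ends, offsets = target._index[chrom]
        hi = int(ends[-1])
        diff = np.zeros(hi + 1, dtype=np.int64)
        if lst:
            arr = np.asarray(lst, dtype=np.int64)
            np.add.at(diff, np.minimum(arr[:, 0], hi), 1)
            np.add.at(diff, np.minimum(arr[:, 1], hi), -1)
            # spans starting before 0 impossible (pos >= 0)
        cov = np.cumsum(diff)
        for s, e, off in zip(starts, ends, offsets):
            values[off : off + (e - s)] = cov[s:e]
    return DepthProfile(target, values, n_skipped=n_skipped)


def mean_on_target_depth(profile: DepthProfile) -> float:
    """Arithmetic mean depth over all targeted positions."""
    if profile.values.size == 0:
        raise ParameterError("mean_on_target_depth undefined for an empty target")
    return float(profile.values.mean())


@dataclass(frozen=True)
class KnownSite:
    """A known biallelic polymorphic site, optionally with per-sample
    genotypes ('het' | 'hom' | 'hom-ref')."""

    chrom: str
    pos: int  # 0-based
    ref_allele: str
    alt_allele: str
    genotypes: Optional[Mapping[str, str]] = None

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise FormatError(f"ref == alt at {self.chrom}:{self.pos}")
        if self.pos < 0:
            raise FormatError("negative position")

    @property
    def key(self) -> Tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref_allele, self.alt_allele)


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------

_FLAG_PAIRED = 0x1
_FLAG_UNMAPPED = 0x4
_FLAG_FIRST = 0x40
_FLAG_LAST = 0x80
_FLAG_SECONDARY = 0x100
_FLAG_SUPPLEMENTARY = 0x800


def read_sam(path) -> List[AlignedRead]:
    """Parse a SAM text file into AlignedRead records.

    Unmapped, secondary and supplementary records are skipped (logged).
    Malformed input raises FormatError.
    """
    out: List[AlignedRead] = []
    n_skip = 0
    try:
        with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
            sample_by_rg = {
                rg.get("ID"): rg.get("SM", "") for rg in fh.header.to_dict().get("RG", [])
            }
            for rec in fh:
                if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                    n_skip += 1
                    continue
                cig = tuple(
                    (_PYSAM_TO_OP[op], n)
                    for op, n in (rec.cigartuples or ())
                    if op in _PYSAM_TO_OP
                )
                quals = rec.query_qualities
                rg = rec.get_tag("RG") if rec.has_tag("RG") else None
                out.append(
                    AlignedRead(
                        name=rec.query_name,
                        chrom=rec.reference_name,
                        pos=rec.reference_start,
                        cigar=cig,
                        bases=rec.query_sequence or "",
                        quals=tuple(int(q) for q in quals) if quals is not None else (),
                        is_paired=rec.is_paired,
                        is_first=not rec.is_read2,
                        sample=sample_by_rg.get(rg, ""),
                    )
                )
    except (ValueError, OSError) as exc:
        raise FormatError(f"cannot parse SAM {path}: {exc}") from exc
    if n_skip:
        log.info("read_sam(%s): skipped %d unmapped/secondary/supplementary records",
                 path, n_skip)
    return out


def write_sam(
    reads: Iterable[AlignedRead],
    path,
    reference_lengths: Mapping[str, int],
    sample: Optional[str] = None,
) -> None:
    """Write AlignedRead records as SAM text with an @HD/@SQ header."""
    names = list(reference_lengths)
    header: Dict = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": int(reference_lengths[c])} for c in names],
    }
    if sample:
        header["RG"] = [{"ID": "rg0", "SM": sample}]
    tid = {c: i for i, c in enumerate(names)}
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for r in reads:
            a = pysam.AlignedSegment(fh.header)
            a.query_name = r.name
            a.reference_id = tid[r.chrom]
            a.reference_start = r.pos
            a.cigartuples = [(_OP_TO_PYSAM[op], n) for op, n in r.cigar]
            a.query_sequence = r.bases
            a.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(min(q, 93) + 33) for q in r.quals)
            )
            a.mapping_quality = 60
            flag = 0
            if r.is_paired:
                flag |= _FLAG_PAIRED | (_FLAG_FIRST if r.is_first else _FLAG_LAST)
            a.flag = flag
            if sample:
                a.set_tag("RG", "rg0")
            fh.write(a)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_GT_TO_TUPLE = {"het": (0, 1), "hom": (1, 1), "hom-ref": (0, 0)}


def _tuple_to_gt(alleles: Tuple) -> Optional[str]:
    called = [a for a in alleles if a is not None]
    if not called:
        return None
    if all(a == 0 for a in called):
        return "hom-ref"
    if all(a != 0 for a in called):
        return "hom"
    return "het"


def read_vcf_sites(path) -> List[KnownSite]:
    """Read a VCF into KnownSite records.

    Multiallelic records are split into biallelic sites; symbolic or
    breakend alleles are rejected per-record with a warning count.
    Per-sample GT fields, when present, are mapped to het/hom/hom-ref
    (for split records, genotypes are interpreted against each alt in turn).
    """
    sites: List[KnownSite] = []
    n_symbolic = 0
    try:
        with pysam.VariantFile(str(path)) as vf:
            samples = list(vf.header.samples)
            for rec in vf:
                alts = rec.alts or ()
                for ai, alt in enumerate(alts, start=1):
                    if alt is None or any(c in alt for c in "<>[].*"):
                        n_symbolic += 1
                        continue
                    genotypes: Optional[Dict[str, str]] = None
                    if samples:
                        genotypes = {}
                        for s in samples:
                            gt = rec.samples[s].get("GT")
                            if gt is None:
                                continue
                            # project onto {ref, this alt}; other alts -> skip
                            if any(a not in (None, 0, ai) for a in gt):
                                continue
                            proj = tuple(None if a is None else (1 if a == ai else 0)
                                         for a in gt)
                            label = _tuple_to_gt(proj)
                            if label is not None:
                                genotypes[s] = label
                    sites.append(
                        KnownSite(rec.chrom, rec.pos - 1, rec.ref, alt,
                                  genotypes=genotypes or None)
                    )
    except (ValueError, OSError) as exc:
        raise FormatError(f"cannot parse VCF {path}: {exc}") from exc
    if n_symbolic:
        log.warning("read_vcf_sites(%s): rejected %d symbolic alleles", path, n_symbolic)
    return sites


def write_vcf(
    calls: Iterable,
    sample: str,
    path,
    contigs: Mapping[str, int],
) -> None:
    """Write calls (anything with chrom/pos/ref_allele/alt_allele/genotype
    and optional qual/depth_at_site) as a single-sample VCF with GT, DP, GQ."""
    header = pysam.VariantHeader()
    for c, ln in contigs.items():
        header.contigs.add(c, length=int(ln))
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Read depth at site")
    header.formats.add("GQ", 1, "Integer", "Genotype quality")
    header.add_sample(sample)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for call in calls:
            rec = vf.new_record(
                contig=call.chrom,
                start=call.pos,
                stop=call.pos + len(call.ref_allele),
                alleles=(call.ref_allele, call.alt_allele),
            )
            qual = getattr(call, "qual", None)
            if qual is not None:
                rec.qual = float(min(qual, 99999.0))
            rec.samples[sample]["GT"] = _GT_TO_TUPLE[call.genotype]
            rec.samples[sample].phased = False
            depth = getattr(call, "depth_at_site", None)
            if depth is not None:
                rec.samples[sample]["DP"] = int(depth)
            if qual is not None:
                rec.samples[sample]["GQ"] = int(min(round(qual), 99))
            vf.write(rec)


# ---------------------------------------------------------------------------
# BED / bedGraph / FASTA
# ---------------------------------------------------------------------------


def read_bed(path) -> List[GenomicInterval]:
    """Read BED3 (extra columns ignored) as 0-based half-open intervals."""
    return [iv for _, iv in read_bed_regions(path)]


def read_bed_regions(path) -> List[Tuple[str, GenomicInterval]]:
    """Read BED with an optional name column: list of (label, interval).
    Unnamed rows are labelled region_<n>."""
    out: List[Tuple[str, GenomicInterval]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 BED columns")
            try:
                iv = GenomicInterval(parts[0], int(parts[1]), int(parts[2]))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            label = parts[3] if len(parts) > 3 and parts[3] else f"region_{len(out) + 1}"
            out.append((label, iv))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path,
              labels: Optional[Sequence[str]] = None) -> None:
    ivs = list(intervals)
    with open(path, "w") as fh:
        for i, iv in enumerate(ivs):
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if labels is not None:
                cols.append(labels[i])
            fh.write("\t".join(cols) + "\n")


def read_fasta(path) -> Dict[str, str]:
    try:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    except (ValueError, OSError) as exc:  # pragma: no cover - Bio raises rarely
        raise FormatError(f"cannot parse FASTA {path}: {exc}") from exc


def write_fasta(sequences: Mapping[str, str], path) -> None:
    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(recs, str(path), "fasta")


def read_bedgraph(path, target: Optional[TargetSet] = None) -> DepthProfile:
    """Read a (chrom, start, end, depth) bedGraph into a DepthProfile.

    If ``target`` is omitted it is derived by merging the bedGraph
    intervals themselves (zero-depth rows included).
    """
    rows: List[Tuple[GenomicInterval, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 bedGraph columns")
            try:
                iv = GenomicInterval(parts[0], int(parts[1]), int(parts[2]))
                depth = int(float(parts[3]))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            rows.append((iv, depth))
    if target is None:
        target = merge_intervals([iv for iv, _ in rows])
    values = np.zeros(target.total_length, dtype=np.int64)
    for iv, depth in rows:
        for pos in range(iv.start, iv.end):
            i = target.position_index(iv.chrom, pos)
            if i is not None:
                values[i] = depth
    return DepthProfile(target, values)


def write_bedgraph(profile_or_track_values, target: TargetSet, path) -> None:
    """Write per-position values over a target as run-length-merged bedGraph."""
    values = np.asarray(
        getattr(profile_or_track_values, "values", profile_or_track_values)
    )
    with open(path, "w") as fh:
        off = 0
        for iv in target:
            vals = values[off : off + iv.length]
            off += iv.length
            run_start = 0
            for i in range(1, iv.length + 1):
                if i == iv.length or vals[i] != vals[run_start]:
                    v = vals[run_start]
                    v_str = str(int(v)) if float(v).is_integer() else f"{float(v):.6g}"
                    fh.write(
                        f"{iv.chrom}\t{iv.start + run_start}\t{iv.start + i}\t{v_str}\n"
                    )
                    run_start = i
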