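"""Pair-preserving down-sampling and a diploid genotype-likelihood caller.

The caller is a deliberately transparent stand-in for a production
genotyper: per observed base with error probability ``eps = 10**(-q/10)``,

    P(b | hom G)  = 1 - eps         if b == G, else eps / 3
    P(b | het RA) = (P(b | RR) + P(b | AA)) / 2

column log-likelihoods are summed over observations and combined with the
prior (1 - theta_het - theta_hom, theta_het, theta_hom).  A variant is
emitted when the Phred-scaled posterior probability that the genotype is
not hom-ref reaches ``call_threshold``; the reported genotype is the
posterior argmax among het / hom-alt.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.special import logsumexp

from .errors import ParameterError
from .intervals_io import (
    AlignedRead,
    DepthProfile,
    TargetSet,
    compute_depth_profile,
)

_MAX_QUAL = 10000.0


# ---------------------------------------------------------------------------
# down-sampling
# ---------------------------------------------------------------------------


def _pair_uniform(seed: int, name: str) -> float:
    """Deterministic uniform in [0, 1) from (seed, read name).

    One draw per template name, so mates always share their fate and the
    kept-set at p1 contains the kept-set at any p2 < p1 for a fixed seed.
    """
    key = int(seed).to_bytes(8, "little", signed=True)
    digest = hashlib.blake2b(name.encode(), digest_size=8, key=key).digest()
    return int.from_bytes(digest, "little") / 2.0**64


def downsample_reads(
    reads: Iterable[AlignedRead], p: float, seed: int
) -> List[AlignedRead]:
    """Keep each read pair (or unpaired read) with probability ``p``."""
    if not 0.0 <= p <= 1.0:
        raise ParameterError(f"down-sampling probability {p} outside [0, 1]")
    if p == 1.0:
        return list(reads)
    if p == 0.0:
        return []
    kept: List[AlignedRead] = []
    cache: Dict[str, bool] = {}
    for r in reads:
        keep = cache.get(r.name)
        if keep is None:
            keep = _pair_uniform(seed, r.name) < p
            cache[r.name] = keep
        if keep:
            kept.append(r)
    return kept


# ---------------------------------------------------------------------------
# genotyping
# ---------------------------------------------------------------------------


@dataclass
class PileupColumn:
    """Base/quality observations from reads whose M ops cover ``pos``."""

    chrom: str
    pos: int
    ref_base: str
    obs: List[Tuple[str, int]]


@dataclass(frozen=True)
class VariantCall:
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    genotype: str  # 'het' | 'hom'
    qual: float
    depth_at_site: int

    @property
    def key(self) -> Tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref_allele, self.alt_allele)


@dataclass(frozen=True)
class CallerParams:
    theta_het: float = 1e-3
    theta_hom: float = 5e-4
    call_threshold: float = 30.0

    def __post_init__(self) -> None:
        if self.theta_het < 0 or self.theta_hom < 0:
            raise ParameterError("priors must be non-negative")
        if self.theta_het + self.theta_hom >= 1.0:
            raise ParameterError("theta_het + theta_hom must be < 1")
        if self.call_threshold < 0:
            raise ParameterError("call_threshold must be >= 0")

    @property
    def log_priors(self) -> np.ndarray:
        return np.log(
            np.array([1.0 - self.theta_het - self.theta_hom,
                      self.theta_het, self.theta_hom])
        )


def genotype_likelihoods(col: PileupColumn, alt: str) -> np.ndarray:
    """Natural-log likelihoods of (hom-ref, het, hom-alt) for the column.

    An empty column yields flat (zero) log-likelihoods.
    """
    if alt == col.ref_base:
        raise ParameterError("alt allele equals ref")
    if not col.obs:
        return np.zeros(3)
    bases = np.array([b for b, _ in col.obs])
    eps = 10.0 ** (-np.array([q for _, q in col.obs], dtype=float) / 10.0)
    p_ref = np.where(bases == col.ref_base, 1.0 - eps, eps / 3.0)
    p_alt = np.where(bases == alt, 1.0 - eps, eps / 3.0)
    p_het = 0.5 * (p_ref + p_alt)
    return np.array(
        [np.log(p_ref).sum(), np.log(p_het).sum(), np.log(p_alt).sum()]
    )


def genotype_posteriors(
    col: PileupColumn, alt: str, params: CallerParams
) -> np.ndarray:
    """Posterior probabilities of (hom-ref, het, hom-alt); sums to 1."""
    log_post = genotype_likelihoods(col, alt) + params.log_priors
    return np.exp(log_post - logsumexp(log_post))


def _decide(
    col: PileupColumn, alt: str, params: CallerParams
) -> Optional[Tuple[str, float]]:
    """Emit decision for one column: (genotype, qual) or None."""
    log_post = genotype_likelihoods(col, alt) + params.log_priors
    log_norm = logsumexp(log_post)
    log_p_homref = log_post[0] - log_norm
    # Phred of P(genotype != hom-ref | data)
    qual = min(-10.0 * log_p_homref / np.log(10.0), _MAX_QUAL)
    if qual < params.call_threshold:
        return None
    genotype = "het" if log_post[1] >= log_post[2] else "hom"
    return genotype, float(qual)


def _best_alt(col: PileupColumn) -> Optional[str]:
    """Non-reference base with the highest summed quality, or None."""
    scores: Dict[str, float] = {}
    for b, q in col.obs:
        if b != col.ref_base and b in "ACGT":
            scores[b] = scores.get(b, 0.0) + q
    if not scores:
        return None
    return max(sorted(scores), key=lambda b: scores[b])


def pileup_columns(
    reads: Iterable[AlignedRead],
    positions_by_chrom: Mapping[str, np.ndarray],
    reference: Mapping[str, str],
) -> Dict[Tuple[str, int], PileupColumn]:
    """Build pileup columns at the given (sorted) positions only.

    Only M-aligned bases contribute observations; positions with zero
    M-coverage produce no column.
    """
    columns: Dict[Tuple[str, int], PileupColumn] = {}
    pos_arrays = {c: np.asarray(p, dtype=np.int64) for c, p in positions_by_chrom.items()}
    for r in reads:
        parr = pos_arrays.get(r.chrom)
        if parr is None or parr.size == 0:
            continue
        rpos, qpos = r.pos, 0
        for op, n in r.cigar:
            if op == "M":
                lo = int(np.searchsorted(parr, rpos))
                hi = int(np.searchsorted(parr, rpos + n))
                for j in range(lo, hi):
                    p = int(parr[j])
                    off = qpos + (p - rpos)
                    key = (r.chrom, p)
                    col = columns.get(key)
                    if col is None:
                        col = PileupColumn(r.chrom, p, reference[r.chrom][p], [])
                        columns[key] = col
                    col.obs.append((r.bases[off], int(r.quals[off])))
                rpos += n
                qpos += n
            elif op == "D":
                rpos += n
            else:
                qpos += n
    return columns


def call_variants(
    reads: Sequence[AlignedRead],
    target: TargetSet,
    reference: Mapping[str, str],
    params: CallerParams = CallerParams(),
    depth_profile: Optional[DepthProfile] = None,
    positions: Optional[Mapping[str, Sequence[int]]] = None,
) -> List[VariantCall]:
    """Call diploid genotypes at targeted positions.

    ``positions`` restricts calling to the given per-chrom positions
    (e.g. a known-site panel); by default every targeted position is
    examined.  ``depth_at_site`` on each call uses the depth-profile
    definition (M+D) even though genotyping uses M-only observations.
    """
    if positions is None:
        positions = {}
        for iv in target:
            positions.setdefault(iv.chrom, []).extend(range(iv.start, iv.end))
    positions_by_chrom = {
        c: np.unique(np.asarray(list(p), dtype=np.int64)) for c, p in positions.items()
    }
    if depth_profile is None:
        depth_profile = compute_depth_profile(reads, target)
    columns = pileup_columns(reads, positions_by_chrom, reference)
    calls: List[VariantCall] = []
    for key in sorted(columns):
        col = columns[key]
        alt = _best_alt(col)
        if alt is None:
            continue
        decision = _decide(col, alt, params)
        if decision is None:
            continue
        genotype, qual = decision
        if not target.contains(col.chrom, col.pos):
            continue
        calls.append(
            VariantCall(
                chrom=col.chrom,
                pos=col.pos,
                ref_allele=col.ref_base,
                alt_allele=alt,
                genotype=genotype,
                qual=qual,
                depth_at_site=depth_profile.depth_at(col.chrom, col.pos),
            )
        )
    return calls
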