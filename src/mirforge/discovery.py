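"""Genome-based pre-miRNA discovery from collapsed small-RNA reads.

The pipeline anchors collapsed reads on the genome by exact match (both
strands, via an in-repo k-mer index), excises up to three flanking windows
around each sufficiently abundant anchor, folds each window, derives the
mature/star duplex from the pairing table under the Dicer 2-nt 3'-overhang
rule, scores the read signature (reads consistent with mature/star 5' ends
versus everything else in the window), filters against a contaminant
tRNA/rRNA database by local alignment, and merges overlapping candidate loci.

Filter defaults follow the corn-rootworm study design: 150-nt flanks, 56-nt
minimum precursor, mature abundance >= 10 RPM in at least one library,
contaminant rejection at >= 80% precursor coverage and >= 90% identity.
"""

from __future__ import annotations

import logging
import math
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .fold import resolve_backend
from .profiling import CollapsedRead, rpm
from .seqio import revcomp_dna, to_dna, to_rna

log = logging.getLogger(__name__)


@dataclass
class DiscoveryParams:
    flank: int = 150
    min_precursor: int = 56
    min_mature_rpm: float = 10.0
    contaminant_len_cov: float = 0.80
    contaminant_identity: float = 0.90
    max_genomic_hits: int = 15
    jitter: int = 2
    min_score: float = 1.0
    min_paired_fraction: float = 0.60
    min_anchor_count: int = 3  # absolute read-stack floor to seed a candidate
    fold_backend: str = "auto"
    name_prefix: str = "dvv-mir-N"


@dataclass(slots=True)
class MultiRead:
    """A collapsed read pooled across libraries."""
    sequence: str  # RNA
    count: int  # pooled
    per_library: Dict[str, int]


@dataclass(slots=True)
class Anchor:
    read: object  # CollapsedRead or MultiRead
    contig_id: str
    strand: str
    start: int  # 0-based genomic
    end: int  # half-open
    n_genomic_hits: int = 1

    @property
    def five_prime(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class HairpinCandidate:
    contig_id: str
    strand: str
    window_start: int
    window_end: int
    precursor_seq: str  # RNA, 5'->3' (reverse-complemented for -)
    structure: str
    pairing: List[int]
    mature_start: int  # precursor-local, half-open
    mature_end: int
    star_start: int
    star_end: int
    mature_rpm: float = 0.0
    signature_score: float = 0.0
    structure_paired_fraction: float = 0.0
    mature_paired_fraction: float = 0.0
    flags: Dict[str, bool] = field(default_factory=dict)

    def _local_to_genomic(self, lo: int, hi: int) -> Tuple[int, int]:
        if self.strand == "+":
            return self.window_start + lo, self.window_start + hi
        return self.window_end - hi, self.window_end - lo

    @property
    def mature_genomic(self) -> Tuple[int, int]:
        return self._local_to_genomic(self.mature_start, self.mature_end)

    @property
    def star_genomic(self) -> Tuple[int, int]:
        return self._local_to_genomic(self.star_start, self.star_end)

    @property
    def mature_five_prime(self) -> int:
        lo, hi = self.mature_genomic
        return lo if self.strand == "+" else hi - 1


@dataclass
class MiRnaRecord:
    name: str
    candidate: HairpinCandidate
    mature_seq: str
    star_seq: str

    @property
    def contig_id(self) -> str:
        return self.candidate.contig_id

    @property
    def strand(self) -> str:
        return self.candidate.strand

    @property
    def precursor_span(self) -> Tuple[int, int]:
        return self.candidate.window_start, self.candidate.window_end

    @property
    def mature_five_prime(self) -> int:
        return self.candidate.mature_five_prime


# --------------------------------------------------------------------------
# read mapping

class KmerIndex:
    """Exact-match seed index over the forward strand of every contig."""

    def __init__(self, contigs: Dict[str, str], k: int = 18):
        self.k = k
        self.contigs = {c: to_dna(s) for c, s in contigs.items()}
        index: Dict[str, List[Tuple[str, int]]] = {}
        for cid, seq in self.contigs.items():
            for i in range(len(seq) - k + 1):
                index.setdefault(seq[i:i + k], []).append((cid, i))
        self.index = index

    def _hits_forward(self, read: str) -> List[Tuple[str, int]]:
        k = self.k
        if len(read) < k:  # shorter than the seed: brute scan
            out = []
            for cid, seq in self.contigs.items():
                p = seq.find(read)
                while p != -1:
                    out.append((cid, p))
                    p = seq.find(read, p + 1)
            return out
        out = []
        for cid, p in self.index.get(read[:k], ()):
            if self.contigs[cid][p:p + len(read)] == read:
                out.append((cid, p))
        return out

    def find(self, read_dna: str) -> List[Tuple[str, int, str]]:
        """All exact occurrences as (contig, start, strand)."""
        hits = [(c, p, "+") for c, p in self._hits_forward(read_dna)]
        hits += [(c, p, "-") for c, p in self._hits_forward(revcomp_dna(read_dna))]
        return hits


def merge_libraries(collapsed_by_library: Dict[str, List[CollapsedRead]]) -> List[MultiRead]:
    pooled: Dict[str, Dict[str, int]] = {}
    for lib, reads in collapsed_by_library.items():
        for r in reads:
            pooled.setdefault(r.sequence, {})[lib] = (
                pooled.get(r.sequence, {}).get(lib, 0) + r.count)
    out = [MultiRead(sequence=s, count=sum(d.values()), per_library=d)
           for s, d in pooled.items()]
    out.sort(key=lambda m: (-m.count, m.sequence))
    return out


def map_reads(collapsed: Sequence, genome: Dict[str, str],
              max_genomic_hits: int = 15, index: Optional[KmerIndex] = None,
              ) -> List[Anchor]:
    """Anchor reads by exact match on both strands; multi-mappers above the
    cap are discarded."""
    if index is None:
        index = KmerIndex(genome)
    anchors: List[Anchor] = []
    n_discarded = 0
    for read in collapsed:
        hits = index.find(to_dna(read.sequence))
        if not hits:
            continue
        if len(hits) > max_genomic_hits:
            n_discarded += 1
            continue
        L = len(read.sequence)
        for cid, pos, strand in hits:
            anchors.append(Anchor(read=read, contig_id=cid, strand=strand,
                                  start=pos, end=pos + L,
                                  n_genomic_hits=len(hits)))
    if n_discarded:
        log.info("map_reads: discarded %d reads with > %d genomic hits",
                 n_discarded, max_genomic_hits)
    return anchors


# --------------------------------------------------------------------------
# window excision and duplex calling

def excise_windows(anchor: Anchor, genome: Dict[str, str],
                   flank: int = 150) -> List[Tuple[int, int]]:
    """Up to three genomic candidate windows around an anchor, clipped to the
    contig: full flanks, mature-on-5'-arm, mature-on-3'-arm."""
    clen = len(genome[anchor.contig_id])
    raw = [
        (anchor.start - flank, anchor.end + flank),
        (anchor.start - flank, anchor.end + 30),
        (anchor.start - 30, anchor.end + flank),
    ]
    out: List[Tuple[int, int]] = []
    for lo, hi in raw:
        win = (max(0, lo), min(clen, hi))
        if win not in out:
            out.append(win)
    return out


def window_sequence(genome: Dict[str, str], contig_id: str, start: int, end: int,
                    strand: str) -> str:
    seq = genome[contig_id][start:end]
    return to_rna(seq if strand == "+" else revcomp_dna(seq))


def call_duplex(pairing: List[int], mature_start: int, mature_end: int,
                max_loop_overlap: int = 4) -> Optional[Tuple[int, int]]:
    """Derive star coordinates from the pairing table with 2-nt 3' overhangs.

    The star spans the partners of mature[0 .. len-3] extended by 2 nt at its
    own 3' end; unpaired mature termini are resolved by the nearest paired
    position toward the loop. Returns None when the mature is entirely
    unpaired, crosses both arms, or overlaps the loop by more than
    ``max_loop_overlap`` nt.
    """
    n = len(pairing)
    m0, m1 = mature_start, mature_end
    if m0 < 0 or m1 > n or m1 - m0 < 3:
        return None
    core = [pairing[i] for i in range(m0, m1 - 2) if pairing[i] >= 0]
    paired_all = [i for i in range(m0, m1) if pairing[i] >= 0]
    if not core or not paired_all:
        return None
    below = [p for p in core if p < m0]
    above = [p for p in core if p >= m1]
    if below and above:  # partners on both sides: mature crosses the arms
        return None
    if not below and not above:  # only self-pairing within the mature
        return None
    partners = above if above else below
    star_lo, star_hi = min(partners), max(partners) + 1 + 2
    star_lo = max(0, star_lo)
    star_hi = min(n, star_hi)
    if star_hi - star_lo < 3:
        return None
    # loop intrusion: unpaired mature tail on the loop-facing side
    if above:  # mature on 5' arm, loop to its right
        intrusion = (m1 - 1) - max(paired_all)
    else:  # mature on 3' arm, loop to its left
        intrusion = min(paired_all) - m0
    if intrusion > max_loop_overlap:
        return None
    if star_lo < m1 and m0 < star_hi:  # star overlapping mature
        return None
    return star_lo, star_hi


# --------------------------------------------------------------------------
# read-signature scoring

class _AnchorLocator:
    """Per-(contig, strand) sorted arrays for fast window queries."""

    def __init__(self, anchors: Sequence[Anchor]):
        buckets: Dict[Tuple[str, str], List[Anchor]] = {}
        for a in anchors:
            buckets.setdefault((a.contig_id, a.strand), []).append(a)
        self.data: Dict[Tuple[str, str], Tuple[List[int], List[Anchor]]] = {}
        for key, anc in buckets.items():
            anc.sort(key=lambda a: a.start)
            self.data[key] = ([a.start for a in anc], anc)

    def overlapping(self, contig_id: str, strand: str, lo: int, hi: int,
                    max_read_len: int = 40) -> List[Anchor]:
        starts, anc = self.data.get((contig_id, strand), ([], []))
        i = bisect_left(starts, lo - max_read_len)
        j = bisect_right(starts, hi)
        return [a for a in anc[i:j] if a.start < hi and a.end > lo]


def signature_score(candidate: HairpinCandidate, anchors_in_window: Sequence[Anchor],
                    jitter: int = 2) -> Tuple[float, bool]:
    """Log-odds of duplex-consistent versus inconsistent read abundance.

    consistent = reads lying entirely within the precursor whose 5' end falls
    within +/- jitter of the mature or star 5' end; inconsistent = every other
    read overlapping the window. A +2 bonus applies when at least one read
    starts exactly at the star 5' end.
    """
    w0, w1 = candidate.window_start, candidate.window_end
    m5 = candidate.mature_five_prime
    s_lo, s_hi = candidate.star_genomic
    s5 = s_lo if candidate.strand == "+" else s_hi - 1
    consistent = 0
    inconsistent = 0
    star_exact = False
    for a in anchors_in_window:
        inside = a.start >= w0 and a.end <= w1
        d_m = abs(a.five_prime - m5)
        d_s = abs(a.five_prime - s5)
        if inside and (d_m <= jitter or d_s <= jitter):
            consistent += a.read.count
            if a.five_prime == s5:
                star_exact = True
        else:
            inconsistent += a.read.count
    score = math.log2((consistent + 1) / (inconsistent + 1))
    if star_exact:
        score += 2.0
    return score, star_exact


def mature_rpm_by_library(candidate: HairpinCandidate,
                          anchors_in_window: Sequence[Anchor],
                          lib_sizes: Dict[str, int], jitter: int = 2,
                          ) -> Dict[str, float]:
    """Per-library RPM of reads consistent with the mature 5' end."""
    w0, w1 = candidate.window_start, candidate.window_end
    m5 = candidate.mature_five_prime
    totals: Dict[str, int] = {}
    for a in anchors_in_window:
        if a.start >= w0 and a.end <= w1 and abs(a.five_prime - m5) <= jitter:
            per_lib = getattr(a.read, "per_library", None)
            if per_lib is None:
                per_lib = {a.read.library_id: a.read.count}
            for lib, c in per_lib.items():
                totals[lib] = totals.get(lib, 0) + c
    return {lib: rpm(c, lib_sizes[lib]) for lib, c in totals.items()}


# --------------------------------------------------------------------------
# contaminant filter (local Smith-Waterman alignment)

def _alignment_stats(aln) -> Tuple[int, int, int]:
    """(matches, aligned columns, target span) of a pairwise local alignment."""
    t_segs, q_segs = aln.aligned
    target = str(aln.target)
    query = str(aln.query)
    matches = 0
    columns = 0
    prev_t = prev_q = None
    for (t0, t1), (q0, q1) in zip(t_segs, q_segs):
        if prev_t is not None:
            columns += (t0 - prev_t) + (q0 - prev_q)
        for a, b in zip(target[t0:t1], query[q0:q1]):
            matches += a == b
        columns += t1 - t0
        prev_t, prev_q = t1, q1
    span = int(t_segs[-1][1] - t_segs[0][0]) if len(t_segs) else 0
    return matches, columns, span


def contaminant_filter(precursor_seq: str, contaminant_db: Dict[str, str],
                       len_cov: float = 0.80, identity: float = 0.90) -> bool:
    """True iff the precursor passes (is NOT a contaminant).

    Fails when a local alignment against any database entry (either
    orientation) covers >= ``len_cov`` of the precursor at >= ``identity``
    over the aligned span. Smith-Waterman scoring: match +1, mismatch -1,
    gap -2.
    """
    if not contaminant_db:
        log.info("contaminant_filter: empty database, auto-pass")
        return True
    from Bio import Align

    aligner = Align.PairwiseAligner(mode="local", match_score=1,
                                    mismatch_score=-1, open_gap_score=-2,
                                    extend_gap_score=-2)
    prec = to_dna(precursor_seq)
    for cont in contaminant_db.values():
        for query in (to_dna(cont), revcomp_dna(to_dna(cont))):
            alns = aligner.align(prec, query)
            if len(alns) == 0:
                continue
            matches, columns, span = _alignment_stats(alns[0])
            if columns == 0:
                continue
            if span / len(prec) >= len_cov and matches / columns >= identity:
                return False
    return True


# --------------------------------------------------------------------------
# the assembled discovery pipeline

def discover(collapsed_by_library: Dict[str, List[CollapsedRead]],
             genome: Dict[str, str], params: DiscoveryParams = DiscoveryParams(),
             contaminant_db: Optional[Dict[str, str]] = None,
             lib_sizes: Optional[Dict[str, int]] = None) -> List[MiRnaRecord]:
    """Full discovery: map, excise, fold, call duplex, score, filter, merge.

    ``lib_sizes`` should be each library's total retained read count (the RPM
    denominator); it defaults to the sum of the supplied collapsed counts.
    """
    folder = resolve_backend(params.fold_backend)
    if lib_sizes is None:
        lib_sizes = {lib: sum(r.count for r in reads)
                     for lib, reads in collapsed_by_library.items()}
    pooled = merge_libraries(collapsed_by_library)
    index = KmerIndex(genome)
    anchors = map_reads(pooled, genome, params.max_genomic_hits, index=index)
    locator = _AnchorLocator(anchors)

    # fold only anchors that could plausibly clear the abundance gate
    prefilter = 0.5 * params.min_mature_rpm
    def anchor_max_rpm(a: Anchor) -> float:
        return max((rpm(c, lib_sizes[lib]) for lib, c in a.read.per_library.items()
                    if lib in lib_sizes), default=0.0)

    candidates: List[HairpinCandidate] = []
    seen_five_primes: Dict[Tuple[str, str], List[int]] = {}
    work = [a for a in anchors
            if a.read.count >= params.min_anchor_count
            and anchor_max_rpm(a) >= prefilter]
    work.sort(key=lambda a: (-a.read.count, a.contig_id, a.start))
    for anchor in work:
        key = (anchor.contig_id, anchor.strand)
        if any(abs(anchor.five_prime - fp) <= params.jitter
               for fp in seen_five_primes.get(key, ())):
            continue  # jitter variant / star of an already-processed locus
        best: Optional[HairpinCandidate] = None
        for w0, w1 in excise_windows(anchor, genome, params.flank):
            if w1 - w0 < params.min_precursor:
                continue
            cand = _evaluate_window(anchor, w0, w1, genome, folder, locator,
                                    lib_sizes, params)
            if cand is None:
                continue
            if best is None or (cand.signature_score, cand.mature_rpm) > (
                    best.signature_score, best.mature_rpm):
                best = cand
        if best is not None and _passes(best, params, contaminant_db):
            candidates.append(best)
            lo, hi = best.mature_genomic
            s_lo, s_hi = best.star_genomic
            fps = seen_five_primes.setdefault(key, [])
            fps.append(best.mature_five_prime)
            fps.append(s_lo if best.strand == "+" else s_hi - 1)
    merged = merge_loci(candidates)
    merged.sort(key=lambda c: (c.contig_id, c.window_start))
    records = []
    for i, cand in enumerate(merged, 1):
        mat = cand.precursor_seq[cand.mature_start:cand.mature_end]
        star = cand.precursor_seq[cand.star_start:cand.star_end]
        records.append(MiRnaRecord(name=f"{params.name_prefix}{i}",
                                   candidate=cand, mature_seq=mat, star_seq=star))
    return records


def _evaluate_window(anchor: Anchor, w0: int, w1: int, genome: Dict[str, str],
                     folder, locator: _AnchorLocator, lib_sizes: Dict[str, int],
                     params: DiscoveryParams) -> Optional[HairpinCandidate]:
    seq = window_sequence(genome, anchor.contig_id, w0, w1, anchor.strand)
    if anchor.strand == "+":
        lm0, lm1 = anchor.start - w0, anchor.end - w0
    else:
        lm0, lm1 = w1 - anchor.end, w1 - anchor.start
    if lm0 < 0 or lm1 > len(seq):
        return None
    structure, pairing, pfrac = folder(seq)
    star = call_duplex(pairing, lm0, lm1)
    if star is None:
        return None
    mat_paired = sum(1 for i in range(lm0, lm1) if pairing[i] >= 0) / (lm1 - lm0)
    cand = HairpinCandidate(
        contig_id=anchor.contig_id, strand=anchor.strand,
        window_start=w0, window_end=w1, precursor_seq=seq, structure=structure,
        pairing=pairing, mature_start=lm0, mature_end=lm1,
        star_start=star[0], star_end=star[1],
        structure_paired_fraction=pfrac, mature_paired_fraction=mat_paired,
    )
    win_anchors = locator.overlapping(anchor.contig_id, anchor.strand, w0, w1)
    by_lib = mature_rpm_by_library(cand, win_anchors, lib_sizes, params.jitter)
    cand.mature_rpm = max(by_lib.values(), default=0.0)
    score, star_supported = signature_score(cand, win_anchors, params.jitter)
    cand.signature_score = score
    cand.flags["star_supported"] = star_supported
    return cand


def _passes(cand: HairpinCandidate, params: DiscoveryParams,
            contaminant_db: Optional[Dict[str, str]]) -> bool:
    cand.flags["passed_length"] = (
        cand.window_end - cand.window_start >= params.min_precursor)
    cand.flags["passed_abundance"] = cand.mature_rpm >= params.min_mature_rpm
    cand.flags["passed_structure"] = (
        cand.mature_paired_fraction >= params.min_paired_fraction)
    cand.flags["passed_score"] = cand.signature_score >= params.min_score
    ok = all(cand.flags[k] for k in
             ("passed_length", "passed_abundance", "passed_structure", "passed_score"))
    if not ok:
        log.debug("candidate %s:%d-%d rejected: %s", cand.contig_id,
                  cand.window_start, cand.window_end, cand.flags)
        return False
    cand.flags["passed_contaminant"] = contaminant_filter(
        cand.precursor_seq, contaminant_db or {},
        params.contaminant_len_cov, params.contaminant_identity)
    return cand.flags["passed_contaminant"]


def merge_loci(candidates: List[HairpinCandidate]) -> List[HairpinCandidate]:
    """Merge candidates whose mature/star duplex spans overlap on the same
    contig and strand; the highest signature score (then mature RPM) wins."""
    def duplex_span(c: HairpinCandidate) -> Tuple[int, int]:
        (m0, m1), (s0, s1) = c.mature_genomic, c.star_genomic
        return min(m0, s0), max(m1, s1)

    kept: List[HairpinCandidate] = []
    for cand in sorted(candidates,
                       key=lambda c: (-c.signature_score, -c.mature_rpm,
                                      c.contig_id, c.window_start)):
        lo, hi = duplex_span(cand)
        clash = any(k.contig_id == cand.contig_id and k.strand == cand.strand
                    and lo < duplex_span(k)[1] and duplex_span(k)[0] < hi
                    for k in kept)
        if not clash:
            kept.append(cand)
    return kept


# --------------------------------------------------------------------------
# export

def write_gff3(records: Sequence[MiRnaRecord], path) -> None:
    """GFF3 with pre-miRNA / miRNA / miRNA* features (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rec in records:
            c = rec.candidate
            fh.write("\t".join([
                c.contig_id, "mirforge", "pre_miRNA",
                str(c.window_start + 1), str(c.window_end),
                f"{c.signature_score:.3f}", c.strand, ".",
                f"ID={rec.name};mature_rpm={c.mature_rpm:.2f}"]) + "\n")
            for feat, (lo, hi) in (("miRNA", c.mature_genomic),
                                   ("miRNA_star", c.star_genomic)):
                fh.write("\t".join([
                    c.contig_id, "mirforge", feat, str(lo + 1), str(hi), ".",
                    c.strand, ".", f"ID={rec.name}.{feat};Parent={rec.name}"]) + "\n")


def records_to_frame(records: Sequence[MiRnaRecord]):
    import pandas as pd

    rows = []
    for rec in records:
        c = rec.candidate
        (m0, m1), (s0, s1) = c.mature_genomic, c.star_genomic
        rows.append({
            "name": rec.name, "contig_id": c.contig_id, "strand": c.strand,
            "window_start": c.window_start, "window_end": c.window_end,
            "mature_start": m0, "mature_end": m1,
            "star_start": s0, "star_end": s1,
            "mature_seq": rec.mature_seq, "star_seq": rec.star_seq,
            "mature_rpm": c.mature_rpm, "signature_score": c.signature_score,
            "mature_paired_fraction": c.mature_paired_fraction,
            "star_supported": c.flags.get("star_supported", False),
        })
    return pd.DataFrame(rows)
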