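"""PARE degradome analysis: tag mapping, target scoring, categories, p-values.

Twenty-nt PARE tags mark uncapped 5' ends of cleaved transcripts. Candidate
miRNA target sites are scored by the position-weighted complementarity
penalty standard for plant/animal degradome pipelines: per miRNA position
(1-based from the 5' end) a mismatch costs 1, a G:U wobble 0.5, Watson-Crick
0, with positions 2-13 doubled; the candidate cleavage position is the
transcript nucleotide pairing miRNA position 10 (the canonical 10-11 cut).
Occupied sites are ranked into categories 0-4 by tag abundance relative to
the transcript's maximum and median, and assessed against a
dinucleotide-shuffle null. Final calls keep categories 0-2 with p < 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .seqio import revcomp_rna, to_rna

log = logging.getLogger(__name__)

TAG_LEN = 20
SEED_DOUBLED = (2, 13)  # 1-based inclusive positions with doubled weight


@dataclass
class DegradomeProfile:
    transcript_id: str
    length: int
    five_prime_counts: np.ndarray  # per-position tag 5'-end counts

    @property
    def total_tags(self) -> int:
        return int(self.five_prime_counts.sum())


@dataclass
class TargetHit:
    mirna_name: str
    transcript_id: str
    cleavage_pos: int  # 0-based transcript coordinate
    duplex_score: float
    category: int = -1
    p_value: float = 1.0
    site_reads: int = 0
    site_start: int = 0  # 0-based start of the paired site on the transcript
    library_id: str = ""


def map_tags(tags: Sequence[str], transcriptome: Dict[str, str],
             ) -> Dict[str, DegradomeProfile]:
    """Exact sense-strand mapping of 20-nt tags; counts accrue at the mapped
    5'-most position, in every matching transcript."""
    if not transcriptome:
        raise ValueError("empty transcriptome")
    from .discovery import KmerIndex

    index = KmerIndex({k: v for k, v in transcriptome.items()}, k=TAG_LEN)
    profiles = {tid: DegradomeProfile(tid, len(seq), np.zeros(len(seq), dtype=np.int64))
                for tid, seq in transcriptome.items()}
    n_bad = n_unmapped = 0
    from collections import Counter

    counted = Counter(to_rna(t) for t in tags)
    for tag_rna, count in counted.items():
        if len(tag_rna) != TAG_LEN:
            n_bad += count
            continue
        hits = index._hits_forward(tag_rna.replace("U", "T"))
        if not hits:
            n_unmapped += count
            continue
        if len(hits) > 1:
            log.debug("tag maps to %d transcripts; counted in each", len(hits))
        for tid, pos in hits:
            profiles[tid].five_prime_counts[pos] += count
    if n_bad:
        log.warning("map_tags: dropped %d tags with length != %d", n_bad, TAG_LEN)
    if n_unmapped:
        log.info("map_tags: %d tags had no exact sense match", n_unmapped)
    return profiles


# --------------------------------------------------------------------------
# complementarity scoring

_ENC = {"A": 0, "C": 1, "G": 2, "U": 3}
# penalty[miRNA base, target base] for an antiparallel duplex:
# 0 = Watson-Crick, 0.5 = G:U wobble, 1 = mismatch
_PENALTY = np.ones((4, 4), dtype=float)
for _m, _t in [("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")]:
    _PENALTY[_ENC[_m], _ENC[_t]] = 0.0
for _m, _t in [("G", "U"), ("U", "G")]:
    _PENALTY[_ENC[_m], _ENC[_t]] = 0.5


def _weights(m: int) -> np.ndarray:
    w = np.ones(m)
    w[SEED_DOUBLED[0] - 1:SEED_DOUBLED[1]] = 2.0
    return w


def duplex_score(mirna_seq: str, target_site_seq: str) -> float:
    """Position-weighted complementarity penalty of an ungapped duplex.

    ``target_site_seq`` is the transcript site in sense orientation, the same
    length as the miRNA; the miRNA is compared against its reverse-complement
    register (miRNA position i pairs the site's (len-i)-th nucleotide).
    """
    q = to_rna(mirna_seq)
    s = to_rna(target_site_seq)
    if len(q) != len(s):
        raise ValueError("site length must equal miRNA length")
    m = len(q)
    qi = np.array([_ENC[c] for c in q])
    si = np.array([_ENC[c] for c in s[::-1]])  # site base pairing miRNA pos i
    return float((_PENALTY[qi, si] * _weights(m)).sum())


def _scan_scores(mirna_enc: np.ndarray, tx_enc: np.ndarray) -> np.ndarray:
    """duplex_score at every ungapped register of a transcript (vectorized)."""
    m = len(mirna_enc)
    n = len(tx_enc)
    if n < m:
        return np.empty(0)
    windows = np.lib.stride_tricks.sliding_window_view(tx_enc, m)[:, ::-1]
    pen = _PENALTY[mirna_enc[None, :], windows]
    return pen @ _weights(m)


def find_sites(mirna_seq: str, transcript_seq: str, max_score: float = 7.0,
               mirna_name: str = "", transcript_id: str = "") -> List[TargetHit]:
    """All ungapped registers scoring <= max_score (inclusive threshold).

    The whole transcript is searched, not only the 3' UTR. The cleavage
    position is the transcript coordinate opposite miRNA position 10.
    """
    q = to_rna(mirna_seq)
    tx = to_rna(transcript_seq)
    if len(tx) < len(q):
        return []
    qi = np.array([_ENC[c] for c in q])
    ti = np.array([_ENC[c] for c in tx])
    scores = _scan_scores(qi, ti)
    m = len(q)
    out = []
    for p in np.flatnonzero(scores <= max_score + 1e-9):
        out.append(TargetHit(mirna_name=mirna_name, transcript_id=transcript_id,
                             cleavage_pos=int(p) + m - 10,
                             duplex_score=float(scores[p]), site_start=int(p)))
    return out


# --------------------------------------------------------------------------
# categories

def categorize(profile: DegradomeProfile, cleavage_pos: int) -> Optional[int]:
    """Abundance category 0-4 of an occupied cleavage position.

    With max = the transcript's maximum per-position count and med = the
    median over occupied positions: 4 = single read; 0 = unique maximum;
    1 = shared maximum; 2 = above the median but below the maximum;
    3 = at or below the median. Unoccupied positions get no category.
    """
    counts = profile.five_prime_counts
    if cleavage_pos < 0 or cleavage_pos >= len(counts):
        raise ValueError("cleavage position out of transcript range")
    if counts.sum() == 0:
        raise ValueError("profile has no mapped tags")
    site = int(counts[cleavage_pos])
    if site == 0:
        return None
    if site == 1:
        return 4
    mx = int(counts.max())
    occupied = counts[counts >= 1]
    med = float(np.median(occupied))
    if site == mx:
        return 0 if int((counts == mx).sum()) == 1 else 1
    if site > med:
        return 2
    return 3


# --------------------------------------------------------------------------
# dinucleotide-shuffle null

def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Dinucleotide-composition-preserving shuffle (random Eulerian walk)."""
    s = to_rna(seq)
    if len(s) <= 2:
        return s
    edges: Dict[str, List[str]] = {}
    for a, b in zip(s, s[1:]):
        edges.setdefault(a, []).append(b)
    # retry random walks on the dinucleotide multigraph until one consumes
    # every edge (a valid walk exists because the original sequence is one)
    for _ in range(50):
        trial_edges = {a: list(v) for a, v in edges.items()}
        out = [s[0]]
        cur = s[0]
        ok = True
        for _i in range(len(s) - 1):
            lst = trial_edges.get(cur)
            if not lst:
                ok = False
                break
            idx = int(rng.integers(0, len(lst)))
            cur = lst.pop(idx)
            out.append(cur)
        if ok:
            return "".join(out)
    return s  # degenerate composition; fall back to the original


def site_pvalue(hit: TargetHit, mirna_seq: str, transcriptome: Dict[str, str],
                profile: Optional[DegradomeProfile] = None,
                n_shuffles: int = 100, seed: int = 1) -> float:
    """Empirical p against dinucleotide-shuffled miRNAs, add-one corrected.

    A shuffle succeeds when it reaches duplex_score <= the observed score at
    >= 1 site of the same transcript whose cleavage position has category <=
    the observed category (any occupied site when no profile is supplied).
    """
    rng = np.random.default_rng([int(seed), 131])
    tx = to_rna(transcriptome[hit.transcript_id])
    ti = np.array([_ENC[c] for c in tx])
    m = len(to_rna(mirna_seq))
    successes = 0
    obs_cat = hit.category if hit.category is not None and hit.category >= 0 else 4
    for _ in range(n_shuffles):
        shuf = dinucleotide_shuffle(mirna_seq, rng)
        qi = np.array([_ENC[c] for c in to_rna(shuf)])
        scores = _scan_scores(qi, ti)
        good = np.flatnonzero(scores <= hit.duplex_score + 1e-9)
        for p in good:
            cpos = int(p) + m - 10
            if profile is None:
                successes += 1
                break
            if 0 <= cpos < len(profile.five_prime_counts):
                cat = (categorize(profile, cpos)
                       if profile.five_prime_counts[cpos] > 0 else None)
                if cat is not None and cat <= obs_cat:
                    successes += 1
                    break
    return (1 + successes) / (n_shuffles + 1)


# --------------------------------------------------------------------------
# assembled target calling

@dataclass
class DegradomeParams:
    max_score: float = 7.0
    max_category: int = 2
    alpha: float = 0.05
    n_shuffles: int = 100
    seed: int = 1


@dataclass
class VennSummary:
    shared: int
    private: Dict[str, int] = field(default_factory=dict)
    targets_by_library: Dict[str, set] = field(default_factory=dict)


def call_targets(mirnas: Dict[str, str], transcriptome: Dict[str, str],
                 profiles_by_library: Dict[str, Dict[str, DegradomeProfile]],
                 params: DegradomeParams = DegradomeParams(),
                 ) -> Tuple[List[TargetHit], Optional[VennSummary]]:
    """Score, categorize and filter target candidates in each PARE library.

    Retains hits with category <= 2 and p < 0.05 (strict). With >= 2
    libraries a summary counts targets shared by all libraries versus
    library-specific ones.
    """
    if not profiles_by_library:
        raise ValueError("at least one PARE profile library is required")
    retained: List[TargetHit] = []
    per_lib_targets: Dict[str, set] = {}
    for lib, profiles in profiles_by_library.items():
        keys = set()
        for mname, mseq in mirnas.items():
            for tid, tseq in transcriptome.items():
                prof = profiles.get(tid)
                if prof is None or prof.total_tags == 0:
                    continue
                for hit in find_sites(mseq, tseq, params.max_score,
                                      mirna_name=mname, transcript_id=tid):
                    if not 0 <= hit.cleavage_pos < prof.length:
                        continue
                    hit.site_reads = int(prof.five_prime_counts[hit.cleavage_pos])
                    if hit.site_reads == 0:
                        continue
                    hit.category = categorize(prof, hit.cleavage_pos)
                    if hit.category is None or hit.category > params.max_category:
                        continue
                    hit.p_value = site_pvalue(hit, mseq, transcriptome, prof,
                                              params.n_shuffles, params.seed)
                    if hit.p_value < params.alpha:
                        hit.library_id = lib
                        retained.append(hit)
                        keys.add((mname, tid, hit.cleavage_pos))
        per_lib_targets[lib] = keys
    venn = None
    if len(profiles_by_library) >= 2:
        sets = list(per_lib_targets.values())
        shared = set.intersection(*sets)
        others = {lib: len(k - set.union(*(v for l2, v in per_lib_targets.items()
                                           if l2 != lib)))
                  for lib, k in per_lib_targets.items()}
        venn = VennSummary(shared=len(shared), private=others,
                           targets_by_library=per_lib_targets)
    return retained, venn


def hits_to_frame(hits: Sequence[TargetHit]):
    import pandas as pd

    return pd.DataFrame([{
        "mirna": h.mirna_name, "transcript": h.transcript_id,
        "cleavage_pos_1based": h.cleavage_pos + 1, "score": h.duplex_score,
        "category": h.category, "p_value": h.p_value, "site_reads": h.site_reads,
        "library": h.library_id,
    } for h in hits])
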