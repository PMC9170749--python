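"""Synthetic data with planted ground truth.

Everything downstream of this module (profiling, discovery, conservation,
expression, clusters, degradome) is exercised on data generated here:

* a random i.i.d.-uniform background genome carrying non-overlapping planted
  stem-loop precursors whose mature/star duplex obeys the canonical Dicer
  2-nt 3' overhang geometry on a fully paired stem (at most 2 mismatches are
  injected into the stem *outside* the duplex region);
* per-library read sets emulating a multi-stage design: Dicer-processed
  mature/star read stacks with 5'-end jitter, a 26-29-nt piRNA-like positional
  background whose relative abundance follows a per-stage gradient, abundant
  contaminant (rRNA-like) fragment stacks, and random-position degradation
  filler of 21-24 nt topping each library up to its configured depth;
* a sibling-species mature set derived by per-sequence point mutation;
* PARE tag libraries concentrated at planted cleavage positions.

All randomness flows from ``SimulationConfig.seed``; identical seeds yield
byte-identical artifacts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .seqio import revcomp_dna, to_rna

_BASES = np.array(list("ACGT"))
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
_WOBBLE = {"G": "C", "T": "G"}  # DNA letters whose partner also wobble-pairs them

DEFAULT_STAGES: Tuple[Tuple[str, int], ...] = (
    ("egg", 3), ("L1", 3), ("L2", 3), ("early_pupa", 3), ("late_pupa", 3), ("adult", 3),
)

# piRNA size-class fraction gradient, highest in eggs, lowest in adults.
DEFAULT_PIRNA_FRACTIONS: Dict[str, float] = {
    "egg": 0.40, "L1": 0.37, "L2": 0.34, "early_pupa": 0.31,
    "late_pupa": 0.28, "adult": 0.25,
}


class CapacityError(ValueError):
    """Raised when planted features cannot be placed without overlap."""


@dataclass
class PlantedHairpin:
    name: str
    contig_id: str
    strand: str
    precursor_start: int
    precursor_end: int
    mature_seq: str  # RNA, 5'->3'
    star_seq: str
    loop_len: int
    arm: str  # "5p" | "3p"
    per_stage_abundance: Dict[str, float]
    # genomic duplex coordinates (0-based half-open)
    mature_start: int = 0
    mature_end: int = 0
    star_start: int = 0
    star_end: int = 0

    @property
    def mature_five_prime(self) -> int:
        return self.mature_start if self.strand == "+" else self.mature_end - 1

    @property
    def max_rpm(self) -> float:
        return max(self.per_stage_abundance.values(), default=0.0)


@dataclass
class ContaminantInsert:
    name: str
    sequence: str  # DNA, genome orientation
    start: int
    end: int
    fragment_sites: List[Tuple[int, int]] = field(default_factory=list)  # (genomic start, length)


@dataclass
class SimulationConfig:
    genome_len: int = 100_000
    n_hairpins: int = 20
    stages: Sequence[Tuple[str, int]] = DEFAULT_STAGES
    pirna_fraction_by_stage: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PIRNA_FRACTIONS))
    read_depth: int = 1_000_000
    snp_rate: float = 0.3
    seed: int = 1
    contaminant_count: int = 4
    # read-stack error model
    jitter_probs: Tuple[float, float, float] = (0.1, 0.8, 0.1)  # P(-1), P(0), P(+1)
    star_fraction: float = 0.05
    # abundance model: planted matures share the per-stage miRNA-class budget
    # (1 - piRNA fraction) of the library, proportionally to log-uniform weights
    weight_range: Tuple[float, float] = (1.0, 20.0)
    frac_low_abundance: float = 0.10   # planted below the 10-RPM discovery gate
    low_rpm: float = 3.0
    frac_stage_specific: float = 0.20
    stage_specific_fold: float = 8.0
    degradation_fraction: float = 0.0  # random-position 21-24 nt filler share
    contaminant_rpm: float = 200.0
    contig_id: str = "chr1"

    def validate(self) -> None:
        if not self.stages:
            raise ValueError("stages must be non-empty")
        for stage, _reps in self.stages:
            f = self.pirna_fraction_by_stage.get(stage)
            if f is None or not 0.0 <= f <= 1.0:
                raise ValueError(f"piRNA fraction for stage {stage!r} must be in [0,1]")
        if not 0.0 <= self.snp_rate <= 1.0:
            raise ValueError("snp_rate must be in [0,1]")
        if abs(sum(self.jitter_probs) - 1.0) > 1e-9:
            raise ValueError("jitter probabilities must sum to 1")

    @property
    def stage_names(self) -> List[str]:
        return [s for s, _ in self.stages]


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, n)])


def _place(rng: np.random.Generator, genome_len: int, length: int,
           occupied: List[Tuple[int, int]], margin: int = 350) -> int:
    """Place a feature in unoccupied space, keeping ``margin`` nt clearance.

    The margin exceeds the discovery excision window's half-width so one
    locus's read stack cannot fall inside a neighboring locus's window
    (stacked neighbors would otherwise count against its read signature);
    loci can still co-cluster at gaps up to the 3-kb cluster threshold.
    """
    for _ in range(2000):
        pos = int(rng.integers(0, genome_len - length))
        if all(pos >= e + margin or pos + length + margin <= s for s, e in occupied):
            occupied.append((pos, pos + length))
            return pos
    raise CapacityError("could not place feature without overlap; genome too small")


def _build_hairpin(rng: np.random.Generator) -> Tuple[str, int, int, int, int, int, str, int]:
    """Construct one precursor (DNA) with planted duplex geometry.

    Returns (precursor, m0, m1, s0, s1, loop_len, arm, stem_len) with
    precursor-local, half-open mature/star coordinates.
    """
    mlen = int(rng.integers(21, 24))
    loop_len = int(rng.integers(8, 16))
    ext = int(rng.integers(4, 11))
    stem = mlen + 4 + ext
    arm5 = _random_dna(rng, stem)
    loop = _random_dna(rng, loop_len)
    precursor = arm5 + loop + revcomp_dna(arm5)
    n = len(precursor)
    t = n - 1  # perfect-stem partner of position i is t - i
    arm = "5p" if rng.random() < 0.5 else "3p"
    if arm == "5p":
        m0, m1 = 2, 2 + mlen
    else:
        m1 = n - 2
        m0 = m1 - mlen
    s0, s1 = t - m1 + 3, t - m0 + 3
    # plant 2-3 G:U wobbles inside the mature/star duplex: the stem stays fully
    # paired, but the locus is no longer a perfect inverted repeat, so duplex
    # reads map to their true strand only (as in real genomes)
    chars = list(precursor)
    arm5_lo = m0 if arm == "5p" else t - (m1 - 1)
    n_wob = int(rng.integers(2, 4))
    wob_pos = sorted(rng.choice(np.arange(3, mlen - 5), size=n_wob, replace=False))
    for off in wob_pos:
        p5 = arm5_lo + int(off)
        chars[p5] = "G"
        chars[t - p5] = "T"  # G:U wobble (DNA alphabet)
    precursor = "".join(chars)
    # inject <=2 stem mismatches between the duplex and the loop
    duplex_hi = max(m1 if arm == "5p" else s1, 0)
    free = [p for p in range(duplex_hi + 2, stem - 1)]
    n_mm = int(rng.integers(0, 3))
    chars = list(precursor)
    for p in rng.choice(len(free), size=min(n_mm, len(free)), replace=False) if free else []:
        pos5 = free[int(p)]
        partner = t - pos5
        good = _COMP[chars[pos5]]
        banned = {good}
        if chars[pos5] in _WOBBLE:
            banned.add(_WOBBLE[chars[pos5]])
        choices = [b for b in "ACGT" if b not in banned]
        chars[partner] = choices[int(rng.integers(0, len(choices)))]
    precursor = "".join(chars)
    return precursor, m0, m1, s0, s1, loop_len, arm, stem


def _assign_abundances(rng: np.random.Generator, cfg: SimulationConfig,
                       n: int) -> List[Dict[str, float]]:
    """Per-stage RPM for each hairpin.

    A few hairpins sit at a fixed low RPM (below the discovery gate); the rest
    split each stage's miRNA-class read budget, (1 - piRNA fraction -
    degradation fraction) x 10^6 RPM, proportionally to log-uniform weights.
    Stage-specific hairpins carry full weight in one randomly chosen stage and
    1/stage_specific_fold elsewhere.
    """
    stages = cfg.stage_names
    lo, hi = cfg.weight_range
    kinds: List[Tuple[str, float, str]] = []  # (kind, weight, hot_stage)
    for _ in range(n):
        u = rng.random()
        w = float(math.exp(rng.uniform(math.log(lo), math.log(hi))))
        if u < cfg.frac_low_abundance:
            kinds.append(("low", 0.0, ""))
        elif u < cfg.frac_low_abundance + cfg.frac_stage_specific:
            kinds.append(("specific", w, stages[int(rng.integers(0, len(stages)))]))
        else:
            kinds.append(("flat", w, ""))
    out: List[Dict[str, float]] = [dict() for _ in range(n)]
    contaminant_rpm_total = 2 * cfg.contaminant_count * cfg.contaminant_rpm
    for stage in stages:
        budget = (1.0 - cfg.pirna_fraction_by_stage[stage]
                  - cfg.degradation_fraction) * 1e6
        budget -= contaminant_rpm_total
        budget -= sum(cfg.low_rpm for k, _, _ in kinds if k == "low")
        # star reads ride along at star_fraction of each mature stack
        budget /= 1.0 + cfg.star_fraction
        mults = [0.0 if k == "low" else
                 (w if k == "flat" or hot == stage else w / cfg.stage_specific_fold)
                 for k, w, hot in kinds]
        total_w = sum(mults)
        for i, (kind, _w, _hot) in enumerate(kinds):
            if kind == "low":
                out[i][stage] = cfg.low_rpm
            else:
                out[i][stage] = mults[i] / total_w * max(budget, 0.0) if total_w else 0.0
    return out


def plant_genome(cfg: SimulationConfig) -> Tuple[Dict[str, str], List[PlantedHairpin],
                                                 List[ContaminantInsert]]:
    """Generate a background genome with planted precursors and contaminants."""
    cfg.validate()
    if cfg.n_hairpins and cfg.genome_len < cfg.n_hairpins * 400:
        raise CapacityError("genome_len must be >= n_hairpins * 400")
    rng = np.random.default_rng([int(cfg.seed), 11])
    genome = list(_random_dna(rng, cfg.genome_len))
    occupied: List[Tuple[int, int]] = []
    truth: List[PlantedHairpin] = []
    abundances = _assign_abundances(rng, cfg, cfg.n_hairpins)
    for i in range(cfg.n_hairpins):
        precursor, m0, m1, s0, s1, loop_len, arm, _stem = _build_hairpin(rng)
        n = len(precursor)
        strand = "+" if rng.random() < 0.5 else "-"
        pos = _place(rng, cfg.genome_len, n, occupied)
        inserted = precursor if strand == "+" else revcomp_dna(precursor)
        genome[pos:pos + n] = inserted

        def g(local_lo: int, local_hi: int) -> Tuple[int, int]:
            if strand == "+":
                return pos + local_lo, pos + local_hi
            return pos + n - local_hi, pos + n - local_lo

        ms, me = g(m0, m1)
        ss, se = g(s0, s1)
        hp = PlantedHairpin(
            name=f"planted-{i + 1}",
            contig_id=cfg.contig_id,
            strand=strand,
            precursor_start=pos,
            precursor_end=pos + n,
            mature_seq=to_rna(precursor[m0:m1]),
            star_seq=to_rna(precursor[s0:s1]),
            loop_len=loop_len,
            arm=arm,
            per_stage_abundance=abundances[i],
            mature_start=ms, mature_end=me, star_start=ss, star_end=se,
        )
        truth.append(hp)
    contaminants: List[ContaminantInsert] = []
    for c in range(cfg.contaminant_count):
        length = int(rng.integers(350, 501))
        seq = _random_dna(rng, length)
        pos = _place(rng, cfg.genome_len, length, occupied)
        genome[pos:pos + length] = seq
        mid = pos + length // 2
        contaminants.append(ContaminantInsert(
            name=f"contam-{c + 1}", sequence=seq, start=pos, end=pos + length,
            fragment_sites=[(mid - 40, 21), (mid + 10, 22)],
        ))
    return {cfg.contig_id: "".join(genome)}, truth, contaminants


def _stack_reads(rng: np.random.Generator, genome: str, strand: str,
                 g_start: int, g_end: int, n_reads: int,
                 jitter_probs: Tuple[float, float, float], out: List[str]) -> None:
    """Emit n_reads copies of a duplex-strand read with 5'-end jitter of -1/0/+1."""
    if n_reads <= 0:
        return
    length = g_end - g_start
    counts = rng.multinomial(n_reads, jitter_probs)
    for shift, c in zip((-1, 0, 1), counts):
        if c == 0:
            continue
        if strand == "+":
            lo = g_start + shift
            seq = genome[lo:lo + length]
        else:
            five = (g_end - 1) - shift
            seq = revcomp_dna(genome[five - length + 1:five + 1])
        if len(seq) == length:
            out.extend([seq] * int(c))


def simulate_reads(genome: Dict[str, str], truth: List[PlantedHairpin],
                   cfg: SimulationConfig,
                   contaminants: Sequence[ContaminantInsert] = (),
                   ) -> Tuple[Dict[str, List[str]], pd.DataFrame]:
    """Simulate per-library read sets (DNA strings) and a library manifest."""
    cfg.validate()
    contig = genome[cfg.contig_id]
    glen = len(contig)
    libraries: Dict[str, List[str]] = {}
    manifest_rows = []
    lib_idx = 0
    for stage, reps in cfg.stages:
        pf = cfg.pirna_fraction_by_stage[stage]
        for rep in range(1, reps + 1):
            rng = np.random.default_rng([int(cfg.seed), 23, lib_idx])
            lib_idx += 1
            lib_id = f"{stage}_r{rep}"
            depth = cfg.read_depth
            reads: List[str] = []
            for hp in truth:
                rpm = hp.per_stage_abundance.get(stage, 0.0)
                n_m = int(rng.poisson(rpm * depth / 1e6)) if rpm > 0 else 0
                _stack_reads(rng, contig, hp.strand, hp.mature_start, hp.mature_end,
                             n_m, cfg.jitter_probs, reads)
                n_s = int(rng.binomial(n_m, cfg.star_fraction)) if n_m else 0
                _stack_reads(rng, contig, hp.strand, hp.star_start, hp.star_end,
                             n_s, cfg.jitter_probs, reads)
            for cont in contaminants:
                for fs, flen in cont.fragment_sites:
                    n_f = int(rng.poisson(cfg.contaminant_rpm * depth / 1e6))
                    if n_f:
                        reads.extend([contig[fs:fs + flen]] * n_f)
            n_pirna = int(rng.binomial(depth, pf))
            _random_position_reads(rng, contig, glen, n_pirna, 26, 29, reads)
            if cfg.degradation_fraction > 0:
                n_fill = int(rng.binomial(depth, cfg.degradation_fraction))
                _random_position_reads(rng, contig, glen, n_fill, 21, 24, reads)
            libraries[lib_id] = reads
            manifest_rows.append((lib_id, stage, rep, len(reads)))
    manifest = pd.DataFrame(manifest_rows,
                            columns=["library_id", "stage", "replicate", "depth"])
    return libraries, manifest


def _random_position_reads(rng: np.random.Generator, contig: str, glen: int,
                           n: int, min_len: int, max_len: int, out: List[str]) -> None:
    if n <= 0:
        return
    lens = rng.integers(min_len, max_len + 1, n)
    poss = rng.integers(0, glen - max_len, n)
    strands = rng.random(n) < 0.5
    for ln, p, fwd in zip(lens, poss, strands):
        seq = contig[p:p + ln]
        out.append(seq if fwd else revcomp_dna(seq))


@dataclass
class SiblingMature:
    name: str
    sequence: str  # RNA
    snp_position: Optional[int] = None  # 0-based within the mature
    allele_a: Optional[str] = None
    allele_b: Optional[str] = None


def mutate_sibling(matures: Sequence, snp_rate: float, seed: int) -> List[SiblingMature]:
    """Derive a sibling-species mature set by per-sequence point mutation.

    Each mature independently receives exactly one random substitution with
    probability ``snp_rate``. Accepts PlantedHairpin records or (name, seq)
    pairs; sequences are handled in the RNA alphabet.
    """
    if not 0.0 <= snp_rate <= 1.0:
        raise ValueError("snp_rate must be in [0,1]")
    rng = np.random.default_rng([int(seed), 101])
    out: List[SiblingMature] = []
    for m in matures:
        name, seq = (m.name, m.mature_seq) if hasattr(m, "mature_seq") else m
        seq = to_rna(seq)
        if rng.random() < snp_rate:
            pos = int(rng.integers(0, len(seq)))
            alts = [b for b in "ACGU" if b != seq[pos]]
            new = alts[int(rng.integers(0, 3))]
            out.append(SiblingMature(name=name,
                                     sequence=seq[:pos] + new + seq[pos + 1:],
                                     snp_position=pos, allele_a=seq[pos], allele_b=new))
        else:
            out.append(SiblingMature(name=name, sequence=seq))
    return out


# --------------------------------------------------------------------------
# PARE / degradome simulation

PARE_TAG_LEN = 20


@dataclass
class CleavageSite:
    transcript_id: str
    position: int  # 0-based 5' end of the downstream cleavage fragment
    n_tags: int
    mirna_name: Optional[str] = None


def make_pare_dataset(n_transcripts: int = 20, transcript_len: int = 1000,
                      n_mirnas: int = 10, mirna_len: int = 21, seed: int = 1,
                      tags_per_site: int = 50,
                      ) -> Tuple[Dict[str, str], Dict[str, str], List[CleavageSite]]:
    """Random transcriptome + miRNA set with one planted perfect site per miRNA.

    The target site is the exact reverse complement of the miRNA, and the
    recorded cleavage position sits opposite miRNA nucleotides 10-11.
    """
    rng = np.random.default_rng([int(seed), 57])
    transcripts = {f"tx{i + 1}": _random_dna(rng, transcript_len)
                   for i in range(n_transcripts)}
    mirnas: Dict[str, str] = {}
    truth: List[CleavageSite] = []
    tx_ids = list(transcripts)
    occupied: Dict[str, List[Tuple[int, int]]] = {tid: [] for tid in tx_ids}
    for j in range(n_mirnas):
        name = f"syn-mir-{j + 1}"
        mseq = _random_dna(rng, mirna_len)
        mirnas[name] = to_rna(mseq)
        tid = tx_ids[j % len(tx_ids)]  # round-robin keeps sites from colliding
        tx = transcripts[tid]
        for _ in range(100):
            pos = int(rng.integers(50, len(tx) - 50 - mirna_len))
            if all(pos + mirna_len + 10 <= s or e + 10 <= pos
                   for s, e in occupied[tid]):
                break
        else:
            raise CapacityError("could not place a non-overlapping target site")
        occupied[tid].append((pos, pos + mirna_len))
        site = revcomp_dna(mseq)
        transcripts[tid] = tx[:pos] + site + tx[pos + mirna_len:]
        cleavage = pos + mirna_len - 10  # opposite miRNA position 10
        truth.append(CleavageSite(transcript_id=tid, position=cleavage,
                                  n_tags=tags_per_site, mirna_name=name))
    return transcripts, mirnas, truth


def simulate_pare(transcripts: Dict[str, str], cleavage_truth: Sequence[CleavageSite],
                  seed: int = 1, signal_fraction: float = 0.8) -> List[str]:
    """Simulate 20-nt PARE tags (DNA strings, transcript sense strand)."""
    if not 0.0 <= signal_fraction <= 1.0:
        raise ValueError("signal_fraction must be in [0,1]")
    rng = np.random.default_rng([int(seed), 71])
    tags: List[str] = []
    for site in cleavage_truth:
        tx = transcripts[site.transcript_id]
        if site.position > len(tx) - PARE_TAG_LEN or site.position < 0:
            raise ValueError(
                f"cleavage site {site.position} beyond usable range of "
                f"{site.transcript_id} (len {len(tx)})")
        n_signal = int(rng.binomial(site.n_tags, signal_fraction))
        tags.extend([tx[site.position:site.position + PARE_TAG_LEN]] * n_signal)
        n_noise = site.n_tags - n_signal
        if n_noise:
            poss = rng.integers(0, len(tx) - PARE_TAG_LEN + 1, n_noise)
            tags.extend(tx[p:p + PARE_TAG_LEN] for p in poss)
    return tags


def write_truth_tsv(path, truth: Sequence[PlantedHairpin]) -> None:
    rows = [{
        "name": h.name, "contig_id": h.contig_id, "strand": h.strand,
        "precursor_start": h.precursor_start, "precursor_end": h.precursor_end,
        "mature_start": h.mature_start, "mature_end": h.mature_end,
        "star_start": h.star_start, "star_end": h.star_end,
        "mature_seq": h.mature_seq, "star_seq": h.star_seq,
        "loop_len": h.loop_len, "arm": h.arm,
        **{f"rpm_{s}": v for s, v in h.per_stage_abundance.items()},
    } for h in truth]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
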