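"""miRNA count matrices, differential expression, and life-stage categories.

Differential expression between stages uses an exact conditional
negative-binomial test: replicate counts are scaled to a common library size,
summed per group, and the per-group sums compared conditionally on their
total, with a single common dispersion estimated across all miRNAs by the
method of moments (floored at 0.01). A miRNA is differentially expressed when
the fold change exceeds ``fold_change_min`` and p < ``alpha`` (raw p-values;
an optional Benjamini-Hochberg correction is off by default).

Life-stage categories: ``unique:<stage>`` when a miRNA is up-regulated and
significant against every other stage group; ``broad`` when no pairwise
comparison is significant and the overall mean RPM exceeds ``broad_rpm_min``;
``other`` for everything else. Categories partition the miRNA set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .profiling import rpm as rpm_of


@dataclass
class StageCallParams:
    fold_change_min: float = 2.0
    alpha: float = 0.05
    broad_rpm_min: float = 50.0  # the study's Methods value; 100 also defensible
    merge_groups: Optional[List[Tuple[str, str, str]]] = None  # (a, b, merged label)
    bh_correction: bool = False
    dispersion_floor: float = 0.01

    def __post_init__(self):
        if self.fold_change_min <= 1:
            raise ValueError("fold_change_min must exceed 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0,1)")


@dataclass
class CountMatrix:
    counts: pd.DataFrame  # rows miRNAs, columns library ids, integer counts
    lib_sizes: pd.Series  # per-library totals (RPM denominator)
    stages: pd.Series  # library id -> stage label

    def __post_init__(self):
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate miRNA names in count matrix")
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        missing = [c for c in self.counts.columns if c not in self.stages.index]
        if missing:
            raise ValueError(f"libraries without stage labels: {missing}")

    def stage_libraries(self, stage: str) -> List[str]:
        return [lib for lib in self.counts.columns if self.stages[lib] == stage]

    def stage_names(self) -> List[str]:
        seen = []
        for lib in self.counts.columns:
            if self.stages[lib] not in seen:
                seen.append(self.stages[lib])
        return seen

    def rpm(self) -> pd.DataFrame:
        return self.counts * 1e6 / self.lib_sizes[self.counts.columns]

    def to_tsv(self, path) -> None:
        out = self.counts.copy()
        out.columns = [f"{lib}|{self.stages[lib]}" for lib in out.columns]
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, lib_sizes: Optional[Dict[str, int]] = None) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        libs, stages = [], {}
        for col in df.columns:
            lib, stage = col.split("|", 1)
            libs.append(lib)
            stages[lib] = stage
        df.columns = libs
        sizes = pd.Series(lib_sizes) if lib_sizes else df.sum(axis=0)
        return cls(counts=df.astype(int), lib_sizes=sizes.astype(float),
                   stages=pd.Series(stages))


def count_mature(records: Sequence, collapsed_by_library: Dict[str, List],
                 genome: Dict[str, str], stages_by_library: Dict[str, str],
                 jitter: int = 2, lib_sizes: Optional[Dict[str, int]] = None,
                 max_genomic_hits: int = 15) -> CountMatrix:
    """Raw mature counts per discovered miRNA per library.

    A read contributes when its genomic 5' end falls within +/- ``jitter`` of
    the locus mature 5' end (same contig and strand) and its length is within
    +/- 2 of the mature length.
    """
    from .discovery import KmerIndex, map_reads

    names = [r.name for r in records]
    if len(set(names)) != len(names):
        raise ValueError("duplicate miRNA names")
    index = KmerIndex(genome)
    data = {}
    for lib, collapsed in collapsed_by_library.items():
        anchors = map_reads(collapsed, genome, max_genomic_hits, index=index)
        by_key: Dict[tuple, List] = {}
        for a in anchors:
            by_key.setdefault((a.contig_id, a.strand), []).append(a)
        col = []
        for rec in records:
            c = rec.candidate
            m5 = c.mature_five_prime
            mlen = c.mature_end - c.mature_start
            total = 0
            for a in by_key.get((c.contig_id, c.strand), ()):
                if (abs(a.five_prime - m5) <= jitter
                        and abs((a.end - a.start) - mlen) <= 2):
                    total += a.read.count
            col.append(total)
        data[lib] = col
    counts = pd.DataFrame(data, index=names)
    sizes = pd.Series(lib_sizes) if lib_sizes else pd.Series(
        {lib: sum(r.count for r in reads)
         for lib, reads in collapsed_by_library.items()})
    return CountMatrix(counts=counts, lib_sizes=sizes.astype(float),
                       stages=pd.Series(stages_by_library))


def _common_dispersion(scaled: np.ndarray, floor: float) -> float:
    """Method-of-moments common dispersion pooled across miRNAs.

    For NB counts, E[var] = mean + phi * mean^2; pooling moments as
    phi = sum(var - mean) / sum(mean^2) weights each miRNA by its information
    and is close to unbiased at small replicate numbers, where per-miRNA
    moment estimates are individually very noisy.
    """
    m = scaled.mean(axis=1)
    v = scaled.var(axis=1, ddof=1)
    ok = m > 0
    if not ok.any():
        return floor
    est = float((v[ok] - m[ok]).sum() / (m[ok] ** 2).sum())
    return max(est, floor)


def _exact_nb_pvalue(sa: int, sb: int, na: int, nb: int, phi: float) -> float:
    """Two-sided exact test of group-sum counts conditional on their total.

    The sum of n i.i.d. NB(mu, phi) replicates is NB(n*mu, phi/n); p is the
    total conditional probability of outcomes no more likely than the one
    observed.
    """
    t = sa + sb
    if t == 0:
        return 1.0
    mu = t / (na + nb)
    ra, rb = na / phi, nb / phi
    pa_, pb_ = ra / (ra + na * mu), rb / (rb + nb * mu)
    k = np.arange(t + 1)
    logp = (stats.nbinom.logpmf(k, ra, pa_)
            + stats.nbinom.logpmf(t - k, rb, pb_))
    logp -= logp.max()
    p = np.exp(logp)
    total = p.sum()
    p_obs = p[sa]
    return float(p[p <= p_obs * (1 + 1e-12)].sum() / total)


def de_test(matrix: CountMatrix, stage_a: str, stage_b: str,
            params: StageCallParams = StageCallParams()) -> pd.DataFrame:
    """Per-miRNA log2 fold change (mean RPM, pseudocount 0.5) and exact-NB p."""
    libs_a = matrix.stage_libraries(stage_a)
    libs_b = matrix.stage_libraries(stage_b)
    if not libs_a or not libs_b:
        raise ValueError(f"stage missing from matrix: "
                         f"{stage_a if not libs_a else stage_b!r}")
    counts_a = matrix.counts[libs_a].to_numpy(float)
    counts_b = matrix.counts[libs_b].to_numpy(float)
    sizes_a = matrix.lib_sizes[libs_a].to_numpy(float)
    sizes_b = matrix.lib_sizes[libs_b].to_numpy(float)
    rpm_a = (counts_a * 1e6 / sizes_a).mean(axis=1)
    rpm_b = (counts_b * 1e6 / sizes_b).mean(axis=1)
    log2fc = np.log2((rpm_a + 0.5) / (rpm_b + 0.5))

    ref = float(np.concatenate([sizes_a, sizes_b]).mean())
    scaled_a = np.rint(counts_a * (ref / sizes_a)).astype(int)
    scaled_b = np.rint(counts_b * (ref / sizes_b)).astype(int)
    phi = _common_dispersion(np.hstack([scaled_a, scaled_b]),
                             params.dispersion_floor)
    na, nb = len(libs_a), len(libs_b)
    pvals = np.array([
        _exact_nb_pvalue(int(sa), int(sb), na, nb, phi)
        for sa, sb in zip(scaled_a.sum(axis=1), scaled_b.sum(axis=1))])
    out = pd.DataFrame({"log2fc": log2fc, "p_value": pvals},
                       index=matrix.counts.index)
    padj = out["p_value"]
    if params.bh_correction:
        padj = pd.Series(_bh(out["p_value"].to_numpy()), index=out.index)
        out["p_adj"] = padj
    out["de"] = (np.abs(out["log2fc"]) > math.log2(params.fold_change_min)) & (
        padj < params.alpha)
    return out


def _bh(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def maybe_merge_stages(matrix: CountMatrix, stage_a: str, stage_b: str,
                       merged_label: str,
                       params: StageCallParams = StageCallParams(),
                       ) -> Tuple[CountMatrix, bool, int]:
    """Merge two stage labels when fewer than five miRNAs separate them."""
    n_de = int(de_test(matrix, stage_a, stage_b, params)["de"].sum())
    if n_de >= 5:
        return matrix, False, n_de
    stages = matrix.stages.replace({stage_a: merged_label, stage_b: merged_label})
    return CountMatrix(counts=matrix.counts, lib_sizes=matrix.lib_sizes,
                       stages=stages), True, n_de


def classify_expression(matrix: CountMatrix,
                        params: StageCallParams = StageCallParams()) -> pd.Series:
    """Assign each miRNA exactly one of broad / unique:<stage> / other."""
    stages = matrix.stage_names()
    pair_results: Dict[Tuple[str, str], pd.DataFrame] = {}
    for i, a in enumerate(stages):
        for b in stages[i + 1:]:
            pair_results[(a, b)] = de_test(matrix, a, b, params)

    def result(a: str, b: str) -> Tuple[pd.Series, pd.Series]:
        """(de flag, log2fc of a over b) for an ordered stage pair."""
        if (a, b) in pair_results:
            r = pair_results[(a, b)]
            return r["de"], r["log2fc"]
        r = pair_results[(b, a)]
        return r["de"], -r["log2fc"]

    mean_rpm = matrix.rpm().mean(axis=1)
    labels = {}
    for mirna in matrix.counts.index:
        any_de = any(pair_results[p]["de"][mirna] for p in pair_results)
        label = None
        for s in stages:
            up_everywhere = all(
                result(s, t)[0][mirna] and result(s, t)[1][mirna] > 0
                for t in stages if t != s)
            if up_everywhere:
                label = f"unique:{s}"
                break
        if label is None:
            if not any_de and mean_rpm[mirna] > params.broad_rpm_min:
                label = "broad"
            else:
                label = "other"
        labels[mirna] = label
    return pd.Series(labels, name="category")
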