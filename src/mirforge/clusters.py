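"""Genomic miRNA cluster detection and co-expression summaries.

A cluster is a maximal run of >= 2 precursors on the same contig and strand
with every neighboring gap (next start minus current end, half-open
coordinates) at most ``max_gap`` nt — 3 kb by default, inclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Dict, List, Sequence, Tuple

import numpy as np

log = logging.getLogger(__name__)


@dataclass
class ClusterRecord:
    contig_id: str
    strand: str
    members: List[Tuple[str, int, int]]  # (name, start, end), sorted by start
    gaps: List[int]

    @property
    def span(self) -> Tuple[int, int]:
        return self.members[0][1], self.members[-1][2]

    @property
    def member_names(self) -> List[str]:
        return [m[0] for m in self.members]


def scan_clusters(annotations: Sequence[Tuple[str, str, str, int, int]],
                  max_gap: int = 3000) -> List[ClusterRecord]:
    """Single left-to-right sweep per (contig, strand).

    ``annotations``: iterable of (name, contig, strand, start, end) with
    0-based half-open coordinates. Overlapping precursors are chained with a
    gap of 0 (warned).
    """
    groups: Dict[Tuple[str, str], List[Tuple[str, int, int]]] = {}
    for name, contig, strand, start, end in annotations:
        groups.setdefault((contig, strand), []).append((name, int(start), int(end)))
    clusters: List[ClusterRecord] = []
    for (contig, strand), precs in sorted(groups.items()):
        precs.sort(key=lambda p: (p[1], p[2], p[0]))
        run: List[Tuple[str, int, int]] = []
        gaps: List[int] = []
        def flush():
            if len(run) >= 2:
                clusters.append(ClusterRecord(contig_id=contig, strand=strand,
                                              members=list(run), gaps=list(gaps)))
        for prec in precs:
            if not run:
                run = [prec]
                gaps = []
                continue
            gap = prec[1] - run[-1][2]
            if gap < 0:
                log.warning("overlapping precursors %s and %s on %s%s; gap set to 0",
                            run[-1][0], prec[0], contig, strand)
                gap = 0
            if gap <= max_gap:
                run.append(prec)
                gaps.append(gap)
            else:
                flush()
                run = [prec]
                gaps = []
        flush()
    clusters.sort(key=lambda c: (c.contig_id, c.strand, c.span[0]))
    return clusters


def cluster_coexpression(cluster: ClusterRecord, matrix,
                         ) -> Tuple[Dict[Tuple[str, str], float], float]:
    """Pairwise Pearson correlation of members' log2(mean stage RPM + 0.5)
    profiles, and the median pairwise r."""
    names = cluster.member_names
    missing = [n for n in names if n not in matrix.counts.index]
    if missing:
        raise ValueError(f"cluster members missing from count matrix: {missing}")
    stages = matrix.stage_names()
    rpm = matrix.rpm()
    profiles = {}
    for n in names:
        prof = [rpm.loc[n, matrix.stage_libraries(s)].mean() for s in stages]
        profiles[n] = np.log2(np.asarray(prof) + 0.5)
    pairwise = {}
    for a, b in combinations(names, 2):
        x, y = profiles[a], profiles[b]
        if np.std(x) == 0 or np.std(y) == 0:
            r = 0.0
        else:
            r = float(np.corrcoef(x, y)[0, 1])
        pairwise[(a, b)] = r
    median_r = float(np.median(list(pairwise.values()))) if pairwise else float("nan")
    return pairwise, median_r


def write_bed(clusters: Sequence[ClusterRecord], path) -> None:
    with open(path, "w") as fh:
        for i, c in enumerate(clusters, 1):
            lo, hi = c.span
            fh.write(f"{c.contig_id}\t{lo}\t{hi}\tcluster{i}\t{len(c.members)}"
                     f"\t{c.strand}\n")
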