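"""Cross-species mature-miRNA conservation, families, SNPs, 5'-nt spectrum.

Matching follows the two joint criteria used throughout the field for mature
miRNA orthology: an ungapped overlap of at least 20 nt with at most 2
mismatches, evaluated over every sliding offset of query against reference
(no reverse complement — mature miRNAs are orientation-fixed). A miRNA is
"conserved" when a qualifying match exists in at least one other species.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass
from importlib import resources
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .seqio import to_rna

MIN_ALIGNED = 20
MAX_MISMATCHES = 2

TABLE1_SHA256 = "7e8560ff16807eaa30abd4941eef659a3ad52384064b69e5849cae66ea7c2f70"


@dataclass(frozen=True, slots=True)
class MatureRef:
    species_code: str
    name: str
    sequence: str  # RNA

    def __post_init__(self):
        if not 18 <= len(self.sequence) <= 26:
            raise ValueError(f"mature reference {self.name}: length "
                             f"{len(self.sequence)} outside 18-26 nt")


@dataclass(slots=True)
class ConservationHit:
    query_name: str
    ref: MatureRef
    aligned_len: int
    mismatches: int
    offset: int  # query start position minus reference start position


def match_mature(query_seq: str, ref_set: Sequence[MatureRef],
                 query_name: str = "query",
                 min_aligned: int = MIN_ALIGNED,
                 max_mismatches: int = MAX_MISMATCHES) -> List[ConservationHit]:
    """Best qualifying ungapped hit per reference (max overlap, min mismatches)."""
    q = to_rna(query_seq)
    hits: List[ConservationHit] = []
    for ref in ref_set:
        r = ref.sequence
        best: Optional[Tuple[int, int, int]] = None  # (aligned, -mism, offset) keyed
        for offset in range(-(len(q) - min_aligned), len(r) - min_aligned + 1):
            # query position i aligns reference position i - offset
            lo = max(0, offset)
            hi = min(len(q), len(r) + offset)
            aligned = hi - lo
            if aligned < min_aligned:
                continue
            mism = sum(q[i] != r[i - offset] for i in range(lo, hi))
            if mism > max_mismatches:
                continue
            key = (aligned, -mism)
            if best is None or key > (best[0], -best[1]):
                best = (aligned, mism, offset)
        if best is not None:
            hits.append(ConservationHit(query_name=query_name, ref=ref,
                                        aligned_len=best[0], mismatches=best[1],
                                        offset=best[2]))
    return hits


_FAMILY_ROOTS = {"mir", "let", "bantam", "iab", "lin", "lsy"}


def family_from_name(name: str) -> str:
    """Canonical family label of a miRBase-style identifier.

    dme-miR-2a-3p -> mir-2; dvi-mir-279b -> mir-279; dvi-let-7 -> let-7;
    dvi-mir-iab-4 -> mir-iab-4; dvi-bantam -> bantam.
    """
    core = re.sub(r"-[35]p$", "", name.strip().lower())
    parts = core.split("-")
    if len(parts) > 1 and parts[0] not in _FAMILY_ROOTS and parts[1] in _FAMILY_ROOTS:
        core = "-".join(parts[1:])  # drop the species prefix
    # strip a trailing paralog letter after the family number (mir-2a -> mir-2)
    return re.sub(r"(\d)[a-z]+$", r"\1", core)


def classify_conservation(queries: Sequence[Tuple[str, str]],
                          ref_sets_by_species: Dict[str, Sequence[MatureRef]],
                          query_species: str = "dvv") -> pd.DataFrame:
    """Label queries conserved/non-conserved; inherit or assign family names.

    A query is conserved iff it has a qualifying hit in at least one species
    other than its own. Non-conserved queries get serial novel names
    (``<species>-mir-N<k>``) in discovery order.
    """
    if not ref_sets_by_species:
        raise ValueError("at least one reference species set is required")
    rows = []
    novel = 0
    for name, seq in queries:
        best_hit: Optional[ConservationHit] = None
        hit_species = []
        for sp, refs in ref_sets_by_species.items():
            if sp == query_species:
                continue
            hits = match_mature(seq, refs, query_name=name)
            if hits:
                hit_species.append(sp)
                top = max(hits, key=lambda h: (h.aligned_len, -h.mismatches))
                if best_hit is None or (top.aligned_len, -top.mismatches) > (
                        best_hit.aligned_len, -best_hit.mismatches):
                    best_hit = top
        conserved = bool(hit_species)
        if conserved:
            family = family_from_name(best_hit.ref.name)
        else:
            novel += 1
            family = f"{query_species}-mir-N{novel}"
        rows.append({"query": name, "sequence": to_rna(seq), "conserved": conserved,
                     "family": family, "n_species": len(hit_species),
                     "best_ref": best_hit.ref.name if best_hit else "",
                     "best_mismatches": best_hit.mismatches if best_hit else pd.NA})
    return pd.DataFrame(rows)


def presence_matrix(sets_by_species: Dict[str, Sequence[MatureRef]]) -> pd.DataFrame:
    """Family x species boolean matrix; rows ordered by decreasing species
    count, then family name."""
    if len(sets_by_species) < 2:
        raise ValueError("need at least 2 species")
    families: Dict[str, Dict[str, bool]] = {}
    for sp, refs in sets_by_species.items():
        for ref in refs:
            families.setdefault(family_from_name(ref.name), {})[sp] = True
    cols = list(sets_by_species)
    mat = pd.DataFrame(
        [[families[f].get(sp, False) for sp in cols] for f in families],
        index=list(families), columns=cols, dtype=bool)
    order = sorted(mat.index, key=lambda f: (-int(mat.loc[f].sum()), f))
    return mat.loc[order]


def detect_snps(set_a: Sequence[MatureRef], set_b: Sequence[MatureRef],
                ) -> List[Tuple[str, str, int, str, str]]:
    """Mismatch positions between counterpart matures of two sibling sets.

    Counterparts are established by best qualifying match; each record is
    (name_a, name_b, position_in_a, allele_a, allele_b). Identical pairs
    contribute nothing.
    """
    out = []
    for a in set_a:
        hits = match_mature(a.sequence, set_b, query_name=a.name)
        if not hits:
            continue
        best = max(hits, key=lambda h: (h.aligned_len, -h.mismatches))
        if best.mismatches == 0:
            continue
        r = best.ref.sequence
        off = best.offset
        lo = max(0, off)
        hi = min(len(a.sequence), len(r) + off)
        for i in range(lo, hi):
            if a.sequence[i] != r[i - off]:
                out.append((a.name, best.ref.name, i, a.sequence[i], r[i - off]))
    return out


def first_nt_spectrum(sequences: Iterable[str]) -> Dict[str, float]:
    """Fractions of A/C/G/U at the first position of a mature set."""
    seqs = [to_rna(s) for s in sequences]
    if not seqs:
        raise ValueError("empty mature set")
    counts = {b: 0 for b in "ACGU"}
    for s in seqs:
        counts[s[0]] += 1
    n = len(seqs)
    return {b: c / n for b, c in counts.items()}


# --------------------------------------------------------------------------
# packaged conserved-miRNA fixture

def table1_path():
    return resources.files("mirforge.data").joinpath("table1_wcr_conserved.tsv")


def load_table1(verify_checksum: bool = True) -> pd.DataFrame:
    """The packaged conserved-miRNA table (family, member, mature_seq, ncr_flag)."""
    p = table1_path()
    raw = p.read_bytes()
    if verify_checksum:
        digest = hashlib.sha256(raw).hexdigest()
        if digest != TABLE1_SHA256:
            raise ValueError("packaged conserved-miRNA fixture failed its checksum")
    from io import BytesIO

    return pd.read_csv(BytesIO(raw), sep="\t",
                       dtype={"family": str, "member": str, "mature_seq": str,
                              "ncr_flag": int})
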