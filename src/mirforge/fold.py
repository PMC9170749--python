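"""RNA secondary-structure prediction by nested base-pair maximization.

The default backend is a Nussinov-style dynamic program maximizing the number
of nested base pairs (AU/UA, GC/CG, GU/UG) with a minimum hairpin loop of
3 unpaired nucleotides. Traceback is deterministic: the outermost compatible
pair is preferred, then the leftmost bifurcation. A thermodynamic backend
(ViennaRNA's RNAfold, if its Python binding is importable) can be substituted;
every consumer in this package reads only the (structure, pairing) contract.

Base-pair maximization is a combinatorial, not thermodynamic, objective: on
long windows many co-optimal structures exist, which is why the discovery
pipeline prefers the thermodynamic backend when present.
"""

from __future__ import annotations

from typing import Callable, Dict, List, Tuple

import numpy as np

from .seqio import to_rna

MIN_LOOP = 3

# Watson-Crick + wobble, encoded over A=0 C=1 G=2 U=3.
_CAN_PAIR = np.zeros((4, 4), dtype=bool)
for a, b in [(0, 3), (3, 0), (2, 1), (1, 2), (2, 3), (3, 2)]:
    _CAN_PAIR[a, b] = True

_ENC = {"A": 0, "C": 1, "G": 2, "U": 3}


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_ENC[c] for c in seq], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"non-RNA character in sequence: {exc.args[0]!r}") from None


def pairing_from_dotbracket(structure: str) -> List[int]:
    """Partner table from a dot-bracket string (-1 = unpaired)."""
    pairing = [-1] * len(structure)
    stack: List[int] = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            j = stack.pop()
            pairing[j] = i
            pairing[i] = j
    if stack:
        raise ValueError("unbalanced dot-bracket string")
    return pairing


def paired_fraction(pairing: List[int]) -> float:
    if not pairing:
        return 0.0
    return sum(1 for p in pairing if p >= 0) / len(pairing)


def _nussinov_dp(code: np.ndarray, min_loop: int = MIN_LOOP) -> np.ndarray:
    """Fill the max-pair DP table, vectorized over anti-diagonals."""
    n = len(code)
    dp = np.zeros((n, n), dtype=np.int32)
    can = _CAN_PAIR[code[:, None], code[None, :]]
    for s in range(min_loop + 1, n):
        i = np.arange(n - s)
        j = i + s
        # bifurcation over split point d (d=0 covers "i unpaired", d=s-1 covers "j unpaired")
        rows = i[:, None]
        d = np.arange(s)[None, :]
        best = (dp[rows, rows + d] + dp[rows + d + 1, rows + s]).max(axis=1)
        pair = dp[i + 1, j - 1] + 1
        dp[i, j] = np.where(can[i, j], np.maximum(best, pair), best)
    return dp


def _traceback(code: np.ndarray, dp: np.ndarray, min_loop: int = MIN_LOOP) -> List[int]:
    n = len(code)
    pairing = [-1] * n
    can = _CAN_PAIR
    stack = [(0, n - 1)] if n else []
    while stack:
        i, j = stack.pop()
        if j - i <= min_loop or dp[i, j] == 0:
            continue
        if can[code[i], code[j]] and dp[i, j] == dp[i + 1, j - 1] + 1:
            pairing[i] = j
            pairing[j] = i
            stack.append((i + 1, j - 1))
            continue
        for k in range(i, j):
            if dp[i, j] == dp[i, k] + dp[k + 1, j]:
                stack.append((i, k))
                stack.append((k + 1, j))
                break
    return pairing


def fold_nussinov(seq: str) -> Tuple[str, List[int], float]:
    rna = to_rna(seq)
    if not rna:
        raise ValueError("empty sequence")
    code = _encode(rna)
    dp = _nussinov_dp(code)
    pairing = _traceback(code, dp)
    structure = "".join(
        "." if p < 0 else ("(" if p > i else ")") for i, p in enumerate(pairing)
    )
    return structure, pairing, paired_fraction(pairing)


def fold_vienna(seq: str) -> Tuple[str, List[int], float]:
    """Thermodynamic MFE structure via the ViennaRNA Python binding."""
    import RNA  # noqa: deferred so the default path has no hard dependency

    rna = to_rna(seq)
    if not rna:
        raise ValueError("empty sequence")
    _encode(rna)  # alphabet validation
    structure, _mfe = RNA.fold(rna)
    pairing = pairing_from_dotbracket(structure)
    return structure, pairing, paired_fraction(pairing)


BACKENDS: Dict[str, Callable[[str], Tuple[str, List[int], float]]] = {
    "nussinov": fold_nussinov,
    "vienna": fold_vienna,
}


def resolve_backend(name: str = "nussinov") -> Callable[[str], Tuple[str, List[int], float]]:
    """Resolve a folding backend name; "auto" prefers the thermodynamic folder."""
    if name == "auto":
        try:
            import RNA  # noqa: F401

            return fold_vienna
        except ImportError:
            return fold_nussinov
    return BACKENDS[name]


def fold(seq: str, backend: str = "nussinov") -> Tuple[str, List[int], float]:
    """Fold an RNA string; returns (dot-bracket, partner table, paired fraction)."""
    return resolve_backend(backend)(seq)
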