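"""Pairwise-alignment scoring shared by the taxonomy module.

Reads are compared to references with banded edit-distance alignment
(edlib). Raw distances are converted to a match/mismatch score
(match +1, any edit -2) and then to E-values with Karlin-Altschul
statistics, so that the classification decision rules can be expressed
as E-value cutoffs and between-clade E-value ratios.
"""

from __future__ import annotations

import math
import re
from functools import lru_cache

import edlib
import numpy as np
from scipy.optimize import brentq

MATCH_SCORE = 1
EDIT_SCORE = -2  # mismatches and gap columns
KA_K = 0.3  # Karlin-Altschul K for this score scheme (fixed)

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

#: symmetric base pairs edlib should treat as equal (IUPAC ambiguity codes)
IUPAC_EQUALITIES = [
    (code, base)
    for code, bases in IUPAC.items()
    if len(bases) > 1
    for base in bases
]

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

_CIGAR_RE = re.compile(r"(\d+)([=XID])")


def revcomp(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@lru_cache(maxsize=None)
def karlin_lambda(match: int = MATCH_SCORE, edit: int = EDIT_SCORE) -> float:
    """Ungapped Karlin-Altschul lambda for a uniform-composition
    match/mismatch score scheme: the positive root of
    sum_ij p_i p_j exp(lambda * s_ij) = 1 with p = 1/4.
    """
    def f(lam: float) -> float:
        return 0.25 * math.exp(lam * match) + 0.75 * math.exp(lam * edit) - 1.0

    return brentq(f, 1e-6, 10.0)


def log10_evalue(score: float, query_len: int, db_len: int) -> float:
    """log10 of E = K * m * n * exp(-lambda * S)."""
    if query_len <= 0 or db_len <= 0:
        return math.inf
    lam = karlin_lambda()
    return math.log10(KA_K * query_len * db_len) - lam * score / math.log(10.0)


def evalue(score: float, query_len: int, db_len: int) -> float:
    """E-value clamped into (0, +inf) to stay representable."""
    return 10.0 ** max(min(log10_evalue(score, query_len, db_len), 300.0), -300.0)


def edit_distance(a: str, b: str, k: int = -1) -> int:
    """Banded global (NW) edit distance; -1 if it exceeds the band k."""
    return edlib.align(a, b, mode="NW", task="distance", k=k)["editDistance"]


def global_identity(a: str, b: str) -> float:
    """Global identity 1 - d / max(len): the fraction of the longer
    sequence matched under an end-to-end alignment."""
    if not a or not b:
        return 0.0
    d = edit_distance(a, b)
    return 1.0 - d / max(len(a), len(b))


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    return [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]


class AlignmentStats:
    """Summary of one read-vs-reference alignment.

    Computed from an end-to-end extended-CIGAR alignment with terminal
    indel runs stripped, which makes the aligned region equivalent to a
    semi-global (glocal) alignment for near-full-length amplicons:

    - ``identity``: matches / alignment columns over the aligned region,
      with internal gap columns counted as mismatches.
    - ``ref_coverage``: aligned reference span / full reference length.
    - ``score``: matches - 2 * (mismatches + internal gap columns).
    """

    __slots__ = ("score", "identity", "ref_coverage", "distance", "columns")

    def __init__(self, score, identity, ref_coverage, distance, columns):
        self.score = score
        self.identity = identity
        self.ref_coverage = ref_coverage
        self.distance = distance
        self.columns = columns


def align_stats(read_seq: str, ref_seq: str) -> AlignmentStats | None:
    """Align a read to one reference and summarize; None for empty input."""
    if not read_seq or not ref_seq:
        return None
    res = edlib.align(read_seq, ref_seq, mode="NW", task="path",
                      additionalEqualities=IUPAC_EQUALITIES)
    ops = parse_cigar(res["cigar"])
    # strip terminal indel runs (unaligned read / reference overhangs)
    start, end = 0, len(ops)
    while start < end and ops[start][1] in "ID":
        start += 1
    while end > start and ops[end - 1][1] in "ID":
        end -= 1
    region = ops[start:end]
    matches = mismatches = gaps = ref_span = 0
    for n, op in region:
        if op == "=":
            matches += n
            ref_span += n
        elif op == "X":
            mismatches += n
            ref_span += n
        elif op == "D":  # reference base opposite a read gap
            gaps += n
            ref_span += n
        else:  # "I": read base opposite a reference gap
            gaps += n
    columns = matches + mismatches + gaps
    if columns == 0:
        return None
    score = MATCH_SCORE * matches + EDIT_SCORE * (mismatches + gaps)
    return AlignmentStats(
        score=score,
        identity=matches / columns,
        ref_coverage=ref_span / len(ref_seq),
        distance=mismatches + gaps,
        columns=columns,
    )
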