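"""Plant-style miRNA target prediction by antisense complementarity scoring.

A target site is scored by an expectation penalty summed over the miRNA
aligned antiparallel to the transcript site: Watson-Crick match 0, G:U
wobble 0.5, mismatch 1.0, gap 2.0, with penalties doubled inside the seed
region (miRNA positions 2-13, 1-based from the 5' end).  The optimal
alignment is found by a banded global dynamic program, and transcripts are
scanned over every window within the gap band; sites with expectation at or
below the cutoff (default 3.0, the predictor-style default) are reported.
All scheme constants are overridable arguments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np

from .simulate import rna

DEFAULT_CUTOFF = 3.0
GAP_PENALTY = 2.0
SEED_REGION = (2, 13)  # 1-based inclusive miRNA positions with doubled penalties
GAP_BAND = 2  # max net gaps per alignment

_CODE = {"A": 0, "C": 1, "G": 2, "U": 3}
_INF = 1e9

# penalty for miRNA base (rows) against the transcript site base (cols),
# antiparallel pairing: A:U and G:C match, G:U wobbles
_PEN = np.ones((4, 4))
for _m, _s in (("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")):
    _PEN[_CODE[_m], _CODE[_s]] = 0.0
for _m, _s in (("G", "U"), ("U", "G")):
    _PEN[_CODE[_m], _CODE[_s]] = 0.5


def _codes(seq: str) -> np.ndarray:
    s = rna(seq)
    if set(s) - set("ACGU"):
        raise ValueError(f"non-ACGU symbols in sequence: {sorted(set(s) - set('ACGU'))}")
    return np.array([_CODE[c] for c in s], dtype=int)


def _seed_weight(pos_1based: int, seed: Tuple[int, int]) -> float:
    return 2.0 if seed[0] <= pos_1based <= seed[1] else 1.0


@dataclass
class TargetHit:
    mirna_id: str
    transcript_id: str
    expectation: float
    t_start: int  # 0-based half-open on the transcript
    t_end: int
    alignment: str  # three lines: miRNA 5'->3', marks, site 3'->5'
    inhibition: str = "cleavage"  # "translational" if the centre is mismatched


def score_duplex(
    mirna: str,
    site: str,
    gap_penalty: float = GAP_PENALTY,
    seed: Tuple[int, int] = SEED_REGION,
    band: int = GAP_BAND,
) -> Tuple[float, str]:
    """Minimum expectation of the miRNA bound antisense to ``site``.

    Banded global alignment: the miRNA (5'->3') is aligned against the site
    read 3'->5', both fully consumed, with at most ``band`` positions of
    offset between the strands.  Returns ``(expectation, alignment)`` where
    the alignment is three lines (miRNA, match marks, site) using ``:`` for
    a match, ``o`` for a G:U wobble, ``.`` for a mismatch and ``-`` for gaps.
    """
    m = _codes(mirna)
    srev = _codes(site)[::-1]  # 3'->5' so miRNA position 1 faces the site 3' end
    L, w = len(m), len(srev)
    if abs(L - w) > band:
        raise ValueError(f"site length {w} incompatible with band {band}")
    D = np.full((L + 1, w + 1), _INF)
    D[0, 0] = 0.0
    for j in range(1, min(band, w) + 1):  # leading site bulges, miRNA pos 1 pending
        D[0, j] = D[0, j - 1] + gap_penalty * _seed_weight(1, seed)
    for i in range(1, L + 1):
        wt = _seed_weight(i, seed)
        for j in range(max(0, i - band), min(w, i + band) + 1):
            best = _INF
            if j > 0:
                best = D[i - 1, j - 1] + _PEN[m[i - 1], srev[j - 1]] * wt
            cand = D[i - 1, j] + gap_penalty * wt  # site gap (miRNA base bulged)
            if cand < best:
                best = cand
            if j > 0:
                cand = D[i, j - 1] + gap_penalty * _seed_weight(min(i + 1, L), seed)
                if cand < best:  # miRNA gap (site base bulged)
                    best = cand
            D[i, j] = best
    expectation = float(D[L, w])

    # traceback
    i, j = L, w
    top, mid, bot = [], [], []
    while i > 0 or j > 0:
        wt = _seed_weight(max(i, 1), seed)
        if i > 0 and j > 0 and abs(D[i, j] - (D[i - 1, j - 1] + _PEN[m[i - 1], srev[j - 1]] * wt)) < 1e-9:
            pen = _PEN[m[i - 1], srev[j - 1]]
            top.append(rna(mirna)[i - 1])
            bot.append(rna(site)[::-1][j - 1])
            mid.append(":" if pen == 0 else ("o" if pen == 0.5 else "."))
            i, j = i - 1, j - 1
        elif i > 0 and abs(D[i, j] - (D[i - 1, j] + gap_penalty * wt)) < 1e-9:
            top.append(rna(mirna)[i - 1])
            bot.append("-")
            mid.append(" ")
            i -= 1
        else:
            top.append("-")
            bot.append(rna(site)[::-1][j - 1])
            mid.append(" ")
            j -= 1
    aln = "\n".join("".join(reversed(x)) for x in (top, mid, bot))
    return expectation, aln


def _central_mismatch(alignment: str) -> bool:
    # mismatch facing miRNA positions 9-11 suggests translational inhibition
    top, mid, _ = alignment.splitlines()
    pos = 0
    for col, mark in zip(top, mid):
        if col != "-":
            pos += 1
        if 9 <= pos <= 11 and mark in ".o- ":
            if mark in ". ":
                return True
    return False


def _scan_one(
    m: np.ndarray,
    tcode: np.ndarray,
    cutoff: float,
    gap_penalty: float,
    seed: Tuple[int, int],
    band: int,
) -> List[Tuple[int, int, float]]:
    """All windows (start, end, expectation<=cutoff) for one transcript.

    For each window length within the band the global banded DP is run
    vectorised across all start positions at once.
    """
    L = len(m)
    n = len(tcode)
    out: List[Tuple[int, int, float]] = []
    for w in range(max(1, L - band), L + band + 1):
        if w > n:
            continue
        starts = np.arange(0, n - w + 1)
        js = np.arange(w)
        # window read 3'->5': column j is transcript[start + w - 1 - j]
        S = tcode[starts[:, None] + (w - 1 - js)[None, :]]
        D = np.full((len(starts), L + 1, w + 1), _INF)
        D[:, 0, 0] = 0.0
        for j in range(1, min(band, w) + 1):
            D[:, 0, j] = D[:, 0, j - 1] + gap_penalty * _seed_weight(1, seed)
        for i in range(1, L + 1):
            wt = _seed_weight(i, seed)
            for j in range(max(0, i - band), min(w, i + band) + 1):
                best = np.full(len(starts), _INF)
                if j > 0:
                    best = D[:, i - 1, j - 1] + _PEN[m[i - 1], S[:, j - 1]] * wt
                np.minimum(best, D[:, i - 1, j] + gap_penalty * wt, out=best)
                if j > 0:
                    np.minimum(
                        best,
                        D[:, i, j - 1] + gap_penalty * _seed_weight(min(i + 1, L), seed),
                        out=best,
                    )
                D[:, i, j] = best
        exp = D[:, L, w]
        for k in np.nonzero(exp <= cutoff)[0]:
            out.append((int(starts[k]), int(starts[k]) + w, float(exp[k])))
    return out


def scan_transcripts(
    mirna: str,
    transcripts: Dict[str, str],
    cutoff: float = DEFAULT_CUTOFF,
    mirna_id: str = "mirna",
    gap_penalty: float = GAP_PENALTY,
    seed: Tuple[int, int] = SEED_REGION,
    band: int = GAP_BAND,
) -> List[TargetHit]:
    """Report every transcript window with expectation <= ``cutoff``.

    Hits are ordered deterministically by (expectation, transcript_id,
    position), so the best site of each transcript precedes its others.
    """
    if not transcripts:
        warnings.warn("empty transcript set: no targets to scan")
        return []
    m = _codes(mirna)
    raw: List[Tuple[float, str, int, int]] = []
    for tid in sorted(transcripts):
        tcode = _codes(transcripts[tid])
        for start, end, exp in _scan_one(m, tcode, cutoff, gap_penalty, seed, band):
            raw.append((exp, tid, start, end))
    raw.sort()
    hits = []
    for exp, tid, start, end in raw:
        _, aln = score_duplex(
            mirna, transcripts[tid][start:end], gap_penalty=gap_penalty,
            seed=seed, band=band,
        )
        hits.append(
            TargetHit(
                mirna_id=mirna_id, transcript_id=tid, expectation=exp,
                t_start=start, t_end=end, alignment=aln,
                inhibition="translational" if _central_mismatch(aln) else "cleavage",
            )
        )
    return hits


def hits_table(hits: List[TargetHit]):
    import pandas as pd

    return pd.DataFrame(
        [
            (h.mirna_id, h.transcript_id, h.expectation, h.t_start + 1, h.t_end, h.inhibition)
            for h in hits
        ],
        columns=["mirna_id", "transcript_id", "expectation", "t_start", "t_end", "inhibition"],
    )
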