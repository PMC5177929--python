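"""Conserved-miRNA classification from precursor, hairpin and star evidence.

A distinct tag is promoted to a genuine miRNA when (i) it matches a known
precursor locus perfectly, (ii) that precursor folds into a hairpin with
MFE/nt < -0.2 kcal/mol/nt, and (iii) the duplex geometry admits a star
sequence on the opposite arm with 2-nt 3' overhangs on both strands.  A
miRNA is additionally flagged ``star_supported`` when the predicted star
sequence is itself observed among the sequenced tags.  Tags are grouped into
families by matching a known mature catalogue, and named
``<family>_<sequence>`` in the study's convention.

Coordinates are 0-based half-open internally; report helpers convert to
1-based closed.
"""

from __future__ import annotations

import re
from bisect import bisect_right
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .preprocess import DistinctTag
from .simulate import dna, rna
from .structure import EnergyModel, SecondaryStructure, fold_mfe, passes_mfe_gate


@dataclass
class MatureHit:
    """A perfect match of a tag inside a precursor (0-based half-open)."""

    tag_id: str
    locus_id: str
    start: int
    end: int
    exact: bool = True


@dataclass
class StarPrediction:
    locus_id: str
    star_start: int = -1
    star_end: int = -1
    star_sequence: str = ""
    observed: bool = False
    exact: bool = False
    valid: bool = False
    reason: str = ""


@dataclass
class AnnotatedMiRNA:
    tag_id: str
    sequence: str  # DNA alphabet
    name: str  # "<family>_<sequence lowercase>"
    family: str  # family label, "AMBIGUOUS" or "UNASSIGNED"
    loci: List[str]
    star_supported: bool
    size_class: int
    mfe_per_nt: float
    star: Optional[StarPrediction] = None
    witness: Optional[Tuple[MatureHit, SecondaryStructure]] = field(default=None, repr=False)


@dataclass
class Rejection:
    tag_id: str
    sequence: str
    reason: str


# ---------------------------------------------------------------------------
# precursor mapping
# ---------------------------------------------------------------------------

def map_to_precursors(
    tags: Sequence[DistinctTag], precursors: Dict[str, str]
) -> List[MatureHit]:
    """All exact substring occurrences of tags in the precursor set.

    A tag may hit multiple loci and multiple positions.  Matching is done on
    a concatenated, separator-joined index of the precursors after U->T
    canonicalisation.
    """
    if not precursors:
        return []
    names = list(precursors)
    seqs = [dna(precursors[n]) for n in names]
    blob = "#".join(seqs)
    offsets = []
    pos = 0
    for s in seqs:
        offsets.append(pos)
        pos += len(s) + 1
    hits: List[MatureHit] = []
    for t in tags:
        q = dna(t.sequence)
        i = blob.find(q)
        while i >= 0:
            k = bisect_right(offsets, i) - 1
            start = i - offsets[k]
            if start + len(q) <= len(seqs[k]):  # never spans the separator anyway
                hits.append(MatureHit(t.tag_id, names[k], start, start + len(q)))
            i = blob.find(q, i + 1)
    return hits


# ---------------------------------------------------------------------------
# star geometry
# ---------------------------------------------------------------------------

def predict_star(
    s: SecondaryStructure,
    hit: MatureHit,
    overhang: int = 2,
    min_paired_frac: float = 0.6,
) -> StarPrediction:
    """Locate the star interval implied by the fold and the 2-nt overhang rule.

    The star is the pairing partner interval of ``mature[0 .. L-overhang)``
    extended so that both strands carry ``overhang``-nt 3' overhangs:
    ``star_end = pair[first paired mature base] + 1 + overhang`` and
    ``star_start = pair[last paired mature base at or before the mature 3'
    overhang]``.  Bulges are absorbed by using the nearest paired positions
    inside the mature interval; imperfect duplexes are flagged inexact.
    """
    p = s.pair_table
    n = len(s.sequence)
    start, end = hit.start, hit.end
    sp = StarPrediction(hit.locus_id)

    inside = range(start, end)
    if any(p[i] >= 0 and start <= p[i] < end for i in inside):
        sp.reason = "spans loop"
        return sp
    paired = [i for i in inside if p[i] >= 0]
    if len(paired) < min_paired_frac * (end - start):
        sp.reason = "mature insufficiently paired"
        return sp
    partners = [p[i] for i in paired]
    if not (all(q >= end for q in partners) or all(q < start for q in partners)):
        sp.reason = "spans loop"
        return sp

    i0 = paired[0]  # outermost paired base at the mature 5' end
    inner = [i for i in paired if i <= end - 1 - overhang]
    if not inner:
        sp.reason = "mature 3' region unpaired"
        return sp
    i1 = inner[-1]
    star_start = min(p[i0], p[i1])
    star_end = max(p[i0], p[i1]) + 1 + overhang
    if star_start < 0 or star_end > n:
        sp.reason = "star out of precursor bounds"
        return sp
    if max(star_start, start) < min(star_end, end):
        sp.reason = "star overlaps mature"
        return sp
    if any(star_start <= p[q] < star_end for q in range(star_start, star_end) if p[q] >= 0):
        sp.reason = "star crosses the hairpin loop"
        return sp

    # perfect duplex: every base of mature[0..L-overhang) paired, consecutively
    duplex = list(range(start, end - overhang))
    perfect = all(p[i] >= 0 for i in duplex) and all(
        p[duplex[k]] - p[duplex[k + 1]] == 1 for k in range(len(duplex) - 1)
    )
    sp.star_start, sp.star_end = star_start, star_end
    sp.star_sequence = dna(s.sequence[star_start:star_end])
    sp.valid = True
    sp.exact = bool(perfect)
    return sp


def check_star_expression(sp: StarPrediction, all_tags: Sequence[DistinctTag]) -> bool:
    """True iff the predicted star sequence was sequenced (>= 1 read anywhere)."""
    if not sp.valid or not sp.star_sequence:
        return False
    star = dna(sp.star_sequence)
    for t in all_tags:
        if t.sequence == star and int(np.sum(t.counts)) >= 1:
            return True
    return False


# ---------------------------------------------------------------------------
# family assignment
# ---------------------------------------------------------------------------

_FAMILY_RE = re.compile(r"(mir)[-_]?([a-z]?)(\d+)", re.IGNORECASE)


def family_of(name: str) -> Optional[str]:
    """Extract a family label like ``miR398`` from a catalogue entry name."""
    m = _FAMILY_RE.search(name)
    if not m:
        return None
    return f"miR{m.group(3)}"


def _seed_matches(a: str, b: str, max_mismatch: int) -> bool:
    # equal length, <= max_mismatch substitutions, identical 2-8 seed (1-based)
    if len(a) != len(b):
        return False
    mism = sum(x != y for x, y in zip(a, b))
    if mism > max_mismatch:
        return False
    return a[1:8] == b[1:8]


def assign_family(
    tag_sequence: str,
    known_matures: Dict[str, str],
    max_mismatch: int = 2,
) -> str:
    """Family of the known matures matching the tag.

    A match is exact identity, containment either way (isomiR length
    variants), or an equal-length comparison with <= ``max_mismatch``
    substitutions and an identical position 2-8 seed.  Matches spanning more
    than one family yield ``AMBIGUOUS``; none yield ``UNASSIGNED``.
    """
    q = dna(tag_sequence)
    fams = set()
    for name, seq in known_matures.items():
        ref = dna(seq)
        if q == ref or q in ref or ref in q or _seed_matches(q, ref, max_mismatch):
            fam = family_of(name)
            fams.add(fam if fam else name)
    if not fams:
        return "UNASSIGNED"
    if len(fams) > 1:
        return "AMBIGUOUS"
    return fams.pop()


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify_mirna(
    tag: DistinctTag,
    hits: Sequence[MatureHit],
    structures: Dict[str, SecondaryStructure],
    all_tags: Sequence[DistinctTag],
    known_matures: Optional[Dict[str, str]] = None,
    mfe_threshold: float = -0.2,
    overhang: int = 2,
    min_paired_frac: float = 0.6,
):
    """Promote one tag to a genuine miRNA or reject it with a reason code.

    Acceptance requires a perfect precursor hit whose fold passes the MFE
    gate and whose duplex geometry admits a star; ``star_supported`` further
    requires the star sequence to be expressed.  Returns ``AnnotatedMiRNA``
    or ``Rejection``.
    """
    my_hits = [h for h in hits if h.tag_id == tag.tag_id]
    if not my_hits:
        return Rejection(tag.tag_id, tag.sequence, "no precursor")
    reasons = []
    for h in my_hits:
        s = structures.get(h.locus_id)
        if s is None:
            reasons.append("no structure")
            continue
        if not passes_mfe_gate(s, mfe_threshold):
            reasons.append("mfe gate failed")
            continue
        sp = predict_star(s, h, overhang=overhang, min_paired_frac=min_paired_frac)
        if not sp.valid:
            reasons.append(f"no star geometry: {sp.reason}")
            continue
        sp.observed = check_star_expression(sp, all_tags)
        family = (
            assign_family(tag.sequence, known_matures) if known_matures else "UNASSIGNED"
        )
        return AnnotatedMiRNA(
            tag_id=tag.tag_id,
            sequence=tag.sequence,
            name=f"{family}_{tag.sequence.lower()}",
            family=family,
            loci=sorted({h2.locus_id for h2 in my_hits}),
            star_supported=sp.observed,
            size_class=len(tag.sequence),
            mfe_per_nt=s.mfe_per_nt,
            star=sp,
            witness=(h, s),
        )
    return Rejection(tag.tag_id, tag.sequence, "; ".join(sorted(set(reasons))))


def annotate_tags(
    candidate_tags: Sequence[DistinctTag],
    precursors: Dict[str, str],
    all_tags: Sequence[DistinctTag],
    known_matures: Optional[Dict[str, str]] = None,
    mfe_threshold: float = -0.2,
    overhang: int = 2,
    min_paired_frac: float = 0.6,
    energy_model: Optional[EnergyModel] = None,
    structures: Optional[Dict[str, SecondaryStructure]] = None,
) -> Tuple[List[AnnotatedMiRNA], List[Rejection]]:
    """Classify every candidate tag; collapse mature/star duplex partners.

    Precursor folds come from the built-in MFE provider unless pre-computed
    ``structures`` (e.g. parsed external-folder output) are supplied.  When
    two accepted tags form a duplex on the same locus, the lower-expressed
    one is reported as the star of the other (reason ``star_of_mirna``), not
    as a distinct miRNA, matching the convention that star reads are
    evidence rather than separate annotations.
    """
    hits = map_to_precursors(candidate_tags, precursors)
    hit_loci = {h.locus_id for h in hits}
    if structures is None:
        model = energy_model or EnergyModel.default()
        structures = {name: fold_mfe(rna(precursors[name]), model) for name in hit_loci}

    accepted: List[AnnotatedMiRNA] = []
    rejected: List[Rejection] = []
    for tag in candidate_tags:
        res = classify_mirna(
            tag, hits, structures, all_tags, known_matures,
            mfe_threshold=mfe_threshold, overhang=overhang,
            min_paired_frac=min_paired_frac,
        )
        if isinstance(res, AnnotatedMiRNA):
            accepted.append(res)
        else:
            rejected.append(res)

    # duplex collapse: an accepted tag lying inside the predicted star of a
    # higher-expressed accepted tag on a shared locus is that miRNA's star
    expr = {t.tag_id: t.max_rpm if t.rpm is not None else float(np.sum(t.counts))
            for t in candidate_tags}
    star_of: Dict[str, str] = {}
    for a in accepted:
        if a.star is None or not a.star.valid:
            continue
        for b in accepted:
            if b.tag_id == a.tag_id or not set(b.loci) & set(a.loci):
                continue
            if b.sequence in a.star.star_sequence and expr[b.tag_id] < expr[a.tag_id]:
                star_of.setdefault(b.tag_id, a.tag_id)
    if star_of:
        kept = []
        for a in accepted:
            if a.tag_id in star_of:
                rejected.append(
                    Rejection(a.tag_id, a.sequence, f"star_of_mirna:{star_of[a.tag_id]}")
                )
            else:
                kept.append(a)
        accepted = kept
    return accepted, rejected


def family_summary(annotated: Sequence[AnnotatedMiRNA]) -> pd.DataFrame:
    """Per-family member counts and 18-24 nt size-class histogram."""
    groups: Dict[str, List[AnnotatedMiRNA]] = defaultdict(list)
    for a in annotated:
        groups[a.family].append(a)
    rows = []
    for fam in sorted(groups):
        members = groups[fam]
        row = {"family": fam, "n_members": len(members)}
        for size in range(18, 25):
            row[f"n_{size}nt"] = sum(1 for m in members if m.size_class == size)
        rows.append(row)
    return pd.DataFrame(rows)


def annotation_table(annotated: Sequence[AnnotatedMiRNA]) -> pd.DataFrame:
    """Report table with 1-based closed star coordinates."""
    rows = []
    for a in annotated:
        star = a.star
        rows.append(
            {
                "tag_id": a.tag_id,
                "name": a.name,
                "family": a.family,
                "loci": ",".join(a.loci),
                "size_class": a.size_class,
                "mfe_per_nt": round(a.mfe_per_nt, 4),
                "star_supported": a.star_supported,
                "star_start": star.star_start + 1 if star and star.valid else "",
                "star_end": star.star_end if star and star.valid else "",
            }
        )
    return pd.DataFrame(rows)
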