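"""Raw FASTQ -> distinct-tag table: trimming, size selection, RPM, decoy removal.

Reads are adapter-trimmed, quality-gated, restricted to 18-24 nt inserts,
collapsed across all libraries into consistently named distinct tags with
per-library counts, normalised to reads per million (RPM, denominator =
retained 18-24 nt reads of the library), screened against ncRNA/chloroplast
decoy references (exact substring, either strand), and filtered to tags with
>= 10 RPM in at least one library.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .simulate import ADAPTER3, LibraryDesign, dna, revcomp_dna

MIN_TAG_LEN = 18
MAX_TAG_LEN = 24
DEFAULT_MIN_RPM = 10.0


@dataclass(eq=False)
class DistinctTag:
    """A unique 18-24 nt sequence with per-library counts and RPM."""

    sequence: str
    tag_id: str
    counts: np.ndarray
    rpm: Optional[np.ndarray] = None

    @property
    def size_class(self) -> int:
        return len(self.sequence)

    @property
    def max_rpm(self) -> float:
        return float(np.max(self.rpm)) if self.rpm is not None else 0.0


@dataclass
class LibraryStats:
    """Per-library read accounting along the pipeline stages."""

    library_id: str
    raw_reads: int = 0
    quality_reads: int = 0
    trimmed_reads: int = 0
    retained_reads: int = 0  # 18-24 nt inserts; RPM denominator
    reads_after_decoy_removal: int = 0
    size_reads: Dict[int, int] = field(default_factory=dict)

    def check(self) -> None:
        seq = [self.raw_reads, self.quality_reads, self.trimmed_reads, self.retained_reads]
        if any(a < b for a, b in zip(seq, seq[1:])):
            raise ValueError(f"{self.library_id}: stage totals increased along the pipeline")


def trim_adapter(read: str, adapter3: str = ADAPTER3, min_overlap: int = 5) -> Tuple[str, bool]:
    """Cut the read at the leftmost exact match of the adapter's prefix.

    At least ``min_overlap`` adapter bases must match (exact, no mismatches);
    a truncated adapter at the read 3' end counts when long enough.  Returns
    ``(insert, trimmed)``; reads without a match come back whole, untrimmed.
    """
    if min_overlap < 5:
        raise ValueError("min_overlap must be >= 5")
    read = dna(read)
    if not read:
        return "", False
    n = len(read)
    probe = adapter3[:min_overlap]
    start = 0
    while True:
        i = read.find(probe, start)
        if i < 0:
            return read, False
        k = min(len(adapter3), n - i)
        if read[i : i + k] == adapter3[:k]:
            return read[:i], True
        start = i + 1


def size_select(
    inserts: Iterable[str], min_len: int = MIN_TAG_LEN, max_len: int = MAX_TAG_LEN
) -> List[str]:
    """Keep inserts of 18-24 nt, preserving order."""
    return [s for s in inserts if min_len <= len(s) <= max_len]


def collapse_and_name(
    per_library_inserts: Dict[str, Sequence[str]],
    design: Sequence[LibraryDesign],
) -> List[DistinctTag]:
    """Collapse identical inserts across all libraries into named distinct tags.

    One tag per unique sequence; ``counts[i]`` is the multiplicity in the
    i-th design library.  Naming is deterministic given the sequence set:
    tags are sorted by sequence and numbered serially, so neither input order
    nor library order changes a tag's id.
    """
    lib_ids = [d.library_id for d in design]
    index = {lib: i for i, lib in enumerate(lib_ids)}
    counts: Dict[str, np.ndarray] = {}
    for lib, inserts in per_library_inserts.items():
        li = index[lib]
        for s in inserts:
            row = counts.get(s)
            if row is None:
                row = counts[s] = np.zeros(len(lib_ids), dtype=np.int64)
            row[li] += 1
    tags = []
    for serial, seq in enumerate(sorted(counts), start=1):
        tags.append(DistinctTag(seq, f"tag{serial:06d}", counts[seq]))
    return tags


def compute_rpm(tags: Sequence[DistinctTag], retained_reads: Sequence[int]) -> List[DistinctTag]:
    """Fill ``rpm[i] = counts[i] / retained_reads[i] * 1e6`` for every tag."""
    denom = np.asarray(retained_reads, dtype=float)
    for t in tags:
        if np.any((denom == 0) & (t.counts > 0)):
            raise ValueError(f"{t.tag_id}: nonzero count in a library with zero retained reads")
    safe = np.where(denom > 0, denom, 1.0)
    for t in tags:
        t.rpm = t.counts / safe * 1e6
    return list(tags)


def _read_fasta_dict(path) -> Dict[str, str]:
    from Bio import SeqIO

    try:
        return {rec.id: dna(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")}
    except (OSError, ValueError) as exc:
        raise ValueError(f"cannot read FASTA {path}: {exc}") from exc


def filter_known_ncRNA(
    tags: Sequence[DistinctTag], decoy_fastas: Sequence
) -> Tuple[List[DistinctTag], List[DistinctTag]]:
    """Remove tags matching ncRNA/chloroplast references.

    A tag is removed iff its sequence or its reverse complement is an exact
    substring of any decoy reference (matching after U->T canonicalisation).
    Returns ``(retained, removed)``.
    """
    refs: Dict[str, str] = {}
    for fa in decoy_fastas:
        if isinstance(fa, dict):
            refs.update({k: dna(v) for k, v in fa.items()})
        else:
            refs.update(_read_fasta_dict(fa))
    blob = "N".join(refs.values())
    retained, removed = [], []
    for t in tags:
        if t.sequence in blob or revcomp_dna(t.sequence) in blob:
            removed.append(t)
        else:
            retained.append(t)
    return retained, removed


def filter_min_rpm(
    tags: Sequence[DistinctTag], threshold: float = DEFAULT_MIN_RPM
) -> List[DistinctTag]:
    """Keep tags with >= ``threshold`` RPM in at least one library (inclusive)."""
    out = []
    for t in tags:
        if t.rpm is None:
            raise ValueError("compute_rpm must run before filter_min_rpm")
        if np.max(t.rpm) >= threshold:
            out.append(t)
    return out


def size_distribution(
    tags: Sequence[DistinctTag], design: Sequence[LibraryDesign]
) -> pd.DataFrame:
    """Size-class (18..24) read and distinct-tag counts per treatment.

    The ``reads`` table weights by multiplicity; the ``tags`` table counts a
    distinct tag once per treatment in which it was observed.
    """
    rows = []
    treatments = sorted({d.treatment for d in design})
    for trt in treatments:
        cols = [i for i, d in enumerate(design) if d.treatment == trt]
        for size in range(MIN_TAG_LEN, MAX_TAG_LEN + 1):
            nreads = 0
            ntags = 0
            for t in tags:
                if t.size_class != size:
                    continue
                c = int(t.counts[cols].sum())
                nreads += c
                ntags += int(c > 0)
            rows.append((trt, size, nreads, ntags))
    return pd.DataFrame(rows, columns=["treatment", "size", "reads", "tags"])


def mean_quality(qual: str) -> float:
    return float(np.mean([ord(c) - 33 for c in qual])) if qual else 0.0


@dataclass
class PreprocessResult:
    tags: List[DistinctTag]  # >= min RPM, decoy-free: annotation candidates
    all_tags: List[DistinctTag]  # every decoy-free distinct tag (for star evidence)
    removed_ncRNA: List[DistinctTag]
    stats: List[LibraryStats]
    design: List[LibraryDesign]

    @property
    def retained_reads(self) -> List[int]:
        return [s.retained_reads for s in self.stats]

    def tag_counts(self, tags: Optional[Sequence[DistinctTag]] = None) -> pd.DataFrame:
        tags = self.tags if tags is None else tags
        return pd.DataFrame(
            {d.library_id: [int(t.counts[i]) for t in tags] for i, d in enumerate(self.design)},
            index=[t.sequence for t in tags],
        )


def run_pipeline(
    fastq_paths: Dict[str, Path],
    design: Sequence[LibraryDesign],
    adapter3: str = ADAPTER3,
    decoy_fastas: Sequence = (),
    min_rpm: float = DEFAULT_MIN_RPM,
    min_overlap: int = 5,
    min_mean_quality: float = 20.0,
) -> PreprocessResult:
    """Full preprocessing chain from per-library FASTQ files to a tag table."""
    per_lib: Dict[str, List[str]] = {}
    stats: List[LibraryStats] = []
    for d in design:
        st = LibraryStats(d.library_id)
        inserts = []
        path = fastq_paths.get(d.library_id)
        if path is not None:
            with open(path) as fh:
                for _title, seq, qual in FastqGeneralIterator(fh):
                    st.raw_reads += 1
                    if mean_quality(qual) < min_mean_quality:
                        continue
                    st.quality_reads += 1
                    insert, trimmed = trim_adapter(seq, adapter3, min_overlap)
                    if not trimmed:
                        continue
                    st.trimmed_reads += 1
                    if MIN_TAG_LEN <= len(insert) <= MAX_TAG_LEN:
                        st.retained_reads += 1
                        st.size_reads[len(insert)] = st.size_reads.get(len(insert), 0) + 1
                        inserts.append(insert)
        per_lib[d.library_id] = inserts
        stats.append(st)

    all_tags = collapse_and_name(per_lib, design)
    compute_rpm(all_tags, [s.retained_reads for s in stats])
    if decoy_fastas:
        kept, removed = filter_known_ncRNA(all_tags, decoy_fastas)
    else:
        kept, removed = list(all_tags), []
    for i, st in enumerate(stats):
        st.reads_after_decoy_removal = int(sum(t.counts[i] for t in kept))
        st.check()
    candidates = filter_min_rpm(kept, min_rpm)
    return PreprocessResult(candidates, kept, removed, stats, list(design))


def tags_to_frame(tags: Sequence[DistinctTag], design: Sequence[LibraryDesign]) -> pd.DataFrame:
    """Flat table (tag_id, sequence, count_<lib>..., rpm_<lib>...) for TSV export."""
    data: Dict[str, list] = {
        "tag_id": [t.tag_id for t in tags],
        "sequence": [t.sequence for t in tags],
    }
    for i, d in enumerate(design):
        data[f"count_{d.library_id}"] = [int(t.counts[i]) for t in tags]
    for i, d in enumerate(design):
        data[f"rpm_{d.library_id}"] = [
            float(t.rpm[i]) if t.rpm is not None else np.nan for t in tags
        ]
    return pd.DataFrame(data)
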