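"""Synthetic sRNA-seq study generator with recorded ground truth.

Emulates the statistical structure of a 72-library abiotic-stress study
(4 treatments x 3 replicates x 6 sampling days): hairpin precursors carrying
mature/star duplexes with 2-nt 3' overhangs, isomiR length variants, 24-nt
siRNA-like background, rRNA/tRNA/chloroplast contaminants, adapter-flanked
50-cycle reads, and negative-binomial counts with planted treatment-by-time
log2 fold changes.  Everything planted is recorded in a :class:`SimTruth`
so the full pipeline can be verified against known answers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

TREATMENTS = ("control", "heat", "light", "uv")
TIME_POINTS = (0, 1, 2, 3, 7, 10)

#: 3' sequencing adapter ligated to every insert (DNA alphabet).
ADAPTER3 = "ATCTCGTATGCCGTCTTCTGCTTGT"
READ_LENGTH = 50

_COMPLEMENT_RNA = str.maketrans("ACGU", "UGCA")
_COMPLEMENT_DNA = str.maketrans("ACGT", "TGCA")


def rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def revcomp_rna(seq: str) -> str:
    return rna(seq).translate(_COMPLEMENT_RNA)[::-1]


def revcomp_dna(seq: str) -> str:
    return dna(seq).translate(_COMPLEMENT_DNA)[::-1]


@dataclass(frozen=True)
class LibraryDesign:
    """One sequencing library of the factorial design."""

    library_id: str
    treatment: str
    replicate: int
    time_dat: int

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise ValueError(f"unknown treatment {self.treatment!r}")
        if self.time_dat not in TIME_POINTS:
            raise ValueError(f"unknown time point {self.time_dat}")
        if not 1 <= self.replicate <= 3:
            raise ValueError("replicate must be 1..3")


def full_design() -> List[LibraryDesign]:
    """The complete 4 x 3 x 6 = 72 library design."""
    libs = []
    for trt in TREATMENTS:
        for t in TIME_POINTS:
            for rep in (1, 2, 3):
                libs.append(LibraryDesign(f"{trt}_t{t}_r{rep}", trt, rep, t))
    return libs


def write_design(design: Sequence[LibraryDesign], path) -> None:
    df = pd.DataFrame(
        [(d.library_id, d.treatment, d.replicate, d.time_dat) for d in design],
        columns=["library_id", "treatment", "replicate", "time_dat"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_design(path) -> List[LibraryDesign]:
    df = pd.read_csv(path, sep="\t")
    return [
        LibraryDesign(str(r.library_id), str(r.treatment), int(r.replicate), int(r.time_dat))
        for r in df.itertuples()
    ]


@dataclass
class Precursor:
    locus_id: str
    sequence: str  # RNA alphabet
    mature_interval: Tuple[int, int]  # 0-based half-open
    star_interval: Tuple[int, int]

    @property
    def mature_seq(self) -> str:
        return self.sequence[self.mature_interval[0] : self.mature_interval[1]]

    @property
    def star_seq(self) -> str:
        return self.sequence[self.star_interval[0] : self.star_interval[1]]


@dataclass
class SimTruth:
    """Planted ground truth: loci, effects and count-model parameters."""

    precursors: List[Precursor]
    planted_effects: Dict[str, Dict[Tuple[str, int], float]]  # DNA tag -> {(trt, time): lfc}
    baseline_means: Dict[str, float]  # DNA tag -> mean count
    dispersion: float
    seed: int
    size_factors: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        for p in self.precursors:
            (ms, me), (ss, se) = p.mature_interval, p.star_interval
            n = len(p.sequence)
            if not (0 <= ms < me <= n and 0 <= ss < se <= n):
                raise ValueError(f"{p.locus_id}: intervals outside precursor bounds")
            if max(ms, ss) < min(me, se):
                raise ValueError(f"{p.locus_id}: mature and star intervals overlap")
        tags = set(self.baseline_means)
        for tag in self.planted_effects:
            if tag not in tags:
                raise ValueError(f"planted effect for unknown tag {tag[:12]}...")


class HairpinError(ValueError):
    pass


def _safe_loop(loop_len: int, mature_tail: str) -> str:
    """Loop sequence that cannot extend the stem.

    A homopolymer of A or C cannot pair internally; the letter is chosen so
    that at most one mature-overhang base (which sits in the hairpin loop)
    could pair with it, and an isolated pair is never energetically
    favourable, so the fold keeps the planted duplex register.
    """
    pairable = {"A": "U", "C": "G"}
    n_a = sum(1 for b in mature_tail if b == pairable["A"])
    n_c = sum(1 for b in mature_tail if b == pairable["C"])
    return ("A" if n_a <= n_c else "C") * loop_len


def build_hairpin(
    mature: str,
    loop_len: int = 8,
    overhang: int = 2,
    bulges: int = 0,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[str, Tuple[int, int], Tuple[int, int]]:
    """Build a stem-loop precursor around ``mature`` with a planted star.

    The precursor is 5'-arm + loop + 3'-arm.  The mature occupies the 5' arm;
    its terminal ``overhang`` nucleotides are the mature-side 3' overhang of
    the duplex (unpaired, loop-proximal), and the star arm carries the
    star-side 3' overhang at the precursor 3' end, so both strands of the
    excised duplex end in ``overhang``-nt 3' overhangs.  ``bulges`` inserts up
    to 2 single-nucleotide bulges into the star arm for robustness testing.

    Returns ``(precursor, mature_interval, star_interval)`` with 0-based
    half-open intervals.
    """
    m = rna(mature)
    if set(m) - set("ACGU"):
        raise HairpinError("mature must be ACGU/ACGT only")
    L = len(m)
    if not 18 <= L <= 24:
        raise HairpinError(f"mature length {L} outside the 18-24 nt size selection")
    if loop_len < 3:
        raise HairpinError("loop_len must be >= 3")
    if not 0 <= bulges <= 2:
        raise HairpinError("at most 2 bulges are supported")

    # paired star body is the reverse complement of mature[:-overhang]; the
    # final `overhang` nt extend 3' of the duplex
    star_arm = revcomp_rna(m[:-overhang]) + revcomp_rna(m[-overhang:])
    if bulges:
        rng = rng or np.random.default_rng(0)
        arm = list(star_arm)
        for _ in range(bulges):
            pos = int(rng.integers(3, len(arm) - overhang - 3))
            # a bulge base that cannot pair with the mature bases it faces
            facing = {m[max(0, L - overhang - 1 - pos - d)] for d in (-1, 0, 1)}
            avoid = {b.translate(_COMPLEMENT_RNA) for b in facing}
            choices = [c for c in "CAGU" if c not in avoid] or ["C"]
            arm.insert(pos, choices[0])
        star_arm = "".join(arm)

    loop = _safe_loop(loop_len, m[-overhang:])
    precursor = m + loop + star_arm
    n = len(precursor)
    return precursor, (0, L), (L + loop_len, n)


def random_mature(rng: np.random.Generator, length: Optional[int] = None) -> str:
    """A random mature sequence (RNA) of realistic length and composition."""
    length = int(length or rng.integers(20, 23))
    while True:
        seq = "".join(rng.choice(list("ACGU"), size=length))
        # avoid low-complexity matures whose duplex register is ambiguous
        if len(set(seq)) >= 3 and max(seq.count(b) for b in "ACGU") <= 0.6 * length:
            return seq


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def simulate_counts(
    design: Sequence[LibraryDesign],
    truth: SimTruth,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Draw a tags x libraries negative-binomial count matrix.

    Mean for tag g in library l is ``baseline_g * 2**lfc(g, treatment_l,
    time_l) * size_factor_l``; counts are NB with the truth's common
    dispersion (variance mu + phi mu^2).  Reproducible given ``truth.seed``.
    """
    rng = rng or np.random.default_rng(truth.seed)
    phi = truth.dispersion
    tags = sorted(truth.baseline_means)
    lib_ids = [d.library_id for d in design]
    sf = np.array([truth.size_factors.get(d.library_id, 1.0) for d in design])
    base = np.array([truth.baseline_means[t] for t in tags])
    if np.any(base <= 0):
        raise ValueError("baseline means must be positive")
    lfc = np.zeros((len(tags), len(design)))
    for gi, tag in enumerate(tags):
        eff = truth.planted_effects.get(tag)
        if eff:
            for li, d in enumerate(design):
                lfc[gi, li] = eff.get((d.treatment, d.time_dat), 0.0)
    mu = base[:, None] * np.power(2.0, lfc) * sf[None, :]
    r = 1.0 / phi
    counts = rng.negative_binomial(r, r / (r + mu))
    return pd.DataFrame(counts, index=tags, columns=lib_ids)


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

def _make_read(insert_dna: str, adapter3: str, read_length: int) -> str:
    if set(insert_dna) - set("ACGT"):
        raise ValueError(f"insert contains non-ACGT symbols: {insert_dna[:20]}")
    read = (insert_dna + adapter3)[:read_length]
    return read.ljust(read_length, "A")  # pad past-adapter cycles


def emit_fastq(
    counts: pd.DataFrame,
    out_dir,
    adapter3: str = ADAPTER3,
    read_length: int = READ_LENGTH,
    phred: int = 40,
    error_rate: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> Dict[str, Path]:
    """Write one Phred+33 FASTQ per library from a tag x library count matrix.

    Every read is insert + 3'-adapter, padded/truncated to ``read_length``
    cycles; per-tag read counts equal the count matrix exactly.  Base
    qualities are uniform (perfect by default); ``error_rate`` optionally
    introduces uniform substitution errors.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    qual = chr(phred + 33) * read_length
    if error_rate and rng is None:
        rng = np.random.default_rng(0)
    paths = {}
    for lib in counts.columns:
        path = out_dir / f"{lib}.fastq"
        with open(path, "w") as fh:
            serial = 0
            for tag in counts.index:  # index order is deterministic
                c = int(counts.at[tag, lib])
                if c <= 0:
                    continue
                read = _make_read(dna(tag), adapter3, read_length)
                for _ in range(c):
                    serial += 1
                    r = read
                    if error_rate:
                        mask = rng.random(read_length) < error_rate
                        if mask.any():
                            chars = list(r)
                            for pos in np.nonzero(mask)[0]:
                                chars[pos] = rng.choice(
                                    [b for b in "ACGT" if b != chars[pos]]
                                )
                            r = "".join(chars)
                    fh.write(f"@{lib}:{serial}\n{r}\n+\n{qual}\n")
        paths[lib] = path
    return paths


# ---------------------------------------------------------------------------
# decoys
# ---------------------------------------------------------------------------

_DECOY_CLASSES = ("rRNA", "tRNA", "snoRNA", "lncRNA")


def emit_decoys(
    n_rfam: int,
    n_chloro: int,
    n_sirna24: int,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[Dict[str, str], List[str], List[str]]:
    """Generate contaminant references and reads without planted precursors.

    Returns ``(references, decoy_tags, sirna_tags)`` in DNA alphabet: decoy
    tags are exact substrings of the references (so the ncRNA/chloroplast
    filter removes them); siRNA tags are free-standing 24-mers that match no
    reference and no precursor (so the classifier must reject them).
    """
    if min(n_rfam, n_chloro, n_sirna24) < 0:
        raise ValueError("decoy counts must be >= 0")
    rng = rng or np.random.default_rng(0)
    refs: Dict[str, str] = {}

    def _random_seq(n: int) -> str:
        return "".join(rng.choice(list("ACGT"), size=n))

    def _make_refs(n_tags: int, prefix_pool, min_len: int, max_len: int) -> List[str]:
        names = []
        n_refs = max(1, n_tags // 5) if n_tags else 0
        for k in range(n_refs):
            cls = prefix_pool[k % len(prefix_pool)]
            name = f"{cls}_{k + 1}"
            refs[name] = _random_seq(int(rng.integers(min_len, max_len)))
            names.append(name)
        return names

    rfam_names = _make_refs(n_rfam, _DECOY_CLASSES, 120, 400)
    chloro_names = _make_refs(n_chloro, ("chloroplast",), 300, 800)

    def _tags_from(names: List[str], n: int) -> List[str]:
        tags = []
        while len(tags) < n:
            ref = refs[names[int(rng.integers(len(names)))]]
            k = int(rng.integers(18, 25))
            start = int(rng.integers(0, len(ref) - k))
            tag = ref[start : start + k]
            if tag not in tags:
                tags.append(tag)
        return tags

    decoy_tags = []
    if n_rfam:
        decoy_tags += _tags_from(rfam_names, n_rfam)
    if n_chloro:
        decoy_tags += _tags_from(chloro_names, n_chloro)
    sirna_tags: List[str] = []
    ref_blob = "N".join(refs.values())
    while len(sirna_tags) < n_sirna24:
        tag = _random_seq(24)
        if tag not in ref_blob and tag not in sirna_tags:
            sirna_tags.append(tag)
    return refs, decoy_tags, sirna_tags


# ---------------------------------------------------------------------------
# whole-study convenience
# ---------------------------------------------------------------------------

#: conserved plant miRNA family numbers used to label simulated loci
_FAMILY_POOL = (156, 159, 160, 164, 166, 167, 169, 171, 172, 319, 393, 396, 398, 399, 408, 528)


@dataclass
class StudyData:
    """Everything one simulated study writes to disk, plus in-memory truth."""

    design: List[LibraryDesign]
    truth: SimTruth
    counts: pd.DataFrame
    fastq_paths: Dict[str, Path]
    precursor_fasta: Path
    decoy_fastas: List[Path]
    matures_fasta: Path
    design_path: Path
    truth_path: Path
    families: Dict[str, str]  # mature DNA tag -> family label


def simulate_study(
    out_dir,
    n_mirnas: int = 50,
    n_rfam: int = 100,
    n_chloro: int = 100,
    n_sirna: int = 300,
    seed: int = 0,
    mature_mean: float = 30.0,
    star_mean: float = 2.0,
    background_mean: float = 8.0,
    dispersion: float = 0.1,
    n_heat_affected: Optional[int] = None,
    heat_lfc: float = -2.0,
    effect_times: Tuple[int, ...] = (0, 1),
    isomirs_per_mirna: int = 0,
    bulges: int = 0,
    error_rate: float = 0.0,
) -> StudyData:
    """Simulate a full study: FASTQ reads, references, design sheet, truth.

    Defaults mirror the study conditions this package targets: 72 libraries,
    hairpin-borne miRNAs with expressed star partners, ncRNA/chloroplast
    contaminants, precursor-less 24-nt siRNA background, and heat-stress
    downregulation (log2FC ``heat_lfc``) at the early sampling days for half
    the planted miRNAs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    design = full_design()

    # precursors and planted tags
    precursors: List[Precursor] = []
    families: Dict[str, str] = {}
    matures: List[str] = []
    stars: List[str] = []
    seen = set()
    while len(precursors) < n_mirnas:
        m = random_mature(rng)
        if m in seen:
            continue
        seen.add(m)
        i = len(precursors)
        loop_len = int(rng.integers(6, 13))
        seq, m_iv, s_iv = build_hairpin(m, loop_len=loop_len, bulges=bulges, rng=rng)
        fam = f"miR{_FAMILY_POOL[i % len(_FAMILY_POOL)]}"
        locus = f"locus_{fam}_{i + 1:03d}"
        precursors.append(Precursor(locus, seq, m_iv, s_iv))
        families[dna(m)] = fam
        matures.append(dna(m))
        stars.append(dna(seq[s_iv[0] : s_iv[1]]))

    refs, decoy_tags, sirna_tags = emit_decoys(n_rfam, n_chloro, n_sirna, rng)

    baselines: Dict[str, float] = {}
    for t in matures:
        baselines[t] = float(mature_mean * rng.lognormal(0.0, 0.4))
    for t in stars:
        baselines.setdefault(t, float(star_mean * rng.lognormal(0.0, 0.3)))
    for t in decoy_tags + sirna_tags:
        baselines.setdefault(t, float(background_mean * rng.lognormal(0.0, 0.5)))
    if isomirs_per_mirna:
        for m in list(matures):
            for k in range(isomirs_per_mirna):
                iso = m[: len(m) - (k + 1)]
                if len(iso) >= 18 and iso not in baselines:
                    baselines[iso] = float(mature_mean / 4 * rng.lognormal(0.0, 0.3))
                    families[iso] = families[m]

    if n_heat_affected is None:
        n_heat_affected = n_mirnas // 2
    effects: Dict[str, Dict[Tuple[str, int], float]] = {}
    for t in matures[:n_heat_affected]:
        effects[t] = {("heat", tp): heat_lfc for tp in effect_times}

    size_factors = {
        d.library_id: float(rng.lognormal(0.0, 0.15)) for d in design
    }
    truth = SimTruth(
        precursors=precursors,
        planted_effects=effects,
        baseline_means=baselines,
        dispersion=dispersion,
        seed=seed,
        size_factors=size_factors,
    )
    counts = simulate_counts(design, truth, rng)
    fastq_paths = emit_fastq(counts, out_dir / "fastq", error_rate=error_rate, rng=rng)

    # references
    precursor_fasta = out_dir / "precursors.fasta"
    _write_fasta(precursor_fasta, {p.locus_id: dna(p.sequence) for p in precursors})
    rfam_fa = out_dir / "decoys_rfam.fasta"
    chloro_fa = out_dir / "decoys_chloroplast.fasta"
    _write_fasta(rfam_fa, {k: v for k, v in refs.items() if not k.startswith("chloroplast")})
    _write_fasta(chloro_fa, {k: v for k, v in refs.items() if k.startswith("chloroplast")})
    matures_fasta = out_dir / "known_matures.fasta"
    _write_fasta(
        matures_fasta,
        {f"tae-{families[m]}-{i + 1}": m for i, m in enumerate(matures)},
    )
    design_path = out_dir / "design.tsv"
    write_design(design, design_path)
    truth_path = out_dir / "truth.tsv"
    write_truth(truth, truth_path)
    return StudyData(
        design=design,
        truth=truth,
        counts=counts,
        fastq_paths=fastq_paths,
        precursor_fasta=precursor_fasta,
        decoy_fastas=[rfam_fa, chloro_fa],
        matures_fasta=matures_fasta,
        design_path=design_path,
        truth_path=truth_path,
        families=families,
    )


def _write_fasta(path, records: Dict[str, str]) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()]
    seqio_write(recs, str(path), "fasta")


def write_truth(truth: SimTruth, path) -> None:
    """Sidecar TSV with the planted loci and effects (one row per fact)."""
    rows = []
    for p in truth.precursors:
        rows.append(
            (
                "precursor",
                p.locus_id,
                dna(p.sequence),
                f"{p.mature_interval[0]}-{p.mature_interval[1]}",
                f"{p.star_interval[0]}-{p.star_interval[1]}",
                "",
            )
        )
    for tag, eff in truth.planted_effects.items():
        for (trt, tp), lfc in sorted(eff.items()):
            rows.append(("effect", tag, "", trt, str(tp), f"{lfc:.4f}"))
    for tag, mean in truth.baseline_means.items():
        rows.append(("baseline", tag, "", "", "", f"{mean:.4f}"))
    pd.DataFrame(
        rows, columns=["record", "id", "sequence", "field1", "field2", "value"]
    ).to_csv(path, sep="\t", index=False)
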