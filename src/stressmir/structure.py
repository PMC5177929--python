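"""RNA secondary structure: dot-bracket parsing and a simplified MFE fold.

Precursor candidates are screened on the stability of their hairpin fold,
expressed as minimum free energy per nucleotide.  Structures can come from
two providers: the output of an external folder (RNAfold-style
``sequence / dot-bracket (energy)`` records, read by :func:`parse_dotbracket`)
or the built-in dynamic program :func:`fold_mfe`, which finds the optimal
pseudoknot-free structure under a simplified nearest-neighbour energy model
(stacking energies per pair type, logarithmic hairpin and interior loop
penalties, linear multibranch model) shipped as a YAML parameter table.

The gate applied downstream is MFE / length < -0.2 kcal/mol/nt.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import numpy as np
import yaml

WATSON_CRICK_WOBBLE = frozenset({"AU", "UA", "GC", "CG", "GU", "UG"})

_PAIR_CODE = {"AU": 0, "UA": 1, "GC": 2, "CG": 3, "GU": 4, "UG": 5}
_CODE_PAIR = {v: k for k, v in _PAIR_CODE.items()}

INF = 1e9


class StructureError(ValueError):
    """Raised for malformed structures or sequences."""


def _as_rna(sequence: str) -> str:
    seq = sequence.strip().upper().replace("T", "U")
    if not seq or set(seq) - set("ACGU"):
        bad = sorted(set(seq) - set("ACGU"))
        raise StructureError(f"sequence contains non-ACGU symbols: {bad}")
    return seq


@dataclass
class EnergyModel:
    """Simplified nearest-neighbour parameters (kcal/mol)."""

    stack: dict
    hairpin_init: float
    hairpin_slope: float
    internal_init: float
    internal_slope: float
    multi_init: float
    multi_branch: float
    multi_unpaired: float
    min_hairpin_loop: int = 3
    max_interior_loop: int = 30
    _stack_mat: np.ndarray = field(default=None, repr=False, compare=False)

    @classmethod
    def default(cls) -> "EnergyModel":
        text = resources.files("stressmir.data").joinpath("energy_params.yaml").read_text()
        return cls.from_dict(yaml.safe_load(text))

    @classmethod
    def from_dict(cls, cfg: dict) -> "EnergyModel":
        return cls(
            stack=dict(cfg["stack"]),
            hairpin_init=float(cfg["hairpin_init"]),
            hairpin_slope=float(cfg["hairpin_slope"]),
            internal_init=float(cfg["internal_init"]),
            internal_slope=float(cfg["internal_slope"]),
            multi_init=float(cfg["multi_init"]),
            multi_branch=float(cfg["multi_branch"]),
            multi_unpaired=float(cfg["multi_unpaired"]),
            min_hairpin_loop=int(cfg.get("min_hairpin_loop", 3)),
            max_interior_loop=int(cfg.get("max_interior_loop", 30)),
        )

    def __post_init__(self) -> None:
        mat = np.full((6, 6), INF)
        for key, val in self.stack.items():
            outer, inner = key.split("/")
            mat[_PAIR_CODE[outer], _PAIR_CODE[inner]] = float(val)
        self._stack_mat = mat

    # -- loop terms ---------------------------------------------------------
    def hairpin_energy(self, unpaired: int) -> float:
        if unpaired < self.min_hairpin_loop:
            return INF
        return self.hairpin_init + self.hairpin_slope * math.log(unpaired / self.min_hairpin_loop)

    def interior_energy(self, unpaired: int) -> float:
        # unpaired >= 1; the 0-unpaired case is a stack
        return self.internal_init + self.internal_slope * math.log(unpaired)

    def stack_energy(self, outer: str, inner: str) -> float:
        return float(self._stack_mat[_PAIR_CODE[outer], _PAIR_CODE[inner]])


@dataclass
class SecondaryStructure:
    """A sequence with its nested pairing and free energy.

    ``pair_table[i]`` is the partner of position ``i`` (0-based) or -1.
    """

    sequence: str
    dotbracket: str
    mfe_kcal_mol: float
    pair_table: list

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.dotbracket):
            raise StructureError("sequence and structure lengths differ")
        for i, j in enumerate(self.pair_table):
            if j >= 0:
                if self.pair_table[j] != i:
                    raise StructureError("pair_table is not an involution")
                if i < j and self.sequence[i] + self.sequence[j] not in WATSON_CRICK_WOBBLE:
                    raise StructureError(
                        f"disallowed pair {self.sequence[i]}{self.sequence[j]} at ({i},{j})"
                    )

    @property
    def mfe_per_nt(self) -> float:
        return self.mfe_kcal_mol / len(self.sequence)

    @property
    def pairs(self) -> list:
        return [(i, j) for i, j in enumerate(self.pair_table) if j > i]

    def serialize(self) -> str:
        return f"{self.sequence}\n{self.dotbracket} ({self.mfe_kcal_mol:.2f})\n"


def pair_table_from_dotbracket(dotbracket: str) -> list:
    """Stack-match a dot-bracket string into a partner table."""
    table = [-1] * len(dotbracket)
    stack: list = []
    for i, ch in enumerate(dotbracket):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise StructureError(f"unbalanced ')' at position {i}")
            j = stack.pop()
            table[j], table[i] = i, j
        elif ch != ".":
            raise StructureError(f"illegal structure character {ch!r} at position {i}")
    if stack:
        raise StructureError(f"unbalanced '(' at position {stack[-1]}")
    return table


def dotbracket_from_pairs(n: int, pairs) -> str:
    chars = ["."] * n
    for i, j in pairs:
        a, b = (i, j) if i < j else (j, i)
        chars[a], chars[b] = "(", ")"
    return "".join(chars)


_ENERGY_RE = re.compile(r"\(\s*(-?\d+(?:\.\d+)?)\s*\)\s*$")


def parse_dotbracket(record: str) -> SecondaryStructure:
    """Parse a ``sequence\\nstructure (energy)`` record (external-folder dialect).

    A leading ``>name`` FASTA-style line is tolerated and ignored.
    """
    lines = [ln for ln in record.strip().splitlines() if ln.strip()]
    if lines and lines[0].startswith(">"):
        lines = lines[1:]
    if len(lines) < 2:
        raise StructureError("record needs a sequence line and a structure line")
    seq = _as_rna(lines[0])
    struct_line = lines[1].strip()
    m = _ENERGY_RE.search(struct_line)
    dotbracket = struct_line[: m.start()].strip() if m else struct_line
    if m is None:
        # all-dot structures are allowed to state no energy: it is zero
        if set(dotbracket) - {"."}:
            raise StructureError("missing or unparseable trailing (energy) term")
        energy = 0.0
    else:
        energy = float(m.group(1))
    table = pair_table_from_dotbracket(dotbracket)
    return SecondaryStructure(seq, dotbracket, energy, table)


# ---------------------------------------------------------------------------
# energy of an explicit structure (loop decomposition)
# ---------------------------------------------------------------------------

def energy_of_structure(sequence: str, pairs, model: Optional[EnergyModel] = None) -> float:
    """Score an explicit set of nested pairs under the shipped energy model.

    Decomposes the structure into stacks, hairpin loops, interior/bulge loops
    and multibranch loops; the exterior loop is free.  Used to re-validate
    stored witnesses; the fold DP minimises exactly this quantity.
    """
    model = model or EnergyModel.default()
    seq = _as_rna(sequence)
    n = len(seq)
    table = [-1] * n
    for i, j in pairs:
        a, b = (i, j) if i < j else (j, i)
        if seq[a] + seq[b] not in WATSON_CRICK_WOBBLE:
            raise StructureError(f"disallowed pair at ({a},{b})")
        table[a], table[b] = b, a

    def pair_str(i: int) -> str:
        return seq[i] + seq[table[i]]

    total = 0.0
    for i, j in sorted((i, j) for i, j in enumerate(table) if j > i):
        # walk the loop closed by (i, j)
        children = []
        unpaired = 0
        k = i + 1
        while k < j:
            if table[k] > k:
                children.append(k)
                k = table[k] + 1
            elif table[k] == -1:
                unpaired += 1
                k += 1
            else:  # partner before k: malformed nesting
                raise StructureError("pairs are not properly nested")
        if not children:
            total += model.hairpin_energy(unpaired)
        elif len(children) == 1:
            if unpaired == 0:
                total += model.stack_energy(pair_str(i), pair_str(children[0]))
            else:
                total += model.interior_energy(unpaired)
        else:
            total += (
                model.multi_init
                + model.multi_branch * (len(children) + 1)
                + model.multi_unpaired * unpaired
            )
    return total


# ---------------------------------------------------------------------------
# minimum free energy dynamic program
# ---------------------------------------------------------------------------

def fold_mfe(sequence: str, model: Optional[EnergyModel] = None) -> SecondaryStructure:
    """Fold ``sequence`` into its minimum-energy pseudoknot-free structure.

    Zuker-style recursions over the simplified model: V(i,j) is the optimal
    energy given (i,j) paired (hairpin, stack/interior with loop size capped
    at ``max_interior_loop``, or multibranch closing); WM supports the linear
    multibranch decomposition; the exterior loop is unpenalised.  Ties are
    broken by a fixed traceback preference (documented in the methods note).
    """
    model = model or EnergyModel.default()
    seq = _as_rna(sequence)
    n = len(seq)
    if not 10 <= n <= 500:
        raise StructureError(f"sequence length {n} outside supported range 10..500")

    codes = np.array([{"A": 0, "C": 1, "G": 2, "U": 3}[c] for c in seq])
    pair_code = np.full((n, n), -1, dtype=int)
    for i in range(n):
        for j in range(i + 4, n):
            pc = _PAIR_CODE.get(seq[i] + seq[j])
            if pc is not None:
                pair_code[i, j] = pc
    del codes

    mh = model.min_hairpin_loop
    mil = model.max_interior_loop
    # interior penalty lookup: PEN[a, b] for a = k-i-1, b = j-l-1 unpaired counts
    PEN = np.full((mil + 1, mil + 1), INF)
    for a in range(mil + 1):
        for b in range(mil + 1):
            u = a + b
            if 1 <= u <= mil:
                PEN[a, b] = model.interior_energy(u)
    SM = model._stack_mat

    V = np.full((n, n), INF)
    WM = np.full((n, n), INF)

    for d in range(4, n):
        for i in range(0, n - d):
            j = i + d
            pc = pair_code[i, j]
            if pc >= 0:
                best = model.hairpin_energy(j - i - 1)
                # stack
                pin = pair_code[i + 1, j - 1]
                if pin >= 0 and V[i + 1, j - 1] < INF / 2:
                    cand = V[i + 1, j - 1] + SM[pc, pin]
                    if cand < best:
                        best = cand
                # interior / bulge (at least one unpaired base)
                ka = min(mil, j - i - 6) + 1  # k ranges i+1 .. i+ka
                if ka > 0:
                    sub = V[i + 1 : i + 1 + ka, max(i + 1, j - 1 - mil) : j]
                    if sub.size:
                        lo = max(i + 1, j - 1 - mil)
                        # columns correspond to l = lo..j-1 -> b = j-1-l
                        sub = sub[:, ::-1]  # now column b = 0.. j-1-lo
                        pen = PEN[: sub.shape[0], : sub.shape[1]]
                        cand = float(np.min(sub + pen))
                        if cand < best:
                            best = cand
                # multibranch closing: >= 2 inner helices
                if d >= 10:
                    left = WM[i + 1, i + 1 : j - 5]
                    right = WM[i + 2 : j - 4, j - 1]
                    if left.size:
                        m2 = float(np.min(left + right))
                        if m2 < INF / 2:
                            cand = model.multi_init + model.multi_branch + m2
                            if cand < best:
                                best = cand
                V[i, j] = best
            # WM
            wm = INF
            if V[i, j] < INF / 2:
                wm = V[i, j] + model.multi_branch
            wm = min(wm, WM[i + 1, j] + model.multi_unpaired if i + 1 <= j else INF)
            wm = min(wm, WM[i, j - 1] + model.multi_unpaired if i <= j - 1 else INF)
            if j - i >= 9:
                split = WM[i, i + 4 : j - 4] + WM[i + 5 : j - 3, j]
                if split.size:
                    wm = min(wm, float(np.min(split)))
            WM[i, j] = wm

    # exterior loop
    W = np.zeros(n + 1)  # W[j+1] = optimal over prefix 0..j
    for j in range(n):
        best = W[j]
        for i in range(0, j - 3):
            if V[i, j] < INF / 2:
                cand = W[i] + V[i, j]
                if cand < best:
                    best = cand
        W[j + 1] = best

    mfe = float(W[n])

    # -- traceback ---------------------------------------------------------
    eps = 1e-7
    pairs: list = []

    def trace_v(i: int, j: int) -> None:
        pairs.append((i, j))
        target = V[i, j]
        pc = pair_code[i, j]
        # preference: stack, interior (k ascending, l descending), multi, hairpin
        pin = pair_code[i + 1, j - 1]
        if pin >= 0 and abs(V[i + 1, j - 1] + SM[pc, pin] - target) < eps:
            trace_v(i + 1, j - 1)
            return
        for k in range(i + 1, min(i + 1 + mil, j - 5) + 1):
            a = k - i - 1
            for l in range(j - 1, k + 3, -1):
                u = a + (j - 1 - l)
                if u < 1 or u > mil:
                    continue
                if V[k, l] < INF / 2 and abs(V[k, l] + model.interior_energy(u) - target) < eps:
                    trace_v(k, l)
                    return
        if j - i >= 10:
            for m in range(i + 2, j - 4):
                if (
                    WM[i + 1, m - 1] < INF / 2
                    and WM[m, j - 1] < INF / 2
                    and abs(
                        model.multi_init
                        + model.multi_branch
                        + WM[i + 1, m - 1]
                        + WM[m, j - 1]
                        - target
                    )
                    < eps
                ):
                    trace_wm(i + 1, m - 1)
                    trace_wm(m, j - 1)
                    return
        # hairpin: nothing inside
        return

    def trace_wm(i: int, j: int) -> None:
        target = WM[i, j]
        if V[i, j] < INF / 2 and abs(V[i, j] + model.multi_branch - target) < eps:
            trace_v(i, j)
            return
        if i + 1 <= j and abs(WM[i + 1, j] + model.multi_unpaired - target) < eps:
            trace_wm(i + 1, j)
            return
        if i <= j - 1 and abs(WM[i, j - 1] + model.multi_unpaired - target) < eps:
            trace_wm(i, j - 1)
            return
        for m in range(i + 5, j - 3):
            if (
                WM[i, m - 1] < INF / 2
                and WM[m, j] < INF / 2
                and abs(WM[i, m - 1] + WM[m, j] - target) < eps
            ):
                trace_wm(i, m - 1)
                trace_wm(m, j)
                return

    j = n
    while j > 0:
        if abs(W[j] - W[j - 1]) < eps:
            j -= 1
            continue
        done = False
        for i in range(0, j - 4):
            if V[i, j - 1] < INF / 2 and abs(W[i] + V[i, j - 1] - W[j]) < eps:
                trace_v(i, j - 1)
                j = i
                done = True
                break
        if not done:  # pragma: no cover - defensive
            j -= 1

    table = [-1] * n
    for a, b in pairs:
        table[a], table[b] = b, a
    db = dotbracket_from_pairs(n, pairs)
    return SecondaryStructure(seq, db, mfe, table)


def passes_mfe_gate(s: SecondaryStructure, threshold: float = -0.2) -> bool:
    """Hairpin stability gate: MFE per nucleotide strictly below ``threshold``."""
    return s.mfe_per_nt < threshold
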