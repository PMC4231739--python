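"""Sequence combinatorics under Watson–Crick symmetry.

Double-stranded DNA fragments are written 5'→3' along one backbone (the
"Watson" strand); the antiparallel complementary reading describes the same
physical fragment, so k-mers come in reverse-complement equivalence classes.
This module enumerates and names those classes (dinucleotide steps,
tetranucleotide contexts), builds the repeating 18-mer oligomer designs that
pack every tetranucleotide into a minimal set of simulations, and locates the
centermost occurrence of a tetranucleotide within a design.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")
_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G", "R": "Y", "Y": "R"}

#: Alphabets accepted by the enumeration routines.
FULL_ALPHABET = "ACGT"
RY_ALPHABET = "RY"


def _validate(seq: str, alphabet: str = FULL_ALPHABET) -> str:
    if not seq:
        raise ValueError("empty sequence")
    up = seq.upper()
    for i, ch in enumerate(up):
        if ch not in alphabet:
            raise ValueError(
                f"invalid character {seq[i]!r} at position {i + 1}: "
                f"alphabet is {{{','.join(alphabet)}}}"
            )
    return up


def complement(base: str) -> str:
    """Complement of a single base (A↔T, G↔C; R↔Y in the coarse alphabet)."""
    b = base.upper()
    if b not in _COMPLEMENT:
        raise ValueError(f"invalid character {base!r} at position 1")
    return _COMPLEMENT[b]


def reverse_complement(seq: str) -> str:
    """5'→3' reading of the complementary strand of ``seq``.

    Case-insensitive; returns upper case. An involution:
    ``reverse_complement(reverse_complement(s)) == s.upper()``.
    """
    alphabet = RY_ALPHABET if set(seq.upper()) <= set(RY_ALPHABET) else FULL_ALPHABET
    up = _validate(seq, alphabet)
    return "".join(_COMPLEMENT[c] for c in reversed(up))


def is_purine(base: str) -> bool:
    return base.upper() in PURINES


def ry_code(seq: str) -> str:
    """Map a sequence to the purine/pyrimidine (R/Y) alphabet."""
    return "".join("R" if c in PURINES else "Y" for c in _validate(seq))


def _rank(word: str) -> tuple:
    """Canonical-preference key: more purines first, then more G, then
    alphabetically first.  Higher rank (smaller tuple) wins."""
    n_pur = sum(c in "AGR" for c in word)
    n_g = word.count("G")
    return (-n_pur, -n_g, word)


def canonical_reading(seq: str) -> str:
    """The canonical member of {seq, reverse_complement(seq)}.

    Preference: the reading with the most purines, then (if balanced) the one
    with more G, then the alphabetically first.  For dinucleotides this
    reproduces the conventional 10 step names AA, AT, TA, GG, GC, CG, GA, AG,
    GT, TG; the strand carrying the canonical reading is the Watson backbone.
    """
    up = _validate(seq, RY_ALPHABET if set(seq.upper()) <= set(RY_ALPHABET) else FULL_ALPHABET)
    rc = reverse_complement(up)
    return min(up, rc, key=_rank)


@dataclass(frozen=True)
class StepClass:
    """A dinucleotide step equivalence class under Watson–Crick symmetry."""

    canonical_name: str
    members: tuple[str, ...]
    self_symmetric: bool

    def __str__(self) -> str:  # pragma: no cover
        return self.canonical_name


@dataclass(frozen=True)
class TetraClass:
    """A tetranucleotide equivalence class under Watson–Crick symmetry."""

    canonical_name: str
    members: tuple[str, ...]
    self_symmetric: bool
    central_step: StepClass = field(compare=False)
    flanking_family: str = field(compare=False)


@dataclass(frozen=True)
class SeqClass:
    """Generic k-mer reverse-complement class (coarse or full alphabet)."""

    canonical_name: str
    members: tuple[str, ...]
    self_symmetric: bool


def step_class(dinucleotide: str) -> StepClass:
    """Resolve a dinucleotide to its named step class."""
    up = _validate(dinucleotide)
    if len(up) != 2:
        raise ValueError("a step is a 2-letter sequence")
    canon = canonical_reading(up)
    rc = reverse_complement(canon)
    self_sym = canon == rc
    members = (canon,) if self_sym else (canon, rc)
    return StepClass(canon, members, self_sym)


def canonical_step_name(dinucleotide: str) -> str:
    """Canonical name of a dinucleotide step (e.g. TT → AA, CA → TG)."""
    return step_class(dinucleotide).canonical_name


def flanking_family(tetra: str) -> str:
    """Purine/pyrimidine family of the flanking base pairs, e.g. ``R..Y``."""
    up = _validate(tetra)
    if len(up) != 4:
        raise ValueError("a tetranucleotide is a 4-letter sequence")
    code = ry_code(up)
    return f"{code[0]}..{code[3]}"


def tetra_class(tetra: str) -> TetraClass:
    """Resolve a tetranucleotide to its named class.

    The canonical name follows the same deterministic rule as step naming
    (most purines, then most G, then alphabetical); the class records the
    central step and the flanking R/Y family of the canonical reading.
    """
    up = _validate(tetra)
    if len(up) != 4:
        raise ValueError("a tetranucleotide is a 4-letter sequence")
    canon = canonical_reading(up)
    rc = reverse_complement(canon)
    self_sym = canon == rc
    members = (canon,) if self_sym else (canon, rc)
    return TetraClass(canon, members, self_sym, step_class(canon[1:3]), flanking_family(canon))


def enumerate_classes(k: int, alphabet: str = "full") -> list[SeqClass]:
    """All reverse-complement equivalence classes of k-mers.

    ``alphabet`` is ``"full"`` (A,C,G,T) or ``"purine_pyrimidine"`` (R,Y).
    Every k-mer belongs to exactly one class; a class is self-symmetric when
    its member equals its own reverse complement.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    letters = {"full": FULL_ALPHABET, "purine_pyrimidine": RY_ALPHABET}[alphabet]
    seen: set[str] = set()
    classes: list[SeqClass] = []
    from itertools import product

    for tup in product(letters, repeat=k):
        word = "".join(tup)
        if word in seen:
            continue
        rc = reverse_complement(word)
        seen.add(word)
        seen.add(rc)
        canon = canonical_reading(word)
        if word == rc:
            classes.append(SeqClass(canon, (canon,), True))
        else:
            classes.append(SeqClass(canon, (canon, reverse_complement(canon)), False))
    return classes


def class_counts(classes: Iterable[SeqClass]) -> dict[str, int]:
    """Total / self-symmetric / pair counts for a class enumeration."""
    cls = list(classes)
    n_sym = sum(c.self_symmetric for c in cls)
    return {"total": len(cls), "self_symmetric": n_sym, "pairs": len(cls) - n_sym}


def all_tetra_classes() -> list[TetraClass]:
    """The 136 tetranucleotide classes with full naming metadata."""
    return [tetra_class(c.canonical_name) for c in enumerate_classes(4)]


# ---------------------------------------------------------------------------
# Cyclic (oligomer-design) classes
# ---------------------------------------------------------------------------

def _rotations(word: str) -> list[str]:
    return [word[i:] + word[:i] for i in range(len(word))]


@dataclass(frozen=True)
class CyclicClass:
    """Orbit of a k-mer under cyclic rotation and reverse complementation.

    Each orbit corresponds to one repeating oligomer design: an oligomer built
    on repeat unit ABCD contains the tetranucleotides ABCD, BCDA, CDAB and
    DABC (folded through reverse-complement identification).
    """

    representative: str
    members: tuple[str, ...]
    covered: tuple[str, ...]  # canonical tetranucleotide class names


def enumerate_cyclic_classes(k: int = 4) -> list[CyclicClass]:
    """Equivalence classes of k-mers under rotation + reverse complement.

    For k = 4 there are 39 classes, i.e. 39 oligomer designs suffice to cover
    all 136 tetranucleotide classes.  The representative is chosen by the same
    purine/G/alphabetical preference rule used for class naming.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    from itertools import product

    seen: set[str] = set()
    classes: list[CyclicClass] = []
    for tup in product(FULL_ALPHABET, repeat=k):
        word = "".join(tup)
        if word in seen:
            continue
        orbit: set[str] = set()
        frontier = {word}
        while frontier:
            w = frontier.pop()
            if w in orbit:
                continue
            orbit.add(w)
            frontier.update(_rotations(w))
            frontier.add(reverse_complement(w))
        seen.update(orbit)
        rep = min(orbit, key=_rank)
        covered = sorted({canonical_reading(r) for r in _rotations(rep)})
        classes.append(CyclicClass(rep, tuple(sorted(orbit)), tuple(covered)))
    return classes


# ---------------------------------------------------------------------------
# Oligomer designs and occurrences
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OligomerDesign:
    """An 18-mer of the form 5'-GC-CD-ABCD-ABCD-ABCD-GC-3'.

    The GC caps suppress end fraying; the 3.5 repeats of the unit ABCD place
    three full repeats at levels 5–8, 9–12 and 13–16 so that every rotation of
    the unit occurs away from the capped termini.
    """

    repeat_unit: str
    sequence: str

    @property
    def name(self) -> str:
        return self.repeat_unit

    def __len__(self) -> int:
        return len(self.sequence)


def build_oligomer(repeat_unit: str) -> OligomerDesign:
    """Construct the 18-mer design for a 4-letter repeat unit ABCD."""
    unit = _validate(repeat_unit)
    if len(unit) != 4:
        raise ValueError("repeat unit must be 4 letters")
    seq = "GC" + unit[2:] + unit * 3 + "GC"
    assert len(seq) == 18
    return OligomerDesign(unit, seq)


def all_designs() -> list[OligomerDesign]:
    """The 39 oligomer designs covering all 136 tetranucleotide classes."""
    return [build_oligomer(c.representative) for c in enumerate_cyclic_classes(4)]


@dataclass(frozen=True)
class Occurrence:
    """One occurrence of a tetranucleotide within an oligomer.

    ``start`` is the 1-based Watson-strand position of the leftmost covered
    level; ``levels`` are the four covered base-pair levels; ``strand`` says
    on which strand reading the query sequence appears 5'→3'.
    """

    tetra: str
    strand: str  # "Watson" | "Crick"
    start: int
    levels: tuple[int, int, int, int]

    @property
    def central_junction(self) -> int:
        """1-based index of the central junction (between levels j, j+1)."""
        return self.start + 1


def find_occurrences(tetra: str, oligomer: OligomerDesign) -> list[Occurrence]:
    """All occurrences of ``tetra`` on either strand reading of the design."""
    query = _validate(tetra)
    if len(query) != 4:
        raise ValueError("a tetranucleotide is a 4-letter sequence")
    seq = oligomer.sequence
    occs: list[Occurrence] = []
    for strand, probe in (("Watson", query), ("Crick", reverse_complement(query))):
        start = seq.find(probe)
        while start != -1:
            s = start + 1  # 1-based
            occs.append(Occurrence(query, strand, s, (s, s + 1, s + 2, s + 3)))
            start = seq.find(probe, start + 1)
    # Self-symmetric queries appear identically on both strands; keep Watson.
    if query == reverse_complement(query):
        occs = [o for o in occs if o.strand == "Watson"]
    return occs


def centermost_occurrence(tetra: str, oligomer: OligomerDesign) -> Occurrence:
    """The occurrence whose covered-level midpoint is nearest the oligomer
    midpoint.  Ties prefer the 5'-most occurrence on the Watson strand."""
    occs = find_occurrences(tetra, oligomer)
    if not occs:
        raise ValueError(
            f"{tetra!r} does not occur on either strand of oligomer {oligomer.name}"
        )
    mid = (len(oligomer) + 1) / 2.0

    def key(o: Occurrence):
        return (abs((o.start + 1.5) - mid), o.strand != "Watson", o.start)

    return min(occs, key=key)


def design_index() -> dict[str, tuple[str, Occurrence]]:
    """Map every canonical tetranucleotide to (design name, centermost
    occurrence) over the 39-design set."""
    index: dict[str, tuple[str, Occurrence]] = {}
    designs = {d.name: d for d in all_designs()}
    covered_by = {
        d: c.covered for c in enumerate_cyclic_classes(4) for d in [c.representative]
    }
    for name, design in designs.items():
        for tetra in covered_by[name]:
            if tetra not in index:
                index[tetra] = (name, centermost_occurrence(tetra, design))
    return index
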