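"""PROSITE-style motif patterns and the CNGC family keep/reject rule.

Plant CNGC channels are recognized by the co-occurrence of a cyclic
nucleotide-binding domain (CNBD) and an ion-transport/transmembrane domain,
plus a family-diagnostic consensus motif spanning the phosphate-binding
cassette (PBC) and hinge region inside the CNBD. Domain presence arrives as
an input table (SMART/CDD-style); the motif is matched here.

Pattern syntax: dash-separated elements. ``A`` is a literal residue, ``[ABC]``
a residue class, ``X`` a wildcard, and any of these may carry a repeat count
``(n)`` or ``(m,n)`` — so ``X(2)``, ``X(10,20)`` and ``[FY](0,1)`` are all
valid. Matching is case-insensitive; an ambiguous ``X`` in the *subject*
sequence matches nothing (strict). For variable-length elements the shortest
satisfying expansion per start position is reported (leftmost-shortest),
which is deterministic and sufficient for presence/absence classification.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .seqio import AMINO_ACIDS, DomainAnnotation, SequenceRecord

#: Family-diagnostic consensus motif over the PBC and hinge region.
CNGC_CONSENSUS = ("[LI]-X(2)-[GSE]-X-[VFIY]-X-G-X(0,1)-[DE]-L-L-X-W-X-[LQ]-"
                  "X(10,20)-S-X-[SAR]-X(7)-[VTI]-E-[AG]-F-X-L")

#: Isoleucine-glutamine calmodulin-binding motif.
IQ_MOTIF = "[IV]-Q-X-X-W-R-X-X-X-[RKQ]"

#: Calmodulin-binding domain pattern. The published rendering has unbalanced
#: brackets; this balanced reading is an interpretation and the pattern is
#: not used for classification.
CAMBD_MOTIF = "[FLY]-X(10,12)-[AFI]-R-[FY](0,1)"


class PatternError(ValueError):
    """Parse error in a PROSITE-style pattern; message carries the position."""


@dataclass(frozen=True)
class PatternElement:
    """One pattern element: an allowed-residue set repeated min..max times."""

    residues: frozenset[str] | None  # None means wildcard (any amino acid)
    min_count: int = 1
    max_count: int = 1

    def char_class(self) -> str:
        if self.residues is None:
            return "[" + AMINO_ACIDS + "]"
        return "[" + "".join(sorted(self.residues)) + "]"


@dataclass(frozen=True)
class MotifPattern:
    name: str
    elements: tuple[PatternElement, ...]
    _regex: re.Pattern = field(repr=False, compare=False, default=None)

    @property
    def min_length(self) -> int:
        return sum(e.min_count for e in self.elements)

    @property
    def max_length(self) -> int:
        return sum(e.max_count for e in self.elements)


@dataclass(frozen=True)
class PatternMatch:
    pattern_name: str
    protein_id: str
    start: int  # 1-based inclusive residue position
    end: int
    matched_span: str


_ELEMENT_RE = re.compile(
    r"(?P<body>\[(?P<cls>[A-Za-z]*)\]|(?P<lit>[A-Za-z]))"
    r"(?:\((?P<m>\d+)(?:,(?P<n>\d+))?\))?$")


def compile_pattern(text: str, name: str = "pattern") -> MotifPattern:
    """Compile a dash-separated PROSITE-style pattern string."""
    elements: list[PatternElement] = []
    pos = 0
    for raw in text.strip().split("-"):
        token = raw.strip()
        m = _ELEMENT_RE.match(token)
        if m is None or not token:
            raise PatternError(
                f"{name}: malformed element {token!r} at position {pos}")
        if m.group("cls") is not None:
            if not m.group("cls"):
                raise PatternError(
                    f"{name}: empty residue class at position {pos}")
            letters = set(m.group("cls").upper())
            bad = letters - set(AMINO_ACIDS)
            if bad:
                raise PatternError(
                    f"{name}: non-amino-acid {sorted(bad)} at position {pos}")
            residues: frozenset[str] | None = frozenset(letters)
        else:
            lit = m.group("lit").upper()
            if lit == "X":
                residues = None
            elif lit in AMINO_ACIDS:
                residues = frozenset(lit)
            else:
                raise PatternError(
                    f"{name}: unknown residue {lit!r} at position {pos}")
        lo = int(m.group("m")) if m.group("m") else 1
        hi = int(m.group("n")) if m.group("n") else lo
        if lo > hi:
            raise PatternError(
                f"{name}: count ({lo},{hi}) has m > n at position {pos}")
        elements.append(PatternElement(residues, lo, hi))
        pos += 1
    if not elements:
        raise PatternError(f"{name}: empty pattern")
    regex = re.compile("".join(
        e.char_class() + (f"{{{e.min_count},{e.max_count}}}"
                          if (e.min_count, e.max_count) != (1, 1) else "")
        for e in elements))
    return MotifPattern(name=name, elements=tuple(elements), _regex=regex)


def find_matches(pattern: MotifPattern, protein: SequenceRecord
                 ) -> list[PatternMatch]:
    """All match start positions, overlaps allowed, ordered by (start, end).

    For each start the shortest window length whose full extent satisfies the
    pattern is reported (leftmost-shortest expansion of variable wildcards).
    """
    seq = protein.residues.upper()
    n = len(seq)
    lo, hi = pattern.min_length, pattern.max_length
    out: list[PatternMatch] = []
    for start in range(0, n - lo + 1):
        for length in range(lo, min(hi, n - start) + 1):
            window = seq[start:start + length]
            if pattern._regex.fullmatch(window):
                out.append(PatternMatch(
                    pattern.name, protein.id, start + 1, start + length,
                    window))
                break
    return out


# ---------------------------------------------------------------------------
# Family classification
# ---------------------------------------------------------------------------

#: Domain labels expected in the annotation table.
CNBD_LABEL = "CNBD"
ION_TRANSPORT_LABEL = "ION_TRANSPORT"

#: Minimum residue count operationalizing "truncated". The shortest accepted
#: family member among the reference set is 558 aa, so 400 is a conservative
#: floor.
DEFAULT_MIN_LENGTH = 400


@dataclass(frozen=True)
class ClassificationResult:
    protein_id: str
    verdict: str  # "accepted" | "rejected"
    reasons: tuple[str, ...]

    def __post_init__(self) -> None:
        assert (self.verdict == "accepted") == (not self.reasons)


def classify_candidate(protein: SequenceRecord,
                       domains: "DomainAnnotation | None",
                       min_length: int = DEFAULT_MIN_LENGTH,
                       pattern: MotifPattern | None = None
                       ) -> ClassificationResult:
    """Apply the family keep/reject rule to one candidate protein.

    Accepted iff the CNBD and ion-transport domains are both annotated, the
    diagnostic consensus motif matches at least once, and the protein is at
    least ``min_length`` residues. Reasons enumerate every failed criterion.
    An absent annotation row means no domains.
    """
    if pattern is None:
        pattern = compile_pattern(CNGC_CONSENSUS, "CNGC_consensus")
    labels = domains.domain_labels if domains is not None else frozenset()
    reasons: list[str] = []
    if CNBD_LABEL not in labels:
        reasons.append("missing_CNBD")
    if ION_TRANSPORT_LABEL not in labels:
        reasons.append("missing_ion_transport")
    if not find_matches(pattern, protein):
        reasons.append("missing_CNGC_motif")
    if len(protein) < min_length:
        reasons.append("truncated")
    verdict = "accepted" if not reasons else "rejected"
    return ClassificationResult(protein.id, verdict, tuple(reasons))


def classify_family(proteins: list[SequenceRecord],
                    annotations: dict[str, "DomainAnnotation"],
                    min_length: int = DEFAULT_MIN_LENGTH,
                    pattern: MotifPattern | None = None
                    ) -> list[ClassificationResult]:
    """Classify a candidate set; annotation rows must reference known ids."""
    known = {p.id for p in proteins}
    for pid in annotations:
        if pid not in known:
            raise KeyError(f"domain annotation references unknown protein "
                           f"id {pid!r}")
    if pattern is None:
        pattern = compile_pattern(CNGC_CONSENSUS, "CNGC_consensus")
    return [classify_candidate(p, annotations.get(p.id), min_length, pattern)
            for p in proteins]


def load_patterns(path: str) -> dict[str, MotifPattern]:
    """Load named patterns from a plain-text file: ``name<whitespace>pattern``
    per line; blank lines and ``#`` comments ignored."""
    out: dict[str, MotifPattern] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(maxsplit=1)
            if len(parts) != 2:
                raise PatternError(f"bad pattern line: {line!r}")
            out[parts[0]] = compile_pattern(parts[1], parts[0])
    return out
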