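"""Ortholog-pair selection analysis and duplication classification.

Ka/Ks follows Nei & Gojobori (1986): synonymous/nonsynonymous site counts are
potential-change fractions per codon position (changes to stop codons
excluded from the denominator), averaged over the two sequences; observed
differences in multi-hit codons are averaged over all minimal mutational
pathways that avoid stop codons; the Jukes-Cantor correction
d = -(3/4) ln(1 - (4/3) p) is applied to both proportions. A Ka/Ks ratio
above 1 indicates positive selection, below 1 purifying selection
(functional constraint), and exactly 1 neutrality.

Tandem duplicates are same-chromosome family pairs whose intergenic gap
(nearest feature ends) is below 50 kb; clusters are the transitive closure of
that pairwise relation. Segmental duplicates come from a syntenic-block input
table. Sub-genome fractionation (LF / MF-I / MF-II, the least/most
fractionated partitions left by whole-genome triplication) is summarized
from an assignment table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations, permutations

import pandas as pd
from Bio.Align import substitution_matrices
from Bio.Data.CodonTable import standard_dna_table

from .seqio import GeneModel, SequenceRecord

TANDEM_MAX_GAP = 50_000  # bp

CODON_TABLE = dict(standard_dna_table.forward_table)
STOP_CODONS = set(standard_dna_table.stop_codons)
_BASES = "ACGT"


class EvolutionError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Global protein alignment (Needleman-Wunsch, linear gaps)
# ---------------------------------------------------------------------------

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_BLOSUM62_DICT = {(a, b): float(_BLOSUM62[a, b])
                  for a in _BLOSUM62.alphabet for b in _BLOSUM62.alphabet}


def global_protein_align(a: SequenceRecord, b: SequenceRecord,
                         matrix=None, gap_penalty: float = 8.0
                         ) -> tuple[str, str, float]:
    """Optimal global alignment of two proteins; returns (ali_a, ali_b, score).

    Linear gap penalty; traceback ties broken deterministically by preferring
    the diagonal move, then the up move (gap in ``b``), then left.
    """
    if not a.residues or not b.residues:
        raise EvolutionError("cannot align an empty sequence")
    if matrix is None:
        matrix = _BLOSUM62_DICT
    elif not isinstance(matrix, dict):  # Biopython Array -> fast plain dict
        matrix = {(x, y): float(matrix[x, y])
                  for x in matrix.alphabet for y in matrix.alphabet}
    sa, sb = a.residues.upper(), b.residues.upper()
    n, m = len(sa), len(sb)
    score = [[0.0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        score[i][0] = -gap_penalty * i
    for j in range(1, m + 1):
        score[0][j] = -gap_penalty * j
    for i in range(1, n + 1):
        row, prev = score[i], score[i - 1]
        ai = sa[i - 1]
        for j in range(1, m + 1):
            row[j] = max(prev[j - 1] + matrix[ai, sb[j - 1]],
                         prev[j] - gap_penalty,
                         row[j - 1] - gap_penalty)
    # traceback: diagonal > up > left on ties
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0 and math.isclose(
                score[i][j],
                score[i - 1][j - 1] + matrix[sa[i - 1], sb[j - 1]]):
            out_a.append(sa[i - 1]); out_b.append(sb[j - 1]); i -= 1; j -= 1
        elif i > 0 and math.isclose(score[i][j], score[i - 1][j] - gap_penalty):
            out_a.append(sa[i - 1]); out_b.append("-"); i -= 1
        else:
            out_a.append("-"); out_b.append(sb[j - 1]); j -= 1
    return "".join(reversed(out_a)), "".join(reversed(out_b)), score[n][m]


# ---------------------------------------------------------------------------
# Codon back-translation
# ---------------------------------------------------------------------------

def codon_backtranslate(aligned_a: str, aligned_b: str,
                        cds_a: str, cds_b: str
                        ) -> tuple[list[str], list[str]]:
    """Expand a protein alignment to a codon alignment.

    Each aligned residue column becomes its source codon; protein gaps become
    ``---`` codons. CDS lengths must be 3x the ungapped protein lengths and
    every codon must translate to its residue (terminal stop codons may be
    omitted from the protein, and are dropped here).
    """
    cols_a, cols_b = [], []
    for name, aligned, cds, out in (("a", aligned_a, cds_a, cols_a),
                                    ("b", aligned_b, cds_b, cols_b)):
        cds = cds.upper().replace("U", "T")
        ungapped = aligned.replace("-", "").upper()
        if len(cds) % 3 != 0:
            raise EvolutionError(
                f"CDS {name} length {len(cds)} not divisible by 3")
        n_codons = len(cds) // 3
        if n_codons == len(ungapped) + 1 and cds[-3:] in STOP_CODONS:
            cds = cds[:-3]
            n_codons -= 1
        if n_codons != len(ungapped):
            raise EvolutionError(
                f"CDS {name} has {n_codons} codons for {len(ungapped)} "
                f"residues")
        k = 0
        for col, res in enumerate(aligned.upper()):
            if res == "-":
                out.append("---")
                continue
            codon = cds[3 * k:3 * k + 3]
            trans = CODON_TABLE.get(codon, "*")
            if trans != res:
                raise EvolutionError(
                    f"CDS {name}: codon {codon} at codon index {k} "
                    f"translates to {trans!r}, protein has {res!r}")
            out.append(codon)
            k += 1
    return cols_a, cols_b


# ---------------------------------------------------------------------------
# Nei-Gojobori
# ---------------------------------------------------------------------------

def _syn_sites(codon: str) -> float:
    """Synonymous potential of one codon (0..3), stop targets excluded."""
    aa = CODON_TABLE[codon]
    total = 0.0
    for pos in range(3):
        syn = valid = 0
        for base in _BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1:]
            if alt in STOP_CODONS:
                continue
            valid += 1
            if CODON_TABLE[alt] == aa:
                syn += 1
        if valid:
            total += syn / valid
    return total


def _pathway_differences(c1: str, c2: str) -> tuple[float, float]:
    """(syn, nonsyn) difference counts averaged over minimal pathways.

    Pathways passing through a stop codon are excluded; if every pathway is
    blocked, all pathways are used (standard fallback).
    """
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    results = []
    blocked_results = []
    for order in permutations(diff_pos):
        cur = c1
        syn = nonsyn = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                ok = False
            aa_change = (CODON_TABLE.get(cur, "*")
                         != CODON_TABLE.get(nxt, "*"))
            if aa_change:
                nonsyn += 1
            else:
                syn += 1
            cur = nxt
        (results if ok else blocked_results).append((syn, nonsyn))
    use = results or blocked_results
    s = sum(r[0] for r in use) / len(use)
    n = sum(r[1] for r in use) / len(use)
    return s, n


def jukes_cantor(p: float) -> float:
    """d = -(3/4) ln(1 - (4/3) p); undefined (ValueError) for p >= 3/4."""
    if p >= 0.75:
        raise ValueError(f"proportion {p} >= 3/4: correction undefined")
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p) + 0.0


@dataclass(frozen=True)
class OrthologPairResult:
    gene_a: str
    gene_b: str
    Ka: float | None
    Ks: float | None
    ratio: float | None
    selection_class: str  # positive | purifying | neutral | undefined
    S: float = 0.0
    N: float = 0.0
    Sd: float = 0.0
    Nd: float = 0.0


def nei_gojobori(codons_a: list[str], codons_b: list[str],
                 gene_a: str = "a", gene_b: str = "b") -> OrthologPairResult:
    """Nei-Gojobori Ka/Ks from a codon alignment.

    Columns containing a gap or a stop codon in either sequence are excluded.
    """
    if len(codons_a) != len(codons_b):
        raise EvolutionError("codon alignments differ in length")
    pairs = [(x, y) for x, y in zip(codons_a, codons_b)
             if "-" not in x and "-" not in y
             and x not in STOP_CODONS and y not in STOP_CODONS]
    if not pairs:
        raise EvolutionError("no comparable codon columns")
    S = sum((_syn_sites(x) + _syn_sites(y)) / 2 for x, y in pairs)
    N = 3 * len(pairs) - S
    Sd = Nd = 0.0
    for x, y in pairs:
        ds, dn = _pathway_differences(x, y)
        Sd += ds
        Nd += dn
    ps = Sd / S if S > 0 else 0.0
    pn = Nd / N if N > 0 else 0.0
    try:
        Ks = jukes_cantor(ps)
        Ka = jukes_cantor(pn)
    except ValueError:
        return OrthologPairResult(gene_a, gene_b, None, None, None,
                                  "undefined", S, N, Sd, Nd)
    if Ks > 0:
        ratio = Ka / Ks
        if ratio > 1:
            cls = "positive"
        elif ratio < 1:
            cls = "purifying"
        else:
            cls = "neutral"
    else:
        ratio, cls = None, "undefined"
    return OrthologPairResult(gene_a, gene_b, Ka, Ks, ratio, cls, S, N, Sd, Nd)


def kaks_for_pair(protein_a: SequenceRecord, protein_b: SequenceRecord,
                  cds_a: SequenceRecord, cds_b: SequenceRecord
                  ) -> OrthologPairResult:
    """Align proteins, back-translate to codons, and run Nei-Gojobori."""
    ali_a, ali_b, _ = global_protein_align(protein_a, protein_b)
    ca, cb = codon_backtranslate(ali_a, ali_b,
                                 cds_a.to_dna().residues if cds_a.alphabet == "RNA"
                                 else cds_a.residues,
                                 cds_b.to_dna().residues if cds_b.alphabet == "RNA"
                                 else cds_b.residues)
    return nei_gojobori(ca, cb, protein_a.id, protein_b.id)


# ---------------------------------------------------------------------------
# Duplication classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DuplicationCall:
    gene_a: str
    gene_b: str
    kind: str  # tandem | segmental | none
    distance_bp: int | None  # None when genes sit on different chromosomes


def locus_distance(a: GeneModel, b: GeneModel) -> int | None:
    """Gap between nearest feature ends; 0 if overlapping; None if on
    different chromosomes."""
    if a.chromosome != b.chromosome:
        return None
    if a.end < b.start:
        return b.start - a.end
    if b.end < a.start:
        return a.start - b.end
    return 0


def call_tandem(models: list[GeneModel], family_id: str | None = None
                ) -> list[DuplicationCall]:
    """Pairwise tandem calls among family members (gap < 50 kb, same
    chromosome)."""
    members = [m for m in models
               if family_id is None or m.family_id == family_id]
    calls = []
    for a, b in combinations(members, 2):
        d = locus_distance(a, b)
        if d is None:
            calls.append(DuplicationCall(a.gene_id, b.gene_id, "none", None))
        else:
            kind = "tandem" if d < TANDEM_MAX_GAP else "none"
            calls.append(DuplicationCall(a.gene_id, b.gene_id, kind, d))
    return calls


def tandem_clusters(calls: list[DuplicationCall]) -> list[frozenset[str]]:
    """Transitive closure of the pairwise tandem relation (union-find)."""
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for c in calls:
        if c.kind == "tandem":
            parent[find(c.gene_a)] = find(c.gene_b)
    groups: dict[str, set[str]] = {}
    for g in parent:
        groups.setdefault(find(g), set()).add(g)
    return sorted((frozenset(v) for v in groups.values() if len(v) > 1),
                  key=lambda s: sorted(s)[0])


def segmental_calls(blocks: pd.DataFrame) -> list[DuplicationCall]:
    """Segmental duplicate pairs from a syntenic-block table
    (columns gene_a, gene_b)."""
    return [DuplicationCall(str(r.gene_a), str(r.gene_b), "segmental", None)
            for r in blocks.itertuples()]


# ---------------------------------------------------------------------------
# Sub-genome fractionation
# ---------------------------------------------------------------------------

SUBGENOME_LABELS = ("LF", "MF-I", "MF-II")


def summarize_fractionation(assignments: pd.DataFrame | dict[str, str]
                            ) -> dict[str, int]:
    """Gene counts per sub-genome label; unknown labels are an error."""
    if isinstance(assignments, pd.DataFrame):
        mapping = dict(zip(assignments["gene_id"], assignments["subgenome"]))
    else:
        mapping = dict(assignments)
    counts = {label: 0 for label in SUBGENOME_LABELS}
    for gene, label in mapping.items():
        if label not in counts:
            raise EvolutionError(
                f"unknown sub-genome label {label!r} for gene {gene!r}")
        counts[label] += 1
    return counts
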