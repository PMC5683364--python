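"""Exon-intron organisation and intron phase annotation.

The phase of an intron is the cumulative upstream CDS length modulo 3 at its
insertion point: phase 0 sits between complete codons, phase 1 after the
first codon nucleotide, phase 2 between the second and third. Phases are
computed on CDS segments only (UTR exons are out of scope) using the
transcription-order exon convention of :mod:`cngckit.seqio`.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .seqio import GeneModel


@dataclass(frozen=True)
class IntronRecord:
    gene_id: str
    index: int   # 1-based ordinal in transcription order
    length: int  # bp
    phase: int   # 0 | 1 | 2


def annotate_introns(model: GeneModel) -> list[IntronRecord]:
    """Introns between consecutive CDS segments, with lengths and phases.

    Exon overlap is rejected by the GeneModel invariant; a single-exon gene
    has no introns.
    """
    if not model.exons:
        raise ValueError(f"{model.gene_id}: gene model has no exons")
    records: list[IntronRecord] = []
    cumulative = 0
    for idx, ((s1, e1), (s2, e2)) in enumerate(
            zip(model.exons, model.exons[1:]), start=1):
        cumulative += e1 - s1 + 1
        if model.strand == "+":
            length = s2 - e1 - 1
        else:
            length = s1 - e2 - 1
        if length < 1:
            raise ValueError(
                f"{model.gene_id}: non-positive intron between exons "
                f"{idx} and {idx + 1}")
        records.append(IntronRecord(model.gene_id, idx, length,
                                    cumulative % 3))
    return records


def phase_census(models: list[GeneModel]
                 ) -> tuple[dict[int, int], pd.DataFrame]:
    """Family-wide intron-phase totals and a per-gene structure table.

    Returns ``(totals, per_gene)`` where ``totals`` maps phase -> count and
    ``per_gene`` carries exon counts and per-phase intron counts per gene
    (substrate for exon-number contrasts between phylogenetic groups).
    """
    totals = {0: 0, 1: 0, 2: 0}
    rows = []
    for m in models:
        introns = annotate_introns(m)
        per = {0: 0, 1: 0, 2: 0}
        for rec in introns:
            per[rec.phase] += 1
            totals[rec.phase] += 1
        rows.append({
            "gene_id": m.gene_id,
            "exon_count": len(m.exons),
            "intron_count": len(introns),
            "phase0": per[0], "phase1": per[1], "phase2": per[2],
            "intron_lengths": ",".join(str(r.length) for r in introns),
            "phases": ",".join(str(r.phase) for r in introns),
        })
    return totals, pd.DataFrame(rows)
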