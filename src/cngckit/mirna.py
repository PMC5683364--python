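"""miRNA target-site scanning with expectation-penalty scoring.

A miRNA:target duplex is scored ungapped, column by column, with the miRNA
reversed into 3'->5' orientation against the target site read 5'->3':
Watson-Crick pairs cost 0, G:U wobbles 0.5, mismatches 1.0. The expectation
is the penalty sum (lower = better complementarity); sites at or below the
cutoff (stringent default 3.0, permissive 5.0) are reported.

Inhibition mode: translational repression is called iff a mismatch (not a
wobble) falls on miRNA positions 9-11 counted from the miRNA 5' end —
disrupting the central region blocks cleavage — otherwise cleavage.

Target-site accessibility (UPE) energies require an RNA-folding model and are
carried as pass-through annotations only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .seqio import SequenceRecord

WC_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
WOBBLE_PAIRS = {("G", "U"), ("U", "G")}

PENALTY = {"WC": 0.0, "wobble": 0.5, "mismatch": 1.0}
STATE_GLYPH = {"WC": ":", "wobble": ".", "mismatch": " "}

#: Stringent and permissive expectation cutoffs.
CUTOFF_STRINGENT = 3.0
CUTOFF_PERMISSIVE = 5.0

#: miRNA 5'-end positions whose mismatch flips the call to translation.
CENTRAL_POSITIONS = (9, 10, 11)


class MirnaError(ValueError):
    pass


def pair_state(mirna_base: str, target_base: str) -> str:
    """WC / wobble / mismatch state of one duplex column."""
    pair = (mirna_base.upper(), target_base.upper())
    if pair in WC_PAIRS:
        return "WC"
    if pair in WOBBLE_PAIRS:
        return "wobble"
    return "mismatch"


@dataclass(frozen=True)
class DuplexAlignment:
    mirna_id: str
    target_id: str
    mirna_seq: str     # 3'->5' in alignment orientation
    target_site: str   # 5'->3'
    target_start: int  # 1-based transcript coordinates
    target_end: int
    states: tuple[str, ...]
    expectation: float
    inhibition: str    # "cleavage" | "translation"
    upe: float | None = None

    def alignment_string(self) -> str:
        """Rendered pairing line: ':' WC, '.' wobble, ' ' mismatch."""
        return "".join(STATE_GLYPH[s] for s in self.states)


def score_duplex(mirna: SequenceRecord, site: str | SequenceRecord,
                 target_id: str = "", target_start: int = 1,
                 mirna_is_3to5: bool = False,
                 upe: float | None = None) -> DuplexAlignment:
    """Score one ungapped duplex between a miRNA and an equal-length site.

    The miRNA is supplied 5'->3' (miRBase convention) and reversed
    internally; pass ``mirna_is_3to5=True`` when it is already in alignment
    orientation. The site is RNA 5'->3'.
    """
    site_seq = (site.residues if isinstance(site, SequenceRecord)
                else site).upper().replace("T", "U")
    mseq = mirna.residues.upper().replace("T", "U")
    m3to5 = mseq if mirna_is_3to5 else mseq[::-1]
    if len(m3to5) != len(site_seq):
        raise MirnaError(
            f"duplex lengths differ: miRNA {len(m3to5)} vs site "
            f"{len(site_seq)}")
    states = tuple(pair_state(m, t) for m, t in zip(m3to5, site_seq))
    expectation = sum(PENALTY[s] for s in states)
    length = len(states)
    # column i (0-based) pairs miRNA 5'-position length - i
    central_mismatch = any(
        states[i] == "mismatch" and (length - i) in CENTRAL_POSITIONS
        for i in range(length))
    inhibition = "translation" if central_mismatch else "cleavage"
    return DuplexAlignment(
        mirna_id=mirna.id, target_id=target_id, mirna_seq=m3to5,
        target_site=site_seq, target_start=target_start,
        target_end=target_start + length - 1, states=states,
        expectation=expectation, inhibition=inhibition, upe=upe)


@dataclass
class TargetReport:
    mirna_id: str
    target_id: str
    sites: list[DuplexAlignment] = field(default_factory=list)

    @property
    def multiplicity(self) -> int:
        return len(self.sites)


def scan_transcript(mirna: SequenceRecord, transcript: SequenceRecord,
                    cutoff: float = CUTOFF_STRINGENT) -> TargetReport:
    """Score every miRNA-length window of the transcript; report windows with
    expectation <= cutoff, sorted by (expectation, position)."""
    tseq = transcript.residues.upper().replace("T", "U")
    k = len(mirna.residues)
    if len(tseq) < k:
        raise MirnaError(
            f"transcript {transcript.id} shorter than miRNA {mirna.id}")
    hits = []
    for start in range(len(tseq) - k + 1):
        duplex = score_duplex(mirna, tseq[start:start + k],
                              target_id=transcript.id,
                              target_start=start + 1)
        if duplex.expectation <= cutoff:
            hits.append(duplex)
    hits.sort(key=lambda h: (h.expectation, h.target_start))
    return TargetReport(mirna.id, transcript.id, hits)


def scan_all(mirnas: list[SequenceRecord], transcripts: list[SequenceRecord],
             cutoff: float = CUTOFF_STRINGENT) -> list[TargetReport]:
    reports = []
    for m in mirnas:
        for t in transcripts:
            if len(t.residues) < len(m.residues):
                continue
            rep = scan_transcript(m, t, cutoff)
            if rep.sites:
                reports.append(rep)
    return reports


def summarize_targets(reports: list[TargetReport]) -> tuple[int, int]:
    """(number of distinct miRNAs, number of distinct target genes) with at
    least one reported site."""
    mirnas = {r.mirna_id for r in reports if r.sites}
    genes = {r.target_id for r in reports if r.sites}
    return len(mirnas), len(genes)


def reports_to_table(reports: list[TargetReport]):
    """TSV-ready table mirroring the published duplex-report columns."""
    import pandas as pd

    rows = []
    for r in reports:
        for s in r.sites:
            rows.append({
                "mirna_acc": s.mirna_id,
                "target_acc": s.target_id,
                "expectation": s.expectation,
                "target_accessibility": s.upe,
                "target_start": s.target_start,
                "target_end": s.target_end,
                "alignment": s.alignment_string(),
                "inhibition": s.inhibition,
                "multiplicity": r.multiplicity,
            })
    return pd.DataFrame(rows)
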