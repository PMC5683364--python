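"""Accessors for the packaged reference tables.

These tables transcribe the published survey of the *Brassica oleracea* CNGC
family: per-protein physicochemical properties, Ka/Ks values for
ortholog pairs against *A. thaliana*, and the printed miRNA:target duplex
report. They serve as regression fixtures and as inputs to table-derived
statistics; they are data, not computed results.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .mirna import DuplexAlignment, score_duplex
from .seqio import SequenceRecord


def _load(name: str) -> pd.DataFrame:
    with resources.files("cngckit.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def protein_properties_table() -> pd.DataFrame:
    """Published per-protein property table (26 family members)."""
    return _load("table1_properties.tsv")


def kaks_table() -> pd.DataFrame:
    """Published Ka/Ks table for ortholog pairs (24 pairs)."""
    return _load("table2_kaks.tsv")


def duplex_table() -> pd.DataFrame:
    """Published miRNA:target duplex rows (11 sites, 5 miRNAs, 9 genes).

    ``typeset_ambiguous`` marks the two rows whose printed alignment strings
    lost whitespace in typesetting; their printed expectations are not
    reproducible column-by-column and they are excluded from exact
    regression.
    """
    return _load("table4_duplexes.tsv")


def rescore_duplex_row(row) -> DuplexAlignment:
    """Re-score one published duplex row with the reconstructed scheme."""
    mirna = SequenceRecord(row.mirna_id, row.mirna_3to5, "RNA")
    return score_duplex(mirna, row.target_5to3, target_id=row.target_id,
                        target_start=int(row.target_start),
                        mirna_is_3to5=True, upe=float(row.upe))


def patterns_file() -> str:
    """Path-like string of the packaged pattern definitions."""
    return str(resources.files("cngckit.data").joinpath("patterns.txt"))
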