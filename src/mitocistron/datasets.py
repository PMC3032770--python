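"""Packaged reference tables for the *Maruca vitrata* mitogenome study system.

Three small TSV files ship with the package: the gene annotation of the
14-kb partial mitogenome (13 PCGs, 2 rRNAs, 19 tRNAs), the codon-usage
table of its 14 protein-coding sequences, and the expression profile of the
10 EST-assembled cistron contigs.  They let every pipeline stage run and be
tested without downloads; the real genome sequence (GenBank HZ751150) is an
optional user-supplied input and is never fetched.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .model import Annotation, read_annotation_table

__all__ = [
    "fixture_path",
    "load_mitogenome_annotation",
    "load_codon_counts",
    "load_expression_profile",
]


def fixture_path(name: str) -> Path:
    """Filesystem path of a packaged data file."""
    return Path(resources.files("mitocistron.data") / name)


def load_mitogenome_annotation() -> Annotation:
    """The packaged 34-feature mitogenome annotation (published coordinates)."""
    return read_annotation_table(
        fixture_path("table2_features.tsv"), dialect="table2_tsv", genome_id="HZ751150"
    )


def load_codon_counts(corrected_uca: bool = False) -> pd.DataFrame:
    """Published codon usage of the 14 PCGs.

    Columns: codon (RNA alphabet), aa, count, rscu (both as published),
    corrected_count.  With ``corrected_uca=True`` the ``count`` column is
    replaced by ``corrected_count``, which repairs the single internally
    inconsistent row (UCA) from the published RSCU values.
    """
    df = pd.read_csv(fixture_path("table3_codon_usage.tsv"), sep="\t", comment="#")
    if corrected_uca:
        df = df.assign(count=df["corrected_count"])
    return df


def load_expression_profile() -> pd.DataFrame:
    """Published per-cistron expression profile (10 EST contigs, 7,608 reads).

    Columns: cistron_id, genes (comma-joined), length, total_nt, mean_depth,
    read_count, proportion_pct (share of the whole EST library, percent).
    """
    return pd.read_csv(fixture_path("table4_expression.tsv"), sep="\t", comment="#")
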