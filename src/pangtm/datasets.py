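"""Bundled reference tables."""

from __future__ import annotations

from importlib import resources

import pandas as pd


def load_genome_stats() -> pd.DataFrame:
    """Summary statistics of the 20 sequenced B. longum APC/DPC isolates.

    Columns: ``orfs`` (predicted ORFs), ``genome_size_bp``, ``gc_percent``
    and ``unique_genes`` (truly unique genes attributed to the strain),
    indexed by strain name.  Used as the worked example for
    :func:`pangtm.pangenome.genome_summary`.
    """
    with resources.files("pangtm.data").joinpath(
        "blongum_genome_stats.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t", index_col="genome")
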