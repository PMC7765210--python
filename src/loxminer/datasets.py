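"""Packaged reference datasets: the published summary tables for the
Spirodela polyrhiza LOX family.

These small TSVs carry the printed characterization of the nine-member
duckweed LOX family — gene coordinates and ORF/protein lengths, domain
intervals (PLAT, LOX, 5-histidine), the pairwise identities of the two
tandem clusters, and the endogenous jasmonate levels of aging Lemna minor
cultures — and serve as worked-example inputs for the pipeline's arithmetic.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .io_formats import GeneModel, read_domain_table, read_gene_table


def _data_path(name: str):
    return resources.files("loxminer").joinpath("data", name)


def load_splox_gene_table() -> pd.DataFrame:
    """Gene-level summary of the nine S. polyrhiza LOX genes, with parsed
    coordinates and the computed genomic length column."""
    with resources.as_file(_data_path("splox_gene_table.tsv")) as p:
        return read_gene_table(p)


def load_splox_domain_table() -> pd.DataFrame:
    """PLAT / LOX / 5HIS amino-acid intervals for the nine SpLOX proteins."""
    with resources.as_file(_data_path("splox_domain_table.tsv")) as p:
        return read_domain_table(p)


def load_splox_pair_identities() -> pd.DataFrame:
    """Printed pairwise nucleotide/protein identities of the tandem pairs."""
    with resources.as_file(_data_path("splox_pair_identities.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def load_lemna_ja_levels() -> pd.DataFrame:
    """Endogenous jasmonate levels (ng/g FW) in aging L. minor cultures."""
    with resources.as_file(_data_path("lemna_ja_levels.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def splox_gene_models() -> list[GeneModel]:
    """The nine SpLOX loci as single-interval gene models (coordinates
    only; exon structure is not part of the published summary)."""
    table = load_splox_gene_table()
    models = []
    for row in table.itertuples():
        scaffold = row.sequence_id.split("G")[0]
        models.append(GeneModel(
            gene_id=row.gene, scaffold=scaffold,
            start=row.start, end=row.end, strand=row.strand,
            exons=[(row.start, row.end)],
        ))
    return models


def percent_decrease(earlier: float, later: float) -> float:
    """Percent drop from an earlier to a later level, e.g. hormone decay
    across culture ages."""
    if earlier <= 0:
        raise ValueError("earlier level must be positive")
    return (earlier - later) / earlier * 100.0
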