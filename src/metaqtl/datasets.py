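"""Packaged reference datasets.

``load_reference_mqtls`` returns a published consensus-locus table for
maize plant height (PH) and ear height (EH): 29 MQTLs distilled by
meta-analysis from 187 literature QTLs across 13 mapping studies, with
their consensus-map positions and 95% CIs (cM), member-QTL counts,
flanking-marker intervals, physical intervals (Mb) and chromosome bins.
One row (MQTL5-1) prints a position outside its own CI in the published
table; the loader preserves the row as printed and does not enforce
position-in-CI for this dataset.
"""
from __future__ import annotations

from importlib import resources

import pandas as pd

from .meta_analysis import MQTL


def _data_path(name: str):
    return resources.files("metaqtl.data").joinpath(name)


def load_reference_mqtls() -> pd.DataFrame:
    """The 29-row maize PH/EH reference MQTL table as a DataFrame."""
    with resources.as_file(_data_path("maize_ph_eh_mqtl_reference.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def reference_mqtl_objects() -> list[MQTL]:
    """The reference table as :class:`~metaqtl.meta_analysis.MQTL` objects.

    Member QTL identities are not published, so ``member_qtl_ids`` is left
    empty and only ``n_members`` is filled.  Physical intervals are
    converted from Mb to bp.
    """
    df = load_reference_mqtls()
    out = []
    for row in df.itertuples(index=False):
        marker_interval = str(row.marker_interval).split("-")
        out.append(MQTL(
            mqtl_id=str(row.mqtl_id),
            chromosome=int(row.chromosome),
            position=float(row.position_cM),
            ci_lo=float(row.ci_lo_cM),
            ci_hi=float(row.ci_hi_cM),
            trait_class=str(row.trait_class),
            n_members=int(row.n_qtls),
            flank_left=marker_interval[0],
            flank_right=marker_interval[-1],
            physical_lo=int(round(float(row.phys_lo_Mb) * 1e6)),
            physical_hi=int(round(float(row.phys_hi_Mb) * 1e6)),
        ))
    return out


def load_keyword_map() -> dict[str, str]:
    """Default annotation-term -> functional-category table."""
    with resources.as_file(_data_path("gene_keywords.tsv")) as p:
        df = pd.read_csv(p, sep="\t")
    return dict(zip(df["term"], df["category"]))
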