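"""Bundled reference data for the E. coli YidC TM2-TM6 use case.

Two small curated tables ship with the package:

* the published top-50 covariation residue pairs of the YidC TM2-TM6
  region, with per-residue region labels, the curated exclusion reasons,
  and the Cβ-Cβ distances in the covariation-based model and in the
  BhYidC2 crystal form 3WO6;
* a helix/loop segmentation of the same region (seven predicted helices:
  TM2-TM6 plus the two cytoplasmic paddle helices).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .annotations import HelixAnnotation
from .constraints import RankedPair


def _data_path(name: str):
    return resources.files("helixcov.data").joinpath(name)


def load_yidc_pair_table() -> pd.DataFrame:
    """The curated top-50 covariation pair table for YidC TM2-TM6.

    Columns: rank, res_i/aa_i/region_i, res_j/aa_j/region_j (partner empty
    for indel rows), d_model and d_3wo6 (Å, Cβ-Cβ; NaN where excluded),
    status_printed (curated exclusion reason or ``retained``).
    """
    with resources.as_file(_data_path("yidc_top50_pairs.tsv")) as p:
        df = pd.read_csv(p, sep="\t")
    df["res_j"] = df["res_j"].astype("Int64")
    return df


def load_yidc_segments() -> HelixAnnotation:
    """Helix/loop segmentation of YidC TM2-TM6 (seven helices)."""
    with resources.as_file(_data_path("yidc_segments.toml")) as p:
        return HelixAnnotation.from_toml(p)


def yidc_ranked_pairs() -> tuple[list[RankedPair], dict]:
    """The curated pair table as ranked pairs plus the curated statuses.

    Returns the 50 pairs in printed rank order and a mapping
    ``(res_i, res_j) -> status`` suitable for the strict mode of
    :func:`helixcov.constraints.apply_exclusions`.
    """
    df = load_yidc_pair_table()
    pairs = []
    status = {}
    for row in df.itertuples():
        res_j = None if pd.isna(row.res_j) else int(row.res_j)
        p = RankedPair(res_i=int(row.res_i), res_j=res_j)
        pairs.append(p)
        status[p.key] = row.status_printed
    return pairs, status
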