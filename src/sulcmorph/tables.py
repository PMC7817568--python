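"""Published reference counts used as inputs and generator defaults.

Two contingency tables from a 50-participant (100-hemisphere) study of the
central/subcentral sulcal region ship with the package:

* ``MORPHOTYPE_COUNTS`` — observed frequencies of the five subcentral
  morphotypes per hemisphere.  Rows are hemispheres, columns morphotypes
  1–5.  These proportions are the default morphotype mixing probabilities
  of the synthetic cohort generator.
* ``PEAK_LABEL_COUNTS`` — counts of somatomotor activation peaks (n = 20
  functional participants) by the sulcal segment underlying the peak, per
  hemisphere and effector.  The hand localizer was only available for the
  left hemisphere.  The ventral-larynx column's split between ``cs_5`` and
  ``ascs_lat`` (14 of 40 peaks in ``ascs_lat``) sets the generator's
  default anchor-mixing ratio for that effector.
"""

from __future__ import annotations

import pandas as pd

MORPHOTYPES = [1, 2, 3, 4, 5]

MORPHOTYPE_COUNTS = pd.DataFrame(
    [[20, 17, 9, 3, 1], [24, 3, 9, 9, 5]],
    index=pd.Index(["left", "right"], name="hemisphere"),
    columns=pd.Index(MORPHOTYPES, name="morphotype"),
)

EFFECTORS = ["hand", "larynx_dorsal", "lip", "tongue", "larynx_ventral"]

_SEG_ROWS = ["cs_1", "cs_2", "cs_3", "cs_4", "cs_5", "ascs_lat"]

PEAK_LABEL_COUNTS = pd.DataFrame(
    {
        ("left", "hand"): [0, 16, 4, 0, 0, 0],
        ("left", "larynx_dorsal"): [0, 1, 19, 0, 0, 0],
        ("left", "lip"): [0, 1, 19, 0, 0, 0],
        ("left", "tongue"): [0, 0, 1, 17, 2, 0],
        ("left", "larynx_ventral"): [0, 0, 0, 2, 12, 6],
        ("right", "larynx_dorsal"): [0, 1, 18, 1, 0, 0],
        ("right", "lip"): [0, 0, 15, 5, 0, 0],
        ("right", "tongue"): [0, 0, 0, 19, 1, 0],
        ("right", "larynx_ventral"): [0, 0, 0, 0, 12, 8],
    },
    index=pd.Index(_SEG_ROWS, name="segment"),
)
PEAK_LABEL_COUNTS.columns = pd.MultiIndex.from_tuples(
    PEAK_LABEL_COUNTS.columns, names=["hemisphere", "effector"]
)


def default_type_probs() -> pd.DataFrame:
    """Per-hemisphere morphotype probabilities from the reference counts."""
    totals = MORPHOTYPE_COUNTS.sum(axis=1)
    return MORPHOTYPE_COUNTS.div(totals, axis=0)


def ventral_larynx_ascs_lat_fraction() -> float:
    """Fraction of ventral-larynx peaks anchored in ascs_lat (pooled hemispheres)."""
    col = PEAK_LABEL_COUNTS.xs("larynx_ventral", axis=1, level="effector")
    total = float(col.to_numpy().sum())
    ascs = float(col.loc["ascs_lat"].sum())
    return ascs / total


def ventral_larynx_ascs_lat_count() -> tuple[int, int]:
    """(peaks in ascs_lat, total ventral-larynx peaks) across hemispheres."""
    col = PEAK_LABEL_COUNTS.xs("larynx_ventral", axis=1, level="effector")
    return int(col.loc["ascs_lat"].sum()), int(col.to_numpy().sum())
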