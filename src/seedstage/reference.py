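"""Published worked-example data: Syrah grape-seed stage summary table.

Published per-stage means and standard deviations of the ten compression-test
texture parameters for Syrah grape seeds grouped into five color-based
maturity stages (MS1 least mature .. MS5 over-ripe).  They serve as a compact
worked example for the integration step: recomputing Si = Bd/Th, Ar = Be/De,
the stage-mean correlation matrix and the standardized PCA from this table
reproduces the printed report values.

Note the printed means are themselves rounded to two decimals, so statistics
recomputed from them can differ from the originals in the last decimal.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["stage_means", "stage_sds", "snk_letters"]

_STAGES = ["MS1", "MS2", "MS3", "MS4", "MS5"]

_MEANS = {
    "Np": [3.66, 3.92, 4.40, 4.58, 4.18],
    "Bf": [50.42, 54.24, 58.18, 59.82, 56.78],
    "Bdc": [20.04, 20.88, 20.21, 22.93, 18.82],
    "E": [98.11, 104.92, 105.68, 111.32, 103.70],
    "Be": [13.75, 14.74, 16.71, 16.66, 16.60],
    "De": [36.01, 72.93, 77.82, 80.74, 78.30],
    "Th": [2.19, 3.17, 3.22, 3.24, 3.27],
    "Bd": [0.53, 0.54, 0.57, 0.55, 0.57],
    "Si": [0.24, 0.17, 0.18, 0.17, 0.18],
    "Ar": [0.39, 0.20, 0.22, 0.21, 0.21],
}

_SDS = {
    "Np": [1.39, 1.26, 1.48, 1.65, 1.29],
    "Bf": [11.30, 9.14, 9.67, 12.49, 14.29],
    "Bdc": [8.10, 7.18, 6.65, 9.23, 8.66],
    "E": [16.90, 15.04, 13.20, 18.59, 17.84],
    "Be": [5.30, 4.16, 5.17, 5.20, 6.56],
    "De": [9.08, 11.76, 14.14, 15.26, 17.29],
    "Th": [0.26, 0.27, 0.26, 0.34, 0.33],
    "Bd": [0.11, 0.08, 0.09, 0.08, 0.12],
    "Si": [0.05, 0.03, 0.03, 0.03, 0.04],
    "Ar": [0.13, 0.05, 0.06, 0.07, 0.08],
}

_SNK = {
    "Np": ["a", "ab", "ab", "b", "ab"],
    "Bf": ["a", "ab", "b", "b", "b"],
    "Bdc": ["a", "a", "a", "a", "a"],
    "E": ["a", "ab", "ab", "b", "ab"],
    "Be": ["a", "ab", "b", "ab", "ab"],
    "De": ["a", "b", "bc", "c", "bc"],
    "Th": ["a", "b", "b", "b", "b"],
    "Bd": ["a", "a", "a", "a", "a"],
    "Si": ["a", "b", "b", "b", "b"],
    "Ar": ["a", "b", "b", "b", "b"],
}


def stage_means() -> pd.DataFrame:
    """Stage x parameter matrix of published means (stages as rows)."""
    return pd.DataFrame(_MEANS, index=pd.Index(_STAGES, name="stage"))


def stage_sds() -> pd.DataFrame:
    """Stage x parameter matrix of published standard deviations."""
    return pd.DataFrame(_SDS, index=pd.Index(_STAGES, name="stage"))


def snk_letters() -> pd.DataFrame:
    """Published Student-Newman-Keuls letter groupings per parameter."""
    return pd.DataFrame(_SNK, index=pd.Index(_STAGES, name="stage"))
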