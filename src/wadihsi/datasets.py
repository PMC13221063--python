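"""Bundled reference tables from the twelve-wadi Hajar Mountain killifish
survey (Oman): per-site suitability and diversity metrics, the published
classification-performance confusion counts, and the national conservation
gap figures. These small printed tables are the package's built-in worked
example and regression anchor.
"""

from __future__ import annotations

from io import StringIO

import pandas as pd

from .validation import ConfusionCounts

__all__ = [
    "hajar_site_metrics",
    "hajar_confusion_counts",
    "hajar_protection_rates",
    "hajar_protected_stream_counts",
    "HAJAR_THRESHOLDS",
]

#: published five-class HSI thresholds of the survey (preset "hajar")
HAJAR_THRESHOLDS = (0.47, 0.51, 0.59, 0.75)

_SITE_METRICS_CSV = """\
site_id,shannon,simpson,evenness,hsi,published_class
A1,1.213,0.665,0.875,0.584,Moderately Suitable
A2,0.871,0.441,0.629,0.490,Less Suitable
A3,0.034,0.010,0.031,0.945,Highly Suitable
AW1,1.184,0.660,0.854,0.587,Suitable
AW2,0.837,0.485,0.604,0.526,Moderately Suitable
AW3,0.942,0.501,0.680,0.443,Unsuitable
D1,0.133,0.050,0.121,0.781,Highly Suitable
D2,0.185,0.076,0.134,0.581,Moderately Suitable
D3,0.678,0.381,0.617,0.496,Less Suitable
K1,0.234,0.095,0.169,0.635,Suitable
K2,0.533,0.268,0.384,0.724,Highly Suitable
K3,0.435,0.203,0.314,0.433,Unsuitable
"""


def hajar_site_metrics() -> pd.DataFrame:
    """Twelve-site survey table: HSI, Shannon, Gini–Simpson, Pielou
    evenness and the class label as published.

    Note the published labels are internally inconsistent with the
    published thresholds for sites K2 (0.724 labelled Highly Suitable,
    i.e. >= 0.75) and AW1 (0.587 labelled Suitable, i.e. >= 0.59); both
    the labels and the thresholds are kept verbatim so either reading can
    be reproduced.
    """
    return pd.read_csv(StringIO(_SITE_METRICS_CSV), index_col="site_id")


def hajar_confusion_counts() -> ConfusionCounts:
    """Published site-classification outcome: 4 true positives, 6 true
    negatives, 2 false negatives, no false positives over the 12 sites."""
    return ConfusionCounts(tp=4, fp=0, tn=6, fn=2)


def hajar_protection_rates() -> dict[str, float]:
    """Current protection rate (%) of top-decile habitat per species."""
    return {"A_kruppi": 0.31, "A_stoliczkanus": 1.34}


def hajar_protected_stream_counts() -> dict[str, int]:
    """Streams inside the protected-area network by density class."""
    return {"high": 58, "medium": 427, "low": 1731}
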