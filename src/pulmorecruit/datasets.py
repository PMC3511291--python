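"""Bundled reference tables of per-subject fitted model parameters.

An experimental porcine PEEP-titration study (nine healthy anaesthetised
piglets, three of which — subjects 5, 6 and 9 — later developed
oleic-acid-induced ARDS) provides per-subject fitted mean TOP/TCP values
at each PEEP level and the TOP/TCP distribution SDs in both states.
These printed per-subject values are bundled here as inputs for the
summary-statistics stage; raw waveform recordings are not available.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "reference_mean_table",
    "reference_sd_table",
    "PEEP_LEVELS",
]

PEEP_LEVELS = (5.0, 10.0, 15.0, 20.0)

# Healthy state: mean TOP (inflation) per subject at PEEP 5/10/15/20 cmH2O.
_HEALTHY_TOP = {
    1: (42.4, 39.2, 32.9, 27.2),
    2: (36.3, 40.0, 33.8, 29.3),
    3: (44.6, 37.4, 32.2, 25.1),
    4: (39.0, 33.9, 29.0, 19.2),
    5: (42.6, 32.7, 24.8, 19.2),
    6: (31.3, 28.1, 23.8, 21.5),
    7: (47.7, 40.8, 34.1, 27.0),
    8: (46.0, 40.2, 33.4, 27.9),
    9: (38.2, 33.9, 29.4, 22.8),
}

# Healthy state: mean TCP (deflation) per subject.
_HEALTHY_TCP = {
    1: (9.6, 13.4, 16.6, 19.8),
    2: (8.2, 13.5, 16.8, 20.4),
    3: (10.2, 13.2, 16.4, 19.7),
    4: (10.4, 13.7, 16.6, 19.0),
    5: (10.2, 13.2, 15.7, 18.4),
    6: (9.03, 12.5, 15.5, 18.8),
    7: (11.1, 14.6, 17.2, 19.6),
    8: (10.6, 13.4, 16.6, 19.5),
    9: (8.7, 12.3, 15.8, 19.3),
}

# ARDS state (subjects 5, 6, 9 only).
_ARDS_TOP = {
    5: (48.1, 44.1, 33.3, 22.7),
    6: (49.5, 41.6, 31.1, 19.1),
    9: (68.1, 64.7, 58.7, 49.4),
}

_ARDS_TCP = {
    5: (10.2, 14.0, 16.7, 19.0),
    6: (10.2, 13.7, 16.7, 18.9),
    9: (9.6, 14.1, 18.2, 21.8),
}

# TOP/TCP distribution SDs for the subjects that developed ARDS, cmH2O.
# (subject -> (healthy inflation, healthy deflation, ARDS inflation,
#              ARDS deflation))
_SD_TABLE = {
    5: (23.0, 4.0, 25.0, 4.0),
    6: (14.0, 3.0, 25.0, 4.0),
    9: (21.0, 3.0, 23.0, 3.0),
}


def reference_mean_table() -> pd.DataFrame:
    """Per-subject fitted mean TOP/TCP values in tidy form.

    Columns: ``subject``, ``state`` (healthy/ards), ``limb``
    (inflation/deflation), ``peep_cmH2O``, ``mean_cmH2O``.
    """
    rows = []
    for state, limb, table in (
        ("healthy", "inflation", _HEALTHY_TOP),
        ("healthy", "deflation", _HEALTHY_TCP),
        ("ards", "inflation", _ARDS_TOP),
        ("ards", "deflation", _ARDS_TCP),
    ):
        for subject, values in table.items():
            for peep, value in zip(PEEP_LEVELS, values):
                rows.append(
                    {
                        "subject": subject,
                        "state": state,
                        "limb": limb,
                        "peep_cmH2O": peep,
                        "mean_cmH2O": value,
                    }
                )
    return pd.DataFrame(rows)


def reference_sd_table() -> pd.DataFrame:
    """Distribution SDs for the subjects that developed ARDS, tidy form.

    Columns: ``subject``, ``state``, ``limb``, ``sd_cmH2O``.
    """
    rows = []
    for subject, (hi, hd, ai, ad) in _SD_TABLE.items():
        for state, limb, value in (
            ("healthy", "inflation", hi),
            ("healthy", "deflation", hd),
            ("ards", "inflation", ai),
            ("ards", "deflation", ad),
        ):
            rows.append(
                {"subject": subject, "state": state, "limb": limb, "sd_cmH2O": value}
            )
    return pd.DataFrame(rows)
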