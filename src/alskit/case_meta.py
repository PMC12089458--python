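"""Descriptive aggregation of published ALS-FUS case reports.

Case reports are pooled into one table (one row per unique patient; studies
reporting the same case are expected to be merged upstream, a helper flags
candidate duplicates).  Disease duration runs from onset to the endpoint,
defined as respiratory failure, the time of tracheostomy, or else death —
whichever is reported.  Summaries are per-mutation n, mean and sample
standard deviation (n − 1 denominator) of onset age (years) and disease
duration (months); missing values are dropped per variable, and cases still
alive without a reached endpoint are excluded from the duration summary and
counted separately.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["summarize_cases", "flag_candidate_duplicates", "ENDPOINT_TYPES"]

ENDPOINT_TYPES = ("respiratory_failure", "tracheostomy", "death")


def summarize_cases(
    cases: pd.DataFrame,
    grouping: str = "mutation",
    onset_col: str = "onset_age_y",
    duration_col: str = "duration_mo",
    censored_col: str | None = "censored",
) -> pd.DataFrame:
    """Per-group descriptive summaries of onset and duration.

    Returns one row per group with ``n_onset``, ``onset_mean_y``,
    ``onset_sd_y``, ``n_duration``, ``duration_mean_mo``, ``duration_sd_mo``
    and ``n_censored``.  The sd is undefined (NaN) at n = 1; a group with no
    non-missing values gets NaN mean and n = 0.
    """
    if grouping not in cases.columns:
        raise ValueError(f"grouping column {grouping!r} missing")
    df = cases.copy()
    if censored_col and censored_col in df.columns:
        censored = df[censored_col].fillna(False).astype(bool)
    else:
        censored = pd.Series(False, index=df.index)
    rows = []
    for group, grp in df.groupby(grouping, sort=True, dropna=False):
        onset = pd.to_numeric(grp.get(onset_col), errors="coerce").dropna()
        cens = censored.loc[grp.index]
        duration = pd.to_numeric(grp.loc[~cens, duration_col], errors="coerce").dropna()
        rows.append(
            {
                grouping: group,
                "n_onset": len(onset),
                "onset_mean_y": onset.mean() if len(onset) else np.nan,
                "onset_sd_y": onset.std(ddof=1) if len(onset) > 1 else np.nan,
                "n_duration": len(duration),
                "duration_mean_mo": duration.mean() if len(duration) else np.nan,
                "duration_sd_mo": duration.std(ddof=1) if len(duration) > 1 else np.nan,
                "n_censored": int(cens.sum()),
            }
        )
    return pd.DataFrame(rows)


def flag_candidate_duplicates(
    cases: pd.DataFrame,
    keys: Sequence[str] = ("mutation", "onset_age_y", "sex", "country"),
) -> pd.Series:
    """Flag rows that share all available key fields with an earlier row.

    Candidate duplicates are reported, never auto-merged: the same
    (mutation, onset, sex, country) combination can legitimately describe
    two patients, so merging needs the source publications.
    """
    present = [k for k in keys if k in cases.columns]
    if not present:
        return pd.Series(False, index=cases.index)
    return cases.duplicated(subset=present, keep="first") & cases[present].notna().all(axis=1)
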