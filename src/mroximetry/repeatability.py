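"""Test-retest repeatability: within-subject SD and coefficient of variation.

For paired session estimates (x1_i, x2_i) over n subjects, the Bland-Altman
within-subject standard deviation is

    sigma_inter = sqrt( sum_i (x1_i - x2_i)^2 / (2 n) )

and the inter-session within-subject coefficient of variation divides this
by the mean value across participants (the grand mean of all 2n
measurements; per-subject means average to the same number).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SessionPair", "RepeatabilityStats", "within_subject_sd", "cov",
           "repeatability_table"]


@dataclass(frozen=True)
class SessionPair:
    """Paired per-subject estimates of one (territory, parameter)."""

    x1: np.ndarray
    x2: np.ndarray

    def __post_init__(self) -> None:
        x1 = np.asarray(self.x1, dtype=float)
        x2 = np.asarray(self.x2, dtype=float)
        if x1.ndim != 1 or x1.shape != x2.shape:
            raise ValueError("sessions must be paired 1-D arrays of equal length")
        if x1.size < 2:
            raise ValueError("need at least 2 subjects")
        object.__setattr__(self, "x1", x1)
        object.__setattr__(self, "x2", x2)

    @property
    def n(self) -> int:
        return self.x1.size


@dataclass(frozen=True)
class RepeatabilityStats:
    sigma_inter: float  # parameter units
    mean: float  # parameter units
    cov_percent: float  # 100 * sigma_inter / mean


def within_subject_sd(pair: SessionPair) -> float:
    """Bland-Altman within-subject SD, sqrt(sum d_i^2 / 2n)."""
    d = pair.x1 - pair.x2
    return float(np.sqrt(np.sum(d ** 2) / (2.0 * pair.n)))


def cov(pair: SessionPair) -> float:
    """Inter-session within-subject CoV, percent of the grand mean."""
    grand_mean = float(np.mean(np.concatenate([pair.x1, pair.x2])))
    if grand_mean == 0.0:
        raise ValueError("grand mean is zero; CoV undefined")
    return 100.0 * within_subject_sd(pair) / grand_mean


def stats(pair: SessionPair) -> RepeatabilityStats:
    grand_mean = float(np.mean(np.concatenate([pair.x1, pair.x2])))
    return RepeatabilityStats(sigma_inter=within_subject_sd(pair),
                              mean=grand_mean, cov_percent=cov(pair))


def repeatability_table(table: pd.DataFrame,
                        parameters: tuple[str, ...] = ("OEF", "CBF", "ATT", "CMRO2"),
                        subject_col: str = "subject",
                        session_col: str = "session",
                        territory_col: str = "territory") -> pd.DataFrame:
    """Territory x parameter repeatability summary from a long regional table.

    Expects one row per (subject, session, territory) with the parameter
    columns; exactly two sessions per subject are paired by sorting on the
    session column. Returns rows of (parameter, territory, mean, s_error,
    sigma_inter, cov_percent); subjects missing either session are dropped
    pairwise per cell.
    """
    rows = []
    for parameter in parameters:
        for territory, sub in table.groupby(territory_col, sort=False):
            wide = sub.pivot_table(index=subject_col, columns=session_col,
                                   values=parameter, aggfunc="first")
            wide = wide.dropna()
            if wide.shape[1] != 2 or wide.shape[0] < 2:
                continue
            sessions = sorted(wide.columns)
            pair = SessionPair(wide[sessions[0]].to_numpy(),
                               wide[sessions[1]].to_numpy())
            st = stats(pair)
            subject_means = wide.mean(axis=1)
            rows.append({
                "parameter": parameter,
                "territory": territory,
                "n": pair.n,
                "mean": st.mean,
                "s_error": float(subject_means.std(ddof=1) / np.sqrt(pair.n)),
                "sigma_inter": st.sigma_inter,
                "cov_percent": st.cov_percent,
            })
    return pd.DataFrame(rows)
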