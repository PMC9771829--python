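"""Mass-univariate connection-wise group comparison and sign-asymmetry test.

Each connection is compared between groups with a two-tailed Mann-Whitney
U-test, corrected for multiplicity within frequency by Benjamini-Hochberg.
Because individual connections rarely survive correction, a second test asks
whether the *signs* of the nominally significant differences are asymmetric:
the proportion of positive signs is rescaled to a conservative number of
effectively independent trials (default df = 40, the rank of a typical MEG
forward model) and tested against 0.5 with an exact two-tailed binomial
test; binomial p-values are FDR-corrected across frequencies within each
coupling mode.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ConnectionTestResult",
    "connectionwise_tests",
    "sign_asymmetry_test",
]


@dataclass
class ConnectionTestResult:
    """Per-connection Mann-Whitney results for one (mode, frequency)."""

    mode: str
    frequency: float
    u: np.ndarray
    p: np.ndarray
    q: np.ndarray
    sign: np.ndarray  # +1 patients greater, -1 controls greater, 0 tied
    alpha: float = 0.05

    @property
    def n_positive_significant(self) -> int:
        return int(np.sum((self.p < self.alpha) & (self.sign > 0)))

    @property
    def n_negative_significant(self) -> int:
        return int(np.sum((self.p < self.alpha) & (self.sign < 0)))


def connectionwise_tests(
    patient_profiles: np.ndarray,
    control_profiles: np.ndarray,
    mode: str = "amplitude",
    frequency: float = 0.0,
    alpha: float = 0.05,
) -> ConnectionTestResult:
    """Two-tailed Mann-Whitney U per connection with BH correction.

    Uses exact null enumeration for group sizes <= 8 (no ties) and the
    tie-corrected normal approximation otherwise.  All-tied connections get
    p = 1 and sign 0.
    """
    pat = np.asarray(patient_profiles, dtype=np.float64)
    con = np.asarray(control_profiles, dtype=np.float64)
    if pat.ndim != 2 or con.ndim != 2 or pat.shape[1] != con.shape[1]:
        raise ValueError("profiles must be 2-D with equal connection counts")
    if pat.shape[0] < 2 or con.shape[0] < 2:
        raise ValueError("both groups need >= 2 subjects")
    method = "exact" if max(pat.shape[0], con.shape[0]) <= 8 else "asymptotic"
    res = stats.mannwhitneyu(
        pat, con, axis=0, alternative="two-sided", method=method
    )
    u = np.asarray(res.statistic, dtype=np.float64)
    p = np.minimum(np.asarray(res.pvalue, dtype=np.float64), 1.0)
    combined = np.vstack([pat, con])
    all_tied = np.ptp(combined, axis=0) == 0
    p[all_tied] = 1.0
    sign = np.sign(np.median(pat, axis=0) - np.median(con, axis=0)).astype(int)
    sign[all_tied] = 0
    q = multipletests(p, method="fdr_bh")[1]
    return ConnectionTestResult(
        mode=mode, frequency=frequency, u=u, p=p, q=q, sign=sign, alpha=alpha
    )


def sign_asymmetry_test(
    results: list[ConnectionTestResult],
    alpha: float = 0.05,
    df: int = 40,
) -> pd.DataFrame:
    """Binomial test of sign asymmetry among significant connections.

    For each (mode, frequency) result, the proportion of positive signs
    among connections with uncorrected p < ``alpha`` is rescaled to
    ``k = round(proportion * df)`` successes in ``df`` trials and tested
    two-tailed (minimum-likelihood convention) against 0.5.  FDR correction
    runs across frequencies separately within each mode.

    Returns a tidy frame with one row per (mode, frequency).
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    rows = []
    for res in results:
        sig = (res.p < alpha) & (res.sign != 0)
        n_sig = int(sig.sum())
        if n_sig == 0:
            rows.append((res.mode, res.frequency, 0, np.nan, np.nan, 1.0))
            continue
        n_pos = int(np.sum(res.sign[sig] > 0))
        prop = n_pos / n_sig
        k = int(round(prop * df))
        p_binom = stats.binomtest(k, df, 0.5, alternative="two-sided").pvalue
        rows.append((res.mode, res.frequency, n_sig, prop, float(k), p_binom))
    out = pd.DataFrame(
        rows,
        columns=["mode", "frequency", "n_significant", "proportion_positive",
                 "k_rescaled", "p"],
    )
    out["df"] = df
    out["q"] = np.nan
    for mode in out["mode"].unique():
        mask = out["mode"] == mode
        out.loc[mask, "q"] = multipletests(out.loc[mask, "p"], method="fdr_bh")[1]
    return out
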