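"""Outlier calling from locus-specific effects, and FDR/FNR scoring.

A normal law is fitted a posteriori (by maximum likelihood, no trimming) to
the per-locus posterior medians of the elevation effect theta; each locus
gets a two-tailed probability of departing from that genome-wide null.
Upper-tail outliers are more differentiated than the neutral background
(candidates for divergent selection), lower-tail outliers less (homogenizing
selection or rare variants). Fixed probability thresholds of 1% and 5% are
used — no further multiple-testing correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .popdata import ValidationError


class DegenerateFitError(ValueError):
    """All theta medians identical: the normal null has zero spread."""


@dataclass
class OutlierCalls:
    """Per-locus outlier table plus the fitted null.

    ``table`` is sorted by decreasing theta median and carries, per locus:
    theta_median, p_value (two-tailed), tail in {above, below, none} at the
    call-level alpha, and significance flags at both 1% and 5%.
    """

    table: pd.DataFrame
    null_mean: float
    null_sd: float
    alpha: float

    @property
    def flagged(self) -> list:
        return list(self.table.loc[self.table["p_value"] < self.alpha, "locus"])

    def flagged_at(self, alpha: float) -> list:
        return list(self.table.loc[self.table["p_value"] < alpha, "locus"])

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def call_outliers(theta_medians, alpha: float = 0.01) -> OutlierCalls:
    """Fit the normal null to theta medians and flag tail loci.

    ``theta_medians`` is a Series (index = loci) or array of per-locus
    posterior medians. ``alpha`` is the probability threshold that defines
    the flagged set (the study retains 1%; 5% is also tabulated).
    """
    s = pd.Series(theta_medians)
    if len(s) < 3:
        raise ValidationError("outlier calling needs at least 3 loci")
    if alpha not in (0.01, 0.05):
        raise ValidationError("alpha must be 0.01 or 0.05")
    vals = s.to_numpy(float)
    mean = float(vals.mean())
    sd = float(vals.std(ddof=0))  # maximum-likelihood fit
    if sd <= 1e-9 * max(1.0, float(np.abs(vals).max())):
        raise DegenerateFitError("all theta medians are identical; normal fit is degenerate")
    z = (vals - mean) / sd
    p = 2 * stats.norm.sf(np.abs(z))
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    tail = np.where(p < alpha, np.where(vals > mean, "above", "below"), "none")
    df = pd.DataFrame(
        {
            "locus": s.index,
            "theta_median": vals,
            "p_value": p,
            "tail": tail,
            "sig_1pct": p < 0.01,
            "sig_5pct": p < 0.05,
        }
    ).sort_values("theta_median", ascending=False, kind="mergesort").reset_index(drop=True)
    return OutlierCalls(df, mean, sd, alpha)


@dataclass
class PowerMetrics:
    """Detection scores against simulation truth.

    FDR = V/R (false positives over rejections; None when R = 0) and
    FNR = T/(m - R) (false negatives over accepted nulls), as fractions.
    """

    V: int
    R: int
    T: int
    m: int
    fdr: float | None
    fnr: float


def score_calls(calls: OutlierCalls, truth) -> PowerMetrics:
    """Score flagged loci (at the calls' own alpha) against the truth set."""
    truth = set(truth)
    loci = set(calls.table["locus"])
    unknown = truth - loci
    if unknown:
        raise ValidationError(f"truth loci absent from the calls: {sorted(unknown)[:5]}")
    flagged = set(calls.flagged)
    V = len(flagged - truth)
    R = len(flagged)
    T = len(truth - flagged)
    m = len(loci)
    fdr = None if R == 0 else V / R
    fnr = T / (m - R)
    return PowerMetrics(V=V, R=R, T=T, m=m, fdr=fdr, fnr=fnr)
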