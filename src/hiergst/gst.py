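"""Step 1: Bayesian allele-frequency inference and pairwise Nei GST.

Allele frequencies are inferred per population and locus from allelic counts
(n, N) under a Binomial likelihood with a Beta(1, 1) prior. The prior is
conjugate, so the posterior is exactly Beta(n + 1, N - n + 1) and is sampled
i.i.d. rather than by MCMC — the same distribution, with no autocorrelation
and full seed control.

Frequency uncertainty is propagated into the pairwise fixation index by
computing, per posterior draw,

    H_T = (p_i + p_j)(q_i + q_j) / 2        (total heterozygosity)
    H_S = p_i q_i + p_j q_j                  (mean within-population het.)
    GST = (H_T - H_S) / H_T

and summarising each locus x population-pair cell by its posterior median.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .popdata import AlleleCounts, GenotypeDataset, ValidationError


@dataclass
class FreqPosterior:
    """Posterior draws of an allele frequency given allelic counts."""

    samples: np.ndarray
    counts: AlleleCounts


def freq_posterior(counts: AlleleCounts, n_samples: int, seed=None) -> FreqPosterior:
    """Draw from the exact Beta(n+1, N-n+1) posterior.

    With n = N = 0 this is the uniform prior.
    """
    if n_samples < 1:
        raise ValidationError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    draws = rng.beta(counts.n + 1, counts.N - counts.n + 1, size=n_samples)
    return FreqPosterior(draws, counts)


def nei_gst(p_i, p_j):
    """Pairwise Nei GST for two allele frequencies (vectorised).

    Raises on H_T = 0 (both populations fixed for the same allele), which
    cannot occur for posterior draws in the open interval (0, 1).
    """
    p_i = np.asarray(p_i, dtype=float)
    p_j = np.asarray(p_j, dtype=float)
    q_i, q_j = 1.0 - p_i, 1.0 - p_j
    h_t = 0.5 * (p_i + p_j) * (q_i + q_j)
    if np.any(h_t == 0):
        raise ValidationError("GST undefined: both populations fixed for the same allele (H_T = 0)")
    h_s = p_i * q_i + p_j * q_j
    return (h_t - h_s) / h_t


class GstMatrix:
    """Per-locus, per-population-pair posterior-median GST.

    Stored in long form (locus, pop_i, pop_j, gst_median, n_draws); the
    pair index is the ordered list of unordered population pairs.
    """

    COLUMNS = ["locus", "pop_i", "pop_j", "gst_median", "n_draws"]

    def __init__(self, table: pd.DataFrame):
        missing = set(self.COLUMNS) - set(table.columns)
        if missing:
            raise ValidationError(f"GstMatrix table missing columns {sorted(missing)}")
        self.table = table[self.COLUMNS].reset_index(drop=True)

    @property
    def loci(self) -> list[str]:
        return list(dict.fromkeys(self.table["locus"]))

    @property
    def pairs(self) -> list[tuple[str, str]]:
        sub = self.table[["pop_i", "pop_j"]].drop_duplicates()
        return list(sub.itertuples(index=False, name=None))

    def value(self, locus, pop_i, pop_j) -> float:
        t = self.table
        m = (t["locus"] == locus) & (
            ((t["pop_i"] == pop_i) & (t["pop_j"] == pop_j))
            | ((t["pop_i"] == pop_j) & (t["pop_j"] == pop_i))
        )
        hit = t[m]
        if hit.empty:
            raise KeyError(f"no GST entry for locus {locus!r}, pair ({pop_i!r}, {pop_j!r})")
        return float(hit["gst_median"].iloc[0])

    def wide(self) -> pd.DataFrame:
        """Loci x pairs matrix of medians; columns are (pop_i, pop_j) tuples."""
        t = self.table.copy()
        t["pair"] = list(zip(t["pop_i"], t["pop_j"]))
        w = t.pivot(index="locus", columns="pair", values="gst_median")
        return w.loc[self.loci, self.pairs]

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path) -> "GstMatrix":
        return cls(pd.read_csv(path, sep="\t"))


def gst_median_matrix(
    ds: GenotypeDataset,
    n_samples: int = 2000,
    seed=None,
    populations=None,
) -> GstMatrix:
    """Posterior-median pairwise GST for every locus and population pair.

    For each population the allele-frequency posterior is sampled once
    (``n_samples`` draws per locus); GST is computed draw-by-draw for each
    pair from the two populations' independent posteriors, and the per-cell
    median is retained.
    """
    pops, n, N = ds.counts_matrix(populations)
    if len(pops) < 2:
        raise ValidationError("pairwise GST needs at least two populations")
    rng = np.random.default_rng(seed)
    L = ds.n_loci
    # (pop, locus, draw) posterior frequency samples
    p = rng.beta(n[:, :, None] + 1, (N - n)[:, :, None] + 1, size=(len(pops), L, n_samples))
    rows = []
    for a, b in combinations(range(len(pops)), 2):
        g = nei_gst(p[a], p[b])
        med = np.median(g, axis=1)
        rows.append(
            pd.DataFrame(
                {
                    "locus": ds.loci,
                    "pop_i": pops[a],
                    "pop_j": pops[b],
                    "gst_median": med,
                    "n_draws": n_samples,
                }
            )
        )
    return GstMatrix(pd.concat(rows, ignore_index=True))
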