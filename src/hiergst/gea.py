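"""Within-site genotype-environment association (GEA) test.

For one study site (a low- and a high-elevation population), the test asks,
genotype by genotype, whether the observed genotypic frequency at an
elevation departs from what resampling a single unstructured population
would produce. The null accounts for departures from Hardy-Weinberg via the
site's own empirical F_IS distribution:

1. F_IS is computed per locus over the pooled site (elevations confounded).
2. n1 F_IS values are drawn from that empirical pool; for each, a population
   of N_pop diploids is simulated with genotype probabilities
   P(hom1) = p^2 + pq F_IS, P(het) = 2pq(1 - F_IS), P(hom2) = q^2 + pq F_IS
   at the locus's pooled allele frequency p.
3. From each simulated population, n2 disjoint subpopulation pairs of N_sub
   diploids are drawn without replacement; the n1 x n2 genotype frequencies
   form the empirical null (10000 iterations at the defaults).
4. Each observed frequency gets p = min(F(obs), 1 - F(obs)) under the null
   CDF, with a sign: '+' if the genotype is more abundant than the null
   median, '-' if less, 'ns' if not significant at alpha.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .popdata import GenotypeDataset, MISSING, ValidationError, fis_per_locus


@dataclass
class GeaConfig:
    """Null-simulation settings (defaults: n1 = n2 = 100 for 10000
    iterations, populations of 1000 diploids split into halves of 500)."""

    n1: int = 100
    n2: int = 100
    N_pop: int = 1000
    N_sub: int = 500
    alpha: float = 0.05
    seed: int | None = None

    def __post_init__(self) -> None:
        if 2 * self.N_sub > self.N_pop:
            raise ValidationError("two disjoint subpopulations need 2*N_sub <= N_pop")
        if min(self.n1, self.n2, self.N_pop, self.N_sub) < 1:
            raise ValidationError("all GEA sizes must be positive")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")


GENOTYPES = ("hom1", "het", "hom2")  # hom1 = reference homozygote


def fis_corrected_genotype_probs(p: float, fis: float):
    """Hardy-Weinberg genotype probabilities corrected by F_IS.

    Negative components (possible when F_IS < 0 pushes a homozygote class
    below zero) are clipped and the triple renormalised to sum to 1.
    """
    if not 0 <= p <= 1:
        raise ValidationError("allele frequency must be in [0, 1]")
    if fis > 1:
        raise ValidationError("F_IS cannot exceed 1")
    q = 1.0 - p
    probs = np.array([p * p + p * q * fis, 2 * p * q * (1 - fis), q * q + p * q * fis])
    probs = np.clip(probs, 0.0, None)
    total = probs.sum()
    if total == 0:  # unreachable for valid inputs; guard division
        return np.array([0.0, 0.0, 1.0])
    return probs / total


def null_genotype_distribution(p: float, fis_pool, cfg: GeaConfig,
                               rng=None) -> np.ndarray:
    """Empirical null of genotype frequencies in a subpopulation.

    Returns an array of shape (n1 * n2, 3): for each iteration, the
    frequency of (hom1, het, hom2) in one subpopulation of N_sub diploids
    drawn without replacement from a simulated population of N_pop.
    """
    fis_pool = np.asarray(fis_pool, dtype=float)
    if fis_pool.size == 0:
        raise ValidationError("empty F_IS pool")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    out = np.empty((cfg.n1 * cfg.n2, 3))
    k = 0
    for _ in range(cfg.n1):
        fis = float(rng.choice(fis_pool))
        probs = fis_corrected_genotype_probs(p, fis)
        counts = rng.multinomial(cfg.N_pop, probs)
        for _ in range(cfg.n2):
            sub = rng.multivariate_hypergeometric(counts, cfg.N_sub)
            out[k] = sub / cfg.N_sub
            k += 1
    return out


def _observed_freqs(ds: GenotypeDataset, population: str) -> pd.DataFrame:
    iix = [i for i, ind in enumerate(ds.individuals) if ds.population_of[ind] == population]
    block = ds.codes[iix, :]
    obs = block != MISSING
    n_obs = obs.sum(axis=0)
    rows = {}
    for g, code in zip(GENOTYPES, (0, 1, 2)):
        with np.errstate(invalid="ignore"):
            rows[g] = np.where(n_obs > 0, (block == code).sum(axis=0) / n_obs, np.nan)
    return pd.DataFrame(rows, index=ds.loci)


@dataclass
class GeaResult:
    """Per locus x genotype x elevation association table."""

    table: pd.DataFrame
    config: GeaConfig

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["sign"] != "ns"]

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def gea_test(site_ds: GenotypeDataset, cfg: GeaConfig | None = None) -> GeaResult:
    """Run the GEA test on one site (exactly two populations).

    Monomorphic loci must be removed beforehand (loci with zero pooled
    heterozygosity are skipped with a warning entry-free table).
    """
    cfg = cfg or GeaConfig()
    pops = site_ds.populations
    if len(pops) != 2:
        raise ValidationError(f"GEA needs exactly two populations (low/high), got {len(pops)}")
    rng = np.random.default_rng(cfg.seed)
    fis = fis_per_locus(site_ds)
    if fis.empty:
        raise ValidationError("no polymorphic loci in the site")
    fis_pool = fis["fis"].to_numpy()
    _, n, N = site_ds.counts_matrix()
    n_tot, N_tot = n.sum(axis=0), N.sum(axis=0)
    obs_by_pop = {p: _observed_freqs(site_ds, p) for p in pops}
    polymorphic = set(fis["locus"])
    rows = []
    for j, locus in enumerate(site_ds.loci):
        if locus not in polymorphic:
            continue
        p_pool = n_tot[j] / N_tot[j]
        null = null_genotype_distribution(p_pool, fis_pool, cfg, rng=rng)
        null_sorted = np.sort(null, axis=0)
        n_null = null.shape[0]
        medians = np.median(null, axis=0)
        for pop in pops:
            for g_idx, g in enumerate(GENOTYPES):
                obs = obs_by_pop[pop].loc[locus, g]
                if np.isnan(obs):
                    continue
                # empirical CDF at the observation
                below = np.searchsorted(null_sorted[:, g_idx], obs, side="right")
                f_hat = below / n_null
                pval = min(f_hat, 1.0 - f_hat)
                pval = max(pval, 1.0 / n_null)
                if pval < cfg.alpha:
                    sign = "+" if obs > medians[g_idx] else "-"
                else:
                    sign = "ns"
                rows.append(
                    {
                        "locus": locus,
                        "genotype": g,
                        "population": pop,
                        "obs_freq": obs,
                        "p_value": pval,
                        "sign": sign,
                    }
                )
    return GeaResult(pd.DataFrame(rows), cfg)
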