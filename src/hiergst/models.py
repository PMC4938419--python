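"""Step 2: Bayesian partitioning of logit-GST into genome-wide and
locus-specific effects.

Two models are provided, both fitted by Gibbs sampling:

``HierarchicalGstModel`` (the multi-site model) partitions the logit of the
per-locus pairwise GST medians into genome-wide effects of the nested
neutral structure and a locus-specific elevation effect::

    logit(GST_(i,j),m) ~ N(mean_(i,j),m , tau_R)
    mean_(i,j),m = mu_G + k_Clus(i,j) mu_Clus + k_SubClus(i,j) mu_SubClus
                   + k_Elev(i,j) (mu_Elev + theta_Elev(m))

with k_Clus = 1 for pairs in different clusters, k_SubClus = 1 for pairs in
different sub-clusters of the same cluster, and k_Elev = 1 for pairs at
different elevations. Priors: mu_G ~ N(0, tau_G) with fixed tau_G = 1e-4;
mu_Clus, mu_SubClus, mu_Elev ~ N(0, tau) with tau ~ Gamma(0.01, 0.01);
theta_m ~ N(0, tau_m) with fixed tau_m = 1e-4; residual precision
tau_R ~ Gamma(0.01, 0.01). Identifiability comes from the sum-to-zero
constraint on theta, imposed by recentring theta every sweep and absorbing
the offset into mu_Elev.

``SingleSiteGstModel`` (the within-site model) drops the genome-wide
structure terms — with a single population pair every observation sits at
k_Elev = 1, so the elevation effect is confounded with the intercept — and
fits logit(GST_m) ~ N(mu_G + theta_m, tau_R) with the same priors and the
same sum-to-zero constraint.

Because every conditional is conjugate (normal for locations, gamma for
precisions) the Gibbs sweep needs no tuning and is deterministic given the
seed. A split-chain potential-scale-reduction diagnostic is reported per
parameter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .gst import GstMatrix
from .popdata import HierarchyAssignment, ValidationError

TAU_G = 1e-4       # fixed prior precision of the global mean
TAU_THETA = 1e-4   # fixed prior precision of the locus effects
GAMMA_A = 0.01     # shape of the Gamma prior on free precisions
GAMMA_B = 0.01     # rate of the Gamma prior on free precisions


@dataclass
class McmcConfig:
    """Chain configuration. Defaults follow the simulated-data settings
    (2000 iterations, 1000 burn-in); real-data runs use 10000/5000."""

    n_iter: int = 2000
    n_burnin: int = 1000
    thin: int = 1
    n_chains: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_burnin >= self.n_iter:
            raise ValidationError("n_burnin must be smaller than n_iter")
        if self.thin < 1:
            raise ValidationError("thin must be >= 1")
        if self.n_chains < 1:
            raise ValidationError("n_chains must be >= 1")


def build_design(hier: HierarchyAssignment) -> pd.DataFrame:
    """Binary pair-level design: one row per unordered population pair.

    k_clus = 1 iff the two populations belong to different clusters;
    k_subclus = 1 iff same cluster but different sub-clusters;
    k_elev = 1 iff different elevation classes. k_clus and k_subclus are
    mutually exclusive by construction.
    """
    rows = []
    for a, b in combinations(hier.populations, 2):
        diff_clus = hier.cluster_of[a] != hier.cluster_of[b]
        diff_sub = (not diff_clus) and hier.subcluster_of[a] != hier.subcluster_of[b]
        rows.append(
            {
                "pop_i": a,
                "pop_j": b,
                "k_clus": int(diff_clus),
                "k_subclus": int(diff_sub),
                "k_elev": int(hier.elevation_of[a] != hier.elevation_of[b]),
            }
        )
    return pd.DataFrame(rows)


def logit_transform(g, eps: float = 1e-6):
    """Elementwise logit with clamping to [eps, 1 - eps].

    Returns ``(transformed, n_clamped)``; clamping keeps boundary GST values
    (0 or 1, possible after rounding) finite on the logit scale.
    """
    g = np.asarray(g, dtype=float)
    if eps <= 0 or eps >= 0.5:
        raise ValidationError("eps must be in (0, 0.5)")
    clamped = np.clip(g, eps, 1.0 - eps)
    n_clamped = int(np.sum((g < eps) | (g > 1.0 - eps)))
    return np.log(clamped / (1.0 - clamped)), n_clamped


def inv_logit(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def _split_rhat(chains: np.ndarray) -> float:
    """Potential scale reduction over split chains.

    ``chains``: (n_chains, n_draws). Each chain is split in half; the
    classic between/within variance ratio is returned.
    """
    halves = []
    for c in chains:
        h = len(c) // 2
        if h < 2:
            return float("nan")
        halves.extend([c[:h], c[h: 2 * h]])
    arr = np.asarray(halves)
    m, n = arr.shape
    means = arr.mean(axis=1)
    w = arr.var(axis=1, ddof=1).mean()
    b = n * means.var(ddof=1)
    if w == 0:
        return 1.0
    return float(np.sqrt(((n - 1) / n * w + b / n) / w))


class _BaseResults:
    """Shared posterior-summary machinery for both models."""

    scalar_names: list[str] = []

    def __init__(self, model, samples: dict[str, np.ndarray], config: McmcConfig):
        self.model = model
        self.samples = samples          # name -> (n_chains, n_kept) or (n_chains, n_kept, L)
        self.config = config
        self.loci = model.loci

    def _flat(self, name):
        return self.samples[name].reshape(-1, *self.samples[name].shape[2:])

    @property
    def params(self) -> pd.Series:
        """Posterior medians of the scalar parameters."""
        return pd.Series({n: float(np.median(self._flat(n))) for n in self.scalar_names})

    @property
    def theta(self) -> pd.Series:
        """Posterior medians of the locus-specific effects."""
        flat = self._flat("theta")
        return pd.Series(np.median(flat, axis=0), index=self.loci, name="theta")

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        lo, hi = 100 * alpha / 2, 100 * (1 - alpha / 2)
        rows = {}
        for n in self.scalar_names:
            f = self._flat(n)
            rows[n] = np.percentile(f, [lo, hi])
        th = self._flat("theta")
        ci = np.percentile(th, [lo, hi], axis=0)
        for i, loc in enumerate(self.loci):
            rows[f"theta[{loc}]"] = ci[:, i]
        return pd.DataFrame(rows, index=["lower", "upper"]).T

    @property
    def rhat(self) -> pd.Series:
        vals = {n: _split_rhat(self.samples[n]) for n in self.scalar_names}
        th = self.samples["theta"]
        vals["theta(max)"] = max(
            _split_rhat(th[:, :, i]) for i in range(th.shape[2])
        )
        return pd.Series(vals)

    def summary(self) -> pd.DataFrame:
        """Posterior median, 95% credible interval and split-chain
        diagnostic for every parameter (thetas included)."""
        ci = self.conf_int()
        rows = []
        for n in self.scalar_names:
            f = self._flat(n)
            rows.append((n, float(np.median(f)), ci.loc[n, "lower"], ci.loc[n, "upper"],
                         _split_rhat(self.samples[n])))
        th = self.samples["theta"]
        med = self.theta
        for i, loc in enumerate(self.loci):
            key = f"theta[{loc}]"
            rows.append((key, med[loc], ci.loc[key, "lower"], ci.loc[key, "upper"],
                         _split_rhat(th[:, :, i])))
        return pd.DataFrame(rows, columns=["parameter", "median", "ci2.5", "ci97.5", "rhat"])

    def write_summary(self, path) -> None:
        self.summary().to_csv(path, sep="\t", index=False)

    def write_chains(self, path) -> None:
        """Dump retained draws in columnar plain text (chains stacked)."""
        cols = {n: self._flat(n) for n in self.scalar_names}
        df = pd.DataFrame(cols)
        th = self._flat("theta")
        for i, loc in enumerate(self.loci):
            df[f"theta[{loc}]"] = th[:, i]
        df.to_csv(path, sep="\t", index=False)

    def call_outliers(self, alpha: float = 0.01):
        from .outliers import call_outliers

        return call_outliers(self.theta, alpha=alpha)


class HbmResults(_BaseResults):
    """Posterior of the hierarchical (multi-site) partitioning model."""

    scalar_names = ["mu_g", "mu_clus", "mu_subclus", "mu_elev",
                    "tau_r", "tau_clus", "tau_subclus", "tau_elev"]


class SbmResults(_BaseResults):
    """Posterior of the single-site partitioning model."""

    scalar_names = ["mu_g", "tau_r"]


class HierarchicalGstModel:
    """Multi-site partitioning of logit-GST (model described above).

    Parameters
    ----------
    gst : GstMatrix or long DataFrame
        Posterior-median pairwise GST per locus (step-1 output).
    hierarchy : HierarchyAssignment
        Cluster / sub-cluster / elevation labels for every population in
        the GST pair index.
    eps : float
        Clamp width for the logit transform.
    """

    def __init__(self, gst, hierarchy: HierarchyAssignment, eps: float = 1e-6):
        if isinstance(gst, pd.DataFrame):
            gst = GstMatrix(gst)
        self.hierarchy = hierarchy
        design = build_design(hierarchy)
        pair_key = {tuple(sorted(p)): i for i, p in
                    enumerate(zip(design["pop_i"], design["pop_j"]))}
        pairs = gst.pairs
        for p in pairs:
            if tuple(sorted(p)) not in pair_key:
                raise ValidationError(f"GST pair {p} absent from the hierarchy design")
        if len(pairs) != len(pair_key):
            raise ValidationError(
                f"GST matrix has {len(pairs)} pairs but the hierarchy implies {len(pair_key)}"
            )
        order = [pair_key[tuple(sorted(p))] for p in pairs]
        design = design.iloc[order].reset_index(drop=True)
        wide = gst.wide()
        self.loci = list(wide.index)
        if len(self.loci) < 2:
            raise ValidationError("the hierarchical model needs at least 2 loci")
        self.y, self.n_clamped = logit_transform(wide.to_numpy(), eps)
        if not np.isfinite(self.y).all():
            raise ValidationError("non-finite logit-GST values")
        self.design = design
        self.k_clus = design["k_clus"].to_numpy(float)
        self.k_subclus = design["k_subclus"].to_numpy(float)
        self.k_elev = design["k_elev"].to_numpy(float)
        if self.k_elev.sum() == 0:
            raise ValidationError("no population pair contrasts elevations; theta is not estimable")

    @classmethod
    def from_dataset(cls, ds, hierarchy, n_samples: int = 2000, seed=None, eps: float = 1e-6):
        """Run step 1 (GST inference) on a genotype dataset, then build the model."""
        from .gst import gst_median_matrix

        return cls(gst_median_matrix(ds, n_samples=n_samples, seed=seed), hierarchy, eps=eps)

    # -- Gibbs sampler --------------------------------------------------

    def _run_chain(self, cfg: McmcConfig, rng) -> dict[str, np.ndarray]:
        y = self.y
        L, P = y.shape
        kC, kS, kE = self.k_clus, self.k_subclus, self.k_elev
        idxE = kE == 1
        nE = int(idxE.sum())
        n_obs = L * P

        mu_g = float(y.mean())
        mu_c = mu_s = mu_e = 0.0
        theta = np.zeros(L)
        tau_r = tau_c = tau_s = tau_e = 1.0

        kept = (cfg.n_iter - cfg.n_burnin) // cfg.thin
        out = {n: np.empty(kept) for n in HbmResults.scalar_names}
        out["theta"] = np.empty((kept, L))
        k = 0

        # pair-level design for the genome-wide block; its columns are
        # correlated, so the four effects are drawn jointly (blocked Gibbs)
        Xp = np.stack([np.ones(P), kC, kS, kE], axis=1)
        XtX = Xp.T @ Xp * L
        for it in range(cfg.n_iter):
            # joint conditional of (mu_g, mu_clus, mu_subclus, mu_elev)
            r = y - theta[:, None] * kE[None, :]
            prec = np.diag([TAU_G, tau_c, tau_s, tau_e]) + tau_r * XtX
            rhs = tau_r * (Xp.T @ r.sum(axis=0))
            chol = np.linalg.cholesky(prec)
            mean = np.linalg.solve(prec, rhs)
            b = mean + np.linalg.solve(chol.T, rng.standard_normal(4))
            mu_g, mu_c, mu_s, mu_e = b

            # locus effects, then recentre to enforce sum(theta) = 0
            base = mu_g + kC * mu_c + kS * mu_s
            r = y[:, idxE] - (base[idxE] + mu_e)[None, :]
            prec_t = TAU_THETA + tau_r * nE
            theta = rng.normal(tau_r * r.sum(axis=1) / prec_t, prec_t ** -0.5)
            shift = theta.mean()
            theta -= shift
            mu_e += shift

            # precisions (gamma conditionals)
            fitted = (base + kE * mu_e)[None, :] + theta[:, None] * kE[None, :]
            ssr = float(((y - fitted) ** 2).sum())
            tau_r = rng.gamma(GAMMA_A + n_obs / 2, 1.0 / (GAMMA_B + ssr / 2))
            tau_c = rng.gamma(GAMMA_A + 0.5, 1.0 / (GAMMA_B + mu_c ** 2 / 2))
            tau_s = rng.gamma(GAMMA_A + 0.5, 1.0 / (GAMMA_B + mu_s ** 2 / 2))
            tau_e = rng.gamma(GAMMA_A + 0.5, 1.0 / (GAMMA_B + mu_e ** 2 / 2))

            if not (np.isfinite(tau_r) and np.isfinite(theta).all()):
                raise RuntimeError(f"divergent chain at iteration {it}")
            if it >= cfg.n_burnin and (it - cfg.n_burnin) % cfg.thin == 0:
                for name, val in (("mu_g", mu_g), ("mu_clus", mu_c), ("mu_subclus", mu_s),
                                  ("mu_elev", mu_e), ("tau_r", tau_r), ("tau_clus", tau_c),
                                  ("tau_subclus", tau_s), ("tau_elev", tau_e)):
                    out[name][k] = val
                out["theta"][k] = theta
                k += 1
        return out

    def fit(self, config: McmcConfig | None = None, **kwargs) -> HbmResults:
        """Run the Gibbs sampler and return an :class:`HbmResults`."""
        cfg = config if config is not None else McmcConfig(**kwargs)
        seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_chains)
        chains = [self._run_chain(cfg, np.random.default_rng(s)) for s in seeds]
        samples = {
            name: np.stack([c[name] for c in chains]) for name in chains[0]
        }
        return HbmResults(self, samples, cfg)


class SingleSiteGstModel:
    """Within-site partitioning of logit-GST for one population pair.

    Accepts either a :class:`GstMatrix` restricted to a single pair or a
    per-locus GST vector (Series indexed by locus). Requires at least three
    loci — the downstream normal fit is meaningless below that.
    """

    def __init__(self, gst, eps: float = 1e-6):
        if isinstance(gst, GstMatrix) or isinstance(gst, pd.DataFrame):
            if isinstance(gst, pd.DataFrame) and "gst_median" in gst.columns:
                gst = GstMatrix(gst)
            if isinstance(gst, GstMatrix):
                if len(gst.pairs) != 1:
                    raise ValidationError(
                        f"the single-site model takes exactly one population pair, got {len(gst.pairs)}"
                    )
                series = gst.wide().iloc[:, 0]
            else:
                raise ValidationError("unrecognised GST input")
        else:
            series = pd.Series(gst)
        if len(series) < 3:
            raise ValidationError("the single-site model needs at least 3 loci")
        self.loci = list(series.index)
        self.y, self.n_clamped = logit_transform(series.to_numpy(float), eps)

    def _run_chain(self, cfg: McmcConfig, rng) -> dict[str, np.ndarray]:
        y = self.y
        L = y.size
        mu_g = float(y.mean())
        theta = np.zeros(L)
        tau_r = 1.0
        kept = (cfg.n_iter - cfg.n_burnin) // cfg.thin
        out = {"mu_g": np.empty(kept), "tau_r": np.empty(kept), "theta": np.empty((kept, L))}
        k = 0
        for it in range(cfg.n_iter):
            prec = TAU_G + tau_r * L
            mu_g = rng.normal(tau_r * (y - theta).sum() / prec, prec ** -0.5)
            prec = TAU_THETA + tau_r
            theta = rng.normal(tau_r * (y - mu_g) / prec, prec ** -0.5)
            shift = theta.mean()
            theta -= shift
            mu_g += shift
            ssr = float(((y - mu_g - theta) ** 2).sum())
            tau_r = rng.gamma(GAMMA_A + L / 2, 1.0 / (GAMMA_B + ssr / 2))
            if not (np.isfinite(tau_r) and np.isfinite(theta).all()):
                raise RuntimeError(f"divergent chain at iteration {it}")
            if it >= cfg.n_burnin and (it - cfg.n_burnin) % cfg.thin == 0:
                out["mu_g"][k] = mu_g
                out["tau_r"][k] = tau_r
                out["theta"][k] = theta
                k += 1
        return out

    def fit(self, config: McmcConfig | None = None, **kwargs) -> SbmResults:
        cfg = config if config is not None else McmcConfig(**kwargs)
        seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_chains)
        chains = [self._run_chain(cfg, np.random.default_rng(s)) for s in seeds]
        samples = {name: np.stack([c[name] for c in chains]) for name in chains[0]}
        return SbmResults(self, samples, cfg)


def run_hbm(gst, hierarchy: HierarchyAssignment, cfg: McmcConfig | None = None,
            eps: float = 1e-6) -> HbmResults:
    """Functional wrapper: fit the hierarchical model."""
    return HierarchicalGstModel(gst, hierarchy, eps=eps).fit(cfg or McmcConfig())


def run_sbm(gst, cfg: McmcConfig | None = None, eps: float = 1e-6) -> SbmResults:
    """Functional wrapper: fit the single-site model."""
    return SingleSiteGstModel(gst, eps=eps).fit(cfg or McmcConfig())
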