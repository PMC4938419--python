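"""Forward-time Wright-Fisher simulator under a hierarchical island model.

Populations are arranged as clusters > sub-clusters > sites > two
elevations (low/high); the default 2 x 2 x 2 x 2 design gives 16
populations of N = 200 diploids. Migration is nested: each population
exchanges migrants at rate m3 with the other populations of its sub-cluster,
m2 with the other sub-clusters of its cluster, and m1 with the other
clusters (m1 <= m2 <= m3).

Selection acts only during the final ``selection_onset`` generations: the
neutral hierarchical structure (lineages diverged long ago) predates the
selective contrast between elevations, and a locus under directional
homogenizing selection for the whole history would simply fix everywhere
and leave nothing to analyse.

Per generation and unlinked locus: (1) deterministic migration mixing of
allele frequencies, (2) viability selection with additive fitnesses
w(A1A1) = 1, w(A1A2) = 1 - s/2, w(A2A2) = 1 - s where A1 is the locally
favoured allele — under divergent selection the favoured allele differs
between elevations; under homogenizing selection it is the same everywhere —
then (3) Wright-Fisher binomial resampling of 2N gametes. Because loci are
unlinked and mating is random, tracking allele frequencies with exact
binomial resampling is distributionally equivalent to an individual-based
simulation for every statistic consumed downstream; genotypes are
materialised only at the end, from within-population Hardy-Weinberg
proportions at the terminal frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .popdata import GenotypeDataset, HierarchyAssignment, ValidationError

REGIMES = ("divergent", "homogenizing")


@dataclass
class SelectedLocus:
    locus: int               # 0-based locus index
    regime: str              # 'divergent' or 'homogenizing'
    s: float                 # selection strength, s = 1 - fitness of the
                             # disfavoured homozygote

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValidationError(f"unknown selection regime {self.regime!r}")
        if not 0 <= self.s <= 1:
            raise ValidationError(f"selection strength must be in [0, 1], got {self.s}")


@dataclass
class ScenarioConfig:
    """Simulation scenario.

    The default hierarchy (2 clusters x 2 sub-clusters x 2 sites x 2
    elevations) reproduces the 16-population power-study design; the
    within-site design uses 1 x 1 x 1 x 2 with N = 1600.
    """

    n_clusters: int = 2
    n_subclusters: int = 2   # per cluster
    n_sites: int = 2         # per sub-cluster
    N: int = 200             # diploids per population
    L: int = 100             # unlinked bi-allelic loci
    selected: list[SelectedLocus] = field(default_factory=list)
    m1: float = 0.001        # between clusters
    m2: float = 0.002        # between sub-clusters within a cluster
    m3: float = 0.05         # among populations within a sub-cluster
    generations: int = 800
    selection_onset: int = 100   # selection acts in the final generations only
    p0: float = 0.5
    seed: int | None = None

    def __post_init__(self) -> None:
        if min(self.n_clusters, self.n_subclusters, self.n_sites, self.N, self.L) < 1:
            raise ValidationError("hierarchy sizes, N and L must be positive")
        if not 0 <= self.m1 <= self.m2 <= self.m3:
            raise ValidationError("migration rates must satisfy 0 <= m1 <= m2 <= m3")
        if self.m1 + self.m2 + self.m3 >= 1:
            raise ValidationError("total migration must be below 1")
        if not 0 <= self.p0 <= 1:
            raise ValidationError("p0 must be in [0, 1]")
        if self.selection_onset < 0:
            raise ValidationError("selection_onset must be non-negative")
        for sel in self.selected:
            if not 0 <= sel.locus < self.L:
                raise ValidationError(f"selected locus index {sel.locus} outside 0..{self.L - 1}")

    @property
    def n_populations(self) -> int:
        return self.n_clusters * self.n_subclusters * self.n_sites * 2

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in
             ("n_clusters", "n_subclusters", "n_sites", "N", "L", "m1", "m2", "m3",
              "generations", "selection_onset", "p0", "seed")}
        d["selected"] = [{"locus": s.locus, "regime": s.regime, "s": s.s} for s in self.selected]
        return d

    def write(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def read(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        sel = [SelectedLocus(**s) for s in d.pop("selected", [])]
        return cls(selected=sel, **d)


@dataclass
class SimulatedDataset:
    """Genotypes + hierarchy + per-locus selection truth."""

    dataset: GenotypeDataset
    hierarchy: HierarchyAssignment
    truth: dict[str, tuple[str, float]]   # locus id -> (regime, s)
    scenario: ScenarioConfig
    final_freqs: np.ndarray               # (n_populations, L) terminal p
    site_of: dict[str, str] = field(default_factory=dict)

    @property
    def selected_loci(self) -> set[str]:
        return set(self.truth)

    def write_truth(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("locus\tregime\ts\n")
            for loc, (regime, s) in self.truth.items():
                fh.write(f"{loc}\t{regime}\t{s}\n")


def _population_labels(cfg: ScenarioConfig):
    """Population ids and hierarchy labels, clusters outermost."""
    pops, clus, sub, site, elev = [], {}, {}, {}, {}
    for c in range(cfg.n_clusters):
        for sc in range(cfg.n_subclusters):
            for st in range(cfg.n_sites):
                for e in ("low", "high"):
                    pid = f"c{c + 1}_s{sc + 1}_t{st + 1}_{e}"
                    pops.append(pid)
                    clus[pid] = f"cluster{c + 1}"
                    sub[pid] = f"subcluster{c + 1}.{sc + 1}"
                    site[pid] = f"site{c + 1}.{sc + 1}.{st + 1}"
                    elev[pid] = e
    return pops, clus, sub, site, elev


def _migration_matrix(cfg: ScenarioConfig, pops, clus, sub) -> np.ndarray:
    """Row-stochastic mixing matrix A with p' = A @ p.

    Each population draws a fraction m3 of its gene pool from the mean of
    the other populations in its sub-cluster, m2 from the other sub-clusters
    of its cluster, and m1 from the other clusters; rates whose donor set is
    empty (e.g. a single-cluster design) are dropped.
    """
    P = len(pops)
    A = np.zeros((P, P))
    for i, pi in enumerate(pops):
        donors3 = [j for j, pj in enumerate(pops) if j != i and sub[pj] == sub[pi]]
        donors2 = [j for j, pj in enumerate(pops)
                   if clus[pj] == clus[pi] and sub[pj] != sub[pi]]
        donors1 = [j for j, pj in enumerate(pops) if clus[pj] != clus[pi]]
        applied = 0.0
        for rate, donors in ((cfg.m3, donors3), (cfg.m2, donors2), (cfg.m1, donors1)):
            if donors:
                A[i, donors] += rate / len(donors)
                applied += rate
        A[i, i] += 1.0 - applied
    return A


def _selection_step(p: np.ndarray, favored_A1: np.ndarray, s_vec: np.ndarray,
                    sel_cols: np.ndarray) -> np.ndarray:
    """Viability selection on the selected loci only.

    ``favored_A1``: (n_pops, n_selected) boolean — is the reference allele
    the locally favoured one. ``s_vec``: per-selected-locus strength.
    """
    ps = p[:, sel_cols]
    qs = 1.0 - ps
    # fitnesses when A1 favoured: w11=1, w12=1-s/2, w22=1-s; swapped otherwise
    s = s_vec[None, :]
    w11 = np.where(favored_A1, 1.0, 1.0 - s)
    w12 = 1.0 - s / 2
    w22 = np.where(favored_A1, 1.0 - s, 1.0)
    wbar = ps * ps * w11 + 2 * ps * qs * w12 + qs * qs * w22
    with np.errstate(invalid="ignore", divide="ignore"):
        new = ps * (ps * w11 + qs * w12) / wbar
    p = p.copy()
    p[:, sel_cols] = np.where(wbar > 0, new, ps)
    return p


def simulate(cfg: ScenarioConfig, seed=None) -> SimulatedDataset:
    """Run the forward simulation and materialise a genotype dataset.

    ``seed`` overrides ``cfg.seed`` when given. Deterministic under seed.
    """
    if seed is None:
        seed = cfg.seed
    rng = np.random.default_rng(seed)
    pops, clus, sub, site, elev = _population_labels(cfg)
    P, L = len(pops), cfg.L
    A = _migration_matrix(cfg, pops, clus, sub)

    sel_cols = np.array([s.locus for s in cfg.selected], dtype=int)
    s_vec = np.array([s.s for s in cfg.selected], dtype=float)
    is_high = np.array([elev[p] == "high" for p in pops])
    favored = np.ones((P, len(cfg.selected)), dtype=bool)  # A1 favoured
    for k, selspec in enumerate(cfg.selected):
        if selspec.regime == "divergent":
            favored[is_high, k] = False  # A2 favoured at high elevation

    p = np.full((P, L), float(cfg.p0))
    two_n = 2 * cfg.N
    # selection switches on for the final `selection_onset` generations:
    # the neutral hierarchy is older than the selective contrast it carries
    sel_start = max(0, cfg.generations - cfg.selection_onset)
    for gen in range(cfg.generations):
        p = A @ p
        if len(sel_cols) and gen >= sel_start:
            p = _selection_step(p, favored, s_vec, sel_cols)
        np.clip(p, 0.0, 1.0, out=p)  # guard rounding at the boundaries
        p = rng.binomial(two_n, p) / two_n

    loci = [f"L{j + 1:03d}" for j in range(L)]
    individuals, pop_of = [], {}
    codes = np.empty((P * cfg.N, L), dtype=np.int8)
    for i, pid in enumerate(pops):
        # genotype counts from within-population Hardy-Weinberg proportions
        pi = p[i]
        probs = np.stack([pi * pi, 2 * pi * (1 - pi), (1 - pi) ** 2], axis=1)
        block = np.empty((cfg.N, L), dtype=np.int8)
        for j in range(L):
            counts = rng.multinomial(cfg.N, probs[j])
            block[:, j] = np.repeat(np.array([0, 1, 2], dtype=np.int8), counts)
        rows = slice(i * cfg.N, (i + 1) * cfg.N)
        codes[rows] = block
        for k in range(cfg.N):
            ind = f"{pid}_ind{k + 1:04d}"
            individuals.append(ind)
            pop_of[ind] = pid

    ds = GenotypeDataset(loci, individuals, codes, pop_of,
                         {loc: ("A", "G") for loc in loci})
    hier = HierarchyAssignment(pops, clus, sub, {p_: elev[p_] for p_ in pops})
    truth = {loci[s_.locus]: (s_.regime, s_.s) for s_ in cfg.selected}
    return SimulatedDataset(ds, hier, truth, replace(cfg, seed=seed), p, dict(site))


def scenario_from_table2(selection_type: str, n_selected, s_spec,
                         within_site: bool = False, seed=None) -> ScenarioConfig:
    """Build the scenario matching one power-study row.

    ``selection_type``: 'no selection', 'divergent', 'homogenizing' or
    'homogenizing/divergent'. ``s_spec`` is a float (uniform strength), a
    (lo, hi) tuple (per-locus strengths drawn uniformly in the range, one
    draw per scenario seed), or None for no selection. ``within_site``
    switches to the two-population design (one site, N = 1600 each).
    For the mixed type, ``n_selected`` is (n_homogenizing, n_divergent).
    """
    kind = selection_type.strip().lower()
    rng = np.random.default_rng(seed)

    def strengths(n):
        if isinstance(s_spec, (tuple, list)):
            lo, hi = s_spec
            return rng.uniform(lo, hi, size=n)
        return np.full(n, float(s_spec))

    selected: list[SelectedLocus] = []
    if kind in ("no selection", "none"):
        pass
    elif kind in ("divergent", "homogenizing"):
        n_sel = int(n_selected)
        for i, s in enumerate(strengths(n_sel)):
            selected.append(SelectedLocus(i, kind, float(s)))
    elif kind in ("homogenizing/divergent", "mixed"):
        n_h, n_d = (int(n_selected[0]), int(n_selected[1])) \
            if isinstance(n_selected, (tuple, list)) else (int(n_selected), int(n_selected))
        s_h = strengths(n_h)
        s_d = strengths(n_d)
        for i in range(n_h):
            selected.append(SelectedLocus(i, "homogenizing", float(s_h[i])))
        for i in range(n_d):
            selected.append(SelectedLocus(n_h + i, "divergent", float(s_d[i])))
    else:
        raise KeyError(f"unknown power-study scenario {selection_type!r}")

    if within_site:
        return ScenarioConfig(n_clusters=1, n_subclusters=1, n_sites=1,
                              N=1600, selected=selected, seed=seed)
    return ScenarioConfig(selected=selected, seed=seed)
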