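"""Genotype data model, file I/O and per-population summary statistics.

The central container is :class:`GenotypeDataset`: diploid, bi-allelic SNP
genotypes for a set of individuals, each assigned to exactly one population.
Genotypes are stored as small integer codes (0 = homozygous reference,
1 = heterozygous, 2 = homozygous alternate, -1 = missing) so that allele
counting and filtering are simple vectorised operations.

Three on-disk dialects are supported: a flat genotype table (one row per
individual, two-character allele cells), a STRUCTURE-style file (two rows
per individual, integer allele codes, -9 = missing) and VCF (bi-allelic SNP
records, GT field only, via pysam).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = -1
_CODES = (0, 1, 2, MISSING)


class GenotypeParseError(ValueError):
    """Malformed genotype file; message names the offending line."""


class ValidationError(ValueError):
    """Dataset violates an invariant (e.g. a tri-allelic locus)."""


@dataclass
class AlleleCounts:
    """Allelic counts for one population at one locus.

    ``n`` counts the reference allele among non-missing genotypes and ``N``
    is the total allelic count (twice the number of non-missing diploids).
    """

    n: int
    N: int

    def __post_init__(self) -> None:
        if not (0 <= self.n <= self.N):
            raise ValidationError(f"allele counts require 0 <= n <= N, got n={self.n}, N={self.N}")
        if self.N % 2 != 0:
            raise ValidationError(f"total allelic count must be even, got N={self.N}")


class GenotypeDataset:
    """Bi-allelic diploid genotypes with population labels.

    Parameters
    ----------
    loci : sequence of str
        Ordered locus identifiers.
    individuals : sequence of str
        Ordered individual identifiers.
    codes : ndarray of shape (n_individuals, n_loci)
        Integer genotype codes: 0 hom-ref, 1 het, 2 hom-alt, -1 missing.
    population_of : mapping individual -> population identifier
    alleles : mapping locus -> (ref, alt)
        Allele labels; ``alt`` may be ``None`` when only one allele was
        ever observed. The reference allele is, by convention, the first
        allele encountered in file order — every downstream statistic is
        invariant to this labelling.
    """

    def __init__(self, loci, individuals, codes, population_of, alleles=None):
        self.loci = list(loci)
        self.individuals = list(individuals)
        self.codes = np.asarray(codes, dtype=np.int8)
        self.population_of = dict(population_of)
        if alleles is None:
            alleles = {loc: ("A", "C") for loc in self.loci}
        self.alleles = dict(alleles)
        self._validate()
        self._locus_idx = {loc: i for i, loc in enumerate(self.loci)}
        self._pop_members: dict[str, np.ndarray] = {}
        for i, ind in enumerate(self.individuals):
            self._pop_members.setdefault(self.population_of[ind], []).append(i)
        self._pop_members = {p: np.asarray(ix) for p, ix in self._pop_members.items()}

    def _validate(self) -> None:
        if self.codes.shape != (len(self.individuals), len(self.loci)):
            raise ValidationError(
                f"genotype matrix shape {self.codes.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.loci)} loci"
            )
        bad = ~np.isin(self.codes, _CODES)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"illegal genotype code {self.codes[i, j]} for individual "
                f"{self.individuals[i]} at locus {self.loci[j]}"
            )
        missing_pop = [ind for ind in self.individuals if ind not in self.population_of]
        if missing_pop:
            raise ValidationError(f"individuals without a population label: {missing_pop[:5]}")
        if len(set(self.individuals)) != len(self.individuals):
            raise ValidationError("duplicate individual identifiers")
        if len(set(self.loci)) != len(self.loci):
            raise ValidationError("duplicate locus identifiers")

    # -- basic views ----------------------------------------------------

    @property
    def populations(self) -> list[str]:
        """Population identifiers in order of first appearance."""
        seen: dict[str, None] = {}
        for ind in self.individuals:
            seen.setdefault(self.population_of[ind], None)
        return list(seen)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def individuals_in(self, population: str) -> list[str]:
        if population not in self._pop_members:
            raise KeyError(f"unknown population {population!r}")
        return [self.individuals[i] for i in self._pop_members[population]]

    def subset(self, populations=None, loci=None) -> "GenotypeDataset":
        """Restrict to the given populations and/or loci (order preserved)."""
        pops = self.populations if populations is None else list(populations)
        keep_loci = self.loci if loci is None else list(loci)
        for p in pops:
            if p not in self._pop_members:
                raise KeyError(f"unknown population {p!r}")
        lix = [self._locus_idx[loc] for loc in keep_loci]
        iix = [i for i, ind in enumerate(self.individuals) if self.population_of[ind] in set(pops)]
        inds = [self.individuals[i] for i in iix]
        return GenotypeDataset(
            keep_loci,
            inds,
            self.codes[np.ix_(iix, lix)],
            {ind: self.population_of[ind] for ind in inds},
            {loc: self.alleles[loc] for loc in keep_loci},
        )

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, GenotypeDataset)
            and self.loci == other.loci
            and self.individuals == other.individuals
            and np.array_equal(self.codes, other.codes)
            and self.population_of == other.population_of
        )

    # -- summary statistics ---------------------------------------------

    def allele_counts(self, population: str, locus: str) -> AlleleCounts:
        """Reference-allele count ``n`` and total allelic count ``N``."""
        if locus not in self._locus_idx:
            raise KeyError(f"unknown locus {locus!r}")
        col = self.codes[self._pop_members[population], self._locus_idx[locus]] \
            if population in self._pop_members else self._missing_pop(population)
        obs = col[col != MISSING]
        # ref-allele dosage is 2 - code for codes 0/1/2
        return AlleleCounts(int((2 - obs).sum()), int(2 * obs.size))

    def _missing_pop(self, population):
        raise KeyError(f"unknown population {population!r}")

    def counts_matrix(self, populations=None):
        """Vectorised allele counts.

        Returns ``(pops, n, N)`` where ``n`` and ``N`` are integer arrays of
        shape (n_populations, n_loci).
        """
        pops = self.populations if populations is None else list(populations)
        n = np.zeros((len(pops), self.n_loci), dtype=np.int64)
        N = np.zeros_like(n)
        for k, p in enumerate(pops):
            if p not in self._pop_members:
                raise KeyError(f"unknown population {p!r}")
            block = self.codes[self._pop_members[p], :]
            obs = block != MISSING
            n[k] = np.where(obs, 2 - block, 0).sum(axis=0)
            N[k] = 2 * obs.sum(axis=0)
        return pops, n, N


def filter_monomorphic(ds: GenotypeDataset, scope=None):
    """Drop loci fixed for one allele within the pooled scope.

    A locus is retained iff both alleles are observed when the scoped
    populations are pooled. Returns ``(filtered_dataset, dropped_loci)``.
    """
    scope = ds.populations if scope is None else list(scope)
    if not scope:
        raise ValidationError("scope must be non-empty")
    _, n, N = ds.counts_matrix(scope)
    n_tot, N_tot = n.sum(axis=0), N.sum(axis=0)
    keep = (n_tot > 0) & (n_tot < N_tot)
    kept = [loc for loc, k in zip(ds.loci, keep) if k]
    dropped = [loc for loc, k in zip(ds.loci, keep) if not k]
    return ds.subset(loci=kept), dropped


def fis_per_locus(ds: GenotypeDataset, scope=None) -> pd.DataFrame:
    """Per-locus fixation index over the pooled scope.

    Pools all scoped populations into one (elevations confounded) and
    computes, per polymorphic locus, the observed heterozygote fraction
    Hobs, the Hardy–Weinberg expectation Hexp = 2pq at the pooled allele
    frequency p, and F_IS = 1 - Hobs/Hexp. Loci with Hexp = 0 are omitted.
    """
    scope = set(ds.populations if scope is None else scope)
    iix = [i for i, ind in enumerate(ds.individuals) if ds.population_of[ind] in scope]
    block = ds.codes[iix, :]
    obs = block != MISSING
    n_obs = obs.sum(axis=0)
    n_het = ((block == 1) & obs).sum(axis=0)
    n_ref = np.where(obs, 2 - block, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_obs > 0, n_ref / (2 * n_obs), np.nan)
        hobs = np.where(n_obs > 0, n_het / n_obs, np.nan)
        hexp = 2 * p * (1 - p)
        fis = 1 - hobs / hexp
    out = pd.DataFrame({"locus": ds.loci, "hobs": hobs, "hexp": hexp, "fis": fis})
    return out[(out["hexp"] > 0)].reset_index(drop=True)


@dataclass
class HierarchyAssignment:
    """Cluster / sub-cluster / elevation membership per population.

    Each population carries all three labels; each sub-cluster is nested in
    exactly one cluster; elevation is the binary contrast {low, high}.
    """

    populations: list[str]
    cluster_of: dict[str, str]
    subcluster_of: dict[str, str]
    elevation_of: dict[str, str]

    def __post_init__(self) -> None:
        for p in self.populations:
            for name, m in (("cluster", self.cluster_of),
                            ("subcluster", self.subcluster_of),
                            ("elevation", self.elevation_of)):
                if p not in m:
                    raise ValidationError(f"population {p!r} missing a {name} label")
            if self.elevation_of[p] not in ("low", "high"):
                raise ValidationError(
                    f"elevation of {p!r} must be 'low' or 'high', got {self.elevation_of[p]!r}"
                )
        nest: dict[str, str] = {}
        for p in self.populations:
            sc, c = self.subcluster_of[p], self.cluster_of[p]
            if nest.setdefault(sc, c) != c:
                raise ValidationError(f"sub-cluster {sc!r} spans more than one cluster")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "population": self.populations,
                "cluster": [self.cluster_of[p] for p in self.populations],
                "subcluster": [self.subcluster_of[p] for p in self.populations],
                "elevation": [self.elevation_of[p] for p in self.populations],
            }
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path) -> "HierarchyAssignment":
        df = pd.read_csv(path, sep="\t", dtype=str)
        need = {"population", "cluster", "subcluster", "elevation"}
        if not need.issubset(df.columns):
            raise GenotypeParseError(f"hierarchy map must have columns {sorted(need)}")
        return cls(
            list(df["population"]),
            dict(zip(df["population"], df["cluster"])),
            dict(zip(df["population"], df["subcluster"])),
            dict(zip(df["population"], df["elevation"])),
        )


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def read_genotypes(path, format: str = "table", sample_map=None) -> GenotypeDataset:
    """Read genotypes from one of the supported dialects.

    ``format`` is one of ``table``, ``structure`` or ``vcf``. For VCF a
    ``sample_map`` file (tab-separated individual -> population) is required
    because VCF carries no population labels.
    """
    if format == "table":
        return _read_table(path)
    if format == "structure":
        return _read_structure(path)
    if format == "vcf":
        if sample_map is None:
            raise ValidationError("reading VCF requires a sample_map file")
        return _read_vcf(path, sample_map)
    raise ValueError(f"unknown format {format!r}")


def write_genotypes(ds: GenotypeDataset, path, format: str = "table", sample_map=None) -> None:
    if format == "table":
        _write_table(ds, path)
    elif format == "structure":
        _write_structure(ds, path)
    elif format == "vcf":
        _write_vcf(ds, path)
        if sample_map is not None:
            pd.DataFrame(
                {"individual": ds.individuals,
                 "population": [ds.population_of[i] for i in ds.individuals]}
            ).to_csv(sample_map, sep="\t", index=False, header=False)
    else:
        raise ValueError(f"unknown format {format!r}")


def _finish(loci, individuals, pop_of, cells):
    """Assemble codes from per-locus allele-pair cells; reject tri-allelic loci."""
    codes = np.full((len(individuals), len(loci)), MISSING, dtype=np.int8)
    alleles: dict[str, tuple] = {}
    for j, loc in enumerate(loci):
        order: list[str] = []   # alleles in file order; first = reference
        for i in range(len(individuals)):
            pair = cells[i][j]
            if pair is None:
                continue
            for a in pair:
                if a not in order:
                    order.append(a)
        if len(order) > 2:
            raise ValidationError(f"locus {loc!r} has more than two alleles: {sorted(order)}")
        if not order:
            order = ["A"]
        ref = order[0]
        alt = order[1] if len(order) > 1 else None
        alleles[loc] = (ref, alt)
        for i in range(len(individuals)):
            pair = cells[i][j]
            if pair is None:
                continue
            codes[i, j] = sum(a != ref for a in pair)
    return GenotypeDataset(loci, individuals, codes, pop_of, alleles)


def _read_table(path) -> GenotypeDataset:
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise GenotypeParseError(f"{path}: empty file")
    header = lines[0].rstrip("\n").split("\t")
    if len(header) < 3:
        raise GenotypeParseError(f"{path}:1: header must be individual, population, loci...")
    loci = header[2:]
    individuals, pop_of, cells = [], {}, []
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != len(header):
            raise GenotypeParseError(f"{path}:{ln}: expected {len(header)} columns, got {len(parts)}")
        ind, pop = parts[0], parts[1]
        individuals.append(ind)
        pop_of[ind] = pop
        row = []
        for loc, cell in zip(loci, parts[2:]):
            if cell == "--":
                row.append(None)
            elif len(cell) == 2:
                row.append((cell[0], cell[1]))
            else:
                raise GenotypeParseError(
                    f"{path}:{ln}: bad genotype cell {cell!r} at locus {loc} "
                    "(expected two allele characters or '--')"
                )
        cells.append(row)
    return _finish(loci, individuals, pop_of, cells)


def _write_table(ds: GenotypeDataset, path) -> None:
    with open(path, "w") as fh:
        fh.write("individual\tpopulation\t" + "\t".join(ds.loci) + "\n")
        for i, ind in enumerate(ds.individuals):
            cells = []
            for j, loc in enumerate(ds.loci):
                ref, alt = ds.alleles[loc]
                c = ds.codes[i, j]
                if c == MISSING:
                    cells.append("--")
                else:
                    a = "" if alt is None else alt
                    cells.append({0: ref + ref, 1: ref + a, 2: a + a}[int(c)])
            fh.write(f"{ind}\t{ds.population_of[ind]}\t" + "\t".join(cells) + "\n")


def _read_structure(path) -> GenotypeDataset:
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines:
        raise GenotypeParseError(f"{path}: empty file")
    loci = lines[0].split("\t")[2:]
    body = lines[1:]
    if len(body) % 2:
        raise GenotypeParseError(f"{path}: odd number of genotype rows (two expected per individual)")
    individuals, pop_of, cells = [], {}, []
    for k in range(0, len(body), 2):
        rows = []
        for off in (0, 1):
            ln = k + off + 2
            parts = body[k + off].split("\t")
            if len(parts) != 2 + len(loci):
                raise GenotypeParseError(f"{path}:{ln}: expected {2 + len(loci)} columns, got {len(parts)}")
            rows.append(parts)
        if rows[0][0] != rows[1][0]:
            raise GenotypeParseError(
                f"{path}:{k + 3}: consecutive rows belong to different individuals "
                f"({rows[0][0]!r} vs {rows[1][0]!r})"
            )
        ind, pop = rows[0][0], rows[0][1]
        individuals.append(ind)
        pop_of[ind] = pop
        row = []
        for j in range(len(loci)):
            a1, a2 = rows[0][2 + j], rows[1][2 + j]
            if a1 == "-9" or a2 == "-9":
                row.append(None)
            else:
                row.append((a1, a2))
        cells.append(row)
    return _finish(loci, individuals, pop_of, cells)


def _write_structure(ds: GenotypeDataset, path) -> None:
    # allele labels cannot survive integer encoding: ref -> 1, alt -> 2
    with open(path, "w") as fh:
        fh.write("individual\tpopulation\t" + "\t".join(ds.loci) + "\n")
        for i, ind in enumerate(ds.individuals):
            r1, r2 = [], []
            for j in range(ds.n_loci):
                c = int(ds.codes[i, j])
                if c == MISSING:
                    r1.append("-9")
                    r2.append("-9")
                else:
                    r1.append("1" if c <= 1 else "2")
                    r2.append("1" if c == 0 else "2")
            fh.write(f"{ind}\t{ds.population_of[ind]}\t" + "\t".join(r1) + "\n")
            fh.write(f"{ind}\t{ds.population_of[ind]}\t" + "\t".join(r2) + "\n")


def _read_vcf(path, sample_map) -> GenotypeDataset:
    import pysam

    sm = pd.read_csv(sample_map, sep="\t", header=None, names=["individual", "population"], dtype=str)
    pop_of = dict(zip(sm["individual"], sm["population"]))
    vf = pysam.VariantFile(str(path))
    individuals = list(vf.header.samples)
    for ind in individuals:
        if ind not in pop_of:
            raise ValidationError(f"VCF sample {ind!r} absent from the sample map")
    loci, alleles, cols = [], {}, []
    for rec in vf:
        if rec.alts is not None and len(rec.alts) > 1:
            raise ValidationError(f"locus {rec.id or rec.chrom!r} is not bi-allelic")
        loc = rec.id if rec.id not in (None, ".") else f"{rec.chrom}:{rec.pos}"
        loci.append(loc)
        alt = rec.alts[0] if rec.alts else None
        alleles[loc] = (rec.ref, alt)
        col = np.full(len(individuals), MISSING, dtype=np.int8)
        for i, ind in enumerate(individuals):
            gt = rec.samples[ind].get("GT")
            if gt is None or len(gt) != 2 or any(a is None for a in gt):
                continue
            col[i] = gt[0] + gt[1]
        cols.append(col)
    vf.close()
    codes = np.stack(cols, axis=1) if cols else np.zeros((len(individuals), 0), dtype=np.int8)
    return GenotypeDataset(loci, individuals, codes, {i: pop_of[i] for i in individuals}, alleles)


def _write_vcf(ds: GenotypeDataset, path) -> None:
    import pysam

    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for j, loc in enumerate(ds.loci):
        header.contigs.add(f"ctg{j}", length=1000)
    for ind in ds.individuals:
        header.add_sample(ind)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for j, loc in enumerate(ds.loci):
            ref, alt = ds.alleles[loc]
            rec = out.new_record(
                contig=f"ctg{j}", start=0, stop=1, id=loc,
                alleles=(ref, alt) if alt is not None else (ref,),
            )
            for i, ind in enumerate(ds.individuals):
                c = int(ds.codes[i, j])
                rec.samples[ind]["GT"] = None if c == MISSING else ((0, 0), (0, 1), (1, 1))[c]
            out.write(rec)
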