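"""Phased haplotype panels, meiosis, mating and truncation selection.

A ``HaplotypePanel`` stores one cohort: phased biallelic haplotypes plus
pedigree metadata.  Mating produces discrete non-overlapping generations;
sexes are assigned deterministically half male / half female per cohort so
that the 100-male / 200-female selection quota is always feasible.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ._kernels import drop_gametes
from .errors import ConfigurationError, SelectionError
from .genome import GeneticMap

__all__ = [
    "HaplotypePanel", "BREED_A", "BREED_B", "BREED_AB", "HISTORICAL",
    "meiosis", "mate", "select_top", "found_breeds", "random_mating_generation",
]

BREED_A = 0
BREED_B = 1
BREED_AB = 2
HISTORICAL = -1

_SEX_MALE = 0
_SEX_FEMALE = 1


@dataclass
class HaplotypePanel:
    """One cohort of phased individuals.

    haplotypes has shape (n, 2, n_loci), uint8 alleles coded 0/1; allele 1
    is the "A" allele whose homozygote has genotypic value +a at QTL.
    """
    ids: np.ndarray          # (n,) int64, unique within the panel
    sire: np.ndarray         # (n,) int64, -1 for founders
    dam: np.ndarray          # (n,) int64
    sex: np.ndarray          # (n,) int8, 0 = male, 1 = female
    breed: np.ndarray        # (n,) int8, BREED_A / BREED_B / BREED_AB / HISTORICAL
    generation: int
    haplotypes: np.ndarray   # (n, 2, L) uint8

    def __post_init__(self):
        if len(np.unique(self.ids)) != len(self.ids):
            raise ConfigurationError("panel ids must be unique")
        if self.haplotypes.ndim != 3 or self.haplotypes.shape[1] != 2:
            raise ConfigurationError("haplotypes must have shape (n, 2, n_loci)")

    @property
    def n_individuals(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.haplotypes.shape[2]

    @property
    def males(self) -> np.ndarray:
        return np.flatnonzero(self.sex == _SEX_MALE)

    @property
    def females(self) -> np.ndarray:
        return np.flatnonzero(self.sex == _SEX_FEMALE)

    def dosages(self, loci: np.ndarray | None = None) -> np.ndarray:
        """Genotype dosage x_ij in {0, 1, 2}: copies of allele 1 ("A")."""
        h = self.haplotypes if loci is None else self.haplotypes[:, :, loci]
        return h.sum(axis=1, dtype=np.int8)

    def allele_frequencies(self, loci: np.ndarray | None = None) -> np.ndarray:
        """Frequency of allele 1 per locus across the panel."""
        h = self.haplotypes if loci is None else self.haplotypes[:, :, loci]
        return h.mean(axis=(0, 1))

    def mean_heterozygosity(self, loci: np.ndarray | None = None) -> float:
        """Mean observed heterozygosity over loci."""
        h = self.haplotypes if loci is None else self.haplotypes[:, :, loci]
        return float((h[:, 0, :] != h[:, 1, :]).mean())

    def subset(self, rows: np.ndarray) -> "HaplotypePanel":
        return replace(
            self, ids=self.ids[rows], sire=self.sire[rows], dam=self.dam[rows],
            sex=self.sex[rows], breed=self.breed[rows],
            haplotypes=self.haplotypes[rows],
        )

    def pedigree_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "id": self.ids, "sire": self.sire, "dam": self.dam,
            "sex": np.where(self.sex == _SEX_MALE, "M", "F"),
            "breed": self.breed, "generation": self.generation,
        })


def _alternating_sexes(n: int) -> np.ndarray:
    """Deterministic half-male / half-female assignment (M, F, M, F, ...)."""
    sex = np.empty(n, dtype=np.int8)
    sex[0::2] = _SEX_MALE
    sex[1::2] = _SEX_FEMALE
    return sex


def _new_panel_from_gametes(gam_s, gam_d, sire_ids, dam_ids, breed_code,
                            generation, id_start) -> HaplotypePanel:
    n = gam_s.shape[0]
    haps = np.empty((n, 2, gam_s.shape[1]), dtype=np.uint8)
    haps[:, 0, :] = gam_s
    haps[:, 1, :] = gam_d
    return HaplotypePanel(
        ids=np.arange(id_start, id_start + n, dtype=np.int64),
        sire=np.asarray(sire_ids, dtype=np.int64),
        dam=np.asarray(dam_ids, dtype=np.int64),
        sex=_alternating_sexes(n),
        breed=np.full(n, breed_code, dtype=np.int8),
        generation=generation,
        haplotypes=haps,
    )


def _kernel_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


def meiosis(panel: HaplotypePanel, individual: int, gmap: GeneticMap,
            rng: np.random.Generator, mutation_rate: float = 0.0) -> np.ndarray:
    """One gamete from one parent: a recombinant mosaic of its two haplotypes."""
    rows = np.array([individual], dtype=np.int64)
    gam = drop_gametes(panel.haplotypes, rows, gmap.chrom_starts, gmap.position,
                       gmap.chrom_lengths, mutation_rate, _kernel_seed(rng))
    return gam[0]


def mate(sire_panel: HaplotypePanel, sire_rows: np.ndarray,
         dam_panel: HaplotypePanel, dam_rows: np.ndarray,
         n_offspring: int, gmap: GeneticMap, rng: np.random.Generator,
         breed_code: int, generation: int | None = None,
         mutation_rate: float = 0.0, id_start: int = 0) -> HaplotypePanel:
    """Random mating: each offspring draws an independent uniform (sire, dam) pair.

    Sires and dams may live in different panels (crossbreeding).  Sexes are
    assigned half male / half female; offspring generation defaults to
    sire_panel.generation + 1.
    """
    sire_rows = np.asarray(sire_rows, dtype=np.int64)
    dam_rows = np.asarray(dam_rows, dtype=np.int64)
    if sire_rows.size == 0 or dam_rows.size == 0:
        raise ConfigurationError("need at least one sire and one dam")
    if n_offspring <= 0:
        raise ConfigurationError("n_offspring must be positive")
    s_pick = sire_rows[rng.integers(0, sire_rows.size, n_offspring)]
    d_pick = dam_rows[rng.integers(0, dam_rows.size, n_offspring)]
    gam_s = drop_gametes(sire_panel.haplotypes, s_pick, gmap.chrom_starts,
                         gmap.position, gmap.chrom_lengths, mutation_rate,
                         _kernel_seed(rng))
    gam_d = drop_gametes(dam_panel.haplotypes, d_pick, gmap.chrom_starts,
                         gmap.position, gmap.chrom_lengths, mutation_rate,
                         _kernel_seed(rng))
    gen = sire_panel.generation + 1 if generation is None else generation
    return _new_panel_from_gametes(gam_s, gam_d, sire_panel.ids[s_pick],
                                   dam_panel.ids[d_pick], breed_code, gen, id_start)


def random_mating_generation(panel: HaplotypePanel, n_offspring: int,
                             gmap: GeneticMap, rng: np.random.Generator,
                             mutation_rate: float = 0.0,
                             breed_code: int | None = None,
                             id_start: int = 0) -> HaplotypePanel:
    """One generation of random union of gametes (Wright-Fisher style).

    Both parents of each offspring are drawn uniformly from the whole panel,
    independently; used for the historical population and breed expansion
    where the sexes play no role.
    """
    rows = np.arange(panel.n_individuals, dtype=np.int64)
    code = panel.breed[0] if breed_code is None else breed_code
    return mate(panel, rows, panel, rows, n_offspring, gmap, rng, code,
                mutation_rate=mutation_rate, id_start=id_start)


def select_top(panel: HaplotypePanel, scores: np.ndarray,
               n_males: int, n_females: int) -> np.ndarray:
    """Rows of the top-scoring n_males males and n_females females.

    Ties are broken by ascending individual id.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.shape[0] != panel.n_individuals:
        raise SelectionError("scores not aligned to candidates")
    selected = []
    for rows, need, label in ((panel.males, n_males, "males"),
                              (panel.females, n_females, "females")):
        if rows.size < need:
            raise SelectionError(
                f"need {need} {label} but only {rows.size} available")
        order = np.lexsort((panel.ids[rows], -scores[rows]))
        selected.append(rows[order[:need]])
    return np.concatenate(selected)


def found_breeds(historical: HaplotypePanel, gmap: GeneticMap,
                 rng: np.random.Generator, n_founders: int = 100,
                 n_expansion_generations: int = 100,
                 n_candidates: int = 1000) -> tuple[HaplotypePanel, HaplotypePanel]:
    """Found breeds A and B from the historical population.

    Two disjoint random samples of ``n_founders`` animals are drawn, each is
    randomly mated at constant size for ``n_expansion_generations``
    generations, then expanded in one round of random mating to
    ``n_candidates`` generation-0 selection candidates.  No mutation is
    applied after the historical phase.
    """
    if historical.n_individuals < 2 * n_founders:
        raise ConfigurationError(
            f"historical population of {historical.n_individuals} cannot supply "
            f"2 x {n_founders} disjoint founders")
    pick = rng.choice(historical.n_individuals, size=2 * n_founders, replace=False)
    panels = []
    for b, code in ((0, BREED_A), (1, BREED_B)):
        sub = historical.subset(pick[b * n_founders:(b + 1) * n_founders])
        sub = replace(sub, breed=np.full(n_founders, code, dtype=np.int8),
                      generation=0)
        for _ in range(n_expansion_generations):
            sub = random_mating_generation(sub, n_founders, gmap, rng,
                                           breed_code=code)
        if n_candidates != n_founders:
            sub = random_mating_generation(sub, n_candidates, gmap, rng,
                                           breed_code=code)
        sub = replace(sub, generation=0)
        panels.append(sub)
    return panels[0], panels[1]


def export_ped_map(panel: HaplotypePanel, gmap: GeneticMap, prefix: str) -> None:
    """Write PLINK PED/MAP text files (alleles 1/2, phased order preserved)."""
    with open(f"{prefix}.map", "w") as fh:
        for j in range(gmap.n_loci):
            cm = gmap.position[j] * 100.0
            fh.write(f"{gmap.chromosome[j] + 1}\tL{j}\t{cm:.6f}\t{j + 1}\n")
    sex_code = np.where(panel.sex == _SEX_MALE, 1, 2)
    with open(f"{prefix}.ped", "w") as fh:
        for i in range(panel.n_individuals):
            row = [str(panel.breed[i]), str(panel.ids[i]), str(panel.sire[i]),
                   str(panel.dam[i]), str(sex_code[i]), "0"]
            h = panel.haplotypes[i] + 1
            alleles = np.empty(2 * panel.n_loci, dtype=np.uint8)
            alleles[0::2] = h[0]
            alleles[1::2] = h[1]
            row.extend(map(str, alleles))
            fh.write(" ".join(row) + "\n")
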