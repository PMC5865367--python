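"""Simulate the historical population and found the two breeds.

Builds the neutral base: 2000 generations of random mating at N = 2000
over ~8800 biallelic loci on four 1-Morgan chromosomes with recurrent
mutation, then founds breeds A and B from 100 animals each and lets them
drift apart for 100 generations.  Prints the polymorphism available for
the marker panel and the realized breed divergence.

Run:  python examples/01_base_population.py   (about one minute)
"""
import numpy as np

from heterosim import (GenomeConfig, found_breeds, sample_architecture,
                       simulate_historical)

rng = np.random.default_rng(1)
cfg = GenomeConfig()
print(f"historical population: N={cfg.historical_size}, "
      f"{cfg.historical_generations} generations, "
      f"{cfg.n_candidate_loci} candidate loci ...")
hist, gmap = simulate_historical(cfg, rng)
p = hist.allele_frequencies()
maf = np.minimum(p, 1 - p)
print(f"  mean heterozygosity {hist.mean_heterozygosity():.3f}; "
      f"{(maf > 0.05).sum()} loci with MAF > 0.05 "
      f"(need {cfg.n_snps_target + cfg.n_qtl_target})")

gmap = sample_architecture(hist, gmap, cfg, rng)
print(f"  architecture: {gmap.snp_indices.size} SNPs + "
      f"{gmap.qtl_indices.size} QTL, disjoint, per chromosome "
      f"{gmap.snp_indices.size // 4}/{gmap.qtl_indices.size // 4}")

pa, pb = found_breeds(hist, gmap, rng)
qa = pa.allele_frequencies(gmap.qtl_indices)
qb = pb.allele_frequencies(gmap.qtl_indices)
pbar = (qa + qb) / 2
fst = np.mean((qa - qb) ** 2 / 4) / np.mean(pbar * (1 - pbar))
print(f"breeds founded: {pa.n_individuals} candidates each; "
      f"QTL-frequency F_ST between breeds {fst:.2f} "
      f"(drift expectation t/(t+4N) = {100 / (100 + 400):.2f})")
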