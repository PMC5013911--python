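# microbeta

Distance-based association testing for microbial community composition:

* **Six beta-diversity distances** — Bray-Curtis, Jaccard, weighted /
  generalized / unweighted UniFrac, and **presence-weighted UniFrac**
  `D_PW(alpha)`, which weights each tree branch by the relative richness
  difference `|n_jl - n_kl| / (n_jl + n_kl)` of the present-OTU counts below
  it, with `alpha` attenuating high-richness branches.
* **Pseudo-F permutation tests** on any distance matrix, with flexible
  confounder adjustment: residual permutation with refitting for continuous
  covariates, a parametric bootstrap of the fitted logistic model for binary
  covariates, and within-stratum permutation for paired / repeated designs.
* **A multi-distance omnibus test** that uses the minimal single-distance
  P-value as its statistic, calibrated by one shared set of permutations
  across all distances with a multistage escalation of the permutation count
  (plus Bonferroni and maxF comparators).
* **A simulation harness** — Dirichlet-multinomial community generation,
  PAM lineage partitioning on patristic distances, three richness/evenness
  differentiation patterns, confounded group assignment, and
  type-I-error / power experiment drivers.

## Library quick start

```python
import numpy as np
from microbeta import (read_otu_table, read_tree, DistanceSpec, distance_matrices,
                       TestSpec, UnifiedConfig, unified_test)

table = read_otu_table("table.tsv")            # samples x OTUs, TSV
tree = read_tree("tree.nwk")                   # Newick with branch lengths
specs = [DistanceSpec.parse(s) for s in
         ["w_unifrac", "bray_curtis", "pw_unifrac:1", "pw_unifrac:0",
          "uw_unifrac", "jaccard"]]
mats = distance_matrices(table, specs, tree)

x = np.array([...])                            # covariate per sample, 0/1
spec = TestSpec(x=x, kind="binary", z=None, b=500, seed=1)
res = unified_test(mats, spec, UnifiedConfig(distances=specs, seed=1))
print(res.p_values, res.p_unified, res.p_bonferroni, res.b_final)
```

Confounders: pass `z=` (an n x q matrix) in `TestSpec`; continuous covariates
use residual permutation (`freedman_lane_test`), binary ones the parametric
bootstrap (`parametric_bootstrap_test`). Paired designs: pass `strata=`.

## Command line

```bash
microbeta simulate --n 20 --depth 1000 --out-dir sim/        # synthetic fixtures
microbeta distances --table sim/table.tsv --tree sim/tree.nwk \
    --distances w_unifrac,pw_unifrac:1,pw_unifrac:0 --out-dir dist/
microbeta test --table sim/table.tsv --metadata sim/metadata.tsv \
    --covariate group --covariate-type binary --distance bray_curtis \
    -B 999 --seed 1 --out-dir run/
microbeta unified --table sim/table.tsv --tree sim/tree.nwk \
    --metadata sim/metadata.tsv --covariate group --covariate-type binary \
    -B 500 --tol 0.1 --seed 1 --out-dir run/
microbeta experiment --kind type1 --reps 200 -B 500 --out type1.tsv
```

Every command writes TSV outputs plus a JSON manifest; identical
configuration + seed reproduces outputs byte-for-byte. Distance matrices can
be written once (`--save-distances`) and reused via `--distance-matrix`.

`--rarefy-depth` rarefies the table for the presence-absence distances only
(abundance distances use the unrarefied counts), the recommended practice for
mixed-depth data.

## Notes

* The synthetic Dirichlet-multinomial parameters are a deterministic
  stand-in (no real-data estimates are bundled): 20 phylogenetic lineages with abundance shares from 19.7% down to
  0.9%, dispersion 0.02. `fit_dm_moments` fits DM parameters to your own
  table if you want to simulate from something closer to your data.
* P-value conventions: single-distance tests report the add-one permutation
  p-value (ties counted as exceedances) plus the literal strict proportion;
  the omnibus p-value is the proportion of permuted min-P statistics below
  the observed one and can never undercut it.
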