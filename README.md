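# guildaging

Guild-based analysis of gut-microbiome aging for 16S cohort studies: from an
OTU count table and sample metadata to co-abundance guilds, age-related guild
signatures, a sex-specific random-forest **microbial age**, and downstream
health and lifestyle associations. It is written for microbiome
epidemiologists who want the full chain — compositional network inference,
tree-cut guild construction, diversity and abundance modelling, and
prospective survival analysis — as one tested, reproducible pipeline, plus a
synthetic cohort generator so every stage can be validated without access to
restricted cohort data.

## The method

Taxon-level analyses treat all strains of a taxon as one variable, which can
mask opposing strain-level effects. Here bacteria are grouped instead into
**guilds**: groups of co-abundant OTUs that respond coherently to
perturbations.

1. **Co-abundance network (SparCC).** For prevalent OTUs (nonzero in ≥ 20% of
   samples) correlations are estimated from log-ratio variances
   t_ij = Var log(x_i/x_j) = ω_i² + ω_j² − 2 ρ_ij ω_i ω_j, with basis
   variances ω² solved by least squares under a sparsity assumption and
   strongly correlated pairs iteratively excluded. Edges require a
   permutation p < 0.05 and |ρ| > 0.4; edge weight is |ρ|.
2. **Guilds.** The distance D = 1 − ρ is clustered with Ward's algorithm and
   the tree is cut top-down: each split is kept while PERMANOVA finds the two
   child clades heterogeneous (p < α) and both meet a size floor. Each guild
   gets a dominant OTU (highest weighted degree, falling back to mean
   relative abundance). Partitions are compared by 1 − NVI, where
   NVI = VI/log n is the normalized variation of information.
3. **Diversity and associations.** Guild tables are rarefied; Chao1, Shannon,
   Pielou evenness, Bray–Curtis dissimilarity, per-sample uniqueness (minimum
   Bray–Curtis to any other sample), PCoA with an age arrow, and PERMANOVA.
   Guild abundances are CLR-transformed (zeros → 0.5) and regressed on age
   with covariates, per sex and with an age × sex interaction, under BH-FDR.
4. **Microbial age.** Per sex, a random forest (ntree = 1000, mtry = p/3)
   predicts chronological age from the age-related guilds (raw p < 0.05);
   healthy training samples are scored out-of-bag. An OLS line of microbial
   age on chronological age over healthy samples defines the *average healthy
   microbial age*; deviation > 0 labels a sample "old", otherwise "young".
5. **Outcomes.** A healthy lifestyle index (HLI 0–4: exercise, non-smoking,
   non-drinking, healthy diet) is linked to microbial age by regression;
   residual life expectancy is the area under the conditional survival curve
   from age 45 to 100 under a parametric fit; incident diabetes with death as
   a competing event is summarised by Aalen–Johansen cumulative incidence and
   a cause-specific Cox model.

## Worked example

```python
from guildaging.synth import SynthConfig, generate_cohort
from guildaging.sparcc import estimate_correlations, sparcc_pvalues
from guildaging.network import build_network, connectivity
from guildaging.guilds import correlation_to_distance, ward_tree, cut_by_permanova, nvi

cfg = SynthConfig(n_samples=300, n_otus=120, n_guilds=6,
                  guild_size_range=(15, 20), seed=42)
table, meta, truth = generate_cohort(cfg)

res = estimate_correlations(table)                      # SparCC correlations
sparcc_pvalues(table, res, n_permutations=99, seed=42)  # permutation p-values
net = build_network(res)                                # |rho| > 0.4, p < 0.05

D = correlation_to_distance(res)                        # D = 1 - rho
part = cut_by_permanova(ward_tree(D), D, seed=42)       # Ward + PERMANOVA cut
rep = connectivity(net, part.assignment)

print(f"guilds found: {part.n_guilds} (planted: 6, "
      f"similarity 1-NVI vs truth = {1 - nvi(part, truth):.3f})")
print(f"network: {rep.n_edges} edges, {rep.weighted_edges:.1f} weighted edges, "
      f"{100 * rep.intra_weighted / rep.weighted_edges:.1f}% intraguild")
```

Output:

```
guilds found: 9 (planted: 6, similarity 1-NVI vs truth = 0.962)
network: 979 edges, 653.5 weighted edges, 95.6% intraguild
```

The six planted co-abundance blocks are recovered almost exactly (a 1 − NVI
of 0.962 means the few extra guilds are small sub-splits of true blocks),
and nearly all of the network's edge weight lies within guilds, as expected
when guilds capture the co-abundance structure.

The same pipeline runs end-to-end from the shell:

```bash
guildaging all --config config.yaml --seed 42 --outdir out/
```

writing per-stage TSV/JSON artifacts and manifests (`synth`, `guilds`,
`diversity`, `assoc`, `age`, `outcomes` can also be run individually).
Re-running with the same config and seed reproduces every artifact
byte-for-byte.

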