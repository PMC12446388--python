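# domainrates

Domain-partitioned evolutionary rate analysis for protein families.

The package implements a small comparative molecular-evolution pipeline
around vertebrate TRPA1:

- **Substitution model** (`domainrates.substitution`): the JTT empirical
  amino-acid model (embedded as a plain-text data file), reversible rate
  matrix construction, stable eigendecomposition-based `P(t) = exp(Qt)`,
  and maximum-likelihood pairwise distances with complete or pairwise gap
  deletion.
- **Tree machinery** (`domainrates.trees`): deterministic neighbor joining,
  Felsenstein-pruning log-likelihoods, round-robin ML branch-length
  optimization, patristic / root-to-tip distances, midpoint and outgroup
  rooting (trees are [dendropy](https://dendropy.org) objects).
- **Domain rates** (`domainrates.domain_rates`): reference-anchored region
  slicing of an MSA and per-clade-group region/full-length distance-ratio
  reports (for each region: slice → ML distances → NJ → ML branch lengths →
  group summaries → ratios).
- **Residue scan** (`domainrates.residue_scan`): locate the alignment column
  homologous to a reference residue (human TRPA1 position 878 by default),
  classify V/G/other/gap per taxon, and tabulate against clade groups and
  thermal-sensitivity labels.
- **Simulator** (`domainrates.simulate`): clade-structured protein
  alignments evolved under the model along random trees, with per-region
  rate multipliers in designated clades and an optionally planted diagnostic
  column; this provides the offline acceptance surface.
- **IO and annotations** (`domainrates.io`): FASTA / aligned FASTA, Newick,
  tab-separated clade-group and thermal-label tables, YAML domain maps, and
  packaged defaults (26-group vertebrate clade table, human TRPA1 domain map
  with 16 ankyrin-repeat entries, climate table).

The packaged domain-map interval boundaries are illustrative placeholders —
edit `src/domainrates/data/domain_map.yaml` before interpreting real-data
results. All quantitative tests use simulator-defined maps.

## Command line

```sh
# synthetic fixtures (alignment + tree + tables in one directory)
domainrates simulate --fixture marine --seed 1 --out fx/
domainrates simulate --fixture residue --seed 1 --out fxr/

# region/full-length rate-ratio report
domainrates domain-rates --alignment msa.fasta --groups groups.tsv \
    --domains domains.yaml --regions ARD1_9,ARD10_16_linker,S1_S6_COOH \
    --scheme mean_pairwise_within_group --deletion complete --out report/

# diagnostic-residue scan
domainrates residue-scan --alignment msa.fasta --groups groups.tsv \
    --reference human_TRPA1 --position 878 --out scan/

# temperature-table averages (packaged table by default)
domainrates climate
```

All report files are tab-separated with `#`-prefixed provenance headers
(config hash, schemes, per-region trees written alongside).

Real sequence data is always user-supplied (aligned FASTA); the package
never downloads anything.

## Notes on defaults

- Distances: complete deletion within each analyzed region; `pairwise`
  selectable. `X` and gaps are excluded from likelihood columns.
- Distance summaries default to `mean_pairwise_within_group`; root-to-tip
  distances from a midpoint root are available via `--scheme root_to_tip`
  but inflate systematically on short noisy region slices (the midpoint
  chases the longest path), which is why they are not the default.
- ML distance optimization is bounded on t ∈ [0, 20] (absolute tolerance
  1e-6); hitting the bound flags the pair as saturated.
- Topologies are rebuilt per region by NJ (deterministic, smallest-index
  tie-breaking, negative branch lengths clamped with the deficit moved to
  the sibling); `--shared-topology` reuses the full-length topology.
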