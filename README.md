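# protniche

Comparative proteome profiling for archaea (and prokaryotes generally):
a tested, reusable implementation of the classic comparative-genomics
workflow used to search for lineage- and niche-specific proteome
signatures — e.g. the contrast between methane-producing and
sulphur-metabolising archaea.

It is aimed at researchers who have per-organism predicted proteomes
(protein FASTA), COG annotations and organism metadata, and want the whole
downstream analysis as composable, unit-tested Python instead of a chain of
one-off tools.

## What it computes

- **Amino-acid usage** (`aa_usage`): residue-weighted relative frequencies
  per organism (rows sum to 1), column z-scores for heat maps, the
  GC-unbiased reduction to the eight residues whose codons carry no G+C
  bias (Val, Ser, Thr, His, Gln, Asp, Glu, Cys; the other twelve pooled
  into an `other` column), and per-group extreme summaries
  (highest/lowest group mean per residue, in %).
- **Physico-chemical indices** (`physchem`): per-protein isoelectric point
  (bisection root of the Henderson–Hasselbalch net charge
  `Q(pH) = Σ_pos n_g/(1+10^(pH−pKa_g)) − Σ_neg n_g/(1+10^(pKa_g−pH))`,
  EMBOSS pKa set, swappable), GRAVY (mean Kyte–Doolittle hydropathy),
  aromaticity (F+Y+W fraction), aliphatic index
  `100·(X_A + 2.9·X_V + 3.9·(X_I + X_L))`, Guruprasad instability index;
  binned pI distributions (half-open 0.5-pH bins over [2, 14], percentages)
  and group mean ± SD profiles.
- **Multivariate structure** (`multivariate`): complete-linkage clustering
  on Euclidean distances (documented lexicographic tie-break, Newick
  export) and correspondence analysis from first principles — SVD of
  `S = D_r^{−1/2}(P − r cᵀ)D_c^{−1/2}`, per-axis inertia percentages, and
  Pearson correlations of axes with covariates such as genomic GC.
- **Directional substitution bias** (`substitution`): ortholog filtering
  (similarity ≥ 40%, length difference < 20%, e-value ≤ 1e-10),
  deterministic Needleman–Wunsch alignment (BLOSUM62, affine gaps), a
  20×20 directed replacement-count matrix, and for each of the 190
  unordered residue pairs the forward/reverse ratio, gain and a 1-df
  chi-square against the 1:1 null, with top-k tables by gain and by ratio.
- **COG repertoires** (`cog_repertoire`): per-organism functional-category
  percentage profiles, group mean ± SD, core COGs (intersection),
  group-exclusive core COGs, and 4-way Venn partitions.
- **Synthetic data** (`synthetic_data`): GC-driven proteome simulator
  (codon weights ∝ g^GC·(1−g)^AT over the 61 sense codons), ortholog pairs
  with an injected directional replacement preference and exact truth
  counts, planted COG universes, and whole study bundles — everything the
  pipeline reads can be generated deterministically from a seed.

## Worked example

```python
import json, numpy as np
from protniche.synthetic_data import StudySpec, simulate_study
from protniche.io_core import read_proteome_fasta
from protniche.aa_usage import compute_relative_usage, build_usage_matrix
from protniche.multivariate import correspondence_analysis, axis_variable_correlation
from protniche.physchem import isoelectric_point

bundle = simulate_study(StudySpec(seed=42), "demo_bundle")
profiles, gc = [], []
for org, path in bundle.proteome_paths.items():
    proteome = read_proteome_fasta(path)
    profiles.append(compute_relative_usage(proteome))
    gc.append(bundle.truths[org].realized_gc)

ca = correspondence_analysis(build_usage_matrix(profiles))
print(f"axis 1 inertia: {ca.inertia_percent[0]:.2f}%")
corr = axis_variable_correlation(ca.row_scores, 1, gc, "GC")
print(f"axis 1 vs GC: r = {corr.r:.3f} (p = {corr.p_value:.2e})")

groups = json.loads(bundle.manifest_path.read_text())["groups"]
for grp in ("methanogen", "sulphur_metaboliser"):
    pis = [isoelectric_point(r.sequence)
           for org, g in groups.items() if g == grp
           for r in read_proteome_fasta(bundle.proteome_paths[org])]
    print(f"{grp}: mean pI = {np.mean(pis):.2f}")
```

prints

```
axis 1 inertia: 78.21%
axis 1 vs GC: r = 0.996 (p = 1.83e-07)
methanogen: mean pI = 7.83
sulphur_metaboliser: mean pI = 12.15
```

The first CA axis of the usage matrix is almost perfectly aligned with
genomic GC — the dominant force on amino-acid composition — while the two
planted metabolic groups separate in proteome-wide isoelectric point: the
acidic-planted (methanogen-like) group sits well below the basic-planted
(sulphur-metaboliser-like) group, the charge contrast the analysis is
designed to expose.

The same pipeline is scriptable from the shell:

```bash
protniche simulate --seed 3 --out bundle
protniche usage bundle/proteomes/*.fasta --out results/usage
protniche spast bundle/ortholog_source.fasta bundle/ortholog_target.fasta \
    --hit-table bundle/hits.tsv --out results/spast
protniche cogs bundle/cogs/*.tsv --metadata bundle/metadata.tsv --out results/cogs
```

which reports, for example, `8 organisms; axis1 inertia 78.60%`,
`40 ortholog pairs, 1804 replacements` and
`methanogen: 60 core, 5 exclusive COGs` for that seed.

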