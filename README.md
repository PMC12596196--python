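# modulome

Robust independent component analysis (ICA) of bulk RNA-seq compendia:
inference of **iModulons** — independently modulated gene sets, the
data-driven analogue of regulons — together with statistical gene-membership
calling, regulon enrichment against a known transcriptional regulatory
network (TRN), and condition-level analysis of module activities. The
package targets microbial transcriptomics (it was built around a
*Bacteroides thetaiotaomicron* compendium workflow) but is organism-agnostic:
any genes × samples log-TPM matrix with sample metadata works.

## The model

A reference-centered log₁₀(TPM + 1) expression matrix **X** (genes ×
samples) is factored as

    X ≈ M · A

where the columns of **M** (genes × K) are gene-weight vectors and the rows
of **A** (K × samples) are condition-dependent activities. Robustness comes
from an ensemble of FastICA runs with random seeds (default 100 runs,
tolerance 10⁻⁷): the pooled components are clustered with DBSCAN under the
distance

    d(x, y) = 1 − |ρ(x, y)|        (absolute Pearson correlation)

with ε = 0.1 and a minimum cluster seed size of 50; each sufficiently
recurrent cluster becomes one robust component, and **A** is the
least-squares projection of **X** onto the consensus **M**. Each component's
member genes are the outliers of its weight vector, found by iteratively
stripping the largest |weight| genes until the D'Agostino K² normality
statistic of the remainder drops below a cutoff. Member sets are scored
against curated regulons with one-sided Fisher's exact tests
(Benjamini–Hochberg FDR; components with best q < 10⁻⁴ are "regulatory"),
summarized by iModulon recall |members ∩ regulon|/|members| and regulon
recall |members ∩ regulon|/|regulon|, and classified into four groups at a
0.7 cut (well-matched / regulon subset / unknown-containing / closest
match). Member genes of an enriched regulator absent from the curated TRN
count as novel regulator–target predictions.

A synthetic-data module generates planted-module compendia (sparse
heavy-tailed gene weights, condition-block activities, Gaussian noise, and
a planted TRN with exact/extended/partial/unrelated regulon classes) so the
whole pipeline is verifiable end to end without downloads.

## Worked example

```python
import modulome as m

ds = m.generate(n_genes=2000, n_samples=120, k_modules=10,
                module_size_range=(10, 30), effect_size=5.0,
                noise_sd=0.25, seed=42)
xc = ds.centered()
runs = m.run_ensemble(xc, dimension=10, n_runs=20)
decomp = m.cluster_components(runs, xc, min_cluster_size=10)
print(f"robust components: {decomp.K}")
print(f"explained variance: {m.explained_variance(xc, decomp):.3f}")

imodulons = m.build_imodulons(decomp)
result = m.match_components(decomp.M, ds.M_star)
print(f"matched planted modules: {result.matched_fraction:.2f}")
print(f"mean membership F1: {result.membership_f1.mean():.2f}")

enriched = m.enrich_all([im for im in imodulons if im.members], ds.trn_star)
regulatory = [r for r in enriched if r.is_regulatory]
print(f"regulatory iModulons: {len(regulatory)} / {decomp.K}")
total, novel, frac = m.count_trn_expansion(regulatory, imodulons, ds.trn_star)
print(f"TRN expansion: {total} associations, {novel} novel ({100*frac:.1f}%)")
```

prints

```
robust components: 10
explained variance: 0.806
matched planted modules: 1.00
mean membership F1: 1.00
regulatory iModulons: 10 / 10
TRN expansion: 243 associations, 33 novel (15.7%)
```

All 10 planted modules are recovered as robust components with exact
member sets; the reconstruction explains 80.6% of the centered matrix's
variance (the remainder is planted measurement noise); every module is
significantly enriched for its planted regulator; and the members that the
generator deliberately left out of the "partial" regulons come back as
novel regulator–target predictions, expanding the planted TRN by 15.7%.

## Command line

The same stages are available as subcommands driven by one YAML config
(all randomness flows from a single seed; every run writes a manifest):

```sh
modulome simulate --out synth --seed 7
modulome run --config config.yaml            # decompose → threshold → enrich → activities
modulome decompose --config config.yaml      # or stage by stage
modulome evaluate --recovered out/M.tsv --truth synth/M_star.tsv
```

Outputs are plain text: `M.tsv`, `A.tsv`, `imodulons.json`,
`enrichment.tsv`, `trn_expansion.json`, activity clustering tables, and
`manifest.json` with parameters and input checksums.

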