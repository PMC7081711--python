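"""Link disease-specific CpGs to transcripts and region sets.

Promoter windows (-2.5 kb, +0.5 kb around the TSS) connect called CpGs to
genes; Pearson correlation across tumors (|r| >= 0.7, p < 0.05) keeps the
genes whose expression tracks promoter methylation.  Region-set enrichment
uses a two-sided Fisher test with all retained probes as background, and
pri-miRNA promoters are promoter segments within 100 kb upstream of the
miRNA TSS, tested with Spearman (|rho| >= 0.35).
"""

from methylcoom import (
    SimulationConfig, assign_mirna_promoters, call_classes, compute_deltas,
    correlate, filter_probes, infer_coo_methylome, place_samples,
    promoter_windows, refit_with_linear_cpgs, region_enrichment,
    simulate_scenario,
)

scenario = simulate_scenario(SimulationConfig(n_probes=5000, seed=0, tumor_noise_sd=0.05,
                                              planted_counts={"A": 120, "B": 25, "C": 100, "D": 25}))
ref = filter_probes(scenario.ref, scenario.annotation)
axis, model, table = refit_with_linear_cpgs(ref, scenario.sheet)
cpgs = list(table.index[table["linear"]])
assignments = place_samples(scenario.tumors, ref, scenario.sheet, axis, cpgs)
coo = infer_coo_methylome(model, assignments)
calls = call_classes(compute_deltas(scenario.tumors, coo), table["dynamic"])

pmap = promoter_windows(scenario.genes, scenario.annotation)
pairs = (pmap[["gene_id", "probes"]].explode("probes").dropna()
         .rename(columns={"gene_id": "feature_id", "probes": "probe_id"}))
corr = correlate(scenario.tumors, scenario.expr_tumor, pairs, method="pearson")
passing = sorted(set(corr.loc[corr["passes"], "feature_id"]))
planted = set(scenario.gene_truth.index[scenario.gene_truth["planted"]])
print(f"genes passing the Pearson rule: {len(passing)} "
      f"({len(planted & set(passing))} of {len(planted)} planted)")

enr = region_enrichment(calls, scenario.annotation, scenario.region_sets, classes=("A",))
for row in enr.itertuples(index=False):
    print(f"class A in {row.region_set}: fold change {row.fold_change:.2f}, "
          f"Fisher p {row.fisher_p:.2e}")

pmap_m = assign_mirna_promoters(scenario.segment_sources, scenario.mirna_tss,
                                scenario.annotation)
pairs_m = (pmap_m[["mirna_id", "probes"]].explode("probes").dropna()
           .rename(columns={"mirna_id": "feature_id", "probes": "probe_id"})
           .drop_duplicates())
corr_m = correlate(scenario.tumors, scenario.mirna_expr, pairs_m,
                   method="spearman", r_threshold=0.35)
print(f"miRNAs passing the Spearman rule: "
      f"{corr_m.loc[corr_m['passes'], 'feature_id'].nunique()}")
# a fold change far above 1 with small p marks the region set as enriched
# for class A hypomethylation; passing genes/miRNAs are the candidate
# epigenetically deregulated transcripts.
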