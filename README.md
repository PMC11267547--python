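# slctools

Compilation and scoring of tool compounds for human solute carrier (SLC)
transporters.

The SLC superfamily (>455 genes in 66 families) moves nutrients, ions and
metabolites across cell membranes, yet potent, selective, well-characterised
inhibitors — *tool compounds* — are scarce, and the dose–response data that
exist are scattered across heterogeneous databases. `slctools` implements a
reproducible pipeline that ingests bioactivity exports in three source
dialects (ChEMBL-activities-like, Guide-to-Pharmacology-interactions-like,
PubChem-bioactivities-like), harmonises them into per-compound/per-target
potency summaries, scores selectivity, applies tool-compound criteria and
emits a full inhibitor table, a shortlist and a dashboard-ready JSON
payload.

## What it computes

Potencies are standardised to pActivity, the negative base-10 log of the
molar value: a potency of *v* nM maps to `p = 9 − log10(v)` (200 nM ↔
6.699). After source-specific inclusion filters (human targets, assay
confidence ≥ 7, no validity comments, excluded depositors, nM units after
exact µM→nM conversion), records of type pIC50/pKi/pEC50/pKd are pooled,
mutant-assay rows dropped, exact duplicates removed on the six-field key
(type, value, parent compound, SMILES, gene, accession), and the **median
pActivity** per (compound, target) pair is taken.

Each compound is then scored by its **selectivity entropy**: with
association weights `K_i = 10^{p_i}` and fractions `φ_i = K_i / Σ_j K_j`,

    S = − Σ_i φ_i ln φ_i   (nats),

computed once over its SLC targets (`S_SLCs`) and once over all targets
(`S_other`). S is 0 for a single-target compound and ln n for n equipotent
targets, and is invariant under unit changes. Because most compounds were
tested on very few targets, a low entropy alone does not prove
selectivity; a **Pareto ranking** (non-dominated sorting) therefore
minimises the two entropies while maximising the best SLC pActivity and
the number of SLCs tested.

A compound is shortlisted as a potential tool compound when

1. its primary (most potent) reported target is the SLC of interest,
2. the median potency there is **≤ 200 nM** (inclusive),
3. it is **≥ 30-fold** selective against the best other tested SLC
   (vacuous when only one SLC was tested), and
4. its structure matches **no PAINS** substructure (SMARTS filters; a
   missing/unparseable structure blocks shortlisting by default).

The package also implements the plate-QC formulas used to validate
screening assays: `%Activity = 100·(x − MIN)/(MAX − MIN)` against control
medians, and the robust Z′ factor
`RZ′ = 1 − 3·(RSD_max + RSD_min)/|median_max − median_min|` with robust
SD = 1.4826·MAD.

## Worked example

All inputs can be simulated — the generator plants ground truth (boundary
potencies, duplicates, mutant rows, PAINS positives) so the whole pipeline
is testable offline:

```
$ slctools simulate --out demo_bundle --seed 7
bundle written to demo_bundle (41 scored compounds)

$ slctools run --chembl demo_bundle/chembl_activities.csv \
    --gtopdb demo_bundle/gtopdb_interactions.csv \
    --pubchem demo_bundle/pubchem_bioactivities.csv \
    --slc-table demo_bundle/slc_table.tsv \
    --substance-to-cid demo_bundle/substance_to_cid.tsv \
    --cid-to-chembl demo_bundle/cid_to_chembl.tsv \
    --child-to-parent demo_bundle/child_to_parent.tsv \
    --pains demo_bundle/pains.smarts --curated demo_bundle/curated.csv \
    --out demo_out
full list: 93 rows, tool compounds: 11 of 41 compounds shortlisted
```

The run writes `full_inhibitor_list.csv`, `tool_compounds.csv`,
`scores.csv`, `flags.csv`, `marginal_counts.csv` (unique molecules and
tool compounds by number of SLCs tested), `dashboard.json` (ranked
activities plus per-compound and per-target panels) and
`filter_report.json` (every exclusion count). For this bundle the marginal
table starts

```
n_slcs_tested,unique_molecules,unique_tool_compounds
1,20,5
2,9,3
3,5,1
```

i.e. 20 of the 41 compounds were tested on a single SLC (so their entropy
of 0 cannot be read as evidence of selectivity), and 5 of them pass the
tool-compound criteria. The shortlist includes the planted boundary cases:
`CHEMBL800001` at exactly 200 nM on one SLC (pActivity 6.69897, entropy 0)
and `CHEMBL800003` at exactly 30-fold between two SLCs.

The same steps are available as library functions (`generate_source_bundle`,
`run_pipeline`, `selectivity_entropy`, `pareto_rank`, `evaluate_criteria`,
`robust_z_prime`, ...).

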