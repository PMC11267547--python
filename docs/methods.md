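# Methods

This note documents the models, conventions and design choices behind
`slctools`, in the order the pipeline applies them.

## Source ingestion

Live database access is replaced by file contracts: each loader consumes
an exported CSV in a fixed dialect (column registries in
`slctools.ingest`) plus an offline identifier map of three two-column
TSVs (substance→CID, CID→canonical accession, child→parent). This makes
every inclusion rule a testable predicate rather than a query against a
moving service.

Inclusion rules, per source:

- **ChEMBL dialect** — human organism (case-insensitive "Homo sapiens" or
  "Human"), assay confidence score ≥ 7, empty data-validity comment, not
  flagged as a potential duplicate, depositor source codes 7 (PubChem
  mirror) and 58 (consortium deposits) excluded, activity type in
  {IC50, Ki, EC50, Kd}, units nM after exact ×1000 µM→nM conversion. Any
  other unit excludes the row with a logged reason; guessing conversions
  for e.g. µg/mL would require molecular weights the export does not
  carry.
- **Interactions dialect** — human SLC targets only; affinity ranges are
  replaced by the arithmetic mean of their endpoints; rows with
  qualifier-style or missing units are excluded with a logged reason
  rather than interpreted.
- **Bioassay dialect** — targets restricted to Entrez IDs in the SLC
  reference table; assays deposited by the other two sources dropped to
  avoid double counting; missing values dropped.

Compound identity is the canonical **parent** accession (salt-stripped
forms resolve through the child→parent map). When the CID→canonical link
is missing, the CID itself keys the compound (`cid-fallback`); an
accession absent from every map is `unresolved` and the caller decides.
Resolution is idempotent: a parent resolves to itself. Every loader
reports exclusion counts such that kept + excluded = input rows.

## Harmonisation

After concatenation: (1) whitelist filter to pIC50/pKi/pEC50/pKd with
non-empty values; (2) mutant-assay filter — a case-insensitive plain
substring match for "mutant" in the assay description, which is exactly
the `*mutant*` glob; (3) exact deduplication on (type, value, parent
compound, SMILES, gene, accession), first occurrence kept, records
without a structure participating with an empty-string key; (4) median
pActivity per (compound, target) pair.

The median **pools all activity types together**; per-type medians are
retained as JSON metadata for transparency. Pooling matches a workflow
that concatenates all types before aggregating; type-specific systematic
offsets (Ki vs IC50) are deliberately not modelled. Even-count medians
use the midpoint of the central pair. Compounds never tested on at least
one SLC are removed entirely, including their non-SLC rows.

## Selectivity scoring

The selectivity entropy treats potencies as association constants
`K_i = 10^{p_i}`, normalises to fractions and takes the Shannon entropy in
nats. It is evaluated with the maximum pActivity shifted to zero before
exponentiation, which is numerically stable up to arbitrary potency
ranges and makes shift invariance exact by construction; the result is
clamped at 0 to remove the `-0.0` float artifact. `S_other` is computed
over *all* tested targets, SLCs included (the inclusive reading of
"against all proteins").

The primary target is the one with maximal median pActivity over all
targets. Exact ties are flagged (`primary_tie`) and broken
deterministically — SLC targets first, then accession order — rather than
silently. Fold selectivity is `10^(best SLC p − best other-SLC p)`,
infinite when only one SLC was tested.

Pareto ranking uses non-dominated sorting with domination counts over
four objectives: minimise `S_SLCs` and `S_other`, maximise the best SLC
pActivity and the number of SLCs tested. The "activity value" objective
is the best **SLC** potency, not the best overall potency: the ranking
exists to find SLC tool compounds, and using overall potency would reward
off-target strength. No crowding distance or within-front ordering is
applied beyond a compound-id sort for determinism. Tests check the ranks
against an independent brute-force per-front dominance oracle.

## Tool-compound criteria

Thresholds are inclusive — ≤ 200 nM and ≥ 30-fold — matching "values
≤200 nM" and "at least 30-fold". Comparisons carry a relative slack of
1e-9 so that a potency planted at exactly 200 nM still passes after the
nM → pActivity → median round trip; the slack is orders of magnitude
below any meaningful potency difference. Potency is evaluated on the
median at the compound's best SLC target, the "SLC of interest" of the
shortlist. Selectivity is vacuously satisfied when no other SLC was
tested (the flag cannot be falsified), which is why single-SLC compounds
dominate any shortlist — the marginal-count table exists precisely to
expose this.

PAINS filtering parses a user-supplied `pattern_id<TAB>SMARTS` file with
RDKit; a compound fails on any substructure match. A missing or
unparseable structure yields status `unknown`, which blocks shortlisting
by default (PAINS-freedom cannot be certified without a structure); a
config switch relaxes this. The repo ships a small five-pattern test set
covering common alert classes (rhodanine, catechol, quinone, azo,
hydrazone-phenol); the full PAINS catalog is a versioned external
artifact the user supplies in the same format.

## Curated lists and probe cross-check

Curated compound–SLC pairs join the full list on (parent accession, gene
symbol), case-insensitive on the symbol. Pairs already mined from the
databases gain a boolean provenance column; absent pairs are appended as
curated-only rows with empty activity — they appear in the full table but
are excluded from entropy/Pareto scoring, having nothing to score. The
merge is idempotent and reports overlapping + curated-only = total pairs
per list. Probe-portal pairs are cross-checked for presence, Pareto rank
and shortlist status.

## Plate QC

`%Activity` anchors the blank-control median at 0% and the
neutral-control median at 100%; values outside [0, 100] are allowed. The
robust Z′ replaces means/SDs with medians and robust SDs; the robust SD
is 1.4826 × MAD, the normal-consistent estimator, chosen as the standard
convention where the original software's estimator is unspecified.

## Synthetic bundles

The generator writes all input files with a ground-truth sidecar computed
by construction (inline arithmetic at planning time — the pipeline is
never consulted). Defaults: 32 random compounds over 18 SLC and 6 non-SLC
targets, potencies log-uniform over 1 nM–100 µM, 1–3 records per pair,
~15% PAINS-positive structures, 6 planted exact duplicates plus one
cross-source duplicate, 5 mutant rows planted at pActivity 12 so that a
missing mutant filter would visibly distort medians, and one decoy input
row per loader-exclusion reason. Boundary compounds are always planted:
exactly 200 nM single-SLC (passes), 250 nM (fails), exactly 30-fold
(passes), 10-fold (fails), a PAINS positive, an unparseable structure, a
kinase-primary compound and a kinase-only compound. µM-emitted rows use
binary-exact values (0.25, 0.5, ...) so the conversion is lossless.

What passing the ground-truth test shows: the pipeline's filters,
medians, entropies, flags, merge counts and marginal table are exactly
the planted ones. What it does not show: behaviour on real exports'
statistical texture (skewed target coverage, correlated assays, qualifier
operators, inconsistent identifiers beyond the planted cases).

## Sizes and tolerances

Numeric agreement in tests is 1e-9 absolute for medians and entropies
(pure float-pipeline error), exact for flags, ranks and counts. The
Pareto oracle check runs 100 random instances of up to 200 compounds; the
end-to-end check uses the default bundle at a fixed seed. These sizes
exercise every code path while keeping the suite around ten seconds.

## Known limitations

- No structure standardisation is performed in-repo; parenthood is
  whatever the identifier map says.
- No reconciliation of conflicting measurements beyond the median, and no
  outlier rejection.
- Percent-inhibition data (no dose–response value) are invisible to the
  workflow, a known source of missed associations.
- Dose–response curve fitting (4PL) is out of scope; only the plate-level
  normalisation and RZ′ are implemented.
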