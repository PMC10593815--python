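# Methods

This note documents the models behind each stage, the parameters that matter,
the numerical choices, and what the synthetic benchmark does and does not
establish about real data.

## Index-jump correction

During demultiplexing, a small fraction of reads receives the wrong index
(pair) and is attributed to the wrong replicate. Unused index combinations —
entries in the demultiplexing sheet that correspond to no physical library —
receive *only* such reads, so they calibrate the severity of the process
without any model assumptions.

For ASV *a* and replicate *s*, define p(a,s) = counts(a,s)/R(a), with R(a) the
ASV's **whole-dataset** total (used, unused and control columns; totals are
always recomputed from the matrix, and when a correction is re-applied the
caller may pass the pre-filter totals, which makes the filter idempotent).
The correction threshold is the global maximum of p(a,u) over all ASVs and
unused columns; every cell with p(a,s) ≤ threshold is zeroed (survival
requires strictly *more than* the threshold). A per-ASV threshold mode
(`estimate_per_asv_thresholds`) is available behind a flag; the global value
is the default because a single correction value is the natural reading of
"a threshold" for a run-level process. A threshold above a sanity cap
(default 0.05) triggers a warning rather than an error: such values arise
from pathological inputs (an ASV observed *only* in an unused column scores
1.0) and would silently erase the dataset.

## Replicate-consistency (PCR-error) filter

Each site is sequenced in `n_filters × n_pcr_tags` replicates (default
4 × 5 = 20). A PCR error (polymerase substitution, early-cycle artifact)
originates in one reaction, so an ASV occupying fewer than `min_replicates`
(default 2) of a site's replicates is zeroed at that site. The rule uses the
**absolute** occupied-replicate count, not a fraction, so a site with a
failed filter (15 replicates) is treated consistently. A group with a single
replicate is left untouched with a warning — the rule would indiscriminately
erase everything seen once.

Negative controls are pooled into one replicate group of their own and
cleaned by the same rule (default `include_controls=True`). This mirrors a
protocol in which controls run through the identical pipeline, and it is what
makes the two-filter pipeline leave controls read-free: the jump filter
removes every control cell at or below the threshold by construction, and the
rare cell that exceeds it (the maximum jump proportion lands on the control
side of the symmetric unused/control split in a substantial minority of runs)
is then a singleton in the control group. Without this, no threshold rule
alone can reliably clean controls, because unused and control columns receive
identically distributed jumped reads.

The order is fixed: index-jump first, then replicate filter. They do not
commute — the replicate filter judges occupancy patterns, which jumped reads
would otherwise inflate.

## Alignment and identity

`align_identity` uses an overlap (semi-global) dynamic program with match +1,
mismatch −1, gap −1, and free end gaps on **both** sequences. Freeing only
the reference ends would force full-query alignment and make query coverage
identically 100%; with overlap semantics a short amplicon contained in a
full-length barcode aligns cleanly (reference overhangs free), while
unalignable query ends reduce *coverage* rather than corrupting *identity*.
Identity = matched columns / aligned query columns (gap columns inside the
aligned region included) × 100; coverage = query bases inside the aligned
region / query length × 100. Identity is therefore computed only over the
aligned region, which is what makes a threshold like "94%" interpretable
across query lengths.

Tie-breaking is deterministic and part of the contract (the test suite holds
the kernel to an independently written pure-Python DP): the recurrence
prefers diagonal, then query-consuming, then reference-consuming moves, and
the end cell is the first maximum scanning the last row left-to-right, then
the last column top-to-bottom. Matching is exact character equality on
upper-cased IUPAC codes; a sequence consisting solely of ambiguity codes is
rejected. The kernel is numba-compiled; a 205 nt × 658 nt alignment takes
well under a millisecond, and `assign_sequences` skips query/reference pairs
sharing no exact 11-mer (the classic seed heuristic — a hit near a ≥ 91%
identity threshold necessarily shares many, so the screen only skips hopeless
pairs).

## Barcoding gap and assignment

All pairwise distances (100 − identity) in the species-labelled reference
database are split into intra- and inter-specific sets. If
max(intra) < min(inter), the gap exists and the suggested identity threshold
is the midpoint, 100 − (max_intra + min_inter)/2 — strictly inside the gap,
so both error directions have margin. Species represented by a single
sequence contribute no intra pairs and are warned about; a database with no
intra pairs at all is an error (the gap is undefined).

Assignment: discard hits with coverage < 99%, require identity strictly
above the threshold (default 94), take the species of the best-identity
reference. Two or more distinct species within 1e-9 of the top identity give
status `ambiguous` — an assignment is a claim about species presence and is
not decided by tie-breaking. The fallback cascade against external databases
is modelled as successive `assign_sequences` calls against user-supplied
references; no network access. For non-target ASVs, `classify_placements`
keeps the highest-LWR placement iff LWR > 0.5, else `unassigned`.

## Detection matrices and congruence

Citizen science detects (site, species) iff ≥ 1 assigned specimen; the
`same_date` mode keeps only specimens whose weekly collection date equals the
site's eDNA sampling date exactly (the eDNA event coincides with a net
check, so exact-date matching is well defined). Specimens that could not be
assigned are excluded from matrices and richness; a flag controls whether
they count in abundance totals (default: excluded). eDNA detects (site,
species) iff ≥ 1 read of an ASV assigned to that species in a used replicate
of the site, against either the corrected or the raw table. Congruence
reports both/a-only/b-only counts with proportions over the union
(Venn semantics). Abundance is individuals per sampling day, since windows
span 7–71 days.

## Co-occurrence and correlation

The species-ASV co-occurrence test conditions on both margins: with the
species at n1 of N sites and the ASV at n2, the shared count J is
hypergeometric; p_gt = P(J ≥ j_obs) and p_lt = P(J ≤ j_obs) are exact
one-tailed probabilities (scipy's log-gamma implementation, accurate far
below the 1e-12 oracle tolerance used in the tests). Classification:
positive if p_gt < α, negative if p_lt < α (α = 0.05); degenerate margins
(0 or N) are flagged and never classified. The screen tests every pair whose
ASV occupies ≥ 2 sites; an expected-overlap filter (n1·n2/N ≥ 1, the
customary screen in probabilistic co-occurrence software) is on by default
and can be disabled. No multiple-testing correction is applied by default —
the screen is exploratory; note the exact test is conservative on discrete
support, so the family-wise behaviour is better than the nominal α suggests.
Restricting reports to widespread species (e.g. those at > 2 sites) is left
to presentation, not to the testing layer.

`pearson_log_correlation` takes explicit transform names per axis
(`identity`, `log`, `log1p`, `log10`). Natural log with `log1p` is the
default recommendation for per-day abundance because zero-amphipod sites are
real observations that must stay in; richness is left untransformed.
Sites undefined under a transform are dropped pairwise; fewer than 3
remaining points or zero variance is an error. p-values come from the exact
t-distribution of r√((n−2)/(1−r²)).

## Synthetic study design

Defaults encode the emulated field design: 20 sites × (4 filters × 5 tagged
PCR groups), 8 unused index combinations, 8 pooled negative controls,
sampling windows uniform on 7–71 days with weekly net checks, and the eDNA
event on one of the check dates. Six amphipod species occupy sites
independently (occupancy 0.25 → ≈ 30 occupied pairs). Captures per occupied
pair are Poisson(0.35/day × duration) batched to the next check date — a
high-effort regime in which citizen science almost never misses an occupied
pair, matching the intended contrast with single-event eDNA.

eDNA reads: per occupied pair, the sampling event captures the species' DNA
with probability 0.35 (site-level; chosen to match a field regime in which
roughly a third of specimen-confirmed occupancies are recovered by one
sampling event); where captured, each of the site's 20 replicates detects it
with probability 0.7 (per-replicate dropout 0.3) and draws reads from a
negative binomial (mean 5000, dispersion 1.8 — SD comparable to the mean, as
real per-replicate depths show). A background community of 80 non-target
ASVs (random sequences, unassignable) occupies sites at 0.35 with per-ASV
lognormal depths floored at 150 reads/replicate; the floor bounds the
worst-case jump-threshold contribution (~1/R for the rarest ASV) safely below
true-cell proportions, which keeps the correction from erasing genuine
detections. PCR-error artifacts arise at 3 per site (Poisson), each a
one-to-two-substitution copy of a parent ASV present at that site, injected
into exactly one replicate at ~25 reads. Finally every read is independently
reassigned with probability 0.002 to a uniformly random other column (used,
unused or control) — reads are conserved, and the truth records every
planted fact (occupancy, planted eDNA presence, ASV ancestry, jumped-in
read counts, artifact origins).

Reference databases are built from a shared root: per-species centroids at a
controlled distance (targeting ~1.4× the inter-species floor), members within
half the intra budget of their centroid, so intraspecific distances stay
below `intra_divergence_max` by construction; inter-species distances are
verified post hoc with the same aligner the gap analysis uses, and the set
is redrawn (bounded retries) on failure. Species ASVs are a 205 nt window of
the centroid with 0–1 substitutions, so assignment identities land at
99–100% as real conspecific amplicons do.

**What passing the synthetic benchmark shows** — that the correction recovers
planted truth (≥ 99% of artifact occurrences removed, controls read-free in
≥ 95% of studies, ≥ 99% of sequenced occupied pairs retained), that gap
calibration and assignment are consistent end to end, and that eDNA
detections are nested within citizen-science ones under a
high-effort/low-sensitivity contrast. **What it does not show**: performance
under sequence-level error, chimeras, non-uniform jump topologies (real tag
jumps favour half-matching index pairs), taxon-specific amplification bias,
or eDNA transport. The generator also plants no coupling between amphipod
abundance and background ASV richness, so diversity correlations on synthetic
data centre on zero by design; the correlation machinery is validated by its
exact-oracle and type-I calibration tests instead.

## Problem sizes and determinism

The shipped tests and the acceptance script run each Monte-Carlo property on
100 (tests) or 30 (script) independently seeded studies, 10,000/5,000
replicates for Pearson calibration and 1,000 for co-occurrence calibration,
and exhaustive sweeps to N = 12 (subset enumeration) and N = 25 (pmf
normalisation) — sizes at which every property is measured with margins of
several Monte-Carlo standard errors while a full run stays in the tens of
seconds. All randomness flows through `numpy.random.default_rng` seeds;
fixed seeds give bit-identical tables, truth and FASTA output.

## Known limitations

* The jump-destination model is uniform; real index-jumping concentrates on
  combinations sharing one real index. The unused-combination calibration is
  agnostic to this, but synthetic control cleanliness rates would differ
  under a structured topology.
* Identity is defined over the aligned query region of a single optimal
  alignment; co-optimal alignments with different identities are resolved by
  the declared tie-break, not enumerated.
* One ASV per species: intraspecific amplicon variation (multiple haplotypes
  per species) is not emulated.
* `EffortTable` carries one duration and one eDNA date per site; protocols
  with multiple eDNA events per site would need a widened table.
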