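# Methods

This note documents the models, conventions and numerical choices behind
phycodelim, in the order the pipeline applies them.

## Sequence and structure handling

All sequences are normalized to RNA on ingest (T→U, upper case); IUPAC
ambiguity codes and `-` gaps are legal everywhere. Structures arrive as
nested Vienna dot-bracket strings — **thermodynamic folding is not part of
the package**; structures are inputs, produced by whatever folding tool
the user trusts. Pseudoknot bracket tiers are rejected: the ITS-2
three-helix model and the V4 E23 helices are nested. As an alternative to
per-strain structures, `transfer_pairing` imposes one reference structure
on aligned strains column-by-column (a pair is dropped for a strain that
has a gap on either side). Internally all coordinates are 0-based;
reports and template files are 1-based inclusive.

## ITS-2 three-helix annotation

`annotate_helices` decomposes the pairing into stems: consecutive nested
pairs with at most 3 unpaired nucleotides of interior bulge on either
strand belong to one stem, and stems need ≥ 2 stacked pairs to count as
helices (both thresholds are parameters; these defaults reflect standard
stem decomposition — the three-helix model itself prints no rule). Stems
are labelled I, II, III in 5′→3′ order of their opening strand; a fourth
qualifying stem is an error (the model does not apply — override the
filter or supply a template), fewer than three is a warning. A helix's
terminal loop is the run of positions enclosed by its innermost pair with
no pairs inside.

`conserved_columns` keeps exactly the alignment columns paired in *every*
strain with a consistent partner, minus the terminal-loop columns of
helices I and II (the variable loops; configurable). Inconsistent
partners across strains are an error rather than a silent exclusion,
because they mean the structures are not homologous at those columns.
Conserved columns of a strain set are always a subset of those of any
subset of strains.

## The 8-state number code and change classes

Each conserved pair is encoded as: 1 = A–U, 2 = U–A, 3 = G–C, 4 = C–G,
5 = G·U, 6 = U·G, 7 = any other two non-gap bases (mismatch), 8 = a gap
or unpaired position on either side. Change classification between two
strains at one column:

* `IDENTICAL` — same bases both sides (gap-vs-gap included);
* `CBC` — both codes in 1–6 and both strands differ;
* `HCBC` — both codes in 1–6 and exactly one strand differs;
* `INDEL_CHANGE` — a code-8 column on exactly one side; two *different*
  code-8 columns (e.g. (A,–) vs (–,U)) are also classified
  `INDEL_CHANGE`, a case the class enumeration would otherwise miss;
* `MISMATCH_CHANGE` — a code-7 column involved;
* `AMBIGUOUS` — an IUPAC ambiguity on either side. Ambiguous columns are
  excluded from every count and reported separately; this is the
  conservative choice (an R could hide either a CBC or identity).

Variable-position counting uses **base identity, not code identity**: two
distinct mismatches both encode 7 but still count as variable. Codes are
lossy; the bases are the data.

## Species delimitation

Input: candidate lineages (strain sets with optional bootstrap/posterior
support) plus barcodes. Two lineages are separable when some column
classifies as CBC for *every* cross-pair of their members, or as HCBC for
every cross-pair *and* both lineages pass the support gate (bootstrap
≥ 70% or, when posteriors are supplied, posterior ≥ 0.95; both
thresholds configurable). Non-separable lineages merge by transitive
closure; groups are reported sorted by their smallest strain ID, so the
result is invariant to input order. The support gate applies to HCBC-only
splits because a hemi-CBC is a single mutation and weak evidence on its
own; a CBC separates regardless of support. Where both support types are
present, passing either gate suffices.

## Distance trees and lineage support

The in-repo tree machinery is deliberately minimal plumbing —
study-grade ML/Bayesian supports can be imported onto bipartitions from a
TSV (`import_supports`). Internally: uncorrected p-distances over
pairwise comparable (unambiguous, non-gap) columns; neighbor joining with
a deterministic tie-break (the smallest (i, j) pair in current working
order on equal Q-values — documented because topology depends on it);
negative branch-length estimates clamp to zero (never triggered by
additive input, which NJ recovers exactly). Bootstrap resamples columns
with replacement; support of an original internal bipartition is the
percentage of replicate trees containing it, reproducible by seed.

Supported-lineage extraction roots at a declared outgroup, else at the
midpoint, and walks from the root collecting maximal clades whose
subtending edge support passes the threshold; unassigned strains become
singletons. Two refinements make this robust: (i) a root child whose
subtending edge *is* the rooting edge and which contains supported
internal structure is descended into instead of accepted wholesale
(otherwise the whole ingroup would always be one "lineage"); (ii) a
supported split whose midpoint root lands exactly on a node exists only
as a bipartition, not a rooted clade, so supported bipartition sides
whose strains are all still unassigned are promoted afterwards, finest
first.

## V4 template and clade diagnostics

The E23 helix coordinates ship as a TSV template (helix, start, end,
partner_helix; 1-based inclusive on the ungapped reference row). The
packaged `synthetic_v4_template.tsv` is a synthetic demonstration file,
not the structure of any real strain; real analyses supply their own
template. Template strands pair antiparallel and must be equal length.

`extract_v4` maps template coordinates through the reference row's gaps
and slices every strain over the same columns. `annotate_v4` labels each
column with its helix, `loop(X)` between a hairpin's strands, or
`spacer(X–Y)` between consecutive helices.

An NHS requires a non-gap, unambiguous state fixed in all clade members
and absent from every outside strain; with a tree, the binary presence
character must additionally cost exactly one change under Fitch parsimony
(so the NHS set with the tree check is a subset of the set without). A
clade of size one yields autapomorphy-flagged features. Paired columns
can be excluded from the NHS scan (pass the template pairing): changes
there belong to the CBC/HCBC synapomorphy classification, which compares
the clade's fixed pair against the outside **majority** pair; a
polymorphic outside is flagged on the feature, never silently
classified. Singleton states that break a pairing — the signature of a
sequencing error — are flagged by `flag_singleton_mismatches` and never
auto-removed.

## Statistical-parsimony networks

Identical sequences collapse into haplotypes (aligned rows are compared,
so indel states survive; degapped lengths must agree when inputs are
unaligned). Default haplotype IDs are H01, H02, … by decreasing
multiplicity; `rename_haplotypes` applies any user naming scheme.

**Connection limit.** The limit is the largest step count *j* whose
estimated probability of parsimony reaches the confidence level (default
0.95), in the spirit of the statistical-parsimony criterion of Templeton,
Crandall & Sing (1992) popularized by TCS (Clement et al. 2000). The
estimator used here (documented exactly, since the criterion's historical
implementations differ): substitutions hit each site as Poisson events
with mean λ per site, solved from the Jukes–Cantor relation
`j/m = (3/4)(1 − e^(−4λ/3))` for `j` observed differences over `m` sites;
a site observed identical was parsimonious iff it had zero hits, a site
observed different iff exactly one, giving

```
P(j, m) = [e^(−λ) / (1/4 + 3/4·e^(−4λ/3))]^(m−j) · [λe^(−λ) / (j/m)]^j
```

evaluated in log space. P decreases in j and the limit is non-decreasing
in m. The limit is floored at 1 — single steps are always treated as
connectable, so confidence → 1 gives limit 1. This estimator is more
conservative than the table of the original TCS program (7 vs ~14 steps
at 600 nt); for the short V4 fragments targeted here the difference is
1–2 steps and only makes species separation stricter.

**Construction.** Haplotype pairs are visited in increasing step
distance (ties: higher multiplicity, then lexicographic ID); a pair in
different components at distance ≤ limit is connected by a fresh path of
median nodes, mutating differing positions left-to-right so every edge
spans exactly one step (a contiguous gap run switches in one step, the
gap being treated as a fifth state). Because connections always join the
closest components and medians are not reused across connections, the
total number of unit edges equals the minimum-spanning total over the
observed haplotypes — an exactly checkable property. Steiner-style
median sharing (which can undercut the spanning minimum) is deliberately
not attempted; it is an approximation of the original agglomerative TCS
procedure. "Maximal under the limit" means every *connection event*
respects the limit; as in the original program, a chain of near
neighbours may transitively connect haplotypes whose direct distance
exceeds it.

**Query assignment** reproduces the acceptance thresholds of a local
database search on user-supplied candidates (no remote searching): the
best ungapped sliding match must cover the full reference region
(coverage = aligned span / reference length ≥ 1.0) with identity
strictly above 0.97. Both thresholds sit in `AnalysisConfig`.

## Synthetic data: what it emulates, and what it does not

The generators plant *exact* counts instead of simulating evolution — no
substitution model, no branch lengths. `generate_its2_dataset` draws an
ancestral core barcode over codes 1–6, splits `core_width` base pairs
across three helices (≥ 2 each), and derives every species after the
first by applying exactly the requested CBCs and HCBCs at globally
disjoint private pairs; free variation occurs only in helix I/II
terminal loops at `loop_noise_rate` (default 0.1 per loop position), so
core counts are exact rather than statistical. Pairwise planted counts
are the sums of the two species' private counts, recorded per pair in
`SyntheticTruth`. `generate_v4_dataset` builds an E23-style template,
gives each species private diagnostic positions (NHS), private stem-pair
changes (CBC/HCBC features) and enough extra private substitutions that
every between-species distance exceeds the connection limit (the tail
region grows until the limit is self-consistent); within-species
haplotypes form a chain with exactly `steps_between` fresh substitutions
per link. One integer seed drives all draws; identical seeds give
byte-identical output.

Consequences for interpretation: passing tests show the pipeline
recovers *planted* signal exactly and deterministically; they do not
show robustness to alignment error, rate heterogeneity, intra-individual
ITS polymorphism, chimeric environmental reads, or structures mis-folded
by the upstream folding program. Defaults (3 species × 3 strains, a
24-pair core, 1 CBC + 1 HCBC per split; 2 haplotypes × 2 samples per V4
species) mirror the scale of a typical culture-collection study of these
algae so that the whole suite runs in seconds.

## Known limitations

* No thermodynamic folding, pseudoknots, helix IV, or rRNA covariance
  models; structures and templates are user inputs.
* ML/Bayesian inference and model selection are out of scope; import
  external supports instead.
* CBC logic applies only to paired conserved columns; CBCs in unpaired
  regions are meaningless and not counted.
* The delimitation rule is deterministic, not probabilistic (no
  GMYC/bPTP-style models).
* Median-node placement is a greedy approximation; layouts for figures
  are left to downstream tools (GraphML export).
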