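# Methods

This note documents the statistical model behind `mimoscan`, the choices
that were genuinely open, and what the synthetic benchmarks do and do not
demonstrate.

## The inference problem

A biopanning experiment returns, per patient and antibody isotype, a panel
of `n` distinct peptide inserts (each with a clonal copy number).  Some of
these mimic sequential epitopes of a protein antigen; others mimic
conformational or carbohydrate epitopes, or are selection noise.  Matching
the peptides against a proteome produces, for every protein of length `L`,
a count `k` of distinct matching peptides.  Because the informative motifs
are only 4–6 residues, `k ≥ 1` is commonplace by chance, and the chance
rate grows linearly with `L`.  The question the pipeline answers is: for
which (panel, protein) pairs is the observed `k` inconsistent with chance?

Unless `--weight-by-copies` is set, all statistics count unique insert
sequences, not phage particles: clonal copies are one selection event
amplified, not independent evidence.

## Matcher

Exact mode (default) reports every *maximal* shared window of length ≥ `w`
(default 5) with at most `m` substitutions (default 0) between a peptide
and a protein; maximality means the window cannot be extended on either
side within the mismatch budget, so each match region is reported once.
Window 4 reproduces PWSK-type motif matches but roughly 20-fold increases
the chance rate; it is a flag, not the default.  Scored mode follows
short-query protein-search conventions (PAM30, word size 2, ungapped
extension to maximal score, default cutoff 35) for users who want graded
similarity.  Matches are ungapped; no E-value is computed, because
significance is deliberately delegated to the empirical null below rather
than to per-alignment statistics.  When both peptide and proteome scans use
the default exact/0-mismatch mode, the scan is accelerated by a proteome
w-mer index; the indexed path is property-tested to be identical to the
per-pair diagonal scan.

Multiple matched sites of one peptide within one protein count once (best
score, then leftmost): the statistics count matching peptides, not sites.
Near-identical database entries (homolog families such as FUT3/FUT5/FUT6)
are deliberately left as independent rows.

## Reversed-peptide null

All panel peptides are reversed and searched with byte-identical
parameters (one shared `MatchParams` object; a mismatch is a hard error).
Reversal preserves length and amino-acid composition while destroying any
real epitope, so reversed matches estimate the chance background of the
search engine itself, composition bias included.  The per-protein
length-normalized frequency is

    f_i = M_i / (N · L_i / 1000)   [matches per peptide per 1000 aa]

with `M_i` distinct reversed peptides matching protein `i` and `N` the
number of reversed peptides searched.  `N` counts only peptides long
enough to match under the current parameters, mirroring the forward-side
exclusion from `n`.  Palindromic peptides are kept: excluding them would
bias `N` and there is no principled exclusion rule.

`f_mean ± f_sd` aggregates `f_i` over proteins retained by
`min_matches_threshold`:

* **Threshold 4 (default).**  Estimating `f` from the most overrepresented
  proteins (four or more reversed matches) reproduces the original
  procedure at reference-proteome scale.  Conditioning on
  overrepresentation biases `f` upward, which is *conservative*: it
  inflates the null and makes forward significance harder to reach.  The
  dispersion is reported as the sample standard deviation over qualifying
  proteins; whether the historical "±" denoted an SD or an eyeballed range
  is not stated anywhere, so the SD is this package's definition.
* **Threshold 0 (synthetic scale).**  Against a few hundred proteins no
  protein can accumulate four chance matches (expected `M_i` « 1 under
  exact window-5 matching), so desk-scale runs average `f_i` over *all*
  proteins, zeros included.  This estimator is unbiased — its expectation
  equals the i.i.d. closed-form rate — and is what the simulation
  benchmarks use.  Requesting an unreachable threshold raises an error
  rather than silently returning 0.

The chance probability that one peptide matches a protein of length `L` is
`p0 = min(1, f · L / 1000)` — proportionality to length, capped.

## Motif-redundancy collapse

If several distinct peptides all match one protein through a single shared
motif at one site, those selections reflect one antibody specificity
sampled repeatedly, not independent draws — the multiplicity is not
evidence.  Two matching peptides are therefore grouped when their matched
protein intervals overlap *and* their matched substrings share a common
substring of ≥ 4 residues; `k_eff` is the number of groups, and when
everything collapses into one group the shared motif (longest common
substring) is reported.  The collapse can only reduce significance, never
increase it, and it propagates into both the binomial and the Fisher
statistic — the stricter reading of the negation argument.

The flip side: a genuine antigen typically elicits antibodies against
*several* of its epitopes, so its matching peptides are unrelated sequences
hitting different sites and survive the collapse.  This is exactly the
structural difference between the discarded shared-PWSK candidate and the
retained multi-epitope candidates, and it is what the synthetic generator
reproduces (below).

## Candidate scoring

For every (panel, protein) with `k ≥ 1`:

* `p_binomial = P(X ≥ k_eff)`, `X ~ Binomial(n, p0)`, computed by direct
  summation with exact binomial coefficients (no normal approximation; the
  implementation is cross-checked against an independent survival-function
  routine and, for n = 3, against full outcome-space enumeration).
* `p_fisher`: one-sided upper hypergeometric tail of the 2×2 table
  contrasting `k_eff` of `n` in this panel against matches among all other
  panels' peptides.  Sidedness is not dictated by any source; enrichment
  (one-sided "greater") is the default and a two-sided option is exposed.
  The healthy-donor control panel is included in the "other" group by
  default (a flag excludes it).
* `LENGTH_SUSPECT` is set when `n·p0 ≥ k`: the protein is long enough that
  chance alone predicts at least as many matches as observed (the mucin-16
  / nesprin-1 situation; e.g. f = 0.02, L = 14,507, n = 70 predicts 20.3
  chance matches, so 7 observed matches are unremarkable and
  `P(X ≥ 7) ≈ 1`).
* Benjamini–Hochberg q-values are computed per panel over proteins with
  `k ≥ 2` and reported, but not used for ranking — the ranking replicates
  the uncorrected procedure; the q-values are there so users can see the
  multiplicity burden.
* Candidates sort by `p_binomial`, then `p_fisher`, then `L`, then protein
  id; ties are therefore deterministic and reports are byte-stable.

Peptides shorter than the matcher's minimum are excluded from `n` (they
cannot match by construction) and the exclusion is logged.

The biopanning enrichment QC (`cfu_panel / cfu_control ≥ 2`) and the
expression cross-check (gene value in the patient's own tumor sample at
least twice the maximum over all other samples) are thin, separately
testable utilities; the expression rule operationalizes "overexpressed
only in the corresponding tumor".

## Synthetic data

The generator emulates the *structure* of biopanning output so every stage
has a ground-truthed benchmark:

* **Proteome**: i.i.d. sequences, uniform amino-acid frequencies by default
  (so closed-form chance rates are available for validation; a natural-
  composition preset exists for realism experiments), lognormal lengths
  with median 450 aa and σ = 0.6 — a realistic proteome-like spread — plus
  explicit oversized decoys (14,507 and 8,749 aa) so length normalization
  is always exercised.
* **Panels**: clonal copy numbers drawn geometric with mean 2; epitope
  carriers embedding a planted epitope inside otherwise-random peptides;
  optional motif families (distinct peptides sharing a planted 4-mer that
  also occurs in a designated background protein — the PWSK analogue);
  random singletons.  Peptide lengths default to 7–12 aa.
* **Epitopes**: by default each carrier mimics *its own* 6-mer epitope,
  planted at distinct non-overlapping sites of the planted protein and
  nowhere else in the proteome — the multi-epitope response of a genuine
  antigen, which survives motif collapse.  `shared_epitope=True` instead
  gives every carrier one common epitope; those matches then pile onto a
  single protein site and the collapse correctly reduces them to one piece
  of evidence.  Epitope mutations are substitutions only (the matcher is
  ungapped).  The planted protein's length is pinned to 400 aa by default
  so the benchmark's `p0` is stable across seeds.
* **Scenario defaults**: one 3-peptide target panel with two carriers plus
  a 67-peptide background panel, so the pooled reversed-peptide null runs
  on 70 unique peptides — the scale of the original screen.

The generator does **not** model selection-round dynamics, amplification
bias, antibody affinity, or real proteome homology/repeat structure.
Passing benchmarks therefore demonstrate the statistical machinery is
correct and calibrated under its stated assumptions, not that any
particular sensitivity holds on real repeat-rich proteomes — on real data
the empirical reversed-peptide null absorbs composition effects, but
paralog families still produce correlated rows (left visible by design).

A reference reading of the published peptide inventory ships as
`table1_fixture()`.  The source table typesets several inserts as run-on
strings; the fixture splits them at annotation boundaries (superscripts,
copy-number parentheses).  Reconstructed per-panel totals under this
reading: A/IgG 3 unique / 18 phage (unambiguous, dominant insert 9 copies),
A/IgM 8/17, B/IgG 9/12, C/IgG 4/17, D/IgG 15/21, D/IgM 16/32, healthy
control 6 entries.  Prose totals quoted elsewhere ("14 phage", "24
peptides", "70 inserts") are not all reconstructable from the table; the
structure that matters downstream — the KxxGHH family contributing 5
phage, the 5 PWSK carriers, the SPTH and GRxNKSG motifs — is reproduced
exactly.

## Numerical and interface choices

* Internal coordinates are 0-based half-open; files and reports use the
  1-based inclusive BLAST dialect, converted only at I/O boundaries.
* Ambiguity letters (B, J, O, U, X, Z) are rejected at parse time: the
  null model assumes a fixed 20-letter alphabet.
* Report floats print with 6 significant digits, scientific notation below
  1e-4; the JSON mirror keeps full precision, so write→read round-trips
  are exact.
* Emitted match tables use the 12-column tabular dialect with E-value 0
  (none is defined) and the matcher score in the bitscore column, so
  built-in and imported matches are interchangeable.  Imported external
  hits must come with an externally computed null from the same engine;
  mixing engines is refused, as is any forward/null parameter mismatch.
* Motif extraction enumerates candidate patterns of length 4–6 with at
  most one interior wildcard (defaults), then extends each pattern with
  residues on which all members agree, up to 10 residues — so a 7-residue
  consensus like GRxNKSG is reported as one maximal motif rather than two
  overlapping 6-mers.  Maximality is defined by member-set equality:
  among patterns shared by the same peptides, only the longest (then
  least-wildcarded) are reported.  Motifs require ≥ 2 *distinct*
  sequences; clonal identity is not a motif.
* Tie-breaks everywhere (dominant clone, best hit, candidate order) fall
  back to lexicographic/leftmost rules so all outputs are deterministic;
  rerunning a pipeline config with the same seed reproduces every output
  file byte for byte.

## Known limitations

* The matcher is ungapped by design; epitopes mimicked with insertions or
  deletions are out of reach of both modes.
* Conformational and carbohydrate mimotopes produce no database signal;
  the pipeline can only rank candidates for sequential epitopes.
* At desk scale the threshold-4 null is unreachable; users comparing
  against reference-proteome-scale numbers should remember that the
  threshold-0 and threshold-4 estimators condition differently (unbiased
  vs deliberately inflated).
* The Fisher contrast treats panels as independent; repeated screening of
  one patient violates this.
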