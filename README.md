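# mimoscan

**From biopanning mimotopes to candidate tumor-associated antigens.**

Screening a random-peptide phage-display library (RPPDL) on a cancer
patient's serum IgG or IgM antibodies yields a panel of short peptides
(5–16 aa) with clonal copy numbers — mimotopes of whatever the antibodies
recognize — but not the identity of the antigens themselves.  For
*sequential* (linear) epitopes the antigen can be found by searching the
peptides against a protein database.  The catch is statistical: the
recognized motifs are only 4–6 residues long, so a short peptide matches
dozens of proteins by pure chance, and the chance of a match grows in
proportion to protein length — enormous proteins such as the 14,507-aa
mucin 16 soak up matches without meaning anything.

`mimoscan` implements the analysis that separates signal from this
background, for bioinformaticians working on serological antigen
discovery:

1. **Search.** A transparent short-peptide matcher (exact maximal shared
   windows with a mismatch budget, or PAM30-scored ungapped seed-and-extend)
   replaces a short-query BLAST run; externally produced BLAST tabular
   results can be imported instead.
2. **Null model.** Every panel peptide is reversed ("spelt backwards") and
   searched with identical parameters.  Reversal preserves length and
   composition but destroys epitope signal, giving the length-normalized
   chance-match frequency *f* (matches per peptide per 1000 aa).
3. **Motif collapse.** Peptides that all match one protein through a single
   shared motif at one site (e.g. a common PWSK fragment) are counted as
   *one* independent piece of evidence, `k_eff`.
4. **Scoring.** For each (panel, protein) pair with `k` of `n` peptides
   matching a protein of length `L`:
   * `p_binomial` = exact tail P(X ≥ k_eff), X ~ Binomial(n, p₀) with
     p₀ = f·L/1000;
   * `p_fisher` = one-sided Fisher exact contrast of the panel's matches
     against all other patients' and control panels;
   * proteins whose *expected* chance matches n·p₀ already exceed the
     observed k are flagged `LENGTH_SUSPECT`.
5. **Expression cross-check (optional).** Candidates whose gene is
   overexpressed only in the matching patient's tumor sample are flagged
   `EXPRESSION_SUPPORTED`.

A seeded synthetic-data module generates proteomes (lognormal lengths plus
mucin-16/nesprin-1-sized decoys) and biopanning-style panels (clonal
expansions, motif families, planted epitope carriers) with machine-readable
ground truth, so the whole pipeline is testable without downloading any
reference database.

## Worked example

The headline calculation, at the Python prompt: a 403-aa candidate antigen
matched by 2 of a panel's 3 peptides, under a chance frequency of
f = 0.02 per peptide per 1000 aa:

```python
>>> from mimoscan import chance_prob, binomial_tail, fisher_contrast
>>> p0 = chance_prob(0.02, 403)        # 0.00806
>>> binomial_tail(3, 2, p0)
0.0001938435867680001                  # far below 0.001: not chance
>>> binomial_tail(70, 7, chance_prob(0.02, 14507))
0.9999702352553054                     # 7 hits on a 14,507-aa decoy: chance
>>> fisher_contrast(2, 3, 0, 67)       # 2/3 in this panel, 0/67 elsewhere
0.0012422360248447203
```

The same logic end to end on synthetic data — a 3-peptide panel with two
epitope carriers of a planted 400-aa antigen, a 67-peptide background
panel, and a 300-protein proteome containing a 14,507-aa decoy:

```bash
$ cat demo.yaml
params: {mode: exact, min_exact_window: 5, max_mismatches: 0}
simulate: {n_proteins: 300}
null_model: {min_matches_threshold: 0}

$ mimoscan run-all --config demo.yaml --out-dir demo_run --seed 1
run complete: 18 candidates in demo_run
  #1 A/IgG SYN00000 k=2 k_eff=2 p_binomial=6.44e-07
  #2 A/IgG SYN00011 k=1 k_eff=1 p_binomial=0.00217
  #3 B/IgG SYN00204 k=1 k_eff=1 p_binomial=0.023
  ...
```

`SYN00000` is indeed the planted antigen (`demo_run/truth.json`), and its
Fisher contrast in `demo_run/candidates.tsv` is 0.00124224 — the exact
one-sided value for 2-of-3 versus 0-of-67.  The run directory also holds
`hits.tsv` (BLAST-outfmt-6 dialect), `null.json` (the audited reversed-
peptide estimate; here f = 0.00116 ± 0.00695 per 1000 aa from N = 70
peptides) and a `manifest.json` with input digests for reproducibility.

Panel utilities work on the bundled reference inventory of the
colorectal-cancer screen:

```bash
$ mimoscan table1 --out panels.tsv
$ mimoscan scan --panels panels.tsv --panel B/IgG --pattern KxxGHH
KxxGHH  5 phage 4 sequences
KGMGHHGNG
KAYGHHLSAE
KSHGHHR
KQSGHHRSE
```

## Layout

```
src/mimoscan/io.py            panels, proteomes, match tables, reports
src/mimoscan/search.py        exact / PAM30-scored short-peptide matcher
src/mimoscan/motifs.py        shared-motif extraction, wildcard scans
src/mimoscan/null_model.py    reversed-peptide chance-match frequency
src/mimoscan/significance.py  collapse, binomial & Fisher, ranking, QC
src/mimoscan/simulate.py      synthetic proteomes/panels + ground truth
src/mimoscan/pipeline.py      run-all orchestration with manifest
src/mimoscan/cli.py           command-line interface
docs/methods.md               model, assumptions, parameter rationale
```
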