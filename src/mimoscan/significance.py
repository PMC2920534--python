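"""Candidate antigen scoring: motif collapse, binomial tail, Fisher contrast.

For each (panel, protein) pair with at least one matching peptide the
module computes:

* ``k_eff`` — matching peptides after motif-redundancy collapse.  Peptides
  that all hit one protein through a single shared motif at one site are a
  single independent piece of evidence, not k of them.
* ``p_binomial`` — exact upper tail P(X >= k_eff), X ~ Binomial(n, p0)
  with p0 = f * L / 1000 from the reversed-peptide null.  Long proteins get
  large p0, which is precisely how chance-driven pile-ups on huge decoys
  (mucin-16-sized) are recognized: their expected chance matches exceed the
  observed count and the candidate is flagged LENGTH_SUSPECT.
* ``p_fisher`` — one-sided exact test contrasting the panel's match count
  with matches from every other panel's peptides; a protein recognized by
  one patient's antibodies and nobody else's scores low.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from scipy.stats import hypergeom, fisher_exact
from statsmodels.stats.multitest import multipletests

from .io import PeptidePanel, ProteinRecord
from .null_model import NullEstimate, chance_prob
from .search import MatchHit, MatchParams, dedupe_protein_level

logger = logging.getLogger(__name__)

MOTIF_COLLAPSED = "MOTIF_COLLAPSED"
LENGTH_SUSPECT = "LENGTH_SUSPECT"
EXPRESSION_SUPPORTED = "EXPRESSION_SUPPORTED"

#: Minimum shared-substring length for two matches to count as one motif.
MOTIF_COLLAPSE_MIN_OVERLAP = 4


class SignificanceError(ValueError):
    pass


@dataclass(frozen=True)
class CandidateResult:
    """Scored candidate antigen for one panel."""

    panel_id: str
    protein_id: str
    length_aa: int
    n: int
    k: int
    k_eff: int
    shared_motif: str | None
    p_binomial: float
    p_fisher: float
    other_matches: int
    other_total: int
    q_value: float | None
    flags: frozenset[str]
    rank: int
    hits: tuple[MatchHit, ...] = ()


# ---------------------------------------------------------------------------
# motif-redundancy collapse


def _longest_common_substring(strings: Sequence[str]) -> str:
    """Longest substring present in every string (ties: lexicographic min)."""
    if not strings:
        return ""
    shortest = min(strings, key=len)
    others = [s for s in strings if s is not shortest]
    for L in range(len(shortest), 0, -1):
        found = sorted(
            shortest[o : o + L]
            for o in range(len(shortest) - L + 1)
            if all(shortest[o : o + L] in s for s in others)
        )
        if found:
            return found[0]
    return ""


def collapse_motif_redundancy(
    hits: Sequence[MatchHit],
) -> tuple[int, str | None]:
    """Count independent matches among one panel's hits to one protein.

    ``hits`` must already be deduped to one best hit per peptide.  Two
    peptides belong to one evidence group when their matched protein
    intervals overlap *and* their matched substrings share a common
    substring of at least 4 residues — the situation where one shared motif
    produced every match.  Returns the number of groups and, when the whole
    set collapses to a single group of >= 2 peptides, the motif (longest
    substring common to all matched substrings).
    """
    k = len(hits)
    if k == 0:
        return 0, None
    parent = list(range(k))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    for i in range(k):
        for j in range(i + 1, k):
            hi, hj = hits[i], hits[j]
            overlap = (
                hi.protein_start < hj.protein_end
                and hj.protein_start < hi.protein_end
            )
            if overlap and len(
                _longest_common_substring(
                    [hi.matched_substring, hj.matched_substring]
                )
            ) >= MOTIF_COLLAPSE_MIN_OVERLAP:
                union(i, j)
    groups = len({find(i) for i in range(k)})
    motif = None
    if groups == 1 and k >= 2:
        motif = _longest_common_substring([h.matched_substring for h in hits]) or None
    return groups, motif


# ---------------------------------------------------------------------------
# exact statistics


def binomial_tail(n: int, k: int, p0: float) -> float:
    """Exact P(X >= k) for X ~ Binomial(n, p0), by direct summation."""
    if not 0 <= k <= n:
        raise SignificanceError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not 0.0 <= p0 <= 1.0:
        raise SignificanceError(f"p0 must be in [0, 1], got {p0}")
    if k == 0:
        return 1.0
    total = 0.0
    for i in range(k, n + 1):
        total += math.comb(n, i) * p0**i * (1.0 - p0) ** (n - i)
    return min(1.0, total)


def fisher_contrast(
    k_panel: int,
    n_panel: int,
    k_other: int,
    n_other: int,
    two_sided: bool = False,
) -> float:
    """Exact test of match enrichment in one panel against all others.

    One-sided (default) upper hypergeometric tail on the 2x2 table
    [[k_panel, n_panel - k_panel], [k_other, n_other - k_other]]; the
    two-sided variant sums all tables at most as probable.
    """
    for name, (k, n) in {
        "panel": (k_panel, n_panel),
        "other": (k_other, n_other),
    }.items():
        if k < 0 or n < 0 or k > n:
            raise SignificanceError(f"invalid {name} counts: k={k}, n={n}")
    if two_sided:
        table = [[k_panel, n_panel - k_panel], [k_other, n_other - k_other]]
        return float(fisher_exact(table, alternative="two-sided")[1])
    if n_panel + n_other == 0:
        return 1.0
    return float(
        hypergeom.sf(k_panel - 1, n_panel + n_other, k_panel + k_other, n_panel)
    )


# ---------------------------------------------------------------------------
# ranking


def _weighted_counts(
    group_hits: Sequence[MatchHit], groups: Mapping[int, list[int]]
) -> int:
    """Weight-by-copies k_eff: each group counts its best peptide's copies."""
    total = 0
    for members in groups.values():
        best = max(
            members,
            key=lambda i: (
                group_hits[i].score,
                -group_hits[i].protein_start,
                -group_hits[i].peptide_offset,
            ),
        )
        total += group_hits[best].peptide.copy_number
    return total


def rank_candidates(
    hits: Iterable[MatchHit],
    panels: Sequence[PeptidePanel],
    proteome: Sequence[ProteinRecord],
    null: NullEstimate,
    params: MatchParams,
    weight_by_copies: bool = False,
    control_panels: Sequence[str] = (),
    two_sided_fisher: bool = False,
    compute_qvalues: bool = True,
) -> list[CandidateResult]:
    """Score and rank every (panel, protein) pair with >= 1 match.

    The forward hits must have been produced with the same MatchParams as
    the null estimate (hard error otherwise).  Peptides too short to match
    are excluded from n.  Candidates sort by p_binomial, then p_fisher,
    then protein length, then protein id.  BH q-values are computed per
    panel over proteins with k >= 2 (reported, not used for ranking).
    """
    if params != null.params:
        raise SignificanceError(
            "forward MatchParams differ from the null model's; both searches "
            "must use one parameter set"
        )
    by_protein = {p.protein_id: p for p in proteome}
    panel_by_id = {p.panel_id: p for p in panels}
    exclude = set(control_panels)
    unknown = exclude - set(panel_by_id)
    if unknown:
        raise SignificanceError(f"unknown control panel ids: {sorted(unknown)}")

    def panel_n(panel: PeptidePanel) -> int:
        eligible = [
            r for r in panel.records if len(r.sequence) >= params.min_peptide_length
        ]
        skipped = panel.n_unique - len(eligible)
        if skipped:
            logger.info(
                "panel %s: %d peptide(s) shorter than %d excluded from n",
                panel.panel_id,
                skipped,
                params.min_peptide_length,
            )
        if weight_by_copies:
            return sum(r.copy_number for r in eligible)
        return len(eligible)

    n_of = {p.panel_id: panel_n(p) for p in panels}

    # one best hit per (panel, peptide, protein)
    per_panel_hits: dict[str, list[MatchHit]] = {p.panel_id: [] for p in panels}
    for hit in hits:
        if hit.peptide.panel_id not in per_panel_hits:
            raise SignificanceError(
                f"hit references unknown panel {hit.peptide.panel_id!r}"
            )
        per_panel_hits[hit.peptide.panel_id].append(hit)
    deduped: dict[str, dict[tuple[str, str], MatchHit]] = {
        pid: dedupe_protein_level(hlist) for pid, hlist in per_panel_hits.items()
    }
    # distinct matching peptide counts per (panel, protein), for the contrast
    match_count: dict[tuple[str, str], int] = {}
    weighted_match_count: dict[tuple[str, str], int] = {}
    for pid, table in deduped.items():
        for (seq, protein_id), hit in table.items():
            key = (pid, protein_id)
            match_count[key] = match_count.get(key, 0) + 1
            weighted_match_count[key] = (
                weighted_match_count.get(key, 0) + hit.peptide.copy_number
            )

    results: list[CandidateResult] = []
    for panel in panels:
        pid = panel.panel_id
        table = deduped[pid]
        by_prot: dict[str, list[MatchHit]] = {}
        for (seq, protein_id), hit in sorted(table.items()):
            by_prot.setdefault(protein_id, []).append(hit)
        n = n_of[pid]
        other_panels = [
            p.panel_id for p in panels if p.panel_id != pid and p.panel_id not in exclude
        ]
        other_total = sum(n_of[o] for o in other_panels)
        for protein_id, prot_hits in sorted(by_prot.items()):
            prot = by_protein.get(protein_id)
            if prot is None:
                raise SignificanceError(f"protein {protein_id!r} not in proteome")
            counts = weighted_match_count if weight_by_copies else match_count
            k = counts[(pid, protein_id)]
            k_groups, motif = collapse_motif_redundancy(prot_hits)
            if weight_by_copies:
                # weight each evidence group by its best member's copies
                k_eff = _weighted_counts(prot_hits, _group_indices(prot_hits))
            else:
                k_eff = k_groups
            p0 = chance_prob(null.f_mean, prot.length_aa)
            p_binom = binomial_tail(n, k_eff, p0)
            other_matches = sum(
                counts.get((o, protein_id), 0) for o in other_panels
            )
            p_fish = fisher_contrast(
                k_eff, n, other_matches, other_total, two_sided=two_sided_fisher
            )
            flags = set()
            if k_eff < k:
                flags.add(MOTIF_COLLAPSED)
            if n * p0 >= k:
                flags.add(LENGTH_SUSPECT)
            results.append(
                CandidateResult(
                    panel_id=pid,
                    protein_id=protein_id,
                    length_aa=prot.length_aa,
                    n=n,
                    k=k,
                    k_eff=k_eff,
                    shared_motif=motif,
                    p_binomial=p_binom,
                    p_fisher=p_fish,
                    other_matches=other_matches,
                    other_total=other_total,
                    q_value=None,
                    flags=frozenset(flags),
                    rank=0,
                    hits=tuple(prot_hits),
                )
            )
    if compute_qvalues:
        results = _attach_qvalues(results)
    results.sort(
        key=lambda r: (r.p_binomial, r.p_fisher, r.length_aa, r.protein_id, r.panel_id)
    )
    return [replace(r, rank=i + 1) for i, r in enumerate(results)]


def _group_indices(prot_hits: Sequence[MatchHit]) -> dict[int, list[int]]:
    """Motif-collapse grouping as index lists (weight-by-copies helper)."""
    k = len(prot_hits)
    parent = list(range(k))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(k):
        for j in range(i + 1, k):
            hi, hj = prot_hits[i], prot_hits[j]
            if (
                hi.protein_start < hj.protein_end
                and hj.protein_start < hi.protein_end
                and len(
                    _longest_common_substring(
                        [hi.matched_substring, hj.matched_substring]
                    )
                )
                >= MOTIF_COLLAPSE_MIN_OVERLAP
            ):
                ra, rb = find(i), find(j)
                if ra != rb:
                    parent[rb] = ra
    groups: dict[int, list[int]] = {}
    for i in range(k):
        groups.setdefault(find(i), []).append(i)
    return groups


def _attach_qvalues(results: list[CandidateResult]) -> list[CandidateResult]:
    """BH adjustment per panel over proteins with k >= 2."""
    out = list(results)
    by_panel: dict[str, list[int]] = {}
    for idx, res in enumerate(out):
        if res.k >= 2:
            by_panel.setdefault(res.panel_id, []).append(idx)
    for panel_id, indices in by_panel.items():
        pvals = [out[i].p_binomial for i in indices]
        qvals = multipletests(pvals, method="fdr_bh")[1]
        for i, q in zip(indices, qvals):
            out[i] = replace(out[i], q_value=float(q))
    return out


# ---------------------------------------------------------------------------
# QC and expression cross-check


def enrichment_qc(cfu_panel: float, cfu_control: float, fold: float = 2.0) -> tuple[float, bool]:
    """Biopanning enrichment ratio; selection passes at >= ``fold``."""
    if cfu_panel < 0 or cfu_control < 0:
        raise SignificanceError("cfu counts must be non-negative")
    if cfu_control == 0:
        raise SignificanceError("cfu_control must be >= 1")
    ratio = cfu_panel / cfu_control
    return ratio, ratio >= fold


def expression_cross_check(
    candidates: Sequence[CandidateResult],
    expression,
    sample_map: Mapping[str, str],
    gene_map: Mapping[str, str],
    fold_threshold: float = 2.0,
) -> list[CandidateResult]:
    """Flag candidates overexpressed only in their own patient's tumor.

    ``expression`` is a genes x samples DataFrame; ``sample_map`` maps a
    panel id (or its patient id) to the column holding that patient's tumor
    sample; ``gene_map`` maps protein ids to expression gene ids.  A
    candidate is EXPRESSION_SUPPORTED when its gene's value in the own
    sample is at least ``fold_threshold`` times the maximum over all other
    samples.  Unmapped genes leave the candidate unflagged with a logged
    warning.
    """
    out: list[CandidateResult] = []
    for cand in candidates:
        gene = gene_map.get(cand.protein_id)
        sample = sample_map.get(cand.panel_id) or sample_map.get(
            cand.panel_id.split("/")[0]
        )
        if gene is None or gene not in expression.index:
            logger.warning(
                "no expression mapping for protein %s; left unflagged",
                cand.protein_id,
            )
            out.append(cand)
            continue
        if sample is None or sample not in expression.columns:
            logger.warning(
                "no tumor sample mapped for panel %s; left unflagged",
                cand.panel_id,
            )
            out.append(cand)
            continue
        row = expression.loc[gene]
        own = float(row[sample])
        others = row.drop(labels=[sample])
        other_max = float(others.max()) if len(others) else 0.0
        if own >= fold_threshold * other_max and own > 0:
            out.append(replace(cand, flags=cand.flags | {EXPRESSION_SUPPORTED}))
        else:
            out.append(cand)
    return out
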