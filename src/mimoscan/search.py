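"""Short-peptide versus protein matcher.

BLAST is poorly specified for 5-16-mer queries, so this module provides two
transparent modes instead:

* ``exact`` (default): report every *maximal* shared window of length >=
  ``min_exact_window`` with at most ``max_mismatches`` substitutions.
  Maximality means the window cannot be extended on either side without
  exceeding the mismatch budget.  With the default window of 5 and no
  mismatches this captures the "identical or nearly identical" fragments
  that linear-epitope mimotopes produce; window 4 reproduces PWSK-type
  motif matches at the cost of more chance hits.
* ``scored``: ungapped local alignments seeded by exact words of
  ``word_size`` residues, extended in both directions to the maximal
  substitution-matrix score (PAM30 by default, following blastp-short
  conventions) and reported when the score reaches ``min_score``.

Matches are ungapped throughout and no E-value is computed — significance
is handled by the reversed-peptide null model downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

from .io import (
    ExternalMatchRow,
    PeptidePanel,
    PeptideRecord,
    ProteinRecord,
)

_MATRIX_CACHE: dict[str, object] = {}


def _load_matrix(name: str):
    if name not in _MATRIX_CACHE:
        from Bio.Align import substitution_matrices

        _MATRIX_CACHE[name] = substitution_matrices.load(name)
    return _MATRIX_CACHE[name]


@dataclass(frozen=True)
class MatchParams:
    """Matcher configuration shared by the forward and null searches."""

    mode: str = "exact"
    min_exact_window: int = 5
    max_mismatches: int = 0
    score_matrix: str = "PAM30"
    word_size: int = 2
    min_score: int = 35

    def __post_init__(self) -> None:
        if self.mode not in ("exact", "scored"):
            raise ValueError(f"mode must be 'exact' or 'scored', got {self.mode!r}")
        if self.min_exact_window < 4:
            raise ValueError("min_exact_window must be >= 4")
        if not 0 <= self.max_mismatches < self.min_exact_window:
            raise ValueError("max_mismatches must satisfy 0 <= m < min_exact_window")
        if self.word_size < 1:
            raise ValueError("word_size must be >= 1")

    @property
    def min_peptide_length(self) -> int:
        """Shortest peptide the matcher can process in this mode."""
        return self.min_exact_window if self.mode == "exact" else self.word_size


@dataclass(frozen=True)
class MatchHit:
    """One peptide-to-protein match (0-based half-open coordinates).

    ``matched_substring`` holds the protein-side residues of the aligned
    window — the epitope-mimicking motif that the redundancy collapse
    inspects later.
    """

    peptide: PeptideRecord
    protein_id: str
    protein_start: int
    matched_substring: str
    peptide_offset: int
    score: int

    @property
    def protein_end(self) -> int:
        """Exclusive end of the matched window on the protein."""
        return self.protein_start + len(self.matched_substring)


class SearchError(ValueError):
    pass


# ---------------------------------------------------------------------------
# exact mode


def _exact_windows(pep: str, prot: str, w: int, m: int) -> Iterator[tuple[int, int, int]]:
    """Yield maximal shared windows as (peptide_offset, protein_start, length).

    Scans each alignment diagonal with a two-pointer sweep: for every left
    end the furthest right end within the mismatch budget is found, and a
    window is maximal exactly when that right end strictly advances.
    """
    lp, lq = len(pep), len(prot)
    for d in range(-(lp - 1), lq):
        i0 = -d if d < 0 else 0
        j0 = i0 + d
        t = min(lp - i0, lq - j0)
        if t < w:
            continue
        pref = [0] * (t + 1)
        for s in range(t):
            pref[s + 1] = pref[s] + (pep[i0 + s] != prot[j0 + s])
        b = 0
        r_prev = -1
        for a in range(t):
            if b < a:
                b = a
            while b < t and pref[b + 1] - pref[a] <= m:
                b += 1
            if (a == 0 or b > r_prev) and b - a >= w:
                yield (i0 + a, j0 + a, b - a)
            r_prev = b


# ---------------------------------------------------------------------------
# scored mode


def _scored_hits(
    pep: str, prot: str, params: MatchParams
) -> list[tuple[int, int, int, int]]:
    """Ungapped seed-and-extend hits as (pep_off, prot_start, length, score).

    Every exact shared word of ``word_size`` seeds one extension; the
    extension maximizes the summed substitution score independently to the
    left and right of the seed.  Overlapping extensions on one diagonal are
    merged, keeping the best score, then the leftmost start.
    """
    matrix = _load_matrix(params.score_matrix)
    w = params.word_size
    lp, lq = len(pep), len(prot)
    words: dict[str, list[int]] = {}
    for i in range(lp - w + 1):
        words.setdefault(pep[i : i + w], []).append(i)
    raw: dict[tuple[int, int, int], int] = {}
    for j in range(lq - w + 1):
        for i in words.get(prot[j : j + w], ()):
            score = sum(matrix[pep[i + s], prot[j + s]] for s in range(w))
            # extend left
            best_l, run, li = 0.0, 0.0, 0
            k = 1
            while i - k >= 0 and j - k >= 0:
                run += matrix[pep[i - k], prot[j - k]]
                if run > best_l:
                    best_l, li = run, k
                k += 1
            # extend right
            best_r, run, ri = 0.0, 0.0, 0
            k = 0
            while i + w + k < lp and j + w + k < lq:
                run += matrix[pep[i + w + k], prot[j + w + k]]
                if run > best_r:
                    best_r, ri = run, k + 1
                k += 1
            total = int(score + best_l + best_r)
            if total >= params.min_score:
                key = (j - i, i - li, w + li + ri)
                if key not in raw or total > raw[key]:
                    raw[key] = total
    # merge overlapping windows on the same diagonal: best score, then leftmost
    by_diag: dict[int, list[tuple[int, int, int]]] = {}
    for (d, i_start, length), score in raw.items():
        by_diag.setdefault(d, []).append((i_start, length, score))
    out: list[tuple[int, int, int, int]] = []
    for d, wins in by_diag.items():
        wins.sort()
        merged: list[tuple[int, int, int]] = []
        for i_start, length, score in wins:
            if merged and i_start < merged[-1][0] + merged[-1][1]:
                pi, pl, ps = merged[-1]
                if score > ps:
                    merged[-1] = (i_start, length, score)
            else:
                merged.append((i_start, length, score))
        for i_start, length, score in merged:
            out.append((i_start, i_start + d, length, score))
    return out


# ---------------------------------------------------------------------------
# public API


def find_hits(
    peptide: PeptideRecord, protein: ProteinRecord, params: MatchParams
) -> list[MatchHit]:
    """All matches of one peptide within one protein under ``params``."""
    pep, prot = peptide.sequence, protein.sequence
    if len(pep) < params.min_peptide_length:
        raise SearchError(
            f"peptide {pep!r} shorter than minimum {params.min_peptide_length}"
        )
    hits: list[MatchHit] = []
    if params.mode == "exact":
        for i, j, length in _exact_windows(
            pep, prot, params.min_exact_window, params.max_mismatches
        ):
            hits.append(
                MatchHit(
                    peptide=peptide,
                    protein_id=protein.protein_id,
                    protein_start=j,
                    matched_substring=prot[j : j + length],
                    peptide_offset=i,
                    score=length,
                )
            )
    else:
        for i, j, length, score in sorted(_scored_hits(pep, prot, params)):
            hits.append(
                MatchHit(
                    peptide=peptide,
                    protein_id=protein.protein_id,
                    protein_start=j,
                    matched_substring=prot[j : j + length],
                    peptide_offset=i,
                    score=score,
                )
            )
    hits.sort(key=lambda h: (h.protein_start, h.peptide_offset))
    return hits


def _build_word_index(
    proteome: Sequence[ProteinRecord], w: int
) -> dict[str, list[tuple[int, int]]]:
    index: dict[str, list[tuple[int, int]]] = {}
    for pi, prot in enumerate(proteome):
        s = prot.sequence
        for j in range(len(s) - w + 1):
            index.setdefault(s[j : j + w], []).append((pi, j))
    return index


def _search_records_indexed(
    records: Sequence[PeptideRecord],
    proteome: Sequence[ProteinRecord],
    w: int,
    index: Mapping[str, list[tuple[int, int]]],
) -> list[MatchHit]:
    """Exact mode, zero mismatches: w-mer seeds extended to maximal runs.

    Equivalent to the diagonal scan (every shared window of length >= w
    contains at least one shared w-mer), but linear in the number of seed
    hits rather than in peptide x protein length.
    """
    out: list[tuple[int, int, int, int, int]] = []
    for ri, rec in enumerate(records):
        pep = rec.sequence
        seen: set[tuple[int, int, int]] = set()
        for o in range(len(pep) - w + 1):
            for pi, j in index.get(pep[o : o + w], ()):
                prot = proteome[pi].sequence
                i0, j0 = o, j
                while i0 > 0 and j0 > 0 and pep[i0 - 1] == prot[j0 - 1]:
                    i0 -= 1
                    j0 -= 1
                i1, j1 = o + w, j + w
                lp, lq = len(pep), len(prot)
                while i1 < lp and j1 < lq and pep[i1] == prot[j1]:
                    i1 += 1
                    j1 += 1
                key = (pi, j0 - i0, i0)
                if key not in seen:
                    seen.add(key)
                    out.append((ri, pi, j0, i0, i1 - i0))
    out.sort()
    return [
        MatchHit(
            peptide=records[ri],
            protein_id=proteome[pi].protein_id,
            protein_start=j,
            matched_substring=proteome[pi].sequence[j : j + length],
            peptide_offset=i,
            score=length,
        )
        for ri, pi, j, i, length in out
    ]


def search_records(
    records: Sequence[PeptideRecord],
    proteome: Sequence[ProteinRecord],
    params: MatchParams,
    index: Mapping[str, list[tuple[int, int]]] | None = None,
) -> list[MatchHit]:
    """Search a list of peptides against the proteome.

    Peptides shorter than the mode's minimum are skipped (callers that need
    the exclusion count filter beforehand).  Hit order is deterministic:
    record order, then proteome order, then position.
    """
    if not proteome:
        raise SearchError("empty proteome")
    eligible = [r for r in records if len(r.sequence) >= params.min_peptide_length]
    if params.mode == "exact" and params.max_mismatches == 0:
        if index is None:
            index = _build_word_index(proteome, params.min_exact_window)
        return _search_records_indexed(
            eligible, proteome, params.min_exact_window, index
        )
    hits: list[MatchHit] = []
    for rec in eligible:
        for prot in proteome:
            hits.extend(find_hits(rec, prot, params))
    order = {id(r): i for i, r in enumerate(eligible)}
    prot_order = {p.protein_id: i for i, p in enumerate(proteome)}
    hits.sort(
        key=lambda h: (
            order[id(h.peptide)],
            prot_order[h.protein_id],
            h.protein_start,
            h.peptide_offset,
        )
    )
    return hits


def search_panel(
    panel: PeptidePanel,
    proteome: Sequence[ProteinRecord],
    params: MatchParams,
    index: Mapping[str, list[tuple[int, int]]] | None = None,
) -> list[MatchHit]:
    """Search every peptide of one panel against the proteome."""
    return search_records(panel.records, proteome, params, index=index)


def search_panels(
    panels: Sequence[PeptidePanel],
    proteome: Sequence[ProteinRecord],
    params: MatchParams,
) -> list[MatchHit]:
    """Search several panels, building the proteome word index only once."""
    index = None
    if params.mode == "exact" and params.max_mismatches == 0:
        index = _build_word_index(proteome, params.min_exact_window)
    hits: list[MatchHit] = []
    for panel in panels:
        hits.extend(search_panel(panel, proteome, params, index=index))
    return hits


def dedupe_protein_level(hits: Iterable[MatchHit]) -> dict[tuple[str, str], MatchHit]:
    """Reduce hits to one best hit per (peptide sequence, protein).

    The statistics count matching peptides, not matching sites, so multiple
    windows of one peptide within one protein collapse to the best hit:
    highest score, then leftmost on the protein, then leftmost on the
    peptide.
    """
    best: dict[tuple[str, str], MatchHit] = {}
    for hit in hits:
        key = (hit.peptide.sequence, hit.protein_id)
        cur = best.get(key)
        if cur is None or (-hit.score, hit.protein_start, hit.peptide_offset) < (
            -cur.score,
            cur.protein_start,
            cur.peptide_offset,
        ):
            best[key] = hit
    return best


# ---------------------------------------------------------------------------
# interchange with external (BLAST-style) match tables


def external_peptide_id(panel_id: str, sequence: str) -> str:
    """Identifier convention used in emitted match tables."""
    return f"{panel_id}|{sequence}"


def hits_to_external_rows(hits: Iterable[MatchHit]) -> list[list]:
    """Render hits in the 12-column outfmt-6 dialect (1-based inclusive).

    The E-value column is written as 0 (none is computed); the bitscore
    column carries the matcher score.
    """
    rows = []
    for h in hits:
        length = len(h.matched_substring)
        pep_window = h.peptide.sequence[h.peptide_offset : h.peptide_offset + length]
        matches = sum(a == b for a, b in zip(pep_window, h.matched_substring))
        pident = 100.0 * matches / length if length else 0.0
        rows.append(
            [
                external_peptide_id(h.peptide.panel_id, h.peptide.sequence),
                h.protein_id,
                f"{pident:.2f}",
                length,
                length - matches,
                0,
                h.peptide_offset + 1,
                h.peptide_offset + length,
                h.protein_start + 1,
                h.protein_start + length,
                0,
                h.score,
            ]
        )
    return rows


def write_hits_tsv(hits: Iterable[MatchHit], path) -> None:
    with open(path, "w") as fh:
        for row in hits_to_external_rows(hits):
            fh.write("\t".join(str(v) for v in row) + "\n")


def hits_from_external(
    rows: Iterable[ExternalMatchRow],
    panels: Sequence[PeptidePanel],
    proteome: Sequence[ProteinRecord],
) -> list[MatchHit]:
    """Convert imported match rows back into MatchHits.

    ``peptide_id`` must follow the ``panel_id|sequence`` convention used by
    :func:`write_hits_tsv`; the matched protein-side substring is
    reconstructed from the proteome.
    """
    by_panel: dict[str, dict[str, PeptideRecord]] = {
        p.panel_id: {r.sequence: r for r in p.records} for p in panels
    }
    by_protein = {p.protein_id: p for p in proteome}
    hits: list[MatchHit] = []
    for row in rows:
        try:
            panel_id, seq = row.peptide_id.rsplit("|", 1)
        except ValueError:
            raise SearchError(
                f"peptide_id {row.peptide_id!r} does not follow 'panel|sequence'"
            ) from None
        rec = by_panel.get(panel_id, {}).get(seq)
        if rec is None:
            raise SearchError(f"peptide {row.peptide_id!r} not found in panels")
        prot = by_protein.get(row.protein_id)
        if prot is None:
            raise SearchError(f"protein {row.protein_id!r} not found in proteome")
        start = row.align_start - 1
        substring = prot.sequence[start : row.align_end]
        offset = (row.qstart - 1) if row.qstart else max(0, rec.sequence.find(substring))
        hits.append(
            MatchHit(
                peptide=rec,
                protein_id=row.protein_id,
                protein_start=start,
                matched_substring=substring,
                peptide_offset=offset,
                score=len(substring),
            )
        )
    return hits
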