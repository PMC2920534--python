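"""Conserved-motif extraction and wildcard pattern scanning within panels.

Biopanning panels typically contain clonal groups (identical inserts),
motif families (different inserts sharing a 4-6 residue fragment), and
singletons.  This module finds the shared fragments: literal substring
patterns, optionally with interior wildcard positions written ``x``, that
occur in at least two *distinct* peptide sequences.  Clonal identity is not
a motif — identical inserts are one sequence with a copy number.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable

from .io import PeptidePanel

WILDCARD = "x"
MAX_MOTIF_LEN = 10


class MotifError(ValueError):
    pass


@dataclass(frozen=True)
class MotifCluster:
    """A shared motif: consensus pattern plus the peptides carrying it."""

    consensus: str
    member_peptides: frozenset[str]
    phage_support: int

    @property
    def motif_length(self) -> int:
        return len(self.consensus)


def _pattern_matches(pattern: str, seq: str) -> bool:
    return _first_occurrence(pattern, seq) is not None


def _first_occurrence(pattern: str, seq: str) -> int | None:
    L = len(pattern)
    for o in range(len(seq) - L + 1):
        if all(pc == WILDCARD or pc == seq[o + t] for t, pc in enumerate(pattern)):
            return o
    return None


def _occurrences(pattern: str, seq: str) -> list[int]:
    L = len(pattern)
    return [
        o
        for o in range(len(seq) - L + 1)
        if all(pc == WILDCARD or pc == seq[o + t] for t, pc in enumerate(pattern))
    ]


def _extend_literal(pattern: str, members: list[str], cap: int = MAX_MOTIF_LEN) -> str:
    """Greedily grow a pattern with residues on which every member agrees.

    Extension adds literal positions only (never new wildcards), so the
    member set is preserved exactly; it stops at sequence boundaries, at the
    first position where members disagree, or at the length cap.
    """
    changed = True
    while changed and len(pattern) < cap:
        changed = False
        # right
        common: set[str] | None = None
        for seq in members:
            letters = {
                seq[o + len(pattern)]
                for o in _occurrences(pattern, seq)
                if o + len(pattern) < len(seq)
            }
            common = letters if common is None else common & letters
            if not common:
                break
        if common:
            pattern = pattern + min(common)
            changed = True
            continue
        # left
        common = None
        for seq in members:
            letters = {seq[o - 1] for o in _occurrences(pattern, seq) if o > 0}
            common = letters if common is None else common & letters
            if not common:
                break
        if common:
            pattern = min(common) + pattern
            changed = True
    return pattern


def extract_shared_motifs(
    panel: PeptidePanel,
    min_len: int = 4,
    max_len: int = 6,
    max_wildcards: int = 1,
) -> list[MotifCluster]:
    """Find maximal patterns shared by >= 2 distinct peptides of a panel.

    Candidate patterns of length ``min_len``..``max_len`` with at most
    ``max_wildcards`` interior wildcard positions (never at either end) are
    enumerated from every peptide substring, then literally extended while
    all members agree on the flanking residue (up to ``MAX_MOTIF_LEN``).
    For each member set only the longest patterns with the fewest wildcards
    are reported, so e.g. a 4-mer contained in a reported 7-mer with the
    same members is dropped.  Clusters sort by member count, then phage
    support, then consensus.
    """
    if panel.n_unique < 2:
        return []
    copies = {r.sequence: r.copy_number for r in panel.records}
    seqs = sorted(copies)
    # enumerate candidate patterns -> member sets
    members_of: dict[str, set[str]] = {}
    for seq in seqs:
        n = len(seq)
        for L in range(min_len, max_len + 1):
            interior = range(1, L - 1)
            for o in range(n - L + 1):
                window = seq[o : o + L]
                for k in range(0, max_wildcards + 1):
                    for positions in combinations(interior, k):
                        pattern = "".join(
                            WILDCARD if t in positions else c
                            for t, c in enumerate(window)
                        )
                        members_of.setdefault(pattern, set()).add(seq)
    shared = {p: m for p, m in members_of.items() if len(m) >= 2}
    # literal extension; recompute membership is unnecessary (preserved)
    extended: dict[str, frozenset[str]] = {}
    for pattern, members in shared.items():
        grown = _extend_literal(pattern, sorted(members))
        extended.setdefault(grown, frozenset(members))
    # keep, per member set, the longest then least-wildcarded patterns
    by_members: dict[frozenset[str], list[str]] = {}
    for pattern, members in extended.items():
        by_members.setdefault(members, []).append(pattern)
    clusters: list[MotifCluster] = []
    for members, patterns in by_members.items():
        best_len = max(len(p) for p in patterns)
        at_len = [p for p in patterns if len(p) == best_len]
        min_wc = min(p.count(WILDCARD) for p in at_len)
        for pattern in at_len:
            if pattern.count(WILDCARD) == min_wc:
                clusters.append(
                    MotifCluster(
                        consensus=pattern,
                        member_peptides=members,
                        phage_support=sum(copies[s] for s in members),
                    )
                )
    clusters.sort(
        key=lambda c: (-len(c.member_peptides), -c.phage_support, c.consensus)
    )
    return clusters


def scan_pattern(
    panel: PeptidePanel, pattern: str, min_length: int = 4
) -> tuple[int, list[str]]:
    """Count phage particles whose insert matches a wildcard pattern.

    ``x``/``X`` match any residue; leading and trailing wildcards are
    trimmed before matching (they constrain nothing) and the trimmed
    pattern must still reach ``min_length`` residues (floor 3).  Returns
    the phage count (sum of copy numbers of matching records) and the
    distinct matching sequences in panel order.
    """
    if not pattern:
        raise MotifError("empty pattern")
    if min_length < 3:
        raise MotifError("min_length must be >= 3")
    norm = "".join(WILDCARD if c in ("x", "X") else c.upper() for c in pattern)
    trimmed = norm.strip(WILDCARD)
    if len(trimmed) < min_length:
        raise MotifError(
            f"pattern {pattern!r} is {len(trimmed)} informative residues long "
            f"after trimming wildcards; minimum is {min_length}"
        )
    from .io import _AA_SET  # letters must be standard amino acids

    bad = {c for c in trimmed if c != WILDCARD and c not in _AA_SET}
    if bad:
        raise MotifError(f"illegal characters in pattern: {sorted(bad)}")
    matches = [r for r in panel.records if _pattern_matches(trimmed, r.sequence)]
    return sum(r.copy_number for r in matches), [r.sequence for r in matches]


def clone_summary(panel: PeptidePanel) -> tuple[int, int, str, int]:
    """(n_unique, n_phage, dominant sequence, its copy number).

    Ties on copy number resolve to the lexicographically smallest sequence.
    """
    if not panel.records:
        raise MotifError(f"panel {panel.panel_id} is empty")
    top = min(panel.records, key=lambda r: (-r.copy_number, r.sequence))
    return panel.n_unique, panel.n_phage, top.sequence, top.copy_number
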