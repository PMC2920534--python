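"""Chance-match null model from reversed ("spelt backwards") peptides.

Reversing each insert preserves its length and amino-acid composition but
destroys any real epitope signal, so matches of reversed peptides measure
the chance-match background of the search itself.  Because the chance of a
match grows in proportion to protein length, the background is summarized
as a length-normalized frequency

    f_i = M_i / (N * L_i / 1000)

matches per peptide per 1000 aa, where M_i is the number of distinct
reversed peptides matching protein i of length L_i and N is the number of
reversed peptides searched.  ``f_mean``/``f_sd`` aggregate f_i over the
proteins retained by ``min_matches_threshold``.

The threshold of 4 matches mirrors the original procedure of estimating f
from the most overrepresented proteins; conditioning on overrepresentation
biases f upward, which is conservative (it makes forward significance
harder to reach).  At small proteome scale no protein can reach 4 chance
matches, so synthetic runs use threshold 0, which averages over all
proteins and is unbiased.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import PeptidePanel, PeptideRecord, ProteinRecord
from .search import MatchParams, dedupe_protein_level, search_records


class NullModelError(ValueError):
    pass


def reverse_peptide(sequence: str) -> str:
    """Character-reversed sequence; an involution, composition-preserving."""
    return sequence[::-1]


@dataclass(frozen=True)
class ProteinNullRow:
    """Per-protein audit row of the null estimate."""

    protein_id: str
    matches: int
    length_aa: int
    f_i: float


@dataclass(frozen=True)
class NullEstimate:
    """Length-normalized chance-match frequency with its audit trail."""

    f_mean: float
    f_sd: float
    n_peptides_used: int
    proteins_used: tuple[ProteinNullRow, ...]
    min_matches_threshold: int
    params: MatchParams

    def to_dict(self) -> dict:
        return {
            "f_mean": self.f_mean,
            "f_sd": self.f_sd,
            "n_peptides_used": self.n_peptides_used,
            "min_matches_threshold": self.min_matches_threshold,
            "params": asdict(self.params),
            "proteins_used": [asdict(r) for r in self.proteins_used],
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "NullEstimate":
        return cls(
            f_mean=payload["f_mean"],
            f_sd=payload["f_sd"],
            n_peptides_used=payload["n_peptides_used"],
            proteins_used=tuple(
                ProteinNullRow(**row) for row in payload["proteins_used"]
            ),
            min_matches_threshold=payload["min_matches_threshold"],
            params=MatchParams(**payload["params"]),
        )


def write_null(estimate: NullEstimate, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(estimate.to_dict(), fh, indent=1)
        fh.write("\n")


def read_null(path: str | Path) -> NullEstimate:
    with open(path) as fh:
        return NullEstimate.from_dict(json.load(fh))


def null_from_counts(
    n_peptides: int,
    protein_counts: Sequence[tuple[str, int, int]],
    params: MatchParams,
    min_matches_threshold: int = 4,
) -> NullEstimate:
    """Assemble a NullEstimate from per-protein (id, matches, length) rows.

    Split out from :func:`estimate_null` so the arithmetic is testable
    without running a search.
    """
    if n_peptides <= 0:
        raise NullModelError("n_peptides must be positive")
    rows = [
        ProteinNullRow(pid, m, L, 1000.0 * m / (n_peptides * L))
        for pid, m, L in protein_counts
        if m >= min_matches_threshold
    ]
    if not rows:
        raise NullModelError(
            f"no protein reached {min_matches_threshold} reversed-peptide matches; "
            "lower min_matches_threshold or enlarge the proteome"
        )
    f = np.array([r.f_i for r in rows], dtype=float)
    f_mean = float(f.mean())
    f_sd = float(f.std(ddof=1)) if len(f) > 1 else 0.0
    if f_mean == 0.0:
        warnings.warn(
            "null estimate is exactly 0: no reversed peptide matched any protein",
            stacklevel=2,
        )
    return NullEstimate(
        f_mean=f_mean,
        f_sd=f_sd,
        n_peptides_used=n_peptides,
        proteins_used=tuple(rows),
        min_matches_threshold=min_matches_threshold,
        params=params,
    )


def estimate_null(
    panels: Sequence[PeptidePanel],
    proteome: Sequence[ProteinRecord],
    params: MatchParams,
    min_matches_threshold: int = 4,
    include_panels: Sequence[str] | None = None,
) -> NullEstimate:
    """Estimate the chance-match frequency from reversed panel peptides.

    The unique peptides of the included panels (all panels by default;
    restrict with ``include_panels`` e.g. to exclude a healthy-donor
    control) are reversed and searched with the *same* MatchParams as the
    forward analysis.  N counts only peptides long enough to match under
    ``params``.  With ``min_matches_threshold`` 0, every protein enters the
    average, including those with zero matches.
    """
    if include_panels is not None:
        wanted = set(include_panels)
        found = {p.panel_id for p in panels} & wanted
        if found != wanted:
            raise NullModelError(f"unknown panel ids: {sorted(wanted - found)}")
        panels = [p for p in panels if p.panel_id in wanted]
    unique: dict[str, None] = {}
    for panel in panels:
        for rec in panel.records:
            if len(rec.sequence) >= params.min_peptide_length:
                unique.setdefault(rec.sequence, None)
    n = len(unique)
    if n < 10:
        raise NullModelError(
            f"only {n} unique matchable peptides; at least 10 are required "
            "for a usable null estimate"
        )
    if n < 30:
        warnings.warn(
            f"null estimate based on only {n} unique peptides; "
            "frequencies will be noisy",
            stacklevel=2,
        )
    reversed_records = [
        PeptideRecord(reverse_peptide(seq), panel_id="null/reversed")
        for seq in unique
    ]
    hits = search_records(reversed_records, proteome, params)
    per_protein: dict[str, int] = {}
    for (seq, pid) in dedupe_protein_level(hits):
        per_protein[pid] = per_protein.get(pid, 0) + 1
    counts = [
        (prot.protein_id, per_protein.get(prot.protein_id, 0), prot.length_aa)
        for prot in proteome
    ]
    return null_from_counts(n, counts, params, min_matches_threshold)


def chance_prob(f: float, length_aa: float) -> float:
    """Chance probability that one peptide matches a protein of length L.

    The chance of a match is proportional to protein length, so
    p0 = f * L / 1000, capped at 1 for extremely long proteins.
    """
    if f < 0 or length_aa < 1:
        raise NullModelError("f must be >= 0 and length_aa >= 1")
    return min(1.0, f * length_aa / 1000.0)
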