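"""Readers and writers for peptide panels, proteomes, match tables and reports.

Every downstream stage consumes only the domain types defined here.  Panels
arrive as TSV (columns ``patient_id``, ``antibody_class``, ``sequence``,
``copy_number``) or as FASTA with ``patient|class|copies`` headers; proteomes
are plain FASTA; externally produced match tables use the 12-column
BLAST-outfmt-6 dialect.  Internal coordinates are 0-based half-open; the
1-based inclusive convention of the tabular dialect is applied only at these
I/O boundaries.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

#: The 20 standard amino acids; the match statistics assume this alphabet.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

#: Ambiguity / non-standard letters rejected at parse time.
REJECTED_LETTERS = frozenset("BJOUXZ")

MIN_PEPTIDE_LEN = 4
MAX_PEPTIDE_LEN = 50
ANTIBODY_CLASSES = ("IgG", "IgM")

_FASTA_SUFFIXES = {".fa", ".fasta", ".faa", ".fna"}


class ParseError(ValueError):
    """Malformed input file; message carries file and line context."""


def _check_peptide_sequence(seq: str) -> None:
    if not MIN_PEPTIDE_LEN <= len(seq) <= MAX_PEPTIDE_LEN:
        raise ValueError(
            f"peptide length {len(seq)} outside [{MIN_PEPTIDE_LEN}, {MAX_PEPTIDE_LEN}]: {seq!r}"
        )
    for ch in seq:
        if ch not in _AA_SET:
            raise ValueError(f"illegal character {ch!r} in peptide sequence {seq!r}")


@dataclass(frozen=True)
class PeptideRecord:
    """One phage-insert amino-acid sequence with its clonal copy number.

    ``copy_number`` is the number of independently sequenced phage carrying
    this identical insert after selection; statistics count unique sequences
    by default and use copy numbers only for clone summaries and the
    optional weight-by-copies mode.
    """

    sequence: str
    copy_number: int = 1
    panel_id: str = ""
    source_label: str = ""

    def __post_init__(self) -> None:
        _check_peptide_sequence(self.sequence)
        if self.copy_number < 1:
            raise ValueError(f"copy_number must be >= 1, got {self.copy_number}")


@dataclass(frozen=True)
class PeptidePanel:
    """All peptides selected on one patient's antibodies of one isotype.

    Record sequences are pairwise distinct: identical inserts are clonal
    copies and must be merged into ``copy_number`` at load time (see
    :func:`make_panel`).
    """

    patient_id: str
    antibody_class: str
    records: tuple[PeptideRecord, ...]

    def __post_init__(self) -> None:
        if self.antibody_class not in ANTIBODY_CLASSES:
            raise ValueError(
                f"antibody_class must be one of {ANTIBODY_CLASSES}, got {self.antibody_class!r}"
            )
        seqs = [r.sequence for r in self.records]
        if len(seqs) != len(set(seqs)):
            dupes = sorted({s for s in seqs if seqs.count(s) > 1})
            raise ValueError(f"duplicate sequences within panel {self.panel_id}: {dupes}")

    @property
    def panel_id(self) -> str:
        return f"{self.patient_id}/{self.antibody_class}"

    @property
    def n_unique(self) -> int:
        """Number of distinct insert sequences."""
        return len(self.records)

    @property
    def n_phage(self) -> int:
        """Total phage particles (sum of clonal copy numbers)."""
        return sum(r.copy_number for r in self.records)


def make_panel(
    patient_id: str,
    antibody_class: str,
    entries: Iterable[tuple[str, int]],
    source_label: str = "",
) -> PeptidePanel:
    """Build a panel from (sequence, copy_number) pairs, merging duplicates.

    Duplicate sequences have their copy numbers summed; record order is the
    input order of first occurrence.
    """
    panel_id = f"{patient_id}/{antibody_class}"
    merged: dict[str, int] = {}
    for seq, copies in entries:
        merged[seq] = merged.get(seq, 0) + copies
    records = tuple(
        PeptideRecord(seq, copies, panel_id=panel_id, source_label=source_label)
        for seq, copies in merged.items()
    )
    return PeptidePanel(patient_id, antibody_class, records)


@dataclass(frozen=True)
class ProteinRecord:
    """One database protein: accession, free-text description, sequence."""

    protein_id: str
    description: str
    sequence: str

    @property
    def length_aa(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ExternalMatchRow:
    """One row of a BLAST-outfmt-6-style table (1-based inclusive coords).

    Only the columns the pipeline consumes are retained: query and subject
    identifiers, subject (protein) coordinates, and — when available — the
    query (peptide) coordinates, from which the matched substring is later
    reconstructed against the proteome.
    """

    peptide_id: str
    protein_id: str
    align_start: int
    align_end: int
    matched_peptide_substring: str = ""
    qstart: int | None = None
    qend: int | None = None

    def __post_init__(self) -> None:
        if self.align_start > self.align_end:
            raise ValueError(
                f"align_start {self.align_start} > align_end {self.align_end}"
            )
        if self.matched_peptide_substring and (
            len(self.matched_peptide_substring) != self.align_end - self.align_start + 1
        ):
            raise ValueError("matched substring length inconsistent with coordinates")


# ---------------------------------------------------------------------------
# panels


def read_panels(path: str | Path) -> list[PeptidePanel]:
    """Read peptide panels from TSV (or FASTA, detected by suffix).

    Panels are grouped by (patient_id, antibody_class); duplicate sequences
    within a panel are merged with summed copy numbers.
    """
    path = Path(path)
    if path.suffix.lower() in _FASTA_SUFFIXES:
        return read_panels_fasta(path)
    groups: dict[tuple[str, str], list[tuple[str, int]]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise ParseError(f"{path}: empty panel file")
        required = {"patient_id", "antibody_class", "sequence"}
        missing = required - set(reader.fieldnames)
        if missing:
            raise ParseError(f"{path}: missing columns {sorted(missing)}")
        for row in reader:
            line = reader.line_num
            patient = (row.get("patient_id") or "").strip()
            ab = (row.get("antibody_class") or "").strip()
            seq = (row.get("sequence") or "").strip().upper()
            copies_raw = (row.get("copy_number") or "").strip()
            if not patient or not ab or not seq:
                raise ParseError(f"{path}:{line}: malformed row (empty field)")
            try:
                copies = int(copies_raw) if copies_raw else 1
                if copies < 1:
                    raise ValueError
            except ValueError:
                raise ParseError(
                    f"{path}:{line}: invalid copy_number {copies_raw!r}"
                ) from None
            try:
                _check_peptide_sequence(seq)
            except ValueError as exc:
                raise ParseError(f"{path}:{line}: {exc}") from None
            if ab not in ANTIBODY_CLASSES:
                raise ParseError(f"{path}:{line}: unknown antibody class {ab!r}")
            groups.setdefault((patient, ab), []).append((seq, copies))
    return [
        make_panel(patient, ab, entries, source_label=str(path))
        for (patient, ab), entries in groups.items()
    ]


def read_panels_fasta(path: str | Path) -> list[PeptidePanel]:
    """Read panels from FASTA with headers ``patientID|class|copyN``."""
    path = Path(path)
    groups: dict[tuple[str, str], list[tuple[str, int]]] = {}
    n = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        n += 1
        fields = rec.description.split("|")
        if len(fields) < 2:
            raise ParseError(f"{path}: header {rec.description!r} lacks 'patient|class'")
        patient = fields[0].strip()
        ab = fields[1].strip()
        try:
            copies = int(fields[2]) if len(fields) > 2 and fields[2].strip() else 1
        except ValueError:
            raise ParseError(f"{path}: invalid copy count in header {rec.description!r}") from None
        seq = str(rec.seq).upper()
        try:
            _check_peptide_sequence(seq)
        except ValueError as exc:
            raise ParseError(f"{path}: record {rec.description!r}: {exc}") from None
        if ab not in ANTIBODY_CLASSES:
            raise ParseError(f"{path}: unknown antibody class {ab!r}")
        groups.setdefault((patient, ab), []).append((seq, copies))
    if n == 0:
        raise ParseError(f"{path}: empty FASTA panel file")
    return [
        make_panel(patient, ab, entries, source_label=str(path))
        for (patient, ab), entries in groups.items()
    ]


def write_panels(panels: Sequence[PeptidePanel], path: str | Path) -> None:
    """Write panels as the canonical four-column TSV."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["patient_id", "antibody_class", "sequence", "copy_number"])
        for panel in panels:
            for rec in panel.records:
                writer.writerow(
                    [panel.patient_id, panel.antibody_class, rec.sequence, rec.copy_number]
                )


# ---------------------------------------------------------------------------
# proteome


def read_proteome(path: str | Path) -> list[ProteinRecord]:
    """Read a protein database from FASTA; sequences are uppercased.

    The first whitespace-delimited header token is the protein id; duplicate
    ids and empty files are errors.
    """
    path = Path(path)
    proteins: list[ProteinRecord] = []
    seen: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        proteins.append(ProteinRecord(rec.id, desc, str(rec.seq).upper()))
        seen[rec.id] = seen.get(rec.id, 0) + 1
    if not proteins:
        raise ParseError(f"{path}: no FASTA records found")
    dupes = sorted(pid for pid, cnt in seen.items() if cnt > 1)
    if dupes:
        raise ParseError(f"{path}: duplicate protein ids: {dupes}")
    return proteins


def write_proteome(proteins: Sequence[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write proteins as wrapped FASTA."""
    with open(path, "w") as fh:
        for prot in proteins:
            header = f">{prot.protein_id}"
            if prot.description:
                header += f" {prot.description}"
            fh.write(header + "\n")
            for i in range(0, len(prot.sequence), width):
                fh.write(prot.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# external match tables (BLAST outfmt-6 dialect)


def read_external_matches(path: str | Path) -> list[ExternalMatchRow]:
    """Read a 12-column BLAST-outfmt-6-like table.

    Columns 1, 2, 9, 10 are used as peptide_id, protein_id, align_start and
    align_end (1-based inclusive); columns 7, 8 (query start/end) are kept so
    the peptide-side window can be recovered.  An empty file yields an empty
    list.
    """
    path = Path(path)
    rows: list[ExternalMatchRow] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 12:
                raise ParseError(
                    f"{path}:{lineno}: expected 12 columns, got {len(fields)}"
                )
            try:
                qstart, qend = int(fields[6]), int(fields[7])
                sstart, send = int(fields[8]), int(fields[9])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from None
            try:
                rows.append(
                    ExternalMatchRow(
                        peptide_id=fields[0],
                        protein_id=fields[1],
                        align_start=sstart,
                        align_end=send,
                        qstart=qstart,
                        qend=qend,
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
    return rows


# ---------------------------------------------------------------------------
# reports


def format_float(value) -> str:
    """Fixed report formatting: 6 significant digits, scientific < 1e-4."""
    if value is None:
        return "NA"
    v = float(value)
    if v == 0:
        return "0"
    if abs(v) < 1e-4:
        return f"{v:.5e}"
    return f"{v:.6g}"


REPORT_COLUMNS = (
    "panel_id",
    "protein_id",
    "length_aa",
    "n",
    "k",
    "k_eff",
    "p_binomial",
    "p_fisher",
    "flags",
)


def write_report(results: Sequence, path: str | Path) -> Path:
    """Write ranked candidates as TSV plus a JSON mirror with per-hit detail.

    Output is byte-identical for identical input: candidate order is taken
    as given (results are pre-ranked), floats use :func:`format_float`, and
    flags are emitted sorted.  Returns the JSON path.
    """
    path = Path(path)
    json_path = path.with_suffix(".json")
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(REPORT_COLUMNS)
        for res in results:
            writer.writerow(
                [
                    res.panel_id,
                    res.protein_id,
                    res.length_aa,
                    res.n,
                    res.k,
                    res.k_eff,
                    format_float(res.p_binomial),
                    format_float(res.p_fisher),
                    ",".join(sorted(res.flags)),
                ]
            )
    payload = [
        {
            "panel_id": res.panel_id,
            "protein_id": res.protein_id,
            "length_aa": res.length_aa,
            "n": res.n,
            "k": res.k,
            "k_eff": res.k_eff,
            "shared_motif": res.shared_motif,
            "p_binomial": res.p_binomial,
            "p_fisher": res.p_fisher,
            "other_matches": res.other_matches,
            "other_total": res.other_total,
            "q_value": res.q_value,
            "flags": sorted(res.flags),
            "rank": res.rank,
            "hits": [
                {
                    "peptide": h.peptide.sequence,
                    "copy_number": h.peptide.copy_number,
                    "protein_start": h.protein_start + 1,  # 1-based in files
                    "matched_substring": h.matched_substring,
                    "peptide_offset": h.peptide_offset + 1,
                    "score": h.score,
                }
                for h in res.hits
            ],
        }
        for res in results
    ]
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")
    return json_path


def read_report(json_path: str | Path) -> list:
    """Read back the JSON side of a report as CandidateResult objects."""
    from .search import MatchHit
    from .significance import CandidateResult

    with open(json_path) as fh:
        payload = json.load(fh)
    results = []
    for entry in payload:
        hits = tuple(
            MatchHit(
                peptide=PeptideRecord(
                    h["peptide"], h["copy_number"], panel_id=entry["panel_id"]
                ),
                protein_id=entry["protein_id"],
                protein_start=h["protein_start"] - 1,
                matched_substring=h["matched_substring"],
                peptide_offset=h["peptide_offset"] - 1,
                score=h["score"],
            )
            for h in entry["hits"]
        )
        results.append(
            CandidateResult(
                panel_id=entry["panel_id"],
                protein_id=entry["protein_id"],
                length_aa=entry["length_aa"],
                n=entry["n"],
                k=entry["k"],
                k_eff=entry["k_eff"],
                shared_motif=entry["shared_motif"],
                p_binomial=entry["p_binomial"],
                p_fisher=entry["p_fisher"],
                other_matches=entry["other_matches"],
                other_total=entry["other_total"],
                q_value=entry["q_value"],
                flags=frozenset(entry["flags"]),
                rank=entry["rank"],
                hits=hits,
            )
        )
    return results
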