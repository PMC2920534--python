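"""Seeded generator of synthetic proteomes and biopanning-style panels.

The generator emulates the structure of real biopanning output — clonal
expansions (identical inserts with copy numbers), motif families (distinct
inserts sharing a short fragment that also occurs in some database
protein), planted epitope carriers, and random singletons — against a
proteome with a lognormal length spread that includes very long decoys
(mucin-16- and nesprin-1-sized, 14,507 and 8,749 aa) so the
length-normalization machinery is always exercised.

Ground truth (which protein carries the epitope, which peptides carry it,
which protein anchors each motif family) is emitted alongside, so any
pipeline run over the generated files can be scored without re-reading the
configuration.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .io import AMINO_ACIDS, PeptidePanel, ProteinRecord, make_panel

DEFAULT_DECOY_LENGTHS = (14507, 8749)


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class PanelSpec:
    """One synthetic panel: size, peptide length law, planted content.

    ``copy_geometric_p`` parameterizes the clonal copy-number law
    (geometric on {1, 2, ...}; p = 0.5 gives mean 2, matching the modest
    clonal expansions typical of a four-round selection).
    """

    patient_id: str
    antibody_class: str = "IgG"
    n_unique: int = 3
    peptide_length: tuple[int, int] = (7, 12)
    copy_geometric_p: float = 0.5
    n_epitope_peptides: int = 0
    epitope_mutations: int = 0
    motif_family_size: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.peptide_length
        if not (4 <= lo <= hi <= 50):
            raise SimulationError(f"peptide_length {self.peptide_length} out of range")
        if self.n_epitope_peptides > self.n_unique:
            raise SimulationError("n_epitope_peptides cannot exceed n_unique")
        if not 0.0 < self.copy_geometric_p <= 1.0:
            raise SimulationError("copy_geometric_p must be in (0, 1]")
        if self.motif_family_size and self.motif_family_size < 2:
            raise SimulationError("motif_family_size must be 0 or >= 2")


@dataclass(frozen=True)
class SimConfig:
    """Full simulation scenario.

    Defaults mirror the study conditions of a single-patient analysis
    embedded in a multi-panel screen: one 3-peptide target panel with two
    epitope carriers against a 400-aa planted antigen, plus a 67-peptide
    background panel so the pooled reversed-peptide null runs on 70 unique
    peptides; a 300-protein uniform-composition proteome (lognormal
    lengths, median 450 aa) with the two very long decoys appended.

    With ``shared_epitope`` False (default) every carrier mimics its own
    epitope, planted at a distinct site of the planted protein — the
    multi-epitope humoral response of a genuine antigen, where each
    distinct peptide is independent evidence.  With ``shared_epitope``
    True all carriers embed one common epitope; their matches then fall on
    one protein site and the downstream motif-redundancy collapse counts
    them as a single piece of evidence, as it should.
    """

    seed: int = 0
    n_proteins: int = 300
    length_median: float = 450.0
    length_sigma: float = 0.6
    min_protein_length: int = 60
    decoy_lengths: tuple[int, ...] = DEFAULT_DECOY_LENGTHS
    aa_frequencies: tuple[float, ...] | None = None
    panels: tuple[PanelSpec, ...] = (
        PanelSpec(patient_id="A", n_unique=3, n_epitope_peptides=2),
        PanelSpec(patient_id="B", n_unique=67),
    )
    planted_protein: int = 0
    planted_protein_length: int | None = 400
    epitope_length: int = 6
    shared_epitope: bool = False

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise SimulationError("n_proteins must be >= 1")
        if not 0 <= self.planted_protein < self.n_proteins:
            raise SimulationError("planted_protein index out of range")
        if self.aa_frequencies is not None:
            freqs = np.asarray(self.aa_frequencies, dtype=float)
            if len(freqs) != 20 or abs(freqs.sum() - 1.0) > 1e-9:
                raise SimulationError("aa_frequencies must be 20 values summing to 1")
        for spec in self.panels:
            if spec.n_epitope_peptides and self.epitope_length > spec.peptide_length[0]:
                raise SimulationError(
                    f"epitope length {self.epitope_length} exceeds the shortest "
                    f"peptide ({spec.peptide_length[0]}) of panel {spec.patient_id}"
                )


#: Approximate human amino-acid composition, for realism experiments.
NATURAL_AA_FREQUENCIES = (
    0.070, 0.023, 0.047, 0.071, 0.036, 0.066, 0.026, 0.044, 0.057, 0.100,
    0.021, 0.036, 0.063, 0.048, 0.056, 0.083, 0.053, 0.060, 0.012, 0.028,
)


@dataclass
class GroundTruth:
    """Everything needed to score a pipeline run on generated data."""

    planted_protein_id: str
    epitopes: list[dict]  # [{"sequence": ..., "site": 0-based}, ...]
    carriers: dict[str, list[dict]]  # panel_id -> [{"peptide", "epitope", "site"}]
    motif_families: dict[str, dict]  # panel_id -> {motif, protein_id, members}
    decoy_protein_ids: list[str]

    def carrier_peptides(self, panel_id: str) -> list[str]:
        return [c["peptide"] for c in self.carriers.get(panel_id, [])]

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, payload: dict) -> "GroundTruth":
        return cls(**payload)


def _random_seq(rng: np.random.Generator, length: int, freqs) -> str:
    letters = rng.choice(list(AMINO_ACIDS), size=length, p=freqs)
    return "".join(letters)


def _mutate(rng: np.random.Generator, seq: str, n_mut: int, freqs) -> str:
    if n_mut == 0:
        return seq
    positions = rng.choice(len(seq), size=min(n_mut, len(seq)), replace=False)
    chars = list(seq)
    for pos in positions:
        alternatives = [a for a in AMINO_ACIDS if a != chars[pos]]
        chars[pos] = str(rng.choice(alternatives))
    return "".join(chars)


def generate(
    config: SimConfig,
) -> tuple[list[ProteinRecord], list[PeptidePanel], GroundTruth]:
    """Generate (proteome, panels, ground truth); deterministic per seed."""
    rng = np.random.default_rng(config.seed)
    freqs = (
        np.asarray(config.aa_frequencies, dtype=float)
        if config.aa_frequencies is not None
        else None
    )
    # proteome
    lengths = rng.lognormal(
        mean=math.log(config.length_median),
        sigma=config.length_sigma,
        size=config.n_proteins,
    )
    lengths = np.maximum(lengths.round().astype(int), config.min_protein_length)
    proteins: list[ProteinRecord] = [
        ProteinRecord(f"SYN{i:05d}", "synthetic protein", _random_seq(rng, L, freqs))
        for i, L in enumerate(lengths)
    ]
    decoy_ids = []
    for j, L in enumerate(config.decoy_lengths):
        pid = f"DECOY{j}_L{L}"
        decoy_ids.append(pid)
        proteins.append(
            ProteinRecord(pid, "synthetic oversized decoy", _random_seq(rng, L, freqs))
        )
    # fix the planted protein's length when the scenario pins it
    if config.planted_protein_length is not None:
        target = proteins[config.planted_protein]
        proteins[config.planted_protein] = ProteinRecord(
            target.protein_id,
            target.description,
            _random_seq(rng, config.planted_protein_length, freqs),
        )
    # plant epitopes: one per carrier slot (distinct sites), or one shared
    n_slots = sum(s.n_epitope_peptides for s in config.panels)
    epitopes: list[dict] = []
    if n_slots:
        n_epitopes = 1 if config.shared_epitope else n_slots
        target = proteins[config.planted_protein]
        seq = target.sequence
        e_len = config.epitope_length
        if n_epitopes * e_len * 3 > len(seq):
            raise SimulationError(
                "planted protein too short for the requested number of epitopes"
            )
        used: list[tuple[int, int]] = []
        for _ in range(n_epitopes):
            for _attempt in range(1000):
                epi = _random_seq(rng, e_len, freqs)
                site = int(rng.integers(0, len(seq) - e_len + 1))
                if any(site < hi and lo < site + e_len for lo, hi in used):
                    continue
                cand = seq[:site] + epi + seq[site + e_len :]
                if cand.count(epi) != 1:
                    continue
                if any(cand.count(e["sequence"]) != 1 for e in epitopes):
                    continue
                if any(
                    epi in p.sequence
                    for i, p in enumerate(proteins)
                    if i != config.planted_protein
                ):
                    continue
                seq = cand
                used.append((site, site + e_len))
                epitopes.append({"sequence": epi, "site": site})
                break
            else:  # pragma: no cover - astronomically unlikely
                raise SimulationError("could not plant a unique epitope")
        proteins[config.planted_protein] = ProteinRecord(
            target.protein_id, target.description, seq
        )

    panels: list[PeptidePanel] = []
    carriers: dict[str, list[dict]] = {}
    motif_families: dict[str, dict] = {}
    slot = 0
    for spec in config.panels:
        panel_id = f"{spec.patient_id}/{spec.antibody_class}"
        lo, hi = spec.peptide_length
        sequences: list[str] = []
        seen: set[str] = set()

        def draw_peptide(min_len: int = lo) -> str:
            length = int(rng.integers(max(lo, min_len), hi + 1))
            return _random_seq(rng, length, freqs)

        # epitope carriers
        panel_carriers: list[dict] = []
        for _ in range(spec.n_epitope_peptides):
            entry = epitopes[0] if config.shared_epitope else epitopes[slot]
            slot += 1
            for _ in range(1000):
                pep = draw_peptide(min_len=config.epitope_length)
                insert = _mutate(rng, entry["sequence"], spec.epitope_mutations, freqs)
                off = int(rng.integers(0, len(pep) - len(insert) + 1))
                pep = pep[:off] + insert + pep[off + len(insert) :]
                if pep not in seen:
                    break
            seen.add(pep)
            sequences.append(pep)
            panel_carriers.append(
                {"peptide": pep, "epitope": entry["sequence"], "site": entry["site"]}
            )
        # motif family: distinct peptides sharing a 4-mer that also occurs
        # in a designated non-planted, regular-sized protein
        if spec.motif_family_size:
            candidates = [
                i
                for i in range(config.n_proteins)
                if i != config.planted_protein
            ]
            anchor_idx = int(rng.choice(candidates))
            anchor = proteins[anchor_idx]
            motif = _random_seq(rng, 4, freqs)
            if motif not in anchor.sequence:
                pos = int(rng.integers(0, anchor.length_aa - 4 + 1))
                proteins[anchor_idx] = ProteinRecord(
                    anchor.protein_id,
                    anchor.description,
                    anchor.sequence[:pos] + motif + anchor.sequence[pos + 4 :],
                )
            members = []
            for _ in range(spec.motif_family_size):
                for _ in range(1000):
                    pep = draw_peptide()
                    off = int(rng.integers(0, len(pep) - 4 + 1))
                    pep = pep[:off] + motif + pep[off + 4 :]
                    if pep not in seen:
                        break
                seen.add(pep)
                sequences.append(pep)
                members.append(pep)
            motif_families[panel_id] = {
                "motif": motif,
                "protein_id": proteins[anchor_idx].protein_id,
                "members": members,
            }
        # random background
        while len(sequences) < spec.n_unique:
            pep = draw_peptide()
            if pep in seen:
                continue
            seen.add(pep)
            sequences.append(pep)
        copies = rng.geometric(spec.copy_geometric_p, size=len(sequences))
        panels.append(
            make_panel(
                spec.patient_id,
                spec.antibody_class,
                list(zip(sequences, (int(c) for c in copies))),
                source_label="synthetic",
            )
        )
        if panel_carriers:
            carriers[panel_id] = panel_carriers

    truth = GroundTruth(
        planted_protein_id=(
            proteins[config.planted_protein].protein_id if n_slots else ""
        ),
        epitopes=epitopes,
        carriers=carriers,
        motif_families=motif_families,
        decoy_protein_ids=decoy_ids,
    )
    return proteins, panels, truth


def write_truth(truth: GroundTruth, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=1)
        fh.write("\n")


def read_truth(path: str | Path) -> GroundTruth:
    with open(path) as fh:
        return GroundTruth.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# Table 1 reference fixture


_TABLE1 = (
    ("A", "IgG", (
        ("TGVRGQRISQ", 9),
        ("QNPGETSKMN", 6),
        ("KYRWYK", 3),
    )),
    ("A", "IgM", (
        ("AVHFPDDLITPGD", 2),
        ("AEPPFEF", 2),
        ("PSKAAYVV", 3),
        ("QDLYSSA", 3),
        ("QDIFSSA", 3),
        ("MSSVMTY", 1),
        ("FQSPK", 2),
        ("ASHQNRPFRQAAS", 1),
    )),
    ("B", "IgG", (
        ("FSRRAQQVGAK", 3),
        ("DHNRSMSHNRVSNK", 1),
        ("KGMGHHGNG", 1),
        ("KAYGHHLSAE", 2),
        ("GLGVGHKSYSGYWHSWIFGA", 1),
        ("KSHGHHR", 1),
        ("KSNKCFM", 1),
        ("KQSGHHRSE", 1),
        ("WTRRPYDELIV", 1),
    )),
    ("C", "IgG", (
        ("KENGRSPTHS", 10),
        ("GRSNKSG", 1),
        ("SPTHP", 5),
        ("GRRNKSG", 1),
    )),
    ("D", "IgG", (
        ("VPWSKPW", 1),
        ("WTQGHNNHNRHHP", 1),
        ("SNVRSFDNPIANT", 1),
        ("PWSKTL", 2),
        ("IPLPPPSRPF", 2),
        ("HNTRNWTLPP", 1),
        ("SNVISYPDVGN", 1),
        ("PWSKQINIVNTTSYNMRP", 2),
        ("LPWSKLSSPSSNVKNYMAIPQLHPHNLHSP", 1),
        ("TLHTTHSPFK", 1),
        ("NYEPVPRGAR", 1),
        ("TDAAPWSKVT", 2),
        ("GKSLHGSHHP", 1),
        ("SNVISFRHAS", 1),
        ("TNVISYTPLY", 3),
    )),
    ("D", "IgM", (
        ("QSLDHSSC", 5),
        ("LNPQSPRD", 4),
        ("YSWRAT", 4),
        ("NERSEAR", 1),
        ("HFHHLAVRGRPQGWLGWGTVEPDPTRWGARLVK", 1),
        ("GGRWNR", 2),
        ("PETTDK", 2),
        ("PGHVRGTLGR", 2),
        ("YVDTLSKLRGQSLA", 1),
        ("AVRRPD", 4),
        ("QRLAAGFHQLAETLF", 1),
        ("GRKTELF", 1),
        ("YLASPFE", 1),
        ("FRVARAARTGRMWRLVYPQQVVGLVP", 2),
        ("QIQLSGG", 1),
        ("VKNRGR", 1),
    )),
    ("Normal control", "IgG", (
        ("DIRLSAQLSW", 1),
        ("SGYYTYTNGVHHGRGLYNFMGK", 1),
        ("RRTDYLLNGDPTVSESS", 1),
        ("APQGYLFKESSTKSE", 1),
        ("NQHLILSVGS", 1),
        ("IAAAVHRANKEPAT", 1),
    )),
)


def table1_fixture() -> list[PeptidePanel]:
    """The reference peptide inventory of the colorectal-cancer screen.

    Four IgG-positive patients (A-D), two of them also IgM-positive, plus a
    healthy-donor control panel.  Copy numbers are clone counts from
    sequencing.  The published table typesets several inserts as run-on
    strings; this fixture encodes one documented reading (run-ons split at
    annotation boundaries), so per-panel phage totals can differ slightly
    from totals quoted in prose.  The A/IgG panel is unambiguous:
    {TGVRGQRISQ:9, QNPGETSKMN:6, KYRWYK:3}, 18 phage in all.
    """
    return [
        make_panel(patient, ab, entries, source_label="table1")
        for patient, ab, entries in _TABLE1
    ]
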