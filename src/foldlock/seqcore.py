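"""Sequence types and construction of locking-to-unlocking probes.

A locking-to-unlocking probe is a single DNA strand with three segments:

* a *sensing sequence* — the full reverse complement of the target miRNA;
* a hexacytosine (by default) *loop* that hosts the emissive silver
  nanocluster;
* a short *fold-back anchor* — the reverse complement of a terminal segment
  of the sensing sequence, so that anchor and sensing close a hairpin stem
  around the loop.

Target hybridization opens ("unlocks") the stem and extinguishes the
nanocluster fluorescence.  The anchor length is the central design variable.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

__all__ = [
    "Strand",
    "PairingEnd",
    "SequenceError",
    "NucleicAcidSequence",
    "TargetMiRNA",
    "ProbeDesign",
    "PublishedProbeEntry",
    "PublishedProbeRegistry",
    "validate_sequence",
    "reverse_complement",
    "build_probe",
    "enumerate_panel",
    "probe_name",
    "read_targets",
    "write_probes_fasta",
    "load_packaged_targets",
    "load_registry",
]

_DNA_ALPHABET = frozenset("ACGT")
_RNA_ALPHABET = frozenset("ACGU")
_COMPLEMENT_DNA = {"A": "T", "T": "A", "U": "A", "G": "C", "C": "G"}
_COMPLEMENT_RNA = {"A": "U", "T": "A", "U": "A", "G": "C", "C": "G"}

# Typical mature miRNA length range; designs outside it are allowed but
# flagged because the packaged assay defaults assume a mature miRNA target.
MIRNA_LEN_RANGE = (17, 27)


class Strand(str, Enum):
    """Strand chemistry of a sequence."""

    DNA = "DNA"
    RNA = "RNA"


class PairingEnd(str, Enum):
    """Which terminus of the sensing sequence the fold-back anchor covers.

    The stem must be contiguous with the loop for a hairpin to close, so the
    segment order of the full probe follows from this choice:

    * ``FIVE_PRIME``  — probe is 5'-anchor-loop-sensing-3'; the anchor pairs
      with the 5'-terminal segment of the sensing sequence.
    * ``THREE_PRIME`` — probe is 5'-sensing-loop-anchor-3'; the anchor pairs
      with the 3'-terminal segment of the sensing sequence.

    Both conventions produce the same stem thermodynamics for a given stem
    segment; which one the published probes use is fixed by calibration
    against the published anchor lengths (see :mod:`foldlock.design`).
    """

    FIVE_PRIME = "five_prime"
    THREE_PRIME = "three_prime"


class SequenceError(ValueError):
    """Raised for empty, mixed-alphabet or otherwise invalid sequences."""


@dataclass(frozen=True)
class NucleicAcidSequence:
    """A validated 5'→3' nucleic-acid sequence.

    ``residues`` is canonical uppercase over {A,C,G,T} (DNA) or {A,C,G,U}
    (RNA).  IUPAC ambiguity codes are rejected: the assay is single-target
    and ambiguous bases have no defined nearest-neighbor thermodynamics.
    """

    residues: str
    strand_class: Strand

    def __post_init__(self) -> None:
        if not isinstance(self.strand_class, Strand):
            object.__setattr__(self, "strand_class", Strand(self.strand_class))
        _check_alphabet(self.residues, self.strand_class)

    def __len__(self) -> int:
        return len(self.residues)

    def __str__(self) -> str:
        return self.residues


def _check_alphabet(residues: str, strand_class: Strand) -> None:
    if not residues:
        raise SequenceError("empty sequence")
    alphabet = _DNA_ALPHABET if strand_class is Strand.DNA else _RNA_ALPHABET
    for pos, base in enumerate(residues, start=1):
        if base not in alphabet:
            if strand_class is Strand.DNA and base == "U":
                raise SequenceError(f"U is not a DNA residue (position {pos})")
            if strand_class is Strand.RNA and base == "T":
                raise SequenceError(f"T is not an RNA residue (position {pos})")
            raise SequenceError(
                f"illegal {strand_class.value} residue {base!r} at position {pos}"
            )


def validate_sequence(raw: str, strand_class: Strand | str) -> NucleicAcidSequence:
    """Validate ``raw`` and return its canonical uppercase form.

    Raises :class:`SequenceError` for empty input or characters outside the
    strand alphabet; error messages report the 1-based offending position.
    """
    strand_class = Strand(strand_class)
    if raw is None or not raw.strip():
        raise SequenceError("empty sequence")
    return NucleicAcidSequence(raw.strip().upper(), strand_class)


def reverse_complement(
    seq: NucleicAcidSequence, out_class: Strand | str = Strand.DNA
) -> NucleicAcidSequence:
    """Watson–Crick reverse complement in the requested alphabet.

    A↔T/U and G↔C; applying the operation twice with matching classes is the
    identity.
    """
    out_class = Strand(out_class)
    table = _COMPLEMENT_DNA if out_class is Strand.DNA else _COMPLEMENT_RNA
    out = "".join(table[b] for b in reversed(seq.residues))
    return NucleicAcidSequence(out, out_class)


@dataclass(frozen=True)
class TargetMiRNA:
    """A named target miRNA (RNA, 5'→3')."""

    identifier: str
    sequence: NucleicAcidSequence

    def __post_init__(self) -> None:
        if self.sequence.strand_class is not Strand.RNA:
            raise SequenceError("target miRNA must be RNA")
        n = len(self.sequence)
        lo, hi = MIRNA_LEN_RANGE
        if not lo <= n <= hi:
            warnings.warn(
                f"target {self.identifier!r} length {n} nt is outside the "
                f"typical mature miRNA range {lo}-{hi} nt",
                stacklevel=2,
            )


@dataclass(frozen=True)
class ProbeDesign:
    """A three-segment locking-to-unlocking probe.

    The anchor is the exact reverse complement of a terminal segment of the
    sensing sequence (which terminus is set by ``pairing_end``); the loop is
    all-cytosine.  ``full_sequence`` is the 5'→3' concatenation in the order
    implied by ``pairing_end``.
    """

    target_id: str
    sensing: NucleicAcidSequence
    loop: NucleicAcidSequence
    anchor: NucleicAcidSequence
    pairing_end: PairingEnd = PairingEnd.FIVE_PRIME
    name: str = ""

    def __post_init__(self) -> None:
        if not isinstance(self.pairing_end, PairingEnd):
            object.__setattr__(self, "pairing_end", PairingEnd(self.pairing_end))
        for seg in (self.sensing, self.loop, self.anchor):
            if seg.strand_class is not Strand.DNA:
                raise SequenceError("probe segments must be DNA")
        if set(self.loop.residues) != {"C"}:
            raise SequenceError("loop must contain only C residues")
        if self.anchor_len > len(self.sensing):
            raise SequenceError("anchor longer than sensing sequence")
        expected = reverse_complement(
            NucleicAcidSequence(self.stem_segment, Strand.DNA), Strand.DNA
        )
        if self.anchor.residues != expected.residues:
            raise SequenceError(
                "anchor is not the reverse complement of the "
                f"{self.pairing_end.value} terminal sensing segment"
            )
        if not self.name:
            object.__setattr__(self, "name", probe_name(self))

    @property
    def anchor_len(self) -> int:
        return len(self.anchor)

    @property
    def loop_len(self) -> int:
        return len(self.loop)

    @property
    def stem_segment(self) -> str:
        """The sensing segment base-paired by the anchor, 5'→3'."""
        k = len(self.anchor)
        if self.pairing_end is PairingEnd.FIVE_PRIME:
            return self.sensing.residues[:k]
        return self.sensing.residues[-k:]

    @property
    def full_sequence(self) -> NucleicAcidSequence:
        if self.pairing_end is PairingEnd.FIVE_PRIME:
            seq = self.anchor.residues + self.loop.residues + self.sensing.residues
        else:
            seq = self.sensing.residues + self.loop.residues + self.anchor.residues
        return NucleicAcidSequence(seq, Strand.DNA)


def probe_name(probe: ProbeDesign) -> str:
    """Canonical probe name, e.g. ``6C-miR-21-10bp``."""
    return f"{probe.loop_len}C-{probe.target_id}-{probe.anchor_len}bp"


def build_probe(
    target: TargetMiRNA,
    anchor_len: int,
    loop_len: int = 6,
    pairing_end: PairingEnd | str = PairingEnd.FIVE_PRIME,
) -> ProbeDesign:
    """Construct a probe for ``target`` with the requested anchor length.

    The sensing sequence is the DNA reverse complement of the target, the
    loop is ``C * loop_len`` and the anchor is the reverse complement of the
    ``pairing_end`` terminal segment of the sensing sequence.  Warns when
    ``loop_len`` < 3 (a stem cannot close around a shorter loop).
    """
    pairing_end = PairingEnd(pairing_end)
    if anchor_len < 1:
        raise SequenceError("anchor_len must be >= 1")
    if loop_len < 1:
        raise SequenceError("loop_len must be >= 1")
    sensing = reverse_complement(target.sequence, Strand.DNA)
    if anchor_len > len(sensing):
        raise SequenceError(
            f"anchor_len {anchor_len} exceeds sensing length {len(sensing)}"
        )
    if loop_len < 3:
        warnings.warn(
            f"loop_len {loop_len} < 3: a hairpin stem cannot close around the loop",
            stacklevel=2,
        )
    if pairing_end is PairingEnd.FIVE_PRIME:
        stem = sensing.residues[:anchor_len]
    else:
        stem = sensing.residues[-anchor_len:]
    anchor = reverse_complement(NucleicAcidSequence(stem, Strand.DNA), Strand.DNA)
    loop = NucleicAcidSequence("C" * loop_len, Strand.DNA)
    return ProbeDesign(
        target_id=target.identifier,
        sensing=sensing,
        loop=loop,
        anchor=anchor,
        pairing_end=pairing_end,
    )


def enumerate_panel(
    target: TargetMiRNA,
    anchor_lens: Sequence[int],
    loop_len: int = 6,
    pairing_end: PairingEnd | str = PairingEnd.FIVE_PRIME,
) -> list[ProbeDesign]:
    """One probe per requested anchor length, order preserved."""
    if not anchor_lens:
        raise SequenceError("anchor_lens must be non-empty")
    return [
        build_probe(target, k, loop_len=loop_len, pairing_end=pairing_end)
        for k in anchor_lens
    ]


# ---------------------------------------------------------------------------
# FASTA / registry I/O
# ---------------------------------------------------------------------------


def read_targets(path: str | Path) -> list[TargetMiRNA]:
    """Read target miRNAs from FASTA (single or multi record) or plain text.

    A file without a ``>`` header is treated as one plain-text sequence named
    after the file stem.  T residues are accepted and transcribed to U so
    DNA-alphabet target listings work unchanged.
    """
    path = Path(path)
    text = path.read_text()
    targets: list[TargetMiRNA] = []
    if text.lstrip().startswith(">"):
        for rec in SeqIO.parse(str(path), "fasta"):
            targets.append(_target_from_raw(rec.id, str(rec.seq)))
    else:
        raw = "".join(text.split())
        if not raw:
            raise SequenceError(f"no sequence found in {path}")
        targets.append(_target_from_raw(path.stem, raw))
    if not targets:
        raise SequenceError(f"no FASTA records found in {path}")
    return targets


def _target_from_raw(identifier: str, raw: str) -> TargetMiRNA:
    seq = validate_sequence(raw.upper().replace("T", "U"), Strand.RNA)
    return TargetMiRNA(identifier, seq)


def write_probes_fasta(probes: Iterable[ProbeDesign], path: str | Path) -> None:
    """Write probes as FASTA, one record per probe, named by probe name."""
    lines = []
    for p in probes:
        lines.append(f">{p.name} target={p.target_id} anchor={p.anchor_len}bp "
                     f"loop={p.loop_len}C pairing_end={p.pairing_end.value}")
        lines.append(p.full_sequence.residues)
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass(frozen=True)
class PublishedProbeEntry:
    """One published probe: name, target, geometry and spectral readout."""

    name: str
    target_id: str
    anchor_len: int
    loop_len: int
    excitation_nm: float
    readout_nm: float
    readout_nominal: bool = False
    excitation_nm_variants: tuple[float, ...] = ()


@dataclass
class PublishedProbeRegistry:
    """The published probe set plus the target sequences they sense."""

    entries: list[PublishedProbeEntry]
    targets: dict[str, TargetMiRNA] = field(default_factory=dict)

    def probe(self, name: str) -> PublishedProbeEntry:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(f"probe {name!r} not in registry")

    def target(self, target_id: str) -> TargetMiRNA:
        try:
            return self.targets[target_id]
        except KeyError:
            raise KeyError(f"target {target_id!r} not in registry") from None

    def probes_for_target(self, target_id: str) -> list[PublishedProbeEntry]:
        return [e for e in self.entries if e.target_id == target_id]


def load_packaged_targets() -> dict[str, TargetMiRNA]:
    """The packaged target/specificity-panel miRNAs (canonical catalog)."""
    ref = resources.files("foldlock.data").joinpath("mirna_targets.fasta")
    out: dict[str, TargetMiRNA] = {}
    with resources.as_file(ref) as path:
        for rec in SeqIO.parse(str(path), "fasta"):
            out[rec.id] = _target_from_raw(rec.id, str(rec.seq))
    return out


def load_registry() -> PublishedProbeRegistry:
    """Load the packaged published-probe registry."""
    ref = resources.files("foldlock.data").joinpath("published_probes.json")
    payload = json.loads(ref.read_text())
    entries = [
        PublishedProbeEntry(
            name=p["name"],
            target_id=p["target"],
            anchor_len=int(p["anchor_len"]),
            loop_len=int(p["loop_len"]),
            excitation_nm=float(p["excitation_nm"]),
            readout_nm=float(p["readout_nm"]),
            readout_nominal=bool(p.get("readout_nominal", False)),
            excitation_nm_variants=tuple(p.get("excitation_nm_variants", [])),
        )
        for p in payload["probes"]
    ]
    return PublishedProbeRegistry(entries=entries, targets=load_packaged_targets())
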