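"""Nearest-neighbor thermodynamics for probe stems and target duplexes.

Implements the additive two-state nearest-neighbor (NN) model: a duplex free
energy is the sum of an initiation term and one stacking term per
dinucleotide step.  Two parameter sets are packaged as versioned CSV files:

* DNA/DNA (Sugimoto et al. 1996) — used for the hairpin stem formed between
  the fold-back anchor and the sensing sequence;
* RNA/DNA hybrid (Sugimoto et al. 1995) — used for the sensing:miRNA duplex
  that forms when the probe is unlocked.

All free energies are standard values at 37 °C (ΔG°37) in kcal/mol, with
ΔH in kcal/mol and ΔS in cal/(mol·K).  Melting temperatures use the
two-state relation with a bimolecular concentration term for duplexes and
no concentration term for unimolecular hairpins; monovalent salt enters as
the entropic correction ΔS += 0.368 · (stacks) · ln[Na+].

The model is deliberately two-state: no dangling ends, terminal mismatches,
internal loops or partition functions — the designed stem and the perfect
target duplex are the only structures scored.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import pandas as pd

from .seqcore import (
    NucleicAcidSequence,
    ProbeDesign,
    Strand,
    reverse_complement,
    validate_sequence,
)

__all__ = [
    "GAS_CONSTANT",
    "T37_K",
    "NNParameterSet",
    "ThermoResult",
    "HairpinModel",
    "UnlockScore",
    "ThermoError",
    "load_dna_dna_params",
    "load_rna_dna_params",
    "stack_dG",
    "stack_params",
    "duplex_thermo",
    "hairpin_thermo",
    "unlock_score",
    "loop_penalty_dG37",
]

GAS_CONSTANT = 1.987  # cal/(mol K)
T37_K = 310.15
# Entropic monovalent-salt coefficient per stack (SantaLucia 1998).
SALT_ENTROPY_COEFF = 0.368

DEFAULT_SALT_M = 0.045  # 20 mM Tris-acetate + 25 mM NaNO3, as Na+ equivalent
DEFAULT_STRAND_CONC_M = 1.5e-6

_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}


class ThermoError(ValueError):
    """Raised for unknown steps, mismatched strands or degenerate stems."""


@dataclass(frozen=True)
class NNParameterSet:
    """A nearest-neighbor stack table plus initiation and loop penalties.

    ``stacks`` maps a dinucleotide step (5'→3' on the reference strand — the
    single DNA strand for DNA/DNA, the RNA strand for RNA/DNA hybrids) to
    ``(dH, dS, dG37)``.  DNA/DNA tables are symmetric: a step and its
    reverse complement share one entry.  ``units`` records the free-energy
    unit of the stored values; some secondary literature prints the same
    stack magnitudes labelled kJ/mol, but the values here are kcal/mol,
    consistent with their ΔH/ΔS sources.
    """

    duplex_class: str  # "DNA/DNA" or "RNA/DNA"
    stacks: dict[str, tuple[float, float, float]]
    initiation: tuple[float, float, float]
    hairpin_loop_penalty: dict[int, float]
    symmetric: bool
    source: str
    units: str = "kcal/mol"
    salt_model: str = "entropic-0.368-ln-Na"

    def lookup(self, step: str) -> tuple[float, float, float]:
        step = step.upper()
        if step in self.stacks:
            return self.stacks[step]
        if self.symmetric:
            rc = _COMPLEMENT.get(step[1], "?") + _COMPLEMENT.get(step[0], "?")
            if rc in self.stacks:
                return self.stacks[rc]
        raise ThermoError(
            f"unknown {self.duplex_class} nearest-neighbor step {step!r}"
        )


def _read_table(name: str) -> pd.DataFrame:
    ref = resources.files("foldlock.data").joinpath(name)
    return pd.read_csv(io.StringIO(ref.read_text()), comment="#")


@lru_cache(maxsize=None)
def _loop_table() -> dict[int, float]:
    df = _read_table("hairpin_loop_dg37.csv")
    return {int(r.loop_len): float(r.dG37_kcal_mol) for r in df.itertuples()}


def loop_penalty_dG37(loop_len: int, table: dict[int, float] | None = None) -> float:
    """Hairpin loop closure penalty at 37 °C (kcal/mol, destabilizing).

    Tabulated sizes are returned directly; larger loops use the
    Jacobson–Stockmayer extrapolation from the largest tabulated size.
    Loops shorter than the smallest tabulated size cannot close a stem.
    """
    table = table if table is not None else _loop_table()
    if loop_len in table:
        return table[loop_len]
    nmax = max(table)
    if loop_len > nmax:
        return table[nmax] + 1.75 * GAS_CONSTANT / 1000.0 * T37_K * math.log(
            loop_len / nmax
        )
    raise ThermoError(f"no hairpin loop penalty for loop of {loop_len} nt")


@lru_cache(maxsize=None)
def load_dna_dna_params() -> NNParameterSet:
    """Packaged DNA/DNA stack table (Sugimoto et al. 1996)."""
    return _load_params(
        "nn_dna_dna_sugimoto1996.csv", "DNA/DNA", symmetric=True,
        source="Sugimoto et al. 1996 NAR 24:4501",
    )


@lru_cache(maxsize=None)
def load_rna_dna_params() -> NNParameterSet:
    """Packaged RNA/DNA hybrid stack table (Sugimoto et al. 1995)."""
    return _load_params(
        "nn_dna_rna_sugimoto1995.csv", "RNA/DNA", symmetric=False,
        source="Sugimoto et al. 1995 Biochemistry 34:11211",
    )


def _load_params(filename: str, duplex_class: str, symmetric: bool,
                 source: str) -> NNParameterSet:
    df = _read_table(filename)
    stacks: dict[str, tuple[float, float, float]] = {}
    initiation = (0.0, 0.0, 0.0)
    for r in df.itertuples():
        triple = (float(r.dH_kcal_mol), float(r.dS_cal_mol_K),
                  float(r.dG37_kcal_mol))
        if r.step == "init":
            initiation = triple
        else:
            stacks[str(r.step)] = triple
    return NNParameterSet(
        duplex_class=duplex_class,
        stacks=stacks,
        initiation=initiation,
        hairpin_loop_penalty=_loop_table(),
        symmetric=symmetric,
        source=source,
    )


def stack_params(step: str, paramset: NNParameterSet) -> tuple[float, float, float]:
    """(ΔH, ΔS, ΔG°37) for one dinucleotide step."""
    if len(step) != 2:
        raise ThermoError(f"a nearest-neighbor step is a dinucleotide, got {step!r}")
    return paramset.lookup(step)


def stack_dG(step: str, paramset: NNParameterSet) -> float:
    """Tabulated ΔG°37 (kcal/mol) for one dinucleotide step."""
    return stack_params(step, paramset)[2]


@dataclass(frozen=True)
class ThermoResult:
    """NN thermodynamics of one duplex or stem under stated conditions."""

    dH: float      # kcal/mol
    dS: float      # cal/(mol K), 1 M salt reference
    dG37: float    # kcal/mol
    tm_c: float    # deg C at the stated salt/concentration
    salt_m: float
    strand_conc_m: float | None
    molecularity: int  # 2 = bimolecular duplex, 1 = unimolecular hairpin
    n_stacks: int


def _sum_stacks(seq: str, paramset: NNParameterSet) -> tuple[float, float, float]:
    dH = dS = dG = 0.0
    for i in range(len(seq) - 1):
        h, s, g = paramset.lookup(seq[i : i + 2])
        dH += h
        dS += s
        dG += g
    return dH, dS, dG


def _salted_entropy(dS: float, n_stacks: int, salt_m: float) -> float:
    return dS + SALT_ENTROPY_COEFF * n_stacks * math.log(salt_m)


def duplex_thermo(
    strand_a: NucleicAcidSequence | str,
    strand_b: NucleicAcidSequence | str,
    paramset: NNParameterSet | None = None,
    salt_m: float = DEFAULT_SALT_M,
    strand_conc_m: float = DEFAULT_STRAND_CONC_M,
) -> ThermoResult:
    """Two-state thermodynamics of a perfect bimolecular duplex.

    ``strand_a`` is DNA (5'→3'); ``strand_b`` must be its exact reverse
    complement, in DNA (homoduplex) or RNA (hybrid).  The paramset defaults
    to the packaged table matching ``strand_b``'s chemistry.  ΔG°37 = stack
    sum + initiation; Tm uses the CT/4 molarity term for non-self-
    complementary association and the entropic salt correction.
    """
    if isinstance(strand_a, str):
        strand_a = validate_sequence(strand_a, Strand.DNA)
    if isinstance(strand_b, str):
        cls = Strand.RNA if "U" in strand_b.upper() else Strand.DNA
        strand_b = validate_sequence(strand_b, cls)
    if strand_a.strand_class is not Strand.DNA:
        raise ThermoError("strand_a must be DNA")
    if len(strand_a) < 2:
        raise ThermoError("duplex must be at least 2 bp")
    expected = reverse_complement(strand_a, strand_b.strand_class)
    if strand_b.residues != expected.residues:
        raise ThermoError(
            "strands are not perfectly complementary: expected "
            f"{expected.residues}, got {strand_b.residues}"
        )
    hybrid = strand_b.strand_class is Strand.RNA
    if paramset is None:
        paramset = load_rna_dna_params() if hybrid else load_dna_dna_params()
    # Hybrid tables are keyed on the RNA strand; homoduplex tables on strand_a.
    ref_seq = strand_b.residues if hybrid else strand_a.residues
    dH, dS, dG = _sum_stacks(ref_seq, paramset)
    ih, is_, ig = paramset.initiation
    dH, dS, dG = dH + ih, dS + is_, dG + ig
    n_stacks = len(strand_a) - 1
    ds_eff = _salted_entropy(dS, n_stacks, salt_m)
    denom = ds_eff + GAS_CONSTANT * math.log(strand_conc_m / 4.0)
    tm_c = dH * 1000.0 / denom - 273.15
    return ThermoResult(
        dH=dH, dS=dS, dG37=dG, tm_c=tm_c, salt_m=salt_m,
        strand_conc_m=strand_conc_m, molecularity=2, n_stacks=n_stacks,
    )


@dataclass(frozen=True)
class HairpinModel:
    """Energetics of the locked hairpin: NN stem plus loop-closure penalty.

    ``tm_stem_c`` is the unimolecular melting estimate with the loop treated
    as a pure entropic cost at 37 °C and the salt correction applied to the
    stem stacks; ``tm_stacks_c`` is the bare stack-limited ΔH/ΔS estimate
    (no loop, no salt), provided as an alternative stem-matching objective.
    """

    probe_name: str
    stem_seq: str
    stem_stacks: tuple[str, ...]
    dH_stem: float
    dS_stem: float
    dG_stem: float
    dG_loop: float
    dG_hairpin: float
    tm_stem_c: float
    tm_stacks_c: float
    salt_m: float


def hairpin_thermo(
    probe: ProbeDesign,
    paramset: NNParameterSet | None = None,
    salt_m: float = DEFAULT_SALT_M,
) -> HairpinModel:
    """Score the locked hairpin of ``probe`` under the DNA/DNA NN model."""
    if paramset is None:
        paramset = load_dna_dna_params()
    stem = probe.stem_segment
    if len(stem) < 2:
        raise ThermoError(
            f"stem of {len(stem)} bp is too short for the NN model (need >= 2)"
        )
    steps = tuple(stem[i : i + 2] for i in range(len(stem) - 1))
    dH, dS, dG = _sum_stacks(stem, paramset)
    dg_loop = loop_penalty_dG37(probe.loop_len, paramset.hairpin_loop_penalty)
    ds_loop = -dg_loop * 1000.0 / T37_K  # loop as pure entropy at 37 C
    ds_eff = _salted_entropy(dS, len(steps), salt_m) + ds_loop
    tm_stem_c = dH * 1000.0 / ds_eff - 273.15
    tm_stacks_c = dH * 1000.0 / dS - 273.15
    return HairpinModel(
        probe_name=probe.name,
        stem_seq=stem,
        stem_stacks=steps,
        dH_stem=dH,
        dS_stem=dS,
        dG_stem=dG,
        dG_loop=dg_loop,
        dG_hairpin=dG + dg_loop,
        tm_stem_c=tm_stem_c,
        tm_stacks_c=tm_stacks_c,
        salt_m=salt_m,
    )


@dataclass(frozen=True)
class UnlockScore:
    """Free-energy comparison of the locked hairpin vs the target duplex.

    ``ddG_unlock = dG_target_duplex − dG_hairpin`` (kcal/mol at 37 °C);
    negative values mean unlocking by the target is thermodynamically
    favorable.
    """

    probe_name: str
    dG_target_duplex: float
    dG_hairpin: float
    ddG_unlock: float


def unlock_score(
    probe: ProbeDesign,
    target,
    params_dna: NNParameterSet | None = None,
    params_hybrid: NNParameterSet | None = None,
    salt_m: float = DEFAULT_SALT_M,
    strand_conc_m: float = DEFAULT_STRAND_CONC_M,
) -> UnlockScore:
    """Score how favorably ``target`` opens the locked probe.

    The unlocked state is the full-length sensing:miRNA hybrid duplex
    (stacks + bimolecular initiation); the locked state is the anchor stem
    plus loop penalty.  The target must be the miRNA the probe was built
    for (checked by reverse complementarity against the sensing sequence).
    """
    expected = reverse_complement(probe.sensing, Strand.RNA)
    if target.sequence.residues != expected.residues:
        raise ThermoError(
            f"probe {probe.name} was not built from target {target.identifier}"
        )
    duplex = duplex_thermo(
        probe.sensing, target.sequence,
        paramset=params_hybrid, salt_m=salt_m, strand_conc_m=strand_conc_m,
    )
    hairpin = hairpin_thermo(probe, paramset=params_dna, salt_m=salt_m)
    return UnlockScore(
        probe_name=probe.name,
        dG_target_duplex=duplex.dG37,
        dG_hairpin=hairpin.dG_hairpin,
        ddG_unlock=duplex.dG37 - hairpin.dG_hairpin,
    )
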