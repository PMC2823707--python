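"""Nearest-neighbor duplex thermodynamics and melting temperatures.

Implements the two-state nearest-neighbor (NN) model for perfect-complement
duplexes: enthalpy/entropy sums over dinucleotide stacks plus a duplex
initiation term, and the corrected melting temperature

    Tm = 1000 * dH / (dS + A + R ln(Ct / 4)) - 273.15
         + 16.6 log10([Na+]) - 0.63 * F

where ``A`` is a helix-initiation factor (cal/(K mol)), ``Ct`` the total
oligonucleotide strand concentration (M), ``[Na+]`` the monovalent salt
concentration (M) and ``F`` the formamide percentage (v/v). The formamide
correction is exactly linear at 0.63 degC per 1% formamide; the salt term is
the classical 16.6 log10 form. Both correction terms can be toggled for
sensitivity studies, and the ``Ct/4`` convention (non-self-complementary
duplexes) is a configurable divisor.

Three duplex chemistries are supported, each backed by a packaged parameter
table: DNA/DNA (SantaLucia unified), RNA/RNA (Xia) and the orientation-
specific RNA/DNA hybrid set (Sugimoto), the latter keyed by the RNA strand
read 5'->3'.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources

from . import seqs
from .errors import (
    ConfigurationError,
    DegenerateInputError,
    InputError,
    IntegrityError,
    NumericalDomainError,
)

T0_KELVIN = 273.15
REFERENCE_T_C = 37.0  # native temperature of the packaged loop tables
GAS_CONSTANT_CAL = 1.987  # cal/(K mol)
GAS_CONSTANT_KCAL = 1.987e-3  # kcal/(K mol)

PARAMETER_SETS = ("DNA/DNA", "RNA/RNA", "RNA/DNA")

_STACK_FILES = {
    "DNA/DNA": "stacks_dna_dna.tsv",
    "RNA/RNA": "stacks_rna_rna.tsv",
    "RNA/DNA": "stacks_rna_dna.tsv",
}
_LOOP_FILES = {
    "DNA/DNA": "loops_dna.tsv",
    "RNA/RNA": "loops_rna.tsv",
    # Hybrid duplexes never fold on their own; interior loops in
    # interaction ensembles reuse the DNA table.
    "RNA/DNA": "loops_dna.tsv",
}
_KEY_ALPHABET = {
    "DNA/DNA": seqs.DNA_ALPHABET,
    "RNA/RNA": seqs.RNA_ALPHABET,
    "RNA/DNA": seqs.RNA_ALPHABET,  # keys are the RNA strand
}
_REFERENCES = {
    "DNA/DNA": "SantaLucia (1998) unified NN parameters",
    "RNA/RNA": "Xia et al. (1998) Watson-Crick NN parameters",
    "RNA/DNA": "Sugimoto et al. (1995) RNA/DNA hybrid NN parameters",
}


@dataclass(frozen=True)
class ThermoConditions:
    """Reaction conditions entering duplex energies and Tm.

    Defaults are the hybridization conditions of the modelled NimbleGen
    experiments: 0.6 M Na+, helix initiation A = -10.8 cal/(K M), strand
    concentration Ct = 6.1e-17 M, formamide slope 0.63 degC per percent.
    """

    temperature_c: float = REFERENCE_T_C
    sodium_m: float = 0.6
    formamide_pct: float = 0.0
    strand_conc_m: float = 6.1e-17
    helix_init_a: float = -10.8
    gas_constant: float = GAS_CONSTANT_CAL
    formamide_slope: float = 0.63
    ct_divisor: float = 4.0
    salt_correction: bool = True
    formamide_correction: bool = True

    def __post_init__(self) -> None:
        if self.sodium_m <= 0:
            raise InputError(f"sodium concentration must be > 0, got {self.sodium_m}")
        if self.formamide_pct < 0:
            raise InputError(f"formamide percentage must be >= 0, got {self.formamide_pct}")
        if self.strand_conc_m <= 0:
            raise InputError(f"strand concentration must be > 0, got {self.strand_conc_m}")
        if self.ct_divisor <= 0:
            raise InputError(f"Ct divisor must be > 0, got {self.ct_divisor}")

    @property
    def temperature_k(self) -> float:
        return self.temperature_c + T0_KELVIN

    def with_(self, **kwargs) -> "ThermoConditions":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class NNParameterSet:
    """A validated nearest-neighbor parameter table for one chemistry."""

    name: str
    stacks: dict  # dinucleotide -> (dH kcal/mol, dS cal/(K mol))
    initiation: tuple  # (dH, dS)
    hairpin: dict = field(default_factory=dict)  # anchor size -> dG37
    bulge: dict = field(default_factory=dict)
    internal: dict = field(default_factory=dict)
    multiloop: tuple = (3.4, 0.4, 0.0)  # (a, b, c) kcal/mol at 37 C
    reference: str = ""

    @property
    def key_alphabet(self) -> frozenset:
        return _KEY_ALPHABET[self.name]

    def stack_dg(self, dinuc: str, temperature_k: float) -> float:
        dh, ds = self.stacks[dinuc]
        return dh - temperature_k * ds / 1000.0


@dataclass(frozen=True)
class DuplexThermo:
    """NN enthalpy/entropy sums of a perfect-complement duplex."""

    dH: float  # kcal/mol
    dS: float  # cal/(K mol)
    dG_at_T: float  # kcal/mol at the conditions' temperature
    n_stacks: int
    parameter_set: str = "DNA/DNA"


def _read_table(filename: str) -> list:
    text = resources.files("hybtherm.data").joinpath(filename).read_text()
    rows = []
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        rows.append(line.split())
    return rows


def _load_stacks(name: str) -> tuple:
    rows = _read_table(_STACK_FILES[name])
    stacks = {}
    initiation = None
    for row in rows:
        if row[0] == "init":
            initiation = (float(row[1]), float(row[2]))
            continue
        if len(row) != 3 or len(row[0]) != 2:
            raise IntegrityError(f"malformed stack row in {_STACK_FILES[name]}: {row}")
        stacks[row[0]] = (float(row[1]), float(row[2]))
    if initiation is None:
        raise IntegrityError(f"{_STACK_FILES[name]}: missing 'init' entry")
    alphabet = sorted(_KEY_ALPHABET[name])
    for a in alphabet:
        for b in alphabet:
            if a + b not in stacks:
                raise IntegrityError(f"{_STACK_FILES[name]}: missing stack entry {a + b}")
    return stacks, initiation


def _load_loops(name: str) -> tuple:
    rows = _read_table(_LOOP_FILES[name])
    hairpin, bulge, internal = {}, {}, {}
    multiloop = None
    table = {"hairpin": hairpin, "bulge": bulge, "internal": internal}
    for row in rows:
        if row[0] == "multiloop":
            multiloop = (float(row[1]), float(row[2]), float(row[3]))
            continue
        if row[0] not in table:
            raise IntegrityError(f"{_LOOP_FILES[name]}: unknown loop kind {row[0]}")
        size, dg = int(row[1]), float(row[2])
        if dg < 0:
            raise IntegrityError(f"{_LOOP_FILES[name]}: negative loop penalty {row}")
        table[row[0]][size] = dg
    if multiloop is None:
        raise IntegrityError(f"{_LOOP_FILES[name]}: missing 'multiloop' entry")
    for kind, tab in table.items():
        if not tab:
            raise IntegrityError(f"{_LOOP_FILES[name]}: missing {kind} entries")
    return hairpin, bulge, internal, multiloop


def load_parameter_set(name: str) -> NNParameterSet:
    """Load and validate the packaged NN table for one duplex chemistry.

    ``name`` must be one of ``"DNA/DNA"``, ``"RNA/RNA"`` or ``"RNA/DNA"``.
    """
    if name not in PARAMETER_SETS:
        raise ConfigurationError(
            f"unknown parameter set {name!r}; supported: {', '.join(PARAMETER_SETS)}"
        )
    stacks, initiation = _load_stacks(name)
    hairpin, bulge, internal, multiloop = _load_loops(name)
    return NNParameterSet(
        name=name,
        stacks=stacks,
        initiation=initiation,
        hairpin=hairpin,
        bulge=bulge,
        internal=internal,
        multiloop=multiloop,
        reference=_REFERENCES[name],
    )


def _resolve_params(params) -> NNParameterSet:
    if isinstance(params, NNParameterSet):
        return params
    return load_parameter_set(params)


def duplex_thermo(probe_seq: str, duplex_type="DNA/DNA", conditions: ThermoConditions | None = None) -> DuplexThermo:
    """NN dH/dS/dG sums for a probe against its exact complement.

    For the hybrid chemistry the probe is the DNA strand; its stacks are
    looked up via the complementary RNA strand (the keyed strand of the
    Sugimoto table), so orientation is handled internally.
    """
    conditions = conditions or ThermoConditions()
    params = _resolve_params(duplex_type)
    if params.name == "RNA/RNA":
        keyed = seqs.validate(probe_seq, seqs.RNA_ALPHABET, "RNA probe")
    else:
        probe = seqs.validate(probe_seq, seqs.DNA_ALPHABET, "DNA probe")
        if params.name == "RNA/DNA":
            # keyed strand = complementary RNA target, read 5'->3'
            keyed = seqs.to_rna(seqs.revcomp_dna(probe))
        else:
            keyed = probe
    if len(keyed) < 2:
        raise DegenerateInputError(
            f"duplex of length {len(keyed)} has no stacks; need length >= 2"
        )
    dh, ds = params.initiation
    for i in range(len(keyed) - 1):
        h, s = params.stacks[keyed[i : i + 2]]
        dh += h
        ds += s
    t_k = conditions.temperature_k
    return DuplexThermo(
        dH=dh,
        dS=ds,
        dG_at_T=dh - t_k * ds / 1000.0,
        n_stacks=len(keyed) - 1,
        parameter_set=params.name,
    )


def melting_temperature(duplex: DuplexThermo, conditions: ThermoConditions | None = None) -> float:
    """Corrected two-state melting temperature in degC.

    Denominator is dS + A + R ln(Ct/divisor) in cal/(K mol); dH enters in
    cal/mol. Salt and formamide corrections apply to the Kelvin result and
    can be switched off individually via the conditions object.
    """
    conditions = conditions or ThermoConditions()
    denom = (
        duplex.dS
        + conditions.helix_init_a
        + conditions.gas_constant * math.log(conditions.strand_conc_m / conditions.ct_divisor)
    )
    if denom >= 0 or duplex.dH >= 0:
        raise NumericalDomainError(
            f"Tm undefined for dH={duplex.dH} kcal/mol, denominator={denom} cal/(K mol) "
            f"(Ct={conditions.strand_conc_m}, A={conditions.helix_init_a})"
        )
    tm_k = 1000.0 * duplex.dH / denom
    if tm_k <= 0:
        raise NumericalDomainError(
            f"non-physical Tm {tm_k} K for dH={duplex.dH}, denom={denom}"
        )
    tm_c = tm_k - T0_KELVIN
    if conditions.salt_correction:
        tm_c += 16.6 * math.log10(conditions.sodium_m)
    if conditions.formamide_correction:
        tm_c -= conditions.formamide_slope * conditions.formamide_pct
    return tm_c


def probe_tm(probe_seq: str, conditions: ThermoConditions | None = None) -> float:
    """Convenience: SantaLucia DNA/DNA Tm of a probe sequence."""
    conditions = conditions or ThermoConditions()
    return melting_temperature(duplex_thermo(probe_seq, "DNA/DNA", conditions), conditions)
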