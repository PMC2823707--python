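"""Secondary-structure ensembles of single strands and duplexes.

A McCaskill-style partition function, minimum-free-energy folding with
traceback, constrained folding for opening (accessibility) energies, and an
interaction-only duplex ensemble replace the external folding tools the
analysis pipeline otherwise depends on.

Energy model
------------
Pseudoknot-free loop decomposition over Watson-Crick pairs: dinucleotide
stack energies from the nearest-neighbor tables (dH - T dS/1000), length-
dependent hairpin/bulge/internal-loop penalties (treated as purely entropic,
i.e. scaled by T/T_ref from their 37 degC values, with Jacobson-Stockmayer
interpolation between anchor sizes), and a linear multiloop model
a + b*branches + c*unpaired. Hairpin loops have at least three unpaired
bases; interior loops are capped at 30 unpaired bases; there are no dangling
ends or coaxial stacks. An exhaustive structure enumerator over the same
model serves as the test oracle for every dynamic program in this module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _kernels, seqs
from .errors import BoundsError, ConfigurationError, InputError
from .nn_thermo import (
    GAS_CONSTANT_KCAL,
    NNParameterSet,
    T0_KELVIN,
    load_parameter_set,
)

TURN = _kernels.TURN
MAXLOOP = 30
ENUM_LIMIT = 20
_T_REF_K = 310.15

_ENC = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}
_CANPAIR = np.zeros((4, 4), dtype=np.bool_)
for _x, _y in ((0, 3), (3, 0), (1, 2), (2, 1)):
    _CANPAIR[_x, _y] = True


@dataclass(frozen=True)
class Region:
    """0-based half-open interval on a strand."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise BoundsError(f"invalid region [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def check_within(self, n: int) -> None:
        if self.end > n:
            raise BoundsError(f"region [{self.start}, {self.end}) outside strand of length {n}")


@dataclass(frozen=True)
class FoldResult:
    partition_Z: float
    ensemble_dG: float  # kcal/mol
    temperature: float  # degC
    parameter_set: str


@dataclass(frozen=True)
class MfeResult:
    structure: str
    mfe_dG: float  # kcal/mol


def _encode(seq: str, params: NNParameterSet) -> np.ndarray:
    if params.name == "RNA/RNA":
        seq = seqs.validate(seq, seqs.RNA_ALPHABET, "RNA strand")
    elif params.name == "DNA/DNA":
        seq = seqs.validate(seq, seqs.DNA_ALPHABET, "DNA strand")
    else:
        raise ConfigurationError(
            f"single-strand folding is not defined for the {params.name} hybrid set"
        )
    return np.array([_ENC[c] for c in seq], dtype=np.int64)


def _loop_dg37(anchors: dict, max_size: int) -> np.ndarray:
    """Dense dG37 array from anchor sizes with Jacobson-Stockmayer filling."""
    sizes = sorted(anchors)
    out = np.full(max_size + 1, np.inf)
    js = 1.75 * GAS_CONSTANT_KCAL * _T_REF_K
    for s in range(sizes[0], max_size + 1):
        if s in anchors:
            out[s] = anchors[s]
        else:
            a = max(x for x in sizes if x < s)
            out[s] = anchors[a] + js * math.log(s / a)
    return out


class EnergyModel:
    """Temperature-resolved tables of one parameter set, shared by all DPs."""

    def __init__(self, params: NNParameterSet, temperature_c: float = 37.0):
        self.params = params
        self.temperature_c = temperature_c
        t_k = temperature_c + T0_KELVIN
        self.t_k = t_k
        self.rt = GAS_CONSTANT_KCAL * t_k
        scale = t_k / _T_REF_K  # loop penalties are treated as entropic
        # letters by encoding: A=0, C=1, G=2, T/U=3
        letter = {0: "A", 1: "C", 2: "G", 3: "U" if "U" in params.key_alphabet else "T"}
        self.stack_e = np.zeros((4, 4))
        for x in range(4):
            for y in range(4):
                self.stack_e[x, y] = params.stack_dg(letter[x] + letter[y], t_k)
        nmax = 2048  # longest supported strand
        self.hairpin_e = _loop_dg37(params.hairpin, nmax) * scale
        self.bulge_e = _loop_dg37(params.bulge, MAXLOOP) * scale
        self.internal_e = _loop_dg37(params.internal, MAXLOOP) * scale
        a, b, c = params.multiloop
        self.ml = (a * scale, b * scale, c * scale)
        # Boltzmann weights
        self.stack_w = np.exp(-self.stack_e / self.rt)
        hp = np.where(np.isfinite(self.hairpin_e), self.hairpin_e, np.inf)
        with np.errstate(over="ignore"):
            self.hairpin_w = np.where(np.isfinite(hp), np.exp(-hp / self.rt), 0.0)
            self.bulge_w = np.where(
                np.isfinite(self.bulge_e), np.exp(-self.bulge_e / self.rt), 0.0
            )
            self.internal_w = np.where(
                np.isfinite(self.internal_e), np.exp(-self.internal_e / self.rt), 0.0
            )
        self.ml_w = tuple(math.exp(-x / self.rt) for x in self.ml)
        dh_i, ds_i = params.initiation
        self.init_e = dh_i - t_k * ds_i / 1000.0
        self.init_w = math.exp(-self.init_e / self.rt)

    # -- scoring of explicit structures (shared by oracle and traceback) --

    def hairpin(self, size: int) -> float:
        return float(self.hairpin_e[size]) if size >= TURN else math.inf

    def bulge(self, size: int) -> float:
        return float(self.bulge_e[size]) if size <= MAXLOOP else math.inf

    def internal(self, size: int) -> float:
        return float(self.internal_e[size]) if size <= MAXLOOP else math.inf

    def stack(self, x: int, y: int) -> float:
        return float(self.stack_e[x, y])

    def multiloop(self, branches: int, unpaired: int) -> float:
        a, b, c = self.ml
        return a + b * branches + c * unpaired


_MODEL_CACHE: dict = {}


def get_model(params, temperature_c: float = 37.0) -> EnergyModel:
    if not isinstance(params, NNParameterSet):
        params = load_parameter_set(params)
    key = (params.name, id(params), round(temperature_c, 9))
    model = _MODEL_CACHE.get(key)
    if model is None:
        model = EnergyModel(params, temperature_c)
        _MODEL_CACHE[key] = model
    return model


class StrandFold:
    """Partition-function fold of one strand with reusable tables.

    Keeps the unconstrained DP matrices so that per-region opening energies
    recompute only the intervals intersecting the constrained region.
    """

    def __init__(self, seq: str, params, temperature_c: float = 37.0):
        self.model = get_model(params, temperature_c)
        self.seq = seqs.clean(seq)
        self.enc = _encode(self.seq, self.model.params)
        if self.enc.shape[0] < 1:
            raise InputError("empty sequence")
        m = self.model
        self._Q, self._Qb, self._Qm, self._Qm1 = _kernels.fill_pf(
            self.enc, _CANPAIR, m.stack_w, m.hairpin_w, m.bulge_w, m.internal_w,
            m.ml_w[0], m.ml_w[1], m.ml_w[2], MAXLOOP,
            -1, -1, self._dummy, self._dummy, self._dummy, self._dummy, False,
        )
        self.partition_Z = float(self._Q[0, -1])
        self.ln_Z = math.log(self.partition_Z)
        self.ensemble_dG = -m.rt * self.ln_Z

    _dummy = np.zeros((1, 1))

    def result(self) -> FoldResult:
        return FoldResult(
            partition_Z=self.partition_Z,
            ensemble_dG=self.ensemble_dG,
            temperature=self.model.temperature_c,
            parameter_set=self.model.params.name,
        )

    def constrained_ln_Z(self, region: Region) -> float:
        region.check_within(len(self.seq))
        m = self.model
        Qc, _, _, _ = _kernels.fill_pf(
            self.enc, _CANPAIR, m.stack_w, m.hairpin_w, m.bulge_w, m.internal_w,
            m.ml_w[0], m.ml_w[1], m.ml_w[2], MAXLOOP,
            region.start, region.end, self._Qb, self._Qm, self._Qm1, self._Q, True,
        )
        return math.log(float(Qc[0, -1]))

    def opening_energy(self, region: Region) -> float:
        """-RT ln P(region fully unpaired), always >= 0."""
        ln_zc = self.constrained_ln_Z(region)
        return max(0.0, self.model.rt * (self.ln_Z - ln_zc))


def partition_function(seq: str, params, temperature: float = 37.0) -> FoldResult:
    """Boltzmann sum over all pseudoknot-free structures of one strand."""
    return StrandFold(seq, params, temperature).result()


def opening_energy(seq: str, region: Region, params, temperature: float = 37.0) -> float:
    """Free-energy cost of forcing ``region`` to be fully unpaired."""
    return StrandFold(seq, params, temperature).opening_energy(region)


def _traceback(enc, model: EnergyModel, F, Eb, Em, Em1) -> list:
    """Recover one mfe structure from the filled min-energy tables."""
    eps = 1e-6
    n = enc.shape[0]
    pairs = []
    tasks = [("F", n - 1)]

    def close(x, y):
        return abs(x - y) <= eps

    mla, mlb, mlc = model.ml
    while tasks:
        kind, *arg = tasks.pop()
        if kind == "F":
            j = arg[0]
            while j >= TURN + 1:
                if close(F[j], F[j - 1] if j > 0 else 0.0):
                    j -= 1
                    continue
                done = False
                for k in range(0, j - TURN):
                    if Eb[k, j] < _kernels.INF:
                        prev = F[k - 1] if k > 0 else 0.0
                        if close(F[j], prev + Eb[k, j]):
                            tasks.append(("C", k, j))
                            j = k - 1
                            done = True
                            break
                if not done:  # numerical fallback: treat as unpaired
                    j -= 1
        elif kind == "C":
            i, j = arg
            pairs.append((i, j))
            e = Eb[i, j]
            if close(e, model.hairpin(j - i - 1)):
                continue
            found = False
            kmax = min(i + 1 + MAXLOOP, j - TURN - 2)
            for k in range(i + 1, kmax + 1):
                g1 = k - i - 1
                for l in range(max(k + TURN + 1, j - 1 - (MAXLOOP - g1)), j):
                    if Eb[k, l] >= _kernels.INF:
                        continue
                    g2 = j - l - 1
                    if g1 == 0 and g2 == 0:
                        w = model.stack(int(enc[i]), int(enc[i + 1]))
                    elif g1 == 0 or g2 == 0:
                        w = model.bulge(g1 + g2)
                    else:
                        w = model.internal(g1 + g2)
                    if close(e, w + Eb[k, l]):
                        tasks.append(("C", k, l))
                        found = True
                        break
                if found:
                    break
            if found:
                continue
            for u in range(i + 2, j - TURN - 1):
                if Em[i + 1, u - 1] < _kernels.INF and Em1[u, j - 1] < _kernels.INF:
                    if close(e, mla + Em[i + 1, u - 1] + Em1[u, j - 1]):
                        tasks.append(("M", i + 1, u - 1))
                        tasks.append(("M1", u, j - 1))
                        break
        elif kind == "M1":
            i, j = arg
            while j > i and close(Em1[i, j], Em1[i, j - 1] + mlc):
                j -= 1
            tasks.append(("C", i, j))
        else:  # M
            i, j = arg
            for k in range(i, j - TURN):
                if Em1[k, j] >= _kernels.INF:
                    continue
                if close(Em[i, j], (k - i) * mlc + Em1[k, j]):
                    tasks.append(("M1", k, j))
                    break
                if k > i and Em[i, k - 1] < _kernels.INF and close(
                    Em[i, j], Em[i, k - 1] + Em1[k, j]
                ):
                    tasks.append(("M", i, k - 1))
                    tasks.append(("M1", k, j))
                    break
    return pairs


def mfe_structure(seq: str, params, temperature: float = 37.0) -> MfeResult:
    """Minimum-free-energy structure (dot-bracket) and its energy."""
    model = get_model(params, temperature)
    seq = seqs.clean(seq)
    enc = _encode(seq, model.params)
    if enc.shape[0] < 1:
        raise InputError("empty sequence")
    F, Eb, Em, Em1 = _kernels.fill_mfe(
        enc, _CANPAIR, model.stack_e,
        np.where(np.isfinite(model.hairpin_e), model.hairpin_e, _kernels.INF),
        np.where(np.isfinite(model.bulge_e), model.bulge_e, _kernels.INF),
        np.where(np.isfinite(model.internal_e), model.internal_e, _kernels.INF),
        model.ml[0], model.ml[1], model.ml[2], MAXLOOP,
    )
    n = enc.shape[0]
    mfe = float(F[n - 1]) if n > 1 else 0.0
    if mfe >= 0.0:
        return MfeResult(structure="." * n, mfe_dG=0.0)
    pairs = _traceback(enc, model, F, Eb, Em, Em1)
    db = ["."] * n
    for i, j in pairs:
        db[i] = "("
        db[j] = ")"
    return MfeResult(structure="".join(db), mfe_dG=mfe)


def dimer_energy(seq_a: str, seq_b: str, params, temperature: float = 37.0) -> float:
    """Ensemble free energy of intermolecular-only pairings, clamped <= 0.

    The two strands are otherwise unstructured; consecutive intermolecular
    pairs may be separated by at most MAXLOOP unpaired bases in total. For
    the hybrid parameter set ``seq_a`` must be the RNA strand (the keyed
    strand of the table). Returns 0 when no Watson-Crick contact exists or
    the interaction ensemble is net unstable.
    """
    model = get_model(params, temperature)
    name = model.params.name
    if not seq_a or not seq_b:
        raise InputError("dimer_energy requires two non-empty sequences")
    if name == "RNA/DNA":
        ea = _encode_alpha(seq_a, seqs.RNA_ALPHABET, "RNA strand")
        eb = _encode_alpha(seq_b, seqs.DNA_ALPHABET, "DNA strand")
    elif name == "RNA/RNA":
        ea = _encode_alpha(seq_a, seqs.RNA_ALPHABET, "RNA strand")
        eb = _encode_alpha(seq_b, seqs.RNA_ALPHABET, "RNA strand")
    else:
        ea = _encode_alpha(seq_a, seqs.DNA_ALPHABET, "DNA strand")
        eb = _encode_alpha(seq_b, seqs.DNA_ALPHABET, "DNA strand")
    total = _kernels.fill_dimer(
        ea, eb, _CANPAIR, model.stack_w, model.bulge_w, model.internal_w, MAXLOOP
    )
    z_int = model.init_w * float(total)
    if z_int <= 0.0:
        return 0.0
    return min(0.0, -model.rt * math.log(z_int))


def _encode_alpha(seq: str, alphabet: frozenset, what: str) -> np.ndarray:
    seq = seqs.validate(seq, alphabet, what)
    return np.array([_ENC[c] for c in seq], dtype=np.int64)


# ---------------------------------------------------------------------------
# exhaustive enumeration (test-support oracle)
# ---------------------------------------------------------------------------


def pairs_from_dotbracket(db: str) -> list:
    stack, pairs = [], []
    for idx, c in enumerate(db):
        if c == "(":
            stack.append(idx)
        elif c == ")":
            pairs.append((stack.pop(), idx))
    if stack:
        raise InputError(f"unbalanced dot-bracket string: {db}")
    return sorted(pairs)


def score_structure(seq: str, pairs, params, temperature: float = 37.0) -> float:
    """Loop-decomposition energy of an explicit structure (kcal/mol).

    Returns ``inf`` for structures outside the model (interior loop above
    the cap), which the dynamic programs exclude entirely.
    """
    model = get_model(params, temperature)
    enc = _encode(seqs.clean(seq), model.params)
    n = enc.shape[0]
    pt = {}
    for i, j in pairs:
        pt[i] = j
        pt[j] = i

    def loop_energy(i: int, j: int) -> float:
        # children directly enclosed by (i, j) (or by the exterior)
        children, unpaired = [], 0
        k = i + 1
        while k < j:
            if k in pt and pt[k] > k:
                children.append((k, pt[k]))
                k = pt[k] + 1
            else:
                unpaired += 1
                k += 1
        if i < 0:  # exterior loop is free
            return sum(loop_energy(a, b) for a, b in children)
        if not children:
            return model.hairpin(j - i - 1)
        if len(children) == 1:
            (a, b) = children[0]
            g1, g2 = a - i - 1, j - b - 1
            if g1 == 0 and g2 == 0:
                e = model.stack(int(enc[i]), int(enc[i + 1]))
            elif g1 == 0 or g2 == 0:
                e = model.bulge(g1 + g2)
            else:
                e = model.internal(g1 + g2)
            return e + loop_energy(a, b)
        e = model.multiloop(len(children), unpaired)
        return e + sum(loop_energy(a, b) for a, b in children)

    return loop_energy(-1, n)


def enumerate_structures(seq: str, params, temperature: float = 37.0) -> list:
    """All pseudoknot-free structures with their energies, in a fixed order.

    Exponential in sequence length; refused above ``ENUM_LIMIT`` bases.
    Structures containing interior loops above the cap (absent from the
    dynamic-programming ensemble) are dropped.
    """
    seq = seqs.clean(seq)
    if len(seq) > ENUM_LIMIT:
        raise InputError(
            f"enumeration refused for length {len(seq)} > {ENUM_LIMIT} (exponential blow-up)"
        )
    model = get_model(params, temperature)
    enc = _encode(seq, model.params)
    n = len(seq)

    memo = {}

    def structs(i: int, j: int):
        if j - i + 1 <= TURN:
            return [()]
        key = (i, j)
        if key in memo:
            return memo[key]
        out = list(structs(i + 1, j))
        for k in range(i + TURN + 1, j + 1):
            if _CANPAIR[enc[i], enc[k]]:
                for left in structs(i + 1, k - 1):
                    base = ((i, k),) + left
                    for right in structs(k + 1, j):
                        out.append(base + right)
        memo[key] = out
        return out

    results = []
    for pairs in structs(0, n - 1) if n > 0 else [()]:
        e = score_structure(seq, pairs, params, temperature)
        if math.isfinite(e):
            db = ["."] * n
            for a, b in pairs:
                db[a] = "("
                db[b] = ")"
            results.append(("".join(db), e))
    return results
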