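"""Independent oracles used by the test suite.

These deliberately avoid the dynamic programs under test: Boltzmann sums are
taken over explicitly enumerated structures, duplex sums re-read the
packaged parameter files, and the duplex-interaction oracle is a direct
recursion over pair chains.
"""

from __future__ import annotations

import math
from importlib import resources

import numpy as np

from hybtherm import fold_engine as fe
from hybtherm.nn_thermo import GAS_CONSTANT_KCAL, T0_KELVIN

RT37 = GAS_CONSTANT_KCAL * (37.0 + T0_KELVIN)

_ENC = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}
_CANP = {(0, 3), (3, 0), (1, 2), (2, 1)}


def read_stack_file(filename: str) -> tuple:
    """(stacks dict, initiation) parsed directly from the packaged TSV."""
    stacks, init = {}, None
    text = resources.files("hybtherm.data").joinpath(filename).read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, dh, ds = line.split()
        if key == "init":
            init = (float(dh), float(ds))
        else:
            stacks[key] = (float(dh), float(ds))
    return stacks, init


def nn_sum(keyed_strand: str, filename: str, temperature_c: float = 37.0) -> tuple:
    """Hand-summed (dH, dS, dG) over the stacks of the keyed strand."""
    stacks, (dh, ds) = read_stack_file(filename)
    for i in range(len(keyed_strand) - 1):
        h, s = stacks[keyed_strand[i : i + 2]]
        dh += h
        ds += s
    t_k = temperature_c + T0_KELVIN
    return dh, ds, dh - t_k * ds / 1000.0


def z_enum(seq: str, params, blocked=None, temperature_c: float = 37.0) -> float:
    """Boltzmann sum over enumerated structures, optionally excluding any
    structure that pairs a base inside the half-open ``blocked`` region."""
    rt = GAS_CONSTANT_KCAL * (temperature_c + T0_KELVIN)
    total = 0.0
    for db, e in fe.enumerate_structures(seq, params, temperature_c):
        if blocked is not None:
            a, b = blocked
            pairs = fe.pairs_from_dotbracket(db)
            if any(a <= i < b or a <= j < b for i, j in pairs):
                continue
        total += math.exp(-e / rt)
    return total


def mfe_enum(seq: str, params, temperature_c: float = 37.0) -> float:
    return min(e for _, e in fe.enumerate_structures(seq, params, temperature_c))


def dimer_enum(seq_a: str, seq_b: str, params, temperature_c: float = 37.0) -> float:
    """Direct recursion over intermolecular pair chains (antiparallel,
    non-crossing, consecutive gaps capped), scored with the same tables."""
    model = fe.get_model(params, temperature_c)
    ea = [_ENC[c] for c in seq_a]
    eb = [_ENC[c] for c in seq_b]
    cap = fe.MAXLOOP
    total = 0.0

    def extend(i: int, j: int, acc: float) -> None:
        nonlocal total
        total += math.exp(-(acc + model.init_e) / model.rt)
        for k in range(i + 1, min(len(ea), i + 2 + cap)):
            g1 = k - i - 1
            if g1 > cap:
                break
            for l in range(max(0, j - 1 - (cap - g1)), j):
                if (ea[k], eb[l]) in _CANP:
                    g2 = j - l - 1
                    if g1 == 0 and g2 == 0:
                        w = model.stack(ea[i], ea[i + 1])
                    elif g1 == 0 or g2 == 0:
                        w = model.bulge(g1 + g2)
                    else:
                        w = model.internal(g1 + g2)
                    extend(k, l, acc + w)

    for i in range(len(ea)):
        for j in range(len(eb)):
            if (ea[i], eb[j]) in _CANP:
                extend(i, j, 0.0)
    if total <= 0.0:
        return 0.0
    return min(0.0, -model.rt * math.log(total))


def steiger_z(r1: float, r2: float, r12: float, n: int) -> float:
    """Steiger's z for comparing two dependent correlations sharing one
    variable: r1 = cor(y, x1) vs r2 = cor(y, x2) given r12 = cor(x1, x2)."""
    rm2 = (r1**2 + r2**2) / 2.0
    f = min((1.0 - r12) / (2.0 * (1.0 - rm2)), 1.0)
    h = (1.0 - f * rm2) / (1.0 - rm2)
    return (np.arctanh(r1) - np.arctanh(r2)) * math.sqrt(
        (n - 3) / (2.0 * (1.0 - r12) * h)
    )


def random_seq(rng: np.random.Generator, n: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(list(alphabet), size=n))
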