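"""Small sequence utilities shared across modules.

Sequences are plain upper-case strings, stored 5'->3'. Probes are DNA
(alphabet ACGT); targets are DNA or RNA (ACGU) depending on the experiment.
"""

from __future__ import annotations

from .errors import AlphabetError

DNA_ALPHABET = frozenset("ACGT")
RNA_ALPHABET = frozenset("ACGU")

_DNA_COMP = str.maketrans("ACGT", "TGCA")
_RNA_COMP = str.maketrans("ACGU", "UGCA")
_DNA2RNA = str.maketrans("T", "U")
_RNA2DNA = str.maketrans("U", "T")


def clean(seq: str) -> str:
    return seq.strip().upper()


def validate(seq: str, alphabet: frozenset, what: str = "sequence") -> str:
    seq = clean(seq)
    bad = set(seq) - alphabet
    if bad:
        raise AlphabetError(
            f"{what} contains characters {sorted(bad)} outside alphabet "
            f"{''.join(sorted(alphabet))}: {seq[:40]}..."
            if len(seq) > 40
            else f"{what} contains characters {sorted(bad)} outside alphabet "
            f"{''.join(sorted(alphabet))}: {seq}"
        )
    return seq


def revcomp_dna(seq: str) -> str:
    return seq.translate(_DNA_COMP)[::-1]


def revcomp_rna(seq: str) -> str:
    return seq.translate(_RNA_COMP)[::-1]


def to_rna(seq: str) -> str:
    return seq.translate(_DNA2RNA)


def to_dna(seq: str) -> str:
    return seq.translate(_RNA2DNA)


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)
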