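"""The multi-state hybridization model: probes, targets and energy profiles.

A tethered DNA probe competes for its target binding site against three
alternative states: its own secondary structure, the secondary structure of
the binding site within the target, and probe-probe dimers within the same
array feature. The effective interaction energy combines them as

    dG = dG_h - dG_p - dG_t - dG_pp

with every competitor term clamped to <= 0 (unstable structures contribute
zero), so dG >= dG_h always holds. dG_h is the perfect-complement duplex
energy (hybrid parameters for RNA targets, DNA/DNA for cDNA targets); dG_p
the sign-flipped ensemble free energy of the whole probe; dG_t the
sign-flipped opening energy of the binding site within a target fragment
that includes up to 200 flanking bases on either side; and dG_pp the
interaction ensemble energy of two probe copies.

This module also provides exact probe-to-target mapping (unique perfect
matches only), probe truncation for steric analyses, the expressed-target
filter, and the per-target log2(max/min) intensity-variation statistic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping

import pandas as pd

from . import fold_engine, nn_thermo, seqs
from .errors import ConsistencyError, DegenerateInputError, InputError
from .fold_engine import Region, StrandFold
from .nn_thermo import ThermoConditions

logger = logging.getLogger(__name__)

DESIGN_LENGTH_RANGE = (25, 100)  # accepted probe lengths at the I/O boundary
SOLUTION_END = "solution_5prime"
TETHERED_END = "tethered_3prime"


@dataclass(frozen=True)
class Probe:
    """A surface-tethered oligonucleotide: 5' solution end, 3' tethered end.

    The optional poly-T linker is metadata only and excluded from ``seq``
    and all thermodynamic computations.
    """

    id: str
    seq: str
    linker_len: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", seqs.validate(self.seq, seqs.DNA_ALPHABET, "probe"))
        if len(self.seq) < 2:
            raise DegenerateInputError(f"probe {self.id!r} shorter than 2 nt")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class TargetFragment:
    """Verbatim substring of a target around one probe binding site."""

    target_id: str
    seq: str
    binding_site: Region  # in fragment coordinates
    left_flank: int
    right_flank: int


@dataclass(frozen=True)
class EnergyProfile:
    """The per-probe predictor bundle of the hybridization model."""

    dG_h: float
    dG_p: float
    dG_t: float
    dG_pp: float
    dG: float
    Tm: float
    probe_mfe: float


@dataclass
class ProbeTargetMap:
    entries: dict  # probe id -> (target id, Region on target)
    excluded: dict  # probe id -> reason in {no_match, multi_locus, multi_target}


@dataclass(frozen=True)
class ExpressionResult:
    expressed: frozenset  # target ids
    threshold: float  # mean intensity over mapped probes


def _find_all(haystack: str, needle: str) -> list:
    out, start = [], 0
    while True:
        idx = haystack.find(needle, start)
        if idx < 0:
            return out
        out.append(idx)
        start = idx + 1


def map_probes(probes: Iterable[Probe], targets: Mapping[str, str]) -> ProbeTargetMap:
    """Exact unique perfect-match mapping of probes onto target records.

    A probe maps iff its reverse complement occurs exactly once in exactly
    one target; otherwise it is excluded with a reason. Matching is on the
    sense strand only (the probe is reverse-complemented for the search);
    RNA targets are matched through U/T equivalence.
    """
    probes = list(probes)
    ids = [p.id for p in probes]
    if len(set(ids)) != len(ids):
        dup = sorted({x for x in ids if ids.count(x) > 1})
        raise InputError(f"duplicate probe ids: {dup[:5]}")
    if not targets:
        raise InputError("no targets given")
    # normalise targets to DNA letters for searching
    norm = {tid: seqs.to_dna(seqs.clean(ts)) for tid, ts in targets.items()}
    entries, excluded = {}, {}
    for p in probes:
        needle = seqs.revcomp_dna(p.seq)
        hits = []
        for tid, ts in norm.items():
            for pos in _find_all(ts, needle):
                hits.append((tid, pos))
        if not hits:
            excluded[p.id] = "no_match"
        elif len({tid for tid, _ in hits}) > 1:
            excluded[p.id] = "multi_target"
        elif len(hits) > 1:
            excluded[p.id] = "multi_locus"
        else:
            tid, pos = hits[0]
            entries[p.id] = (tid, Region(pos, pos + len(p.seq)))
    return ProbeTargetMap(entries=entries, excluded=excluded)


def extract_fragment(
    target_seq: str,
    site: Region,
    flank: int = 200,
    target_id: str = "",
) -> TargetFragment:
    """Cut the binding site plus up to ``flank`` bases on either side."""
    target_seq = seqs.clean(target_seq)
    n = len(target_seq)
    site.check_within(n)
    lo = max(0, site.start - flank)
    hi = min(n, site.end + flank)
    return TargetFragment(
        target_id=target_id,
        seq=target_seq[lo:hi],
        binding_site=Region(site.start - lo, site.end - lo),
        left_flank=site.start - lo,
        right_flank=hi - site.end,
    )


def _check_complementary(probe: Probe, fragment: TargetFragment) -> None:
    site = fragment.binding_site
    target_site = seqs.to_dna(fragment.seq[site.start : site.end])
    expected = seqs.revcomp_dna(probe.seq)
    if target_site != expected:
        for k, (a, b) in enumerate(zip(target_site, expected)):
            if a != b:
                raise ConsistencyError(
                    f"probe {probe.id!r} does not complement its binding site: "
                    f"first mismatch at site offset {k} (target {a!r} vs expected {b!r})"
                )
        raise ConsistencyError(
            f"probe {probe.id!r}: binding site length {len(target_site)} != probe length {len(probe)}"
        )


class ProfileContext:
    """Caches parameter sets and per-fragment folds across many probes."""

    def __init__(
        self,
        target_chemistry: str = "DNA",
        conditions: ThermoConditions | None = None,
        fold_temperature_c: float | None = None,
    ):
        if target_chemistry not in ("DNA", "RNA"):
            raise InputError(f"target_chemistry must be 'DNA' or 'RNA', got {target_chemistry!r}")
        self.target_chemistry = target_chemistry
        self.conditions = conditions or ThermoConditions()
        self.fold_t = (
            fold_temperature_c if fold_temperature_c is not None else self.conditions.temperature_c
        )
        self.dna = nn_thermo.load_parameter_set("DNA/DNA")
        self.rna = nn_thermo.load_parameter_set("RNA/RNA")
        self.hybrid = nn_thermo.load_parameter_set("RNA/DNA")
        self.duplex_params = self.hybrid if target_chemistry == "RNA" else self.dna
        self.target_params = self.rna if target_chemistry == "RNA" else self.dna
        self._fragment_folds: dict = {}
        self._probe_cache: dict = {}

    def fragment_fold(self, seq: str) -> StrandFold:
        fold = self._fragment_folds.get(seq)
        if fold is None:
            fold = StrandFold(seq, self.target_params, self.fold_t)
            self._fragment_folds[seq] = fold
            if len(self._fragment_folds) > 64:  # bound memory; keep recent targets
                self._fragment_folds.pop(next(iter(self._fragment_folds)))
        return fold

    def probe_side(self, probe_seq: str) -> tuple:
        """(dG_h, dG_p, dG_pp, Tm, mfe) — everything independent of the target."""
        cached = self._probe_cache.get(probe_seq)
        if cached is None:
            duplex = nn_thermo.duplex_thermo(probe_seq, self.duplex_params, self.conditions)
            dg_h = min(0.0, duplex.dG_at_T)
            dg_p = StrandFold(probe_seq, self.dna, self.fold_t).ensemble_dG
            dg_pp = fold_engine.dimer_energy(probe_seq, probe_seq, self.dna, self.fold_t)
            tm = nn_thermo.probe_tm(probe_seq, self.conditions)
            mfe = fold_engine.mfe_structure(probe_seq, self.dna, self.fold_t).mfe_dG
            cached = (dg_h, dg_p, dg_pp, tm, mfe)
            self._probe_cache[probe_seq] = cached
        return cached


def energy_profile(
    probe: Probe,
    fragment: TargetFragment,
    target_chemistry: str = "DNA",
    conditions: ThermoConditions | None = None,
    context: ProfileContext | None = None,
) -> EnergyProfile:
    """All thermodynamic predictors of one probe against its binding site."""
    ctx = context or ProfileContext(target_chemistry, conditions)
    _check_complementary(probe, fragment)
    dg_h, dg_p, dg_pp, tm, mfe = ctx.probe_side(probe.seq)
    fold = ctx.fragment_fold(fragment.seq)
    dg_t = -fold.opening_energy(fragment.binding_site)
    dg = dg_h - dg_p - dg_t - dg_pp
    return EnergyProfile(dG_h=dg_h, dG_p=dg_p, dG_t=dg_t, dG_pp=dg_pp, dG=dg, Tm=tm, probe_mfe=mfe)


PROFILE_COLUMNS = [
    "probe_id", "seq", "target_id", "site_start", "site_end",
    "length", "dG_h", "dG_p", "dG_t", "dG_pp", "dG", "Tm", "mfe",
]


def profile_probes(
    probes: Iterable[Probe],
    targets: Mapping[str, str],
    target_chemistry: str = "DNA",
    conditions: ThermoConditions | None = None,
    flank: int = 200,
    pmap: ProbeTargetMap | None = None,
) -> pd.DataFrame:
    """Map probes and emit one profile row per uniquely mapped probe.

    Probes are grouped by target so per-fragment folds are computed once.
    Returns a DataFrame with PROFILE_COLUMNS, indexed by probe_id.
    """
    probes = list(probes)
    if pmap is None:
        pmap = map_probes(probes, targets)
    ctx = ProfileContext(target_chemistry, conditions)
    by_id = {p.id: p for p in probes}
    rows = []
    mapped = sorted(pmap.entries.items(), key=lambda kv: (kv[1][0], kv[1][1].start, kv[0]))
    for pid, (tid, site) in mapped:
        probe = by_id[pid]
        fragment = extract_fragment(targets[tid], site, flank=flank, target_id=tid)
        prof = energy_profile(probe, fragment, context=ctx)
        rows.append(
            (pid, probe.seq, tid, site.start, site.end, len(probe),
             prof.dG_h, prof.dG_p, prof.dG_t, prof.dG_pp, prof.dG, prof.Tm, prof.probe_mfe)
        )
    logger.info(
        "profiled %d mapped probes (%d excluded: %s)",
        len(rows), len(pmap.excluded),
        ", ".join(f"{r}={list(pmap.excluded.values()).count(r)}"
                  for r in ("no_match", "multi_target", "multi_locus")),
    )
    df = pd.DataFrame(rows, columns=PROFILE_COLUMNS)
    return df.set_index("probe_id", drop=False)


def truncate_probe(probe: Probe, end: str, n: int) -> Probe:
    """Remove ``n`` terminal bases from the solution (5') or tethered (3') end."""
    if end in ("5prime", "5'"):
        end = SOLUTION_END
    elif end in ("3prime", "3'"):
        end = TETHERED_END
    if end not in (SOLUTION_END, TETHERED_END):
        raise InputError(f"end must be {SOLUTION_END!r} or {TETHERED_END!r}, got {end!r}")
    if n < 1:
        raise InputError(f"truncation length must be >= 1, got {n}")
    if n >= len(probe):
        raise DegenerateInputError(
            f"cannot remove {n} bases from a {len(probe)} nt probe {probe.id!r}"
        )
    if end == SOLUTION_END:
        new_seq = probe.seq[n:]
        suffix = f"5p-{n}"
    else:
        new_seq = probe.seq[:-n]
        suffix = f"3p-{n}"
    return replace(probe, id=f"{probe.id}|{suffix}", seq=new_seq)


def truncate_site(site: Region, end: str, n: int) -> Region:
    """Binding-site region matching a truncated probe.

    The probe is antiparallel to the target: removing bases from the
    probe's 3' (tethered) end shrinks the site from its 5' (left) side.
    """
    if end in (TETHERED_END, "3prime", "3'"):
        return Region(site.start + n, site.end)
    if end in (SOLUTION_END, "5prime", "5'"):
        return Region(site.start, site.end - n)
    raise InputError(f"unknown end {end!r}")


def full_length_fraction(length: int, stepwise_yield: float) -> float:
    """Fraction of in-situ synthesized probes reaching full length.

    Stepwise coupling efficiency compounds per nucleotide: yield**length.
    """
    if not 0 < stepwise_yield <= 1:
        raise InputError(f"stepwise yield must be in (0, 1], got {stepwise_yield}")
    if length < 1:
        raise InputError(f"length must be >= 1, got {length}")
    return stepwise_yield**length


def _intensity_series(intensities) -> pd.Series:
    if hasattr(intensities, "values_series"):
        return intensities.values_series()
    if isinstance(intensities, pd.Series):
        return intensities
    return pd.Series(dict(intensities))


def expression_filter(intensities, pmap: ProbeTargetMap) -> ExpressionResult:
    """Targets with at least one probe above the mean mapped-probe intensity."""
    ser = _intensity_series(intensities)
    mapped_ids = [pid for pid in ser.index if pid in pmap.entries]
    if not mapped_ids:
        raise InputError("no mapped probe has an intensity value")
    mapped = ser.loc[mapped_ids]
    threshold = float(mapped.mean())
    expressed = set()
    for pid, value in mapped.items():
        if value > threshold:
            expressed.add(pmap.entries[pid][0])
    return ExpressionResult(expressed=frozenset(expressed), threshold=threshold)


def variation_stats(intensities, pmap: ProbeTargetMap) -> tuple:
    """Per-target log2(max/min) probe intensity ratio and its grand mean.

    Returns (per_target: pd.Series, mean: float). Targets with fewer than
    two mapped probes are skipped; non-positive intensities are an error.
    """
    ser = _intensity_series(intensities)
    mapped_ids = [pid for pid in ser.index if pid in pmap.entries]
    if (ser.loc[mapped_ids] <= 0).any():
        bad = ser.loc[mapped_ids][ser.loc[mapped_ids] <= 0].index[0]
        raise InputError(f"non-positive intensity for probe {bad!r}")
    groups: dict = {}
    for pid in mapped_ids:
        groups.setdefault(pmap.entries[pid][0], []).append(ser.loc[pid])
    stats = {
        tid: math.log2(max(vals) / min(vals))
        for tid, vals in groups.items()
        if len(vals) >= 2
    }
    if not stats:
        raise InputError("no target has two or more mapped probes with intensities")
    per_target = pd.Series(stats).sort_index()
    return per_target, float(per_target.mean())
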