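"""Synthetic targets, tiling probes and simulated intensities.

Two presets mirror the modelled experiment regimes: the cDNA-style design
(45-75 nt probes tiling DNA targets at 22 nt resolution) and the rRNA-style
design (fixed 25-mers tiling RNA targets at 1 nt resolution, nine targets,
every target expressed).

Signal model
------------
Probe occupancy follows a Langmuir isotherm theta = K/(1+K) with a binding
constant driven by the probe's effective interaction energy,

    ln K = -(dG - dG_ref) / (m * R * T),

where dG_ref is a pseudo-concentration reference (by default the median dG
of the simulated probe set) and ``m`` a heterogeneity/compression exponent.
A pure two-state isotherm (m = 1) saturates numerically at typical effective
energies of tens of kcal/mol; surface hybridization is well known to show a
compressed apparent dependence on solution free energies, and m spreads the
occupancies over the measurable range while keeping intensity strictly
decreasing in dG. Fluorescence is then

    I = scale * theta * exp(sigma * eps) + background * exp(sigma_b * eps'),

with standard-normal eps: multiplicative lognormal probe noise on the
specific term and a lognormal optical background. Probes of non-expressed
targets receive background only. Everything is deterministic under the
configured seed.
"""

from __future__ import annotations

import io
import zlib
from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import hybmodel, seqs
from .errors import InputError
from .nn_thermo import GAS_CONSTANT_KCAL, T0_KELVIN

_LN2 = float(np.log(2.0))


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; the defaults of each preset are the study design."""

    seed: int
    n_targets: int = 20
    target_length: tuple = (500, 1500)
    gc: float = 0.5
    tiling_step: int = 22
    probe_length: tuple = (45, 75)  # or (25, 25) for the short-probe preset
    target_chemistry: str = "DNA"  # "DNA" (cDNA targets) or "RNA" (rRNA targets)
    linker_len: int = 5
    langmuir_scale: float = 50000.0
    background: float = 500.0
    noise_sigma: float = 0.3  # lognormal sigma (natural log) on the specific term
    background_sigma: float = 0.3
    frac_expressed: float = 0.5
    heterogeneity: float = 14.0  # Langmuir compression exponent m
    dg_ref: float | None = None  # None: median dG of the profile set
    driver: str = "dG"  # profile column driving the signal
    tm_scale: float = 4.0  # degC per ln K unit when driver is "Tm"
    temperature_c: float = 37.0
    name: str = "custom"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise InputError("SimConfig requires an explicit seed")
        if not 0.0 < self.gc < 1.0:
            raise InputError(f"GC fraction must be in (0, 1), got {self.gc}")
        if self.noise_sigma < 0 or self.background_sigma < 0:
            raise InputError("noise sigma must be >= 0")
        if self.tiling_step < 1:
            raise InputError("tiling step must be >= 1")
        if self.target_chemistry not in ("DNA", "RNA"):
            raise InputError(f"unknown target chemistry {self.target_chemistry!r}")
        if not 0.0 <= self.frac_expressed <= 1.0:
            raise InputError("frac_expressed must be in [0, 1]")

    def with_(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


def cdna_preset(seed: int, **overrides) -> SimConfig:
    """Long-probe regime: 45-75-mers, 22 nt tiling resolution, cDNA targets."""
    cfg = SimConfig(
        seed=seed,
        n_targets=40,
        target_length=(500, 1500),
        tiling_step=22,
        probe_length=(45, 75),
        target_chemistry="DNA",
        frac_expressed=0.5,
        name="cdna",
    )
    return cfg.with_(**overrides) if overrides else cfg


def rrna_preset(seed: int, **overrides) -> SimConfig:
    """Short-probe regime: 25-mers, 1 nt resolution, nine RNA targets,
    each hybridized separately (every target expressed)."""
    cfg = SimConfig(
        seed=seed,
        n_targets=9,
        target_length=(120, 200),
        tiling_step=1,
        probe_length=(25, 25),
        target_chemistry="RNA",
        frac_expressed=1.0,
        name="rrna",
    )
    return cfg.with_(**overrides) if overrides else cfg


def _rng(config: SimConfig, stream: str) -> np.random.Generator:
    # independent, reproducible streams per generator stage
    return np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(zlib.crc32(stream.encode()),))
    )


def random_targets(config: SimConfig) -> list:
    """I.i.d. random target records at the configured GC content."""
    rng = _rng(config, "targets")
    lo, hi = config.target_length
    if lo > hi or lo < 1:
        raise InputError(f"bad target length range {config.target_length}")
    alphabet = np.array(list("ACGT" if config.target_chemistry == "DNA" else "ACGU"))
    p = np.array(
        [(1 - config.gc) / 2, config.gc / 2, config.gc / 2, (1 - config.gc) / 2]
    )
    records = []
    for t in range(config.n_targets):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(alphabet, size=length, p=p))
        records.append(SeqRecord(Seq(seq), id=f"T{t:04d}", description=""))
    return records


def _as_target_dict(targets) -> dict:
    if isinstance(targets, dict):
        return {k: str(v) for k, v in targets.items()}
    return {rec.id: str(rec.seq) for rec in targets}


def tile_probes(targets, config: SimConfig) -> list:
    """Reverse-complement tiling probes at the configured step and lengths.

    Probes whose sequence would not map uniquely back onto the target set
    (duplicate windows) are dropped; the count is reported via the return
    of :func:`hybmodel.map_probes` used downstream.
    """
    tdict = _as_target_dict(targets)
    if not tdict:
        raise InputError("tile_probes needs at least one target")
    rng = _rng(config, "probes")
    lo, hi = config.probe_length
    probes = []
    for tid, tseq in tdict.items():
        tseq_dna = seqs.to_dna(seqs.clean(tseq))
        n = len(tseq_dna)
        if n < lo:
            continue  # target shorter than the probe: skip with no probes
        start = 0
        while True:
            length = int(rng.integers(lo, hi + 1)) if hi > lo else lo
            if start + length > n:
                break
            window = tseq_dna[start : start + length]
            probes.append(
                hybmodel.Probe(
                    id=f"{tid}_p{start:05d}",
                    seq=seqs.revcomp_dna(window),
                    linker_len=config.linker_len,
                )
            )
            start += config.tiling_step
    # keep only probes that map uniquely on this target set
    pmap = hybmodel.map_probes(probes, tdict)
    kept = [p for p in probes if p.id in pmap.entries]
    return kept


def expressed_targets(targets, config: SimConfig) -> frozenset:
    """The simulated ground-truth set of expressed target ids."""
    tdict = _as_target_dict(targets)
    rng = _rng(config, "expression")
    ids = sorted(tdict)
    n_exp = int(round(config.frac_expressed * len(ids)))
    chosen = rng.permutation(len(ids))[:n_exp]
    return frozenset(ids[i] for i in sorted(chosen))


@dataclass
class IntensityTable:
    """Probe -> fluorescence mapping with a scale flag."""

    values: pd.Series
    scale: str = "linear"

    def __post_init__(self) -> None:
        if self.scale == "linear" and (self.values <= 0).any():
            raise InputError("intensities must be strictly positive")

    def values_series(self) -> pd.Series:
        return self.values

    def log2(self) -> "IntensityTable":
        if self.scale == "log2":
            return self
        return IntensityTable(values=np.log2(self.values), scale="log2")


def simulate_intensities(
    profiles: pd.DataFrame,
    config: SimConfig,
    expressed: Iterable[str] | None = None,
) -> IntensityTable:
    """Langmuir signal + lognormal noise for every profiled probe.

    ``profiles`` is the frame from :func:`hybmodel.profile_probes` (needs
    the driver column and ``target_id``). Probes of non-expressed targets
    get background-only signal. ``expressed=None`` means every target is
    expressed.
    """
    if config.driver not in profiles.columns:
        raise InputError(f"driver column {config.driver!r} missing from profiles")
    rng = _rng(config, "intensity")
    rt = GAS_CONSTANT_KCAL * (config.temperature_c + T0_KELVIN)
    v = profiles[config.driver].to_numpy(float)
    if config.driver == "Tm":
        ref = float(np.median(v))
        ln_k = (v - ref) / config.tm_scale
    else:  # free-energy driver: lower dG binds tighter
        ref = config.dg_ref if config.dg_ref is not None else float(np.median(v))
        ln_k = -(v - ref) / (config.heterogeneity * rt)
    theta = 1.0 / (1.0 + np.exp(-ln_k))
    if expressed is not None:
        on = profiles["target_id"].isin(set(expressed)).to_numpy()
    else:
        on = np.ones(len(profiles), dtype=bool)
    specific = np.where(on, config.langmuir_scale * theta, 0.0)
    eps = rng.standard_normal(len(profiles))
    eps_b = rng.standard_normal(len(profiles))
    intensity = specific * np.exp(config.noise_sigma * eps) + config.background * np.exp(
        config.background_sigma * eps_b
    )
    return IntensityTable(
        values=pd.Series(intensity, index=profiles.index, name="intensity"),
        scale="linear",
    )


# ---------------------------------------------------------------------------
# serialisation helpers (standard formats; provenance config beside outputs)
# ---------------------------------------------------------------------------


def targets_to_fasta(records) -> str:
    buf = io.StringIO()
    SeqIO.write(records, buf, "fasta")
    return buf.getvalue()


def probes_to_frame(probes) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "probe_id": [p.id for p in probes],
            "seq": [p.seq for p in probes],
            "linker_len": [p.linker_len for p in probes],
        }
    ).set_index("probe_id", drop=False)
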