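"""Instrument-realistic synthetic stopped-flow / flash-photolysis data.

Converts :mod:`glbkin.kinetics` trajectories into absorbance observables
through Beer-Lambert projection onto the species basis spectra, applies
the instrument model (dead time, fixed sampling interval, additive
Gaussian noise), and packages reproducible datasets whose per-trace seeds
derive deterministically from a master seed (splitmix64 counter hashing).

Default instrument profiles:

* stopped flow -- 1.2 ms dead time, 1.2 ms sampling, suited to the NO
  binding (2 s) and NOD assays;
* laser flash photolysis -- 5 us detector dead time;
* scanning spectrophotometer -- 200 ms-1 s sampling for the slow
  dithionite-trap and nitrite-reductase time courses.

Observation noise defaults to 0.002 AU (typical diode-array noise).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .kinetics import (
    AssayConditions,
    AssayKind,
    ProteinModel,
    Trajectory,
    build_scheme,
    simulate,
)
from .spectra import BasisSpectrum, SpectrumSeries, default_grid, make_basis

__all__ = [
    "InstrumentProfile",
    "TimeCourse",
    "stopped_flow",
    "laser_flash",
    "scanning_spectrophotometer",
    "DEFAULT_NOISE_SD",
    "DEFAULT_WAVELENGTH",
    "derive_seed",
    "apply_instrument",
    "simulate_trace",
    "generate_assay_dataset",
    "generate_spectrum_series",
    "write_timecourse_csv",
    "read_timecourse_csv",
    "write_series_csv",
    "read_series_csv",
]

DEFAULT_NOISE_SD = 0.002  # AU

#: Default observation wavelength (nm) per assay, chosen for contrast
#: between the reactant and product basis spectra.
DEFAULT_WAVELENGTH: Dict[AssayKind, float] = {
    AssayKind.O2_DISSOCIATION_TRAP: 430.0,  # deoxy formation vs oxy 412
    AssayKind.CO_REBINDING_LFP: 419.0,      # carboxy Soret
    AssayKind.NO_BINDING: 424.0,            # deoxy 6cLS decay (as measured)
    AssayKind.NOD: 405.0,                   # oxy -> ferric flank
    AssayKind.NIR: 435.0,                   # deoxy Soret decay (5c band; the
                                            # deoxy pool sits mostly 5c under
                                            # the effective gating constants)
}


@dataclass(frozen=True)
class InstrumentProfile:
    kind: str                 # stopped_flow | lfp | scanning_spectrophotometer
    dead_time: float          # s
    sampling_interval: float  # s
    duration: float           # s
    noise_sd: float = DEFAULT_NOISE_SD  # AU
    pathlength: float = 1.0   # cm

    def __post_init__(self) -> None:
        if self.dead_time < 0:
            raise ValueError("dead_time must be >= 0")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def sample_times(self) -> np.ndarray:
        """Observable sample times: dead_time + k * sampling_interval."""
        n = int(np.floor((self.duration - self.dead_time)
                         / self.sampling_interval)) + 1
        if n < 1:
            raise ValueError("duration shorter than the dead time")
        return self.dead_time + self.sampling_interval * np.arange(n)


def stopped_flow(duration: float = 2.0, sampling: float = 1.2e-3,
                 dead_time: float = 1.2e-3, noise_sd: float = DEFAULT_NOISE_SD,
                 pathlength: float = 1.0) -> InstrumentProfile:
    return InstrumentProfile("stopped_flow", dead_time, sampling, duration,
                             noise_sd, pathlength)


def laser_flash(duration: float = 0.1, sampling: float = 1e-4,
                dead_time: float = 5e-6, noise_sd: float = DEFAULT_NOISE_SD,
                pathlength: float = 1.0) -> InstrumentProfile:
    return InstrumentProfile("lfp", dead_time, sampling, duration,
                             noise_sd, pathlength)


def scanning_spectrophotometer(duration: float = 200.0, sampling: float = 1.0,
                               dead_time: float = 0.0,
                               noise_sd: float = DEFAULT_NOISE_SD,
                               pathlength: float = 1.0) -> InstrumentProfile:
    return InstrumentProfile("scanning_spectrophotometer", dead_time, sampling,
                             duration, noise_sd, pathlength)


@dataclass
class TimeCourse:
    """An instrument-filtered absorbance trace at one wavelength."""

    times: np.ndarray
    signal: np.ndarray
    instrument: InstrumentProfile
    wavelength: float
    seed: int
    truth: Optional[Dict] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.times.shape != self.signal.shape:
            raise ValueError("times and signal differ in shape")
        if len(self.times) and self.times[0] < self.instrument.dead_time - 1e-15:
            raise ValueError("times must start at or after the dead time")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal must be finite")


def derive_seed(master_seed: int, counter: int) -> int:
    """Deterministic per-trace seed via splitmix64 counter hashing."""
    z = (int(master_seed) * 0x9E3779B97F4A7C15 + counter * 0xBF58476D1CE4E5B9) \
        & 0xFFFFFFFFFFFFFFFF
    z ^= z >> 30
    z = (z * 0xBF58476D1CE4E5B9) & 0xFFFFFFFFFFFFFFFF
    z ^= z >> 27
    z = (z * 0x94D049BB133111EB) & 0xFFFFFFFFFFFFFFFF
    z ^= z >> 31
    return int(z % (2 ** 31))


def _basis_map(labels: Sequence[str]) -> Dict[str, BasisSpectrum]:
    return {b.species: b for b in make_basis(labels)}


def project_absorbance(
    traj: Trajectory,
    basis: Dict[str, BasisSpectrum],
    wavelength: float,
    pathlength: float,
) -> np.ndarray:
    """Noiseless Beer-Lambert absorbance of a trajectory at one wavelength."""
    assert traj.scheme is not None, "trajectory must carry its scheme"
    a = np.zeros_like(traj.times)
    grid = default_grid()
    if not (grid[0] <= wavelength <= grid[-1]):
        raise ValueError(
            f"wavelength {wavelength} nm outside basis support "
            f"({grid[0]:g}-{grid[-1]:g} nm)"
        )
    n_sites = max(len(traj.scheme.site_species), 1)
    for sp, (label, weight) in traj.scheme.spectral_species.items():
        eps = float(basis[label].extinction(np.array([wavelength]))[0])
        # weight is the site's share of the observable signal; each site
        # holds protein_conc of heme, so scale to keep total amplitude
        # equal to that of an unweighted single-heme protein
        a += traj[sp] * eps * weight * n_sites
    return a * pathlength


def apply_instrument(
    traj: Trajectory,
    basis: Dict[str, BasisSpectrum] | Sequence[BasisSpectrum],
    instr: InstrumentProfile,
    wavelength: float,
    seed: int,
    truth: Optional[Dict] = None,
) -> TimeCourse:
    """Turn a trajectory into an observed absorbance trace.

    Concentrations are projected to absorbance via Beer-Lambert at the
    requested wavelength, samples before the dead time are discarded, the
    remaining signal is taken on the instrument's fixed sampling grid, and
    zero-mean Gaussian noise of ``instr.noise_sd`` is added from ``seed``.
    The trajectory must cover the instrument grid (it is interpolated
    linearly where grids differ).
    """
    if not isinstance(basis, dict):
        basis = {b.species: b for b in basis}
    t_obs = instr.sample_times()
    if traj.times[-1] < t_obs[-1] - 1e-12:
        raise ValueError("trajectory does not cover the instrument duration")
    a_model = project_absorbance(traj, basis, wavelength, instr.pathlength)
    a_obs = np.interp(t_obs, traj.times, a_model)
    rng = np.random.default_rng(seed)
    noisy = a_obs + rng.normal(0.0, instr.noise_sd, size=a_obs.shape) \
        if instr.noise_sd > 0 else a_obs
    rec = dict(truth or {})
    rec.setdefault("noiseless_first_sample", float(a_obs[0]))
    return TimeCourse(
        times=t_obs, signal=noisy, instrument=instr, wavelength=wavelength,
        seed=seed, truth=rec,
    )


def _grid_for(instr: InstrumentProfile) -> np.ndarray:
    """Simulation grid: t=0 plus the instrument sample times."""
    t_obs = instr.sample_times()
    if t_obs[0] == 0.0:
        return t_obs
    return np.concatenate(([0.0], t_obs))


def simulate_trace(
    protein: ProteinModel,
    cond: AssayConditions,
    instr: InstrumentProfile,
    seed: int,
    wavelength: Optional[float] = None,
    fraction_photolysed: float = 1.0,
    truth_extra: Optional[Dict] = None,
) -> TimeCourse:
    """Simulate one assay and observe it through the instrument."""
    kind = AssayKind(cond.assay_kind)
    wl = DEFAULT_WAVELENGTH[kind] if wavelength is None else wavelength
    scheme = build_scheme(protein, cond, fraction_photolysed=fraction_photolysed)
    traj = simulate(scheme, _grid_for(instr))
    labels = sorted({lab for lab, _ in scheme.spectral_species.values()})
    basis = _basis_map(labels)
    truth = {
        "assay": kind.value,
        "protein": protein.name,
        "protein_conc_M": cond.protein_conc,
        "ligand_conc_M": cond.ligand_conc,
        "dithionite_conc_M": cond.dithionite_conc,
        "CO_conc_M": cond.CO_conc,
        "O2_conc_M": cond.O2_conc,
        "pH": cond.pH,
    }
    if truth_extra:
        truth.update(truth_extra)
    # expected full amplitude of the observable transition, for censoring
    a = project_absorbance(traj, basis, wl, instr.pathlength)
    truth["expected_amplitude_au"] = float(a[0] - a[-1])
    return apply_instrument(traj, basis, instr, wl, seed, truth)


def generate_assay_dataset(
    protein: ProteinModel,
    assay: AssayConditions,
    vary: Tuple[str, Sequence[float]],
    n_replicates: int,
    seed: int,
    instrument: Optional[InstrumentProfile] = None,
    wavelength: Optional[float] = None,
) -> List[TimeCourse]:
    """One TimeCourse per (varied value, replicate).

    ``vary`` is ``(field_name, values)`` over :class:`AssayConditions`;
    per-trace seeds derive from the master ``seed`` with a splitmix64
    counter, recorded in each trace's metadata.  The returned list is the
    input contract of the inference layer.
    """
    name, values = vary
    values = list(values)
    if not values:
        raise ValueError("empty value list for varied parameter")
    if not hasattr(assay, name):
        raise ValueError(f"{name!r} is not an AssayConditions field")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    instr = instrument or _default_instrument(AssayKind(assay.assay_kind))
    traces: List[TimeCourse] = []
    counter = 0
    for value in values:
        cond = replace(assay, **{name: value})
        for rep in range(n_replicates):
            trace_seed = derive_seed(seed, counter)
            counter += 1
            tc = simulate_trace(
                protein, cond, instr, trace_seed, wavelength,
                truth_extra={"varied": name, "varied_value": value,
                             "replicate": rep, "master_seed": seed},
            )
            traces.append(tc)
    return traces


def _default_instrument(kind: AssayKind) -> InstrumentProfile:
    if kind is AssayKind.O2_DISSOCIATION_TRAP:
        return scanning_spectrophotometer(duration=25.0, sampling=0.2)
    if kind is AssayKind.NIR:
        # first scan 1 s after mixing: the fast 6c->5c gating relaxation of
        # the freshly mixed deoxy protein completes before observation
        return scanning_spectrophotometer(duration=200.0, sampling=1.0,
                                          dead_time=1.0)
    if kind is AssayKind.CO_REBINDING_LFP:
        return laser_flash()
    return stopped_flow()


def generate_spectrum_series(
    traj: Trajectory,
    basis: Dict[str, BasisSpectrum] | Sequence[BasisSpectrum],
    instr: InstrumentProfile,
    seed: int,
    wavelengths: Optional[np.ndarray] = None,
) -> SpectrumSeries:
    """Time-resolved spectra of a trajectory with per-(wavelength, time) noise."""
    if not isinstance(basis, dict):
        basis = {b.species: b for b in basis}
    assert traj.scheme is not None
    wl = default_grid() if wavelengths is None else np.asarray(wavelengths, float)
    t_obs = instr.sample_times()
    if traj.times[-1] < t_obs[-1] - 1e-12:
        raise ValueError("trajectory does not cover the instrument duration")
    n_sites = max(len(traj.scheme.site_species), 1)
    A = np.zeros((len(wl), len(t_obs)))
    for sp, (label, weight) in traj.scheme.spectral_species.items():
        c = np.interp(t_obs, traj.times, traj[sp])
        A += np.outer(basis[label].extinction(wl), c) * weight * n_sites
    A *= instr.pathlength
    if instr.noise_sd > 0:
        rng = np.random.default_rng(seed)
        A = A + rng.normal(0.0, instr.noise_sd, size=A.shape)
    return SpectrumSeries(wavelengths=wl, times=t_obs, absorbance=A,
                          pathlength=instr.pathlength)


# ---------------------------------------------------------------------------
# CSV formats


def write_timecourse_csv(tc: TimeCourse, path) -> None:
    """CSV with '#'-prefixed metadata header then time_s,absorbance."""
    meta = {
        "dead_time_s": tc.instrument.dead_time,
        "sampling_s": tc.instrument.sampling_interval,
        "duration_s": tc.instrument.duration,
        "noise_sd_au": tc.instrument.noise_sd,
        "pathlength_cm": tc.instrument.pathlength,
        "instrument": tc.instrument.kind,
        "wavelength_nm": tc.wavelength,
        "seed": tc.seed,
    }
    for k, v in (tc.truth or {}).items():
        meta[f"truth.{k}"] = v
    with open(path, "w") as fh:
        for k, v in meta.items():
            fh.write(f"# {k} = {v}\n")
        fh.write("time_s,absorbance\n")
        for t, a in zip(tc.times, tc.signal):
            fh.write(f"{t:.9g},{a:.9g}\n")


def _parse_meta_value(raw: str):
    raw = raw.strip()
    for cast in (int, float):
        try:
            return cast(raw)
        except ValueError:
            pass
    if raw in ("True", "False"):
        return raw == "True"
    return raw


def read_timecourse_csv(path) -> TimeCourse:
    meta: Dict[str, object] = {}
    body_lines: List[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#"):
                try:
                    key, val = line[1:].split("=", 1)
                except ValueError:
                    raise ValueError(
                        f"{path}: malformed metadata at line {lineno}: {line!r}"
                    )
                meta[key.strip()] = _parse_meta_value(val)
            else:
                body_lines.append(line)
    try:
        df = pd.read_csv(io.StringIO("".join(body_lines)))
        times = df["time_s"].to_numpy(float)
        signal = df["absorbance"].to_numpy(float)
    except Exception as exc:
        raise ValueError(f"{path}: malformed data rows: {exc}") from exc
    instr = InstrumentProfile(
        kind=str(meta.get("instrument", "stopped_flow")),
        dead_time=float(meta.get("dead_time_s", 0.0)),
        sampling_interval=float(meta.get("sampling_s", 1.0)),
        duration=float(meta.get("duration_s", times[-1] if len(times) else 0.0)),
        noise_sd=float(meta.get("noise_sd_au", 0.0)),
        pathlength=float(meta.get("pathlength_cm", 1.0)),
    )
    truth = {k[len("truth."):]: v for k, v in meta.items()
             if k.startswith("truth.")}
    return TimeCourse(
        times=times, signal=signal, instrument=instr,
        wavelength=float(meta.get("wavelength_nm", 0.0)),
        seed=int(meta.get("seed", 0)), truth=truth or None,
    )


def write_series_csv(series: SpectrumSeries, path) -> None:
    """CSV: first column wavelength_nm, remaining columns labelled by time."""
    with open(path, "w") as fh:
        fh.write(f"# pathlength_cm = {series.pathlength}\n")
        cols = ",".join(f"{t:.9g}" for t in series.times)
        fh.write(f"wavelength_nm,{cols}\n")
        for i, wl in enumerate(series.wavelengths):
            row = ",".join(f"{a:.9g}" for a in series.absorbance[i])
            fh.write(f"{wl:.9g},{row}\n")


def read_series_csv(path) -> SpectrumSeries:
    pathlength = 1.0
    body: List[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                key, val = line[1:].split("=", 1)
                if key.strip() == "pathlength_cm":
                    pathlength = float(val)
            else:
                body.append(line)
    df = pd.read_csv(io.StringIO("".join(body)))
    wl = df["wavelength_nm"].to_numpy(float)
    times = np.array([float(c) for c in df.columns[1:]])
    A = df.iloc[:, 1:].to_numpy(float)
    return SpectrumSeries(wavelengths=wl, times=times, absorbance=A,
                          pathlength=pathlength)
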