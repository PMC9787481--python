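"""Synthetic LC-HRMS/MS study generator.

Emulates a two-matrix metabolism experiment on a phenolic parent drug:

* **in vitro** — differentiated HepaRG supernatant sampled at H0/H8/H24/H48
  after incubation with the parent compound (10 uM);
* **in vivo** — mouse plasma at H1/H3 after a 5 mg/kg intraperitoneal dose.

The generator's truth set encodes the parent (m/z 211.087, RT 5.8 min, MRM
fragments near 118.0 and 183.1) plus 14 conjugate/oxidation metabolites with
their retention times, matrix presence and biotransformation chains.  Each
metabolite's precursor m/z is computed from its chain's elemental delta, so
the simulated physics is internally consistent: at zero noise the downstream
network + annotation stages must recover every chain exactly.

Fragmentation model: conjugates lose the conjugate moiety as a neutral, so
their MS/MS spectra inherit the parent fragment set unshifted (8 fragments,
guaranteeing the >= 6 shared-ion edge criterion is satisfiable) plus three
chain-shifted fragments.  Decoy features are spectrally unrelated and their
precursors are rejection-sampled away from every parent + library-delta mass,
so they can never be mass-shift annotated by accident.

Randomness: one integer seed governs all draws through a single
``numpy.random.default_rng`` stream consumed in a documented order (matrices
in design order; truth entries in truth-set order; then decoys; within a
spectrum: m/z jitter, intensity noise, noise peaks).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf

from .formulas import (
    DEFAULT_CONVENTIONS,
    ElementalFormula,
    combine,
    delta_mass,
    parse_formula,
    protonated_mz,
)

__all__ = [
    "Peak",
    "MsmsSpectrum",
    "NoiseModel",
    "TruthEntry",
    "StudyDesign",
    "SimulatedMatrix",
    "PARENT_SMILES",
    "PARENT_FORMULA",
    "GENERIC_DELTAS",
    "default_truth_set",
    "simulate_spectra",
    "write_mgf",
    "read_mgf",
    "write_feature_table",
    "read_feature_table",
]

PARENT_SMILES = "OC(C=C1)=CC=C1C2NC3=NC=CC=C3C2"
PARENT_FORMULA = "C13H10N2O"

ACQUISITION_RANGE = (100.0, 700.0)

#: Elemental deltas of the generic biotransformation vocabulary.
GENERIC_DELTAS: Dict[str, Dict[str, int]] = {
    "hydroxylation": {"O": 1},
    "glucuronidation": {"C": 6, "H": 8, "O": 6},
    "sulfation": {"S": 1, "O": 3},
    "methylation": {"C": 1, "H": 2},
}


@dataclass(frozen=True)
class Peak:
    mz: float
    intensity: float

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("peak m/z must be > 0")
        if self.intensity < 0:
            raise ValueError("peak intensity must be >= 0")


@dataclass
class MsmsSpectrum:
    """One MS/MS feature: precursor, RT, fragment peaks, per-sample intensity."""

    feature_id: str
    precursor_mz: float
    rt_min: float
    peaks: List[Peak]
    sample_intensities: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.peaks = sorted(self.peaks, key=lambda p: p.mz)
        lo, hi = ACQUISITION_RANGE
        if not lo <= self.precursor_mz <= hi:
            raise ValueError(
                f"precursor {self.precursor_mz} outside acquisition range {ACQUISITION_RANGE}"
            )

    @property
    def mz_array(self) -> np.ndarray:
        return np.array([p.mz for p in self.peaks])

    @property
    def intensity_array(self) -> np.ndarray:
        return np.array([p.intensity for p in self.peaks])


@dataclass(frozen=True)
class NoiseModel:
    """Stochastic imperfections applied to simulated spectra."""

    mz_jitter_sd: float = 0.005  # Da, below the 0.02 fragment tolerance
    intensity_cv: float = 0.2
    n_noise_peaks: int = 5
    n_decoy_features: int = 20

    @staticmethod
    def none(n_decoy_features: int = 20) -> "NoiseModel":
        """Zero-noise model (decoys retained; they are deterministic draws)."""
        return NoiseModel(0.0, 0.0, 0, n_decoy_features)

    @property
    def stochastic(self) -> bool:
        return (
            self.mz_jitter_sd > 0
            or self.intensity_cv > 0
            or self.n_noise_peaks > 0
            or self.n_decoy_features > 0
        )


@dataclass(frozen=True)
class TruthEntry:
    """Ground-truth metabolite: chain, RT, matrix presence, abundances.

    ``ref`` is a bookkeeping tag for tests and reporting of the truth set;
    the pipeline never sees it.  ``reported_mz`` carries the m/z as printed
    in the source study report (3 dp); the simulated precursor is always the
    chain-consistent theoretical m/z.
    """

    ref: str
    chain: Tuple[str, ...]  # generic biotransformation labels, sorted
    rt_min: float
    in_vitro: bool
    in_vivo: bool
    reported_mz: Optional[float] = None
    invitro_levels: Mapping[str, float] = field(default_factory=dict)
    invivo_levels: Mapping[str, float] = field(default_factory=dict)

    def formula(self, parent: ElementalFormula) -> ElementalFormula:
        f = parent
        for label in self.chain:
            f = combine(f, GENERIC_DELTAS[label])
        return f

    def theoretical_mz(self, parent: ElementalFormula) -> float:
        return protonated_mz(self.formula(parent), DEFAULT_CONVENTIONS)


@dataclass(frozen=True)
class StudyDesign:
    parent_formula: str
    parent_smiles: str
    parent_rt_min: float
    parent_fragments: Tuple[Peak, ...]
    matrices: Mapping[str, Tuple[str, ...]]  # matrix name -> sample labels
    truth: Tuple[TruthEntry, ...]
    parent_invitro_levels: Mapping[str, float] = field(default_factory=dict)
    parent_invivo_levels: Mapping[str, float] = field(default_factory=dict)
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0

    @property
    def parent(self) -> ElementalFormula:
        return parse_formula(self.parent_formula)

    @property
    def parent_mz(self) -> float:
        return protonated_mz(self.parent, DEFAULT_CONVENTIONS)

    def with_noise(self, noise: NoiseModel) -> "StudyDesign":
        return replace(self, noise=noise)


# Parent fragment set: MRM-confirmed ions near 118.0 and 183.1 plus plausible
# secondary fragments; 8 ions so any conjugate pair shares >= 6 within 0.02 Da.
_PARENT_FRAGMENTS = (
    Peak(91.0542, 20.0),
    Peak(118.0651, 100.0),
    Peak(130.0651, 35.0),
    Peak(144.0808, 30.0),
    Peak(156.0808, 45.0),
    Peak(167.0730, 25.0),
    Peak(183.0917, 80.0),
    Peak(194.0839, 40.0),
)

# In vitro kinetics (relative abundance per sampling time): parent declines,
# metabolites appear then decline; magnitudes are free generator parameters.
_VITRO_PARENT = {"H0": 1.0e6, "H8": 6.0e5, "H24": 3.0e5, "H48": 1.5e5}
_VITRO_MET = {"H0": 0.0, "H8": 0.9e5, "H24": 3.0e5, "H48": 1.8e5}
# In vivo kinetics: higher at H1 than H3 for all but one designated exception.
_VIVO_PARENT = {"H1": 8.0e5, "H3": 1.5e5}
_VIVO_MET = {"H1": 3.0e5, "H3": 1.0e5}
_VIVO_EXCEPTION = {"H1": 0.8e5, "H3": 2.5e5}

#: The one in vivo metabolite whose concentration rises from H1 to H3
#: (the hydroxylated glucuronide at RT 4.3 min).
KINETIC_EXCEPTION_REF = "M6b"


def _scaled(levels: Mapping[str, float], factor: float) -> Dict[str, float]:
    return {k: v * factor for k, v in levels.items()}


def default_truth_set(zero_noise: bool = False, seed: int = 0) -> StudyDesign:
    """The study-faithful design: parent + 14 metabolites across two matrices.

    Presence flags, retention times and chains mirror the integrated evidence
    table of the sibiriline study; per-entry abundance factors merely vary
    intensities between isomers.
    """
    rows = [
        # ref, chain, rt, in_vitro, in_vivo, reported_mz, factor, vivo levels
        ("M1a", ("hydroxylation",), 5.0, False, True, 227.082, 1.0, _VIVO_MET),
        ("M1b", ("hydroxylation",), 5.2, False, True, 227.082, 0.7, _VIVO_MET),
        ("M2a", ("sulfation",), 4.4, True, False, 291.044, 1.2, {}),
        ("M2b", ("sulfation",), 5.2, True, True, 291.044, 0.9, _VIVO_MET),
        ("M3a", ("hydroxylation", "sulfation"), 4.4, True, False, 307.038, 0.8, {}),
        ("M3b", ("hydroxylation", "sulfation"), 5.2, True, True, 307.038, 0.6, _VIVO_MET),
        ("M4", ("methylation", "methylation", "sulfation"), 5.1, True, False, 319.075, 0.5, {}),
        ("M5a", ("glucuronidation",), 3.7, True, True, 387.119, 1.5, _VIVO_MET),
        ("M5b", ("glucuronidation",), 4.8, True, True, 387.119, 1.1, _VIVO_MET),
        ("M6a", ("glucuronidation", "hydroxylation"), 4.1, True, True, 403.113, 1.0, _VIVO_MET),
        ("M6b", ("glucuronidation", "hydroxylation"), 4.3, True, True, 403.113, 0.9, _VIVO_EXCEPTION),
        ("M6c", ("glucuronidation", "hydroxylation"), 5.0, True, False, 403.113, 0.6, {}),
        ("M7", ("glucuronidation", "methylation", "methylation"), 4.3, True, False, 415.150, 0.4, {}),
        ("M8", ("glucuronidation", "glucuronidation", "hydroxylation", "hydroxylation"), 5.9, True, False, 595.183, 0.3, {}),
    ]
    truth = []
    for ref, chain, rt, vitro, vivo, rep_mz, factor, vivo_levels in rows:
        truth.append(
            TruthEntry(
                ref=ref,
                chain=tuple(sorted(chain)),
                rt_min=rt,
                in_vitro=vitro,
                in_vivo=vivo,
                reported_mz=rep_mz,
                invitro_levels=_scaled(_VITRO_MET, factor) if vitro else {},
                invivo_levels=_scaled(vivo_levels, factor) if vivo else {},
            )
        )
    noise = NoiseModel.none() if zero_noise else NoiseModel()
    return StudyDesign(
        parent_formula=PARENT_FORMULA,
        parent_smiles=PARENT_SMILES,
        parent_rt_min=5.8,
        parent_fragments=_PARENT_FRAGMENTS,
        matrices={"invitro": ("H0", "H8", "H24", "H48"), "invivo": ("H1", "H3")},
        truth=tuple(truth),
        parent_invitro_levels=dict(_VITRO_PARENT),
        parent_invivo_levels=dict(_VIVO_PARENT),
        noise=noise,
        seed=seed,
    )


@dataclass
class SimulatedMatrix:
    """Output of the generator for one matrix."""

    name: str
    samples: Tuple[str, ...]
    spectra: List[MsmsSpectrum]
    feature_table: pd.DataFrame
    truth_map: Dict[str, str]  # feature_id -> truth ref, "parent" or "decoy"


def _delta_library_masses(max_depth: int = 4) -> List[float]:
    """Cumulative delta masses of all generic chains up to ``max_depth``."""
    masses = []
    labels = sorted(GENERIC_DELTAS)
    for depth in range(1, max_depth + 1):
        for combo in itertools.combinations_with_replacement(labels, depth):
            masses.append(sum(delta_mass(GENERIC_DELTAS[l]) for l in combo))
    return masses


def _metabolite_peaks(
    parent_fragments: Sequence[Peak], shift: float, entry_index: int
) -> List[Peak]:
    """Conjugate fragmentation: parent ions unshifted + 3 shifted ions.

    Each metabolite carries a deterministic fragmentation signature: the
    inherited parent ions are attenuated by a per-metabolite modulation
    pattern and the conjugate-shifted ions originate from a rotating subset
    of parent fragments.  Conjugation genuinely alters fragmentation
    efficiency, and without this the generator would make every metabolite
    pair a perfect spectral match, which no instrument produces.
    """
    n = len(parent_fragments)
    peaks = []
    for i, p in enumerate(parent_fragments):
        mod = 1.0 + 0.45 * math.cos(2.0 * math.pi * (3 * entry_index + i) / n)
        peaks.append(Peak(p.mz, p.intensity * mod))
    src_idx = (entry_index % n, (entry_index + 3) % n, (entry_index + 5) % n)
    for si, inten in zip(src_idx, (30.0, 25.0, 20.0)):
        peaks.append(Peak(parent_fragments[si].mz + shift, inten))
    return peaks


def _jitter(rng: np.random.Generator, sd: float) -> float:
    # Draw even at sd == 0 to keep the stream layout independent of noise level.
    x = rng.normal(0.0, 1.0)
    return x * sd


def simulate_spectra(design: StudyDesign) -> Dict[str, SimulatedMatrix]:
    """Simulate every matrix of the design; deterministic for a fixed seed."""
    if design.noise.stochastic and design.seed is None:
        raise ValueError("a seed is required when noise is enabled")
    rng = np.random.default_rng(design.seed)
    parent = design.parent
    parent_mz = design.parent_mz
    forbidden = [parent_mz] + [parent_mz + d for d in _delta_library_masses()]

    out: Dict[str, SimulatedMatrix] = {}
    for matrix, samples in design.matrices.items():
        spectra: List[MsmsSpectrum] = []
        truth_map: Dict[str, str] = {}
        counter = 0

        def new_id() -> str:
            nonlocal counter
            counter += 1
            return f"{matrix}_F{counter:03d}"

        def noisy_levels(levels: Mapping[str, float]) -> Dict[str, float]:
            vals = {}
            for s in samples:
                base = float(levels.get(s, 0.0))
                mult = float(np.exp(_jitter(rng, design.noise.intensity_cv)))
                vals[s] = base * mult if base > 0 else 0.0
            return vals

        def add_noise_peaks(peaks: List[Peak], precursor: float) -> List[Peak]:
            for _ in range(design.noise.n_noise_peaks):
                mz = float(rng.uniform(60.0, precursor))
                inten = float(rng.uniform(1.0, 10.0))
                peaks.append(Peak(mz, inten))
            return peaks

        # 1. parent feature
        fid = new_id()
        truth_map[fid] = "parent"
        p_levels = (
            design.parent_invitro_levels if matrix == "invitro" else design.parent_invivo_levels
        )
        peaks = [
            Peak(p.mz + _jitter(rng, design.noise.mz_jitter_sd), p.intensity)
            for p in design.parent_fragments
        ]
        spectra.append(
            MsmsSpectrum(
                feature_id=fid,
                precursor_mz=parent_mz + _jitter(rng, design.noise.mz_jitter_sd),
                rt_min=design.parent_rt_min,
                peaks=add_noise_peaks(peaks, parent_mz),
                sample_intensities=noisy_levels(p_levels),
            )
        )

        # 2. truth metabolites present in this matrix
        for entry_index, entry in enumerate(design.truth):
            present = entry.in_vitro if matrix == "invitro" else entry.in_vivo
            if not present:
                continue
            fid = new_id()
            truth_map[fid] = entry.ref
            true_mz = entry.theoretical_mz(parent)
            shift = true_mz - parent_mz
            peaks = [
                Peak(p.mz + _jitter(rng, design.noise.mz_jitter_sd), p.intensity)
                for p in _metabolite_peaks(design.parent_fragments, shift, entry_index)
            ]
            levels = entry.invitro_levels if matrix == "invitro" else entry.invivo_levels
            spectra.append(
                MsmsSpectrum(
                    feature_id=fid,
                    precursor_mz=true_mz + _jitter(rng, design.noise.mz_jitter_sd),
                    rt_min=entry.rt_min,
                    peaks=add_noise_peaks(peaks, true_mz),
                    sample_intensities=noisy_levels(levels),
                )
            )

        # 3. decoy features: spectrally unrelated; precursors kept > 0.05 Da
        #    away from parent + any chain delta so mass-shift annotation can
        #    never claim them.
        for _ in range(design.noise.n_decoy_features):
            while True:
                mz = float(rng.uniform(120.0, 680.0))
                if all(abs(mz - f) > 0.05 for f in forbidden):
                    break
            fid = new_id()
            truth_map[fid] = "decoy"
            n_frag = int(rng.integers(6, 11))
            frag_mz = np.sort(rng.uniform(60.0, mz, size=n_frag))
            frag_int = rng.uniform(5.0, 100.0, size=n_frag)
            peaks = [Peak(float(m), float(i)) for m, i in zip(frag_mz, frag_int)]
            levels = {s: float(rng.uniform(1e4, 1e5)) for s in samples}
            spectra.append(
                MsmsSpectrum(
                    feature_id=fid,
                    precursor_mz=mz,
                    rt_min=float(rng.uniform(0.5, 14.5)),
                    peaks=peaks,
                    sample_intensities=levels,
                )
            )

        table = pd.DataFrame(
            [
                {
                    "feature_id": s.feature_id,
                    "mz": s.precursor_mz,
                    "rt_min": s.rt_min,
                    **{smp: s.sample_intensities.get(smp, 0.0) for smp in samples},
                }
                for s in spectra
            ]
        )
        out[matrix] = SimulatedMatrix(
            name=matrix,
            samples=tuple(samples),
            spectra=spectra,
            feature_table=table,
            truth_map=truth_map,
        )
    return out


# ---------------------------------------------------------------------------
# MGF + feature-table I/O


def write_mgf(spectra: Sequence[MsmsSpectrum], path: str) -> None:
    """Write spectra as MGF (TITLE/PEPMASS/RTINSECONDS + peak list)."""
    records = []
    for s in spectra:
        records.append(
            {
                "m/z array": s.mz_array,
                "intensity array": s.intensity_array,
                "params": {
                    "title": s.feature_id,
                    "pepmass": s.precursor_mz,
                    "rtinseconds": round(s.rt_min * 60.0, 4),
                },
            }
        )
    with open(path, "w") as fh:
        _mgf.write(records, fh)


def read_mgf(path: str) -> List[MsmsSpectrum]:
    """Read an MGF file; blocks without PEPMASS are rejected."""
    spectra = []
    with _mgf.read(path, convert_arrays=1, use_index=False) as reader:
        for rec in reader:
            params = rec.get("params", {})
            pepmass = params.get("pepmass")
            if pepmass is None or pepmass[0] is None:
                raise ValueError(f"MGF block without PEPMASS in {path}")
            rt_s = params.get("rtinseconds")
            rt_min = float(rt_s) / 60.0 if rt_s is not None else 0.0
            title = str(params.get("title", ""))
            peaks = [
                Peak(float(m), float(i))
                for m, i in zip(rec["m/z array"], rec["intensity array"])
            ]
            spectra.append(
                MsmsSpectrum(
                    feature_id=title,
                    precursor_mz=float(pepmass[0]),
                    rt_min=rt_min,
                    peaks=peaks,
                )
            )
    return spectra


def write_feature_table(table: pd.DataFrame, path: str) -> None:
    table.to_csv(path, index=False)


def read_feature_table(
    path: str, expected_samples: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """Read an MZmine-style feature table; validates sample columns if given."""
    table = pd.read_csv(path)
    required = {"feature_id", "mz", "rt_min"}
    if not required.issubset(table.columns):
        raise ValueError(f"feature table missing columns {required - set(table.columns)}")
    if expected_samples is not None:
        present = [c for c in table.columns if c not in required]
        if sorted(present) != sorted(expected_samples):
            raise ValueError(
                f"sample columns {present} do not match expected {list(expected_samples)}"
            )
    return table


def attach_intensities(
    spectra: Sequence[MsmsSpectrum], table: pd.DataFrame
) -> List[MsmsSpectrum]:
    """Join feature-table intensities onto spectra by feature id."""
    sample_cols = [c for c in table.columns if c not in ("feature_id", "mz", "rt_min")]
    by_id = table.set_index("feature_id")
    out = []
    for s in spectra:
        if s.feature_id in by_id.index:
            row = by_id.loc[s.feature_id]
            s.sample_intensities = {c: float(row[c]) for c in sample_cols}
        out.append(s)
    return out
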