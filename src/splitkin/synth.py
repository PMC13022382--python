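"""Synthetic data generation for every assay the pipeline fits.

Each generator produces the noiseless model curve of the corresponding
fitting module plus additive i.i.d. Gaussian noise on the observable (mP for
polarization, response units for sensorgrams, intensity for profiles), the
standard plate-reader noise assumption. All generators are pure functions of
their parameters and seed: a single root seed fans out deterministically to
per-series child seeds through numpy's SeedSequence spawning.

Defaults follow the characterization study design this package models:
labeling reactions with 0.5 nM dye substrate and 2.5 nM protein recorded for
10 h, a twofold peptide dilution series from 1000 nM down to ~0.98 nM
(11 concentrations, two technical replicates), fivefold serial dilutions for
saturation binding, a 300-2 nM analyte series for sensorgrams with 60 s
baseline and 300 s association/dissociation phases, thermal ramps from 20 to
95 degC in 1 degC steps, and a 30 s instrument dead time. Noise defaults to
2% of the observable's dynamic range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import AssayTable
from .kinetics import DEFAULT_DEAD_TIME, TimeCourse, second_order_fp

__all__ = [
    "NoiseSpec",
    "GroundTruth",
    "gen_labeling_timecourse",
    "gen_ec50_dataset",
    "gen_saturation_binding",
    "gen_bli_sensorgrams",
    "gen_gaussian_profile",
    "gen_melt_curve",
    "gen_nnk_reads",
    "twofold_series",
    "fivefold_series",
    "NNK_CODONS",
    "AA_ALPHABET",
]

#: Standard genetic code restricted to NNK codons (third base G or T).
_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W", "CGT": "R", "CGC": "R",
    "CGA": "R", "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}
NNK_CODONS: dict[str, list[str]] = {}
for _codon, _aa in _CODON_TABLE.items():
    if _codon[2] in "GT":
        NNK_CODONS.setdefault(_aa, []).append(_codon)

#: 20 amino acids plus the amber stop, the symbols an NNK codon can encode.
AA_ALPHABET = tuple(sorted(NNK_CODONS))


@dataclass
class NoiseSpec:
    """Measurement-noise description: Gaussian sd, replicates and seed."""

    sd: float = 0.0
    seed: int = 0
    replicate_count: int = 1

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("noise sd must be non-negative")
        if self.replicate_count < 1:
            raise ValueError("replicate_count must be >= 1")


@dataclass
class GroundTruth:
    """Generative parameters that the fitting modules are asked to recover."""

    k_app_max: float = 1e5  # M^-1 s^-1
    ec50: float = 1.654e-9  # M
    fp_free: float = 50.0  # mP
    fp_bound: float = 350.0  # mP
    a0: float = 0.5e-9  # M, dye substrate
    b0: float = 2.5e-9  # M, protein
    kon: float = 4.977e4  # M^-1 s^-1
    koff: float = 2.14e-4  # s^-1
    kd: float | None = None  # M; koff/kon when unset
    fwhm: float = 84.0  # nm
    mT: float = 46.3  # degC

    def __post_init__(self) -> None:
        if self.kd is None and self.kon > 0 and self.koff > 0:
            self.kd = self.koff / self.kon
        if self.kd is not None and self.kon > 0 and self.koff > 0:
            if abs(self.kd - self.koff / self.kon) > 1e-9 * self.kd:
                raise ValueError("kd inconsistent with koff/kon")


def _child_seeds(seed: int, n: int) -> list[int]:
    """Deterministic per-series seeds fanned out from one root seed."""
    return [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(seed).spawn(n)]


def _noisy_mean(signal: np.ndarray, noise: NoiseSpec, rng: np.random.Generator) -> np.ndarray:
    """Average of replicate_count noisy realizations of a noiseless signal."""
    reps = signal[None, :] + rng.normal(0.0, noise.sd, size=(noise.replicate_count, signal.size))
    return reps.mean(axis=0)


def twofold_series(top: float = 1000e-9, n: int = 11) -> np.ndarray:
    """Twofold dilution series starting at ``top`` (default 1000 nM, 11 points
    ending at ~0.98 nM)."""
    return top / 2.0 ** np.arange(n)


def fivefold_series(top: float = 10e-6, n: int = 10) -> np.ndarray:
    """Fivefold serial dilution starting at ``top``."""
    return top / 5.0 ** np.arange(n)


def default_times(duration: float = 36000.0, step: float = 300.0) -> np.ndarray:
    """Recording grid of a 10 h kinetic read at 5 min intervals."""
    return np.arange(0.0, duration + step / 2, step)


def gen_labeling_timecourse(
    truth: GroundTruth,
    times: np.ndarray | None = None,
    noise: NoiseSpec = NoiseSpec(),
    k_app: float | None = None,
    dead_time: float = DEFAULT_DEAD_TIME,
    condition: float = 0.0,
) -> TimeCourse:
    """Simulate one labeling reaction's replicate-averaged FP trace.

    The noiseless signal is the second-order model evaluated at
    ``times + dead_time``: recorded time zero lies ``dead_time`` seconds
    after mixing, mirroring the delay between substrate addition and the
    first plate read. ``k_app`` defaults to ``truth.k_app_max``.
    """
    t = default_times() if times is None else np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    k = truth.k_app_max if k_app is None else k_app
    clean = second_order_fp(t + dead_time, k, truth.fp_free, truth.fp_bound, truth.a0, truth.b0)
    rng = np.random.default_rng(noise.seed)
    fp = _noisy_mean(clean, noise, rng)
    return TimeCourse(t=t, fp=fp, a0=truth.a0, b0=truth.b0, condition=condition)


def k_app_of_conc(truth: GroundTruth, conc: np.ndarray | float) -> np.ndarray | float:
    """Apparent rate constant at a peptide concentration (Hill slope 1)."""
    return truth.k_app_max * conc / (truth.ec50 + conc)


def gen_ec50_dataset(
    truth: GroundTruth,
    dilution: np.ndarray | None = None,
    times: np.ndarray | None = None,
    noise: NoiseSpec = NoiseSpec(),
    dead_time: float = DEFAULT_DEAD_TIME,
) -> AssayTable:
    """Simulate a full EC50 experiment: one labeling trace per concentration.

    For each peptide concentration c the apparent rate is
    k_app(c) = k_app_max * c / (EC50 + c); a second-order time course is then
    generated at that rate. Default design: twofold series 1000 -> 0.98 nM.
    """
    concs = twofold_series() if dilution is None else np.asarray(dilution, dtype=float)
    if len(concs) >= 2 and np.any(np.diff(concs) >= 0):
        raise ValueError("dilution series must be strictly decreasing")
    t = default_times() if times is None else np.asarray(times, dtype=float)
    seeds = _child_seeds(noise.seed, len(concs))
    frames = []
    for i, (c, s) in enumerate(zip(concs, seeds)):
        tc = gen_labeling_timecourse(
            truth,
            times=t,
            noise=NoiseSpec(sd=noise.sd, seed=s, replicate_count=noise.replicate_count),
            k_app=float(k_app_of_conc(truth, c)),
            dead_time=dead_time,
            condition=float(c),
        )
        frames.append(
            pd.DataFrame(
                {"series": f"c{i:02d}", "condition": c, "time": tc.t, "value": tc.fp}
            )
        )
    meta = {"a0": truth.a0, "b0": truth.b0, "dead_time": dead_time,
            "k_app_max": truth.k_app_max, "ec50": truth.ec50}
    return AssayTable(data=pd.concat(frames, ignore_index=True), kind="fp_timecourse", meta=meta)


def saturation_fp(conc: np.ndarray, kd: float, top: float, bottom: float) -> np.ndarray:
    """Single-site saturation binding isotherm for the FP observable."""
    conc = np.asarray(conc, dtype=float)
    return bottom + (top - bottom) * conc / (kd + conc)


def gen_saturation_binding(
    kd: float,
    top: float = 300.0,
    bottom: float = 60.0,
    concs: np.ndarray | None = None,
    noise: NoiseSpec = NoiseSpec(),
) -> AssayTable:
    """Simulate an FP saturation titration of a tracer against protein.

    The titrated protein is assumed in excess over the tracer so free ~=
    total concentration. Default grid: fivefold dilutions from 10 uM.
    """
    if kd <= 0:
        raise ValueError("kd must be positive")
    c = fivefold_series() if concs is None else np.asarray(concs, dtype=float)
    if np.any(c <= 0):
        raise ValueError("concentrations must be positive")
    rng = np.random.default_rng(noise.seed)
    fp = _noisy_mean(saturation_fp(c, kd, top, bottom), noise, rng)
    order = np.argsort(c)
    df = pd.DataFrame(
        {"series": "titration", "condition": c[order], "time": np.arange(len(c), dtype=float),
         "value": fp[order]}
    )
    return AssayTable(data=df, kind="saturation", meta={"kd": kd, "top": top, "bottom": bottom})


def bli_response(
    t: np.ndarray,
    conc: float,
    kon: float,
    koff: float,
    rmax: float,
    t_assoc: float,
) -> np.ndarray:
    """1:1 binding sensorgram (association then dissociation), zero baseline.

    Association: R(t) = Req * (1 - exp(-(kon*c + koff) t)) with
    Req = rmax * c / (Kd + c); dissociation decays mono-exponentially with
    koff from the association end point.
    """
    t = np.asarray(t, dtype=float)
    kd = koff / kon
    req = rmax * conc / (kd + conc)
    kobs = kon * conc + koff
    assoc = req * (1.0 - np.exp(-kobs * np.clip(t, 0.0, None)))
    r_end = req * (1.0 - np.exp(-kobs * t_assoc))
    dissoc = r_end * np.exp(-koff * (t - t_assoc))
    return np.where(t <= t_assoc, assoc, dissoc)


def gen_bli_sensorgrams(
    truth: GroundTruth,
    rmax: float = 1.0,
    concs: np.ndarray | None = None,
    t_assoc: float = 300.0,
    t_dissoc: float = 300.0,
    t_baseline: float = 60.0,
    hz: float = 1.0,
    noise: NoiseSpec = NoiseSpec(),
    drift: float = 0.0,
) -> AssayTable:
    """Simulate multi-concentration sensorgrams with phase labels.

    Default analyte series: twofold dilutions 300 -> 2.34 nM (8 traces).
    Each trace carries a baseline phase (zero response), the association
    phase and the dissociation phase; optional linear drift is added across
    the whole trace.
    """
    if truth.kon <= 0 or truth.koff <= 0:
        raise ValueError("kon and koff must be positive")
    if t_assoc <= 0:
        raise ValueError("t_assoc must be positive")
    c_series = 300e-9 / 2.0 ** np.arange(8) if concs is None else np.asarray(concs, dtype=float)
    dt = 1.0 / hz
    t = np.arange(0.0, t_baseline + t_assoc + t_dissoc, dt)
    phases = np.where(
        t < t_baseline, "baseline", np.where(t < t_baseline + t_assoc, "association", "dissociation")
    )
    seeds = _child_seeds(noise.seed, len(c_series))
    frames = []
    for i, (c, s) in enumerate(zip(c_series, seeds)):
        clean = bli_response(t - t_baseline, c, truth.kon, truth.koff, rmax, t_assoc)
        clean = clean + drift * t
        rng = np.random.default_rng(s)
        r = _noisy_mean(clean, noise, rng)
        frames.append(
            pd.DataFrame(
                {"series": f"trace{i:02d}", "condition": c, "time": t, "value": r, "phase": phases}
            )
        )
    meta = {"kon": truth.kon, "koff": truth.koff, "rmax": rmax,
            "t_baseline": t_baseline, "t_assoc": t_assoc}
    return AssayTable(data=pd.concat(frames, ignore_index=True), kind="sensorgram", meta=meta)


def gaussian_profile(x: np.ndarray, y0: float, area: float, xc: float, omega: float) -> np.ndarray:
    """Area-parameterized Gaussian: y = y0 + A/(w*sqrt(pi/2)) * exp(-2 (x-xc)^2 / w^2)."""
    x = np.asarray(x, dtype=float)
    return y0 + area / (omega * np.sqrt(np.pi / 2.0)) * np.exp(-2.0 * (x - xc) ** 2 / omega**2)


def gen_gaussian_profile(
    truth: GroundTruth,
    amplitude_area: float = 5000.0,
    offset: float = 20.0,
    pixel_nm: float = 20.0,
    window_nm: float = 600.0,
    center_nm: float = 0.0,
    noise: NoiseSpec = NoiseSpec(),
) -> AssayTable:
    """Simulate an intensity line profile across a filament cross-section.

    The width parameter is derived from the ground-truth FWHM through
    omega = FWHM / sqrt(2 ln 2).
    """
    if truth.fwhm <= 0:
        raise ValueError("fwhm must be positive")
    if pixel_nm <= 0:
        raise ValueError("pixel_nm must be positive")
    if window_nm < 3.0 * truth.fwhm:
        raise ValueError("window must span at least 3x the FWHM")
    omega = truth.fwhm / np.sqrt(2.0 * np.log(2.0))
    x = np.arange(-window_nm / 2.0, window_nm / 2.0 + pixel_nm / 2.0, pixel_nm) + center_nm
    rng = np.random.default_rng(noise.seed)
    y = _noisy_mean(gaussian_profile(x, offset, amplitude_area, center_nm, omega), noise, rng)
    df = pd.DataFrame({"series": "profile", "condition": 0.0, "time": x, "value": y})
    return AssayTable(data=df, kind="line_profile",
                      meta={"fwhm": truth.fwhm, "area": amplitude_area, "offset": offset})


def melt_ratio(
    temps: np.ndarray,
    mT: float,
    slope: float,
    lower: tuple[float, float] = (0.85, 0.0),
    upper: tuple[float, float] = (0.95, 0.0),
) -> np.ndarray:
    """350/330 nm intrinsic-fluorescence ratio: sigmoid between two linear baselines."""
    temps = np.asarray(temps, dtype=float)
    lo = lower[0] + lower[1] * temps
    hi = upper[0] + upper[1] * temps
    return lo + (hi - lo) / (1.0 + np.exp(-slope * (temps - mT)))


def gen_melt_curve(
    mT: float = 46.3,
    slope: float = 0.8,
    lower: tuple[float, float] = (0.85, 0.0),
    upper: tuple[float, float] = (0.95, 0.0),
    temps: np.ndarray | None = None,
    noise: NoiseSpec = NoiseSpec(),
) -> AssayTable:
    """Simulate a thermal-unfolding ratio curve with inflection at ``mT``.

    Default grid: 1 degC steps from 20 to 95 degC (the standard 1 degC/min
    ramp read once per minute). ``slope`` is the logistic steepness per degC.
    """
    if not 20.0 <= mT <= 95.0:
        raise ValueError("mT must lie within the 20-95 degC scan window")
    if slope <= 0:
        raise ValueError("slope must be positive")
    T = np.arange(20.0, 95.0 + 0.5) if temps is None else np.asarray(temps, dtype=float)
    rng = np.random.default_rng(noise.seed)
    y = _noisy_mean(melt_ratio(T, mT, slope, lower, upper), noise, rng)
    df = pd.DataFrame({"series": "melt", "condition": 0.0, "time": T, "value": y})
    return AssayTable(data=df, kind="melt_curve", meta={"mT": mT, "slope": slope})


def gen_nnk_reads(
    template: str,
    randomized_positions: list[int],
    profile: dict[int, dict[str, float]] | list[dict[str, float]],
    n: int,
    seed: int = 0,
) -> list[tuple[str, str, str | None]]:
    """Simulate amplicon reads from an NNK saturation-mutagenesis library.

    Reads equal the template except at the randomized codons, where an amino
    acid is drawn from the per-position weight profile and realized as a
    uniformly chosen NNK codon (third base G or T) encoding it. ``profile``
    maps codon index -> {amino acid: weight} (or is a list aligned with
    ``randomized_positions``). Deterministic under ``seed``.
    """
    template = template.upper()
    if len(template) % 3 != 0:
        raise ValueError("template length must be divisible by 3")
    n_codons = len(template) // 3
    for pos in randomized_positions:
        if not 0 <= pos < n_codons:
            raise ValueError(f"randomized codon index {pos} out of range (0-{n_codons - 1})")
    if isinstance(profile, list):
        profile = dict(zip(randomized_positions, profile))
    rng = np.random.default_rng(seed)
    draws: dict[int, np.ndarray] = {}
    for pos in randomized_positions:
        weights = profile[pos]
        aas = sorted(weights)
        p = np.array([weights[a] for a in aas], dtype=float)
        if np.any(p < 0) or p.sum() <= 0:
            raise ValueError(f"invalid weights at codon {pos}")
        p = p / p.sum()
        aa_idx = rng.choice(len(aas), size=n, p=p)
        codons = np.empty(n, dtype=object)
        for j, aa in enumerate(aas):
            mask = aa_idx == j
            opts = NNK_CODONS[aa]
            codons[mask] = rng.choice(opts, size=int(mask.sum()))
        draws[pos] = codons
    reads = []
    for i in range(n):
        seq = list(template)
        for pos in randomized_positions:
            seq[3 * pos : 3 * pos + 3] = draws[pos][i]
        s = "".join(seq)
        reads.append((f"read{i}", s, "I" * len(s)))
    return reads
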