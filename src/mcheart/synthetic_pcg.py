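"""Synthetic phonocardiogram cohorts with known ground truth.

Each cardiac cycle is tiled by four half-open segments — S1, systole, S2,
diastole — and the audio places Hann-windowed tone bursts at the S1/S2
positions (near 80 Hz and 110 Hz, the low-frequency band where fundamental
heart sounds live). Murmurs are band-limited broadband noise gated to the
systolic and/or diastolic segments, and stationary white background noise is
added at a controllable SNR. The generator emulates the statistical structure
a murmur-detection pipeline consumes (periodicity, S1/S2 envelope lobes,
between-lobe murmur energy), not valve-specific murmur morphology.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .io_formats import (
    PatientRecord,
    PcgRecording,
    Segment,
    SegmentTable,
    write_patient_metadata,
    write_segment_tsv,
    write_wav,
)

__all__ = ["SynthSpec", "SynthResult", "generate_recording", "generate_cohort"]

MURMUR_KINDS = ("none", "systolic", "diastolic", "both")

S1_FREQ_HZ = 80.0
S2_FREQ_HZ = 110.0
S2_RELATIVE_AMPLITUDE = 0.8
CYCLE_JITTER = 0.03  # relative spread of cycle lengths
AMP_JITTER = 0.10  # relative spread of burst amplitudes
PEAK_NORM = 0.9


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of one synthetic recording.

    ``heart_rate_bpm=None`` draws the rate from Uniform(60, 120), emulating
    patient-to-patient variation. ``murmur_amplitude`` is the RMS of the
    murmur noise relative to the S1 peak amplitude; ``snr_db=None`` (or
    ``inf``) disables background noise.
    """

    heart_rate_bpm: float | None = None
    n_seconds: float = 20.0
    rate: int = 4000
    murmur: str = "none"
    murmur_amplitude: float = 0.4
    murmur_band_hz: tuple[float, float] = (60.0, 250.0)
    snr_db: float | None = 25.0
    s1_duration_s: float = 0.10
    s2_duration_s: float = 0.08
    s2_offset_fraction: float = 0.35
    site: str = "OTHER"
    recording_id: str = "synthetic"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.murmur not in MURMUR_KINDS:
            raise ValueError(f"murmur must be one of {MURMUR_KINDS}")
        lo, hi = self.murmur_band_hz
        if not 0 < lo < hi:
            raise ValueError("murmur_band_hz must satisfy 0 < low < high")
        if self.heart_rate_bpm is not None and self.heart_rate_bpm <= 0:
            raise ValueError("heart_rate_bpm must be positive")
        if self.n_seconds * self.rate < 1:
            raise ValueError("recording must contain at least one sample")


@dataclass
class SynthResult:
    recording: PcgRecording
    truth: SegmentTable
    murmur_label: str  # Present / Absent


def _burst(n: int, freq: float, rate: int, amplitude: float) -> np.ndarray:
    t = np.arange(n) / rate
    return amplitude * sps.windows.hann(n, sym=True) * np.sin(2 * np.pi * freq * t)


def generate_recording(spec: SynthSpec) -> SynthResult:
    """Synthesize one recording plus its ground-truth segment table."""
    rng = np.random.default_rng(spec.seed)
    hr = spec.heart_rate_bpm
    if hr is None:
        hr = float(rng.uniform(60.0, 120.0))
    rate = spec.rate
    n_samples = int(round(spec.n_seconds * rate))

    # Cycle lengths: jittered, then renormalized so the cycles exactly tile
    # [0, n_seconds). This keeps the cycle count equal to round(duration / HR
    # period) while preserving relative cycle-to-cycle variability.
    base = 60.0 / hr
    n_cycles = max(1, int(round(spec.n_seconds / base)))
    factors = 1.0 + rng.uniform(-CYCLE_JITTER, CYCLE_JITTER, size=n_cycles)
    lengths = factors * (spec.n_seconds / factors.sum())
    starts = np.concatenate([[0.0], np.cumsum(lengths)])

    x = np.zeros(n_samples)
    rows: list[Segment] = []
    for k in range(n_cycles):
        t0, t_end = starts[k], starts[k + 1]
        length = t_end - t0
        t_s1_end = t0 + spec.s1_duration_s
        t_s2 = t0 + spec.s2_offset_fraction * length
        t_s2_end = t_s2 + spec.s2_duration_s
        if not (t0 < t_s1_end <= t_s2 < t_s2_end <= t_end):
            raise ValueError(
                "cycle too short for the requested S1/S2 durations "
                f"(cycle {length:.3f} s at {hr:.0f} bpm)"
            )
        rows += [
            Segment(t0, t_s1_end, "S1"),
            Segment(t_s1_end, t_s2, "systole"),
            Segment(t_s2, t_s2_end, "S2"),
            Segment(t_s2_end, t_end, "diastole"),
        ]
        amp = 1.0 + rng.uniform(-AMP_JITTER, AMP_JITTER)
        for t_a, t_b, freq, rel in (
            (t0, t_s1_end, S1_FREQ_HZ, 1.0),
            (t_s2, t_s2_end, S2_FREQ_HZ, S2_RELATIVE_AMPLITUDE),
        ):
            i0, i1 = int(np.floor(t_a * rate)), int(np.floor(t_b * rate))
            i1 = min(i1, n_samples)
            if i1 > i0:
                x[i0:i1] += _burst(i1 - i0, freq, rate, rel * amp)

    truth = SegmentTable(rows)

    if spec.murmur != "none" and spec.murmur_amplitude > 0:
        gate_labels = {
            "systolic": ("systole",),
            "diastolic": ("diastole",),
            "both": ("systole", "diastole"),
        }[spec.murmur]
        gate = truth.sample_mask(rate, n_samples, *gate_labels)
        noise = rng.standard_normal(n_samples)
        sos = sps.butter(
            4, spec.murmur_band_hz, btype="bandpass", fs=rate, output="sos"
        )
        noise = sps.sosfiltfilt(sos, noise)
        rms = float(np.sqrt(np.mean(noise[gate] ** 2))) if gate.any() else 0.0
        if rms > 0:
            x[gate] += noise[gate] * (spec.murmur_amplitude / rms)

    if spec.snr_db is not None and np.isfinite(spec.snr_db):
        p_signal = float(np.mean(x**2))
        p_noise = p_signal / 10.0 ** (spec.snr_db / 10.0)
        x = x + rng.standard_normal(n_samples) * np.sqrt(p_noise)

    peak = float(np.max(np.abs(x)))
    if peak > 0:
        x = x * (PEAK_NORM / peak)

    recording = PcgRecording(
        samples=x, rate=rate, site=spec.site, recording_id=spec.recording_id
    )
    label = "Absent" if spec.murmur == "none" else "Present"
    return SynthResult(recording=recording, truth=truth, murmur_label=label)


def generate_cohort(
    n_patients: int,
    murmur_prevalence: float = 0.19,
    sites_per_patient: tuple[int, int] = (1, 4),
    seed: int = 0,
    out_dir: str | Path | None = None,
    spec: SynthSpec = SynthSpec(),
) -> dict:
    """Generate a cohort of patients, optionally writing the dataset dialect.

    Each patient draws a heart rate, a murmur status at the given prevalence
    (murmur patients carry a systolic murmur at every site), and 1-4 named
    auscultation sites. When ``out_dir`` is given, the WAV/txt/tsv files plus
    a ``manifest.json`` are written there; the returned manifest maps patient
    ids to file names, murmur label, and ground-truth tables are written per
    recording. Fully deterministic for a given seed.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    lo, hi = sites_per_patient
    if not 1 <= lo <= hi <= 4:
        raise ValueError("sites_per_patient must be a subrange of (1, 4)")
    rng = np.random.default_rng(seed)

    manifest: dict[str, dict] = {}
    results: dict[str, list[SynthResult]] = {}
    patients: list[PatientRecord] = []
    for i in range(n_patients):
        pid = f"p{i:04d}"
        present = bool(rng.random() < murmur_prevalence)
        hr = float(rng.uniform(60.0, 120.0))
        n_sites = int(rng.integers(lo, hi + 1))
        sites = list(rng.permutation(["AV", "PV", "TV", "MV"])[:n_sites])
        entry = {
            "metadata": f"{pid}.txt",
            "murmur": "Present" if present else "Absent",
            "recordings": [],
            "segments": [],
        }
        patient = PatientRecord(
            patient_id=pid,
            murmur=entry["murmur"],
            demographics={"Heart rate": f"{hr:.1f}"},
        )
        per_patient: list[SynthResult] = []
        for site in sites:
            rec_seed = int(rng.integers(0, 2**31 - 1))
            rec_spec = replace(
                spec,
                heart_rate_bpm=hr,
                murmur="systolic" if present else "none",
                site=site,
                recording_id=f"{pid}_{site}",
                seed=rec_seed,
            )
            result = generate_recording(rec_spec)
            per_patient.append(result)
            patient.recordings.append(result.recording)
            entry["recordings"].append(f"{pid}_{site}.wav")
            entry["segments"].append(f"{pid}_{site}.tsv")
        manifest[pid] = entry
        results[pid] = per_patient
        patients.append(patient)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for patient, (pid, per_patient) in zip(patients, results.items()):
            write_patient_metadata(out / f"{pid}.txt", patient)
            for res, wav_name, tsv_name in zip(
                per_patient, manifest[pid]["recordings"], manifest[pid]["segments"]
            ):
                write_wav(out / wav_name, res.recording)
                write_segment_tsv(out / tsv_name, res.truth)
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
    return {"patients": patients, "results": results, "manifest": manifest}
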