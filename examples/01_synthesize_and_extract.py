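"""Synthesize a sustained phonation and recover its acoustic biomarkers.

Generates a 1 s /a/-like vowel with 2% cycle-to-cycle period jitter, 3%
amplitude shimmer and additive noise 25 dB below the harmonic power,
then runs the extraction chain and compares the recovered perturbation
measures with the values computed directly from the generator's
realized per-cycle sequences (the ground truth).
"""

import numpy as np

from voxfuse import (
    PhonationSpec,
    extract_period_sequence,
    f0_statistics,
    generate_phonation,
    harmonics_to_noise_ratio,
    jitter_features,
    shimmer_features,
)
from voxfuse.biomarkers import extract_amplitude_sequence

spec = PhonationSpec(f0=150.0, duration=1.0, jitter_rel=0.02,
                     shimmer_rel=0.03, hnr_db=25.0, seed=42)
waveform, truth = generate_phonation(spec)

periods = extract_period_sequence(waveform)
amplitudes = extract_amplitude_sequence(waveform, periods)
fo, fhi, flo = f0_statistics(periods)
jitter_pct = jitter_features(periods)[0]
shimmer_local = shimmer_features(amplitudes)[0]
hnr = harmonics_to_noise_ratio(waveform, periods)

oracle_jitter = np.mean(np.abs(np.diff(truth.periods)) / truth.periods[:-1]) * 100
oracle_shimmer = np.mean(np.abs(np.diff(truth.amplitudes)) / truth.amplitudes[:-1])

print(f"F0 (mean/max/min):    {fo:6.1f} / {fhi:6.1f} / {flo:6.1f} Hz "
      f"(nominal {spec.f0:.0f} Hz)")
print(f"jitter (local, %):    {jitter_pct:6.3f}   ground truth {oracle_jitter:6.3f}")
print(f"shimmer (local):      {shimmer_local:6.4f}   ground truth {oracle_shimmer:6.4f}")
print(f"HNR:                  {hnr:6.2f} dB  (additive noise alone: {spec.hnr_db:.0f} dB)")
print()
print("Jitter/shimmer are the mean relative cycle-to-cycle differences of the")
print("glottal period and peak-to-peak amplitude; HNR is the dB ratio of")
print("periodic to aperiodic energy. Measured HNR sits below the additive-")
print("noise level because jitter and shimmer are themselves aperiodicity —")
print("which is exactly why HNR falls in dysphonic voices. Elevated")
print("perturbation and depressed HNR are the classic signature of")
print("Parkinsonian hypokinetic dysarthria.")
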