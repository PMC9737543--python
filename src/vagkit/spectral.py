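"""One-sided magnitude spectra of VAG recordings and their resampled variants.

The spectrum of a mean-removed recording is computed with an FFT and scaled
to a one-sided amplitude spectrum: ``|X_k| * 2 / N`` for every non-DC bin.
The DC bin is excluded, so the frequency grid runs from one resolution step
(1/duration Hz) up to the Nyquist frequency. For a 20-s recording sampled at
5 kHz this gives a 0.05 Hz grid up to 2500 Hz.

Two standard band-limited variants used in the joint-vibration literature
are produced by :func:`resample_spectrum` with simple linear interpolation:

- ``norm1``: up to 1000 Hz at 0.1 Hz resolution,
- ``norm2``: up to 500 Hz at 1 Hz resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from vagkit.simulate import VagRecording

#: (f_max, resolution) of the named normalization grids.
NORMALIZATION_GRIDS = {
    "norm1": (1000.0, 0.1),
    "norm2": (500.0, 1.0),
}


@dataclass(frozen=True)
class Spectrum:
    """One-sided magnitude spectrum on a uniform frequency grid."""

    frequencies: np.ndarray
    magnitudes: np.ndarray
    resolution: float
    normalization: str = "raw"

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        m = np.asarray(self.magnitudes, dtype=float)
        if f.shape != m.shape or f.ndim != 1 or len(f) < 1:
            raise ValueError("frequencies and magnitudes must be equal-length 1-D arrays")
        steps = np.diff(f)
        if len(steps) and not np.allclose(steps, self.resolution, rtol=1e-9, atol=0):
            raise ValueError("frequency grid must be uniform at the stated resolution")
        if np.any(m < 0):
            raise ValueError("magnitudes must be non-negative")
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "magnitudes", m)

    @property
    def band(self) -> tuple[float, float]:
        """(f_min, f_max) of the grid in Hz."""
        return float(self.frequencies[0]), float(self.frequencies[-1])


def compute_spectrum(recording: VagRecording) -> Spectrum:
    """One-sided amplitude spectrum of the mean-removed recording.

    Grid spacing is 1/duration; the grid spans (resolution, Nyquist]. Non-DC
    bins are scaled by 2/N (the Nyquist bin included, for a single documented
    constant); the DC bin is dropped.
    """
    x = np.asarray(recording.samples, dtype=float)
    if x.size == 0:
        raise ValueError("recording is empty")
    n = x.size
    spec = np.abs(np.fft.rfft(x - x.mean())) * (2.0 / n)
    df = recording.sampling_rate / n
    freqs = np.arange(1, len(spec)) * df
    return Spectrum(frequencies=freqs, magnitudes=spec[1:], resolution=df,
                    normalization="raw")


def resample_spectrum(spectrum: Spectrum, f_max: float, resolution: float,
                      normalization: str | None = None) -> Spectrum:
    """Resample a spectrum onto the grid {resolution, 2*resolution, ..., f_max}.

    Magnitudes are obtained by linear interpolation between the bracketing
    source bins; querying a source grid point reproduces its value exactly.
    The result is tagged ``norm1``/``norm2`` when (f_max, resolution) matches
    a named grid, else ``custom`` (override with ``normalization``).
    """
    if resolution <= 0:
        raise ValueError("resolution must be > 0")
    if f_max > spectrum.band[1] * (1 + 1e-12):
        raise ValueError(
            f"f_max={f_max} exceeds the source band maximum {spectrum.band[1]}")
    n_bins = int(round(f_max / resolution))
    grid = np.arange(1, n_bins + 1) * resolution
    mags = np.interp(grid, spectrum.frequencies, spectrum.magnitudes)
    if normalization is None:
        normalization = "custom"
        for tag, (fm, res) in NORMALIZATION_GRIDS.items():
            if fm == f_max and res == resolution:
                normalization = tag
    return Spectrum(frequencies=grid, magnitudes=mags, resolution=resolution,
                    normalization=normalization)


def normalized_spectrum(spectrum: Spectrum, normalization: str) -> Spectrum:
    """Return the requested variant of a raw spectrum: raw, norm1 or norm2."""
    if normalization == "raw":
        return spectrum
    try:
        f_max, resolution = NORMALIZATION_GRIDS[normalization]
    except KeyError:
        raise ValueError(f"unknown normalization {normalization!r}") from None
    return resample_spectrum(spectrum, f_max, resolution, normalization)
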