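"""The seven spectral VAG features.

All features are defined on a one-sided magnitude spectrum, treated as a
curve and integrated with the trapezoidal rule:

- **TI** — total integral: area under the spectrum over its whole band.
- **IB3** — area below 300 Hz; the trapezoid straddling 300 Hz is split at
  exactly 300 Hz so that TI = IB3 + IA3 holds as an identity.
- **IA3** — area above 300 Hz, up to the band maximum.
- **IBAR** — IB3 / IA3 (+inf, flagged, when the band ends at or below 300 Hz).
- **PA** — peak spectral amplitude.
- **PF** — frequency of the peak; ties resolved to the lowest frequency.
- **MF** — median frequency: the point splitting the spectral area in half,
  located by linear interpolation of the cumulative trapezoidal integral.

Energy-type features (TI, IB3, IA3, PA) scale linearly with the spectrum's
amplitude scaling convention; IBAR, PF and MF are invariant to it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from vagkit.spectral import Spectrum

#: Canonical feature order used in all tables.
FEATURE_NAMES = ["ti", "ib3", "ia3", "ibar", "pa", "pf", "mf"]

#: Boundary between the "below" and "above" integrals, Hz.
SPLIT_FREQ = 300.0


@dataclass(frozen=True)
class FeatureVector:
    """The seven scalar features of one spectrum."""

    ti: float
    ib3: float
    ia3: float
    ibar: float
    pa: float
    pf: float
    mf: float
    normalization: str = "raw"
    flags: tuple[str, ...] = ()

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FEATURE_NAMES}


def _split_area(freqs: np.ndarray, mags: np.ndarray, split: float) -> tuple[float, float]:
    """Trapezoidal areas (below, above) of the split frequency.

    The bracketing trapezoid is divided at exactly `split`; mass at the split
    itself counts as "below".
    """
    total = float(np.trapezoid(mags, freqs))
    if freqs[-1] <= split:
        return total, 0.0
    if freqs[0] >= split:
        return 0.0, total
    below = float(np.trapezoid(mags[freqs <= split], freqs[freqs <= split]))
    i = int(np.searchsorted(freqs, split, side="right"))
    if freqs[i - 1] < split:  # boundary falls inside the (i-1, i) trapezoid
        f0, f1 = freqs[i - 1], freqs[i]
        m_split = mags[i - 1] + (mags[i] - mags[i - 1]) * (split - f0) / (f1 - f0)
        below += 0.5 * (mags[i - 1] + m_split) * (split - f0)
    return below, total - below


def extract_features(spectrum: Spectrum) -> FeatureVector:
    """Compute TI, IB3, IA3, IBAR, PA, PF and MF from a spectrum."""
    freqs = spectrum.frequencies
    mags = spectrum.magnitudes
    if len(freqs) < 2:
        raise ValueError("spectrum must have at least 2 bins")

    flags: list[str] = []
    ib3, ia3 = _split_area(freqs, mags, SPLIT_FREQ)
    ti = ib3 + ia3
    if ia3 > 0:
        ibar = ib3 / ia3
    else:
        ibar = float("inf")
        flags.append("ibar_infinite")

    peak_idx = int(np.argmax(mags))  # argmax returns the first (lowest-f) maximum
    pa = float(mags[peak_idx])
    pf = float(freqs[peak_idx])

    if ti > 0:
        cum = np.concatenate([[0.0], np.cumsum(
            0.5 * (mags[1:] + mags[:-1]) * np.diff(freqs))])
        mf = float(np.interp(ti / 2.0, cum, freqs))
    else:
        mf = float("nan")
        flags.append("mf_undefined")

    return FeatureVector(ti=ti, ib3=ib3, ia3=ia3, ibar=ibar, pa=pa, pf=pf,
                         mf=mf, normalization=spectrum.normalization,
                         flags=tuple(flags))


def feature_table(records: list[dict], vectors: list[FeatureVector]) -> pd.DataFrame:
    """Assemble one feature row per recording, with metadata columns.

    `records` supplies subject_id/group/side/session per vector; the output
    carries the canonical header used by all downstream stages.
    """
    rows = []
    for meta, vec in zip(records, vectors, strict=True):
        row = {k: meta[k] for k in ("subject_id", "group", "side", "session")}
        row["normalization"] = vec.normalization
        row.update(vec.as_dict())
        rows.append(row)
    cols = ["subject_id", "group", "side", "session", "normalization", *FEATURE_NAMES]
    return pd.DataFrame(rows, columns=cols)
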